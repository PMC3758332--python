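"""Synthetic multi-subject MTR cohorts with planted demyelination effects.

The generator emulates the statistical structure the group analysis
assumes — spatially aligned per-subject MTR maps on a common grid,
tissue probability maps with soft boundaries, a ROI label volume, and a
subject table with matched covariates — so every downstream stage
(GLM, TFCE permutation inference, effect sizes, classification,
volumetry) is testable with known ground truth.

The phantom is a sphere-in-sphere "brain": a WM core inside a GM shell,
with logistic falloff at the boundaries so that probability-threshold
masking is exercised nontrivially.  Baseline MTR plateaus are 45 % in
WM and 35 % in GM (typical literature magnitudes; only contrasts matter
for inference).  Demyelination is planted as ROI-localized MTR
reductions per group; noise is white Gaussian convolved to a target
smoothness and rescaled to a target voxel-wise standard deviation.

The canonical study design mirrors an age/sex/education-matched cohort
of controls, single-domain MCI (sMCI) and multiple-domain MCI (mMCI):
a *shared* posterior/medial-temporal MTR reduction in both patient
groups plus an mMCI-only frontal reduction, and memory scores linked
linearly to ROI-mean MTR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .mtr import fwhm_to_sigma
from .volume import Volume

__all__ = [
    "RoiDef",
    "PhantomSpec",
    "EffectSpec",
    "NoiseSpec",
    "ScoreLinkSpec",
    "CohortVolumes",
    "build_phantom",
    "simulate_cohort",
    "null_cohort_batch",
    "mtr_to_saturation_pair",
    "save_cohort",
    "GROUPS",
]

#: Canonical group labels, in design-matrix order.
GROUPS = ("control", "sMCI", "mMCI")

#: Baseline MTR plateaus in percent.
WM_BASELINE_MTR = 45.0
GM_BASELINE_MTR = 35.0

#: Gender draw P(woman), mirroring an 8/13 men/women split per group of 21.
P_WOMAN = 13.0 / 21.0

#: 3-level education category probabilities (low/middle/high).
EDUCATION_P = (5.0 / 42.0, 23.0 / 42.0, 14.0 / 42.0)


@dataclass(frozen=True)
class RoiDef:
    """A spherical ROI: id, center (voxel coordinates), radius (mm)."""

    roi_id: int
    center: tuple[float, float, float]
    radius_mm: float
    compartment: str  # "GM" or "WM"


@dataclass
class PhantomSpec:
    """Geometry of the synthetic brain phantom.

    ``wm_radius_mm`` / ``brain_radius_mm`` default to 0.60 and 0.95 of
    the smallest half-extent of the grid.  ``tissue_fwhm_mm`` controls
    the logistic softness of compartment boundaries (the logistic scale
    is ``tissue_fwhm_mm / 4``).
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    roi_defs: tuple[RoiDef, ...] = ()
    tissue_fwhm_mm: float = 4.0
    wm_radius_mm: float | None = None
    brain_radius_mm: float | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel_size_mm components must be positive")
        if self.tissue_fwhm_mm < 0:
            raise ValueError("tissue_fwhm_mm must be >= 0")
        ids = [r.roi_id for r in self.roi_defs]
        if len(set(ids)) != len(ids):
            raise ValueError("roi_ids must be unique")
        if any(r.roi_id <= 0 for r in self.roi_defs):
            raise ValueError("roi_ids must be positive")
        if any(r.radius_mm <= 0 for r in self.roi_defs):
            raise ValueError("ROI radii must be positive")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        return aff

    def center_mm(self, roi: RoiDef) -> np.ndarray:
        return np.asarray(roi.center) * np.asarray(self.voxel_size_mm)

    @property
    def half_extent_mm(self) -> float:
        ext = np.asarray(self.grid_shape) * np.asarray(self.voxel_size_mm)
        return float(ext.min()) / 2.0

    def radii(self) -> tuple[float, float]:
        r_wm = self.wm_radius_mm or 0.60 * self.half_extent_mm
        r_brain = self.brain_radius_mm or 0.95 * self.half_extent_mm
        return r_wm, r_brain

    @classmethod
    def default(cls) -> "PhantomSpec":
        """24^3 grid, 2 mm voxels; two WM ROIs and one GM ROI.

        ROI 1 is the posterior WM sphere carrying the effect shared by
        both patient groups; ROI 2 the frontal WM sphere carrying the
        mMCI-only effect; ROI 3 a GM sphere used for volumetry.
        """
        return cls(
            roi_defs=(
                RoiDef(1, (11.5, 7.5, 11.5), 5.0, "WM"),
                RoiDef(2, (11.5, 15.5, 11.5), 5.0, "WM"),
                RoiDef(3, (11.5, 11.5, 20.5), 3.0, "GM"),
            )
        )


@dataclass(frozen=True)
class EffectSpec:
    """A planted group-level effect in one ROI.

    ``mtr_delta`` is an additive MTR change in percentage points
    (negative = demyelination); ``volume_scale`` in (0, 1] scales the
    subject-level region volume (atrophy) used by volumetry.
    """

    group: str
    roi_id: int
    mtr_delta: float = 0.0
    volume_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.volume_scale <= 1:
            raise ValueError("volume_scale must lie in (0, 1]")
        if self.group == "control" and (self.mtr_delta != 0 or self.volume_scale != 1):
            raise ValueError("control effects must be null")


@dataclass(frozen=True)
class NoiseSpec:
    """Smooth-noise model: white Gaussian noise (SD ``sigma`` MTR
    percentage points) convolved to ``smoothness_fwhm_mm`` and rescaled
    so the interior voxel-wise SD equals ``sigma``."""

    sigma: float = 1.5
    smoothness_fwhm_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.smoothness_fwhm_mm < 0:
            raise ValueError("smoothness_fwhm_mm must be >= 0")


@dataclass(frozen=True)
class ScoreLinkSpec:
    """Linear link from subject ROI-mean MTR to a behavioral score:

    ``score = intercept + slope * mean_roi_mtr + covariate terms + N(0, noise_sd)``
    """

    roi_id: int
    slope: float
    intercept: float = 0.0
    noise_sd: float = 1.0
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    name: str = "score_delayed"

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class CohortVolumes:
    """Per-subject volume store plus the shared phantom maps."""

    gm: Volume
    wm: Volume
    labels: Volume
    mtr: dict[str, Volume]
    subject_labels: dict[str, Volume] = field(default_factory=dict)

    def mtr_matrix(self, subject_ids: Sequence[str]) -> np.ndarray:
        """Stack MTR maps into an (n_subjects, n_voxels) matrix."""
        return np.stack([self.mtr[s].data.ravel() for s in subject_ids])


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _radial_distance_mm(spec: PhantomSpec) -> np.ndarray:
    """Distance of each voxel center from the grid center, in mm."""
    vs = np.asarray(spec.voxel_size_mm)
    center = (np.asarray(spec.grid_shape) - 1) / 2.0 * vs
    idx = np.indices(spec.grid_shape, dtype=float)
    mm = idx * vs[:, None, None, None]
    return np.sqrt(((mm - center[:, None, None, None]) ** 2).sum(axis=0))


def _sphere_mask(spec: PhantomSpec, roi: RoiDef) -> np.ndarray:
    """Voxel-center-in-sphere mask (inclusive boundary)."""
    vs = np.asarray(spec.voxel_size_mm)
    idx = np.indices(spec.grid_shape, dtype=float)
    mm = idx * vs[:, None, None, None]
    c = spec.center_mm(roi)
    d2 = ((mm - c[:, None, None, None]) ** 2).sum(axis=0)
    return d2 <= roi.radius_mm**2


def build_phantom(spec: PhantomSpec) -> tuple[Volume, Volume, Volume]:
    """Build GM/WM probability maps and the ROI label volume.

    Returns ``(gm_map, wm_map, label_volume)``.  Raises on overlapping
    ROI spheres, spheres extending outside the grid, or ROIs that land
    in the wrong compartment.
    """
    vs = np.asarray(spec.voxel_size_mm)
    extent = np.asarray(spec.grid_shape) * vs
    for roi in spec.roi_defs:
        c = spec.center_mm(roi)
        if np.any(c - roi.radius_mm < -0.5 * vs) or np.any(
            c + roi.radius_mm > extent - 0.5 * vs
        ):
            raise ValueError(f"ROI {roi.roi_id} sphere extends outside the grid")
    for i, a in enumerate(spec.roi_defs):
        for b in spec.roi_defs[i + 1 :]:
            gap = np.linalg.norm(spec.center_mm(a) - spec.center_mm(b))
            if gap < a.radius_mm + b.radius_mm:
                raise ValueError(f"ROI spheres {a.roi_id} and {b.roi_id} overlap")

    r = _radial_distance_mm(spec)
    r_wm, r_brain = spec.radii()
    if spec.tissue_fwhm_mm > 0:
        s = spec.tissue_fwhm_mm / 4.0
        wm = _logistic((r_wm - r) / s)
        brain = _logistic((r_brain - r) / s)
    else:
        wm = (r <= r_wm).astype(float)
        brain = (r <= r_brain).astype(float)
    gm = np.clip(brain - wm, 0.0, 1.0)

    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    for roi in spec.roi_defs:
        mask = _sphere_mask(spec, roi)
        want = wm if roi.compartment == "WM" else gm
        other = gm if roi.compartment == "WM" else wm
        if np.any(other[mask] > 0.5):
            raise ValueError(
                f"ROI {roi.roi_id} overlaps the wrong compartment "
                f"(declared {roi.compartment})"
            )
        if not np.any(want[mask] > 0.5):
            raise ValueError(f"ROI {roi.roi_id} lies outside its compartment")
        labels[mask] = roi.roi_id

    aff = spec.affine
    return Volume(gm, aff), Volume(wm, aff), Volume(labels.astype(float), aff)


def _smooth_noise_factor(sigma_vox: np.ndarray) -> float:
    """L2 norm of the separable truncated Gaussian kernel: the factor by
    which convolution shrinks white-noise SD in the grid interior."""
    total = 1.0
    for s in sigma_vox:
        if s <= 0:
            continue
        radius = int(4.0 * s + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / s) ** 2)
        k /= k.sum()
        total *= float(np.sqrt((k**2).sum()))
    return total


def smooth_noise_field(
    shape: tuple[int, int, int],
    voxel_size_mm: Sequence[float],
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """One realization of stationary smooth Gaussian noise, interior SD
    equal to ``noise.sigma``."""
    white = rng.standard_normal(shape)
    if noise.smoothness_fwhm_mm == 0:
        return noise.sigma * white
    sigma_vox = fwhm_to_sigma(noise.smoothness_fwhm_mm) / np.asarray(voxel_size_mm)
    smoothed = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="constant")
    return smoothed * (noise.sigma / _smooth_noise_factor(sigma_vox))


def _draw_covariates(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """Matched covariate distributions (identical across groups)."""
    return {
        "age": np.round(rng.normal(70.0, 8.0, size=n), 1),
        "gender": (rng.random(n) < P_WOMAN).astype(int),  # 1 = woman
        "education": rng.choice([1, 2, 3], size=n, p=EDUCATION_P),
        "tiv_mm3": np.round(rng.normal(1.45e6, 1.3e5, size=n), 0),
    }


def _subject_label_volume(
    spec: PhantomSpec,
    roi: RoiDef,
    target_volume_mm3: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Voxel mask of a sphere with the given continuous target volume,
    center jittered sub-voxel so counts vary smoothly across subjects."""
    vs = np.asarray(spec.voxel_size_mm)
    radius = (3.0 * target_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    c = spec.center_mm(roi) + (rng.random(3) - 0.5) * vs
    idx = np.indices(spec.grid_shape, dtype=float)
    mm = idx * vs[:, None, None, None]
    d2 = ((mm - c[:, None, None, None]) ** 2).sum(axis=0)
    return d2 <= radius**2


def simulate_cohort(
    phantom: PhantomSpec,
    n_per_group: Mapping[str, int],
    effects: Iterable[EffectSpec] = (),
    noise: NoiseSpec = NoiseSpec(),
    links: Iterable[ScoreLinkSpec] = (),
    volume_cv: float = 0.10,
    make_subject_labels: bool = False,
) -> tuple[pd.DataFrame, CohortVolumes]:
    """Generate a full synthetic cohort.

    Each subject's MTR map is the tissue-weighted baseline field
    (45 %/35 % WM/GM plateaus) plus the ROI deltas of its group plus one
    realization of smooth noise.  Covariates are drawn from identical
    distributions in every group (matched design).  Scores follow the
    ``links``; score columns without a link get independent filler
    values.  ``make_subject_labels`` additionally generates per-subject
    region label volumes whose volumes scatter with coefficient of
    variation ``volume_cv`` around the phantom ROI volume times the
    group's ``volume_scale`` (for volumetry).

    Identical inputs (including ``noise.seed``) give bit-identical
    cohorts.
    """
    effects = tuple(effects)
    links = tuple(links)
    gm, wm, labels = build_phantom(phantom)
    known = {r.roi_id for r in phantom.roi_defs}
    roi_by_id = {r.roi_id: r for r in phantom.roi_defs}
    for e in effects:
        if e.roi_id not in known:
            raise ValueError(f"effect references unknown roi_id {e.roi_id}")
    for link in links:
        if link.roi_id not in known:
            raise ValueError(f"score link references unknown roi_id {link.roi_id}")

    rng = np.random.default_rng(noise.seed)
    baseline = GM_BASELINE_MTR * gm.data + WM_BASELINE_MTR * wm.data

    rows: list[dict] = []
    mtr_store: dict[str, Volume] = {}
    subject_labels: dict[str, Volume] = {}
    aff = phantom.affine

    for group in n_per_group:
        n = int(n_per_group[group])
        if n < 1:
            raise ValueError(f"need at least one subject in group {group!r}")
        group_delta = np.zeros(phantom.grid_shape)
        vol_scales = {r: 1.0 for r in known}
        for e in effects:
            if e.group != group:
                continue
            group_delta[labels.data == e.roi_id] += e.mtr_delta
            vol_scales[e.roi_id] = e.volume_scale
        covs = _draw_covariates(rng, n)
        for i in range(n):
            sid = f"{group}_{i:03d}"
            field3d = baseline + group_delta + smooth_noise_field(
                phantom.grid_shape, phantom.voxel_size_mm, noise, rng
            )
            mtr_store[sid] = Volume(field3d, aff)
            if make_subject_labels:
                lab = np.zeros(phantom.grid_shape, dtype=np.int32)
                for roi in phantom.roi_defs:
                    base_vol = 4.0 / 3.0 * np.pi * roi.radius_mm**3
                    target = (
                        base_vol
                        * vol_scales[roi.roi_id]
                        * np.exp(rng.normal(0.0, np.log1p(volume_cv**2) ** 0.5))
                    )
                    lab[_subject_label_volume(phantom, roi, target, rng)] = roi.roi_id
                subject_labels[sid] = Volume(lab.astype(float), aff)
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    **{k: covs[k][i] for k in ("age", "gender", "education")},
                    "tiv_mm3": covs["tiv_mm3"][i],
                }
            )

    cohort = pd.DataFrame(rows)

    # Behavioral scores: linked columns first, then independent fillers.
    linked = {link.name for link in links}
    for link in links:
        roi_mask = labels.data == link.roi_id
        vals = np.empty(len(cohort))
        for i, sid in enumerate(cohort["subject_id"]):
            mean_mtr = float(mtr_store[sid].data[roi_mask].mean())
            v = link.intercept + link.slope * mean_mtr
            for cov, beta in link.covariate_effects.items():
                v += beta * float(cohort.iloc[i][cov])
            vals[i] = v + rng.normal(0.0, link.noise_sd)
        cohort[link.name] = np.round(vals, 3)
    if "score_immediate" not in linked:
        cohort["score_immediate"] = np.round(
            rng.normal(30.0, 6.0, size=len(cohort)), 3
        )
    if "score_delayed" not in linked:
        cohort["score_delayed"] = np.round(
            rng.normal(25.0, 6.0, size=len(cohort)), 3
        )
    cohort = cohort[
        [
            "subject_id",
            "group",
            "age",
            "gender",
            "education",
            "score_immediate",
            "score_delayed",
            "tiv_mm3",
        ]
        + [c for c in cohort.columns if c.startswith("score_")
           and c not in ("score_immediate", "score_delayed")]
    ]
    volumes = CohortVolumes(gm, wm, labels, mtr_store, subject_labels)
    return cohort, volumes


def null_cohort_batch(
    phantom: PhantomSpec,
    n_per_group: Mapping[str, int],
    noise: NoiseSpec,
    n_datasets: int,
    base_seed: int,
) -> Iterator[tuple[pd.DataFrame, CohortVolumes]]:
    """Independent zero-effect cohorts with seeds ``base_seed + i``."""
    if n_datasets < 0:
        raise ValueError("n_datasets must be >= 0")
    for i in range(n_datasets):
        spec_i = NoiseSpec(noise.sigma, noise.smoothness_fwhm_mm, base_seed + i)
        yield simulate_cohort(phantom, n_per_group, (), spec_i)


def mtr_to_saturation_pair(mtr: Volume, m0_value: float = 100.0) -> tuple[Volume, Volume]:
    """Invert the MTR definition into a consistent (M0, MS) image pair,
    so the raw-image entry point of the pipeline can be exercised."""
    m0 = mtr.with_data(np.full(mtr.shape, m0_value))
    ms = mtr.with_data(m0_value * (1.0 - mtr.data / 100.0))
    return m0, ms


def save_cohort(
    cohort: pd.DataFrame,
    volumes: CohortVolumes,
    outdir: str | Path,
    effects: Iterable[EffectSpec] = (),
    seed: int | None = None,
) -> None:
    """Write NIfTI volumes, the cohort CSV, and a ground-truth sidecar."""
    from .io import write_volume

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    write_volume(volumes.gm, outdir / "gm.nii.gz")
    write_volume(volumes.wm, outdir / "wm.nii.gz")
    write_volume(volumes.labels, outdir / "labels.nii.gz")
    (outdir / "mtr").mkdir(exist_ok=True)
    for sid, vol in volumes.mtr.items():
        write_volume(vol, outdir / "mtr" / f"{sid}_mtr.nii.gz")
    if volumes.subject_labels:
        (outdir / "labels_subject").mkdir(exist_ok=True)
        for sid, vol in volumes.subject_labels.items():
            write_volume(vol, outdir / "labels_subject" / f"{sid}_labels.nii.gz")
    sidecar = {
        "seed": seed,
        "effects": [
            {
                "group": e.group,
                "roi_id": e.roi_id,
                "mtr_delta": e.mtr_delta,
                "volume_scale": e.volume_scale,
            }
            for e in effects
        ],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
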
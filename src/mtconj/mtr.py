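"""Magnetization transfer ratio computation and tissue-weighted smoothing.

MTR quantifies the percentage of signal lost to the magnetization
transfer effect between an unsaturated acquisition M0 and a saturated
one MS::

    MTR = 100 * (M0 - MS) / M0        [percent]

Because MT saturation is dominated by macromolecule-bound protons, MTR
is a proxy for myelin content and a *decrease* is read as demyelination.

For group analysis each subject's MTR map is restricted to a tissue
compartment (GM or WM) by a weighted-smoothing scheme: the map is
multiplied by the tissue probability map (optionally modulated by a
Jacobian determinant), smoothed with an isotropic Gaussian kernel, and
divided by the identically smoothed weight.  This keeps the blur inside
the compartment instead of mixing GM, WM and CSF signal at boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .volume import Volume, check_same_grid

__all__ = [
    "TissueMaps",
    "CompartmentMap",
    "compute_mtr",
    "average_echoes",
    "gaussian_smooth",
    "tissue_weighted_smoothing",
    "make_tissue_mask",
    "fwhm_to_sigma",
]

Compartment = Literal["GM", "WM"]

#: FWHM -> standard deviation conversion factor, 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Convert a Gaussian kernel FWHM (mm) to its standard deviation (mm)."""
    return fwhm_mm / FWHM_TO_SIGMA


@dataclass
class TissueMaps:
    """GM/WM probability maps and optional Jacobian modulation on one grid."""

    gm: Volume
    wm: Volume
    jacobian: Volume | None = None

    def __post_init__(self) -> None:
        vols = [self.gm, self.wm] + ([self.jacobian] if self.jacobian else [])
        names = ("gm", "wm", "jacobian")[: len(vols)]
        check_same_grid(*vols, names=names)
        for name, v in zip(("gm", "wm"), (self.gm, self.wm)):
            d = v.data[np.isfinite(v.data)]
            if d.size and (d.min() < -1e-9 or d.max() > 1 + 1e-9):
                raise ValueError(f"{name} tissue probabilities must lie in [0, 1]")
        if self.jacobian is not None:
            j = self.jacobian.data[np.isfinite(self.jacobian.data)]
            if j.size and j.min() <= 0:
                raise ValueError("jacobian must be strictly positive")

    def compartment(self, which: Compartment) -> Volume:
        if which == "GM":
            return self.gm
        if which == "WM":
            return self.wm
        raise ValueError(f"unknown compartment {which!r}")

    def jacobian_or_ones(self) -> np.ndarray:
        if self.jacobian is None:
            return np.ones(self.gm.shape)
        return self.jacobian.data


@dataclass
class CompartmentMap:
    """A subject's compartment-restricted MTR map plus its validity mask."""

    compartment: Compartment
    mtr: Volume
    mask: np.ndarray  # boolean; True where the MTR value is usable

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.mtr.shape:
            raise ValueError("mask shape must match the MTR volume")


def compute_mtr(m0: Volume, ms: Volume, min_m0: float = 1e-6) -> Volume:
    """Voxel-wise MTR in percent, ``100 * (M0 - MS) / M0``.

    Voxels where M0 < ``min_m0`` are marked invalid (NaN) and excluded
    from all downstream statistics rather than producing unstable ratios.
    """
    if min_m0 <= 0:
        raise ValueError("min_m0 must be positive")
    check_same_grid(m0, ms, names=("M0", "MS"))
    a, b = m0.data, ms.data
    finite = np.isfinite(a) & np.isfinite(b)
    if np.any(a[finite] < 0) or np.any(b[finite] < 0):
        raise ValueError("negative intensities in M0/MS input")
    valid = finite & (a >= min_m0)
    out = np.full(m0.shape, np.nan)
    out[valid] = 100.0 * (a[valid] - b[valid]) / a[valid]
    return m0.with_data(out)


def average_echoes(echo_volumes: Sequence[Volume]) -> Volume:
    """Voxel-wise arithmetic mean of repeated echo acquisitions."""
    if len(echo_volumes) == 0:
        raise ValueError("need at least one echo volume")
    check_same_grid(*echo_volumes)
    stack = np.stack([v.data for v in echo_volumes])
    return echo_volumes[0].with_data(stack.mean(axis=0))


def _sigma_voxels(volume: Volume, fwhm_mm: float) -> np.ndarray:
    return fwhm_to_sigma(fwhm_mm) / volume.voxel_size_mm


def _smooth_raw(data: np.ndarray, sigma_vox: np.ndarray) -> np.ndarray:
    """Separable Gaussian convolution, zero-padded outside the grid."""
    return ndimage.gaussian_filter(data, sigma=sigma_vox, mode="constant", cval=0.0)


def gaussian_smooth(v: Volume, fwhm_mm: float) -> Volume:
    """Isotropic (in mm) Gaussian smoothing of a volume.

    The kernel standard deviation is ``fwhm / (2*sqrt(2 ln 2))``
    converted per axis to voxel units, so anisotropic voxel sizes are
    handled correctly.  Boundaries (and NaN-invalid voxels) are handled
    by normalized convolution: the zero-padded smoothed data is divided
    by the identically smoothed validity indicator, which avoids edge
    darkening.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return v.with_data(v.data.copy())
    sigma = _sigma_voxels(v, fwhm_mm)
    valid = v.valid_mask()
    num = _smooth_raw(np.where(valid, v.data, 0.0), sigma)
    den = _smooth_raw(valid.astype(float), sigma)
    out = np.full(v.shape, np.nan)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    out[~valid] = np.nan
    return v.with_data(out)


def tissue_weighted_smoothing(
    mtr: Volume,
    tissue: TissueMaps,
    compartment: Compartment,
    fwhm_mm: float = 4.0,
    floor: float = 0.05,
) -> CompartmentMap:
    """Compartment-restricted smoothing: ``smooth(mtr*t*j) / smooth(t*j)``.

    ``t`` is the tissue probability map of the requested compartment and
    ``j`` the Jacobian modulation (1 if absent).  Voxels where the
    smoothed weight falls below ``floor`` are marked invalid rather than
    clamped: a clamped denominator would silently bias group statistics
    at compartment boundaries.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    t = tissue.compartment(compartment)
    check_same_grid(mtr, t, names=("mtr", "tissue"))
    valid_in = mtr.valid_mask()
    w = np.where(valid_in, t.data * tissue.jacobian_or_ones(), 0.0)
    if fwhm_mm == 0:
        num, den = np.where(valid_in, mtr.data, 0.0) * w, w
    else:
        sigma = _sigma_voxels(mtr, fwhm_mm)
        num = _smooth_raw(np.where(valid_in, mtr.data, 0.0) * w, sigma)
        den = _smooth_raw(w, sigma)
    out = np.full(mtr.shape, np.nan)
    ok = den >= floor
    out[ok] = num[ok] / den[ok]
    return CompartmentMap(compartment, mtr.with_data(out), ok)


def make_tissue_mask(tissue_map: Volume, threshold: float = 0.2) -> np.ndarray:
    """Boolean mask of voxels whose tissue probability is >= ``threshold``.

    The default 0.2 keeps voxels most likely to represent the tissue of
    interest; the comparison is inclusive so the boundary case is
    deterministic.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    with np.errstate(invalid="ignore"):
        return np.asarray(tissue_map.data >= threshold) & np.isfinite(tissue_map.data)
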
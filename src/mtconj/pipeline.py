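"""End-to-end pipeline orchestration with reproducible per-stage seeds.

``run_pipeline`` executes an ordered subset of the analysis stages

    simulate -> mtr -> preprocess -> glm -> tfce -> conjoin
             -> effectsize -> regress -> classify -> volume

on a synthetic cohort, writing JSON/TSV/NIfTI artifacts per stage plus a
machine-readable provenance file (resolved configuration, package
versions, per-stage seeds) sufficient to re-run bit-identically.

One global seed expands to per-stage seeds by a fixed counter scheme:
``stage_seed = (global_seed * 1000 + stage_index) mod 2^31`` with the
stage index given by the canonical order above, so any stage can be
re-run independently yet reproducibly.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierSpec, loocv_classify
from .effect import cluster_effect_sizes
from .glm import build_design, fit_glm, voxelwise_regression
from .io import write_volume
from .mtr import TissueMaps, compute_mtr, make_tissue_mask, \
    tissue_weighted_smoothing
from .synth import EffectSpec, NoiseSpec, PhantomSpec, ScoreLinkSpec, \
    mtr_to_saturation_pair, simulate_cohort
from .tfce import TFCEParams, cluster_table, conjunction, permutation_fwe
from .volumetry import region_volume, volume_contrast

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = (
    "simulate", "mtr", "preprocess", "glm", "tfce", "conjoin",
    "effectsize", "regress", "classify", "volume",
)

#: which earlier stage each stage needs
_REQUIRES = {
    "mtr": "simulate",
    "preprocess": "mtr",
    "glm": "preprocess",
    "tfce": "glm",
    "conjoin": "tfce",
    "effectsize": "conjoin",
    "regress": "preprocess",
    "classify": "preprocess",
    "volume": "simulate",
}


@dataclass
class RunConfig:
    """Fully resolved pipeline parameters (written alongside outputs)."""

    output_dir: str = "mtconj_run"
    seed: int = 0
    fwhm_mm: float = 4.0
    tissue_threshold: float = 0.2
    alpha: float = 0.05
    n_permutations: int = 10000
    n_bootstrap: int = 5000
    connectivity: int = 26
    compartment: str = "WM"
    n_features: int = 200
    # synthetic-cohort design (demo scale)
    n_per_group: dict = field(default_factory=lambda: {
        "control": 12, "sMCI": 12, "mMCI": 12})
    mtr_delta_shared: float = -4.0
    mtr_delta_mmci: float = -4.0
    volume_scale_mmci: float = 0.85
    noise_sigma: float = 1.5
    noise_fwhm_mm: float = 4.0

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + STAGES.index(stage)) % 2**31


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=str))


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the requested stages in canonical order; returns the state
    dict of in-memory results.  Raises if a stage's prerequisite was
    neither run now nor before."""
    stages = list(STAGES) if stages is None else list(stages)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    stages = [s for s in STAGES if s in stages]

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}

    def require(stage: str) -> None:
        needed = _REQUIRES.get(stage)
        if needed is not None and needed not in state:
            raise RuntimeError(
                f"stage {stage!r} requires prior stage {needed!r}"
            )

    provenance = {
        "mtconj_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "config": asdict(config),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "stages_run": stages,
    }
    _write_json(out / "provenance.json", provenance)

    for stage in stages:
        require(stage)
        state[stage] = True  # stage marker for dependency checks
        if stage == "simulate":
            phantom = PhantomSpec.default()
            effects = (
                EffectSpec("sMCI", 1, config.mtr_delta_shared),
                EffectSpec("mMCI", 1, config.mtr_delta_shared,
                           config.volume_scale_mmci),
                EffectSpec("mMCI", 2, config.mtr_delta_mmci),
            )
            links = (ScoreLinkSpec(1, 1.0, -15.0, 1.0, name="score_delayed"),)
            cohort, volumes = simulate_cohort(
                phantom, config.n_per_group, effects,
                NoiseSpec(config.noise_sigma, config.noise_fwhm_mm,
                          config.stage_seed("simulate")),
                links, make_subject_labels=True,
            )
            state.update(phantom=phantom, cohort=cohort, volumes=volumes,
                         effects=effects)
            cohort.to_csv(out / "cohort.csv", index=False)
            write_volume(volumes.labels, out / "labels.nii.gz")
        elif stage == "mtr":
            # exercise the raw-image entry point: invert each MTR map to
            # an (M0, MS) pair and recompute
            volumes = state["volumes"]
            recomputed = {}
            for sid, vol in volumes.mtr.items():
                m0, ms = mtr_to_saturation_pair(vol)
                recomputed[sid] = compute_mtr(m0, ms)
            state["mtr_maps"] = recomputed
        elif stage == "preprocess":
            volumes = state["volumes"]
            tissue = TissueMaps(volumes.gm, volumes.wm)
            tmap = tissue.compartment(config.compartment)
            tissue_mask = make_tissue_mask(tmap, config.tissue_threshold)
            comp_maps = [
                tissue_weighted_smoothing(
                    state["mtr_maps"][sid], tissue, config.compartment,
                    config.fwhm_mm,
                )
                for sid in state["cohort"]["subject_id"]
            ]
            state.update(comp_maps=comp_maps, tissue_mask=tissue_mask,
                         tissue=tissue)
        elif stage == "glm":
            design = build_design(state["cohort"], ["age", "gender", "education"],
                                  groups=list(config.n_per_group))
            res = fit_glm(state["comp_maps"], design, "control>sMCI")
            state.update(design=design, glm_result=res)
            write_volume(res.t_map, out / "t_control_gt_sMCI.nii.gz")
            _write_json(out / "glm_report.json", {
                "df": res.df, "contrast": res.contrast.tolist(),
                "mask_voxels": int(res.mask.sum()),
            })
        elif stage == "tfce":
            params = TFCEParams(connectivity=config.connectivity)
            common = dict(
                mask=state["tissue_mask"], params=params,
                n_permutations=config.n_permutations, alpha=config.alpha,
            )
            inf_a = permutation_fwe(
                state["comp_maps"], state["design"], "control>sMCI",
                seed=config.stage_seed("tfce"), **common)
            inf_b = permutation_fwe(
                state["comp_maps"], state["design"], "control>mMCI",
                seed=config.stage_seed("tfce") + 1, **common)
            state.update(inf_a=inf_a, inf_b=inf_b, tfce_params=params)
            for name, inf in (("control_gt_sMCI", inf_a), ("control_gt_mMCI", inf_b)):
                write_volume(inf.tfce_map, out / f"tfce_{name}.nii.gz")
                _write_json(out / f"inference_{name}.json", {
                    "fwe_threshold": inf.fwe_threshold,
                    "alpha": inf.alpha,
                    "n_permutations": inf.n_permutations,
                    "seed": inf.seed,
                    "n_significant_voxels": int(inf.sig_mask.sum()),
                    "max_null": inf.max_null.tolist(),
                })
        elif stage == "conjoin":
            conj = conjunction(state["inf_a"], state["inf_b"])
            state["conjunction_mask"] = conj
            tbl = cluster_table(conj, state["inf_a"].tfce_map,
                                state["volumes"].labels, config.connectivity)
            tbl.to_csv(out / "conjunction_clusters.tsv", sep="\t", index=False)
            state["conjunction_table"] = tbl
        elif stage == "effectsize":
            reports = cluster_effect_sizes(
                state["comp_maps"], state["cohort"], state["conjunction_mask"],
                ("control", "sMCI"), config.connectivity,
                n_bootstrap=config.n_bootstrap,
                seed=config.stage_seed("effectsize"),
            )
            state["effect_sizes"] = reports
            _write_json(out / "effect_sizes.json", {
                f"cluster_{r.cluster_id}": {
                    "D": r.D, "ci": [r.ci_low, r.ci_high],
                    "n_voxels": r.n_voxels, "lambda": r.shrinkage_lambda,
                } for r in reports
            })
        elif stage == "regress":
            reg = voxelwise_regression(
                state["comp_maps"], state["cohort"], "score_delayed",
                ["age", "gender", "education"], ["score_immediate"],
            )
            state["regression"] = reg
            write_volume(reg.slope_map, out / "regression_slope.nii.gz")
        elif stage == "classify":
            report = loocv_classify(
                state["comp_maps"], state["cohort"], ("control", "mMCI"),
                ClassifierSpec(n_features=config.n_features),
                mask=state["tissue_mask"],
                seed=config.stage_seed("classify"),
            )
            state["classification"] = report
            _write_json(out / "classification.json", {
                "groups": list(report.groups),
                "balanced_accuracy": report.balanced_accuracy,
                "ci": [report.ci_low, report.ci_high],
                "p_value": report.p_value_vs_chance,
                "confusion": report.confusion.tolist(),
            })
        elif stage == "volume":
            volumes = state["volumes"]
            region = 1
            reports = [
                region_volume(volumes.subject_labels[sid], region, sid)
                for sid in state["cohort"]["subject_id"]
            ]
            contrast = volume_contrast(
                reports, state["cohort"], ("control", "mMCI"),
                n_permutations=config.n_permutations,
                seed=config.stage_seed("volume"),
            )
            state["volume_contrast"] = contrast
            pd.DataFrame([asdict(r) for r in reports]).to_csv(
                out / "region_volumes.tsv", sep="\t", index=False)
            _write_json(out / "volume_contrast.json", asdict(contrast))
    return state
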
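"""Mask-based regional volumetry with TIV-adjusted permutation contrasts.

A subject's regional volume is simply the count of voxels carrying the
region label in the subject's label volume, times the voxel volume.
Group differences are tested in a GLM of volume on group with total
intracranial volume (TIV) as a covariate; the null distribution of the
group t-contrast is estimated by permuting group labels (TIV stays with
its subject), and the percent difference is referenced to the
first-named group's mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .glm import DesignMatrix
from .volume import Volume

__all__ = ["VolumeReport", "VolumeContrast", "region_volume", "volume_contrast"]


@dataclass
class VolumeReport:
    """One subject's regional volume."""

    subject_id: str
    region_id: int
    n_voxels: int
    volume_mm3: float


@dataclass
class VolumeContrast:
    """Permutation-tested group contrast of regional volumes."""

    groups: tuple[str, str]
    percent_difference: float  # 100 * (mean_A - mean_B) / mean_A
    t_observed: float
    p_value: float
    n_permutations: int
    seed: int | None


def region_volume(
    label_volume: Volume, region_id: int, subject_id: str = ""
) -> VolumeReport:
    """Count voxels with the region label and convert to mm^3."""
    n = int((label_volume.data.astype(int) == region_id).sum())
    if n == 0:
        warnings.warn(f"region {region_id} absent from label volume", stacklevel=2)
    return VolumeReport(subject_id, region_id, n, n * label_volume.voxel_volume_mm3)


def volume_contrast(
    reports: Sequence[VolumeReport],
    cohort: pd.DataFrame,
    groups: tuple[str, str],
    n_permutations: int = 10000,
    seed: int | None = None,
) -> VolumeContrast:
    """GLM ``volume ~ group + TIV`` with a permutation p-value.

    One-sided test of the contrast ``groups[0] > groups[1]``; the
    observed labeling counts as one permutation, so ``p >= 1/n_perm``.
    """
    if "tiv_mm3" not in cohort.columns:
        raise ValueError("cohort table lacks the tiv_mm3 column")
    vol_by_id = {r.subject_id: r.volume_mm3 for r in reports}
    sel = cohort["group"].isin(groups).to_numpy()
    sub = cohort.loc[sel].reset_index(drop=True)
    missing = [s for s in sub["subject_id"] if s not in vol_by_id]
    if missing:
        raise ValueError(f"no volume report for subjects {missing[:3]}...")
    y = np.array([vol_by_id[s] for s in sub["subject_id"]], dtype=float)
    is_a = (sub["group"] == groups[0]).to_numpy()
    n_a, n_b = int(is_a.sum()), int((~is_a).sum())
    if min(n_a, n_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    tiv = sub["tiv_mm3"].to_numpy(dtype=float)
    tiv_c = tiv - tiv.mean()

    def design_for(a_mask: np.ndarray) -> np.ndarray:
        return np.column_stack([a_mask.astype(float),
                                (~a_mask).astype(float), tiv_c])

    X = design_for(is_a)
    names = [groups[0], groups[1], "tiv_mm3"]
    DesignMatrix(X, names, {groups[0]: 0, groups[1]: 1})  # rank check
    c = np.array([1.0, -1.0, 0.0])

    rng = np.random.default_rng(seed)
    n = y.size
    # batched permutation t statistics: the 3x3 normal equations of
    # [A, B, tiv_c] have closed-form entries from the A-membership mask
    masks = np.empty((n_permutations, n), dtype=bool)
    masks[0] = is_a
    for i in range(1, n_permutations):
        perm = rng.permutation(n)
        masks[i] = False
        masks[i, perm[:n_a]] = True
    M = masks.astype(float)
    sum_tiv_a = M @ tiv_c
    sum_tiv = tiv_c.sum()
    sum_tiv2 = float(tiv_c @ tiv_c)
    XtX = np.zeros((n_permutations, 3, 3))
    XtX[:, 0, 0] = n_a
    XtX[:, 1, 1] = n_b
    XtX[:, 0, 2] = XtX[:, 2, 0] = sum_tiv_a
    XtX[:, 1, 2] = XtX[:, 2, 1] = sum_tiv - sum_tiv_a
    XtX[:, 2, 2] = sum_tiv2
    Xty = np.stack([M @ y, y.sum() - M @ y,
                    np.full(n_permutations, float(tiv_c @ y))], axis=1)
    XtX_inv = np.linalg.inv(XtX)
    beta = np.einsum("bij,bj->bi", XtX_inv, Xty)
    rss = float(y @ y) - 2 * np.einsum("bi,bi->b", beta, Xty) \
        + np.einsum("bi,bij,bj->b", beta, XtX, beta)
    df = n - 3
    sigma2 = rss / df
    if sigma2[0] <= 1e-12 * max(float(np.var(y)), 1e-300):
        raise ValueError(
            "volume is (numerically) collinear with the design; the group "
            "contrast is not identifiable"
        )
    var_c = np.einsum("i,bij,j->b", c, XtX_inv, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_all = (beta[:, 0] - beta[:, 1]) / np.sqrt(sigma2 * var_c)
    t_obs = float(t_all[0])
    p = float(np.mean(t_all >= t_obs - 1e-12))

    mean_a, mean_b = y[is_a].mean(), y[~is_a].mean()
    pct = 100.0 * (mean_a - mean_b) / mean_a
    return VolumeContrast(tuple(groups), float(pct), t_obs, float(p),
                          n_permutations, seed)
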
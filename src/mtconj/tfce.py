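"""Threshold-free cluster enhancement and permutation max-null inference.

TFCE replaces the arbitrary cluster-forming threshold of classical
cluster inference by integrating cluster support over all thresholds:
for a statistic map ``S`` and voxel ``p``

    TFCE(p) = sum_{h = dh, 2dh, ... <= max S}  e_h(p)^E * h^H * dh

where ``e_h(p)`` is the voxel count of the connected component containing
``p`` in the suprathreshold set ``{S >= h}``.  Defaults ``E = 0.5``,
``H = 2`` and 26-connectivity are the method's standard recommendation;
``dh`` defaults to ``max(S)/100``.

Family-wise error control uses the permutation distribution of the
*maximum* TFCE value over the analysis mask: group labels are randomly
re-assigned (nuisance covariates stay with their subjects), the t-map
and its TFCE are recomputed, and the observed map is thresholded at the
(1 - alpha) percentile of the max-null sample.  The observed labeling is
counted as one permutation, so p-values are bounded below by
``1/n_permutations``.

Conjunction ("logical AND" of two contrasts, effects shared by both
patient groups) is the intersection of the independently FWE-thresholded
significance masks — a conservative reading; a minimum-statistic variant
is available.  Disjunction (group-specific effects) is simply the
inference on the direct between-subgroup contrast.

Implementation note: the TFCE transform is computed exactly in a single
sweep over voxels sorted by statistic value, maintaining suprathreshold
components with a union-find merge tree (components only ever grow and
merge as the threshold is lowered, so each node's size is constant over
its lifetime and its total award has a closed form).  This is
algebraically identical to labeling components independently at every
threshold, but runs in near-linear time — necessary because permutation
inference performs tens of thousands of transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from numba import njit

from .glm import DesignMatrix, contrast_vector, fit_glm_matrix, _stack_maps
from .mtr import CompartmentMap
from .volume import Volume, check_same_grid

__all__ = [
    "TFCEParams",
    "TFCEInference",
    "tfce_transform",
    "permutation_fwe",
    "conjunction",
    "conjunction_min_stat",
    "disjunction",
    "cluster_table",
]


@dataclass(frozen=True)
class TFCEParams:
    """TFCE exponents, integration step and neighborhood connectivity."""

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None  # None: max(stat)/100 per map
    connectivity: int = 26
    n_steps: int = 100  # used when dh is None

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be non-negative")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class TFCEInference:
    """Observed TFCE map, permutation max-null and the FWE decision."""

    tfce_map: Volume
    max_null: np.ndarray
    fwe_threshold: float
    sig_mask: np.ndarray
    n_permutations: int
    seed: int | None
    alpha: float
    params: TFCEParams
    t_map: Volume | None = None
    mask: np.ndarray | None = None

    @property
    def p_value(self) -> float:
        """Permutation p-value of the observed maximum TFCE."""
        obs = float(np.nanmax(np.where(self.mask, self.tfce_map.data, np.nan))) \
            if self.mask is not None else float(np.nanmax(self.tfce_map.data))
        return float(np.mean(self.max_null >= obs))


# ---------------------------------------------------------------------------
# exact single-sweep TFCE transform
# ---------------------------------------------------------------------------

@njit(cache=True)
def _uf_find(uf: np.ndarray, i: int) -> int:
    root = i
    while uf[root] != root:
        root = uf[root]
    while uf[i] != root:
        nxt = uf[i]
        uf[i] = root
        i = nxt
    return root


@njit(cache=True)
def _tfce_sweep(
    kv: np.ndarray,      # int64, padded flat step index per voxel (0 = inactive)
    order: np.ndarray,   # active padded-flat indices, descending step
    noff: np.ndarray,    # neighbor offsets in padded flat indexing
    E: float,
    dh: float,
    Hcum: np.ndarray,    # Hcum[k] = sum_{j<=k} h_j^H, Hcum[0] = 0
    out: np.ndarray,     # float64, padded flat, pre-zeroed
) -> None:
    m = order.size
    cap = 2 * m + 1
    uf = np.empty(cap, np.int64)
    size = np.zeros(cap, np.int64)
    birth = np.zeros(cap, np.int64)
    death = np.zeros(cap, np.int64)
    tpar = np.full(cap, -1, np.int64)
    vnode = np.full(kv.size, -1, np.int64)
    nn = 0
    for t in range(m):
        v = order[t]
        k = kv[v]
        nid = nn
        nn += 1
        uf[nid] = nid
        size[nid] = 1
        birth[nid] = k
        vnode[v] = nid
        for j in range(noff.size):
            un = vnode[v + noff[j]]
            if un >= 0:
                ra = _uf_find(uf, nid)
                rb = _uf_find(uf, un)
                if ra != rb:
                    c = nn
                    nn += 1
                    uf[c] = c
                    size[c] = size[ra] + size[rb]
                    birth[c] = k
                    death[ra] = k
                    death[rb] = k
                    tpar[ra] = c
                    tpar[rb] = c
                    uf[ra] = c
                    uf[rb] = c
                    nid = c
    total = np.zeros(nn, np.float64)
    for n in range(nn - 1, -1, -1):
        contrib = (size[n] ** E) * dh * (Hcum[birth[n]] - Hcum[death[n]])
        p = tpar[n]
        if p >= 0:
            total[n] = contrib + total[p]
        else:
            total[n] = contrib
    for t in range(m):
        v = order[t]
        out[v] = total[vnode[v]]


def _neighbor_offsets(shape: tuple[int, int, int], connectivity: int) -> np.ndarray:
    """Flat-index offsets of the neighborhood on the padded grid."""
    py, pz = shape[1] + 2, shape[2] + 2
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append(dx * py * pz + dy * pz + dz)
    return np.asarray(offs, dtype=np.int64)


def _tfce_positive(
    stat: np.ndarray, mask: np.ndarray, params: TFCEParams
) -> np.ndarray:
    """TFCE of the positive part of ``stat`` within ``mask``."""
    vals = np.where(mask, stat, 0.0)
    vmax = float(vals.max(initial=0.0))
    if vmax <= 0:
        return np.zeros(stat.shape)
    dh = params.dh if params.dh is not None else vmax / params.n_steps
    n_steps = int(np.floor(vmax / dh + 1e-9))
    if n_steps < 1:
        return np.zeros(stat.shape)
    h = dh * np.arange(1, n_steps + 1)
    Hcum = np.concatenate(([0.0], np.cumsum(h**params.H)))

    kv3 = np.zeros(stat.shape, dtype=np.int64)
    active = mask & (vals >= h[0])
    kv3[active] = np.searchsorted(h, vals[active], side="right")
    padded = np.zeros(tuple(s + 2 for s in stat.shape), dtype=np.int64)
    padded[1:-1, 1:-1, 1:-1] = kv3
    kv_flat = padded.ravel()
    active_idx = np.flatnonzero(kv_flat)
    order = active_idx[np.argsort(-kv_flat[active_idx], kind="stable")]
    out_flat = np.zeros(kv_flat.size, dtype=np.float64)
    _tfce_sweep(
        kv_flat, order, _neighbor_offsets(stat.shape, params.connectivity),
        float(params.E), float(dh), Hcum, out_flat,
    )
    return out_flat.reshape(padded.shape)[1:-1, 1:-1, 1:-1].copy()


def tfce_transform(
    stat_map: Volume | np.ndarray,
    mask: np.ndarray,
    params: TFCEParams = TFCEParams(),
) -> Volume | np.ndarray:
    """Signed TFCE transform of a statistic map within a mask.

    Positive and negative parts are enhanced separately (the transform
    is applied to ``-stat`` for the negative part and negated), so the
    output preserves the sign of the underlying effect.
    """
    is_volume = isinstance(stat_map, Volume)
    stat = stat_map.data if is_volume else np.asarray(stat_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stat.shape:
        raise ValueError("mask shape must match the statistic map")
    if not mask.any():
        raise ValueError("empty mask")
    mask = mask & np.isfinite(stat)
    out = _tfce_positive(stat, mask, params) - _tfce_positive(-stat, mask, params)
    return stat_map.with_data(out) if is_volume else out


# ---------------------------------------------------------------------------
# permutation max-null FWE inference
# ---------------------------------------------------------------------------

def _contrast_groups(design: DesignMatrix, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subject indices of the positive and negative groups of a contrast."""
    pos_cols = [j for g, j in design.group_column_map.items() if c[j] > 0]
    neg_cols = [j for g, j in design.group_column_map.items() if c[j] < 0]
    if not pos_cols or not neg_cols:
        raise ValueError("contrast must oppose at least two group columns")
    if len(pos_cols) > 1 or len(neg_cols) > 1:
        raise ValueError("permutation relabeling supports pairwise group contrasts")
    pos = np.flatnonzero(design.X[:, pos_cols].sum(axis=1) > 0)
    neg = np.flatnonzero(design.X[:, neg_cols].sum(axis=1) > 0)
    return pos, neg


def _relabelings(
    n_involved: int, n_pos: int, n_permutations: int, rng: np.random.Generator
) -> tuple[list[np.ndarray], bool]:
    """Index subsets (positions of the positive group among the involved
    subjects); exact enumeration when it is smaller than the request."""
    total = comb(n_involved, n_pos)
    if total <= n_permutations:
        warnings.warn(
            f"only {total} distinct relabelings exist; enumerating exactly",
            stacklevel=3,
        )
        return [np.asarray(c, dtype=int) for c in
                combinations(range(n_involved), n_pos)], True
    subsets = [np.arange(n_pos)]  # placeholder, replaced by observed labeling
    for _ in range(n_permutations - 1):
        subsets.append(rng.permutation(n_involved)[:n_pos])
    return subsets, False


def permutation_fwe(
    maps: Sequence[CompartmentMap],
    design: DesignMatrix,
    contrast: np.ndarray | str,
    mask: np.ndarray | None = None,
    params: TFCEParams = TFCEParams(),
    n_permutations: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
    two_sided: bool = False,
) -> TFCEInference:
    """FWE-calibrated TFCE inference for a group t-contrast.

    Each permutation re-assigns group membership among the subjects of
    the two contrasted groups (covariates stay attached to subjects),
    recomputes the t-map and its TFCE, and records the maximum over the
    mask.  The threshold is the ``1 - alpha`` percentile (linear
    interpolation) of the max-null sample, with the observed labeling
    included as one permutation.  Only the positive contrast direction
    is thresholded unless ``two_sided``.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if isinstance(contrast, str):
        contrast = contrast_vector(design, contrast)
    contrast = np.asarray(contrast, dtype=float)

    Y, shared, ref = _stack_maps(maps)
    if mask is not None:
        shared = shared & np.asarray(mask, dtype=bool)
    if not shared.any():
        raise ValueError("empty analysis mask")
    flat = shared.ravel()
    Ym = Y[:, flat]

    pos, neg = _contrast_groups(design, contrast)
    involved = np.concatenate([pos, neg])
    rng = np.random.default_rng(seed)
    subsets, exact = _relabelings(involved.size, pos.size, n_permutations, rng)

    pos_cols = [j for j in design.group_column_map.values() if contrast[j] > 0]
    neg_cols = [j for j in design.group_column_map.values() if contrast[j] < 0]

    stat3 = np.zeros(ref.shape)
    max_null = np.empty(len(subsets))
    obs_tfce = None
    obs_t = None
    observed_positions = {int(np.flatnonzero(involved == i)[0]) for i in pos}

    # pure two-group designs admit a vectorized pooled-t over permutation
    # blocks; the generic path refits the GLM per permutation
    fast = (
        design.X.shape[1] == 2
        and len(design.group_column_map) == 2
        and involved.size == design.X.shape[0]
        and np.all(np.isin(contrast, (-1.0, 0.0, 1.0)))
    )
    t_block: np.ndarray | None = None
    block_start = 0
    if fast:
        Yinv = Ym[involved]
        Ysq = Yinv**2
        tot = Yinv.sum(axis=0)
        totsq = Ysq.sum(axis=0)
        n_a, n_b = pos.size, neg.size
        df_fast = n_a + n_b - 2
        se_factor = 1.0 / n_a + 1.0 / n_b

    def _fast_block(i0: int, i1: int) -> np.ndarray:
        M = np.zeros((i1 - i0, involved.size))
        for r, subset in enumerate(subsets[i0:i1]):
            M[r, subset] = 1.0
        sum_a = M @ Yinv
        sumsq_a = M @ Ysq
        mean_a = sum_a / n_a
        mean_b = (tot - sum_a) / n_b
        ss = (sumsq_a - n_a * mean_a**2) + (totsq - sumsq_a - n_b * mean_b**2)
        sp2 = ss / df_fast
        denom = np.sqrt(sp2 * se_factor)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, (mean_a - mean_b) / denom, 0.0)

    for i, subset in enumerate(subsets):
        if fast:
            if t_block is None or i >= block_start + t_block.shape[0]:
                block_start = i
                t_block = _fast_block(i, min(i + 128, len(subsets)))
            t = t_block[i - block_start]
        else:
            X = design.X.copy()
            in_pos = np.zeros(involved.size, dtype=bool)
            in_pos[subset] = True
            if not (not exact and i == 0):
                # re-assign group indicator entries among involved subjects
                for col in pos_cols + neg_cols:
                    X[involved, col] = 0.0
                X[involved[in_pos], pos_cols[0]] = 1.0
                X[involved[~in_pos], neg_cols[0]] = 1.0
            t, _, _ = fit_glm_matrix(Ym, X, contrast)
        is_observed = (not exact and i == 0) or (
            exact and set(int(s) for s in subset) == observed_positions
        )
        stat3.fill(0.0)
        stat3.ravel()[flat] = np.nan_to_num(t, nan=0.0)
        if two_sided:
            tf = np.abs(tfce_transform(stat3, shared, params))
        else:
            tf = _tfce_positive(stat3, shared, params)
        max_null[i] = tf.max(initial=0.0)
        if is_observed:
            obs_tfce = tf.copy()
            obs_t = stat3.copy()

    assert obs_tfce is not None, "observed labeling not evaluated"
    fwe_threshold = float(np.percentile(max_null, 100.0 * (1.0 - alpha)))
    sig = (obs_tfce > fwe_threshold) & shared
    return TFCEInference(
        tfce_map=ref.with_data(obs_tfce),
        max_null=max_null,
        fwe_threshold=fwe_threshold,
        sig_mask=sig,
        n_permutations=len(subsets),
        seed=seed,
        alpha=alpha,
        params=params,
        t_map=ref.with_data(obs_t),
        mask=shared,
    )


def conjunction(inf_a: TFCEInference, inf_b: TFCEInference) -> np.ndarray:
    """Logical AND of two independently FWE-thresholded contrasts."""
    check_same_grid(inf_a.tfce_map, inf_b.tfce_map, names=("A", "B"))
    return inf_a.sig_mask & inf_b.sig_mask


def conjunction_min_stat(
    maps: Sequence[CompartmentMap],
    design: DesignMatrix,
    contrast_a: np.ndarray | str,
    contrast_b: np.ndarray | str,
    mask: np.ndarray | None = None,
    params: TFCEParams = TFCEParams(),
    n_permutations: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> TFCEInference:
    """Minimum-statistic conjunction: TFCE of the voxel-wise min of the
    two contrast t-maps, calibrated against its own permutation null
    (joint relabeling over all three groups)."""
    ca = contrast_vector(design, contrast_a) if isinstance(contrast_a, str) else np.asarray(contrast_a, float)
    cb = contrast_vector(design, contrast_b) if isinstance(contrast_b, str) else np.asarray(contrast_b, float)
    Y, shared, ref = _stack_maps(maps)
    if mask is not None:
        shared = shared & np.asarray(mask, dtype=bool)
    if not shared.any():
        raise ValueError("empty analysis mask")
    flat = shared.ravel()
    Ym = Y[:, flat]

    group_cols = sorted(design.group_column_map.values())
    members = [np.flatnonzero(design.X[:, j] > 0) for j in group_cols]
    involved = np.concatenate(members)
    sizes = [m.size for m in members]
    rng = np.random.default_rng(seed)

    stat3 = np.zeros(ref.shape)
    max_null = np.empty(n_permutations)
    obs_tfce = None
    for i in range(n_permutations):
        X = design.X.copy()
        if i > 0:
            perm = rng.permutation(involved)
            start = 0
            for j, sz in zip(group_cols, sizes):
                X[involved, j] = 0.0
                X[perm[start:start + sz], j] = 1.0
                start += sz
        ta, _, _ = fit_glm_matrix(Ym, X, ca)
        tb, _, _ = fit_glm_matrix(Ym, X, cb)
        tmin = np.fmin(ta, tb)
        stat3.fill(0.0)
        stat3.ravel()[flat] = np.nan_to_num(tmin, nan=0.0)
        tf = _tfce_positive(stat3, shared, params)
        max_null[i] = tf.max(initial=0.0)
        if i == 0:
            obs_tfce = tf.copy()
    fwe_threshold = float(np.percentile(max_null, 100.0 * (1.0 - alpha)))
    sig = (obs_tfce > fwe_threshold) & shared
    return TFCEInference(
        ref.with_data(obs_tfce), max_null, fwe_threshold, sig,
        n_permutations, seed, alpha, params, mask=shared,
    )


def disjunction(inf_ab: TFCEInference) -> np.ndarray:
    """Group-specific effects: the significance mask of the direct
    between-subgroup contrast."""
    return inf_ab.sig_mask


def cluster_table(
    sig_mask: np.ndarray,
    tfce_map: Volume,
    label_volume: Volume,
    connectivity: int = 26,
) -> "pd.DataFrame":
    """Connected components of the significance mask with per-label
    overlap counts and percentages (overlap / label size * 100)."""
    import pandas as pd

    check_same_grid(tfce_map, label_volume, names=("tfce", "labels"))
    sig_mask = np.asarray(sig_mask, dtype=bool)
    structure = np.ones((3, 3, 3)) if connectivity == 26 else (
        None if connectivity == 6 else _conn18_structure()
    )
    lab, n_clusters = _label(sig_mask, structure)
    labels = label_volume.data.astype(int)
    label_ids = sorted(set(np.unique(labels)) - {0})
    label_sizes = {lid: int((labels == lid).sum()) for lid in label_ids}
    rows = []
    for cid in range(1, n_clusters + 1):
        members = lab == cid
        vals = np.where(members, tfce_map.data, -np.inf)
        peak = np.unravel_index(int(np.argmax(vals)), vals.shape)
        row = {
            "cluster_id": cid,
            "n_voxels": int(members.sum()),
            "peak_i": peak[0], "peak_j": peak[1], "peak_k": peak[2],
            "peak_tfce": float(tfce_map.data[peak]),
        }
        for lid in label_ids:
            n_overlap = int((members & (labels == lid)).sum())
            row[f"label{lid}_n"] = n_overlap
            row[f"label{lid}_pct"] = 100.0 * n_overlap / label_sizes[lid]
        rows.append(row)
    return pd.DataFrame(rows)


def _conn18_structure() -> np.ndarray:
    s = np.zeros((3, 3, 3), dtype=bool)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if abs(dx) + abs(dy) + abs(dz) <= 2:
                    s[dx + 1, dy + 1, dz + 1] = True
    return s


def _label(mask: np.ndarray, structure: np.ndarray | None):
    from scipy import ndimage

    return ndimage.label(mask, structure=structure)
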
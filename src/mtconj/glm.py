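"""Voxel-wise General Linear Model: group contrasts and score regression.

The group design is cell-means coded (one indicator column per group)
with mean-centered nuisance covariates, so a contrast vector such as
``(1, -1, 0)`` over ``[control, sMCI, mMCI]`` compares covariate-adjusted
group means.  Fitting is ordinary least squares vectorized over voxels:

    beta = (X'X)^-1 X' Y,   t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c)

with ``sigma2 = RSS / (n - p)``.  A voxel enters the analysis only if it
is valid for *every* subject (listwise deletion): per-voxel subject
dropout would silently change the degrees of freedom.

The score regression regresses MTR on a behavioral score with nuisance
covariates; the reported R^2 is the squared *partial* correlation of the
score with MTR given the covariates, i.e. the share of residual variance
the score explains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .mtr import CompartmentMap
from .volume import Volume, check_same_grid

__all__ = [
    "DesignMatrix",
    "ContrastResult",
    "RegressionResult",
    "build_design",
    "contrast_vector",
    "fit_glm",
    "fit_glm_matrix",
    "voxelwise_regression",
    "extract_roi_fit",
]


@dataclass
class DesignMatrix:
    """Design matrix with named columns and the group-column map."""

    X: np.ndarray
    column_names: list[str]
    group_column_map: dict[str, int]

    def __post_init__(self) -> None:
        n, p = self.X.shape
        if n <= p:
            raise ValueError(f"need more subjects ({n}) than columns ({p})")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError(
                "design matrix is rank deficient; collinear columns: "
                + ", ".join(_collinear_columns(self.X, self.column_names))
            )

    @property
    def df(self) -> int:
        return self.X.shape[0] - self.X.shape[1]


@dataclass
class ContrastResult:
    """A fitted t-contrast: t map, coefficient maps, df and shared mask."""

    contrast: np.ndarray
    t_map: Volume
    beta_maps: list[Volume]
    df: int
    mask: np.ndarray


@dataclass
class RegressionResult:
    """Voxel-wise score regression: slope, partial R^2 and t maps."""

    slope_map: Volume
    r2_map: Volume
    t_map: Volume
    df: int
    mask: np.ndarray


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that are (numerically) linear combinations of the others."""
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        fit, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ fit
        scale = np.linalg.norm(X[:, j]) or 1.0
        if np.linalg.norm(resid) < 1e-8 * scale:
            bad.append(names[j])
    return bad or list(names)


def encode_covariates(
    cohort: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Mean-centered covariate columns; 3-level education becomes two
    dummy columns (the weaker assumption than a linear score)."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov not in cohort.columns:
            raise ValueError(f"covariate {cov!r} not in cohort table")
        if cov == "education":
            edu = cohort["education"].to_numpy()
            for level in (2, 3):
                cols.append((edu == level).astype(float))
                names.append(f"education_{level}")
        else:
            cols.append(cohort[cov].to_numpy(dtype=float))
            names.append(cov)
    if not cols:
        return np.empty((len(cohort), 0)), []
    M = np.column_stack(cols)
    return M - M.mean(axis=0), names


def build_design(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = (),
    groups: Sequence[str] | None = None,
) -> DesignMatrix:
    """Cell-means group design with mean-centered covariates.

    ``groups`` fixes the column order (default: order of first
    appearance in the table); every listed group must be nonempty.
    """
    if groups is None:
        groups = list(dict.fromkeys(cohort["group"]))
    g = cohort["group"].to_numpy()
    ind_cols = []
    group_map: dict[str, int] = {}
    for j, grp in enumerate(groups):
        members = (g == grp).astype(float)
        if members.sum() == 0:
            raise ValueError(f"group {grp!r} has no subjects")
        ind_cols.append(members)
        group_map[grp] = j
    C, cov_names = encode_covariates(cohort, covariates)
    X = np.column_stack(ind_cols + ([C] if C.size else []))
    if C.size == 0:
        X = np.column_stack(ind_cols)
    return DesignMatrix(X, list(groups) + cov_names, group_map)


def contrast_vector(design: DesignMatrix, spec: str) -> np.ndarray:
    """Build a contrast vector from an ``"A>B"`` specification."""
    if ">" not in spec:
        raise ValueError(f"contrast spec must look like 'A>B', got {spec!r}")
    a, b = (s.strip() for s in spec.split(">", 1))
    c = np.zeros(design.X.shape[1])
    for name, sign in ((a, 1.0), (b, -1.0)):
        if name not in design.group_column_map:
            raise ValueError(f"unknown group {name!r} in contrast")
        c[design.group_column_map[name]] = sign
    return c


def _stack_maps(maps: Sequence[CompartmentMap]) -> tuple[np.ndarray, np.ndarray, Volume]:
    """(n_subjects, n_voxels) data matrix and the listwise-shared mask."""
    if len(maps) == 0:
        raise ValueError("no subject maps supplied")
    check_same_grid(*[m.mtr for m in maps])
    shared = np.logical_and.reduce([m.mask & m.mtr.valid_mask() for m in maps])
    Y = np.stack([m.mtr.data.ravel() for m in maps])
    return Y, shared, maps[0].mtr


def fit_glm_matrix(
    Y: np.ndarray, X: np.ndarray, c: np.ndarray, XtX_inv: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS t statistic of contrast ``c`` for every column of ``Y``.

    Returns ``(t, beta, df)``; degenerate voxels (zero residual
    variance) get ``t = NaN``.  The hot path of permutation inference.
    """
    n, p = X.shape
    df = n - p
    if XtX_inv is None:
        XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    var_c = float(c @ XtX_inv @ c)
    denom = np.sqrt(sigma2 * var_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, (c @ beta) / denom, np.nan)
    return t, beta, df


def fit_glm(
    maps: Sequence[CompartmentMap],
    design: DesignMatrix,
    contrast: np.ndarray | str,
) -> ContrastResult:
    """Voxel-wise t-contrast over aligned subject maps.

    ``maps`` must be ordered like the design rows.  Voxels that are
    invalid for any subject, or have zero residual variance, are
    excluded from the result mask.
    """
    if isinstance(contrast, str):
        contrast = contrast_vector(design, contrast)
    contrast = np.asarray(contrast, dtype=float)
    if contrast.shape != (design.X.shape[1],):
        raise ValueError("contrast length must equal the number of design columns")
    if len(maps) != design.X.shape[0]:
        raise ValueError("number of maps must equal number of design rows")
    Y, shared, ref = _stack_maps(maps)
    flat = shared.ravel()
    if not flat.any():
        raise ValueError("no voxel is valid for every subject")
    t, beta, df = fit_glm_matrix(Y[:, flat], design.X, contrast)
    t_full = np.full(ref.shape, np.nan)
    t_full.ravel()[flat] = t
    mask = shared & np.isfinite(t_full)
    beta_maps = []
    for j in range(design.X.shape[1]):
        b = np.full(ref.shape, np.nan)
        b.ravel()[flat] = beta[j]
        beta_maps.append(ref.with_data(b))
    return ContrastResult(contrast, ref.with_data(t_full), beta_maps, df, mask)


def voxelwise_regression(
    maps: Sequence[CompartmentMap],
    cohort: pd.DataFrame,
    score: str,
    covariates: Sequence[str] = (),
    extra_covariates: Sequence[str] = (),
) -> RegressionResult:
    """Regress voxel MTR on a behavioral score with nuisance covariates.

    Subjects with a missing score or covariate are dropped (the design
    is refit on complete rows).  ``extra_covariates`` are additional
    numeric columns (e.g. the immediate-recall score when the target is
    delayed recall).
    """
    if score not in cohort.columns:
        raise ValueError(f"score column {score!r} not in cohort table")
    all_covs = list(covariates) + list(extra_covariates)
    needed = [score] + [c for c in all_covs if c != "education"]
    complete = cohort[needed].notna().all(axis=1).to_numpy()
    if complete.sum() < 3:
        raise ValueError("fewer than 3 complete subjects for the regression")
    sub = cohort.loc[complete].reset_index(drop=True)
    kept_maps = [m for m, keep in zip(maps, complete) if keep]

    s = sub[score].to_numpy(dtype=float)
    if np.ptp(s) == 0:
        raise ValueError(f"score {score!r} is constant")
    C, cov_names = encode_covariates(sub, all_covs)
    X = np.column_stack([np.ones(len(sub)), s - s.mean()] + ([C] if C.size else []))
    names = ["intercept", score] + cov_names
    design = DesignMatrix(X, names, {})

    Y, shared, ref = _stack_maps(kept_maps)
    flat = shared.ravel()
    if not flat.any():
        raise ValueError("no voxel is valid for every subject")
    c = np.zeros(X.shape[1])
    c[1] = 1.0
    t, beta, df = fit_glm_matrix(Y[:, flat], X, c)
    slope = beta[1]
    with np.errstate(invalid="ignore"):
        r2 = t**2 / (t**2 + df)  # squared partial correlation

    def _full(vals: np.ndarray) -> np.ndarray:
        out = np.full(ref.shape, np.nan)
        out.ravel()[flat] = vals
        return out

    t_full = _full(t)
    mask = shared & np.isfinite(t_full)
    return RegressionResult(
        ref.with_data(_full(slope)), ref.with_data(_full(r2)),
        ref.with_data(t_full), df, mask,
    )


@dataclass
class RoiFit:
    """Summary of a regression over the top-TFCE voxels of a region."""

    mean_slope: float
    mean_r2: float
    voxels: list[tuple[int, int, int]]


def extract_roi_fit(
    result: RegressionResult,
    tfce_map: Volume,
    mask: np.ndarray,
    k: int = 10,
) -> RoiFit:
    """Average slope and R^2 over the ``k`` highest-TFCE voxels in a mask.

    Ties in the TFCE value are broken by lexicographic voxel index.  If
    the mask holds fewer than ``k`` usable voxels, all are used (with a
    warning).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    check_same_grid(result.slope_map, tfce_map, names=("regression", "tfce"))
    usable = np.asarray(mask, dtype=bool) & result.mask & np.isfinite(tfce_map.data)
    idx = np.flatnonzero(usable.ravel())
    if idx.size == 0:
        raise ValueError("no usable voxel in the supplied mask")
    if idx.size < k:
        warnings.warn(
            f"only {idx.size} usable voxels in mask; using all", stacklevel=2
        )
        k = idx.size
    vals = tfce_map.data.ravel()[idx]
    # stable sort on descending value; flat index breaks ties
    order = np.lexsort((idx, -vals))[:k]
    chosen = idx[order]
    slopes = result.slope_map.data.ravel()[chosen]
    r2s = result.r2_map.data.ravel()[chosen]
    coords = [tuple(int(x) for x in np.unravel_index(i, result.mask.shape))
              for i in chosen]
    return RoiFit(float(slopes.mean()), float(r2s.mean()), coords)
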
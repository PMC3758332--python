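"""Binary subject classification: feature selection + shrinkage LDA.

Subjects are classified from their masked voxel-wise MTR values with a
two-stage approach evaluated by leave-one-out cross-validation (LOOCV):

1. *Feature selection* on the training fold only: voxels are ranked by
   decreasing absolute score, either the pooled two-sample t score
   (``abs_t``) or the correlation-adjusted t score (``cat_score``),
   i.e. ``(R*)^(-1/2) t`` with ``R*`` a shrinkage-regularized
   correlation matrix — decorrelation down-weights redundant voxels that
   carry the same signal.
2. *Shrinkage linear discriminant analysis* on the selected voxels:
   ``w = S*^(-1) d`` with the diagonal-target shrinkage covariance, a
   decision threshold at the midpoint of the projected class means
   shifted by the log prior ratio (priors = training class proportions).

Feature selection is structurally leakage-free: the ranking function
only ever receives the fold-training split, never the held-out subject.

Performance is summarized as balanced accuracy (mean of sensitivity and
specificity; chance level 0.5 regardless of class imbalance) with a
Jeffreys-interval/delta-method CI and an exact p-value against chance
from the binomial mixture of the two class-conditional fold counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effect import shrink_covariance
from .mtr import CompartmentMap

__all__ = [
    "ClassifierSpec",
    "ClassificationReport",
    "Discriminant",
    "rank_features",
    "fit_shrinkage_lda",
    "loocv_classify",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Feature count and ranking statistic for the LDA classifier."""

    n_features: int = 200
    ranking: Literal["abs_t", "cat_score"] = "cat_score"

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.ranking not in ("abs_t", "cat_score"):
            raise ValueError(f"unknown ranking {self.ranking!r}")


@dataclass
class Discriminant:
    """Linear decision rule: predict class A iff
    ``w'x - w'(mu_A + mu_B)/2 + log(pi_A/pi_B) > 0`` (ties go to A)."""

    w: np.ndarray
    midpoint: np.ndarray
    log_prior_ratio: float

    def score(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        return (x - self.midpoint) @ self.w + self.log_prior_ratio

    def predict_is_a(self, x: np.ndarray) -> np.ndarray:
        return self.score(x) >= 0.0


@dataclass
class ClassificationReport:
    """LOOCV outcome for one binary contrast."""

    groups: tuple[str, str]
    balanced_accuracy: float
    ci_low: float
    ci_high: float
    p_value_vs_chance: float
    confusion: np.ndarray  # rows true (A, B), cols predicted (A, B)
    fold_predictions: pd.DataFrame = field(repr=False)
    n_features: int = 0
    ranking: str = ""
    n_ties: int = 0
    selected_features: list = field(default_factory=list, repr=False)


def _t_scores(train_a: np.ndarray, train_b: np.ndarray) -> np.ndarray:
    """Pooled two-sample t per feature; zero-variance features score 0."""
    nA, nB = train_a.shape[0], train_b.shape[0]
    d = train_a.mean(axis=0) - train_b.mean(axis=0)
    ssa = ((train_a - train_a.mean(axis=0)) ** 2).sum(axis=0)
    ssb = ((train_b - train_b.mean(axis=0)) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / (nA + nB - 2)
    se = np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(se > 0, d / se, 0.0)


def _cat_scores(train_a: np.ndarray, train_b: np.ndarray) -> np.ndarray:
    """Correlation-adjusted t scores ``(R*)^(-1/2) t``.

    The shrunk correlation ``R* = lam I + (1 - lam) R`` uses an analytic
    ``lam``; the inverse square root is applied through the n x n Gram
    matrix of the standardized pooled residuals, so cost is
    ``O(n^2 p)`` rather than ``O(p^3)``.
    """
    t = _t_scores(train_a, train_b)
    nA, nB = train_a.shape[0], train_b.shape[0]
    n = nA + nB
    df = n - 2
    R = np.vstack([train_a - train_a.mean(axis=0), train_b - train_b.mean(axis=0)])
    sd = np.sqrt((R**2).sum(axis=0) / df)
    live = sd > 0
    Z = np.zeros_like(R)
    Z[:, live] = R[:, live] / (sd[live] * np.sqrt(df))  # so corr = Z'Z

    # analytic lambda from n x n quantities: with z scaled so that
    # sum_k z_ki^2 = 1, r_ij = sum_k z_ki z_kj and
    # Var_hat(r_ij) = (n/df) * (sum_k w_kij^2 - r_ij^2 / n), w_kij = z_ki z_kj.
    # All (i != j) sums reduce to n x n Gram-matrix quantities.
    G = Z @ Z.T
    p_live = int(live.sum())
    sum_r2_all = float((G * G).sum())                      # ||Z'Z||_F^2
    sum_w2_all = float(((Z**2).sum(axis=1) ** 2).sum())    # sum_k q_k^2
    diag_w2 = float((Z**4).sum())                          # i = j part
    diag_r2 = float(p_live)                                # r_ii = 1
    num = (n / df) * ((sum_w2_all - diag_w2) - (sum_r2_all - diag_r2) / n)
    den = sum_r2_all - diag_r2
    lam = 1.0 if den <= 1e-30 else float(np.clip(num / den, 1e-6, 1.0))

    if lam >= 1.0 or p_live == 0:
        return t
    # eigen-decomposition of (1 - lam) Z Z' gives the non-null spectrum
    M = (1.0 - lam) * G
    mu, U = np.linalg.eigh(M)
    keep = mu > 1e-12
    mu, U = mu[keep], U[:, keep]
    V = Z.T @ U  # p x r, columns with squared norm mu / (1 - lam)
    norms = np.sqrt((V**2).sum(axis=0))
    V = V[:, norms > 0] / norms[norms > 0]
    mu = mu[norms > 0]
    proj = V.T @ t
    tau = t / np.sqrt(lam) + V @ (((lam + mu) ** -0.5 - lam**-0.5) * proj)
    tau[~live] = 0.0
    return tau


def rank_features(
    train_a: np.ndarray,
    train_b: np.ndarray,
    method: Literal["abs_t", "cat_score"] = "cat_score",
) -> np.ndarray:
    """Feature indices ordered by decreasing absolute score.

    Zero-variance features score 0 and therefore rank last; ties are
    broken by feature index (stable).
    """
    if train_a.shape[0] < 2 or train_b.shape[0] < 2:
        raise ValueError("need at least 2 training subjects per class")
    if method == "abs_t":
        score = _t_scores(train_a, train_b)
    elif method == "cat_score":
        score = _cat_scores(train_a, train_b)
    else:
        raise ValueError(f"unknown ranking {method!r}")
    return np.argsort(-np.abs(score), kind="stable")


def fit_shrinkage_lda(
    train_a: np.ndarray, train_b: np.ndarray
) -> Discriminant:
    """Shrinkage LDA: ``w = S*^(-1) (mu_A - mu_B)``, midpoint threshold
    adjusted by the log ratio of training class proportions."""
    A = np.atleast_2d(np.asarray(train_a, dtype=float))
    B = np.atleast_2d(np.asarray(train_b, dtype=float))
    cov = shrink_covariance(A, B)
    d = A.mean(axis=0) - B.mean(axis=0)
    w = np.linalg.solve(cov.S_star, d)
    midpoint = (A.mean(axis=0) + B.mean(axis=0)) / 2.0
    log_prior = float(np.log(A.shape[0] / B.shape[0]))
    return Discriminant(w, midpoint, log_prior)


def _balanced_accuracy_pvalue(k_a: int, n_a: int, k_b: int, n_b: int) -> float:
    """Exact P(chance BA >= observed BA) under independent fair coins."""
    ba_obs = 0.5 * (k_a / n_a + k_b / n_b)
    pa = stats.binom.pmf(np.arange(n_a + 1), n_a, 0.5)
    pb = stats.binom.pmf(np.arange(n_b + 1), n_b, 0.5)
    ba = 0.5 * (np.arange(n_a + 1)[:, None] / n_a + np.arange(n_b + 1)[None, :] / n_b)
    return float((pa[:, None] * pb[None, :])[ba >= ba_obs - 1e-12].sum())


def _jeffreys_delta_ci(
    k_a: int, n_a: int, k_b: int, n_b: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Delta-method CI for BA from Jeffreys posteriors of the two
    class-conditional accuracies."""
    means, variances = [], []
    for k, n in ((k_a, n_a), (k_b, n_b)):
        a, b = k + 0.5, n - k + 0.5
        means.append(a / (a + b))
        variances.append(a * b / ((a + b) ** 2 * (a + b + 1)))
    ba = 0.5 * sum(means)
    sd = 0.5 * np.sqrt(sum(variances))
    z = stats.norm.ppf(1 - alpha / 2)
    return float(max(0.0, ba - z * sd)), float(min(1.0, ba + z * sd))


def loocv_classify(
    maps: Sequence[CompartmentMap] | np.ndarray,
    cohort: pd.DataFrame,
    groups: tuple[str, str],
    spec: ClassifierSpec = ClassifierSpec(),
    mask: np.ndarray | None = None,
    seed: int | None = None,
) -> ClassificationReport:
    """Leave-one-out cross-validated shrinkage-LDA classification.

    For every held-out subject, features are ranked and the classifier
    fitted on the remaining subjects only.  ``maps`` is either a list of
    :class:`CompartmentMap` aligned with cohort rows, or a prepared
    ``(n_subjects, n_features)`` matrix.
    """
    g = cohort["group"].to_numpy()
    sel = np.isin(g, groups)
    if isinstance(maps, np.ndarray):
        Y = np.asarray(maps, dtype=float)
    else:
        from .glm import _stack_maps

        Yfull, shared, _ = _stack_maps(list(maps))
        if mask is not None:
            shared = shared & np.asarray(mask, dtype=bool)
        Y = Yfull[:, shared.ravel()]
    Y = Y[sel]
    labels_a = g[sel] == groups[0]
    n_a, n_b = int(labels_a.sum()), int((~labels_a).sum())
    if min(n_a, n_b) < 3:
        raise ValueError("need at least 3 subjects per group")
    n_feat = min(spec.n_features, Y.shape[1])

    preds = np.zeros(Y.shape[0], dtype=bool)
    n_ties = 0
    selected: list[np.ndarray] = []
    ids = cohort.loc[sel, "subject_id"].to_numpy()
    for i in range(Y.shape[0]):
        train = np.ones(Y.shape[0], dtype=bool)
        train[i] = False
        tr_a = Y[train & labels_a]
        tr_b = Y[train & ~labels_a]
        ranked = rank_features(tr_a, tr_b, spec.ranking)[:n_feat]
        selected.append(ranked.copy())
        disc = fit_shrinkage_lda(tr_a[:, ranked], tr_b[:, ranked])
        s = float(disc.score(Y[i, ranked])[0])
        if s == 0.0:
            n_ties += 1
        preds[i] = s >= 0.0

    k_a = int((preds & labels_a).sum())           # true A predicted A
    k_b = int((~preds & ~labels_a).sum())         # true B predicted B
    ba = 0.5 * (k_a / n_a + k_b / n_b)
    confusion = np.array([[k_a, n_a - k_a], [n_b - k_b, k_b]])
    ci_low, ci_high = _jeffreys_delta_ci(k_a, n_a, k_b, n_b)
    p = _balanced_accuracy_pvalue(k_a, n_a, k_b, n_b)
    folds = pd.DataFrame(
        {
            "subject_id": ids,
            "true_group": np.where(labels_a, groups[0], groups[1]),
            "predicted_group": np.where(preds, groups[0], groups[1]),
        }
    )
    return ClassificationReport(
        groups=tuple(groups),
        balanced_accuracy=float(ba),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value_vs_chance=p,
        confusion=confusion,
        fold_predictions=folds,
        n_features=n_feat,
        ranking=spec.ranking,
        n_ties=n_ties,
        selected_features=selected,
    )
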
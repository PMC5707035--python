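"""ROC/AUC marker evaluation and multi-marker panel combination.

The per-marker statistic is the Mann–Whitney AUC: the probability that a
randomly chosen case value exceeds a randomly chosen control value, with
half credit for ties.  It is computed from mid-ranks and equals the
trapezoidal area under the empirical ROC curve.

A marker panel combines several proteins into one scalar risk score per
sample.  The default combiner is ridge-penalized logistic regression on
standardized log2 abundances (small fixed penalty, deterministic fit); an
unweighted sum of per-marker z-scores is available as an alternative.
Confidence intervals for the panel AUC come from a stratified (within-group)
percentile bootstrap.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve

from .matrix import CASE, AbundanceMatrix, log2_transform

__all__ = [
    "auc_mann_whitney",
    "RocResult",
    "roc_result",
    "PanelModel",
    "fit_panel",
    "panel_auc",
    "bootstrap_auc_ci",
]


def auc_mann_whitney(case_values, ctrl_values) -> float:
    """Mann–Whitney AUC = [#(case > ctrl) + 0.5 #(ties)] / (n_case * n_ctrl).

    Computed from mid-ranks of the pooled values: U = R_case - n1(n1+1)/2.
    """
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(ctrl_values, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([case, ctrl])
    ranks = rankdata(pooled)
    u = ranks[: case.size].sum() - case.size * (case.size + 1) / 2.0
    return float(u / (case.size * ctrl.size))


@dataclasses.dataclass
class RocResult:
    """ROC curve for one marker or panel score.

    ``fpr``/``tpr`` start at (0, 0) and end at (1, 1); ``auc`` is the
    Mann–Whitney statistic and equals the trapezoidal area of the curve.
    """

    name: str
    auc: float
    n_case: int
    n_ctrl: int
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    @property
    def trapezoid_area(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_result(case_values, ctrl_values, name: str = "marker") -> RocResult:
    """Empirical ROC curve (one point per distinct threshold) plus AUC."""
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(ctrl_values, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be nonempty")
    y = np.concatenate([np.ones(case.size, dtype=int), np.zeros(ctrl.size, dtype=int)])
    scores = np.concatenate([case, ctrl])
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    return RocResult(
        name=name,
        auc=auc_mann_whitney(case, ctrl),
        n_case=case.size,
        n_ctrl=ctrl.size,
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
    )


@dataclasses.dataclass
class PanelModel:
    """Fitted combination rule over a marker subset.

    The score of a sample is ``intercept + sum_m weight_m * z_m`` where
    ``z_m`` is the sample's log2 abundance of marker ``m`` standardized by
    the training mean/sd.  The score is a monotone link of the linear
    combination, so AUC depends only on the linear part.
    """

    markers: list[str]
    weights: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    combiner: str = "ridge_logistic"

    def score(self, matrix: AbundanceMatrix) -> np.ndarray:
        x = _marker_features(matrix, self.markers)
        z = (x - self.feature_means) / self.feature_sds
        return self.intercept + z @ self.weights

    def to_dict(self) -> dict:
        return {
            "markers": self.markers,
            "weights": [float(w) for w in self.weights],
            "intercept": float(self.intercept),
            "feature_means": [float(v) for v in self.feature_means],
            "feature_sds": [float(v) for v in self.feature_sds],
            "combiner": self.combiner,
        }


def _marker_features(matrix: AbundanceMatrix, markers: Sequence[str]) -> np.ndarray:
    """samples x markers array of log2 abundances."""
    missing = [m for m in markers if m not in matrix.data.index]
    if missing:
        raise KeyError(f"markers absent from matrix: {missing}")
    log_mat = log2_transform(matrix) if matrix.scale == "linear" else matrix
    return log_mat.data.loc[list(markers)].to_numpy(dtype=float).T


# Small fixed ridge penalty: enough to keep separable fits finite and the
# optimum deterministic, weak enough not to distort well-conditioned fits.
_RIDGE_C = 100.0


def fit_panel(
    matrix: AbundanceMatrix,
    markers: Sequence[str],
    combiner: str = "ridge_logistic",
) -> PanelModel:
    """Fit the panel combination rule on log2 marker abundances.

    ``ridge_logistic`` maximizes the L2-penalized binomial likelihood of the
    case/control label (deterministic, no random initialization);
    ``zscore_sum`` uses unit weights on the standardized markers.
    """
    markers = list(markers)
    x = _marker_features(matrix, markers)
    y = (matrix.groups.to_numpy() == CASE).astype(int)
    if y.min() == y.max():
        raise ValueError("both case and ctrl samples are required to fit a panel")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    sds = np.where(sds == 0, 1.0, sds)
    z = (x - means) / sds
    if combiner == "ridge_logistic":
        clf = LogisticRegression(C=_RIDGE_C, solver="lbfgs", max_iter=5000)
        clf.fit(z, y)
        weights = clf.coef_[0].astype(float)
        intercept = float(clf.intercept_[0])
    elif combiner == "zscore_sum":
        weights = np.ones(len(markers), dtype=float)
        intercept = 0.0
    else:
        raise ValueError(f"unknown combiner {combiner!r}")
    return PanelModel(
        markers=markers,
        weights=weights,
        intercept=intercept,
        feature_means=means,
        feature_sds=sds,
        combiner=combiner,
    )


def panel_auc(model: PanelModel, matrix: AbundanceMatrix, name: str = "panel") -> RocResult:
    """Score every sample with the panel and evaluate the ROC of the scores."""
    scores = model.score(matrix)
    is_case = matrix.groups.to_numpy() == CASE
    return roc_result(scores[is_case], scores[~is_case], name=name)


def bootstrap_auc_ci(
    matrix: AbundanceMatrix,
    markers: Sequence[str],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
    combiner: str = "ridge_logistic",
) -> tuple[float, float]:
    """Stratified percentile-bootstrap CI for the in-sample panel AUC.

    Samples are resampled with replacement within each group (so both
    classes always remain), the panel is refit on the replicate, and its
    in-sample AUC recorded; the interval is the percentile range of the
    replicate AUCs, truncated to [0, 1].  A replicate that degenerates (all
    resampled values of some marker constant across both groups making the
    fit undefined) is redrawn, up to 100 extra attempts.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    markers = list(markers)
    case_ids = matrix.case_samples
    ctrl_ids = matrix.ctrl_samples
    aucs = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            take_case = rng.integers(0, len(case_ids), len(case_ids))
            take_ctrl = rng.integers(0, len(ctrl_ids), len(ctrl_ids))
            cols = [case_ids[i] for i in take_case] + [ctrl_ids[i] for i in take_ctrl]
            data = matrix.data[cols].copy()
            new_ids = [f"b{j}" for j in range(len(cols))]
            data.columns = new_ids
            groups = [CASE] * len(take_case) + ["ctrl"] * len(take_ctrl)
            boot = AbundanceMatrix(data, dict(zip(new_ids, groups)), matrix.scale)
            try:
                model = fit_panel(boot, markers, combiner=combiner)
                aucs[b] = panel_auc(model, boot).auc
                break
            except (ValueError, np.linalg.LinAlgError):
                redraws += 1
                if redraws > 100:
                    raise RuntimeError("too many degenerate bootstrap replicates")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(max(0.0, lo)), float(min(1.0, hi))
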
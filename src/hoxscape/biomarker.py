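"""CpG-panel biomarker evaluation via ROC/AUC.

Evaluates a user-specified panel of CpG loci (e.g. the eight intronic HOXB9
CpGs at hg19/chr17:46702528-46702583) as a classifier separating disease
groups.  The primary per-sample feature is the MEAN methylation over the
panel loci (matched tumor-normal delta or raw tumor values); a multivariate
per-locus mode is available.  Scores come from a maximum-likelihood logistic
model; on perfect separation or non-convergence the scorer falls back to the
rank of the mean-methylation feature, which leaves the ROC unchanged since
ROC depends only on score order.

The ROC is built from first principles by sweeping unique score thresholds;
the AUC is the trapezoid integral and equals the Mann-Whitney concordance
P(score_pos > score_neg) + 0.5 P(equal).  Confidence intervals use
stratified bootstrap percentiles.  This is an in-sample, descriptive design
mirroring small matched cohorts (n = 6-8 per group), not held-out
validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .methcov import matched_pairs, pct_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "PanelMatrix",
    "ROCResult",
    "build_panel",
    "fit_logistic",
    "roc_auc",
    "auc_mann_whitney",
    "bootstrap_ci",
    "forest_check",
    "evaluate_panel",
]

CONTRASTS = {
    ("PMOL", "TN0"),
    ("PMOL", "TN0plus"),
    ("TN0", "TN0plus"),
}


@dataclass(frozen=True)
class PanelMatrix:
    """Samples x panel-loci methylation values with binary class labels."""

    values: pd.DataFrame  # rows: sample/pair ids; columns: "chrom:pos" loci
    labels: np.ndarray  # 0/1 per row
    contrast: tuple[str, str]  # (class0 name, class1 name)
    mode: str = "matched_delta"

    def __post_init__(self) -> None:
        if self.values.isna().to_numpy().any():
            raise ValueError("panel matrix contains missing values")
        labels = np.asarray(self.labels, dtype=int)
        if set(np.unique(labels)) - {0, 1}:
            raise ValueError("labels must be binary")
        for cls in (0, 1):
            if not np.any(labels == cls):
                raise ValueError(
                    f"contrast {self.contrast[0]} vs {self.contrast[1]}: class {cls} is empty"
                )
        object.__setattr__(self, "labels", labels)

    @property
    def mean_feature(self) -> np.ndarray:
        """Per-sample mean methylation over the panel (primary feature)."""
        return self.values.to_numpy(dtype=float).mean(axis=1)


@dataclass
class ROCResult:
    """ROC curve points, trapezoid AUC, and (optionally) bootstrap CI."""

    points: list[tuple[float, float]]  # (FPR, TPR), (0,0) -> (1,1)
    auc: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0
    seed: int | None = None
    n0: int = 0
    n1: int = 0

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n0": self.n0,
            "n1": self.n1,
        }


def _locus_key(chrom: str, pos: int) -> str:
    return f"{chrom}:{pos}"


def build_panel(
    coverage: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    panel_loci: Sequence[tuple[str, int]],
    contrast: tuple[str, str],
    mode: str = "matched_delta",
) -> PanelMatrix:
    """Assemble the panel matrix for a two-group contrast.

    Groups may be disease groups (PMOL/TN0/TN0plus) or histologies
    (leukoplakia/WDSCC/MDSCC).  ``matched_delta`` rows are per patient
    (tumor - normal percent at each locus); ``raw_tumor`` rows are tumor
    sample percentages.  Samples missing any panel locus are dropped (logged).
    """
    if mode not in {"matched_delta", "raw_tumor"}:
        raise ValueError(f"unknown panel mode {mode!r}")
    known = set(metadata["group"]).union(metadata["histology"])
    for cls in contrast:
        if cls not in known:
            raise ValueError(f"unknown group name {cls!r} in contrast")
    mat = pct_matrix(coverage)
    loci = [(c, p) for c, p in panel_loci]
    missing_loci = [lp for lp in loci if lp not in mat.index]
    if missing_loci:
        raise ValueError(f"panel loci absent from coverage: {missing_loci}")
    site = mat.loc[loci]

    def class_of(row: pd.Series) -> int | None:
        for idx, cls in enumerate(contrast):
            if row["group"] == cls or row["histology"] == cls:
                return idx
        return None

    rows, labels, index = [], [], []
    by_sample = metadata.set_index("sample_id")
    for pid, _group, t_sid, n_sid in matched_pairs(metadata):
        cls = class_of(by_sample.loc[t_sid])
        if cls is None:
            continue
        if mode == "matched_delta":
            vals = site[t_sid].to_numpy(dtype=float) - site[n_sid].to_numpy(dtype=float)
        else:
            vals = site[t_sid].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            logger.info("sample %s dropped: panel locus without retained call", t_sid)
            continue
        rows.append(vals)
        labels.append(cls)
        index.append(pid if mode == "matched_delta" else t_sid)
    values = pd.DataFrame(
        rows, index=index, columns=[_locus_key(c, p) for c, p in loci]
    )
    return PanelMatrix(values=values, labels=np.array(labels), contrast=tuple(contrast), mode=mode)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _rank_scores(feature: np.ndarray) -> np.ndarray:
    """Order-preserving fallback scores in (0, 1)."""
    return rankdata(feature) / (len(feature) + 1.0)


def fit_logistic(matrix: PanelMatrix, multivariate: bool = False) -> np.ndarray:
    """In-sample predicted probabilities from a logistic model.

    Primary feature is the panel mean; ``multivariate`` uses all loci.  On
    perfect separation or non-convergence the univariate mean-methylation
    rank is returned instead (a warning is logged) — ROC is unaffected
    because it only uses score order.
    """
    y = matrix.labels
    for cls in (0, 1):
        if (y == cls).sum() < 3:
            raise ValueError("fit_logistic requires >= 3 samples per class")
    X = matrix.values.to_numpy(dtype=float) if multivariate else matrix.mean_feature[:, None]
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # PerfectSeparationWarning -> raise
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200, method="lbfgs")
        if not np.all(np.isfinite(fit.params)):
            raise ValueError("non-finite coefficients")
        return np.asarray(fit.predict(Xc))
    except Exception as exc:  # separation, non-convergence, singular design
        logger.warning("logistic fit failed (%s); falling back to rank scoring", exc)
        return _rank_scores(matrix.mean_feature)


# ---------------------------------------------------------------------------
# ROC / AUC from first principles
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC by threshold sweep and trapezoid AUC.

    Thresholds run over the unique score values from high to low; each point
    is (FPR, TPR) of the classifier "score >= threshold".  The resulting AUC
    equals the Mann-Whitney concordance statistic (ties count half).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("roc_auc requires both classes present")
    points = [(0.0, 0.0)]
    for thr in np.sort(np.unique(s))[::-1]:
        pred = s >= thr
        tpr = float((pred & (y == 1)).sum() / n1)
        fpr = float((pred & (y == 0)).sum() / n0)
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return ROCResult(points=points, auc=float(auc), n0=n0, n1=n1)


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """Fast AUC via midranks: P(score_pos > score_neg) + 0.5 P(equal)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes required")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def bootstrap_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the AUC.

    Samples are resampled with replacement within each class (so every
    replicate retains both classes); bounds are the alpha/2 and 1-alpha/2
    percentiles of the replicate AUC distribution.  Deterministic given seed.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if idx0.size == 0 or idx1.size == 0:
        raise ValueError("both classes required")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        i0 = rng.choice(idx0, size=idx0.size, replace=True)
        i1 = rng.choice(idx1, size=idx1.size, replace=True)
        take = np.concatenate([i0, i1])
        aucs[b] = auc_mann_whitney(s[take], y[take])
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def forest_check(
    matrix: PanelMatrix, n_trees: int = 500, seed: int | None = None
) -> float:
    """Robustness check: out-of-bag AUC of a bagged random forest on the
    full per-locus panel."""
    y = matrix.labels
    for cls in (0, 1):
        if (y == cls).sum() < 3:
            raise ValueError("forest_check requires >= 3 samples per class")
    X = matrix.values.to_numpy(dtype=float)
    informative = np.ptp(X, axis=0) > 0
    if not informative.any():
        # no splittable feature: OOB probabilities would only reflect in-bag
        # class composition (an anti-correlated artifact), not signal
        logger.warning("forest_check: all features constant; AUC is chance")
        return 0.5
    X = X[:, informative]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # few-tree OOB warnings on tiny n
        rf = RandomForestClassifier(
            n_estimators=n_trees, oob_score=True, bootstrap=True, random_state=seed
        ).fit(X, y)
        oob = rf.oob_decision_function_[:, 1]
    keep = np.isfinite(oob)
    return auc_mann_whitney(oob[keep], y[keep])


def evaluate_panel(
    matrix: PanelMatrix,
    n_boot: int = 2000,
    seed: int | None = None,
    multivariate: bool = False,
) -> ROCResult:
    """Full panel evaluation: logistic scores -> ROC/AUC -> bootstrap CI."""
    scores = fit_logistic(matrix, multivariate=multivariate)
    result = roc_auc(scores, matrix.labels)
    lo, hi = bootstrap_ci(scores, matrix.labels, n_boot=n_boot, seed=seed)
    return replace(result, ci_low=lo, ci_high=hi, n_boot=n_boot, seed=seed)
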
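"""ROC analysis, Youden cut-point selection, stratified predictive values,
contingency tests, correlation intervals, regression, and the replication
based over-optimism correction of the AUROC.

Conventions used throughout:

* a positive test is ``score >= cutoff`` (closed on the left, matching the
  half-open category brackets of the descriptive tables);
* AUROC is the Mann-Whitney concordance probability, with tied cross-class
  pairs counting one half;
* the Youden cut-off maximizes J = sensitivity + specificity - 1 over the
  observed score values (plus +inf, i.e. "never positive"), ties broken by
  the smallest cutoff;
* the over-optimism correction repeatedly (default 100 times) splits the
  data into two equally sized outcome-stratified halves, fits a logistic
  model on the first, evaluates the AUROC of its linear predictor on the
  second, and reports the mean with the empirical 2.5/97.5 percentiles as
  a 95% uncertainty interval.

The two genuinely fit-shaped operations are exposed as scikit-learn style
estimators (:class:`YoudenCutoffClassifier`, :class:`OptimismCorrectedAUC`);
the module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort import SubjectRecord, size_class, SIZE_CLASS_LABELS

__all__ = [
    "ThresholdPerformance",
    "CorrectedAuc",
    "StratifiedPvTable",
    "ContingencyResult",
    "CorrelationCi",
    "OlsResult",
    "auroc",
    "youden_threshold",
    "confusion_at_threshold",
    "stratified_pv",
    "chi_square_2x2",
    "pearson_ci",
    "pearson_ci_from_r",
    "ols_regression",
    "corrected_auroc",
    "YoudenCutoffClassifier",
    "OptimismCorrectedAUC",
    "cohort_frame",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdPerformance:
    """A cut-off with its confusion counts, sensitivity, specificity and J."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass(frozen=True)
class CorrectedAuc:
    """Apparent AUROC with its replication-corrected estimate and interval."""

    apparent_auc: float
    corrected_auc: float
    interval_lo: float
    interval_hi: float
    n_replications: int
    seed: int | None


@dataclass(frozen=True)
class StratifiedPvTable:
    """Per-stratum 2x2 counts below/above a cutoff with NPV and PPV.

    ``rows`` maps stratum label to a dict with keys benign_below,
    cancer_below, benign_above, cancer_above, npv, ppv; predictive values
    are None when their denominator is empty.
    """

    stratifier: str
    cutoff: float
    rows: dict[str, dict]

    def margin_counts(self) -> tuple[int, int, int, int]:
        """(benign_below, cancer_below, benign_above, cancer_above) totals."""
        keys = ("benign_below", "cancer_below", "benign_above", "cancer_above")
        return tuple(sum(r[k] for r in self.rows.values()) for k in keys)


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    chi2_stat: float
    p_value: float
    correction: bool


@dataclass(frozen=True)
class CorrelationCi:
    r: float
    n: int
    ci_lo: float
    ci_hi: float
    level: float


@dataclass(frozen=True)
class OlsResult:
    names: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    resid: np.ndarray


# ---------------------------------------------------------------------------
# AUROC and thresholds
# ---------------------------------------------------------------------------

def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return s, y


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUROC: P(case score > control score) + 0.5 P(tie)."""
    s, y = _check_scores_labels(scores, labels)
    ranks = sps.rankdata(s)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def confusion_at_threshold(scores, labels, cutoff: float) -> ThresholdPerformance:
    """Confusion counts and sensitivity/specificity at a fixed cutoff
    (positive test = score >= cutoff)."""
    s, y = _check_scores_labels(scores, labels)
    pos = s >= cutoff
    tp = int(np.sum(pos & (y == 1)))
    fp = int(np.sum(pos & (y == 0)))
    fn = int(np.sum(~pos & (y == 1)))
    tn = int(np.sum(~pos & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return ThresholdPerformance(float(cutoff), tp, fp, tn, fn, sens, spec, sens + spec - 1.0)


class YoudenCutoffClassifier(BaseEstimator, ClassifierMixin):
    """Dichotomizes a single continuous marker at the Youden-optimal cutoff.

    ``fit`` scans the observed marker values (plus +inf) as candidate
    cutoffs and selects the one maximizing J = sensitivity + specificity -
    1, breaking ties by the smallest cutoff; ``predict`` applies
    ``marker >= cutoff_``.  Follows the scikit-learn estimator contract so
    it composes with pipelines and model selection.

    Attributes set by fit: ``cutoff_``, ``performance_`` (a
    :class:`ThresholdPerformance`), ``classes_``.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("YoudenCutoffClassifier handles a single marker column")
            X = X[:, 0]
        s, yy = _check_scores_labels(X, y)
        order = np.argsort(s, kind="stable")
        s_sorted = s[order]
        y_sorted = yy[order]
        n1 = int(yy.sum())
        n0 = len(yy) - n1
        candidates = np.unique(s_sorted)
        # cases/controls with score >= t, via cumulative counts from the right
        case_cum = np.cumsum(y_sorted[::-1])[::-1]
        ctrl_cum = np.cumsum((1 - y_sorted)[::-1])[::-1]
        idx = np.searchsorted(s_sorted, candidates, side="left")
        tp = case_cum[idx]
        fp = ctrl_cum[idx]
        sens = tp / n1
        spec = (n0 - fp) / n0
        j = sens + spec - 1.0
        # +inf candidate: nobody positive, J = 0.  Ties (within float noise)
        # break toward the smallest cutoff.
        best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
        if j[best] < 0.0:
            chosen = ThresholdPerformance(math.inf, 0, 0, n0, n1, 0.0, 1.0, 0.0)
        else:
            chosen = ThresholdPerformance(
                float(candidates[best]),
                int(tp[best]),
                int(fp[best]),
                int(n0 - fp[best]),
                int(n1 - tp[best]),
                float(sens[best]),
                float(spec[best]),
                float(j[best]),
            )
        self.cutoff_ = chosen.cutoff
        self.performance_ = chosen
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return X - self.cutoff_

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)


def youden_threshold(scores, labels) -> ThresholdPerformance:
    """Youden-optimal cutoff for a single marker; see
    :class:`YoudenCutoffClassifier`."""
    est = YoudenCutoffClassifier().fit(np.asarray(scores, dtype=float).reshape(-1, 1), labels)
    return est.performance_


# ---------------------------------------------------------------------------
# Stratified predictive values
# ---------------------------------------------------------------------------

STRATIFIERS = ("size_class", "lungrads_class", "brock_class")


def cohort_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Score a cohort into a flat analysis frame.

    Columns: subject_id, cfdna_ng_ml, is_cancer, outcome, diagnosis_round,
    main nodule size (0 mm for a negative exam), size_class, Lung-RADS
    category and rank, lungrads_class (merged strata), Brock score and
    brock_class.
    """
    from .brock import brock_score_for_subject, brock_stratum
    from .cohort import main_nodule
    from .lungrads import classify_lungrads, lungrads_stratum

    rows = []
    for rec in records:
        mn = main_nodule(rec)
        size = mn.mean_diameter_mm if mn is not None else 0.0
        cat = classify_lungrads(rec.baseline_nodules(), rec.subject_id)
        score = brock_score_for_subject(rec)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "cfdna_ng_ml": rec.cfdna_ng_ml,
                "is_cancer": int(rec.outcome.is_cancer),
                "outcome": rec.outcome.outcome_class.value,
                "diagnosis_round": rec.outcome.diagnosis_round,
                "size_mm": size,
                "size_class": size_class(size),
                "lungrads": cat.value,
                "lungrads_rank": cat.rank,
                "lungrads_class": lungrads_stratum(cat),
                "brock_score": score,
                "brock_class": brock_stratum(score),
            }
        )
    return pd.DataFrame(rows)


def _stratum_order(stratifier: str) -> tuple[str, ...]:
    from .brock import BROCK_STRATA
    from .lungrads import LUNGRADS_STRATA

    return {
        "size_class": SIZE_CLASS_LABELS,
        "lungrads_class": LUNGRADS_STRATA,
        "brock_class": BROCK_STRATA,
    }[stratifier]


def stratified_pv(data, stratifier: str, cutoff: float = 3.15) -> StratifiedPvTable:
    """Per-stratum benign/cancer counts below/above the cfDNA cutoff with
    NPV and PPV.

    ``data`` is either a list of SubjectRecords (scored internally via
    :func:`cohort_frame`) or a DataFrame already carrying ``cfdna_ng_ml``,
    ``is_cancer`` and the stratifier column.  NPV = benign_below /
    (benign_below + cancer_below); PPV = cancer_above / (benign_above +
    cancer_above); an empty denominator reports None, not 0.
    """
    if stratifier not in STRATIFIERS:
        raise ValueError(f"stratifier must be one of {STRATIFIERS}")
    frame = data if isinstance(data, pd.DataFrame) else cohort_frame(data)
    rows: dict[str, dict] = {}
    for stratum in _stratum_order(stratifier):
        sub = frame[frame[stratifier] == stratum]
        above = sub["cfdna_ng_ml"] >= cutoff
        cancer = sub["is_cancer"] == 1
        bb = int((~above & ~cancer).sum())
        cb = int((~above & cancer).sum())
        ba = int((above & ~cancer).sum())
        ca = int((above & cancer).sum())
        rows[stratum] = {
            "benign_below": bb,
            "cancer_below": cb,
            "benign_above": ba,
            "cancer_above": ca,
            "npv": bb / (bb + cb) if bb + cb else None,
            "ppv": ca / (ba + ca) if ba + ca else None,
        }
    return StratifiedPvTable(stratifier=stratifier, cutoff=float(cutoff), rows=rows)


# ---------------------------------------------------------------------------
# Contingency, correlation, regression
# ---------------------------------------------------------------------------

def chi_square_2x2(table, correction: bool = False) -> ContingencyResult:
    """Pearson chi-square test on a 2x2 table, df = 1, without continuity
    correction by default (available via ``correction=True``)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all row and column margins must be positive")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=correction)
    return ContingencyResult(
        table=tuple(tuple(int(v) for v in row) for row in t),
        chi2_stat=float(chi2),
        p_value=float(p),
        correction=correction,
    )


def pearson_ci_from_r(r: float, n: int, level: float = 0.95) -> CorrelationCi:
    """Fisher-z confidence interval for a correlation given (r, n):
    atanh(r) +/- z * 1/sqrt(n - 3), mapped back through tanh."""
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1) for a Fisher-z interval")
    if n < 4:
        raise ValueError("need n >= 4")
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    q = float(sps.norm.ppf(0.5 + level / 2.0))
    return CorrelationCi(
        r=float(r), n=int(n), ci_lo=math.tanh(z - q * se), ci_hi=math.tanh(z + q * se), level=level
    )


def pearson_ci(x, y, level: float = 0.95) -> CorrelationCi:
    """Pearson product-moment correlation with its Fisher-z interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(sps.pearsonr(x, y).statistic)
    if abs(r) == 1.0:  # degenerate: exact linear relation, interval collapses
        return CorrelationCi(r=r, n=len(x), ci_lo=r, ci_hi=r, level=level)
    return pearson_ci_from_r(r, len(x), level)


def ols_regression(
    response, covariates, names: Sequence[str] | None = None, add_intercept: bool = True
) -> OlsResult:
    """Least-squares linear regression with standard errors and t-test
    p-values (statsmodels OLS under the hood)."""
    y = np.asarray(response, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if names is None:
        names = tuple(f"x{i + 1}" for i in range(X.shape[1]))
    if add_intercept:
        X = sm.add_constant(X, has_constant="raise")
        names = ("intercept", *names)
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    return OlsResult(
        names=tuple(names),
        params=np.asarray(res.params, dtype=float),
        bse=np.asarray(res.bse, dtype=float),
        pvalues=np.asarray(res.pvalues, dtype=float),
        resid=np.asarray(res.resid, dtype=float),
    )


# ---------------------------------------------------------------------------
# Over-optimism corrected AUROC
# ---------------------------------------------------------------------------

def _fit_logistic(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Logistic coefficients (intercept first).  Falls back to a
    least-squares linear-probability fit when maximum likelihood fails
    (e.g. complete separation); only the linear-predictor ranking matters
    for downstream AUROC evaluation, and the fallback preserves it."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=100)
            params = np.asarray(res.params, dtype=float)
            if np.all(np.isfinite(params)):
                return params
        except Exception:
            pass
    coef, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    return np.asarray(coef, dtype=float)


def _linear_predictor(X: np.ndarray, params: np.ndarray) -> np.ndarray:
    return params[0] + X @ params[1:]


class OptimismCorrectedAUC(BaseEstimator):
    """Replication-based over-optimism correction of the AUROC.

    ``fit(X, y)`` fits a logistic model on the full data for the apparent
    (resubstitution) AUROC, then ``n_replications`` times splits the data
    into two equally sized outcome-stratified halves (the odd subject goes
    to the training half), refits on the first half and scores the AUROC of
    the fitted linear predictor on the second.  The corrected estimate is
    the mean of the replicate AUROCs; the 2.5/97.5 empirical percentiles
    form the 95% uncertainty interval.  Deterministic given
    ``random_state``.

    Attributes set by fit: ``apparent_auc_``, ``corrected_auc_``,
    ``interval_``, ``replicate_aucs_``.
    """

    def __init__(self, n_replications: int = 100, random_state: int | None = None):
        self.n_replications = n_replications
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        y = np.asarray(y).ravel().astype(int)
        if X.shape[0] != len(y):
            raise ValueError("X and y must have the same number of rows")
        counts = np.bincount(y, minlength=2)
        if (counts < 2).any():
            raise ValueError("each class needs >= 2 members to appear in both halves")
        rng = np.random.default_rng(self.random_state)

        full = _fit_logistic(X, y)
        self.apparent_auc_ = auroc(_linear_predictor(X, full), y)

        idx_by_class = [np.flatnonzero(y == c) for c in (0, 1)]
        aucs = np.empty(self.n_replications)
        for b in range(self.n_replications):
            train_idx: list[np.ndarray] = []
            test_idx: list[np.ndarray] = []
            for idx in idx_by_class:
                perm = rng.permutation(idx)
                half = (len(perm) + 1) // 2  # odd n: extra subject trains
                train_idx.append(perm[:half])
                test_idx.append(perm[half:])
            tr = np.concatenate(train_idx)
            te = np.concatenate(test_idx)
            params = _fit_logistic(X[tr], y[tr])
            aucs[b] = auroc(_linear_predictor(X[te], params), y[te])
        self.replicate_aucs_ = aucs
        self.corrected_auc_ = float(aucs.mean())
        self.interval_ = (
            float(np.percentile(aucs, 2.5)),
            float(np.percentile(aucs, 97.5)),
        )
        return self

    def result(self) -> CorrectedAuc:
        return CorrectedAuc(
            apparent_auc=self.apparent_auc_,
            corrected_auc=self.corrected_auc_,
            interval_lo=self.interval_[0],
            interval_hi=self.interval_[1],
            n_replications=self.n_replications,
            seed=self.random_state,
        )


def corrected_auroc(X, y, n_rep: int = 100, seed: int | None = None) -> CorrectedAuc:
    """Over-optimism corrected AUROC of a score or feature matrix; see
    :class:`OptimismCorrectedAUC`."""
    est = OptimismCorrectedAUC(n_replications=n_rep, random_state=seed).fit(X, y)
    return est.result()
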
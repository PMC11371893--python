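"""Predictive statistics for lesion metrics: group comparisons, correlations,
ROC/AUC with DeLong inference, Youden cutoffs, and Kaplan–Meier/Cox survival.

The cohort is analysed at the vessel level: future-culprit lesions (FCL) are
the positive/event class, non-culprit lesions (NCL) the controls.  Metric
*orientation* is declared, never auto-flipped: for MLR, MLA and vFFR low
values predict events; for ΔvFFR high values do.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError, SchemaError

__all__ = [
    "GroupComparison",
    "SpearmanResult",
    "ROCResult",
    "CutoffResult",
    "SurvivalResult",
    "AnalysisConfig",
    "AnalysisReport",
    "compare_groups",
    "spearman_corr",
    "roc_delong",
    "youden_cutoff",
    "km_hazard",
    "run_full_analysis",
]

# Table-style metric list and event orientations ("low" = low values predict
# the event).  PROXA/DISTA/lengths showed no discrimination in the study; the
# declared orientations follow the direction of the group medians.
DEFAULT_METRICS = ("MLR", "MLA", "PROXA", "DISTA", "LLR", "PLSL", "LSL", "dvffr", "vffr")
DEFAULT_ORIENTATIONS = {
    "MLR": "low",
    "MLA": "low",
    "PROXA": "high",
    "DISTA": "high",
    "LLR": "low",
    "PLSL": "high",
    "LSL": "high",
    "dvffr": "high",
    "vffr": "low",
}


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    median_iqr: dict  # group -> (q25, q50, q75)
    u_statistic: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class SpearmanResult:
    pair: tuple[str, str]
    rho: float
    p: float
    n: int


@dataclass(frozen=True)
class ROCResult:
    metric: str
    orientation: str
    auc: float
    variance: float  # DeLong variance of the AUC estimate
    ci_low: float
    ci_high: float
    p_vs_chance: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CutoffResult:
    metric: str
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass(frozen=True)
class SurvivalResult:
    metric: str
    threshold: float
    curves: dict  # stratum -> {"time": [...], "survival": [...], "n_at_risk": [...]}
    hazard_ratio: float
    hr_ci_low: float
    hr_ci_high: float
    hr_p: float
    logrank_p: float
    n_low: int
    n_high: int


# ---------------------------------------------------------------------------
# Group comparison (Mann-Whitney + Bonferroni)
# ---------------------------------------------------------------------------


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact enumeration for small untied samples,
    tie-corrected normal approximation otherwise."""
    if len(x) + len(y) < 16 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y):
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    cohort: pd.DataFrame,
    metrics: list[str] | tuple[str, ...] = DEFAULT_METRICS,
    group_col: str = "group",
    groups: tuple[str, str] = ("FCL", "NCL"),
    bonferroni_m: int | None = None,
) -> list[GroupComparison]:
    """Per-metric two-sided Mann-Whitney U with Bonferroni adjustment.

    ``bonferroni_m`` defaults to the number of compared metrics.
    """
    m = bonferroni_m if bonferroni_m is not None else len(metrics)
    out = []
    for metric in metrics:
        if metric not in cohort.columns:
            raise SchemaError(f"metric column missing from cohort: {metric}")
        samples = {}
        for g in groups:
            vals = cohort.loc[cohort[group_col] == g, metric].dropna().to_numpy(float)
            if len(vals) == 0:
                raise AnalysisError(f"group {g!r} empty for metric {metric!r}")
            samples[g] = vals
        u, p = _mannwhitney(samples[groups[0]], samples[groups[1]])
        out.append(
            GroupComparison(
                metric=metric,
                median_iqr={
                    g: tuple(np.percentile(v, [25, 50, 75])) for g, v in samples.items()
                },
                u_statistic=u,
                p_raw=p,
                p_adjusted=min(1.0, m * p),
            )
        )
    return out


def spearman_corr(
    cohort: pd.DataFrame, pairs: list[tuple[str, str]]
) -> list[SpearmanResult]:
    """Spearman rank correlations (midrank ties, t-approximation p) per pair."""
    out = []
    for a, b in pairs:
        sub = cohort[[a, b]].dropna()
        if len(sub) < 4:
            raise AnalysisError(f"need >= 4 paired observations for ({a}, {b})")
        if sub[a].nunique() < 2 or sub[b].nunique() < 2:
            raise AnalysisError(f"correlation undefined: constant column in ({a}, {b})")
        rho, p = sps.spearmanr(sub[a], sub[b])
        out.append(SpearmanResult(pair=(a, b), rho=float(rho), p=float(p), n=len(sub)))
    return out


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------


def _event_scores(labels, scores, orientation: str) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if set(np.unique(labels)) - {0, 1}:
        raise AnalysisError("labels must be binary 0/1")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise AnalysisError("both classes must be present")
    if orientation not in ("low", "high"):
        raise AnalysisError(f"orientation must be 'low' or 'high', got {orientation!r}")
    return labels, (-scores if orientation == "low" else scores)


def roc_delong(labels, scores, orientation: str = "high", metric: str = "") -> ROCResult:
    """AUC with DeLong variance, Wald 95% CI, and two-sided p against 0.5.

    The AUC is the Mann-Whitney pair-counting estimate (0.5 credit for ties)
    of P(score_event > score_nonevent) after applying the declared
    orientation.  The variance comes from the DeLong structural components
    V10 (per event) and V01 (per non-event):
    var = S10/m + S01/n.
    """
    labels, s = _event_scores(labels, scores, orientation)
    pos, neg = s[labels == 1], s[labels == 0]
    m, n = len(pos), len(neg)
    # structural components via midranks
    v10 = np.empty(m)
    v01 = np.empty(n)
    order = np.sort(neg)
    v10 = (np.searchsorted(order, pos, "left") + np.searchsorted(order, pos, "right")) / (2.0 * n)
    order = np.sort(pos)
    v01 = 1.0 - (np.searchsorted(order, neg, "left") + np.searchsorted(order, neg, "right")) / (
        2.0 * m
    )
    auc = float(v10.mean())
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n) if m > 1 and n > 1 else 0.0
    se = np.sqrt(var)
    z = sps.norm.ppf(0.975)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    if se > 0:
        p = 2.0 * sps.norm.sf(abs(auc - 0.5) / se)
    else:
        p = 0.0 if auc != 0.5 else 1.0
    return ROCResult(
        metric=metric,
        orientation=orientation,
        auc=auc,
        variance=var,
        ci_low=lo,
        ci_high=hi,
        p_vs_chance=float(p),
        n_pos=m,
        n_neg=n,
    )


def youden_cutoff(labels, scores, orientation: str = "high", metric: str = "") -> CutoffResult:
    """Threshold maximising Youden's J = sensitivity + specificity − 1.

    Candidate thresholds are the midpoints between consecutive distinct score
    values; a vessel is called positive when its score lies on the event side
    of the threshold (strictly below for orientation ``low``, strictly above
    for ``high``).  Ties in J are broken toward higher specificity.
    """
    labels, s = _event_scores(labels, scores, orientation)
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise AnalysisError("cannot place a threshold: all scores identical")
    # candidates: midpoints between distinct scores, plus the two degenerate
    # classify-all/classify-none thresholds (which attain J = 0)
    cand = np.concatenate([[-np.inf], 0.5 * (uniq[:-1] + uniq[1:]), [np.inf]])
    pos, neg = s[labels == 1], s[labels == 0]
    best = None
    for thr in cand:
        sens = float(np.mean(pos > thr))
        spec = float(np.mean(neg <= thr))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and spec > best[2]):
            best = (j, sens, spec, thr)
    j, sens, spec, thr = best
    # map the internal (event-oriented) threshold back to the metric scale
    threshold = -thr if orientation == "low" else thr
    return CutoffResult(
        metric=metric, threshold=float(threshold), sensitivity=sens, specificity=spec, youden_j=j
    )


# ---------------------------------------------------------------------------
# Survival (Kaplan-Meier + Cox)
# ---------------------------------------------------------------------------


def km_hazard(
    cohort: pd.DataFrame,
    metric: str,
    threshold: float,
    time_col: str = "time_months",
    event_col: str = "event",
) -> SurvivalResult:
    """Kaplan-Meier curves and hazard ratio for low- vs high-metric strata.

    The low stratum is ``metric < threshold`` (strict).  The hazard ratio of
    low vs high comes from a single-covariate Cox proportional-hazards fit
    with Efron tie handling (ties are heavy because all vessels of a patient
    are censored at the same time); the log-rank p is reported alongside.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import logrank_test

    for col in (metric, time_col, event_col):
        if col not in cohort.columns:
            raise SchemaError(f"column missing from cohort: {col}")
    data = cohort[[metric, time_col, event_col]].dropna()
    if (data[time_col] <= 0).any():
        raise AnalysisError("event/censoring times must be > 0")
    if data[event_col].sum() == 0:
        raise AnalysisError("no events in the cohort")
    low = data[metric] < threshold
    n_low, n_high = int(low.sum()), int((~low).sum())
    if n_low == 0 or n_high == 0:
        raise AnalysisError(
            f"dichotomisation at {threshold} leaves an empty stratum for {metric}"
        )
    if data.loc[low, event_col].sum() == 0 and data.loc[~low, event_col].sum() == 0:
        raise AnalysisError("no events in either stratum: hazard ratio undefined")

    curves = {}
    km = KaplanMeierFitter()
    for name, mask in (("low", low), ("high", ~low)):
        km.fit(data.loc[mask, time_col], data.loc[mask, event_col])
        tl = km.event_table.index.to_numpy(float)
        curves[name] = {
            "time": tl.tolist(),
            "survival": km.survival_function_.iloc[:, 0].to_numpy(float).tolist(),
            "n_at_risk": km.event_table["at_risk"].to_numpy(int).tolist(),
        }

    cox_df = pd.DataFrame(
        {"T": data[time_col], "E": data[event_col], "low": low.astype(int)}
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(cox_df, duration_col="T", event_col="E")
    coef = float(cph.params_["low"])
    se = float(cph.standard_errors_["low"])
    z = sps.norm.ppf(0.975)
    lr = logrank_test(
        data.loc[low, time_col],
        data.loc[~low, time_col],
        data.loc[low, event_col],
        data.loc[~low, event_col],
    )
    return SurvivalResult(
        metric=metric,
        threshold=float(threshold),
        curves=curves,
        hazard_ratio=float(np.exp(coef)),
        hr_ci_low=float(np.exp(max(coef - z * se, -700.0))),
        hr_ci_high=float(np.exp(min(coef + z * se, 700.0))),
        hr_p=float(cph.summary.loc["low", "p"]),
        logrank_p=float(lr.p_value),
        n_low=n_low,
        n_high=n_high,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of the full statistical analysis."""

    metrics: tuple = DEFAULT_METRICS
    orientations: dict = field(default_factory=lambda: dict(DEFAULT_ORIENTATIONS))
    bonferroni_m: int = 9
    correlation_pairs: tuple = (("MLR", "dvffr"), ("MLR", "vffr"))
    survival_metrics: tuple = ("MLR",)
    thresholds: dict = field(default_factory=dict)  # metric -> fixed threshold (else Youden)
    stratify_mi_type: bool = True


@dataclass
class AnalysisReport:
    """Machine-readable result of the full analysis."""

    n_vessels: int
    n_patients: int
    comparisons: list = field(default_factory=list)
    correlations: list = field(default_factory=list)
    roc: dict = field(default_factory=dict)  # endpoint -> [ROCResult]
    cutoffs: list = field(default_factory=list)
    survival: dict = field(default_factory=dict)  # endpoint -> [SurvivalResult]
    group_medians: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)  # stage -> message for skipped stages

    def to_dict(self) -> dict:
        def conv(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {k: conv(v) for k, v in asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "n_vessels": self.n_vessels,
            "n_patients": self.n_patients,
            "comparisons": [conv(c) for c in self.comparisons],
            "correlations": [conv(c) for c in self.correlations],
            "roc": {k: [conv(r) for r in v] for k, v in self.roc.items()},
            "cutoffs": [conv(c) for c in self.cutoffs],
            "survival": {k: [conv(s) for s in v] for k, v in self.survival.items()},
            "group_medians": conv(self.group_medians),
            "errors": dict(self.errors),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


_REQUIRED_COLUMNS = ("vessel_id", "patient_id", "group", "event", "time_months")


def run_full_analysis(
    cohort: pd.DataFrame, config: AnalysisConfig | None = None
) -> AnalysisReport:
    """Comparison table, correlations, per-metric ROC (overall and by MI type),
    Youden cutoffs, and dichotomised survival, composed over one cohort table.

    Stages that cannot run on the supplied cohort (e.g. a single group) are
    skipped with the reason recorded under ``report.errors``; descriptive
    summaries are always emitted.
    """
    cfg = config or AnalysisConfig()
    missing = [c for c in _REQUIRED_COLUMNS if c not in cohort.columns]
    missing += [m for m in cfg.metrics if m not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort is missing required columns: {missing}")

    report = AnalysisReport(
        n_vessels=len(cohort), n_patients=cohort["patient_id"].nunique()
    )
    report.group_medians = {
        g: sub[list(cfg.metrics)].median().to_dict()
        for g, sub in cohort.groupby("group")
    }

    try:
        report.comparisons = compare_groups(
            cohort, cfg.metrics, bonferroni_m=cfg.bonferroni_m
        )
    except AnalysisError as exc:
        report.errors["comparisons"] = str(exc)

    try:
        report.correlations = spearman_corr(cohort, list(cfg.correlation_pairs))
    except AnalysisError as exc:
        report.errors["correlations"] = str(exc)

    endpoints = {"any_mi": cohort}
    if cfg.stratify_mi_type and "mi_type" in cohort.columns:
        for mi in ("STEMI", "NSTEMI"):
            # endpoint: event only if the patient's MI is of this type;
            # controls are all NCL vessels (as in per-type ROC panels)
            sub = cohort[(cohort["event"] == 0) | (cohort["mi_type"] == mi)]
            if (sub["event"] == 1).any():
                endpoints[mi.lower()] = sub
            else:
                report.errors[f"roc_{mi.lower()}"] = f"no {mi} events; panel skipped"
                warnings.warn(f"no {mi} events; stratified panel skipped", stacklevel=2)

    for name, sub in endpoints.items():
        results = []
        for metric in cfg.metrics:
            try:
                results.append(
                    roc_delong(
                        sub["event"], sub[metric], cfg.orientations[metric], metric=metric
                    )
                )
            except AnalysisError as exc:
                report.errors[f"roc_{name}_{metric}"] = str(exc)
        if results:
            report.roc[name] = results

    for metric in cfg.metrics:
        try:
            report.cutoffs.append(
                youden_cutoff(
                    cohort["event"], cohort[metric], cfg.orientations[metric], metric=metric
                )
            )
        except AnalysisError as exc:
            report.errors[f"cutoff_{metric}"] = str(exc)

    thresholds = {c.metric: c.threshold for c in report.cutoffs}
    thresholds.update(cfg.thresholds)
    for name, sub in endpoints.items():
        results = []
        for metric in cfg.survival_metrics:
            if metric not in thresholds:
                continue
            try:
                results.append(km_hazard(sub, metric, thresholds[metric]))
            except AnalysisError as exc:
                report.errors[f"survival_{name}_{metric}"] = str(exc)
        if results:
            report.survival[name] = results
    return report
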
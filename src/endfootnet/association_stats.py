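"""Regression and multiple-testing machinery for gene/pathology associations.

Discovery-cohort models: logistic regression of dementia status on gene
expression (covariates: age in 5-year ordinal increments, APOE e4 carrier
status, TBI history; sex optional) and OLS of quantitative pathology on
expression with the same covariates, log-transforming right-skewed outcomes.
Validation-cohort models are deliberately uncorrected (no covariates).

Multiple-comparison control is two-stage: Benjamini-Hochberg FDR across the
entire set of fitted models gates a selection set (q < alpha), which is then
re-adjusted with the step-down Holm-Sidak family-wise correction separately
within each brain region.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import OLSInfluence
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age_increment", "apoe4", "tbi")


@dataclass
class AssociationRecord:
    """One fitted model: a gene (or eigengene/protein) vs one outcome in one region."""

    gene_id: str
    region: str
    outcome: str
    model: str  # "logistic" | "ols"
    statistic: float  # Wald z (logistic) or Wald t (OLS) for the expression term
    coefficient: float
    p_raw: float
    n: int
    p_fdr: float = np.nan
    p_adj: float = np.nan
    log_transformed: bool = False
    covariates: str = ""
    flag: str = ""


@dataclass
class PathologyStateRule:
    """Dichotomization thresholds for the ordinal pathology scores."""

    braak: int = 5
    neuritic_plaque_score: int = 3
    caa_score: int = 3


def _assemble(
    predictor: pd.Series,
    covariate_frame: pd.DataFrame | None,
    outcome: pd.Series,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Align predictor, covariates and outcome on their common index and drop
    incomplete rows (no imputation)."""
    parts = {"__x__": predictor, "__y__": outcome}
    frame = pd.DataFrame(parts)
    if covariate_frame is not None and covariate_frame.shape[1]:
        frame = frame.join(covariate_frame, how="inner")
    frame = frame.dropna()
    y = frame.pop("__y__").to_numpy(dtype=float)
    x = frame.pop("__x__")
    design = sm.add_constant(
        pd.concat([x.rename("expr"), frame], axis=1), has_constant="add"
    )
    return design.to_numpy(dtype=float), y, len(y)


def dementia_logistic(
    expr_gene: pd.Series,
    subjects: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    gene_id: str = "",
    region: str = "",
) -> AssociationRecord:
    """Wald test of the expression coefficient in a covariate-adjusted
    logistic model of dementia status.

    Complete separation yields a flagged record with missing p, not an
    exception. ``subjects`` is the frame from
    :func:`endfootnet.data_io.subjects_to_frame` (must contain ``dementia``).
    """
    cov = subjects[list(covariates)] if covariates else None
    X, y, n = _assemble(expr_gene, cov, subjects["dementia"])
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    rec = AssociationRecord(
        gene_id=gene_id,
        region=region,
        outcome="dementia",
        model="logistic",
        statistic=np.nan,
        coefficient=np.nan,
        p_raw=np.nan,
        n=n,
        covariates=",".join(covariates),
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 50:
            return replace(rec, flag="separation")
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return replace(rec, flag="separation")
    return replace(
        rec,
        statistic=float(res.tvalues[1]),
        coefficient=float(res.params[1]),
        p_raw=float(res.pvalues[1]),
    )


def _log_transform(y: pd.Series, mode: str) -> tuple[pd.Series, bool]:
    """Log-transform right-skewed outcomes: log(y + c), c = half the smallest
    positive value. ``mode``: auto (skewness > 1 triggers), always, never."""
    clean = y.dropna()
    do = {"always": True, "never": False}.get(mode)
    if do is None:
        if mode != "auto":
            raise ValueError(f"unknown transform mode {mode!r}")
        do = len(clean) > 2 and stats.skew(clean) > 1.0
    if not do:
        return y, False
    pos = clean[clean > 0]
    c = 0.5 * pos.min() if len(pos) else 1.0
    log.info("outcome %s log-transformed with offset %.4g", y.name, c)
    return np.log(y + c), True


def pathology_ols(
    expr_gene: pd.Series,
    pathology_outcome: pd.Series,
    subjects: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    transform: str = "auto",
    gene_id: str = "",
    region: str = "",
) -> AssociationRecord:
    """Wald t for the expression coefficient in a covariate-adjusted OLS of a
    continuous pathology outcome, log-transformed when right-skewed."""
    y_t, logged = _log_transform(pathology_outcome, transform)
    cov = subjects[list(covariates)] if covariates else None
    X, y, n = _assemble(expr_gene, cov, y_t)
    if n <= X.shape[1]:
        raise ValueError(f"too few complete observations ({n}) for {X.shape[1]} parameters")
    res = sm.OLS(y, X).fit()
    return AssociationRecord(
        gene_id=gene_id,
        region=region,
        outcome=str(pathology_outcome.name or "pathology"),
        model="ols",
        statistic=float(res.tvalues[1]),
        coefficient=float(res.params[1]),
        p_raw=float(res.pvalues[1]),
        n=n,
        log_transformed=logged,
        covariates=",".join(covariates),
    )


def interaction_contrast(
    expr_gene: pd.Series,
    pathology_outcome: pd.Series,
    subjects: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    transform: str = "auto",
    gene_id: str = "",
    region: str = "",
) -> AssociationRecord:
    """Does the expression-pathology slope differ by dementia status?

    Fits OLS with an expression x dementia interaction and reports the
    interaction term's Wald t.
    """
    status = subjects["dementia"]
    if status.nunique() < 2:
        raise ValueError("both dementia-status groups must be present")
    y_t, logged = _log_transform(pathology_outcome, transform)
    frame = pd.DataFrame({"expr": expr_gene, "dementia": status, "__y__": y_t})
    if covariates:
        frame = frame.join(subjects[list(covariates)], how="inner")
    frame = frame.dropna()
    frame["expr_x_dementia"] = frame["expr"] * frame["dementia"]
    y = frame.pop("__y__").to_numpy(dtype=float)
    X = sm.add_constant(frame, has_constant="add")
    res = sm.OLS(y, X).fit()
    return AssociationRecord(
        gene_id=gene_id,
        region=region,
        outcome=f"{pathology_outcome.name}:interaction",
        model="ols",
        statistic=float(res.tvalues["expr_x_dementia"]),
        coefficient=float(res.params["expr_x_dementia"]),
        p_raw=float(res.pvalues["expr_x_dementia"]),
        n=len(y),
        log_transformed=logged,
        covariates=",".join(covariates),
    )


def adjust_pvalues(
    records: list[AssociationRecord], alpha: float = 0.05
) -> list[AssociationRecord]:
    """Two-stage correction over a complete run's records.

    Stage 1: Benjamini-Hochberg across all records jointly -> ``p_fdr``.
    Stage 2: records with p_fdr < alpha form the selection set; within each
    region, step-down Holm-Sidak over that region's selected records ->
    ``p_adj`` (missing elsewhere). Flagged records (missing p_raw) pass
    through untouched.
    """
    if not records:
        return []
    out = [replace(r) for r in records]
    valid = [i for i, r in enumerate(out) if np.isfinite(r.p_raw)]
    if not valid:
        return out
    praw = np.array([out[i].p_raw for i in valid])
    _, p_fdr, _, _ = multipletests(praw, method="fdr_bh")
    for i, q in zip(valid, p_fdr):
        out[i].p_fdr = float(q)
    selected = [i for i in valid if out[i].p_fdr < alpha]
    by_region: dict[str, list[int]] = {}
    for i in selected:
        by_region.setdefault(out[i].region, []).append(i)
    for idx in by_region.values():
        p = np.array([out[i].p_raw for i in idx])
        _, p_adj, _, _ = multipletests(p, method="holm-sidak")
        for i, q in zip(idx, p_adj):
            out[i].p_adj = float(q)
    return out


def dichotomize_pathology(
    ordinal: pd.DataFrame, rule: PathologyStateRule | None = None
) -> pd.DataFrame:
    """Boolean 'pathological state' flags from ordinal scores.

    Braak >= 5, neuritic plaques >= 3, CAA >= 3 by default; missing scores
    give missing flags (NaN).
    """
    rule = rule or PathologyStateRule()
    out = pd.DataFrame(index=ordinal.index)
    for col, threshold, name in (
        ("braak", rule.braak, "braak_state"),
        ("neuritic_plaque_score", rule.neuritic_plaque_score, "plaque_state"),
        ("caa_score", rule.caa_score, "caa_state"),
    ):
        if col in ordinal.columns:
            vals = ordinal[col].astype(float)
            out[name] = np.where(vals.isna(), np.nan, (vals >= threshold).astype(float))
    return out


def validation_logistic(
    measure: pd.Series,
    outcome: pd.Series,
    gene_id: str = "",
    region: str = "",
    outcome_name: str = "ad_diagnosis",
) -> AssociationRecord:
    """Unadjusted logistic fit for the small validation cohorts (no covariates).

    ``measure`` is gene expression or a protein ratio; ``outcome`` a boolean
    diagnosis or dichotomized pathology state. Constant measures give a
    flagged degenerate record.
    """
    frame = pd.DataFrame({"x": measure, "y": outcome}).dropna()
    rec = AssociationRecord(
        gene_id=gene_id,
        region=region,
        outcome=outcome_name,
        model="logistic",
        statistic=np.nan,
        coefficient=np.nan,
        p_raw=np.nan,
        n=len(frame),
        covariates="",
    )
    if frame["x"].nunique() < 2:
        return replace(rec, flag="degenerate")
    if frame["y"].nunique() < 2:
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(frame[["x"]], has_constant="add").to_numpy(dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(frame["y"].astype(float).to_numpy(), X).fit(disp=0, maxiter=100)
        if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 50:
            return replace(rec, flag="separation")
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return replace(rec, flag="separation")
    return replace(
        rec,
        statistic=float(res.tvalues[1]),
        coefficient=float(res.params[1]),
        p_raw=float(res.pvalues[1]),
    )


@dataclass
class DemographicsResult:
    u_statistic: float
    p_value: float
    median_a: float
    quartiles_a: tuple[float, float]
    median_b: float
    quartiles_b: tuple[float, float]
    n_a: int
    n_b: int


def demographics_test(values_a, values_b) -> DemographicsResult:
    """Two-sided Mann-Whitney U with tie correction, plus medians and
    first/third quartiles per group (demographic-table format)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return DemographicsResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_a=float(np.median(a)),
        quartiles_a=(float(np.percentile(a, 25)), float(np.percentile(a, 75))),
        median_b=float(np.median(b)),
        quartiles_b=(float(np.percentile(b, 25)), float(np.percentile(b, 75))),
        n_a=len(a),
        n_b=len(b),
    )


@dataclass
class DiagnosticsResult:
    cooks_distance: np.ndarray
    dfbetas: np.ndarray
    flagged: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    threshold: float = np.nan


def model_diagnostics(fit, cooks_threshold: float | None = None) -> DiagnosticsResult:
    """Leave-one-out influence diagnostics for an OLS fit.

    Cook's distance and DFBETAS per observation; observations are flagged at
    Cook's D > 4/n (the conventional screening default) unless a threshold
    is given.
    """
    infl = OLSInfluence(fit)
    cooks = infl.cooks_distance[0]
    n = len(cooks)
    threshold = cooks_threshold if cooks_threshold is not None else 4.0 / n
    return DiagnosticsResult(
        cooks_distance=cooks,
        dfbetas=infl.dfbetas,
        flagged=cooks > threshold,
        threshold=threshold,
    )


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Flat DataFrame of association records (for write_results)."""
    import dataclasses

    return pd.DataFrame([dataclasses.asdict(r) for r in records])
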
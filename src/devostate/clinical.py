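"""Downstream association statistics for the fetalness index.

Covers the four analyses that connect the index to clinical and
functional data: Cox proportional-hazards survival models (with or
without age/stage adjustment), Kaplan-Meier median-split grouping,
the stem-cell-marker correlation-shift test, CRISPR-dependency
enrichment (Fisher's exact test on essential vs correlation sign), and
per-drug response correlation.

Conventions: the index is standardized to unit SD before Cox fitting so
hazard ratios are comparable across cohorts; a hazard ratio > 1 means
higher index, worse outcome.  Ties in the Cox partial likelihood are
handled by Efron's method (the lifelines default).  Stage enters the
multivariate model as an ordinal integer.  All multiple-testing
correction is Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter
from statsmodels.stats.multitest import multipletests

from .io_formats import BulkExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_ESSENTIAL_THRESHOLD = -0.5


@dataclass
class CoxResult:
    """Hazard ratio per SD of the index, with Wald CI and p-value."""

    hazard_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    log_hr: float
    log_hr_se: float
    covariates: tuple[str, ...]
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hazard_ratio <= self.ci_high):
            raise ValidationError("Cox CI does not contain the point estimate")


def _validate_survival(surv: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in surv.columns:
            raise ValidationError(f"survival table lacks column {col!r}")
    if (surv["time"] <= 0).any():
        raise ValidationError("survival times must be positive")
    if not surv["event"].isin((0, 1)).all():
        raise ValidationError("event indicator must be 0/1")
    if surv.index.duplicated().any():
        raise ValidationError("duplicated samples in survival table")
    return surv


def cox_association(
    index: pd.Series,
    surv: pd.DataFrame,
    covariates: tuple[str, ...] = (),
) -> CoxResult:
    """Cox PH fit of survival on the (unit-SD standardized) index.

    *surv* is indexed by sample with columns ``time`` (positive, days)
    and ``event`` (0 censored / 1 event), plus any requested covariate
    columns (``age`` numeric, ``stage`` ordinal I=1..IV=4).
    """
    surv = _validate_survival(surv)
    shared = [s for s in surv.index if s in index.index]
    df = surv.loc[shared, ["time", "event", *covariates]].copy()
    sd = index.loc[shared].std()
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError("index has zero variance; Cox fit undefined")
    df["index"] = (index.loc[shared] - index.loc[shared].mean()) / sd
    n_events = int(df["event"].sum())
    if n_events < 10:
        raise ValidationError(f"only {n_events} events; need >= 10")

    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises various convergence errors
        raise ValidationError(f"Cox model failed to converge: {exc}") from exc
    row = cph.summary.loc["index"]
    return CoxResult(
        hazard_ratio=float(np.exp(row["coef"])),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        pvalue=float(row["p"]),
        log_hr=float(row["coef"]),
        log_hr_se=float(row["se(coef)"]),
        covariates=tuple(covariates),
        n=len(df),
        n_events=n_events,
    )


def km_groups(index: pd.Series) -> pd.Series:
    """Median split into ``low`` (< median) and ``high`` (>= median) groups.

    With odd n (no ties) the high group receives the extra member, since
    the median itself lands in ``high``.
    """
    if len(index) < 4:
        raise ValidationError("median split needs at least 4 samples")
    if index.nunique() == 1:
        raise ValidationError("all index values identical; cannot split")
    med = index.median()
    out = pd.Series(np.where(index < med, "low", "high"), index=index.index,
                    name="group")
    return out


def marker_correlation_shift(
    expr: BulkExpressionMatrix | pd.DataFrame,
    index: pd.Series,
    markers: frozenset[str] | set[str],
) -> dict:
    """Test whether marker genes correlate with the index more than the rest.

    Pearson r is computed per gene across samples; the marker r
    distribution is compared with the all-other-genes baseline by a
    two-sided Mann-Whitney U test.  Returns the U statistic, p-value, a
    direction flag (+1 markers above baseline, -1 below), and both r
    distributions.
    """
    values = expr.values if isinstance(expr, BulkExpressionMatrix) else expr
    samples = [s for s in values.index if s in index.index]
    if len(samples) < 3:
        raise ValidationError("correlation shift needs at least 3 samples")
    present = [g for g in markers if g in values.columns]
    absent = sorted(set(markers) - set(present))
    if len(present) < 2:
        raise ValidationError(f"markers absent from expression table: {absent}")
    if absent:
        logger.info("marker_correlation_shift: %d markers absent: %s",
                    len(absent), absent[:5])

    x = values.loc[samples].to_numpy()
    y = index.loc[samples].to_numpy()
    sd = x.std(axis=0)
    keep = sd > 0
    xc = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    yc = (y - y.mean()) / y.std()
    r = pd.Series((xc * yc[:, None]).mean(axis=0), index=values.columns[keep])

    marker_r = r.loc[[g for g in present if g in r.index]]
    baseline_r = r.drop(marker_r.index)
    if len(marker_r) < 2 or len(baseline_r) < 1:
        raise ValidationError("not enough non-constant genes for the shift test")
    stat = scipy.stats.mannwhitneyu(marker_r, baseline_r, alternative="two-sided")
    direction = 1 if marker_r.median() > baseline_r.median() else -1
    return {
        "u_stat": float(stat.statistic),
        "pvalue": float(stat.pvalue),
        "direction": direction,
        "marker_r": marker_r,
        "baseline_r": baseline_r,
    }


def dependency_enrichment(
    dep: pd.Series,
    rho: pd.Series,
    essential_threshold: float = DEFAULT_ESSENTIAL_THRESHOLD,
) -> dict:
    """Fisher's exact test: essentiality vs sign of index correlation.

    Genes with CERES score strictly below the threshold are essential;
    genes with rho exactly 0 are excluded.  The odds ratio is the
    cross-product ratio of the 2x2 table
    [[essential & rho>0, non-essential & rho>0],
     [essential & rho<0, non-essential & rho<0]].
    """
    shared = [g for g in dep.index if g in rho.index]
    d = dep.loc[shared]
    r = rho.loc[shared]
    if not np.isfinite(d).all():
        raise ValidationError("dependency scores contain non-finite values")
    nonzero = r != 0
    d, r = d[nonzero], r[nonzero]
    pos, neg = r > 0, r < 0
    if not pos.any() or not neg.any():
        raise ValidationError("need genes in both correlation-sign groups")
    essential = d < essential_threshold
    table = np.array([
        [int((essential & pos).sum()), int((~essential & pos).sum())],
        [int((essential & neg).sum()), int((~essential & neg).sum())],
    ])
    degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    if degenerate or table[0, 1] * table[1, 0] == 0:
        odds_ratio = float("nan") if degenerate or table[1, 0] == 0 or table[0, 1] == 0 \
            else float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
    else:
        odds_ratio = float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
    p = float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])
    return {
        "odds_ratio": odds_ratio,
        "pvalue": p,
        "table": table,
        "degenerate": bool(degenerate),
    }


#: below this many lines the Spearman p-value is computed by exhausting
#: all rank permutations instead of the t approximation
_EXACT_SPEARMAN_LIMIT = 8


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    import itertools

    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    count = total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def drug_response_correlation(
    index: pd.Series,
    auc: pd.DataFrame,
    min_lines: int = 5,
) -> pd.DataFrame:
    """Spearman correlation between the index and per-drug response AUC.

    *auc* is cell lines x drugs (NaN = not profiled).  Drugs with fewer
    than *min_lines* overlapping lines are skipped with a log entry.
    For very small overlaps (<= 8 lines) the two-sided p-value comes from
    full enumeration of rank permutations; otherwise from the usual
    large-sample approximation.  Returns a drug-indexed DataFrame with
    ``rho``, ``pvalue``, ``n`` and BH ``fdr``.
    """
    rows = []
    for drug in auc.columns:
        series = auc[drug].dropna()
        shared = [s for s in series.index if s in index.index]
        if len(shared) < min_lines:
            logger.info("drug_response_correlation: %r skipped (%d lines)",
                        drug, len(shared))
            continue
        x = index.loc[shared].to_numpy()
        y = series.loc[shared].to_numpy()
        res = scipy.stats.spearmanr(x, y)
        rho = float(res.statistic)
        if len(shared) <= _EXACT_SPEARMAN_LIMIT and abs(rho) < 1.0:
            p = _exact_spearman_p(x, y, rho)
        else:
            p = float(res.pvalue)
        rows.append({"drug": drug, "rho": rho, "pvalue": p, "n": len(shared)})
    if not rows:
        raise ValidationError("no drug has enough overlapping cell lines")
    out = pd.DataFrame(rows).set_index("drug")
    out["fdr"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out
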
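"""Cohort-level descriptive and inferential statistics.

Covers the analysis patterns used downstream of scoring and CMS
classification: pairwise-complete Spearman/Pearson correlation matrices,
Mann-Whitney / Welch two-group comparisons, the Cochran-Armitage chi-square
test for trend across ordered categories, median-split quadrant summaries of
paired standardized scores, and a cross-tabulation of CMS classes against
clinical variables with the denominators a clinical summary table uses
(grand total for class percentages; samples with known sex / site for those
columns; primary tumors for stage percentages).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "ClinicalTable",
    "CorrelationMatrix",
    "StatsError",
    "correlation_matrix",
    "two_group_test",
    "trend_test",
    "median_split_quadrants",
    "table_one",
    "round_half_up",
]

CLINICAL_COLUMNS = {
    "age",
    "sex",
    "site_type",
    "site_subtype",
    "stage",
    "os_time",
    "os_event",
    "kras",
    "nras",
    "braf_v600e",
    "apc",
    "tp53",
    "msi",
}

STAGES = ("I", "II", "III", "IV", "NA")


class StatsError(ValueError):
    pass


@dataclass
class ClinicalTable:
    """Validated per-sample clinical annotations.

    ``df`` is indexed by sample id. Recognized columns (all optional except
    when an analysis needs them): age, sex (F/M), site_type
    (primary/metastatic), site_subtype (regional/distant for metastatic,
    recurrent/other for primary), stage (I..IV, NA; primaries only),
    os_time (days), os_event (bool), mutation flags kras/nras/braf_v600e/
    apc/tp53, msi (MSI/MSS/NA).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise StatsError("duplicate sample ids in clinical table")
        if "os_time" in self.df:
            t = self.df["os_time"].dropna()
            if (t < 0).any():
                raise StatsError("os_time must be non-negative")
            if "os_event" not in self.df or self.df.loc[t.index, "os_event"].isna().any():
                raise StatsError("os_event must be defined wherever os_time is")
        if "stage" in self.df and "site_type" in self.df:
            staged = self.df["stage"].notna() & (self.df["stage"] != "NA")
            if (self.df.loc[staged, "site_type"] == "metastatic").any():
                raise StatsError("stage must only be defined for primary samples")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 -> 0.1), matching printed-table style."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CorrelationMatrix:
    """Symmetric correlation estimate with per-pair p-values and sample sizes."""

    variables: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    method: str


def correlation_matrix(data: pd.DataFrame, method: str = "spearman") -> CorrelationMatrix:
    """Pairwise-complete correlation matrix over the columns of ``data``.

    Spearman uses rank correlation with tie correction; Pearson is
    product-moment. Two-sided p-values come from the t approximation.
    Pairs involving a constant column are reported as missing (NaN), not 0.
    """
    if method not in ("spearman", "pearson"):
        raise StatsError(f"unknown correlation method {method!r}")
    cols = list(data.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    func = sps.spearmanr if method == "spearman" else sps.pearsonr
    for i in range(k):
        for j in range(i, k):
            pair = data.iloc[:, [i, j]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < 3:
                continue
            x, y = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                if i == j and np.ptp(x) != 0:
                    rho[i, j] = 1.0
                continue  # undefined for constant columns: left missing
            if i == j:
                rho[i, j], p[i, j] = 1.0, 0.0
                continue
            r, pv = func(x, y)
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    idx = pd.Index(cols)
    return CorrelationMatrix(
        variables=cols,
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        method=method,
    )


def two_group_test(
    values,
    groups,
    test: str = "mann_whitney",
    exact_cutoff: int = 20,
) -> tuple[float, float]:
    """Two-sided two-group comparison; returns (statistic, p).

    ``test="mann_whitney"`` uses exact enumeration when n1+n2 <= exact_cutoff
    and there are no ties, otherwise the normal approximation with tie
    correction. ``test="welch_t"`` is the unequal-variance t test. Invariant
    to swapping group labels.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise StatsError(f"expected exactly 2 group labels, got {len(labels)}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) == 0 or len(b) == 0:
        raise StatsError("both groups must be non-empty")
    if test == "welch_t":
        if len(a) < 2 or len(b) < 2:
            raise StatsError("welch_t needs n >= 2 per group")
        stat, p = sps.ttest_ind(a, b, equal_var=False)
    elif test == "mann_whitney":
        if len(a) + len(b) < 3:
            raise StatsError("mann_whitney needs total n >= 3")
        ties = len(np.unique(values)) < len(values)
        method = "exact" if (len(a) + len(b) <= exact_cutoff and not ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = res.statistic, res.pvalue
    else:
        raise StatsError(f"unknown test {test!r}")
    return float(stat), float(min(p, 1.0))


def _trend_statistic(successes, totals, scores) -> float:
    a = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    s = np.asarray(scores, dtype=float)
    N, A = n.sum(), a.sum()
    if A == 0 or A == N:
        return 0.0
    sbar = (n * s).sum() / N
    u = (s * a).sum() - A * sbar
    # finite-population (permutation) variance of the score sum of successes
    sigma2 = (n * (s - sbar) ** 2).sum() / N
    var = A * (N - A) / (N - 1.0) * sigma2
    if var <= 0:
        return 0.0
    return float(u * u / var)


def trend_test(
    table, scores=None, method: str = "asymptotic"
) -> tuple[float, float]:
    """Cochran-Armitage chi-square test for trend on a 2 x k ordered table.

    ``table`` rows are (successes, failures) across k >= 3 ordered
    categories; ``scores`` default to 1..k. The statistic uses the exact
    permutation variance, so the asymptotic branch (1-df chi-square) and the
    exact branch (exhaustive enumeration of the conditional
    multivariate-hypergeometric null, i.e. the limit of label shuffling)
    share the same statistic. Returns (statistic, two-sided p).
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] != 2 or tab.shape[1] < 3:
        raise StatsError("trend_test expects a 2 x k table with k >= 3")
    if (tab < 0).any():
        raise StatsError("counts must be non-negative")
    totals = tab.sum(axis=0)
    if (totals == 0).any():
        raise StatsError("every category must have a non-zero total")
    k = tab.shape[1]
    scores = np.arange(1, k + 1, dtype=float) if scores is None else np.asarray(scores, float)
    if len(scores) != k:
        raise StatsError("scores length must match number of categories")
    a = tab[0]
    stat = _trend_statistic(a, totals, scores)
    if method == "asymptotic":
        p = float(sps.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    elif method == "exact":
        p = _trend_exact_p(a, totals, scores, stat)
    else:
        raise StatsError(f"unknown method {method!r}")
    return stat, float(min(p, 1.0))


def _trend_exact_p(a_obs, totals, scores, stat_obs) -> float:
    """Exact conditional p: sum of multivariate-hypergeometric probabilities of
    all tables (same margins) whose trend statistic >= the observed one."""
    totals = np.asarray(totals, dtype=int)
    A = int(np.asarray(a_obs).sum())
    N = int(totals.sum())
    log_denom = _log_comb(N, A)
    p = 0.0
    eps = 1e-12
    for alloc in _allocations(totals, A):
        stat = _trend_statistic(np.asarray(alloc, float), totals, scores)
        if stat >= stat_obs - eps:
            log_num = sum(_log_comb(n_i, a_i) for n_i, a_i in zip(totals, alloc))
            p += np.exp(log_num - log_denom)
    return min(p, 1.0)


def _log_comb(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def _allocations(totals, A):
    """All ways to split A successes across categories with caps ``totals``."""
    k = len(totals)

    def rec(i: int, remaining: int, prefix: tuple):
        if i == k - 1:
            if remaining <= totals[i]:
                yield prefix + (remaining,)
            return
        tail_cap = int(np.sum(totals[i + 1:]))
        lo = max(0, remaining - tail_cap)
        hi = min(int(totals[i]), remaining)
        for a_i in range(lo, hi + 1):
            yield from rec(i + 1, remaining - a_i, prefix + (a_i,))

    yield from rec(0, int(A), ())


QUADRANT_LABELS = ("RUQ", "RLQ", "LUQ", "LLQ")


def median_split_quadrants(x: pd.Series, y: pd.Series):
    """Quadrant labels for paired standardized scores split at zero.

    R/L is x > 0 / x <= 0, U/L is y > 0 / y <= 0 (zeros go left/lower,
    consistent with the boundary-low rule elsewhere). Returns
    (per-sample labels, 2x2 count table with rows upper/lower and columns
    right/left) suitable for enrichment tests.
    """
    if len(x) != len(y):
        raise StatsError("x and y must have equal length")
    xs = np.asarray(x, dtype=float)
    ys = np.asarray(y, dtype=float)
    right = xs > 0
    upper = ys > 0
    labels = np.where(
        right & upper, "RUQ", np.where(right, "RLQ", np.where(upper, "LUQ", "LLQ"))
    )
    counts = pd.DataFrame(
        [
            [int((right & upper).sum()), int((~right & upper).sum())],
            [int((right & ~upper).sum()), int((~right & ~upper).sum())],
        ],
        index=pd.Index(["upper", "lower"]),
        columns=pd.Index(["right", "left"]),
    )
    idx = x.index if isinstance(x, pd.Series) else None
    return pd.Series(labels, index=idx, name="quadrant"), counts


def _fmt(n: int, pct: float) -> str:
    return f"{n} ({round_half_up(pct, 1):.1f})"


def table_one(clinical: ClinicalTable | pd.DataFrame, cms_labels: pd.Series) -> pd.DataFrame:
    """Cross-tabulate CMS classes against sex, site and primary stage.

    Rows: CMS1..CMS4, CMS-NA, Total. Percentages use the denominators a
    clinical summary table reports: class N over the grand total; sex over
    samples with known sex; metastatic/primary over samples with known site;
    stages over the number of primary tumors. Cells are formatted
    ``"N (pct)"`` with half-up rounding to one decimal; numeric companions
    are returned in ``.attrs["counts"]`` and ``.attrs["percentages"]``.
    """
    df = clinical.df if isinstance(clinical, ClinicalTable) else clinical
    cms = cms_labels.reindex(df.index).fillna("NA")
    cms = cms.replace({"NA": "CMS-NA"})
    row_order = ["CMS1", "CMS2", "CMS3", "CMS4", "CMS-NA", "Total"]

    grand = len(df)
    sex = df.get("sex", pd.Series(index=df.index, dtype=object))
    site = df.get("site_type", pd.Series(index=df.index, dtype=object))
    stage = df.get("stage", pd.Series(index=df.index, dtype=object))
    n_sex = int(sex.notna().sum())
    n_site = int(site.notna().sum())
    n_primary = int((site == "primary").sum())

    counts: dict[str, dict[str, int]] = {}
    for row in row_order:
        mask = (cms == row) if row != "Total" else pd.Series(True, index=df.index)
        sub_sex = sex[mask]
        sub_site = site[mask]
        is_primary = mask & (site == "primary")
        sub_stage = stage[is_primary]
        rec = {
            "N": int(mask.sum()),
            "F": int((sub_sex == "F").sum()),
            "M": int((sub_sex == "M").sum()),
            "Metastatic": int((sub_site == "metastatic").sum()),
            "Primary": int((sub_site == "primary").sum()),
        }
        for st in STAGES[:-1]:
            rec[f"Stage {st}"] = int((sub_stage == st).sum())
        rec["Stage NA"] = int((sub_stage.isna() | (sub_stage == "NA")).sum())
        counts[row] = rec

    denoms = {
        "N": grand,
        "F": n_sex,
        "M": n_sex,
        "Metastatic": n_site,
        "Primary": n_site,
        **{f"Stage {st}": n_primary for st in STAGES},
    }
    count_df = pd.DataFrame(counts).T.loc[row_order]
    pct_df = pd.DataFrame(
        {
            col: [
                100.0 * count_df.loc[row, col] / denoms[col] if denoms[col] else np.nan
                for row in row_order
            ]
            for col in count_df.columns
        },
        index=count_df.index,
    )
    formatted = pd.DataFrame(
        {
            col: [_fmt(int(count_df.loc[r, col]), pct_df.loc[r, col]) for r in row_order]
            for col in count_df.columns
        },
        index=count_df.index,
    )
    formatted.attrs["counts"] = count_df
    formatted.attrs["percentages"] = pct_df.map(lambda v: round_half_up(v, 1))
    formatted.attrs["denominators"] = denoms
    return formatted
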
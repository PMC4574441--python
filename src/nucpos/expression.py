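"""Microarray-style expression profiling downstream of a normalized log matrix.

The input is a probe x sample matrix of log2-scale normalized intensities
(e.g., RMA output) with >= 2 replicates per condition.  Per probe and
condition, aberrant replicates are removed by a single-pass Nalimov outlier
test (p = 0.001); fold changes are ratios of antilog replicate means;
significance combines an across-conditions ANOVA with unpaired two-sided
t-tests per condition pair, computed on the log scale (variance stabilized).
Probes collapse to genes by the maximally regulated probe, and gene values
aggregate to BAC probes and to 1 / 2.5 Mbp genomic neighborhoods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: selection threshold on the pairwise t-test p-value
DEFAULT_SELECTION_P = 4e-6

#: significance threshold of the Nalimov outlier stage
DEFAULT_NALIMOV_ALPHA = 0.001


# ---------------------------------------------------------------------------
# Nalimov outlier test
# ---------------------------------------------------------------------------


def nalimov_critical(n: int, alpha: float = DEFAULT_NALIMOV_ALPHA) -> float:
    """Critical value of the Nalimov studentized-extreme-deviation statistic.

    Closed form ``sqrt(n-1) * t / sqrt(n-2 + t^2)`` with
    ``t = t_{1-alpha/2, n-2}``, which reproduces the classical printed tables
    (e.g., 1.757 / 1.918 / 1.982 for n = 5 at alpha = 0.05 / 0.01 / 0.001) to
    their three decimals.  Note the statistic itself is bounded by
    ``sqrt(n-1)``, so at small n the alpha = 0.001 critical value sits close
    to the attainable maximum.
    """
    if n < 3:
        raise ValueError("Nalimov test requires n >= 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    t = sps.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(np.sqrt(n - 1) * t / np.sqrt(n - 2 + t * t))


def nalimov_statistic(values: np.ndarray) -> tuple[float, int]:
    """Nalimov q of the most extreme value: ``|x*-mean|/s * sqrt(n/(n-1))``."""
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    s = x.std(ddof=1)
    if s == 0:
        return 0.0, int(0)
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    return float(dev[idx] / s * np.sqrt(n / (n - 1))), idx


def nalimov_filter(values, alpha: float = DEFAULT_NALIMOV_ALPHA):
    """Single-pass Nalimov outlier removal on a small replicate set.

    Tests only the most extreme value and removes it if its q statistic
    exceeds the critical value at ``alpha``; no re-iteration (with five
    replicates, iterated removal risks emptying the group).  With n < 3 no
    test is performed and everything is kept (variance-based testing is
    undefined); constant replicates (s = 0) are kept as a logged degenerate
    case.

    Returns ``(kept_values, excluded_indices)``.
    """
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    if n < 3:
        logger.info("nalimov_filter: n=%d < 3, no test performed", n)
        return x.copy(), np.array([], dtype=int)
    q, idx = nalimov_statistic(x)
    if x.std(ddof=1) == 0:
        logger.info("nalimov_filter: zero variance, degenerate case, all values kept")
        return x.copy(), np.array([], dtype=int)
    if q > nalimov_critical(n, alpha):
        keep = np.ones(n, dtype=bool)
        keep[idx] = False
        return x[keep], np.array([idx], dtype=int)
    return x.copy(), np.array([], dtype=int)


# ---------------------------------------------------------------------------
# fold changes and significance
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Probe x sample log2-scale matrix plus sample and probe annotation.

    ``sample_conditions`` maps each sample (column) to exactly one condition
    label; every condition must have at least two replicates.  ``probe_map``
    carries probe_id -> gene_id plus genomic coordinates (chrom, start, end;
    0-based half-open).
    """

    values: pd.DataFrame
    sample_conditions: pd.Series
    probe_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_conditions = pd.Series(self.sample_conditions)
        missing = set(self.values.columns) - set(self.sample_conditions.index)
        if missing:
            raise ValueError(f"samples without a condition label: {sorted(missing)}")
        counts = self.sample_conditions.loc[list(self.values.columns)].value_counts()
        thin = counts[counts < 2]
        if not thin.empty:
            raise ValueError(
                f"conditions with fewer than 2 replicates: {thin.index.tolist()}"
            )

    def replicates(self, condition: str) -> pd.DataFrame:
        cols = [c for c in self.values.columns if self.sample_conditions[c] == condition]
        if not cols:
            raise KeyError(f"condition {condition!r} absent from the sample sheet")
        return self.values[cols]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.values.columns:
            cond = self.sample_conditions[c]
            if cond not in seen:
                seen.append(cond)
        return seen


def fold_change(
    matrix: ExpressionMatrix,
    condition_a: str,
    condition_b: str,
    nalimov_alpha: float = DEFAULT_NALIMOV_ALPHA,
) -> pd.DataFrame:
    """Per-probe fold change b/a with t-test and across-conditions ANOVA p-values.

    Per condition, replicates pass the Nalimov stage first.  The fold change
    is the ratio of antilog (2^x) replicate means; the unpaired two-sided
    t-test runs on the kept log-scale values, as does the one-way ANOVA over
    all conditions.  Returns a DataFrame indexed by probe with columns
    fold_change, log2fc, t_p, anova_p, n_excluded.
    """
    reps_a = matrix.replicates(condition_a)
    reps_b = matrix.replicates(condition_b)
    all_conditions = matrix.conditions
    rows = []
    for probe in matrix.values.index:
        kept = {}
        n_excluded = 0
        for cond in all_conditions:
            vals = matrix.replicates(cond).loc[probe].to_numpy(dtype=np.float64)
            k, excl = nalimov_filter(vals, alpha=nalimov_alpha)
            kept[cond] = k
            n_excluded += excl.size
        a, b = kept[condition_a], kept[condition_b]
        fc = float(np.mean(2.0 ** b) / np.mean(2.0 ** a))
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t_p = 0.0 if a.mean() != b.mean() else 1.0
        else:
            t_p = float(sps.ttest_ind(a, b, equal_var=True).pvalue)
        groups = [kept[c] for c in all_conditions if kept[c].size >= 2]
        if len(groups) >= 2 and any(g.std(ddof=1) > 0 for g in groups):
            anova_p = float(sps.f_oneway(*groups).pvalue)
        else:
            anova_p = np.nan
        rows.append(
            {"probe_id": probe, "fold_change": fc, "log2fc": float(np.log2(fc)),
             "t_p": t_p, "anova_p": anova_p, "n_excluded": n_excluded}
        )
    _ = reps_a, reps_b
    return pd.DataFrame(rows).set_index("probe_id")


def select_significant(records: pd.DataFrame, p_threshold: float = DEFAULT_SELECTION_P) -> pd.DataFrame:
    """Flag records whose pairwise t-test p-value is at or below the threshold."""
    out = records.copy()
    out["selected"] = out["t_p"] <= p_threshold
    return out


def collapse_to_gene(records: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-probe records to one record per gene.

    Keeps the maximally regulated probe (largest ``|log2fc|``); ties prefer
    the smaller t-test p-value, then the lexicographically smallest probe id.
    Genes with zero probes are simply absent.
    """
    joined = records.join(probe_map.set_index("probe_id")["gene_id"], how="inner")
    joined = joined.reset_index().rename(columns={"index": "probe_id"})
    joined["_abs_fc"] = joined["log2fc"].abs()
    joined = joined.sort_values(
        by=["_abs_fc", "t_p", "probe_id"], ascending=[False, True, True], kind="mergesort"
    )
    best = joined.groupby("gene_id", sort=True).head(1).drop(columns="_abs_fc")
    return best.set_index("gene_id").sort_index()


# ---------------------------------------------------------------------------
# genomic aggregation
# ---------------------------------------------------------------------------


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def bac_expression(
    gene_records: pd.DataFrame,
    bac: tuple[str, int, int],
) -> tuple[float, pd.DataFrame]:
    """Cumulative expression value of a BAC probe interval.

    ``gene_records`` needs chrom/start/end coordinates plus a ``value`` column
    (maximum per-gene fold change).  Genes partially inside the BAC are
    weighted by the overlapping fraction of the *gene* length; the BAC value
    is the mean of the weighted values over all overlapping genes.  Also
    returns a per-gene table with the percent overlap of each transcript with
    the BAC and of the BAC covered by the transcript.

    A BAC overlapping zero genes yields NaN (missing, logged).
    """
    chrom, b_start, b_end = bac
    if b_end <= b_start:
        raise ValueError("BAC interval must have end > start")
    rows = []
    for gene_id, rec in gene_records.iterrows():
        if rec["chrom"] != chrom:
            continue
        ov = _overlap(int(rec["start"]), int(rec["end"]), b_start, b_end)
        if ov == 0:
            continue
        gene_len = int(rec["end"]) - int(rec["start"])
        frac = ov / gene_len
        rows.append(
            {
                "gene_id": gene_id,
                "overlap_bp": ov,
                "gene_overlap_fraction": frac,
                "pct_transcript_in_bac": 100.0 * frac,
                "pct_bac_covered": 100.0 * ov / (b_end - b_start),
                "value": rec["value"],
                "weighted_value": frac * rec["value"],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "overlap_bp", "gene_overlap_fraction",
                 "pct_transcript_in_bac", "pct_bac_covered", "value", "weighted_value"],
    )
    if table.empty:
        logger.info("bac_expression: BAC %s:%d-%d overlaps no genes; value missing",
                    chrom, b_start, b_end)
        return float("nan"), table
    return float(table["weighted_value"].mean()), table


def neighborhood_expression(
    gene_records: pd.DataFrame,
    center_gene: str,
    half_width: int,
    chrom_length: int | None = None,
    value_column: str = "value",
) -> float:
    """Mean expression value over genes overlapping a window around a gene center.

    The window is ``[center - half_width, center + half_width)`` anchored at
    the midpoint of the center gene's span (rounded down); half_width is
    1 Mbp for the 2-Mbp scale and 2.5 Mbp for the 5-Mbp scale.  Windows
    reaching past the chromosome ends are truncated with a logged note.
    """
    if center_gene not in gene_records.index:
        raise KeyError(f"center gene {center_gene!r} absent from records")
    rec = gene_records.loc[center_gene]
    center = (int(rec["start"]) + int(rec["end"])) // 2
    w_start, w_end = center - half_width, center + half_width
    if w_start < 0 or (chrom_length is not None and w_end > chrom_length):
        logger.info("neighborhood window of %s truncated at chromosome edge", center_gene)
        w_start = max(0, w_start)
        if chrom_length is not None:
            w_end = min(chrom_length, w_end)
    sel = gene_records[
        (gene_records["chrom"] == rec["chrom"])
        & (gene_records["end"] > w_start)
        & (gene_records["start"] < w_end)
    ]
    return float(sel[value_column].mean())


def volcano_table(records: pd.DataFrame, p_column: str = "t_p") -> pd.DataFrame:
    """Fold change vs -log10 p pairs for volcano plotting (no plotting here).

    p = 0 is clamped to the smallest positive float with a logged note.
    """
    p = records[p_column].to_numpy(dtype=np.float64).copy()
    zero = p == 0
    if zero.any():
        logger.info("volcano_table: %d zero p-values clamped to machine minimum", zero.sum())
        p[zero] = np.finfo(np.float64).tiny
    return pd.DataFrame(
        {"fold_change": records["fold_change"].to_numpy(),
         "neg_log10_p": -np.log10(p)},
        index=records.index,
    )
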
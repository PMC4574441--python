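"""Statistical core: chi-square randomness test and Pearson correlation reports.

Two questions drive the analysis.  First, is a gene's normalized position
random?  Under the per-nucleus ECDF normalization a randomly placed locus is
uniform on [0, 1], so binning normalized distances in 0.25 steps gives an
expected relative frequency of 25% per bin; divergence is scored with a
chi-square statistic on the four bins (df = 3).  Second, does positioning
(or repositioning) track gene expression or genomic context?  That is scored
with Pearson's product-moment correlation, a two-sided t-based p-value and a
Fisher z confidence interval at the 0.95 level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: 0.25-wide bins partitioning [0, 1]; the last bin is right-closed
BIN_EDGES = np.array([0.0, 0.25, 0.5, 0.75, 1.0])

DEFAULT_ALPHA = 0.05
DEFAULT_CONFIDENCE = 0.95


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (zero variance in an input)."""


@dataclass(frozen=True)
class RandomnessResult:
    """Chi-square test of one gene/condition/compartment against uniformity."""

    observed: np.ndarray
    expected: float
    chi2: float
    df: int
    p_value: float
    alpha: float
    gene_id: str = ""
    condition: str = ""
    compartment: str = ""

    @property
    def n(self) -> int:
        return int(self.observed.sum())

    @property
    def verdict(self) -> str:
        return "nonrandom" if self.p_value <= self.alpha else "random"


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson R with confidence interval and p-value for one report cell."""

    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    confidence: float = DEFAULT_CONFIDENCE
    labels: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = dict(self.labels)
        row.update(
            {"r": self.r, "ci_low": self.ci_low, "ci_high": self.ci_high,
             "p_value": self.p_value, "n": self.n}
        )
        return row


def randomness_test(
    values,
    alpha: float = DEFAULT_ALPHA,
    gene_id: str = "",
    condition: str = "",
    compartment: str = "",
) -> RandomnessResult:
    """Chi-square test of binned normalized distances against 25% per bin.

    ``chi2 = sum((O_i - E_i)^2 / E_i)`` with ``E_i = n / 4``; p from the
    chi-square distribution with 3 degrees of freedom.
    """
    vals = np.asarray(values, dtype=np.float64)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("randomness_test: empty input")
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("normalized distances must lie in [0, 1]")
    if vals.size < 8:
        logger.warning(
            "randomness_test: n=%d is below the expected-count validity benchmark of 8",
            vals.size,
        )
    observed, _ = np.histogram(vals, bins=BIN_EDGES)
    expected = vals.size / 4.0
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=3))
    return RandomnessResult(
        observed=observed, expected=expected, chi2=chi2, df=3, p_value=p,
        alpha=alpha, gene_id=gene_id, condition=condition, compartment=compartment,
    )


def pearson(
    x,
    y,
    confidence: float = DEFAULT_CONFIDENCE,
    one_sided: bool = False,
    labels: dict | None = None,
) -> CorrelationResult:
    """Pearson product-moment correlation with p-value and Fisher z CI.

    R is computed from centered sums of products; the two-sided p-value comes
    from ``t = R * sqrt((n-2) / (1-R^2))`` with n-2 degrees of freedom; the
    confidence interval uses the Fisher z-transform with standard error
    ``1/sqrt(n-3)``.  With ``one_sided=True`` the interval is open toward the
    side away from R's sign (upper bound 1 for R >= 0, lower bound -1
    otherwise), the convention seen in single-direction reporting.

    Zero variance in either input raises :class:`UndefinedCorrelationError`
    rather than returning R = 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired values, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    r = float(dx @ dy / np.sqrt(sxx * syy))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        if one_sided:
            zc = sps.norm.ppf(confidence)
            lo, hi = (np.tanh(z - zc * se), 1.0) if r >= 0 else (-1.0, np.tanh(z + zc * se))
        else:
            zc = sps.norm.ppf(0.5 + confidence / 2.0)
            lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    else:
        lo, hi = -1.0, 1.0  # degenerate: n = 3 (infinite Fisher SE) or |R| = 1
    return CorrelationResult(
        r=r, ci_low=float(lo), ci_high=float(hi), p_value=p, n=n,
        confidence=confidence, labels=labels or {},
    )


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def correlate_repositioning(
    delta_pos: pd.DataFrame,
    delta_expr: pd.DataFrame,
    scale: str = "gene",
    system: str = "",
    expr_column: str = "log2fc",
    confidence: float = DEFAULT_CONFIDENCE,
    one_sided: bool = False,
) -> list[CorrelationResult]:
    """Correlate per-gene repositioning (ΔD) with expression change, per compartment.

    ``delta_pos`` is the output of :func:`nucpos.mcnorm.delta_position`
    (possibly concatenated over compartments); ``delta_expr`` must carry
    gene_id plus ``expr_column`` (signed log2 fold change by default, so a
    positive R means up-regulated genes move away from the compartment — the
    silencing-compartment direction).  Cells with fewer than 3 paired genes
    are skipped with a logged reason.
    """
    results = []
    expr = delta_expr.set_index("gene_id")[expr_column]
    for compartment, group in delta_pos.groupby("compartment", sort=True):
        merged = group.set_index("gene_id").join(expr, how="inner").dropna(
            subset=["delta", expr_column]
        )
        labels = {"scale": scale, "system": system, "compartment": compartment}
        if len(merged) < 3:
            logger.info("correlate_repositioning: %s has %d paired genes (<3); skipped",
                        labels, len(merged))
            continue
        try:
            results.append(
                pearson(merged[expr_column], merged["delta"], confidence=confidence,
                        one_sided=one_sided, labels=labels)
            )
        except UndefinedCorrelationError as err:
            logger.warning("correlate_repositioning: %s undefined (%s)", labels, err)
            raise
    return results


#: RIDGE feature columns of a WindowFeatures table, and whether each is a
#: RIDGE (True) or anti-RIDGE (False) marker
RIDGE_FEATURES = {
    "n_cpg_islands": True,
    "gc_fraction": True,
    "n_genes": True,
    "sine_coverage": True,
    "line_coverage": False,
}


def correlate_position_features(
    positions: pd.DataFrame,
    features: pd.DataFrame,
    condition: str = "",
    feature_columns=None,
    confidence: float = DEFAULT_CONFIDENCE,
    one_sided: bool = False,
) -> list[CorrelationResult]:
    """Correlate mean normalized distances with RIDGE/anti-RIDGE window features.

    ``positions`` needs columns gene_id, compartment and ``mean_norm`` (mean
    normalized distance of the gene in one condition); ``features`` is a
    per-gene WindowFeatures table.  Positive R means high feature values sit
    farther from the compartment.
    """
    feature_columns = list(feature_columns or RIDGE_FEATURES)
    results = []
    feats = features.set_index("gene_id")
    for compartment, group in positions.groupby("compartment", sort=True):
        merged = group.set_index("gene_id").join(feats, how="inner")
        for feat in feature_columns:
            labels = {
                "condition": condition, "compartment": compartment, "feature": feat,
                "marker": "RIDGE" if RIDGE_FEATURES.get(feat, True) else "anti-RIDGE",
            }
            sub = merged.dropna(subset=["mean_norm", feat])
            if len(sub) < 3:
                logger.info("correlate_position_features: %s has n=%d (<3); skipped",
                            labels, len(sub))
                continue
            results.append(
                pearson(sub[feat], sub["mean_norm"], confidence=confidence,
                        one_sided=one_sided, labels=labels)
            )
    return results


def results_to_frame(results: list[CorrelationResult], adjust: bool = True) -> pd.DataFrame:
    """Tabulate correlation results; optionally append a Benjamini-Hochberg column.

    The BH-adjusted column is supplementary output (the per-cell reports are
    intentionally unadjusted); it is clearly labeled ``p_bh_supplementary``.
    """
    df = pd.DataFrame([r.as_row() for r in results])
    if adjust and not df.empty:
        from statsmodels.stats.multitest import multipletests

        df["p_bh_supplementary"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
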
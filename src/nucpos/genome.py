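"""RIDGE/anti-RIDGE genomic context: CpG islands, GC, gene density, SINE/LINE coverage.

Regions of increased gene expression (RIDGEs) are marked by high gene
density, many CpG islands, high GC, dense SINE coverage and sparse LINE
coverage; anti-RIDGEs show the opposite profile.  This module scores those
five features over windows centered on genes (2 Mbp and 5 Mbp wide: 1 or
2.5 Mbp up- and downstream of the gene midpoint).

Coordinates are 0-based half-open throughout; BED input follows the same
convention.  CpG islands follow the three-threshold definition: length >=
500 bp, GC fraction >= 0.5 and observed/expected CpG ratio >= 0.6, with the
Gardiner-Garden & Frommer form ``obs/exp = N_CpG * L / (N_C * N_G)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

CPG_MIN_LENGTH = 500
CPG_MIN_GC = 0.5
CPG_MIN_OBS_EXP = 0.6


@dataclass(frozen=True)
class CpGIsland:
    chrom: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_ratio: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomicWindow:
    """A gene-centered genomic window (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    gene_id: str
    half_width: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WindowFeatures:
    window: GenomicWindow
    n_genes: int
    n_cpg_islands: int
    gc_fraction: float
    sine_coverage: float
    line_coverage: float

    def as_row(self) -> dict:
        return {
            "gene_id": self.window.gene_id,
            "chrom": self.window.chrom,
            "window_start": self.window.start,
            "window_end": self.window.end,
            "half_width": self.window.half_width,
            "n_genes": self.n_genes,
            "n_cpg_islands": self.n_cpg_islands,
            "gc_fraction": self.gc_fraction,
            "sine_coverage": self.sine_coverage,
            "line_coverage": self.line_coverage,
        }


# ---------------------------------------------------------------------------
# sequence features
# ---------------------------------------------------------------------------


def _sequence_arrays(sequence: str):
    """Uppercase byte view plus indicator arrays used by the sliding scans."""
    seq = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_c = seq == ord("C")
    is_g = seq == ord("G")
    is_n = ~np.isin(seq, np.frombuffer(b"ACGT", dtype=np.uint8))
    is_cpg = np.zeros(len(seq), dtype=bool)
    if len(seq) > 1:
        is_cpg[:-1] = is_c[:-1] & is_g[1:]
    return is_c, is_g, is_n, is_cpg


def gc_content(sequence: str):
    """GC fraction ``(#G + #C) / (#A + #C + #G + #T)``; N excluded from the denominator.

    Returns NaN when the sequence holds no unambiguous base (missing value).
    """
    is_c, is_g, is_n, _ = _sequence_arrays(sequence)
    denom = int((~is_n).sum())
    if denom == 0:
        logger.info("gc_content: no unambiguous bases; missing value")
        return float("nan")
    return float((is_c.sum() + is_g.sum()) / denom)


def _region_stats(csum_c, csum_g, csum_cpg, start: int, end: int):
    """(gc_fraction, obs_exp) of [start, end) from cumulative counts (no-N region)."""
    length = end - start
    n_c = csum_c[end] - csum_c[start]
    n_g = csum_g[end] - csum_g[start]
    # CpG dinucleotides fully inside the region start at positions [start, end-1)
    n_cpg = csum_cpg[end - 1] - csum_cpg[start] if length > 1 else 0
    gc = (n_c + n_g) / length
    obs_exp = n_cpg * length / (n_c * n_g) if n_c > 0 and n_g > 0 else 0.0
    return gc, obs_exp


def call_cpg_islands(sequence: str, chrom: str = "") -> list[CpGIsland]:
    """Call CpG islands by the classic sliding-window / merge / trim scheme.

    Every 500-bp window (step 1) is tested against the three criteria
    (windows containing N never qualify); overlapping or adjacent qualifying
    windows merge into candidate regions; each region is re-tested as a whole
    and trimmed one base from both ends until it qualifies or drops below
    500 bp.  Sequences shorter than 500 bp give an empty result.
    """
    L = len(sequence)
    if L < CPG_MIN_LENGTH:
        return []
    is_c, is_g, is_n, is_cpg = _sequence_arrays(sequence)
    csum_c = np.concatenate([[0], np.cumsum(is_c)])
    csum_g = np.concatenate([[0], np.cumsum(is_g)])
    csum_n = np.concatenate([[0], np.cumsum(is_n)])
    csum_cpg = np.concatenate([[0], np.cumsum(is_cpg)])

    W = CPG_MIN_LENGTH
    starts = np.arange(0, L - W + 1)
    n_n = csum_n[starts + W] - csum_n[starts]
    n_c = csum_c[starts + W] - csum_c[starts]
    n_g = csum_g[starts + W] - csum_g[starts]
    n_cpg = csum_cpg[starts + W - 1] - csum_cpg[starts]
    gc_ok = (n_c + n_g) >= CPG_MIN_GC * W
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_exp = np.where(n_c * n_g > 0, n_cpg * W / (n_c * n_g), 0.0)
    qualifies = (n_n == 0) & gc_ok & (obs_exp >= CPG_MIN_OBS_EXP)

    q_starts = starts[qualifies]
    if q_starts.size == 0:
        return []
    # merge overlapping/adjacent windows into candidate regions
    regions = []
    r_start = r_end = None
    for s in q_starts:
        if r_start is None:
            r_start, r_end = int(s), int(s) + W
        elif s <= r_end:  # overlap or direct adjacency
            r_end = int(s) + W
        else:
            regions.append((r_start, r_end))
            r_start, r_end = int(s), int(s) + W
    regions.append((r_start, r_end))

    islands = []
    for r_start, r_end in regions:
        while r_end - r_start >= CPG_MIN_LENGTH:
            gc, oe = _region_stats(csum_c, csum_g, csum_cpg, r_start, r_end)
            if gc >= CPG_MIN_GC and oe >= CPG_MIN_OBS_EXP:
                islands.append(
                    CpGIsland(chrom=chrom, start=r_start, end=r_end,
                              gc_fraction=float(gc), obs_exp_ratio=float(oe))
                )
                break
            r_start += 1
            r_end -= 1
    return islands


# ---------------------------------------------------------------------------
# interval features
# ---------------------------------------------------------------------------


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file (0-based half-open) into chrom/start/end/name/feature_class.

    Raises a parse error naming the offending line for malformed intervals
    (start >= end or non-numeric coordinates).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from err
            if start >= end:
                raise ValueError(f"{path}:{lineno}: malformed interval start >= end")
            rows.append(
                {"chrom": chrom, "start": start, "end": end,
                 "name": parts[3] if len(parts) > 3 else f"feature_{lineno}",
                 "feature_class": parts[4] if len(parts) > 4 else ""}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "feature_class"])


def write_bed(path, df: pd.DataFrame, extra_columns=()) -> None:
    cols = ["chrom", "start", "end", "name", *extra_columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=[c for c in cols if c in df])


def interval_coverage(window: tuple[int, int], intervals) -> float:
    """Fraction of a window covered by the merged union of intervals.

    ``intervals`` is an iterable of (start, end) pairs (0-based half-open);
    splitting any interval into abutting pieces does not change the result.
    """
    w_start, w_end = window
    if w_end <= w_start:
        raise ValueError("window must have end > start")
    clipped = []
    for start, end in intervals:
        if start >= end:
            raise ValueError(f"malformed interval ({start}, {end}): start >= end")
        s, e = max(start, w_start), min(end, w_end)
        if s < e:
            clipped.append((s, e))
    if not clipped:
        return 0.0
    clipped.sort()
    covered = 0
    cur_s, cur_e = clipped[0]
    for s, e in clipped[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / (w_end - w_start)


def collapse_transcripts(genes: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple transcripts of one gene to the overall gene span."""
    grouped = genes.groupby(["chrom", "name"], sort=True).agg(
        start=("start", "min"), end=("end", "max")
    )
    return grouped.reset_index()


def count_genes(window: tuple[int, int], genes: pd.DataFrame, chrom: str | None = None) -> int:
    """Number of gene spans with >= 1 bp overlap with the half-open window."""
    w_start, w_end = window
    df = genes if chrom is None else genes[genes["chrom"] == chrom]
    return int(((df["end"] > w_start) & (df["start"] < w_end)).sum())


class AnnotationIndex:
    """Interval-tree index over a BED-like table for repeated window queries."""

    def __init__(self, df: pd.DataFrame):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, group in df.groupby("chrom", sort=True):
            self._trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e)) for s, e in zip(group["start"], group["end"])
            )

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [(iv.begin, iv.end) for iv in tree.overlap(start, end)]


# ---------------------------------------------------------------------------
# window assembly
# ---------------------------------------------------------------------------


def gene_window(gene: pd.Series, half_width: int, chrom_length: int | None = None) -> GenomicWindow:
    """Window of +- half_width around the gene midpoint (rounded down), truncated at edges."""
    center = (int(gene["start"]) + int(gene["end"])) // 2
    start, end = center - half_width, center + half_width
    if start < 0 or (chrom_length is not None and end > chrom_length):
        logger.info("window of gene %s truncated at a chromosome edge", gene.get("name", "?"))
        start = max(0, start)
        if chrom_length is not None:
            end = min(chrom_length, end)
    return GenomicWindow(chrom=gene["chrom"], start=start, end=end,
                         gene_id=str(gene["name"]), half_width=half_width)


def window_features(
    center_gene: str,
    half_width: int,
    sequences: dict[str, str],
    genes: pd.DataFrame,
    repeats: pd.DataFrame,
    cpg_islands: pd.DataFrame | None = None,
) -> WindowFeatures:
    """Assemble the five RIDGE features for the window around one gene.

    ``sequences`` maps chromosome name to its sequence (a pyfaidx.Fasta
    satisfies the mapping protocol).  ``repeats`` must carry a
    ``feature_class`` column with SINE/LINE labels.  CpG islands are called
    from sequence by default, or counted from a supplied island BED table
    (``cpg_islands``) to mirror browser-track workflows.
    """
    spans = collapse_transcripts(genes)
    hit = spans[spans["name"] == center_gene]
    if hit.empty:
        raise KeyError(f"center gene {center_gene!r} absent from the gene annotation")
    gene = hit.iloc[0]
    chrom = gene["chrom"]
    seq = str(sequences[chrom][:]) if hasattr(sequences[chrom], "__getitem__") else str(sequences[chrom])
    win = gene_window(gene, half_width, chrom_length=len(seq))

    window_seq = seq[win.start:win.end]
    gc = gc_content(window_seq)

    if cpg_islands is not None:
        island_df = cpg_islands[cpg_islands["chrom"] == chrom]
        n_cpg = count_genes((win.start, win.end), island_df, chrom=chrom)
    else:
        n_cpg = sum(1 for _ in call_cpg_islands(window_seq, chrom=chrom))

    n_genes = count_genes((win.start, win.end), spans, chrom=chrom)

    coverages = {}
    for cls in ("SINE", "LINE"):
        cls_df = repeats[(repeats["feature_class"] == cls) & (repeats["chrom"] == chrom)]
        coverages[cls] = interval_coverage(
            (win.start, win.end), zip(cls_df["start"], cls_df["end"])
        )
    return WindowFeatures(
        window=win, n_genes=n_genes, n_cpg_islands=int(n_cpg), gc_fraction=gc,
        sine_coverage=coverages["SINE"], line_coverage=coverages["LINE"],
    )


def features_for_genes(
    gene_ids,
    half_width: int,
    sequences: dict[str, str],
    genes: pd.DataFrame,
    repeats: pd.DataFrame,
    cpg_islands: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """WindowFeatures table (one row per gene) shaped like the per-gene context reports."""
    rows = [
        window_features(g, half_width, sequences, genes, repeats, cpg_islands).as_row()
        for g in gene_ids
    ]
    return pd.DataFrame(rows)
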
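"""Chromatin accessibility: peak-set comparison, differential accessibility,
integration with differential expression, and motif-displacement scores.

Peak calling itself is out of scope; this module consumes called peaks
(intervals with per-sample counts/presence). Differential accessibility
reuses the NB exact-test machinery with the study's screen on raw p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix, nb_exact_test
from .io import GenomicInterval

__all__ = [
    "VennResult",
    "ConcordanceTable",
    "merge_intervals",
    "venn_peaks",
    "call_dars",
    "integrate_de_dar",
    "md_score",
    "delta_md",
]


@dataclass
class VennResult:
    unique_a: int
    unique_b: int
    shared: int

    @property
    def total(self) -> int:
        return self.unique_a + self.unique_b + self.shared

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {"unique_a": 0.0, "unique_b": 0.0, "shared": 0.0}
        return {
            "unique_a": self.unique_a / t,
            "unique_b": self.unique_b / t,
            "shared": self.shared / t,
        }


def merge_intervals(intervals) -> list[GenomicInterval]:
    """Merge overlapping/book-ended intervals per chromosome."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(
                    out[-1].chrom, out[-1].start, iv.end, name=out[-1].name
                )
        else:
            out.append(iv)
    return out


def _overlap_flags(
    universe: list[GenomicInterval], merged: list[GenomicInterval], min_bp: int
) -> list[bool]:
    """Per-universe-interval flag: overlaps >= min_bp with the merged set.

    Both lists are sorted and internally non-overlapping, so a single
    forward sweep suffices.
    """
    flags = [False] * len(universe)
    j = 0
    for i, iv in enumerate(universe):
        while j < len(merged) and (
            (merged[j].chrom, merged[j].end) <= (iv.chrom, iv.start + min_bp)
            if merged[j].chrom == iv.chrom
            else merged[j].chrom < iv.chrom
        ):
            j += 1
        k = j
        while k < len(merged) and merged[k].chrom == iv.chrom and merged[k].start < iv.end:
            if merged[k].overlaps(iv, min_bp=min_bp):
                flags[i] = True
                break
            k += 1
    return flags


def venn_peaks(
    peaks_a, peaks_b, min_overlap_bp: int = 1
) -> VennResult:
    """Peak-set overlap on the merged universe of two accessibility sets.

    Each set is merged internally; the universe is the merged union. A
    universe peak is shared iff it overlaps (>= min_overlap_bp) a peak in
    BOTH input sets, otherwise unique to whichever set it touches.
    """
    a = merge_intervals(peaks_a)
    b = merge_intervals(peaks_b)
    universe = merge_intervals(list(a) + list(b))
    in_a = _overlap_flags(universe, a, min_overlap_bp)
    in_b = _overlap_flags(universe, b, min_overlap_bp)
    ua = ub = sh = 0
    for fa, fb in zip(in_a, in_b):
        if fa and fb:
            sh += 1
        elif fa:
            ua += 1
        elif fb:
            ub += 1
    return VennResult(unique_a=ua, unique_b=ub, shared=sh)


def call_dars(
    peak_matrix: CountMatrix,
    group_a: str | list[str],
    group_b: str | list[str],
    p_threshold: float = 0.05,
    **test_kwargs,
) -> pd.DataFrame:
    """Differentially accessible regions: NB exact test on peak counts.

    The significance screen follows the study's rule of raw p < p_threshold
    (BH-adjusted p is also reported). Adds ``significant`` and ``direction``
    columns to the DE table.
    """
    de = nb_exact_test(peak_matrix, group_a, group_b, **test_kwargs)
    de["significant"] = de["p"] < p_threshold
    de["direction"] = np.where(de["log2fc"] > 0, "up", "down")
    return de


@dataclass
class ConcordanceTable:
    table: pd.DataFrame
    n_up: int
    n_down: int
    n_up_concordant: int
    n_down_concordant: int

    @property
    def fraction_concordant(self) -> float:
        total = self.n_up + self.n_down
        if total == 0:
            return 0.0
        return (self.n_up_concordant + self.n_down_concordant) / total

    @staticmethod
    def from_counts(
        n_up: int, n_down: int, n_up_concordant: int, n_down_concordant: int
    ) -> "ConcordanceTable":
        return ConcordanceTable(
            pd.DataFrame(), n_up, n_down, n_up_concordant, n_down_concordant
        )


def integrate_de_dar(
    de_genes: pd.DataFrame,
    dars: pd.DataFrame,
    gene_intervals: dict[str, GenomicInterval],
    dar_intervals: dict[str, GenomicInterval],
    window_bp: int = 10_000,
) -> ConcordanceTable:
    """DE-gene / DAR concordance within a gene-body +/- window.

    ``de_genes`` needs a ``direction`` column (up/down); ``dars`` needs
    ``direction`` and ``significant``. A gene is concordant iff at least
    one significant same-direction DAR lies within
    [gene.start - window, gene.end + window) on the same chromosome.
    Genes without intervals count as unmatched. Strand is ignored.
    """
    sig = dars[dars.get("significant", pd.Series(True, index=dars.index))]
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for pid, row in sig.iterrows():
        iv = dar_intervals.get(pid)
        if iv is None:
            continue
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, row["direction"]))
    for lst in by_chrom.values():
        lst.sort()

    rows = []
    for gene, row in de_genes.iterrows():
        iv = gene_intervals.get(gene)
        if iv is None:
            rows.append((gene, row["direction"], None, None, False, False))
            continue
        lo, hi = iv.start - window_bp, iv.end + window_bp
        match_dir = None
        concordant = False
        for s, e, d in by_chrom.get(iv.chrom, []):
            if s >= hi:
                break
            if e > lo:
                match_dir = d
                if d == row["direction"]:
                    concordant = True
                    break
        rows.append((gene, row["direction"], iv.name, match_dir, concordant, True))
    table = pd.DataFrame(
        rows,
        columns=["gene", "direction", "interval", "dar_direction",
                 "concordant", "matched"],
    ).set_index("gene")
    n_up = int((table["direction"] == "up").sum())
    n_down = int((table["direction"] == "down").sum())
    n_up_c = int(((table["direction"] == "up") & table["concordant"]).sum())
    n_down_c = int(((table["direction"] == "down") & table["concordant"]).sum())
    return ConcordanceTable(table, n_up, n_down, n_up_c, n_down_c)


def md_score(
    hit_positions,
    peak_centers,
    small_radius: int = 150,
    large_radius: int = 1500,
) -> float | None:
    """Motif-displacement score: of the motif hits within ``large_radius``
    of the nearest peak center, the fraction within ``small_radius``.

    Positions are 1-D coordinates (single chromosome or pre-flattened);
    returns None when no hit falls within the outer radius.
    """
    if small_radius >= large_radius or small_radius <= 0:
        raise ValueError("need 0 < small_radius < large_radius")
    hits = np.sort(np.asarray(hit_positions, dtype=float))
    centers = np.sort(np.asarray(peak_centers, dtype=float))
    if hits.size == 0 or centers.size == 0:
        return None
    idx = np.searchsorted(centers, hits)
    left = centers[np.clip(idx - 1, 0, centers.size - 1)]
    right = centers[np.clip(idx, 0, centers.size - 1)]
    dist = np.minimum(np.abs(hits - left), np.abs(hits - right))
    n_large = int((dist <= large_radius).sum())
    if n_large == 0:
        return None
    n_small = int((dist <= small_radius).sum())
    return n_small / n_large


def delta_md(
    hits_a, centers_a, hits_b, centers_b,
    small_radius: int = 150, large_radius: int = 1500,
) -> float | None:
    """Signed MD-score difference, condition B minus condition A."""
    md_a = md_score(hits_a, centers_a, small_radius, large_radius)
    md_b = md_score(hits_b, centers_b, small_radius, large_radius)
    if md_a is None or md_b is None:
        return None
    return md_b - md_a
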
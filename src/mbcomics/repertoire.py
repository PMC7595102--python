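"""Heavy-chain repertoire profiling.

Assigns germline V/D/J segments to reads, profiles gene/family usage with
Spearman conservation correlations, summarizes CDR3 lengths, and estimates
the somatic-hypermutation frequency (change/base) after subtracting the
combined polymerase/sequencing error rate (0.008 by default).

The assigner is a deliberately simple germline aligner: best V by edit-
distance prefix alignment (score = length - 2*distance, which equals the
+1 match / -1 mismatch score for substitution-only alignments), best J by
suffix alignment, and D by best ungapped match inside the junction. The
CDR3 convention is IMGT-like: the peptide strictly between the conserved
V-end Cys codon and the J-opening Trp codon (anchors excluded from the
length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .synth import _translate

__all__ = [
    "GermlineGene",
    "GermlineDB",
    "Mismatch",
    "VDJAnnotation",
    "MutationSummary",
    "assign_vdj",
    "assign_many",
    "usage_profile",
    "usage_correlation",
    "cdr3_stats",
    "mutation_frequency",
    "annotations_to_table",
]

MIN_READ_LENGTH = 60
DEFAULT_ERROR_RATE = 0.008
D_SCORE_FLOOR = 5


@dataclass(frozen=True)
class GermlineGene:
    gene_id: str
    family: str
    seq: str
    regions: dict[str, tuple[int, int]] | None = None


@dataclass
class GermlineDB:
    """V/D/J germline segments; V entries carry FR/CDR boundaries."""

    v: dict[str, GermlineGene]
    d: dict[str, GermlineGene]
    j: dict[str, GermlineGene]

    def __post_init__(self) -> None:
        for cls, table in (("V", self.v), ("D", self.d), ("J", self.j)):
            for gid, gene in table.items():
                if set(gene.seq) - set("ACGT"):
                    raise ValueError(f"{cls} gene {gid}: sequence must be ACGT")
        for gid, gene in self.v.items():
            if gene.regions is None:
                raise ValueError(f"V gene {gid} lacks FR/CDR boundaries")

    def families(self, cls: str = "V") -> list[str]:
        table = {"V": self.v, "D": self.d, "J": self.j}[cls]
        return sorted({g.family for g in table.values()})


@dataclass(frozen=True)
class Mismatch:
    position: int          # 0-based in germline V coordinates
    germline: str
    observed: str
    region: str            # FR | CDR
    klass: str             # silent | replacement


@dataclass
class VDJAnnotation:
    read_id: str
    v_call: str | None
    v_score: int
    j_call: str | None
    j_score: int
    d_call: str | None
    d_score: int
    cdr3_aa: str
    mismatches: list[Mismatch] = field(default_factory=list)
    v_aligned_bases: int = 0

    @property
    def assignable(self) -> bool:
        return self.v_call is not None


def _edlib_score(query: str, target: str, mode: str) -> tuple[int, dict]:
    res = edlib.align(query, target, mode=mode, task="path")
    return len(query) - 2 * res["editDistance"], res


def _region_of(pos: int, regions: dict[str, tuple[int, int]]) -> str:
    for name, (a, b) in regions.items():
        if a <= pos < b:
            return "CDR" if name.startswith("CDR") else "FR"
    return "FR"


def _v_mismatches(v: GermlineGene, aligned_read: str) -> list[Mismatch]:
    """Mismatch list for a substitution-only V alignment (equal lengths)."""
    out = []
    g, r = v.seq, aligned_read
    n = min(len(g), len(r))
    for pos in range(n):
        if g[pos] != r[pos]:
            codon_start = 3 * (pos // 3)
            germ_codon = g[codon_start : codon_start + 3]
            read_codon = r[codon_start : codon_start + 3]
            klass = (
                "silent"
                if len(read_codon) == 3 and _translate(germ_codon) == _translate(read_codon)
                else "replacement"
            )
            out.append(
                Mismatch(pos, g[pos], r[pos], _region_of(pos, v.regions), klass)
            )
    return out


def assign_vdj(
    read: str,
    db: GermlineDB,
    read_id: str = "read",
    v_score_floor: int | None = None,
    call_d: bool = True,
) -> VDJAnnotation:
    """Annotate one read with its best germline V/D/J and CDR3 peptide.

    V is the germline whose prefix alignment to the read scores highest;
    reads whose best V score stays below the score floor (default 30% of
    the germline V length, i.e. edit distance above ~35%) are returned
    unassignable. J aligns to the read
    suffix; D is the best ungapped junction match, reported only at score
    >= 5. Mismatches are enumerated over the aligned V span with FR/CDR and
    silent/replacement labels.
    """
    read = read.upper()
    if len(read) < MIN_READ_LENGTH:
        raise ValueError(f"read shorter than {MIN_READ_LENGTH} nt")
    if not db.v or not db.j:
        raise ValueError("germline database must contain V and J genes")

    best_v, best_v_score = None, -(10**9)
    for gene in db.v.values():
        res = edlib.align(gene.seq, read, mode="SHW", task="distance")
        score = len(gene.seq) - 2 * res["editDistance"]
        if score > best_v_score:
            best_v, best_v_score = gene, score
    floor = (
        v_score_floor
        if v_score_floor is not None
        else int(0.3 * len(best_v.seq)) if best_v else 0
    )
    if best_v is None or best_v_score <= floor:
        return VDJAnnotation(read_id, None, best_v_score, None, 0, None, 0, "")
    # substitution-only model: the V span is the full germline prefix (an
    # alignment-located end would drop co-optimal terminal mismatches)
    v_end = min(len(best_v.seq), len(read))

    rev = read[::-1]
    best_j, best_j_score = None, -(10**9)
    for gene in db.j.values():
        res = edlib.align(gene.seq[::-1], rev, mode="SHW", task="distance")
        score = len(gene.seq) - 2 * res["editDistance"]
        if score > best_j_score:
            best_j, best_j_score = gene, score
    j_start = max(v_end, len(read) - len(best_j.seq))

    junction = read[v_end:j_start] if j_start > v_end else ""
    d_call, d_score = None, 0
    if call_d and db.d and junction:
        d_call, d_score = _best_d(junction, db.d)

    cdr3_aa = _translate(junction) if junction else ""
    mismatches = _v_mismatches(best_v, read[:v_end])
    return VDJAnnotation(
        read_id=read_id,
        v_call=best_v.gene_id,
        v_score=best_v_score,
        j_call=best_j.gene_id,
        j_score=best_j_score,
        d_call=d_call,
        d_score=d_score,
        cdr3_aa=cdr3_aa,
        mismatches=mismatches,
        v_aligned_bases=min(v_end, len(best_v.seq)),
    )


def _best_d(junction: str, d_genes: dict[str, GermlineGene]) -> tuple[str | None, int]:
    """Best ungapped D match in the junction: max matches - mismatches over
    all offsets and overlap windows, reported only at score >= 5."""
    jarr = np.frombuffer(junction.encode(), dtype="S1")
    best, best_score = None, 0
    for gene in d_genes.values():
        darr = np.frombuffer(gene.seq.encode(), dtype="S1")
        ld, lj = len(darr), len(jarr)
        for off in range(-(ld - 1), lj):
            a = max(0, off)
            b = min(lj, off + ld)
            if b - a < D_SCORE_FLOOR:
                continue
            seg = jarr[a:b] == darr[a - off : b - off]
            score = int(2 * seg.sum() - len(seg))
            if score > best_score:
                best, best_score = gene.gene_id, score
    if best_score < D_SCORE_FLOOR:
        return None, best_score
    return best, best_score


def assign_many(
    reads: dict[str, str], db: GermlineDB, call_d: bool = True,
    v_score_floor: int | None = None,
) -> tuple[list[VDJAnnotation], dict]:
    """Annotate a read set; unassignable reads are excluded from the
    returned list and counted in the QC dict."""
    annotations, unassignable = [], 0
    for rid, seq in reads.items():
        ann = assign_vdj(seq, db, read_id=rid, call_d=call_d,
                         v_score_floor=v_score_floor)
        if ann.assignable:
            annotations.append(ann)
        else:
            unassignable += 1
    qc = {"n_reads": len(reads), "n_assigned": len(annotations),
          "n_unassignable": unassignable}
    return annotations, qc


def usage_profile(
    annotations: list[VDJAnnotation],
    level: str = "gene",
    db: GermlineDB | None = None,
    segment: str = "V",
) -> pd.Series:
    """Fractional V (or D/J) usage at gene or family resolution.

    Fractions sum to 1; ids present in the database but never called get 0
    (requires ``db``)."""
    attr = {"V": "v_call", "D": "d_call", "J": "j_call"}[segment]
    calls = [getattr(a, attr) for a in annotations if getattr(a, attr)]
    if not calls:
        raise ValueError("no assignable annotations")
    if level == "family":
        if db is None:
            calls = [c.split("-")[0] for c in calls]
        else:
            table = {"V": db.v, "D": db.d, "J": db.j}[segment]
            calls = [table[c].family for c in calls]
    elif level != "gene":
        raise ValueError(f"unknown level {level!r}")
    counts = pd.Series(calls).value_counts()
    if db is not None:
        table = {"V": db.v, "D": db.d, "J": db.j}[segment]
        universe = (
            sorted({g.family for g in table.values()})
            if level == "family"
            else sorted(table)
        )
        counts = counts.reindex(universe, fill_value=0)
    frac = counts / counts.sum()
    frac.name = f"{segment}_{level}_usage"
    return frac.sort_index()


def usage_correlation(a: pd.Series, b: pd.Series) -> float:
    """Spearman rank correlation of two usage profiles over the id union
    (missing ids count as 0)."""
    ids = a.index.union(b.index)
    if len(ids) < 3:
        raise ValueError("need at least 3 ids for a rank correlation")
    x = a.reindex(ids, fill_value=0.0).values
    y = b.reindex(ids, fill_value=0.0).values
    return float(spearmanr(x, y).statistic)


def cdr3_stats(annotations: list[VDJAnnotation]) -> dict:
    """CDR3 length histogram (amino acids) with mean and SEM over reads."""
    lengths = np.array(
        [len(a.cdr3_aa) for a in annotations if a.cdr3_aa], dtype=float
    )
    if lengths.size == 0:
        raise ValueError("no annotations with a non-empty CDR3")
    hist = pd.Series(lengths.astype(int)).value_counts().sort_index()
    sem = float(lengths.std(ddof=1) / np.sqrt(lengths.size)) if lengths.size > 1 else 0.0
    return {
        "histogram": hist,
        "mean": float(lengths.mean()),
        "sem": sem,
        "n": int(lengths.size),
    }


@dataclass
class MutationSummary:
    n_reads: int
    n_aligned_bases: int
    n_mismatches: int
    raw_freq: float
    corrected_freq: float
    error_rate: float
    rs_breakdown: dict[str, int]

    def __post_init__(self) -> None:
        by_class = self.rs_breakdown["silent"] + self.rs_breakdown["replacement"]
        by_region = self.rs_breakdown["FR"] + self.rs_breakdown["CDR"]
        assert by_class == self.n_mismatches and by_region == self.n_mismatches


def mutation_frequency(
    annotations: list[VDJAnnotation], error_rate: float = DEFAULT_ERROR_RATE
) -> MutationSummary:
    """Error-corrected somatic mutation frequency over aligned V bases.

    raw = mismatches / aligned bases; corrected = max(raw - error_rate, 0).
    The breakdown counts silent/replacement and FR/CDR mismatches.
    """
    usable = [a for a in annotations if a.assignable]
    bases = sum(a.v_aligned_bases for a in usable)
    if bases == 0:
        raise ValueError("no aligned bases")
    mismatches = [m for a in usable for m in a.mismatches]
    raw = len(mismatches) / bases
    breakdown = {
        "silent": sum(1 for m in mismatches if m.klass == "silent"),
        "replacement": sum(1 for m in mismatches if m.klass == "replacement"),
        "FR": sum(1 for m in mismatches if m.region == "FR"),
        "CDR": sum(1 for m in mismatches if m.region == "CDR"),
    }
    return MutationSummary(
        n_reads=len(usable),
        n_aligned_bases=bases,
        n_mismatches=len(mismatches),
        raw_freq=raw,
        corrected_freq=max(raw - error_rate, 0.0),
        error_rate=error_rate,
        rs_breakdown=breakdown,
    )


def annotations_to_table(annotations: list[VDJAnnotation]) -> pd.DataFrame:
    """AIRR-style annotation table (one row per assignable read)."""
    rows = [
        {
            "read_id": a.read_id, "v_call": a.v_call, "d_call": a.d_call,
            "j_call": a.j_call, "cdr3_aa": a.cdr3_aa,
            "mutation_count": len(a.mismatches),
            "v_aligned_bases": a.v_aligned_bases,
        }
        for a in annotations
        if a.assignable
    ]
    return pd.DataFrame(rows).set_index("read_id") if rows else pd.DataFrame()
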
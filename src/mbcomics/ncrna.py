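"""Non-coding RNA regulatory screens.

miRNA side: canonical seed-site scanning on 3'UTRs (6mer, 7mer-A1,
7mer-m8, 8mer), a simplified nearest-neighbor duplex free energy, and the
target-release screen (upregulated mRNA + downregulated miRNA + canonical
site + inverse expression correlation across the 12 sorted libraries).

lncRNA side: cis/trans co-expression with mRNAs or miRNAs (cis = same
chromosome within a distance window) and a sponge (ceRNA) screen: an
upregulated lncRNA anti-correlated with a downregulated miRNA and
positively correlated with that miRNA's released targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io import GenomicInterval

__all__ = [
    "SeedMatch",
    "find_seed_sites",
    "duplex_energy",
    "target_release_screen",
    "lncrna_coexpression",
    "sponge_screen",
    "SITE_RANK",
]

SITE_RANK = {"6mer": 0, "7mer-A1": 1, "7mer-m8": 2, "8mer": 3}
_CONTAINED = {  # fallback hierarchy when the full type is not allowed
    "8mer": ["7mer-m8", "7mer-A1", "6mer"],
    "7mer-m8": ["6mer"],
    "7mer-A1": ["6mer"],
    "6mer": [],
}

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


@dataclass(frozen=True)
class SeedMatch:
    mirna: str
    gene: str
    position: int          # 0-based start of the matched site in the UTR
    site_type: str
    delta_g: float | None = None


def find_seed_sites(
    utr: str,
    mirna: str,
    allowed_types: tuple[str, ...] = ("8mer", "7mer-m8", "7mer-A1", "6mer"),
    mirna_id: str = "mirna",
    gene_id: str = "gene",
) -> list[SeedMatch]:
    """Scan a 3'UTR for canonical seed sites of one miRNA.

    The 6mer core matches the reverse complement of miRNA nt 2-7; pairing
    of nt 8 immediately 5' of the core upgrades to 7mer-m8, an A opposite
    nt 1 (3' of the core) to 7mer-A1, and both to 8mer. One maximal site is
    reported per core locus; if the maximal type is not in
    ``allowed_types`` the best allowed contained type is reported instead.
    Ambiguous bases never match. Positions are 0-based starts of the
    reported site (so 7mer-m8/8mer sites start one base 5' of the core).
    """
    mir = _rna(mirna)
    if len(mir) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    utr_r = _rna(utr)
    core = _revcomp(mir[1:7])
    m8 = _revcomp(mir[7])
    out: list[SeedMatch] = []
    start = 0
    while True:
        i = utr_r.find(core, start)
        if i < 0:
            break
        start = i + 1
        has_m8 = i >= 1 and utr_r[i - 1] == m8
        has_a1 = i + 6 < len(utr_r) and utr_r[i + 6] == "A"
        if has_m8 and has_a1:
            full = "8mer"
        elif has_m8:
            full = "7mer-m8"
        elif has_a1:
            full = "7mer-A1"
        else:
            full = "6mer"
        site_type = full if full in allowed_types else next(
            (t for t in _CONTAINED[full] if t in allowed_types), None
        )
        if site_type is None:
            continue
        pos = i - 1 if site_type in ("8mer", "7mer-m8") else i
        out.append(SeedMatch(mirna_id, gene_id, pos, site_type))
    return out


# ---------------------------------------------------------------------------
# nearest-neighbor duplex energy
# ---------------------------------------------------------------------------

# RNA/RNA Watson-Crick nearest-neighbor stack free energies at 37C
# (kcal/mol), keyed by the two consecutive pairs (miRNA base, target base)
# read along the miRNA 5'->3'. Wobble-containing stacks use representative
# weaker values; unlisted wobble contexts fall back to -0.5.
_WC_STACKS: dict[tuple[str, str], float] = {
    ("AU", "AU"): -0.93, ("AU", "UA"): -1.10, ("UA", "AU"): -1.33,
    ("UA", "UA"): -0.93, ("AU", "GC"): -2.08, ("AU", "CG"): -2.11,
    ("UA", "GC"): -2.35, ("UA", "CG"): -2.24, ("GC", "AU"): -2.24,
    ("GC", "UA"): -2.11, ("CG", "AU"): -2.35, ("CG", "UA"): -2.08,
    ("GC", "GC"): -3.26, ("GC", "CG"): -3.42, ("CG", "GC"): -2.36,
    ("CG", "CG"): -3.26, ("GU", "AU"): -1.27, ("GU", "UA"): -1.36,
    ("UG", "AU"): -1.00, ("UG", "UA"): -1.41, ("AU", "GU"): -0.55,
    ("AU", "UG"): -1.36, ("UA", "GU"): -1.27, ("UA", "UG"): -1.00,
    ("GU", "GC"): -1.50, ("UG", "GC"): -1.53, ("GU", "CG"): -2.11,
    ("UG", "CG"): -2.51, ("GC", "GU"): -2.51, ("GC", "UG"): -2.11,
    ("CG", "GU"): -1.53, ("CG", "UG"): -1.50,
}
_DEFAULT_STACK = -0.5
DUPLEX_INITIATION = 4.09
BULGE_PENALTY = 3.2
LOOP_PENALTY = 2.6

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _stack_energy(prev_pair: tuple[str, str], pair: tuple[str, str]) -> float:
    key = ("".join(prev_pair), "".join(pair))
    return _WC_STACKS.get(key, _DEFAULT_STACK)


def duplex_energy(mirna: str, window: str) -> float | None:
    """Hybridization free energy of a miRNA with a target-site window.

    Dynamic program over Watson-Crick and G:U wobble pairs: consecutive
    pairs add nearest-neighbor stack energies, single-sided bulges and 1x1
    internal loops pay fixed penalties, and each duplex pays one
    initiation penalty. Returns the most favorable (most negative) total,
    or None when no stabilizing duplex (<= 0 kcal/mol) exists.
    """
    win = _rna(window)
    mir = _rna(mirna)
    if not 8 <= len(win) <= 40:
        raise ValueError("window length must lie in [8, 40] nt")
    nm, nw = len(mir), len(win)
    inf = float("inf")
    # E[i][j]: best energy of a duplex whose most recent pair is
    # (mir[i], win[j]); antiparallel, so the previous pair is (i-1, j+1)
    E = np.full((nm, nw), inf)
    best = inf
    for i in range(nm):
        for j in range(nw - 1, -1, -1):
            if (mir[i], win[j]) not in _PAIRS:
                continue
            e = DUPLEX_INITIATION  # open a new helix here
            if i >= 1 and j + 1 < nw and np.isfinite(E[i - 1][j + 1]):
                e = min(
                    e,
                    E[i - 1][j + 1]
                    + _stack_energy((mir[i - 1], win[j + 1]), (mir[i], win[j])),
                )
            if i >= 2 and j + 1 < nw and np.isfinite(E[i - 2][j + 1]):
                e = min(e, E[i - 2][j + 1] + BULGE_PENALTY)
            if i >= 1 and j + 2 < nw and np.isfinite(E[i - 1][j + 2]):
                e = min(e, E[i - 1][j + 2] + BULGE_PENALTY)
            if i >= 2 and j + 2 < nw and np.isfinite(E[i - 2][j + 2]):
                e = min(e, E[i - 2][j + 2] + LOOP_PENALTY)
            E[i][j] = e
            best = min(best, e)
    if not np.isfinite(best) or best > 0:
        return None
    return float(best)


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r = spearmanr(x, y)
    return float(r.statistic), float(r.pvalue)


def target_release_screen(
    up_genes,
    down_mirnas,
    seed_matches: pd.DataFrame,
    gene_expr: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    min_site_type: str = "7mer-m8",
    r_max: float = -0.5,
    p_max: float = 0.05,
) -> dict:
    """Predicted targets released from miRNA silencing.

    A gene is a released target of a miRNA iff the gene is upregulated, the
    miRNA downregulated, the UTR carries a site of at least
    ``min_site_type``, and miRNA (RPM) vs gene (RPKM) expression across the
    sorted libraries correlates at r_s <= r_max with p < p_max. Returns the
    per-pair table, per-miRNA target lists, and the fraction of up genes
    targeted by any screened miRNA; features without expression are
    excluded and counted.
    """
    up = set(up_genes)
    down = set(down_mirnas)
    min_rank = SITE_RANK[min_site_type]
    rows = []
    skipped = 0
    if len(seed_matches):
        eligible = seed_matches[
            seed_matches["gene"].isin(up)
            & seed_matches["mirna"].isin(down)
            & (seed_matches["site_type"].map(SITE_RANK) >= min_rank)
        ]
        for (gene, mirna), sites in eligible.groupby(["gene", "mirna"]):
            if gene not in gene_expr.index or mirna not in mirna_expr.index:
                skipped += 1
                continue
            x = mirna_expr.loc[mirna].values.astype(float)
            y = gene_expr.loc[gene].values.astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                skipped += 1
                continue
            r, p = _spearman(x, y)
            best = sites.loc[sites["site_type"].map(SITE_RANK).idxmax()]
            rows.append(
                {
                    "gene": gene, "mirna": mirna, "n_sites": len(sites),
                    "best_site_type": best["site_type"], "r_s": r, "p": p,
                    "released": bool(r <= r_max and p < p_max),
                }
            )
    pairs = pd.DataFrame(
        rows,
        columns=["gene", "mirna", "n_sites", "best_site_type", "r_s", "p", "released"],
    )
    released = pairs[pairs["released"]] if len(pairs) else pairs
    targets_by_mirna = {
        m: sorted(sub["gene"]) for m, sub in released.groupby("mirna")
    } if len(released) else {}
    targeted = set(released["gene"]) if len(released) else set()
    fraction = len(targeted) / len(up) if up else 0.0
    return {
        "pairs": pairs,
        "targets_by_mirna": targets_by_mirna,
        "released_genes": sorted(targeted),
        "fraction_up_targeted": fraction,
        "n_skipped_missing_expression": skipped,
    }


def lncrna_coexpression(
    lnc_expr: pd.DataFrame,
    partner_expr: pd.DataFrame,
    lnc_intervals: dict[str, GenomicInterval],
    partner_intervals: dict[str, GenomicInterval],
    cis_window: int = 1_000_000,
    r_report: float = 0.7,
    pairs: list[tuple[str, str]] | None = None,
) -> dict:
    """Spearman co-expression of lncRNAs with partner features.

    Each pair is labelled cis (same chromosome and gap <= cis_window) or
    trans. The summary reports, separately for cis and trans, the fraction
    of pairs with r_s > r_report and with r_s < -r_report. Pairs with a
    constant expression vector are excluded and counted.
    """
    if pairs is None:
        pairs = [(l, g) for l in lnc_expr.index for g in partner_expr.index]
    rows = []
    excluded = 0
    for l, g in pairs:
        if l not in lnc_expr.index or g not in partner_expr.index:
            raise KeyError(f"pair ({l!r}, {g!r}) missing from expression")
        x = lnc_expr.loc[l].values.astype(float)
        y = partner_expr.loc[g].values.astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            excluded += 1
            continue
        li = lnc_intervals.get(l)
        gi = partner_intervals.get(g)
        relation = "trans"
        if li is not None and gi is not None and li.chrom == gi.chrom:
            if (li.distance(gi) or 0) <= cis_window:
                relation = "cis"
        r, p = _spearman(x, y)
        rows.append({"lncrna": l, "partner": g, "r_s": r, "p": p,
                     "relation": relation})
    records = pd.DataFrame(rows, columns=["lncrna", "partner", "r_s", "p", "relation"])
    summary = {}
    for rel in ("cis", "trans"):
        sub = records[records["relation"] == rel]
        n = len(sub)
        summary[rel] = {
            "n_pairs": n,
            "fraction_positive": float((sub["r_s"] > r_report).mean()) if n else 0.0,
            "fraction_negative": float((sub["r_s"] < -r_report).mean()) if n else 0.0,
        }
    return {"records": records, "summary": summary, "n_excluded_constant": excluded}


def sponge_screen(
    up_lncrnas,
    down_mirnas,
    release_result: dict,
    lnc_expr: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Candidate miRNA sponges among upregulated lncRNAs.

    lncRNA L is a sponge candidate for miRNA M iff L is upregulated, M
    downregulated, r_s(L, M) < 0 with p < p_max, and the median r_s of L
    with M's released targets is positive. When M has no released targets
    the candidate is evaluated on the first three conditions and flagged
    ``partial``.
    """
    targets_by_mirna = release_result.get("targets_by_mirna", {})
    rows = []
    for l in sorted(set(up_lncrnas)):
        if l not in lnc_expr.index:
            continue
        x = lnc_expr.loc[l].values.astype(float)
        if np.all(x == x[0]):
            continue
        for m in sorted(set(down_mirnas)):
            if m not in mirna_expr.index:
                continue
            y = mirna_expr.loc[m].values.astype(float)
            if np.all(y == y[0]):
                continue
            r, p = _spearman(x, y)
            if not (r < 0 and p < p_max):
                continue
            targets = [t for t in targets_by_mirna.get(m, []) if t in gene_expr.index]
            if targets:
                rts = [
                    _spearman(x, gene_expr.loc[t].values.astype(float))[0]
                    for t in targets
                ]
                median_rt = float(np.median(rts))
                if median_rt <= 0:
                    continue
                partial = False
            else:
                median_rt = np.nan
                partial = True
            rows.append(
                {
                    "lncrna": l, "mirna": m, "r_s_mirna": r, "p_mirna": p,
                    "median_r_s_targets": median_rt, "n_targets": len(targets),
                    "partial": partial,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["lncrna", "mirna", "r_s_mirna", "p_mirna",
                 "median_r_s_targets", "n_targets", "partial"],
    )
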
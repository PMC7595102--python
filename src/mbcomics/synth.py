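"""Synthetic multi-omic data with planted ground truth.

Generates every input the pipeline consumes, emulating the statistical
structure of a sorted-B-cell study: 4 subsets (naive NBC, unswitched
unswMBC, class-switched IgG and IgA memory) x 3 subjects = 12 RNA-seq
libraries, plus 4 NBC / 4 MBC ATAC libraries; NB-distributed counts with
subset effects; a planted core transcriptional signature (17 up / 7 down,
shared by both switched subsets and attenuated in unswMBC); heavy-chain
repertoire reads with subset-specific per-base mutation rates on top of a
0.008 sequencing/polymerase error floor; ATAC peaks whose presence follows
a Venn plan and whose differential accessibility is partly concordant with
the planted expression changes; and 3'UTRs carrying canonical MIR181-family
seed sites in designated target genes.

Dispersion model: ``var = mu + phi * mu**2``. ``GeneratorConfig.dispersion``
is the squared biological CV at the typical (median) abundance; by default
a canonical abundance-dispersion trend applies, declining hyperbolically to
``dispersion_floor`` for abundant features (set the floor to None for a flat
dispersion, as used by the calibration simulations).

All randomness flows through explicit seeds via the counter-based Philox
bit generator; identical config + seed gives bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix
from .io import GenomicInterval

__all__ = [
    "GeneratorConfig",
    "SignaturePlan",
    "RepertoirePlan",
    "AtacPlan",
    "MirnaTargetPlan",
    "default_signature_plan",
    "default_mirna_plan",
    "default_lncrna_plan",
    "default_repertoire_plan",
    "build_germline_db",
    "generate_expression",
    "generate_mirnome",
    "generate_lncrnome",
    "generate_repertoire",
    "generate_atac",
    "generate_annotation",
]

SUBSETS = ("NBC", "unswMBC", "IgG", "IgA")

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

# mature miRNA sequences of the planted MIR181 family analogues
# (hsa-miR-181a-5p / hsa-miR-181b-5p); both share the ACAUUCA seed (nt 2-8)
MIR181A_SEQ = "AACAUUCAACGCUGUCGGUGAGU"
MIR181B_SEQ = "AACAUUCAUUGCUGUCGGUGGGU"

SIGNATURE_UP = (
    "AIM2", "BAIAP3", "CD80", "COL4A4", "MUC16", "RASSF6", "RORA",
    "SAMSN1", "TACI", "TGM2", "TOX", "TRERF1", "TRPV3",
    "SIGU14", "SIGU15", "SIGU16", "SIGU17",
)
SIGNATURE_DOWN = ("IKZF2", "PCDH9", "SPRY1", "TCL1A", "ZBTB16", "SIGD06", "SIGD07")
MIR181_TARGET_SIGNATURE_GENES = ("RASSF6", "TOX", "TRERF1", "TRPV3", "RORA")


def _rng(seed, stream: int = 0) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=(int(seed) << 16) + stream))


@dataclass
class GeneratorConfig:
    """Study-level layout and count-model parameters."""

    n_genes: int = 10_000
    n_mirnas: int = 500
    n_lncrnas: int = 1_000
    n_peaks: int = 10_000
    n_subjects: int = 3
    subsets: tuple[str, ...] = SUBSETS
    baseline_mean: float = 15.0
    dispersion: float = 0.1
    dispersion_floor: float | None = 0.01
    lib_size_range: tuple[int, int] = (120_000, 210_000)
    mirna_baseline_mean: float = 50.0
    mirna_lib_size_range: tuple[int, int] = (120_000, 250_000)
    lncrna_baseline_mean: float = 6.0
    lncrna_lib_size_range: tuple[int, int] = (12_000, 21_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_subjects < 1:
            raise ValueError("every subset needs at least one sample")
        if self.lib_size_range[0] <= 0 or self.lib_size_range[0] > self.lib_size_range[1]:
            raise ValueError("invalid lib_size_range")

    def subjects(self) -> list[str]:
        if self.n_subjects <= 3:
            return list("BCG")[: self.n_subjects]
        return [f"S{i+1}" for i in range(self.n_subjects)]

    def dispersion_at(self, baseline: np.ndarray) -> np.ndarray:
        """Per-feature dispersion at a given baseline abundance."""
        baseline = np.asarray(baseline, dtype=float)
        if self.dispersion_floor is None:
            return np.full(baseline.shape, self.dispersion)
        floor = self.dispersion_floor
        with np.errstate(divide="ignore"):
            phi = floor + (self.dispersion - floor) * (
                self.baseline_mean / np.maximum(baseline, 1e-12)
            )
        return np.clip(phi, floor, 2.0)


@dataclass
class SignaturePlan:
    """Planted differential-expression structure for one count matrix.

    ``up_genes``/``down_genes`` carry the core-signature effects (log2,
    applied in both switched subsets and attenuated by ``unsw_fraction`` in
    unswMBC); ``extra_up``/``extra_down`` the broader moderate DE
    background; ``isotype_specific`` maps feature -> {subset: effect} for
    features DE between the two switched subsets only; ``custom`` arbitrary
    per-subset effects (e.g. unswMBC-specific genes); ``feature_class``
    labels features (``IGHC`` members are reported separately by the
    signature step); ``baselines`` pins abundances for named features,
    otherwise planted core features draw around ``planted_baseline_mean``.
    """

    up_genes: dict[str, float] = field(default_factory=dict)
    down_genes: dict[str, float] = field(default_factory=dict)
    isotype_specific: dict[str, dict[str, float]] = field(default_factory=dict)
    extra_up: dict[str, float] = field(default_factory=dict)
    extra_down: dict[str, float] = field(default_factory=dict)
    custom: dict[str, dict[str, float]] = field(default_factory=dict)
    unsw_fraction: float = 0.4
    unsw_override: dict[str, float] = field(default_factory=dict)
    planted_baseline_mean: float = 600.0
    extra_baseline_mean: float | None = 60.0
    baselines: dict[str, float] = field(default_factory=dict)
    feature_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [
            set(self.up_genes), set(self.down_genes), set(self.isotype_specific),
            set(self.extra_up), set(self.extra_down), set(self.custom),
        ]
        seen: set[str] = set()
        for s in sets:
            if seen & s:
                raise ValueError(f"overlapping planted sets: {sorted(seen & s)}")
            seen |= s
        if not 0.0 <= self.unsw_fraction <= 1.0:
            raise ValueError("unsw_fraction must lie in [0, 1]")

    def planted_ids(self) -> list[str]:
        return (
            list(self.up_genes) + list(self.down_genes)
            + list(self.isotype_specific) + list(self.extra_up)
            + list(self.extra_down) + list(self.custom)
        )


def default_signature_plan(
    n_extra_up: int = 445, n_extra_down: int = 605, effect: float = 3.0,
    extra_effect: float = 1.1,
) -> SignaturePlan:
    """The default planted mRNA landscape.

    17 up / 7 down core-signature genes at |log2 effect| = 3 (abundant,
    shared by IgG and IgA, attenuated in unswMBC; the four transitional
    members TRPV3/TACI/COL4A4/SAMSN1 are less attenuated in unswMBC), a
    moderate DE background sized so that planted up/down totals are
    462/612, two unswMBC-specific genes (TFEC/ZBTB32 analogues),
    isotype-specific features (RPS17/RUNX2 analogues higher in IgA) and Ig
    heavy-chain constant-region features carrying the reciprocal isotype
    expression, labelled class ``IGHC``.
    """
    plan = SignaturePlan(
        up_genes={g: effect for g in SIGNATURE_UP},
        down_genes={g: -effect for g in SIGNATURE_DOWN},
        isotype_specific={"RPS17": {"IgA": 2.0}, "RUNX2": {"IgA": 2.5}},
        extra_up={f"EXU{i:04d}": extra_effect for i in range(1, n_extra_up + 1)},
        extra_down={f"EXD{i:04d}": -extra_effect for i in range(1, n_extra_down + 1)},
        unsw_override={g: 0.7 for g in ("TRPV3", "TACI", "COL4A4", "SAMSN1")},
        custom={
            "TFEC": {"unswMBC": 3.0},
            "ZBTB32": {"unswMBC": 3.0},
            "IGHG1": {"IgG": 5.0, "unswMBC": 0.5},
            "IGHA2": {"IgA": 5.0},
            "IGHM": {"IgG": -4.0, "IgA": -4.0, "unswMBC": -0.5},
            "IGHD": {"IgG": -6.0, "IgA": -6.0, "unswMBC": -1.0},
            "IGHE": {"IgG": 3.0},
        },
        feature_class={
            g: "IGHC" for g in ("IGHG1", "IGHA2", "IGHM", "IGHD", "IGHE")
        },
        baselines={"TFEC": 600.0, "ZBTB32": 600.0,
                   "IGHG1": 3000.0, "IGHA2": 3000.0, "IGHM": 5000.0,
                   "IGHD": 2000.0, "IGHE": 100.0},
    )
    return plan


def scaled_signature_plan(n_genes: int) -> SignaturePlan:
    """The default plan with the moderate DE background scaled to fit a
    smaller gene universe (full composition at 10,000 genes)."""
    f = min(1.0, n_genes / 10_000)
    return default_signature_plan(
        n_extra_up=int(round(445 * f)), n_extra_down=int(round(605 * f))
    )


def default_mirna_plan(effect: float = 3.0) -> SignaturePlan:
    """Planted miRNA profile: 6 up / 13 down shared by both switched subsets.

    Baselines are chosen on the small-RNA library scale so that every
    planted miRNA clears the delta-abundance > 1000 annotation rule, with
    the two MIR181-family analogues dropping by >60,000 and >3,000
    normalized transcripts respectively.
    """
    down_ids = ["MIR181A", "MIR181B"] + [f"MIRDN{i:02d}" for i in range(3, 14)]
    up_ids = [f"MIRUP{i:02d}" for i in range(1, 7)]
    baselines = {"MIR181A": 70_000.0, "MIR181B": 3_500.0}
    for i, m in enumerate(down_ids[2:]):
        baselines[m] = 1_500.0 * (1.15 ** i)
    for i, m in enumerate(up_ids):
        baselines[m] = 250.0 * (1.6 ** i)
    return SignaturePlan(
        up_genes={m: effect for m in up_ids},
        down_genes={m: -effect for m in down_ids},
        unsw_fraction=0.4,
        baselines=baselines,
    )


def default_lncrna_plan(effect: float = 3.0) -> SignaturePlan:
    """Planted lncRNA profile: 23 up / 17 down shared by both switched
    subsets; 21 of the 40 have baseline abundance giving a delta-abundance
    above 100. The MIAT analogue (a MIR181 sponge) follows the transitional
    attenuation in unswMBC, mirroring the inverse of the MIR181 profile so
    the planted sponge anticorrelation is graded across all 12 libraries."""
    up_ids = ["MIAT"] + [f"LNCUP{i:02d}" for i in range(2, 24)]
    down_ids = ["TCL6", "TUNAR", "LNC14H13"] + [
        f"LNCDN{i:02d}" for i in range(4, 18)
    ]
    baselines: dict[str, float] = {"MIAT": 400.0}
    for m in up_ids[1:12]:
        baselines[m] = 60.0            # delta = 7 * 60 = 420 > 100
    for m in up_ids[12:]:
        baselines[m] = 8.0             # delta = 56 < 100
    for m in down_ids[:9]:
        baselines[m] = 300.0           # delta = 0.875 * 300 = 262 > 100
    for m in down_ids[9:]:
        baselines[m] = 40.0            # delta = 35 < 100
    return SignaturePlan(
        up_genes={m: effect for m in up_ids},
        down_genes={m: -effect for m in down_ids},
        unsw_fraction=0.4,
        baselines=baselines,
    )


def _effect_matrix(
    plan: SignaturePlan, feature_ids: list[str], subsets: tuple[str, ...]
) -> pd.DataFrame:
    """Per-feature per-subset log2 effects relative to NBC."""
    eff = pd.DataFrame(0.0, index=feature_ids, columns=list(subsets))
    for table in (plan.up_genes, plan.down_genes, plan.extra_up, plan.extra_down):
        for g, e in table.items():
            frac = plan.unsw_override.get(g, plan.unsw_fraction)
            for s in subsets:
                if s in ("IgG", "IgA"):
                    eff.loc[g, s] = e
                elif s == "unswMBC":
                    eff.loc[g, s] = e * frac
    for table in (plan.isotype_specific, plan.custom):
        for g, per_subset in table.items():
            for s, e in per_subset.items():
                if s not in subsets:
                    raise ValueError(f"unknown subset {s!r} for feature {g!r}")
                eff.loc[g, s] = e
    return eff


def _roles(plan: SignaturePlan, feature_ids: list[str]) -> pd.Series:
    roles = pd.Series("null", index=feature_ids)
    for table, label in (
        (plan.up_genes, "signature_up"), (plan.down_genes, "signature_down"),
        (plan.isotype_specific, "isotype"), (plan.extra_up, "extra_up"),
        (plan.extra_down, "extra_down"), (plan.custom, "custom"),
    ):
        for g in table:
            roles[g] = label
    return roles


def _generate_counts(
    n_features: int,
    plan: SignaturePlan,
    config: GeneratorConfig,
    prefix: str,
    baseline_mean: float,
    lib_size_range: tuple[int, int],
    rng: np.random.Generator,
    length_range: tuple[int, int] = (500, 5000),
) -> tuple[CountMatrix, pd.DataFrame]:
    planted = plan.planted_ids()
    if len(planted) > n_features:
        raise ValueError("more planted features than features requested")
    n_null = n_features - len(planted)
    feature_ids = planted + [f"{prefix}{i:05d}" for i in range(1, n_null + 1)]

    baseline = baseline_mean * rng.lognormal(0.0, 1.2, size=n_features)
    for i, g in enumerate(planted):
        if g in plan.baselines:
            baseline[i] = plan.baselines[g]
        elif g in plan.down_genes:
            # downregulated signature genes are abundant where expressed
            # (their naive-subset level matches the switched-subset level of
            # the upregulated members)
            baseline[i] = (
                plan.planted_baseline_mean
                * 2.0 ** abs(plan.down_genes[g])
                * rng.lognormal(0.0, 0.25)
            )
        elif g in plan.up_genes or g in plan.isotype_specific or g in plan.custom:
            baseline[i] = plan.planted_baseline_mean * rng.lognormal(0.0, 0.25)
        elif plan.extra_baseline_mean is not None and (
            g in plan.extra_up or g in plan.extra_down
        ):
            # the moderate DE background sits at adequately-expressed levels
            # (a p_adj screen only ever reports genes with enough counts)
            baseline[i] = plan.extra_baseline_mean * rng.lognormal(0.0, 0.8)
    phi = config.dispersion_at(baseline)

    eff = _effect_matrix(plan, feature_ids, config.subsets)
    subjects = config.subjects()
    sample_ids = [f"{s}_{subj}" for s in config.subsets for subj in subjects]
    sample_subsets = [s for s in config.subsets for _ in subjects]
    sample_subjects = [subj for _ in config.subsets for subj in subjects]
    lo, hi = lib_size_range
    lib_sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(sample_ids)))

    mu = baseline[:, None] * 2.0 ** eff.loc[:, sample_subsets].values
    mu *= lib_sizes / mu.sum(axis=0)
    size = 1.0 / phi
    p = size[:, None] / (size[:, None] + mu)
    counts = np.empty_like(mu, dtype=np.int64)
    small = phi < 1e-8
    if small.any():
        counts[small] = rng.poisson(mu[small])
    if (~small).any():
        counts[~small] = rng.negative_binomial(size[~small, None], p[~small])

    lengths = rng.integers(length_range[0], length_range[1], size=n_features)
    fclass = pd.Series(
        [plan.feature_class.get(g, ".") for g in feature_ids], index=feature_ids
    )
    samples = pd.DataFrame(
        {"subset": sample_subsets, "subject": sample_subjects,
         "target_lib_size": lib_sizes.round().astype(int)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=feature_ids, columns=sample_ids),
        samples=samples,
        lengths=pd.Series(lengths, index=feature_ids, name="length"),
        feature_class=fclass,
    )
    truth = pd.DataFrame(
        {"role": _roles(plan, feature_ids), "baseline": baseline,
         "dispersion": phi, "feature_class": fclass},
        index=pd.Index(feature_ids, name="feature_id"),
    )
    for s in config.subsets:
        truth[f"effect_{s}"] = eff[s]
    return cm, truth


def generate_expression(
    config: GeneratorConfig, plan: SignaturePlan | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB mRNA counts for 4 subsets x n_subjects with the planted signature.

    Returns the count matrix and a truth table holding every planted effect
    (one row per feature; role ``null`` marks unplanted features, so truth
    and null together partition the feature universe).
    """
    if plan is None:
        plan = scaled_signature_plan(config.n_genes)
    rng = _rng(config.seed, stream=1)
    return _generate_counts(
        config.n_genes, plan, config, "G", config.baseline_mean,
        config.lib_size_range, rng,
    )


def generate_mirnome(
    config: GeneratorConfig, plan: SignaturePlan | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Small-RNA counts with the planted 6-up / 13-down miRNA profile."""
    if plan is None:
        plan = default_mirna_plan()
    rng = _rng(config.seed, stream=2)
    return _generate_counts(
        config.n_mirnas, plan, config, "MIR", config.mirna_baseline_mean,
        config.mirna_lib_size_range, rng, length_range=(60, 120),
    )


def generate_lncrnome(
    config: GeneratorConfig, plan: SignaturePlan | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """lncRNA counts with the planted 23-up / 17-down profile."""
    if plan is None:
        plan = default_lncrna_plan()
    rng = _rng(config.seed, stream=3)
    return _generate_counts(
        config.n_lncrnas, plan, config, "LNC", config.lncrna_baseline_mean,
        config.lncrna_lib_size_range, rng, length_range=(400, 4000),
    )


# ---------------------------------------------------------------------------
# Ig heavy-chain repertoire
# ---------------------------------------------------------------------------

_V_FAMILY_SIZES = {"V1": 11, "V2": 4, "V3": 23, "V4": 7, "V5": 2, "V6": 1, "V7": 1}
_V_FAMILY_WEIGHTS = {
    "V1": 0.17, "V2": 0.02, "V3": 0.55, "V4": 0.18,
    "V5": 0.03, "V6": 0.02, "V7": 0.03,
}
_J_WEIGHTS = {"J1": 0.05, "J2": 0.05, "J3": 0.08, "J4": 0.12, "J5": 0.30, "J6": 0.40}
_D_FAMILY_SIZES = {"D1": 4, "D2": 4, "D3": 5, "D4": 4, "D5": 4, "D6": 3, "D7": 3}

# IMGT-like V-region architecture in nt (0-based, half-open), 98 codons
V_REGIONS = {
    "FR1": (0, 78), "CDR1": (78, 102), "FR2": (102, 153),
    "CDR2": (153, 177), "FR3": (177, 294),
}
V_LENGTH = 294

DEFAULT_MUTATION_RATES = {
    "NBC": 0.0020, "unswMBC": 0.0417, "IgG": 0.0314, "IgA": 0.0566,
}
DEFAULT_CDR3_LENGTHS = {
    "NBC": (16.05, 3.3), "unswMBC": (14.86, 3.3),
    "IgG": (15.53, 3.3), "IgA": (15.08, 3.3),
}


@dataclass
class RepertoirePlan:
    """Sampling plan for synthetic heavy-chain reads."""

    germline_db: "object" = None  # repertoire.GermlineDB
    usage_weights: dict[str, float] = field(
        default_factory=lambda: dict(_V_FAMILY_WEIGHTS)
    )
    j_weights: dict[str, float] = field(default_factory=lambda: dict(_J_WEIGHTS))
    cdr3_length_dist: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CDR3_LENGTHS)
    )
    mutation_rate: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_RATES)
    )
    error_rate: float = 0.008

    def __post_init__(self) -> None:
        for w in (self.usage_weights, self.j_weights):
            total = sum(w.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("usage weights must sum to 1")
        rates = list(self.mutation_rate.values()) + [self.error_rate]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("rates must lie in [0, 1]")


def _random_codon_seq(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons))


def build_germline_db(seed: int = 0):
    """A synthetic heavy-chain germline database.

    49 V genes in 7 families (94 codons of framework/CDR architecture plus a
    terminal Cys codon region; members of a family diverge ~8% from the
    family root, families are unrelated), 27 D genes in 7 families and 6 J
    genes each opening with the conserved Trp codon.
    """
    from .repertoire import GermlineDB, GermlineGene

    rng = _rng(seed, stream=7)
    v: dict[str, GermlineGene] = {}
    for fam, size in _V_FAMILY_SIZES.items():
        root = [str(rng.choice(_SENSE_CODONS)) for _ in range(V_LENGTH // 3 - 1)]
        for m in range(1, size + 1):
            codons = list(root)
            # ~12% of codons substituted -> ~8% nt divergence within family
            n_sub = max(1, int(round(0.12 * len(codons))))
            for pos in rng.choice(len(codons), size=n_sub, replace=False):
                codons[pos] = str(rng.choice(_SENSE_CODONS))
            seq = "".join(codons) + "TGT"  # conserved 2nd-CYS codon
            gid = f"{fam}-{m}"
            v[gid] = GermlineGene(gid, fam, seq, regions=dict(V_REGIONS))
    d: dict[str, GermlineGene] = {}
    for fam, size in _D_FAMILY_SIZES.items():
        for m in range(1, size + 1):
            length = int(rng.integers(14, 27))
            gid = f"{fam}-{m}"
            d[gid] = GermlineGene(
                gid, fam, "".join(np.char.decode(rng.choice(_BASES, length)))
            )
    j: dict[str, GermlineGene] = {}
    for fam in _J_WEIGHTS:
        seq = "TGG" + _random_codon_seq(rng, 15)
        j[fam] = GermlineGene(fam, fam, seq)
    return GermlineDB(v=v, d=d, j=j)


def default_repertoire_plan(db=None, seed: int = 0) -> RepertoirePlan:
    if db is None:
        db = build_germline_db(seed)
    return RepertoirePlan(germline_db=db)


def _gene_weights(db, family_weights: dict[str, float]) -> tuple[list[str], np.ndarray]:
    """Split family weights among member genes with a geometric decay
    (within-family usage is uneven in real repertoires)."""
    ids, w = [], []
    members: dict[str, list[str]] = {}
    for gid, gene in db.v.items():
        members.setdefault(gene.family, []).append(gid)
    for fam, weight in family_weights.items():
        fam_members = members.get(fam, [])
        decay = 0.85 ** np.arange(len(fam_members))
        for gid, frac in zip(fam_members, decay / decay.sum()):
            ids.append(gid)
            w.append(weight * frac)
    w = np.asarray(w)
    return ids, w / w.sum()


def generate_repertoire(
    plan: RepertoirePlan, n_reads: int, subset: str, seed: int = 0
) -> tuple[dict[str, str], pd.DataFrame]:
    """Sample heavy-chain reads for one subset with known provenance.

    Each read is V + junction + J with the CDR3 length drawn per subset;
    the junction is N-nucleotides + a D-gene fragment + N-nucleotides.
    Substitutions land i.i.d. at rate mutation_rate + error_rate over the
    whole read and are attributed to true SHM vs sequencing error in the
    truth table. Returns (id -> sequence, truth).
    """
    db = plan.germline_db
    if db is None or not db.v or not db.d or not db.j:
        raise ValueError("germline database must contain V, D and J genes")
    if subset not in plan.mutation_rate:
        raise ValueError(f"no mutation rate for subset {subset!r}")
    rng = _rng(seed, stream=11)
    m_rate = plan.mutation_rate[subset]
    e_rate = plan.error_rate
    total_rate = m_rate + e_rate
    mean_len, sd_len = plan.cdr3_length_dist[subset]

    v_ids, v_w = _gene_weights(db, plan.usage_weights)
    j_ids = list(plan.j_weights)
    j_w = np.array([plan.j_weights[g] for g in j_ids])
    j_w = j_w / j_w.sum()
    d_ids = list(db.d)

    v_choice = rng.choice(len(v_ids), size=n_reads, p=v_w)
    j_choice = rng.choice(len(j_ids), size=n_reads, p=j_w)
    d_choice = rng.choice(len(d_ids), size=n_reads)
    cdr3_aa_len = np.clip(
        np.rint(rng.normal(mean_len, sd_len, size=n_reads)).astype(int), 5, 30
    )

    reads: dict[str, str] = {}
    rows = []
    for i in range(n_reads):
        v = db.v[v_ids[v_choice[i]]]
        dgene = db.d[d_ids[d_choice[i]]]
        jgene = db.j[j_ids[j_choice[i]]]
        total = 3 * int(cdr3_aa_len[i])
        n1 = int(rng.geometric(0.25) - 1)
        n2 = int(rng.geometric(0.25) - 1)
        if n1 + n2 > total:
            n1 = min(n1, total)
            n2 = total - n1
        d_frag = dgene.seq[: total - n1 - n2]
        pad = total - n1 - n2 - len(d_frag)
        junction = (
            "".join(np.char.decode(rng.choice(_BASES, n1)))
            + d_frag
            + "".join(np.char.decode(rng.choice(_BASES, n2 + pad)))
        )
        seq = v.seq + junction + jgene.seq
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        hit = rng.random(len(arr)) < total_rate
        pos = np.flatnonzero(hit)
        mut_pos, err_pos = [], []
        if len(pos):
            is_mut = rng.random(len(pos)) < (m_rate / total_rate if total_rate else 0.0)
            for pidx, p in enumerate(pos):
                old = arr[p]
                choices = _BASES[_BASES != old]
                arr[p] = rng.choice(choices)
                (mut_pos if is_mut[pidx] else err_pos).append(int(p))
        read_id = f"{subset}_r{i:06d}"
        reads[read_id] = arr.tobytes().decode()
        rows.append(
            {
                "read_id": read_id, "v_call": v.gene_id, "d_call": dgene.gene_id,
                "j_call": jgene.gene_id, "v_length": len(v.seq),
                "junction_length": total,
                "cdr3_aa": _translate(junction),
                "n_mutations": len(mut_pos), "n_errors": len(err_pos),
                "mutation_positions": ";".join(map(str, mut_pos)),
                "error_positions": ";".join(map(str, err_pos)),
            }
        )
    truth = pd.DataFrame(rows).set_index("read_id")
    return reads, truth


_CODON_TABLE: dict[str, str] = {}


def _translate(nt: str) -> str:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for a in "ACGT":
            for b in "ACGT":
                for c in "ACGT":
                    _CODON_TABLE[a + b + c] = str(Seq(a + b + c).translate())
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        aa.append(_CODON_TABLE.get(nt[i : i + 3], "X"))
    return "".join(aa)


# ---------------------------------------------------------------------------
# ATAC peaks
# ---------------------------------------------------------------------------


@dataclass
class AtacPlan:
    """Peak-presence Venn, planted DAR composition and DE concordance."""

    concordant_fraction: float = 0.354
    shared_fraction: float = 0.445
    mbc_only_fraction: float = 0.436
    nbc_only_fraction: float = 0.119
    n_dars: int = 4_198
    dar_up_fraction: float = 0.517
    dar_effect: float = 2.0
    peak_mean: float = 50.0
    peak_dispersion: float = 0.15
    absent_factor: float = 0.9
    peak_width: int = 500
    n_samples_per_group: int = 4

    def __post_init__(self) -> None:
        total = self.shared_fraction + self.mbc_only_fraction + self.nbc_only_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("Venn fractions must sum to 1")
        for f in (
            self.concordant_fraction, self.shared_fraction,
            self.mbc_only_fraction, self.nbc_only_fraction, self.dar_up_fraction,
        ):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def generate_atac(
    config: GeneratorConfig,
    plan: AtacPlan,
    truth: pd.DataFrame | None = None,
    gene_intervals: dict[str, GenomicInterval] | None = None,
) -> tuple[CountMatrix, list[GenomicInterval], pd.DataFrame]:
    """Peak counts (4 NBC + 4 MBC libraries), peak intervals and DAR truth.

    Peak presence follows the Venn plan; planted DARs receive +/-dar_effect
    log2 changes on the MBC side. For ``concordant_fraction`` of the planted
    DE genes in ``truth`` a same-direction DAR is placed within the
    assignment window of the gene locus; all other peaks live on a gene-free
    scaffold so concordance in the synthetic genome traces back exactly to
    the planted links.
    """
    rng = _rng(config.seed, stream=4)
    n = config.n_peaks
    cats = rng.choice(
        3, size=n,
        p=[plan.shared_fraction, plan.mbc_only_fraction, plan.nbc_only_fraction],
    )  # 0 shared, 1 mbc_only, 2 nbc_only
    category = np.array(["shared", "mbc_only", "nbc_only"])[cats]

    # concordant DAR placements next to planted DE genes
    linked_gene = np.array([""] * n, dtype=object)
    direction = np.array([""] * n, dtype=object)
    is_dar = np.zeros(n, dtype=bool)
    conc_assignments: list[tuple[str, str]] = []
    if truth is not None and plan.concordant_fraction > 0:
        de = truth[truth["role"].isin(
            ["signature_up", "signature_down", "extra_up", "extra_down"]
        )]
        for sign, roles in (("up", ("signature_up", "extra_up")),
                            ("down", ("signature_down", "extra_down"))):
            ids = list(de.index[de["role"].isin(roles)])
            k = int(round(plan.concordant_fraction * len(ids)))
            chosen = rng.choice(len(ids), size=k, replace=False)
            conc_assignments += [(ids[i], sign) for i in sorted(chosen)]
    n_conc = len(conc_assignments)
    if n_conc > n:
        raise ValueError("more concordant DARs than peaks")

    shared_idx = np.flatnonzero(cats == 0)
    if n_conc > len(shared_idx):
        raise ValueError("not enough shared peaks for concordant DARs")
    conc_slots = shared_idx[:n_conc]
    for slot, (gene, sign) in zip(conc_slots, conc_assignments):
        linked_gene[slot] = gene
        direction[slot] = sign
        is_dar[slot] = True

    # remaining planted DARs on background shared peaks, matching the split
    n_up_total = int(round(plan.dar_up_fraction * plan.n_dars))
    n_dn_total = plan.n_dars - n_up_total
    n_up_left = max(0, n_up_total - sum(1 for _, s in conc_assignments if s == "up"))
    n_dn_left = max(0, n_dn_total - sum(1 for _, s in conc_assignments if s == "down"))
    pool = shared_idx[n_conc:]
    if n_up_left + n_dn_left > len(pool):
        # small peak universes: keep the planted up/down split, shrink the load
        scale = len(pool) / (n_up_left + n_dn_left)
        n_up_left = int(n_up_left * scale)
        n_dn_left = int(n_dn_left * scale)
    picks = rng.choice(len(pool), size=n_up_left + n_dn_left, replace=False)
    for j, slot in enumerate(pool[np.sort(picks)]):
        sign = "up" if j < n_up_left else "down"
        direction[slot] = sign
        is_dar[slot] = True

    # coordinates: concordant peaks upstream of their gene, rest on a
    # gene-free scaffold chromosome
    intervals: list[GenomicInterval] = []
    bg_counter = 0
    for i in range(n):
        pid = f"PK{i+1:05d}"
        if linked_gene[i] and gene_intervals and linked_gene[i] in gene_intervals:
            g = gene_intervals[linked_gene[i]]
            start = max(0, g.start - 3000)
            intervals.append(
                GenomicInterval(g.chrom, start, start + plan.peak_width, name=pid)
            )
        else:
            start = 10_000 + bg_counter * (plan.peak_width + 1500)
            bg_counter += 1
            intervals.append(
                GenomicInterval("chrU", start, start + plan.peak_width, name=pid)
            )

    # counts
    npg = plan.n_samples_per_group
    sample_ids = [f"NBC_{c}" for c in "ADEF"[:npg]] + [f"MBC_{c}" for c in "ADEF"[:npg]]
    base = plan.peak_mean * rng.lognormal(0.0, 0.4, size=n)
    mu_nbc = base.copy()
    mu_mbc = base.copy()
    mu_nbc[cats == 1] *= plan.absent_factor  # MBC-only: weaker in NBC
    mu_mbc[cats == 2] *= plan.absent_factor  # NBC-only: weaker in MBC
    up = is_dar & (direction == "up")
    dn = is_dar & (direction == "down")
    mu_mbc[up] *= 2.0 ** plan.dar_effect
    mu_mbc[dn] *= 2.0 ** -plan.dar_effect
    lib_factor = rng.lognormal(0.0, 0.1, size=2 * npg)
    mu = np.concatenate(
        [np.tile(mu_nbc[:, None], npg), np.tile(mu_mbc[:, None], npg)], axis=1
    ) * lib_factor
    size = 1.0 / plan.peak_dispersion
    counts = rng.negative_binomial(size, size / (size + mu))

    peak_ids = [iv.name for iv in intervals]
    samples = pd.DataFrame(
        {"subset": ["NBC"] * npg + ["MBC"] * npg,
         "subject": list("ADEF"[:npg]) * 2},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=peak_ids, columns=sample_ids),
        samples=samples,
    )
    dar_truth = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "category": category,
            "is_dar": is_dar,
            "direction": direction,
            "linked_gene": linked_gene,
        },
        index=pd.Index(peak_ids, name="peak_id"),
    )
    return cm, intervals, dar_truth


# ---------------------------------------------------------------------------
# Annotation: loci, 3'UTRs, miRNA sequences
# ---------------------------------------------------------------------------


@dataclass
class MirnaTargetPlan:
    """Planted miRNA target sites and lncRNA locus layout.

    ``targets`` maps gene id -> (mirna id, site type, n sites); ``cis_pairs``
    lists (lncrna id, gene id) pairs to be placed within the cis window of
    their partner gene; lncRNAs not listed land on a gene-free chromosome
    (trans). ``coexpr_pairs`` optionally names (lncrna, gene, rho) pairs for
    latent-factor co-expression (consumed by ``apply_coexpression``).
    """

    targets: dict[str, tuple[str, str, int]] = field(default_factory=dict)
    utr_length_range: tuple[int, int] = (300, 1500)
    cis_pairs: list[tuple[str, str]] = field(default_factory=list)
    coexpr_pairs: list[tuple[str, str, float]] = field(default_factory=list)


def default_mirna_target_plan(n_extra_targets: int = 45) -> MirnaTargetPlan:
    """MIR181 seed sites in the 5 signature targets (RORA carries 3 sites,
    RASSF6 two, the rest one 8mer each) plus one 7mer-m8 site in each of
    ``n_extra_targets`` moderate up-regulated genes, giving 50 of the 462
    planted up genes a canonical site."""
    targets: dict[str, tuple[str, str, int]] = {
        "RASSF6": ("MIR181A", "8mer", 2),
        "TOX": ("MIR181A", "8mer", 1),
        "TRERF1": ("MIR181A", "8mer", 1),
        "TRPV3": ("MIR181A", "8mer", 1),
        "RORA": ("MIR181A", "8mer", 3),
    }
    for i in range(1, n_extra_targets + 1):
        targets[f"EXU{i:04d}"] = ("MIR181A", "7mer-m8", 1)
    cis = [(f"LNCUP{i:02d}", f"EXU{i:04d}") for i in range(2, 12)]
    return MirnaTargetPlan(targets=targets, cis_pairs=cis)


@dataclass
class AnnotationSet:
    genes: dict[str, GenomicInterval]
    lncrnas: dict[str, GenomicInterval]
    mirnas: dict[str, GenomicInterval]
    utrs: dict[str, str]
    mirna_seqs: dict[str, str]
    site_truth: pd.DataFrame


def _revcomp_rna(seq: str) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[b] for b in reversed(seq))


def _site_string(mirna_seq: str, site_type: str) -> str:
    """The mRNA-sense site sequence matching a given canonical site type."""
    core = _revcomp_rna(mirna_seq[1:7])        # pairs miRNA nt 2-7
    m8 = _revcomp_rna(mirna_seq[7])            # pairs miRNA nt 8 (site 5' end)
    if site_type == "6mer":
        return core
    if site_type == "7mer-m8":
        return m8 + core
    if site_type == "7mer-A1":
        return core + "A"
    if site_type == "8mer":
        return m8 + core + "A"
    raise ValueError(f"unknown site type {site_type!r}")


def generate_annotation(
    config: GeneratorConfig,
    plan: MirnaTargetPlan | None = None,
    gene_ids: list[str] | None = None,
    lncrna_ids: list[str] | None = None,
    mirna_ids: list[str] | None = None,
) -> AnnotationSet:
    """Gene/lncRNA/miRNA loci, 3'UTR sequences and mature miRNA sequences.

    Designated target genes carry the planted canonical MIR181-family seed
    sites (recorded in ``site_truth`` with 0-based site start positions);
    every other UTR is scrubbed of MIR181-family 6mer cores. Configured cis
    pairs place the lncRNA locus 50 kb from its partner gene; all other
    lncRNAs sit on a gene-free chromosome.
    """
    if plan is None:
        plan = default_mirna_target_plan()
    if gene_ids is None:
        sig = scaled_signature_plan(config.n_genes)
        gene_ids = sig.planted_ids() + [
            f"G{i:05d}" for i in range(1, config.n_genes - len(sig.planted_ids()) + 1)
        ]
    if lncrna_ids is None:
        lnc = default_lncrna_plan()
        lncrna_ids = lnc.planted_ids() + [
            f"LNC{i:05d}"
            for i in range(1, config.n_lncrnas - len(lnc.planted_ids()) + 1)
        ]
    if mirna_ids is None:
        mir = default_mirna_plan()
        mirna_ids = mir.planted_ids() + [
            f"MIR{i:05d}"
            for i in range(1, config.n_mirnas - len(mir.planted_ids()) + 1)
        ]
    rng = _rng(config.seed, stream=5)

    genes_per_chrom = 500
    genes: dict[str, GenomicInterval] = {}
    for i, g in enumerate(gene_ids):
        chrom = f"chr{1 + i // genes_per_chrom}"
        start = 30_000 + (i % genes_per_chrom) * 20_000
        genes[g] = GenomicInterval(chrom, start, start + 5_000, name=g, strand="+")

    lncrnas: dict[str, GenomicInterval] = {}
    cis_partner = dict(plan.cis_pairs)
    off = 0
    for l in lncrna_ids:
        if l in cis_partner and cis_partner[l] in genes:
            g = genes[cis_partner[l]]
            start = g.end + 50_000
            lncrnas[l] = GenomicInterval(g.chrom, start, start + 2_000, name=l)
        else:
            start = 20_000 + off * 25_000
            off += 1
            lncrnas[l] = GenomicInterval("chrL", start, start + 2_000, name=l)

    mirnas: dict[str, GenomicInterval] = {}
    for i, m in enumerate(mirna_ids):
        chrom = "chr1" if m == "MIR181A" else ("chr9" if m == "MIR181B" else "chrM1")
        start = 5_000_000 + i * 10_000
        mirnas[m] = GenomicInterval(chrom, start, start + 90, name=m)

    # mature miRNA sequences (RNA alphabet)
    mirna_seqs: dict[str, str] = {}
    rna = np.frombuffer(b"ACGU", dtype="S1")
    for m in mirna_ids:
        if m == "MIR181A":
            mirna_seqs[m] = MIR181A_SEQ
        elif m == "MIR181B":
            mirna_seqs[m] = MIR181B_SEQ
        else:
            mirna_seqs[m] = "".join(np.char.decode(rng.choice(rna, 22)))

    # UTRs: random sequence, scrubbed of MIR181-family cores, planted sites
    core = _revcomp_rna(MIR181A_SEQ[1:7])
    rows = []
    utrs: dict[str, str] = {}
    lo, hi = plan.utr_length_range
    for g in gene_ids:
        length = int(rng.integers(lo, hi))
        seq = list("".join(np.char.decode(rng.choice(rna, length))))
        utrs[g] = "".join(seq)
    for g in utrs:
        utrs[g] = _scrub(utrs[g], core, rng)
    for g, (mirna, site_type, n_sites) in plan.targets.items():
        if g not in utrs:
            continue
        site = _site_string(mirna_seqs[mirna], site_type)
        # pin the flanks so the planted type is also the scanned maximal
        # type: no accidental m8 pair 5' of the site, no accidental A 3'
        m8 = _revcomp_rna(mirna_seqs[mirna][7])
        left = "" if site_type in ("8mer", "7mer-m8") else _other_base(m8, rng)
        right = "" if site_type in ("8mer", "7mer-A1") else _other_base("A", rng)
        insert = left + site + right
        if len(utrs[g]) < len(insert) + 2:
            raise ValueError(f"UTR of {g} shorter than the planted site")
        seq = utrs[g]
        placed = 0
        attempts = 0
        positions: list[int] = []
        while placed < n_sites and attempts < 200:
            attempts += 1
            pos = int(rng.integers(1, len(seq) - len(insert)))
            if any(abs(pos - q) < len(insert) + 2 for q in positions):
                continue
            cand = seq[:pos] + insert + seq[pos + len(insert):]
            # the insert must not spawn extra cores at its flanks
            if cand.count(core) != len(positions) + 1:
                continue
            seq = cand
            positions.append(pos)
            placed += 1
        if placed < n_sites:
            raise ValueError(f"could not place {n_sites} sites in UTR of {g}")
        utrs[g] = seq
        for pos in sorted(positions):
            rows.append(
                {"gene": g, "mirna": mirna, "position": pos + len(left),
                 "site_type": site_type}
            )
    site_truth = pd.DataFrame(rows, columns=["gene", "mirna", "position", "site_type"])
    return AnnotationSet(genes, lncrnas, mirnas, utrs, mirna_seqs, site_truth)


def _other_base(base: str, rng: np.random.Generator) -> str:
    return str(rng.choice([b for b in "ACGU" if b != base]))


def _scrub(seq: str, core: str, rng: np.random.Generator) -> str:
    """Remove every occurrence of a seed core by point-changing one base."""
    s = list(seq)
    guard = 0
    while True:
        joined = "".join(s)
        pos = joined.find(core)
        if pos < 0:
            return joined
        guard += 1
        if guard > 10_000:
            raise RuntimeError("seed scrub failed to converge")
        mid = pos + len(core) // 2
        alternatives = [b for b in "ACGU" if b != s[mid]]
        s[mid] = str(rng.choice(alternatives))


def apply_coexpression(
    matrix: CountMatrix,
    partner: CountMatrix,
    pairs: list[tuple[str, str, float]],
    seed: int = 0,
) -> tuple[CountMatrix, CountMatrix]:
    """Impose latent-factor co-expression on designated cross-matrix pairs.

    For each (feature in ``matrix``, feature in ``partner``, rho), a shared
    per-sample lognormal latent factor multiplies both features' counts with
    coupling ``rho`` (thinning/boosting by binomial resampling of the scaled
    mean), inducing positive rank correlation without touching other rows.
    """
    rng = _rng(seed, stream=6)
    a = matrix.counts.copy()
    b = partner.counts.copy()
    n_samples = a.shape[1]
    for x, y, rho in pairs:
        z = rng.normal(0.0, 1.0, size=n_samples)
        for df, feat in ((a, x), (b, y)):
            if feat not in df.index:
                raise KeyError(f"unknown feature {feat!r}")
            factor = np.exp(rho * 0.6 * z)
            df.loc[feat] = rng.poisson(df.loc[feat].values.astype(float) * factor)
    cm_a = CountMatrix(a, matrix.samples, matrix.lengths, matrix.feature_class)
    cm_b = CountMatrix(b, partner.samples, partner.lengths, partner.feature_class)
    return cm_a, cm_b
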
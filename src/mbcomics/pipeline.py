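"""Top-level pipeline: simulate -> repertoire -> DE -> signature -> ATAC ->
ncRNA, with every output written to disk and hashed into a manifest.

Re-running with an identical configuration and seed reproduces identical
manifest hashes; all randomness flows through the single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import atac as atac_mod
from . import diffexpr, ncrna, repertoire, signature, synth
from .io import write_bed, write_counts, write_fasta, write_manifest

log = logging.getLogger("mbcomics")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one validated bundle."""

    outdir: str = "mbcomics_out"
    seed: int = 0
    # generator sizes
    n_genes: int = 10_000
    n_mirnas: int = 500
    n_lncrnas: int = 1_000
    n_peaks: int = 10_000
    n_subjects: int = 3
    n_reads_per_subset: int = 2_000
    baseline_mean: float = 15.0
    dispersion: float = 0.1
    # thresholds
    p_adj_core: float = signature.P_ADJ_CORE
    p_adj_unsw: float = signature.P_ADJ_UNSW
    p_cancel: float = signature.P_CANCEL
    mirna_p: float = 0.05
    mirna_min_delta: float = 1000.0
    lncrna_p: float = 0.001
    lncrna_min_delta: float = 100.0
    dar_p: float = 0.05
    window_bp: int = 10_000
    md_small_radius: int = 150
    md_large_radius: int = 1_500
    min_site_type: str = "7mer-m8"
    r_max: float = -0.5
    cis_window: int = 1_000_000
    r_report: float = 0.7
    error_rate: float = 0.008
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("p_adj_core", "p_adj_unsw", "p_cancel", "mirna_p",
                     "lncrna_p", "dar_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_site_type not in ncrna.SITE_RANK:
            raise ValueError(f"unknown site type {self.min_site_type!r}")
        if not self.md_small_radius < self.md_large_radius:
            raise ValueError("md_small_radius must be < md_large_radius")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def generator_config(self) -> synth.GeneratorConfig:
        return synth.GeneratorConfig(
            n_genes=self.n_genes, n_mirnas=self.n_mirnas,
            n_lncrnas=self.n_lncrnas, n_peaks=self.n_peaks,
            n_subjects=self.n_subjects, baseline_mean=self.baseline_mean,
            dispersion=self.dispersion, seed=self.seed,
        )


def _de_contrasts(cm, contrasts):
    return {
        name: diffexpr.nb_exact_test(cm, a, b) for name, (a, b) in contrasts.items()
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on a synthetic dataset and write a report bundle.

    Returns a dict with the in-memory results plus the output manifest.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    gc = config.generator_config()
    paths: dict[str, Path] = {}
    results: dict = {}

    def _stage(name: str, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # pragma: no cover - error surface
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # --- simulate ---------------------------------------------------------
    expr, expr_truth = _stage("simulate.expression",
                              lambda: synth.generate_expression(gc))
    mir, mir_truth = _stage("simulate.mirnome", lambda: synth.generate_mirnome(gc))
    lnc, lnc_truth = _stage("simulate.lncrnome", lambda: synth.generate_lncrnome(gc))
    ann = _stage(
        "simulate.annotation",
        lambda: synth.generate_annotation(
            gc,
            gene_ids=list(expr.feature_ids),
            lncrna_ids=list(lnc.feature_ids),
            mirna_ids=list(mir.feature_ids),
        ),
    )
    peaks_cm, peak_ivs, dar_truth = _stage(
        "simulate.atac",
        lambda: synth.generate_atac(gc, synth.AtacPlan(), expr_truth, ann.genes),
    )

    write_counts(expr, out / "expression_counts.tsv", out / "expression_samples.tsv")
    write_counts(mir, out / "mirna_counts.tsv", out / "mirna_samples.tsv")
    write_counts(lnc, out / "lncrna_counts.tsv", out / "lncrna_samples.tsv")
    write_counts(peaks_cm, out / "peak_counts.tsv", out / "peak_samples.tsv")
    write_bed(ann.genes.values(), out / "genes.bed")
    write_bed(ann.lncrnas.values(), out / "lncrnas.bed")
    write_bed(peak_ivs, out / "peaks.bed")
    write_fasta(ann.utrs, out / "utrs.fasta")
    write_fasta(ann.mirna_seqs, out / "mirnas.fasta")
    for p in out.glob("*.tsv"):
        paths[p.name] = p
    for p in list(out.glob("*.bed")) + list(out.glob("*.fasta")):
        paths[p.name] = p

    # --- repertoire -------------------------------------------------------
    plan = synth.default_repertoire_plan(seed=config.seed)
    rep_summary_rows = []
    for i, subset in enumerate(gc.subsets):
        reads, _ = synth.generate_repertoire(
            plan, config.n_reads_per_subset, subset, seed=config.seed + i
        )
        anns, qc = repertoire.assign_many(reads, plan.germline_db, call_d=False)
        summ = repertoire.mutation_frequency(anns, error_rate=config.error_rate)
        cdr3 = repertoire.cdr3_stats(anns)
        rep_summary_rows.append(
            {
                "subset": subset, "n_reads": qc["n_reads"],
                "n_assigned": qc["n_assigned"],
                "raw_freq": summ.raw_freq,
                "corrected_freq": summ.corrected_freq,
                "cdr3_mean": cdr3["mean"], "cdr3_sem": cdr3["sem"],
            }
        )
    rep_summary = pd.DataFrame(rep_summary_rows).set_index("subset")
    rep_summary.to_csv(out / "repertoire_summary.tsv", sep="\t")
    paths["repertoire_summary.tsv"] = out / "repertoire_summary.tsv"
    results["repertoire"] = rep_summary

    # --- differential expression + signature ------------------------------
    contrasts = {
        "IgG_vs_NBC": ("NBC", "IgG"),
        "IgA_vs_NBC": ("NBC", "IgA"),
        "IgG_vs_IgA": ("IgA", "IgG"),
        "unsw_vs_NBC": ("NBC", "unswMBC"),
    }
    de = _stage("de.mrna", lambda: _de_contrasts(expr, contrasts))
    for name, table in de.items():
        table.to_csv(out / f"de_mrna_{name}.tsv", sep="\t", index_label="feature_id")
        paths[f"de_mrna_{name}.tsv"] = out / f"de_mrna_{name}.tsv"
    sig = _stage(
        "signature.core",
        lambda: signature.core_signature(
            de["IgG_vs_NBC"], de["IgA_vs_NBC"], de["IgG_vs_IgA"],
            p_adj_core=config.p_adj_core, p_cancel=config.p_cancel,
            feature_class=expr.feature_class,
        ),
    )
    sig.to_frame().to_csv(out / "signature.tsv", sep="\t", index=False)
    paths["signature.tsv"] = out / "signature.tsv"
    results["signature"] = sig
    results["de_mrna"] = de

    if len(sig) >= 2:
        log_expr = diffexpr.normalize_units(expr, unit="RPKM", log2=True)
        emb = signature.embed_subsets(
            log_expr.loc[sig.members], expr.samples["subset"]
        )
        emb["coordinates"].to_csv(out / "embedding.tsv", sep="\t",
                                  index_label="sample_id")
        paths["embedding.tsv"] = out / "embedding.tsv"
        results["embedding"] = emb

    # --- miRNA / lncRNA profiles ------------------------------------------
    de_mir = _stage("de.mirna", lambda: _de_contrasts(
        mir, {k: v for k, v in contrasts.items() if k != "unsw_vs_NBC"}))
    mir_profile = signature.shared_de(
        de_mir["IgG_vs_NBC"], de_mir["IgA_vs_NBC"],
        p_threshold=config.mirna_p, min_delta_abundance=config.mirna_min_delta,
    )
    mir_profile.to_csv(out / "mirna_profile.tsv", sep="\t", index_label="feature_id")
    paths["mirna_profile.tsv"] = out / "mirna_profile.tsv"
    results["mirna_profile"] = mir_profile

    de_lnc = _stage("de.lncrna", lambda: _de_contrasts(
        lnc, {k: v for k, v in contrasts.items() if k != "unsw_vs_NBC"}))
    lnc_profile = signature.shared_de(
        de_lnc["IgG_vs_NBC"], de_lnc["IgA_vs_NBC"],
        p_threshold=config.lncrna_p, min_delta_abundance=0.0,
    )
    lnc_profile["high_abundance"] = (
        lnc_profile["delta_abundance"] > config.lncrna_min_delta
    )
    lnc_profile.to_csv(out / "lncrna_profile.tsv", sep="\t", index_label="feature_id")
    paths["lncrna_profile.tsv"] = out / "lncrna_profile.tsv"
    results["lncrna_profile"] = lnc_profile

    # --- ATAC --------------------------------------------------------------
    nbc_peaks = [iv for iv, cat in zip(peak_ivs, dar_truth["category"])
                 if cat in ("shared", "nbc_only")]
    mbc_peaks = [iv for iv, cat in zip(peak_ivs, dar_truth["category"])
                 if cat in ("shared", "mbc_only")]
    venn = atac_mod.venn_peaks(nbc_peaks, mbc_peaks)
    dars = _stage("atac.dars", lambda: atac_mod.call_dars(
        peaks_cm, "NBC", "MBC", p_threshold=config.dar_p))
    dars.to_csv(out / "dars.tsv", sep="\t", index_label="peak_id")
    paths["dars.tsv"] = out / "dars.tsv"
    de_gene_table = signature.shared_de(
        de["IgG_vs_NBC"], de["IgA_vs_NBC"], p_threshold=0.05, use_adjusted=True
    )
    dar_ivs = {iv.name: iv for iv in peak_ivs}
    conc = atac_mod.integrate_de_dar(
        de_gene_table, dars, ann.genes, dar_ivs, window_bp=config.window_bp
    )
    results["venn"] = venn
    results["dars"] = dars
    results["concordance"] = conc

    # --- ncRNA screens ------------------------------------------------------
    gene_rpkm = diffexpr.normalize_units(expr, unit="RPKM")
    mir_rpm = diffexpr.normalize_units(mir, unit="RPM")
    lnc_rpkm = diffexpr.normalize_units(lnc, unit="RPKM")
    up_genes = list(de_gene_table.index[de_gene_table["direction"] == "up"])
    down_mirnas = list(mir_profile.index[mir_profile["direction"] == "down"])
    matches = []
    for m in down_mirnas:
        seq = ann.mirna_seqs.get(m)
        if seq is None:
            continue
        for g in up_genes:
            for sm in ncrna.find_seed_sites(
                ann.utrs[g], seq, mirna_id=m, gene_id=g
            ):
                matches.append(sm)
    match_df = pd.DataFrame(
        [(s.gene, s.mirna, s.position, s.site_type) for s in matches],
        columns=["gene", "mirna", "position", "site_type"],
    )
    release = ncrna.target_release_screen(
        up_genes, down_mirnas, match_df, gene_rpkm, mir_rpm,
        min_site_type=config.min_site_type, r_max=config.r_max,
    )
    release["pairs"].to_csv(out / "target_release.tsv", sep="\t", index=False)
    paths["target_release.tsv"] = out / "target_release.tsv"
    results["release"] = release

    mir181_targets = sorted(
        set(release["targets_by_mirna"].get("MIR181A", []))
        | set(release["targets_by_mirna"].get("MIR181B", []))
    )
    frac_mir181 = len(mir181_targets) / len(up_genes) if up_genes else 0.0

    up_lnc = list(lnc_profile.index[lnc_profile["direction"] == "up"])
    sponges = ncrna.sponge_screen(
        up_lnc, down_mirnas, release, lnc_rpkm, mir_rpm, gene_rpkm
    )
    sponges.to_csv(out / "sponges.tsv", sep="\t", index=False)
    paths["sponges.tsv"] = out / "sponges.tsv"
    results["sponges"] = sponges

    summary = {
        "signature_size": len(sig),
        "signature_up": len(sig.up),
        "signature_down": len(sig.down),
        "n_de_mirnas": int(len(mir_profile)),
        "n_de_lncrnas": int(len(lnc_profile)),
        "venn_fractions": venn.fractions,
        "n_dars": int(dars["significant"].sum()),
        "fraction_concordant": conc.fraction_concordant,
        "fraction_up_targeted": release["fraction_up_targeted"],
        "fraction_up_targeted_mir181": frac_mir181,
        "n_mir181_targets": len(mir181_targets),
        "n_sponge_candidates": int(len(sponges)),
        "repertoire_corrected_freq": rep_summary["corrected_freq"].to_dict(),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["summary.json"] = out / "summary.json"
    results["summary"] = summary
    results["manifest"] = write_manifest(paths, out / "manifest.json")
    return results
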
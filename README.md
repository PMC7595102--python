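# mbcomics

Integrative multi-omic analysis of human memory B cells (MBCs) versus naive
B cells (NBCs), built as a tested, reusable Python pipeline with a
synthetic-data generator that plants known ground truth in every input.

Human class-switched memory B cells (IgG⁺ and IgA⁺ swMBCs), unswitched
memory B cells (IgD⁺ unswMBCs) and naive B cells can be profiled in
parallel by RNA-seq (mRNA/lncRNA), small-RNA-seq (miRNA), ATAC-seq and
heavy-chain V(D)J amplicon sequencing. `mbcomics` implements the analysis
layer of such a study:

- **Differential expression** — TMM (trimmed-mean-of-M-values)
  normalization and a conditional negative-binomial exact test with
  Benjamini–Hochberg FDR control, shared by the mRNA, miRNA, lncRNA and
  ATAC-peak matrices. The NB model is `var = μ + φμ²`; per-feature
  dispersions are moment estimates moderated by an abundance trend, and
  the test conditions the group-B sum on the total (a Beta-negative-
  binomial null, free of the unknown mean).
- **Core transcriptional signature** — the set of genes DE in the *same
  direction* in both swMBC-vs-NBC contrasts at a stringent threshold
  (p_adj < 1e-29) that *cancel out* in the IgG-vs-IgA contrast
  (p_adj ≥ 0.05 there), with Ig heavy-chain constant-region transcripts
  reported separately. PCA embedding with subset silhouettes and 95%
  prediction ellipses, and row-standardized heatmap matrices.
- **Ig repertoire** — germline V/D/J assignment (edit-distance prefix /
  suffix alignment, ungapped D matching), gene- and family-level usage
  with Spearman conservation correlations, IMGT-style CDR3 length
  statistics, and the somatic-hypermutation frequency in change/base,
  corrected by subtracting the combined polymerase/sequencing error rate
  (0.008) with a floor at zero.
- **Chromatin accessibility** — peak-set Venn comparison on merged
  intervals, differential accessibility (raw p < 0.05 screen),
  DE-gene/DAR concordance within gene-body ± 10 kb windows, and
  motif-displacement (MD) scores (fraction of motif hits within 150 bp of
  a peak center among those within 1.5 kb).
- **ncRNA regulation** — canonical miRNA seed-site scanning (6mer,
  7mer-A1, 7mer-m8, 8mer), a nearest-neighbor duplex free-energy score,
  the target-release screen (up gene + down miRNA + canonical site +
  inverse Spearman correlation across the 12 sorted libraries), lncRNA
  cis/trans co-expression, and a miRNA-sponge (ceRNA) screen.
- **Synthetic data** — every input above, generated with planted truth
  that mirrors the study design: 4 subsets × 3 subjects, a 17-up/7-down
  core signature attenuated in unswMBC, 6-up/13-down miRNAs (MIR181a/b
  analogues down by >60,000 and >3,000 normalized transcripts),
  23-up/17-down lncRNAs (a MIAT sponge analogue among them), peak-presence
  Venn fractions 43.6/11.9/44.5%, DARs 51.7% up / 48.3% down with 35.4% of
  DE genes given a concordant DAR, repertoire reads at subset-specific
  mutation rates (0.0020/0.0417/0.0314/0.0566 change/base) over a 0.008
  error floor, and 3'UTRs carrying MIR181-family seed sites in designated
  target genes (RASSF6/TOX/TRERF1/TRPV3/RORA analogues).

## Worked example

Run the whole synthetic study end to end (about 15 s):

```bash
mbcomics run --seed 1 --outdir run1
```

which prints (abridged):

```json
{
  "signature_size": 24,
  "signature_up": 17,
  "signature_down": 7,
  "n_de_mirnas": 19,
  "n_de_lncrnas": 40,
  "venn_fractions": {"shared": 0.4453, "unique_a": 0.1166, "unique_b": 0.4381},
  "n_dars": 4530,
  "fraction_concordant": 0.3685,
  "fraction_up_targeted_mir181": 0.0667,
  "n_sponge_candidates": 276,
  "repertoire_corrected_freq": {
    "NBC": 0.0020, "unswMBC": 0.0416, "IgG": 0.0317, "IgA": 0.0566
  }
}
```

Reading the output: the intersection-and-cancellation screen recovers the
planted 24-gene core signature exactly (17 up, 7 down; the IgH constant-
region features qualify but are excluded by class). The shared miRNA
screen (p < 0.05 in both swMBC contrasts, Δabundance > 1000) returns the
19 planted miRNAs; the lncRNA screen (p < 0.001) the 40 planted lncRNAs.
Peak-presence fractions land on the planted Venn plan within multinomial
noise, about 37% of the shared DE genes have a same-direction DAR within
10 kb (0.354 planted times DAR-detection sensitivity, plus a small
false-positive contribution), and the corrected mutation frequencies
recover the planted per-subset rates. `run1/` holds every intermediate
table (counts, DE tables, signature, DARs, screens) plus `manifest.json`
with a SHA-256 per output; re-running with the same seed reproduces the
hashes bit for bit.

The same steps are available as a library:

```python
from mbcomics import synth, diffexpr, signature

cfg = synth.GeneratorConfig(seed=1)
counts, truth = synth.generate_expression(cfg)
de_g = diffexpr.nb_exact_test(counts, "NBC", "IgG")
de_a = diffexpr.nb_exact_test(counts, "NBC", "IgA")
de_i = diffexpr.nb_exact_test(counts, "IgA", "IgG")
sig = signature.core_signature(de_g, de_a, de_i,
                               feature_class=counts.feature_class)
print(len(sig.up), len(sig.down))   # 17 7
```

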
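# pirsig

Small-RNA signature analysis for piRNA / piRNA-like profiling studies, built
around the kind of question asked in sporadic Parkinson's disease (PD)
modelling: given small-RNA sequencing of patient- and control-derived cells
(fibroblasts, iPSCs, differentiated neurons) or brain tissue, which piRNAs
are deregulated between groups, what characterizes the deregulated set
(transposon element of origin, positional nucleotide composition, 5′U bias),
how much of the signature is epigenetic "memory" carried over from the
parental cells, and how well does it separate cases from controls?

The package provides, as a library plus a `pirsig` command-line tool:

- **Reference handling** — piRNA FASTA + element-of-origin annotation
  (SINE/LINE/LTR/genic/other, piRBase-style), with sequence QC: the canonical
  24–32 nt length fraction, the 5′-uridine bias, and a snoRNA-contamination
  substring screen.
- **Quantification** — read-to-piRNA assignment by exact length match and
  Hamming distance ≤ 1 (substitutions only), with `all` / `unique` /
  `fractional` multi-match policies, RPKM, and marker-gene content scores
  for composition covariates.
- **Differential expression** — a self-contained negative-binomial Wald
  pipeline: median-of-ratios size factors *s<sub>j</sub>*, per-feature
  dispersions *α<sub>i</sub>* (method of moments shrunk toward a fitted
  trend *α(μ) = a₁/μ + a₀*), the NB log-linear model
  log μ<sub>ij</sub> = x<sub>j</sub><sup>T</sup>β<sub>i</sub> + log s<sub>j</sub>
  with additive covariates (sex, passage, neuronal content), a Wald test on
  the contrast coefficient, and Benjamini–Hochberg adjustment. Features are
  called deregulated at **|log₂FC| ≥ 0.6 and adjusted p < 0.1**.
- **Signature statistics** — per-class element-of-origin enrichment against
  genome-wide null proportions *p₀* via the one-vs-rest goodness-of-fit
  statistic χ² = (k − np₀)²/(np₀) + ((n−k) − n(1−p₀))²/(n(1−p₀)) (1 df);
  positional cytosine-composition comparison over positions 1–29; memory
  fractions across differentiation stages; direction-stratified cross-cohort
  overlaps; and TOP-N hierarchical clustering (1 − Pearson, average linkage)
  scored by adjusted Rand index against the group labels.
- **Synthetic data** — a fully seeded generator producing references, NB
  count matrices, sample sheets, FASTQ reads and ground-truth tables with
  the structure the analysis assumes (planted fold changes, SINE-enriched
  down-regulated sets, cytosine bias at positions 2–9 of up-regulated
  piRNAs, 5′U bias, canonical + shorter piRNA-like lengths), so every stage
  is testable end to end without any downloads.

## Worked example

Run the full workflow on a synthetic disease-vs-control cohort (8 vs 8
neurons, 5,000 piRNAs, 4% planted deregulation at |log₂FC| = 1.5):

```sh
cat > cfg.txt <<EOF
scenario = pd_neuron
seed = 11
out_dir = demo
EOF
pirsig all --config cfg.txt
cat demo/summary.txt
```

which prints:

```
pirsig 0.1.0 signature run (seed 11)
reference: 5000 features, canonical fraction 0.792, 5'U fraction 0.798
[neuron] up=83 down=123 cluster ARI=1.000 top20 abundant-DE count share=0.015
```

i.e. 206 piRNAs called deregulated, and the TOP100 most significant piRNAs
separate cases from controls perfectly (ARI = 1.0). The element-of-origin
table for the down-regulated set (`demo/enrichment_neuron.tsv`) shows the
planted transposon signal:

```
origin_class  k   n     p0     chi2            p  direction
        SINE 63 123 0.2030 72.68020 1.524570e-17   enriched
```

63 of 123 down-regulated piRNAs are SINE-derived against a genome-wide null
proportion of 0.20 — a strong enrichment, as expected from the generator's
SINE-heavy override for planted down-regulated features.
`demo/composition_neuron.tsv` holds the positional cytosine profiles (the
up-regulated set exceeds the all-piRNA reference by > 0.2 at each of
positions 2–9), and `demo/memory.tsv` / `demo/overlap.tsv` report
cross-stage statistics when several cell types are present (e.g.
`scenario = differentiation`).

The same stages are available piecewise (`pirsig simulate|quantify|de|signature`)
and as library functions (`pirsig.nb_wald`, `pirsig.origin_enrichment`, …).

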
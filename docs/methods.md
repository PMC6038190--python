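# Methods

## Problem setting

piRNAs are PIWI-interacting small RNAs, canonically 24–32 nt, that silence
retrotransposons; sequence catalogs also contain shorter "piRNA-like"
species, and both are detectable outside the germline, including brain and
neuronal cultures. In disease-modelling studies the questions are (i) which
piRNAs differ between patient- and control-derived samples, (ii) whether the
deregulated set is biased toward transposon-derived (SINE/LINE) piRNAs or a
particular positional nucleotide composition, (iii) how much of a signature
seen in differentiated cells was already present in the parental fibroblasts
("epigenetic memory"), and (iv) whether independent cohorts (e.g. cultured
neurons vs post-mortem tissue) share deregulated piRNAs in a
direction-consistent way. `pirsig` implements that analysis chain as
testable, seeded components.

## Reference model and QC

A reference record is an id, a U-normalized sequence (15–45 nt sanity
range), and an element-of-origin class from the fixed set
{SINE, LINE, LTR, GENIC, OTHER, UNKNOWN}; any other annotation string maps
to OTHER and missing annotations to UNKNOWN. A record is canonical iff its
length is 24–32 nt. QC statistics: the 5′U fraction (canonical piRNAs are
uridine-biased at position 1), the canonical-length fraction, and a snoRNA
screen that counts a piRNA as contaminated iff its full sequence is an exact
substring of a snoRNA on the given strand — the most conservative
reproducible matching rule, since snoRNA degradation fragments are a known
contaminant of piRNA catalogs. UNKNOWN records stay in the enrichment
universe by default (`include_unknown=False` to drop them), because the
natural null is "all piRNAs analysed".

## Quantification

A read matches a reference feature iff lengths are equal and the Hamming
distance is ≤ 1. Substitution-only matching is the standard contract for
≤ 32 nt small RNAs; reads containing N never match. Multi-match policies:
`all` (default; piRNA catalogs contain near-duplicates and per-piRNA counts
are wanted), `unique` (discard ambiguous reads), `fractional` (1/m per
match, per-feature totals rounded half-to-even to keep the matrix integral).
Positional base content is 1-based from the 5′ end; the denominator at
position k counts only sequences of length ≥ k. RPKM uses the mature
sequence length as the "kilobase of model". The 3′-adapter trimming helper
(exact-prefix search, min overlap 10) is a convenience, not part of the core
contract — inputs are assumed adapter-trimmed.

## Differential expression

A deliberately compact NB Wald pipeline in the DESeq2 tradition; numerical
equivalence with any external tool is not a goal — the downstream claims are
threshold-based and the stage is validated by simulation calibration.

- **Size factors**: median-of-ratios. For every feature with no zero count,
  each sample's count is divided by the feature's geometric mean; the
  sample's factor is the median ratio. Note these factors are defined only
  up to the geometric-mean reference: scaling one column by c scales its
  factor *relative to the others* by exactly c (the absolute factor moves by
  c^((n−1)/n)).
- **Dispersions**: per-feature method of moments on normalized counts,
  α̂ = (s² − ξμ̄)/μ̄² with ξ = mean(1/s_j) correcting the Poisson part and
  s² taken from linear-projection residuals with an n−p degree-of-freedom
  correction. A robust trend α(μ) = a₀ + a₁/μ is fitted by Huber-weighted
  non-negative least squares over all finite MoM values — negatives
  included, since truncating them first biases the trend upward when the
  true dispersion is near zero; non-negative LS (rather than clipping a free
  fit coefficient-wise) keeps the intercept honest when 1/μ is nearly
  constant across features. Features with a positive MoM estimate get a
  50/50 log-scale blend of MoM and trend; non-positive MoM estimates take
  the trend value directly; everything is floored at 1e-8. With fewer than
  five usable features the trend is skipped and raw MoM values are used.
- **GLM fit**: per-feature NB log-linear model with log size-factor offsets,
  fitted by IRLS vectorized across features (shared design matrix; batched
  p×p solves; η clipped to ±30; up to 60 iterations, step tolerance 1e-8).
  The contrast is a two-level factor dummy-coded against the first level in
  sample-sheet order; covariates enter additively (numeric as-is,
  categorical dummy-coded against their first observed level). Features with
  all-zero counts, or whose fit does not stabilize, are flagged untested and
  excluded from the multiple-testing adjustment.
- **Test**: Wald statistic log₂FC/SE against a **two-sided t reference with
  residual df (n − p)**. At the cohort sizes this package targets (8 vs 8),
  the Wald statistic with an estimated dispersion is noticeably
  heavier-tailed than normal; a normal reference inflated the far tail
  roughly two-fold and with it the empirical FDR of the call rule, while the
  t reference keeps both the raw type-I rate and the FDR calibrated. This is
  the same style of small-sample correction used by quasi-likelihood small-
  count pipelines.
- **Call rule**: up iff log₂FC ≥ +0.6 and padj < 0.1; down iff
  log₂FC ≤ −0.6 and padj < 0.1. The fold-change threshold is inclusive, the
  adjusted-p threshold strict; the threshold is applied to the unshrunken
  MLE. BH adjustment is the standard step-up procedure (statsmodels).
- Not implemented (out of scope by design): LFC shrinkage, independent
  filtering, Cook's-distance outlier refitting, likelihood-ratio tests.
- The `rlog`-style transform used for clustering and top-variable ranking is
  log₂(normalized + 1); only rank structure matters downstream.

A caveat worth knowing: median-based normalization absorbs planted signal
when deregulation is strongly one-directional and abundant (≥ ~15% of
features in one direction shifts the fold-change scale by ~0.2 log₂). This
is a property of median-of-ratios itself, not of this implementation; the
study-scale scenarios (4% deregulated, 60/40 split) are essentially
unaffected.

## Signature statistics

- **Origin enrichment**: the null proportions p₀ per class are the fixed
  genome-wide shares among all reference piRNAs. Each class is tested
  one-vs-rest with the 1-df goodness-of-fit statistic
  χ² = (k − np₀)²/(np₀) + ((n−k) − n(1−p₀))²/(n(1−p₀)), no continuity
  correction; the reported p is the upper tail, the conventional reading of
  a "two-sided chi-square test". Classes with p₀ ∈ {0, 1} are untestable.
  Per-class results are reported without cross-class multiplicity
  correction, mirroring per-class reporting practice.
- **Composition bias**: positional base profiles (default cytosine,
  positions 1–29) for the up set, the down set and the universe, with
  per-position differences and a configurable flagging threshold
  (default 0.1).
- **Memory fraction**: among a differentiated stage's deregulated piRNAs,
  the share also deregulated in the fibroblast stage. Default is
  direction-agnostic membership ("already differentially expressed"), with a
  direction-matched mode available since the stricter reading is equally
  defensible.
- **Overlap**: direction-stratified (up∩up, down∩down); a piRNA that flips
  direction between cohorts is not "shared".
- **Clustering**: samples are clustered on a feature panel (typically the
  TOP100 by adjusted p) with distance 1 − Pearson correlation, average
  linkage, a two-cluster cut, and the adjusted Rand index against the group
  labels. The dialect (metric/linkage/cut) is fixed for reproducibility and
  exposed as parameters; zero-variance sample columns are an error naming
  the sample.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, with
one `numpy.random.Generator` seeded once and handed through all sub-steps in
fixed order (same parameters ⇒ byte-identical outputs).

- **Reference**: i.i.d. per-position sequences from background base
  probabilities (uniform 0.25 by default); position 1 is U with probability
  0.8; lengths uniform on 24–32 nt for a canonical share of 0.8 and on
  18–23 nt otherwise (the gap makes the canonical/piRNA-like decomposition
  unambiguous). Planted up-regulated features draw C at positions 2–9 with
  probability 0.6 (background 0.25); planted down-regulated features draw
  their origin from a SINE-heavy override (SINE 0.5 vs genome-wide 0.2);
  null features use the genome-wide mixture (SINE 0.2, LINE 0.15, LTR 0.1,
  GENIC 0.25, OTHER 0.3).
- **Counts**: feature baseline means 2^N(6.64, 1) (≈100); group-2 means
  multiplied by 2^(±1.5) on planted features; NB with dispersion α = 0.1;
  per-sample library-size multipliers log-uniform in [0.5, 2]; an optional
  sex effect on the log-mean (0.25 log₂ in the disease scenario, so the
  covariate path is exercised; 0 by default).
- **Scenarios**: `null` (2,000 features, 8 vs 8, no effects),
  `pd_neuron` (5,000 features, 8 vs 8, 4% deregulated at |log₂FC| = 1.5,
  60% down — mirroring the scale of an 8-control / 7-patient neuron
  cohort), and `differentiation` (fibroblast + neuron stages whose planted
  deregulated sets share 8%, below the ~10% memory bound the analysis is
  meant to detect).
- **Reads**: each reference sequence is emitted count-many times with
  independent per-base substitution errors (≤ 5%), in the DNA alphabet.

What the generator does **not** emulate: genomic placement and locus
structure of piRNAs, sequence-composition-dependent counting biases,
correlated features, isomiR-style length heterogeneity around a reference
sequence, batch structure beyond a single sex covariate, and read-quality
variation. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the assumed NB model — not that any particular
biological cohort will reproduce a given signature.

## Pipeline determinism and sizes

The CLI analyses each cell type independently (its own covariates), then
computes cross-stage memory and overlap tables. All outputs are plain TSV
with `#` header comments carrying parameters, plus a JSON manifest without
timestamps, so identical config + seed reproduces the bundle byte for byte.
Default problem sizes (2,000–5,000 features, 16 samples per contrast) keep a
full end-to-end run in the low seconds while leaving Monte-Carlo bands for
the calibration checks (3σ binomial) comfortably narrow.

## Known limitations

- The NB stage targets two-level contrasts only; no continuous contrasts or
  likelihood-ratio tests.
- Dispersion shrinkage is a fixed 50/50 log-scale blend, not an empirical
  Bayes posterior; it is calibrated for the cohort sizes above, and very
  small designs (n < 6) will lean heavily on the trend.
- The snoRNA screen is exact-substring only; a divergent contaminant would
  be missed.
- `fractional` counting rounds to integers half-to-even, so column totals
  can differ slightly from the unrounded fractional mass.
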
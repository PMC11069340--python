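# Methods

`isocat` reimplements, as a reusable pipeline, the integrated screen by
which an isoflavone-catabolism gene cluster can be discovered in a
panel of rhizosphere bacteria: a three-criteria intersection of
expression induction, conservation in degrader strains and loss in
non-degraders, followed by chromosomal hotspot detection, trait
enrichment, growth-inhibition quantification and exact-mass annotation
of catabolic intermediates. A synthetic-data module plants ground truth
so the whole analysis is testable without external sequence deposits.

## The screen

For a reference strain (the strain with RNA-seq data; itself a
degrader) each gene is evaluated against three criteria:

1. **Induced by the substrate.** Counts are CPM-normalized (each sample
   column rescaled to sum to 10⁶) and the per-gene statistic is
   `log2FC = log2((mean treated CPM + p) / (mean control CPM + p))`
   with pseudocount `p = 1` CPM. Means are arithmetic means of CPM over
   replicates (a ratio of means, not a mean of log-ratios). The default
   call is `log2FC ≥ 1`. No dispersion modelling is done: the criterion
   is a threshold on effect size, not a significance test.
2. **Conserved in degraders.** For every reference gene and every
   strain, the best hit is the strain protein with the highest percent
   identity among global alignments with coverage ≥ 50 % of the
   reference and alignment score > 0. By default a gene must be
   conserved (identity ≥ 50 %, coverage ≥ 50 %) in **all** degrader
   strains (fraction configurable).
3. **Lost or diverged in non-degraders.** The gene must be absent (no
   qualifying hit) or below 30 % identity in **all** non-degrader
   strains (fraction configurable).

The reference strain's own column is trivially perfect and is excluded
from both fractions. No numeric cutoffs exist in the published form of
this screen; the defaults above are package choices, exposed in the
config, selected to sit between the two modes of the identity
distribution the generator plants (≈ 95 % for orthologs at the default
divergence, ≤ ~30 % for spurious alignments of unrelated proteins).

### Alignment

Conservation uses global Needleman–Wunsch/Gotoh alignment with
BLOSUM62, affine gap cost `10 + 1·L` for a gap of length `L`, and
penalized end gaps (via Biopython's `PairwiseAligner`). Identity is
counted over both-non-gap columns, with `X` never counting as identical
(conservative); coverage is the fraction of reference residues paired
with a residue. This stands in for a local BLASTP search: the screen
needs a consistent conservation score, not BLAST's exact values, and
the parameters are all configurable.

Two consequences of using a *global* aligner are handled explicitly:

* a global alignment always exists, even between unrelated proteins,
  and at ≥ 50 % coverage it can reach ~25–33 % identity by chance. A
  local search would simply report no hit, so hits are required to have
  a positive alignment score (`min_score = 0`); empirically spurious
  best hits score ≤ 0 while even 30 %-diverged orthologs score in the
  hundreds, so the filter is far from the decision boundary.
* best-hit search against every protein of every strain is quadratic;
  an edit-distance prefilter (edlib) keeps only the `prefilter_k = 5`
  closest targets per strain before full alignment. Set
  `prefilter_k = None` for exhaustive search.

Ties on identity break to the lexicographically lowest locus id.
Alignment-path ties at equal score are resolved by the aligner's
deterministic first-alignment ordering; the score itself is
tie-independent.

### Hotspots

Candidate flags are ordered by gene rank (coordinate order within each
replicon — adjacency of loci, not base pairs). A hotspot is a maximal
run containing ≥ `min_run = 4` candidates with at most `max_gap = 2`
consecutive non-candidates between them, trimmed to candidate genes at
both ends. Its score is the candidate count; `locus_ids` lists the
candidate loci inside the span (gap genes are excluded, which makes
precision/recall against planted truth well defined). Hotspots sort by
score, then replicon, then start rank.

### Trait enrichment

Cluster presence is called per strain when the strain conserves at
least `presence_min_fraction = 0.5` of the top hotspot's genes at the
screen's conservation cutoffs. Presence is crossed with a binary trait
(by default, isolation from a plant-associated source) in a 2×2 table
and tested with a two-sided Fisher exact test: `p` is the sum of
hypergeometric probabilities (margins fixed) of all tables whose point
probability is ≤ the observed one, with a 10⁻⁷ relative slack on the
comparison (the convention of mainstream implementations). The odds
ratio is the unconditioned `ad/bc`, `+inf` when `bc = 0 < ad`. The
implementation enumerates the hypergeometric support directly and is
cross-checked in the tests against exact rational enumeration and
against `scipy.stats.fisher_exact`.

## Growth assay

Each replicate growth curve (OD600 vs time) is reduced to its
composite-trapezoid AUC over the recorded grid (no extrapolation or
baseline subtraction). The inhibition index of a replicate at dose *d*
is `1 − AUC_d / mean(AUC at 0 µM of the same strain)`, so 0 is
control-like and 1 is no growth; the raw ratio convention is available
via `index_variant="ratio"`. Dose-vs-control comparisons use Welch's
unequal-variance t-test (Welch–Satterthwaite df), with
Benjamini–Hochberg FDR adjustment across all comparisons of a run.

One calibration point matters when judging "no effect" for degraders:
the index's normalizer is itself estimated from the control replicates,
so the naive standard error of a dose group's mean index (SD/√n of the
treated replicates alone) understates the sampling error of the mean —
a shared control fluctuation shifts all of a strain's indices
coherently. The correctly calibrated "within 2 SE of 0" statement is
therefore made on the dose-vs-control *difference* with its two-sample
(Welch) SE, i.e. `|t| < 2`; that is what the tests assert.

## Mass annotation

Monoisotopic masses are summed from fixed atomic constants
(C = 12 exactly, H = 1.00782503, D = 2.01410178, N = 14.00307401,
O = 15.99491462, S = 31.97207117, P = 30.97376200), with deuterium a
first-class element so labelling arguments can be computed: replacing
*n* H by D shifts the exact mass by `n × 1.00627675` Da and the nominal
mass by *n* units.

The deprotonated ion is `[M−H]⁻ = M − m(H atom)` by default. This is
the convention that reproduces conventional 4-decimal "calculated
masses" of small phenolics (C₁₅H₁₀O₅ → 269.0450, C₁₀H₁₀O₃ → 177.0552,
C₁₀H₁₀O₄ → 193.0501); the physically stricter proton-removal form
`M − 1.00727646` (which gives 269.0455) is available behind
`electron_correction=True`. Report fields are rounded half-up to 4
decimals, matching instrument-report precision; full precision is kept
internally. Peak–formula matching reports every pair within the ppm
tolerance (default 10 ppm), sorted by |ppm error|; ambiguity is
reported, not resolved.

## Synthetic data

The generator emulates the structure of the study the pipeline is built
for, with one reference strain plus `n_degraders = 5` and
`n_nondegraders = 5` panel strains, `genes_per_strain = 200` genes of
`protein_length = 200` residues on one replicon, and a planted cluster
of `cluster_size = 8` genes starting at rank 97:

* **Proteomes.** Mutation is i.i.d. per-residue substitution to a
  uniformly random different residue, no indels, so expected identity
  is exactly `100(1−p)` — the conservation tests exploit this closed
  form. Background genes diverge at `background_divergence = 0.05` in
  every strain; cluster orthologs in degraders at 0.05; non-degraders
  lose each cluster gene with probability 1.0 by default (whole-record
  loss), and any retained copy diverges at background + 0.25 (capped at
  0.9).
* **Counts.** Negative binomial via gamma–Poisson with
  `nb_dispersion = 0.05` and `mean_count = 1000`, log-normal library
  sizes (σ = 0.2) so normalization is exercised; cluster genes have
  their treated-condition mean multiplied by `2^induction_log2fc`
  (default 3.0). Note that CPM estimation of the planted effect carries
  a composition bias of `log2(1 + (k/G)(2^fc − 1))` (≈ 0.36 at
  k = 8, G = 200) because induced genes inflate the treated library;
  this is a property of relative normalization, not an error.
* **Growth.** Logistic curves from a fixed inoculum: every culture
  starts at the same OD, so the inflection time is `ln(K/x₀ − 1)/r` and
  a dose-reduced rate both flattens and delays the curve — as in a real
  plate assay, and necessary for the inhibition to be visible in the
  AUC at all (with a *fixed* inflection time the logistic AUC is nearly
  independent of the rate; exactly so for an inflection at mid-window).
  `lag = 10 h` is the uninhibited inflection time and fixes the
  inoculum. Non-degraders lose a fraction `0.006 × dose(µM)` of their
  growth rate (clipped at 0); degraders are unaffected. Gaussian read
  noise (SD 0.02 OD) on a 0.5 h grid over 48 h, 6 replicates, doses
  0/10/30/100 µM.
* **Peaks.** One [M−H]⁻ ion per pathway-intermediate formula (defaults:
  C₁₅H₁₀O₅, C₁₀H₁₀O₃, C₁₀H₁₀O₄) with Normal(0, 2 ppm) mass noise, plus
  30 uniform decoy peaks in m/z 50–350.

Every generator is byte-deterministic under a fixed seed (substreams
are derived from the seed, so panel/counts/growth/peaks are
independently reproducible).

What the generator does **not** emulate: phylogenetic correlation among
strains (divergence is i.i.d. per strain), indels and domain-level
rearrangements, codon-level evolution, multi-replicon genomes by
default, batch effects beyond a global library-size factor, retention
times with chromatographic meaning, or isotope envelopes. Passing tests
therefore demonstrate correctness of the computations and recovery
under the planted statistical structure, not performance on real pan-
genomes, where local alignment, paralogy and phylogenetic confounding
would matter.

## Numerical choices and degenerate inputs

* Fisher p-values are computed from `hypergeom.pmf` and normalized by
  the pmf sum, so the all-inclusive case is exactly 1.
* Welch's test with both variances zero returns `t = 0, p = 1` when the
  means agree and a `p = 0` sentinel with a warning when they differ.
* An all-absent gene (zero counts in both conditions) has log2FC = 0 by
  the pseudocount.
* Zero aligned columns define identity 0; empty sequences and illegal
  residues are rejected.
* AUC requires ≥ 2 strictly increasing time points.
* Report JSON replaces non-finite floats by the strings `"inf"` /
  `"-inf"` / `"nan"` to remain strict JSON.

## Problem sizes

The packaged study scale — 11 strains × 200 genes × 200 residues, 3
replicates per RNA-seq condition, 6 growth replicates at 4 doses, 97
time points — runs the full pipeline in well under a minute on one
core; the edlib prefilter keeps the conservation matrix (200 × 11
best-hit searches over 200-protein proteomes) the dominant but modest
cost. These sizes are the package's default study conditions, chosen as
a realistic desk-scale analog of a single-replicon bacterial panel.

## Known limitations

* Global-alignment identity is not BLASTP identity; published per-gene
  identity values from local alignments are not expected to be
  reproduced numerically, only the conserved/diverged contrast.
* The screen's cutoffs are sharp thresholds; near-threshold genes
  flip with noise. Fractions (`conserved_fraction_degraders`,
  `nonconserved_fraction_nondegraders`) relax the all-strains
  requirement when panels are noisy.
* Trait enrichment ignores phylogenetic non-independence of strains.
* With `cluster_loss_prob_in_nondegraders < 1`, retained cluster copies
  diverged at background + 0.25 still align at ≈ 70 % identity — above
  the default 30 % "less conserved" cutoff — so criterion (3) treats
  them as conserved; detecting such partial losses needs either higher
  planted divergence or a relaxed `nonconserved_fraction_nondegraders`.
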
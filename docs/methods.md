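# Methods

## The model

`trnadapt` treats translation adaptation in two cell states as a joint
computation over four measured quantities: tRNA isoacceptor abundance,
mRNA half-life, mRNA expression and coding-sequence codon usage. Nothing
is estimated iteratively; every metric is a closed-form statistic, so
"fitting" the model (`CodonOptimalityModel.fit()`) means evaluating the
metric definitions on the aligned gene set and packaging them with their
diagnostics.

**Gene universe.** All per-gene metrics are computed on the intersection
of genes that carry a coding sequence, a half-life and an expression value
in *both* conditions; genes outside the intersection are dropped with a
logged count. This mirrors the common practice of restricting
cross-condition comparisons to transcripts detected in both states.

**CSC.** The codon stabilization coefficient of codon *c* is Pearson's
*r* across genes between the codon's length-normalized frequency and the
mRNA half-life, on the natural hours scale by default (a log-scale option
exists: decay is exponential, so log half-life is linear in decay rate,
but the natural scale is the field's convention for CSC). Codons whose
frequency column has zero variance have no defined correlation and are
reported missing. Classes use inclusive boundaries: optimal at CSC ≥
+0.01, non-optimal at CSC ≤ −0.01, neutral strictly between.

**tAI.** Per codon, the raw weight is `W_c = Σ_j (1 − s_cj) · A_j` over
cognate anticodons *j*, where `A_j` is the measured isoacceptor abundance
(condition-mean TMM value; gene copy number is the classical stand-in
when no measurement exists) and `s_cj` the wobble penalty. The default
penalty table is the dos Reis eukaryotic set: Watson–Crick 0, G34:U3
0.41, I34:C3 0.28, I34:A3 0.9999, U34:G3 0.68, with anticodon A read as
inosine; the bacterial lysidine rule (C34 reading AUA, s = 0.89) is
carried but disabled. Two deliberate restrictions: initiator methionine
is excluded from abundance pools (tAI models elongation), and ATG is
decoded only by its Watson–Crick anticodon CAT — the mechanical per-box
U34:G3 rule would otherwise let an isoleucine anticodon (UAU) contribute
to methionine decoding, which is not how elongator Met works. Both are
configurable on `WobbleRuleSet`. Weights are normalized within each
synonymous family (`tAI_c = W_c / max family W`), so the best-decoded
codon of every decodable family scores exactly 1; a family with zero
total capacity is an error because no gene using it can be scored.

**tAI_gene and SDR.** Gene-level values are geometric means over codon
positions, computed as `exp(Σ n_c ln v_c / L)` for numerical safety.
Demand is expression-weighted codon usage renormalized to sum to 1 over
the 61 sense codons — the renormalization makes SDR dimensionless and
invariant to expression units, which the bare ratio `tAI_c / Σ(expr ·
freq)` is not. The absolute SDR scale therefore depends on this
convention (a uniform-usage codon has demand 1/61, so SDR_c values sit
around `61 · tAI_c`); ΔSDR comparisons and rankings are unaffected.
ΔSDR = SDR(condition B) − SDR(condition A), positive meaning better
adaptation to B's tRNA pool.

**CAI.** Sharp & Li relative adaptiveness from pooled reference codon
counts: `w_c = count_c / max family count`; gene CAI is the geometric
mean of *w* over the gene's codons excluding the single-codon families
ATG and TGG. Codons absent from the reference within an otherwise used
family get the floor `0.5 / max family count` (logged) so a single
missing synonym does not zero out a gene.

**Undecodable codons.** When a gene uses a codon with tAI = 0 (possible
with sparse tRNA sets), the strict default raises; the pipeline runs with
`zero_policy="floor"`, substituting the smallest positive value (logged);
`"geomean"` substitutes the geometric mean of positive values, the
classical alternative.

## Quantification

TMM scaling factors follow the published construction: reference sample =
the one whose upper quartile of count/library-size is closest to the mean
upper quartile; features zero in either compared sample removed; log2
ratios (M) trimmed 30%, average log intensities (A) trimmed 5% (ranks,
double trim); precision weights = inverse asymptotic variance of M;
factors rescaled to geometric mean 1. Normalized abundance is
`count / (library size · factor) · 10^6` by default. Note that weighted
TMM is exactly scale-invariant only in the mostly-non-differential regime
it assumes; with few features and large M spread, rescaling one column
shifts factors at the ~1e-5 level.

Isoacceptor abundance is the unweighted arithmetic mean of member
isodecoder abundances (a copy-number-weighted option exists; unweighted
is the default because collapsed `-X` groups already aggregate
indistinguishable gene copies). Condition fold change is
`log2(mean_A / mean_B)` of condition-mean abundances, flagged at
|log2FC| ≥ 0.5 inclusive; a 0.5-unit pseudocount enters both means only
when either is zero. Differential significance testing is out of scope —
the table accepts an externally computed q-value column and tightens the
flag to q ≤ 0.1 when present.

## Codon usage

Frequencies are per-gene counts over the 61 sense codons divided by the
gene's sense-codon total L (one terminal stop stripped; internal stops
are strict errors by default since curated CDS sets should be clean, with
a lenient truncate-at-stop mode). Amino-acid-normalized usage re-expresses
each codon as its share within its synonymous family, dropping ATG and
TGG (single-codon families carry no within-family variance), giving the
59-dimensional representation used for PCA and clustering. Families a
gene never uses get 0 for all members by default — inventing uniform
usage for absent amino acids would manufacture signal; PCA centering
absorbs the offset (a uniform-fill option exists).

## Multivariate analysis

PCA runs on centered, unscaled AA-normalized frequencies (values already
share the [0,1] scale; z-scoring is an option). Component signs are fixed
by making the largest-magnitude loading positive, so scores are
reproducible across runs. K-means clusters the 59-dimensional matrix
itself rather than PC scores — clustering the full matrix avoids
dependence on how many components are retained; PCA provides the
visualization coordinates. The cluster number is chosen where the
log-inertia curve has maximal curvature (largest second difference of
log inertia over the candidate range): before the true k the inertia
decays roughly geometrically and after it is flat, so the raw-scale
second difference systematically fires one k early while the log-scale
rule lands on the knee. The full inertia trace is returned so a user can
override k. Hierarchical ordering uses Euclidean average linkage.
All stochastic steps take explicit seeds and are bit-reproducible.

## Synthetic data

The generators produce exactly the files the pipeline consumes, with
planted ground truth:

- **tRNA genes**: gtRNAdb-style names over anticodons chosen to cover
  every amino-acid family (so tAI is always defined downstream), with
  configurable duplicated gene copies to exercise isodecoder collapsing.
- **Counts**: negative-binomial replicates (variance m + φm², φ = 0.05
  by default, Poisson at φ = 0) around log-uniform baselines spanning
  three orders of magnitude at depth 10^6, 3 replicates per condition,
  ±20% library-size jitter; condition-B means are baseline × 2^planted-lfc.
  These are the replicate counts and depth typical of a bulk tRNA-seq
  study.
- **Transcriptome**: 2 (or more) synonymous-usage profiles built by
  interpolating shared and profile-specific Dirichlet draws per family
  (divergence 0.9 by default); amino-acid composition is held fixed
  across profiles so only synonymous usage separates them — exactly the
  confound the AA-normalization removes. Genes are 150–450 codons,
  sampled codon-by-codon, stop-free with a terminal TAA. The default
  two-state study makes profile 2 a 20% minority, emulating a focused
  differentiation program against a proliferation background.
- **Half-lives**: baseline 5 h plus a planted linear codon-frequency
  effect, β_c ~ uniform(−50, +50) h per unit frequency (giving CSC
  magnitudes of a few tenths, as observed in decay datasets), plus
  Gaussian noise with SD = 25% of the noiseless range, floored at 0.1 h.
- **Expression**: log-uniform over two orders of magnitude, with optional
  profile-specific up-weighting to move demand between conditions.
- **Condition tRNA pools**: every Watson–Crick anticodon present with
  log-normal jitter; each condition boosts 4× the anticodons decoding its
  favored profile's preferred codon per family.

What the generators do *not* emulate: multi-mapping and alignment
artifacts of real tRNA-seq, tRNA modifications interfering with reverse
transcription, charged/uncharged fractions, batch structure,
amino-acid-composition differences between gene programs, and
non-linear codon-stability relationships. Passing recovery tests
therefore shows the statistics recover planted linear/compositional
structure at realistic noise — not that real brain tRNA-seq would yield
the same numbers.

## Problem sizes and checks

The validation suite uses 2000 genes for CSC sign recovery (recovery ≥
90% is required for betas above the median magnitude), 80 isodecoders
with 3+3 replicates for fold-change sign recovery (≥ 95% at |lfc| ≥ 1),
600 genes / 5 profiles for elbow selection and cluster recovery, 500
genes for two-profile recovery (ARI ≥ 0.9), and a 1000-gene two-state
study for the ΔSDR decile enrichment (≥ 3-fold for the minority
profile). Oracle comparisons (TMM, Pearson, geometric means, linkage)
are held to 1e-9–1e-12. `scripts/acceptance.py` recomputes all of these
from scratch at a user-supplied seed.

## Known limitations

- CSC inherits the compositional coupling of codon frequencies: a strong
  planted effect on one codon induces small opposite-sign correlations on
  others, which is why sign recovery is asserted for the stronger half of
  the planted coefficients.
- The `-X` naming of merged isodecoder groups appends ordinals when one
  family yields several merged groups; published heatmaps do not specify
  collision handling, so cross-referencing such names across tools may
  need the gene → group mapping table the reference stage writes.
- CCA is always appended to collapsed reference sequences; for genomes
  that encode CCA genomically this would duplicate it, and the reference
  builder does not attempt to detect that case.
- The headline numbers of any specific dataset (counts of
  differential isodecoders, exact ΔSDR ranges, cluster sizes) are
  data-dependent and are not reproduced by the synthetic studies; the
  suite validates the machinery, not a particular dataset.
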
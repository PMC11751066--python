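# Methods

## Overview

`tfconcord` screens transcription factors (TFs) for coordinated
regulation of a transcriptome. The inputs are (a) a
differential-expression (DE) table with per-gene log2 fold change and
FDR, (b) promoter sequences (or a genome plus GFF3 annotation from
which 550-bp upstream promoters are extracted), and (c) TF binding
motifs as JASPAR-style position frequency matrices. The output is one
concordance test per TF between the TF's motif-score ranking of its
target genes and the expression ranking of the transcriptome.

## Motif model and the Jindex

A position frequency matrix is converted to a position weight matrix
(PWM) with a background-distributed pseudocount:

    p[i, b] = (c[i, b] + 4·κ·bg[b]) / (Σ_b c[i, b] + 4·κ),

default κ = 0.25 and uniform background, so all probabilities are
strictly positive. A window w of the motif's width is scored with the
**Jindex**, which this package defines as the base-10 log likelihood
ratio

    Jindex(w) = Σ_i log10( p[i, w_i] / bg[w_i] ).

This is a definition of this package: the score is used upstream only
through "higher = more likely a true site" and the retention threshold
1.0, and the log10 scale makes that threshold read as "ten-fold more
likely under the motif than under the background". `N` bases
contribute zero (neutral); the score is additive over positions and
monotone in per-base motif probability.

Promoters are scanned at every offset on both strands (reverse-strand
windows are scored on the reverse complement; scanning is vectorised
by scoring all windows of all equal-length promoters per motif in one
array pass). Retained hits (Jindex ≥ threshold, default 1.0) are
aggregated per gene: a gene's set score is the **maximum** Jindex over
its hits for that TF — the most confident single site; `sum` and
`count` aggregations are available as options. Set ranks S_i = 1..n
are assigned by descending set score with lexicographic gene-id
tie-breaks for reproducibility.

Promoter convention: the 550 bp immediately upstream of the TSS on the
gene's own strand (GFF 1-based inclusive coordinates; TSS = `start`
for + genes, `end` for − genes), clipped at contig edges; zero-length
promoters are skipped with a warning.

## RDE and the ranked gene list

Each gene's DE evidence collapses to the raw score of differential
expression

    RDE = −sgn(log2FC) · 2^|log2FC| · log10(FDR),

positive for confident upregulation, negative for downregulation, zero
at FDR = 1 or log2FC = 0. **All** genes are ranked (no significance
filter): L_i = 1..n by descending RDE, lexicographic tie-breaks.
FDRs reported as exactly 0 by upstream tools are clamped to the
smallest positive FDR in the table (1e-300 fallback) with a logged
warning. Rank 1 = most upregulated; downstream signs assume this
orientation.

## Weighted Kendall's tau and its null

For one TF, the gene set and the gene list are restricted to their
intersection and both sides re-ranked 1..n preserving their original
orders (keeping global list ranks instead would break the permutation
null, since R would no longer be a permutation of 1..n). With R_i the
list rank paired with set rank i and weights v_i ∈ (0,1),

    τ_w = 2/D · Σ_{i>j} v_i v_j sgn(i−j) sgn(R_i−R_j),
    D   = (Σ v_i)² − Σ v_i².

Because R is a permutation, every pair is concordant or discordant and
τ_w = 1 − 4C/D with C the v_i v_j-weighted discordant-pair sum,
accumulated with a Fenwick tree in O(n log n). Constant weights
recover the classical Kendall τ; τ_w = ±1 at the identity/reversal for
any positive weights; rescaling all weights leaves τ_w unchanged.

**Null variance.** Under a uniformly random permutation R, E τ_w = 0
and the variance has an exact closed form obtained from the sgn-term
covariances (pairs sharing no index are uncorrelated; sharing an index
in the same slot contributes +1/3, across slots −1/3):

    Var(τ_w) = (2/D)² [ Σ_{i>j} (v_i v_j)²
               + ⅔ ( Σ_{p<q<r} (v_p² v_q v_r + v_r² v_p v_q)
                     − Σ_{p<q<r} v_q² v_p v_r ) ],

evaluated in O(n) with prefix sums. For constant weights this reduces
to the classical 2(2n+5)/(9n(n−1)). The implementation is validated
against full n! enumeration (n ≤ 7, to 1e-12) and Monte-Carlo at
n = 200. The standardized statistic LD = τ_w / sd is referred to
N(0, 1) for a two-sided p-value; this normal limit is the test's only
approximation and is cross-checked by an explicit permutation test
(two-sided, (1 + #{|τ*| ≥ |τ|}) / (n_perm + 1), exhaustive below
n = 9). At n = 500 the measured type-I error at α = 0.05 is within
[0.04, 0.06].

**Weighting.** Three modes:

* `mixed_density` (default): pool the normalized rank positions of
  both sides — position i/n carrying the |set score| of the gene at
  set rank i, and position r/n carrying the |RDE| at list rank r — fit
  a Gaussian KDE (Silverman bandwidth; evaluated on a 256-point grid
  and linearly interpolated for n > 256) and min–max rescale the
  density at i/n into (1e-6, 1 − 1e-6). Ranks where either ranking
  concentrates its score mass get the largest weights; with an
  RDE-ranked list this up-weights both extremes of the list, which is
  what a two-sided concordance test wants. Crucially the weights are
  a function of the two *marginal* orderings only — never of the
  pairing R — so the permutation null (and hence the variance formula)
  remains exact conditional on the weights. This construction is this
  package's own; only the "mixed density of the pooled rank values,
  range (0,1)" idea is inherited.
* `uniform`: v_i = 0.5, reducing τ_w to the classical Kendall τ.
* `top_linear`: v_i = 1 − i/(n+1), linearly favouring top set ranks.

**Screening.** TFs with fewer than `min_overlap` (default 3) genes in
the intersection are skipped with a logged reason. q-values are
Benjamini–Hochberg over all tested TFs (default α = 0.05). The
direction label is the sign of τ_w; a negative τ_w for an upregulated
TF is the repressor signature (strongest predicted targets most
downregulated).

## Sliding-window profile

To visualise one TF's hit, its intersection genes are ordered either
by RDE or by a weighted rank, and traversed by a sliding window of
width w = ⌈0.02 n⌉ (step 1 by default; with larger steps a terminal
partial window covers the tail). Each window records the raw Jindex
and RDE values of its members plus the weighted means Saverage
(set/Jindex side) and Laverage (list/RDE side), with per-window
quartiles exported for plotting.

The "weighted rank" ordering key is v_i · (n + 1 − S_i), descending —
a weight-modulated set rank. A combined key of the form
v_i·(S_i+R_i)/2 was considered and rejected: under anticorrelation
(the repressor case the profile is meant to display) S_i + R_i is
nearly constant and the ordering degenerates to noise. With the
implemented key, a planted repressor shows the expected pattern: top
windows carry high Jindex mass and low RDE mass (negative rank
correlation between window medians).

## Synthetic data

The generator produces the exact file dialects the pipeline reads and
encodes a known ground truth:

* **Motifs:** per-position probabilities from a Dirichlet(α·1₄)
  (default α = 0.5 — informative, JASPAR-like motifs of length 10),
  materialised as integer counts (×1000) and passed through the
  standard PFM→PWM conversion so file and in-memory paths agree.
* **Promoters:** default 2,000 genes × 550 bp, i.i.d. uniform
  background (GC bias configurable). A planted fraction (default
  0.15) of genes receives one focal-motif occurrence at a uniform
  random offset; per position the consensus base is emitted with
  probability equal to the gene's "strength" (uniform in (0.5, 1.0)),
  otherwise a uniform non-consensus base. Decoy motifs (default 24)
  are planted the same way in independent gene subsets — decoys first,
  so focal sites are never overwritten — giving decoy TFs realistic
  gene sets that remain null because their planting is independent of
  the DE signal.
* **DE table:** latent z_g = ±effect_size · standardised focal Jindex
  + N(0, σ) for focal targets (σ = 1, sign − for a repressor), pure
  noise otherwise; mapped monotonically to log2FC = z and FDR =
  two-sided normal tail of z/σ clamped to (1e-12, 1]. The map is the
  generator's own convention (real inputs come from limma-like tools);
  it guarantees the RDE ordering reflects the latent ordering.

What the generator does **not** emulate: realistic genome composition
and repeat structure, correlated noise between genes, motif
co-occurrence/clustering in real promoters, and the count-level noise
of RNA-seq. Passing recovery tests therefore demonstrate the
statistical machinery (scanning, ranking, test calibration, direction
labelling), not performance on real chromatin.

At the default scale the planted repressor is the top-ranked hit with
the correct sign in ≥ 90% of seeded runs, and with effect_size = 0 the
BH discovery rate at 0.05 stays at the nominal level.

## Numerical and design choices

* Deterministic tie-breaks everywhere (score desc, then gene id), so
  identical config + seed gives byte-identical outputs.
* τ_w is clipped into [−1, 1] to absorb last-ulp float overshoot.
* Weights are validated strictly positive; the uniform-weight τ_w path
  and the matrix-based batch path agree to 1e-12 and cross-validate
  the Fenwick implementation.
* Test sizes in the suite (e.g. 5,000 calibration replicates at
  n = 500; 50 recovery and 20 null studies at 2,000 genes) were chosen
  to keep Monte-Carlo error comfortably inside the asserted bounds on
  a single CPU.
* Coordinates: GFF 1-based inclusive in, 0-based offsets within
  promoters, BED-like 0-based half-open out.
* One seeded generator per run; the seed and all options are written
  into each run's `metadata.json`.

## Known limitations

* The asymptotic p-value relies on the normal limit of τ_w; for very
  small overlaps (n ≲ 20) prefer the permutation p-value (`n_perm`).
* Weighting modes change what "concordance" emphasises; results report
  the mode used, and modes should not be mixed within one screen.
* The mixed-density KDE weighting is a reconstruction (see above), not
  a reimplementation of any particular external tool's `-w 7` option.
* Promoter scanning assumes position independence within the motif and
  a single background composition; neither CpG islands nor
  conservation are modelled.
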
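# Methods

This note records the model, the tunable parameters, the numerical choices,
and what the synthetic fixtures do and do not establish.

## Sequence model and heteroplasmy encoding

A subject's mitochondrial genome is represented as the reference sequence
with per-position base calls applied (1-based positions, the mtDNA
nucleotide-position convention). A homoplasmic mutation is a plain base
substitution; a heteroplasmic mutation — a mixture of mtDNA molecules
carrying different alleles — is a single degenerate IUPAC symbol covering
the observed alleles. Allele fractions are deliberately not modelled: every
pure base under a degenerate symbol carries equal weight downstream, which
keeps the pipeline a function of the call table alone. Reference `n`
symbols are retained and treated as 4-fold ambiguity rather than skipped;
array no-calls are undetermined symbols like any other.

The call-table exchange format is a minimal 3-column TSV
(`position  ref_base  call`, lowercase). Resequencing-array export formats
are vendor-specific and not publicly documented, so this schema is the
smallest one carrying everything the method consumes; converting a vendor
export to it is a one-line awk job.

## Weighted CGR

The CGR matrix at frame length L counts every length-L sliding window of
the sequence in a 2^L × 2^L grid addressed recursively: the first symbol
picks the coarsest quadrant under the base layout `[[a,c],[g,t]]`, the next
symbol the quadrant within it, and so on. The specific corner assignment is
a recorded convention: any layout related by a dihedral symmetry of the
square yields a congruent image, and gliding-box analysis with square boxes
is invariant under rotations and reflections (this invariance is
property-tested), so the choice does not affect Λ(b) or β. It is fixed so
outputs are reproducible bit for bit.

Windows containing degenerate symbols are expanded into the full Cartesian
product of their base sets, each pure string incrementing its cell by
1/(product of degeneracies). Consequently every window contributes total
weight exactly 1 and the matrix mass equals `len(S) − L + 1`; this mass
conservation is the central invariant of the stage and is asserted to
1e−9. The expansion count per window is capped at 4^6 = 4096 (an error
beyond it): beyond six fully undetermined symbols in one window the
expansion carries essentially no positional information while the cost
grows geometrically.

Windowing is linear, not circular. The mitochondrial genome is circular,
but at L ≤ 8 the difference is L − 1 windows out of ~16 569 and is
immaterial; a `circular` flag adds the wrap-around windows for users who
want exact circular counting.

## Gray-scale lacunarity

The count matrix is min–max scaled to [0, 1]. The scaling constant ahead of
the sigmoid is otherwise arbitrary, and min–max is the one choice that makes
the sigmoid midpoint σ interpretable as a quantile-free gray-level
threshold of the observed dynamic range.

Preprocessing uses the standard logistic
`J = 1/(1 + exp(−k(I − σ)))`, the simplest two-parameter sigmoid with the
required behaviour: k, σ > 0, and increasing k drives the image toward a
binary thresholding at level σ. Defaults k = 7, σ = 0.7 are the operating
point at which cohort results were stable for b_min ∈ {3, 5} and
L ∈ {5, 6}; they are flags, not constants.

Box masses are sums of pixel values over b × b boxes — the natural
continuous extension of white-pixel counting, reducing to it exactly on
binary images. Moments are computed directly from the per-box sums (no
histogram binning), one box per stride-1 placement that lies fully inside
the image (no padding). Λ(b) = Z₂/Z₁² is evaluated at every integer b from
b_min to b_max; b_max defaults to half the shorter image side because the
number of placements, hence the variance estimate, degrades beyond that.
Box sums use a summed-area table; an O(N(b)·b²) per-box double loop is kept
in the test suite as the independent oracle and the two agree to 1e−10.

A box-mass distribution with a single distinct mass has zero variance and
Λ = 1 is returned exactly, avoiding ~1e−16 float jitter from the moment
ratio. An image region with zero mean mass leaves Λ undefined and is
reported as an error rather than silently skipped.

## Hyperbola model and fitting

The lacunarity curves of CGR images decay smoothly to an asymptote, the
shape expected from the asymptotic power-law lacunarity of self-similar
sets. The fitted family is

    L(b) = β · b^(−α) + γ,  α ≥ 0, γ ≥ 0, β free,

the minimal three-parameter hyperbola-like family in which the exponent α
tracks the fractal-dimension-related decay and the amplitude β the
lacunarity itself. Fitting minimises the unweighted sum of squared
residuals on Λ (not log Λ) with `scipy.optimize.least_squares`
(ftol = 1e−10, at most 500 evaluations).

Initialisation is deterministic so fits are bit-reproducible: γ₀ = min Λ,
then α₀ and log β₀ from an ordinary regression of log(Λ − γ₀ + ε) on
log b with ε = 1e−9. Two guards matter in practice. Points within 0.1 % of
the curve minimum are excluded from that regression: at such points the log
is dominated by ε (≈ −20.7), which drags the slope to an arbitrarily steep
power law and parks the optimizer on a flat plateau where b^(−α)
underflows to zero for every b in range (observed as α ≈ 10⁴ with R² = 0).
α₀ is capped at 10 for the same reason. With these guards, noiseless
synthetic curves are recovered to ~1e−12 and real pipeline curves fit with
R² ≈ 0.996.

The precision of β under noise is bounded by the design, not the optimizer:
for the recovery study's design (b = 3…16, truth α = 0.4, β = 2, γ = 1,
noise σ = 0.01) the linearised Cramér–Rao bound gives sd(β̂) ≈ 0.079, i.e.
an expected median absolute error of ≈ 0.053. The constrained fit attains
(slightly beats) this floor; the test suite checks efficiency against the
bound rather than an arbitrary absolute number.

## Cohort statistics

Groups are compared with a pooled-variance Student t-test
(df = n₁ + n₂ − 2), one-tailed in the direction of the observed
difference — the convention used for the demographic and mutation-count
tables this package mirrors; the equal-n design makes pooling appropriate.
The classifier labels a subject positive when β ≤ cutoff: fewer intact
frames (more mutations) lowers β, so the disease-like tail is the lower
one. Ties at the cutoff count positive, the conservative choice for a
screening index. The `"median"` cutoff mode recomputes the median from the
supplied sample.

## Synthetic data: what it emulates, and what it does not

- `random_sequence` draws i.i.d. bases with a configurable composition and
  rejects forbidden dinucleotides at generation time.
  `mtdna_like_sequence` uses the human-mtDNA profile (A ≈ 0.309, C ≈ 0.313,
  G ≈ 0.131, T ≈ 0.247) with CpG suppression, which reproduces the
  hallmark Sierpinski-triangle-like CGR of real vertebrate mtDNA (every
  cell whose substring contains `cg` is empty — this is asserted).
- `inject_mutations` places homoplasmic calls (uniform different base) and
  heteroplasmic calls (2-fold IUPAC code containing the reference allele,
  since biological heteroplasmy is a reference/mutant mixture) at distinct
  random positions. Default loads are the observed cohort scales:
  14 homoplasmic + 3 heteroplasmic (AD-like) and 18 + 5 (control-like);
  the simulated cohort study draws per-subject counts around these means
  with the observed SDs (8/3 and 9/4), clipped at zero.
- `sierpinski_carpet` is the known-answer fractal fixture (carpet rather
  than triangle because it is exactly representable on a square pixel
  grid); `bernoulli_image` provides the analytic oracle
  Λ(b) → 1 + (1 − p)/(p b²) for i.i.d. images.

What passing these tests shows: the machinery — counting, weighting,
addressing, box statistics, fitting, classification — is correct against
independent oracles and analytic values. What it does not show: that β
separates real AD patients from controls. Real mtDNA has phylogenetic
structure, mutation hotspots and strand asymmetries that i.i.d. generators
do not emulate, so cohort-level numbers from the simulated study
characterise the pipeline under its stated generative model, not the
clinical effect size. An i.i.d. sprinkling of ~20 mutations over 16 569
positions perturbs β only mildly; the direction of the group difference is
reported, not asserted.

## Problem sizes and determinism

Default analyses use full-length (16 569 nt) sequences at L = 5
(32 × 32 images, b = 3…16); unit fixtures use 4 000 nt sequences, and the
oracle comparisons use 32 × 32 random images and 512² Bernoulli images —
sizes at which the exact empirical box-mass distribution is computed with
no subsampling. No stage uses unseeded randomness: repeated runs of a
subject are bit-identical (asserted over six repeats), and all simulators
take explicit seeds.

## Known limitations

- Per-allele heteroplasmy fractions are not modelled; a 10 % and a 50 %
  heteroplasmy at the same position are indistinguishable.
- Insertions and deletions are out of scope: the call table is
  substitution-only, matching the resequencing-array output it mirrors.
- The β cutoff is taken as given (or the sample median); no ROC
  optimisation is performed.
- The hyperbola family is the package's reconstruction of a
  hyperbola-like decay; alternative texture models (stretched exponential,
  two-term power laws) are deliberately not offered.
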
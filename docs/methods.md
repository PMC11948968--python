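# Methods

## Model

`telocus` treats each sequenced fragment (a read pair counted once) as a
draw from a mixture over the K loci of a locus-level TE annotation. Two
simplex parameter vectors are estimated by EM: π, the proportion of
fragments originating from each locus, and θ, the reassignment
proportions applied to non-unique fragments. The E-step posterior for
fragment *a* and candidate locus *i* is proportional to
`q(a,i) · π_i · θ_i^{y_a}`, where `q(a,i) = exp(λ·(score − best score))`
maps aligner score differences to likelihood ratios and `y_a` indicates
multi-mapping (≥ 2 candidate loci). A uniquely mapped fragment keeps
posterior 1 on its sole candidate regardless of π.

The M-step is a MAP update: the long-read subfamily fractions `t^Lf`
enter both updates scaled by the weight w (see README for the formulas).
Three structural facts about these updates matter in practice:

* Both updates are algebraically simplex-valued for any w ≥ 0 because the
  denominator carries the same prior mass `w·T·Σ_i t_i^Lf` (respectively
  `w·M·Σ_i t_i^Lf`) that the numerators add. `Σ_i t_i^Lf` equals the
  number of subfamilies with nonzero long-read signal — it is **not**
  renormalized to 1; the update is implemented literally.
* At w = 0 the updates reduce to the prior-free maximum-likelihood EM; as
  w → ∞, π̂ converges to the normalized prior. Both limits are asserted by
  tests (the first against an independently coded reference EM, the
  second at w = 1e9 within 1e-4).
* The θ̂ denominator is implemented as `M + w·M·Σ_i t_i^Lf`, the only
  reading under which the update stays a simplex; the alternative of
  summing the prior term over fragments rather than loci would scale the
  denominator by N and break normalization.

`prior_change` selects which of π/θ receives the prior (`both` by
default; `pi`, `theta`, or `none` for a pure prior-free EM used in A/B
comparisons).

## Prior construction

Long-read counts are converted to TPM
(`1e6 · rate_i / Σ rate`, `rate_i = count_i / length_i`); a supplied TPM
column is used as-is. The rescue constant c replaces zeros **before**
subfamily normalization, so an all-zero subfamily becomes uniform when
c > 0 and stays zero (contributing nothing) when c = 0. Subfamily
fractions are invariant to any common scaling of a subfamily's TPM, which
also makes them invariant to whether the TPM denominator was TE-only or
genome-wide. Annotation loci absent from the table get TPM 0; table ids
absent from the annotation are warned about and ignored. The default
rescue constant is 0; 1e-50 is a reasonable choice when short-read-only
loci must be recoverable.

## Fragment ingestion

A fragment is a template: mates overlapping the same locus form one
candidate with the summed pair score; duplicate alignments of the same
(fragment, locus, mate) keep the best score. Secondary and supplementary
alignments are included. A candidate requires overlap of at least
`min_overlap` of the read's aligned bases (default: any overlap, ≥ 1
base, matching permissive feature-counting conventions). Alignment scores
come from the `AS` tag, falling back to −NM, then to 0 with a warning
(uniform weights). λ defaults to 0.1 per score unit; it is inherited
aligner-dependent scaling and therefore exposed. Matrix construction
sorts fragments by name and candidates by locus index, so the result is
independent of record order. Fragments overlapping no TE locus are
dropped. Reads multi-mapping between a TE and a coding gene are not
apportioned — quantification is against the TE annotation only; an
exclusion BED can pre-filter regions (e.g. coding exons) when desired.

## Reassignment and reporting

Modes: `best` (argmax posterior, seeded uniform tie-break), `average`
(fractional posteriors), `unique` (uniquely mapped only), and the default
`long_read` (argmax with exactly tied sets redistributed by the weighted
mean of the **raw** long-read TPM t^L — not the subfamily fraction, which
would erase cross-subfamily scale). Ties are detected at a relative
tolerance of 1e-9 on posterior weights; exact float equality is too
brittle, while a loose tolerance would merge genuinely distinct
posteriors. If every tied locus has t^L = 0 the mass is split evenly with
a warning. `best`, `average` and `long_read` conserve the fragment total
exactly; `unique` sums to the number of y = 0 fragments.

TPM in the report uses either the TE length-rate sum itself
(`te_total`) or the summed length-rates of a user-supplied coding-gene
count table (`coding_gene_total`), which puts TE TPM on the scale of a
gene-level quantification.

## Synthetic data generator

The generator emulates the benchmark conditions end to end at desk scale:

* **Genome.** Each subfamily is an independent random 1 kb consensus;
  each copy is an independent per-base substitution mutant at the
  within-subfamily divergence rate (default 0.02, the regime of young,
  multi-mapping-prone subfamilies). One copy pair per run (default) is an
  exact duplicate whose second member is forced silent: recently
  duplicated TE copies are typically transcriptionally silenced, and an
  expressed/silent identical pair is precisely the case short-read data
  cannot resolve, so the default bundle always contains the phenomenon
  the prior exists to fix. Substitution-only mutation (no indels) keeps
  all copies length-matched and coordinates trivial; this understates the
  structural heterogeneity of real TE copies.
* **Expression.** 20% of loci are silent (the forced-silent duplicate
  counts toward the quota; the rest are drawn uniformly from
  non-duplicate loci); expressed loci are i.i.d. log-normal (σ = 1) and
  normalized to TPM.
* **Reads.** Per-locus fragment counts are multinomial with probability ∝
  truth TPM × length; fragment starts are uniform within the copy; pairs
  are 76 bp reads from the ends of a 200 bp fragment, with no sequencing
  errors (a simplification — mismatches in real reads blur score
  differences further).
* **Long-read table.** Equal to the truth TPM, or binomially thinned
  (`longread_noise`) to emulate shallow or unmatched long-read samples.
* **Aligner stand-in.** Every copy of the origin's subfamily is scored at
  the fragment's offset (score = matched − mismatched bases per read);
  copies within `score_range` (default 6, i.e. up to 3 pair-level
  mismatches worse) of the best hit are reported, the way spliced
  aligners only emit multi-hits inside a score window, and the true
  origin is always written as the primary alignment. Output is ordinary
  SAM consumed by the same ingestion path as real data.

What passing tests on this generator do **not** show: robustness to
sequencing error, indels, fragment-length variance, spliced or truncated
TE transcripts, or genuinely mismatched long-read tissue — real-data
behavior on those axes is outside the simulator's scope (the
`longread_noise` option probes only the depth axis).

Default problem sizes (2 subfamilies × 5 copies, 5,000 fragments) were
chosen so a full simulate–quantify–evaluate cycle completes in seconds
while still containing ~2,500 multi-mapped fragments and both hard cases
(exact duplicates, silent near-duplicates).

## Numerical choices

* Convergence: max absolute change over the concatenation of π and θ,
  ε = 0.001, max 100 iterations; non-convergence is flagged, not raised.
* E-step normalization divides by the per-fragment maximum before
  summing, guarding against underflow; an all-zero row falls back to a
  uniform posterior with a warning.
* Arithmetic is in linear space: K is small (thousands at most) and the
  per-fragment max-rescaling makes log-space unnecessary.
* M = 0 (no multi-mapped fragments) sets θ uniform.
* The coverage-scale ratio between long-read and simulated short-read
  mapped bases is floored to an integer multiplier.
* Detection scoring calls a locus expressed when its value exceeds 0 on
  each side (configurable threshold); precision with an empty TP+FP
  denominator is reported as 0 with an explicit degenerate flag rather
  than NaN. An inclusion mask restricts scoring to loci captured by at
  least one approach when comparing methods.

## Known limitations

* The mixture does not model a "no transcript" outcome: every fragment is
  assigned within its candidate set. Fragments from unannotated sources
  that happen to overlap a TE inflate counts.
* Winner-take-all dynamics of the π·θ product can starve a weakly
  expressed copy that is nearly (but not exactly) identical to a highly
  expressed one; the prior mitigates but cannot eliminate this when the
  score evidence is uninformative.
* Overlapping or nested TE copies are all returned as candidates;
  disambiguation is left entirely to the EM.
* The CLI warns (but proceeds) when the prior weight is outside
  [0.5, 1.0], the band that worked well in practice; with unmatched
  long-read tissue a weight below 1 is advisable.
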
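# Methods

## Model

The package models a composite population founded by individuals from L
genetically distinct lines. Founder genotypes are treated as a complete
inventory of the alleles available to the cross — not as a sample from the
lines — so the observed line allele frequencies `p_ℓ` fully determine the
expected genetic makeup of every later generation. The base population that
defines the scale of all matrices is the hypothetical infinitely large,
unrelated and non-inbred first intercross generation (the F2 of a two-line
cross) with composite allele frequencies `p̄ = Σ w_ℓ p_ℓ` and scale
`S = 2 Σ p̄(1−p̄)`. With that scaling the expected relationship matrix of
unrelated non-inbred F2 individuals is the identity: the mean F2
self-relationship enumerates to `d_A + d_B = 1` and the mean pairwise
relationship — the Hardy–Weinberg-weighted average over the nine gamete
composition pairs — to `r_AA + 2r_AB + r_BB = 0`. Genetic variance
expressed against this base includes the segregation variance, of which the
fraction `−2 r_AB` (between 0 and 1) is attributable to between-line allele
frequency differences; it reaches 1 for fully inbred lines fixed for
opposite alleles.

Assumptions worth keeping in mind:

* loci are transmitted independently (no linkage) — both the tabular
  recursions and the gene-drop oracle share this assumption;
* founder genotypes within a line are expected to follow line-specific
  Hardy–Weinberg proportions wherever an *expectation* is taken; the
  observed G0 captures the actual deviation (excess or deficit of
  heterozygosity), and the combined H propagates that information;
* line weights express intended contributions to the composite population.
  The X-chromosome composite frequency defaults to the same weights — "as
  if both sexes of every line contributed equally" — because the autosomal
  and X base populations should be comparable; realized contributions
  (e.g. all-male founders on one side supply one X each, shifting the
  equilibrium to ⅓/⅔) can be supplied via the X weight override.

## X chromosome

Hemizygous males carry one X gamete; females two. Gene counts are centered
with `p̄` (males) or `2p̄` (females), and every expectation is gametic
book-keeping: between individuals `ω_ij = n_i · n_j · r_ℓm` with `n` the
number of X copies, on the diagonal `n·d_ℓ + n(n−1)·r_ℓℓ`. The tabular
recursion transmits the sire's X unhalved to daughters and nothing to sons,
whose self-relationship is just the maternal gamete's `s_dam`. Because
male and female founder X pools generally differ in frequency, `s` values
oscillate over the early generations with halving amplitude toward the
equilibrium composition — the package's generation-means diagnostic makes
this visible — whereas autosomal gamete self-relationships are exactly 0.5
from the F2 onward (two lines, uniform weights). When the two lines share
identical allele frequencies the recursion collapses to the classical
constant-0.5 rules.

A note on the female–female between-line X expectation: gametic accounting
gives `4 r_AB` (the covariance sums `r_AB` over the 2×2 gamete pairs), and
only this value is consistent with the sampling definition of E(G0) — for
two inbred opposite lines the observed value is the constant −2 = 4r_AB in
every realization. The package uses `4 r_AB`; the simulation oracle tests
enforce the consistency elementwise.

## Gamete self-relationships

The `s` terms in the diagonal recursions are expected self-relationships of
transmitted gametes. Two variants are provided, both obeying
`s_k = ½(s_sire + s_dam)` (X males: `s_k = s_dam`):

* **expectation form** `s = Σ_ℓ f_ℓ d_ℓ` from the line composition `f`
  (founders are indicators; autosomal `f = ½(f_sire + f_dam)`; X males
  inherit the dam's composition). Used to build Ã. Exact by linearity of
  per-locus expectations, and reproduces the constancy and oscillation
  behavior above.
* **conditional form** for extensions seeded with the *observed* G0: the
  founder base values come from the actual genotypes — per locus
  `(c/2)(1−p̄)² + (1−c/2)p̄²` for diploid carriers, `(c−p̄)²` for
  hemizygous males — so that observed heterozygosity replaces its HWE
  expectation. This is what makes the G0-seeded extension equal the mean of
  gene-drop from fixed founder genotypes (linearity of expectation), which
  the test suite verifies elementwise.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| line weights `w` | uniform `1/L` | intended line contributions defining p̄ (autosomes) |
| X line weights | = `w` | override for realized X contributions |
| blending `α` | 0.98 | `G0_BLD = α·G0 + (1−α)·E(G0)`; restores invertibility of a singular G0 |
| rank / PSD tolerance | 1e−8 relative | eigenvalue threshold for the rank report |
| condition threshold | 1e12 | guard before any symmetric inversion; exceeding it raises a named error advising blending |
| gene-drop replicates | 2000 | Monte-Carlo sample for oracle comparisons (10000 mirrors a full-accuracy run; SE scales as 1/√R) |

Counted-allele choice is per marker (first allele column of the CSV, or the
first allele encountered in a 4-column .ped/.map pair); G0 and everything
downstream are invariant to it because the centering frequency co-varies.
Loci monomorphic across all founders contribute nothing to any sum and are
dropped at load with a logged count, which also makes the reported
"polymorphic marker" inventories explicit. Moment sums over markers use
numpy's pairwise summation; the two-line identities hold to ~1e−12 relative
error at 10⁶ loci.

## Numerical choices

* All recursions run in founder-first topological order, never over
  generation labels; when a new individual is added, its row against all
  previously processed individuals is filled from its parents' rows and
  mirrored, so the matrix is symmetric by construction.
* Relationships among same-generation individuals are resolved by
  processing one individual at a time (standard tabular convention).
* Inversions use a symmetric eigenvalue condition guard followed by dense
  inversion and re-symmetrization; H⁻¹ embeds the founder-block correction
  into Ã⁻¹ so the non-founder block of the correction is zero bitwise.
* `blend` returns its endpoint argument bitwise at α ∈ {0, 1}.
* Gene-drop replicates each draw from an independent `SeedSequence(seed,
  replicate)` stream, so results are bitwise reproducible and independent
  of the internal batch size; replicate variance is accumulated around the
  first replicate's matrix to avoid cancellation (a constant founder block
  gets exactly zero Monte-Carlo standard error).
* The pedigree-sized matrices are dense in memory; an HDF5-chunked output
  mode (`store=` on the extension functions) handles full-size pedigrees
  (~20k individuals) that exceed comfortable RAM.
* Selfing, unknown-sex individuals and half-known parent pairs are rejected
  rather than guessed; every validation rule has its own exception type.

## Degenerate inputs

A partition whose composite frequencies are all 0 or 1 has `S = 0` and no
relationship scale; this raises a named error. Two fully inbred lines fixed
for opposite alleles are a legitimate closed case for G0, E(G0), Ã and the
segregation summary (which equals 1), but E(G0) then has rank 1 and all F1
self-relationships are 0, so Ã is exactly singular and H⁻¹ does not exist —
the assembly refuses with the singularity error. This is a property of the
model, not of the implementation: the H correction needs within-line
variation to be informative.

## Synthetic data

The fixture generator emulates the structure of a laboratory line cross:
L lines with configurable allele-frequency spectra (fixed-opposite,
uniform, beta, or supplied vectors), founder genotypes drawn in
line-specific Hardy–Weinberg proportions with single-allele X males, F1
families from cross-line matings, and later generations by full-sib
rotation or random inter-mating. It intentionally does *not* model
linkage, genotyping error, missing data patterns, litter-size
standardization or selection. Passing tests therefore demonstrate the
internal consistency of the machinery (analytic identities, closed-form
cases, agreement with Mendelian simulation) — they do not certify
robustness to linkage disequilibrium between markers, HWE violations
beyond those the H matrix absorbs, or genotyping artifacts in real data.
Default test problem sizes — 8 founders, 6 generations × 8 pups ≈ 200
individuals, 100 autosomal + 50 X markers, 2000 gene-drop replicates — keep
Monte-Carlo standard errors small enough for 3-SE elementwise comparisons
while the whole suite runs in seconds.

## Known limitations

* REML/mixed-model estimation itself is out of scope; H⁻¹ is exported in
  triplet form for external solvers, and `Dk` is provided to re-express
  their variance estimates against the unrelated base.
* Ã⁻¹ is computed by dense numeric inversion; no sparse closed-form inverse
  is attempted.
* Genotypes of non-founders are not yet merged into the observed block
  (the single-step assembly supports it in principle).
* The marker set is taken as given apart from the stated rules — no LD
  pruning, MAF filtering or marker weighting.
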
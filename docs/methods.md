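# Methods

This note records the models implemented in `itamorigins`, the defaults and
the reasoning behind the genuinely open design choices. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Degenerate motif screen

The probe is the two-half-site arrangement `Y-X-X-[LI]-X(s)-Y-X-X-[LI]`
with spacer s ∈ [6, 12] residues, i.e. a match spans 14–20 residues.
Coordinates are 1-based and inclusive so that reported positions line up
with residue numbering conventions (a lone pair of anchors at residues 191
and 205 scans as one hit with a 10-residue spacer).

Choices that the problem statement leaves open, resolved as follows:

- **Overlap policy.** All (start, spacer) combinations are reported,
  including nested matches sharing a first half-site. "Independent hits" at
  proteome level means unique motif-bearing proteins; per-protein match
  counts are retained.
- **Unknown symbols.** X/B/Z/J/U/O/* never satisfy anchor or tail positions
  (they are not evidence of a tyrosine or leucine/isoleucine) but may occupy
  wildcard and spacer positions, where identity is irrelevant.
- **Cross-dataset ranking.** Each abundance table contributes a
  within-table percentile rank in (0, 1] (midranks for ties); the aggregate
  score is the unweighted mean. Percentiles are scale-free, so counts, FPKM
  and TPM tables mix without normalization. A gene absent from a table
  contributes rank 0 — conservative, since absence of evidence of
  expression should not be neutral for a screen that wants high expressers.
  Ties in the aggregate break lexicographically by gene symbol, making the
  ranking deterministic and permutation-invariant.
- **Exclusion rules are data.** The ordered predicate list ships as an
  editable TSV (`data/exclusion_rules.tsv`); each candidate carries at most
  one reason, the highest-precedence failing rule. The shipped order puts
  identity-level disqualifiers (known ITAM receptor) above localization
  (secreted, nuclear-only) above structural accessibility.

The scanner is validated against an independent brute-force enumeration of
every (start, spacer) pair, and the decoy hit rate on ≥10⁶ uniform random
positions is checked against the analytic expectation of
(1/20)(2/20)(1/20)(2/20) matches per (start, spacer) pair.

## Distance-based clock phylogenetics

Branch lengths are in amino-acid substitutions per site. Pairwise distances
use pairwise deletion (columns with a gap or unknown in either row are
dropped for that pair), because ortholog sets differ in coverage; p is the
mismatch fraction and the corrections are Poisson d = −ln(1−p) and gamma
d = α((1−p)^(−1/α) − 1) with default α = 1.0 (user-settable; no
model-selection machinery is included, and empirical rate matrices are out
of scope — tree inference here is a distance + neighbor-joining surrogate
whose purpose is the branch-length-derived quantities, rates and ages).

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q criterion,
deterministic lowest-index tie-breaking, and negative branch-length
estimates clamped to zero with a logged warning. On additive matrices the
generating tree's topology and lengths are recovered exactly (property
tested against random 6–10 tip trees, and cross-checked against an
independent NJ implementation).

Bootstrap supports resample alignment columns with replacement (default
B = 100); the support of each internal bipartition of the point-estimate
tree is the percentage of replicates containing it. Replicates that
saturate (p = 1 under a corrected model) are skipped and logged; more than
20% skipped aborts.

Clock dating: after outgroup rooting (root at the midpoint of the branch
separating a monophyletic outgroup), each named clade's rate is the mean of
patristic(i, j)/(2 t_ij) over calibrated tip pairs inside the clade, and
its root-age estimate is the clade's mean root-to-tip distance divided by
that rate. For paralogous clades the two estimates are reported as a
[min, max] interval, not averaged — the interval width is itself
informative about rate asymmetry between paralogs. Calibrated pairwise
means were chosen over root-to-tip regression as the rate estimator: with
few taxa per clade a regression through the origin is under-determined,
while pairwise means use every calibration symmetrically.

The rate profile (divergence time vs distance to a focal taxon) uses
patristic distances from the tree by default and accepts externally
computed per-tip distances (e.g. direct corrected pairwise distances from
the alignment) as an override; note that distance to the focal taxon
accumulates on both lineages, so a strict clock of rate r yields a series
of constant slope 2r. Segments between equal calibration times are
reported with an undefined (NaN) slope.

## Synthetic sequence evolution

`evolve_alignment` uses the 20-state symmetric (Poisson) substitution
process: per branch and site the number of events is
Poisson(r · Δt · g_site) and each event replaces the residue uniformly with
one of the other 19; optional site factors are iid gamma(α) with mean 1.
This model was chosen because it admits a closed-form expected p-distance,
E[p] = (19/20)(1 − e^{−(20/19)·2rt}), which the tests verify to within
binomial error — giving an independent oracle for the whole
evolve → distance → NJ → clock recovery loop. The default recovery scenario
is an ultrametric two-clade tree with root age 800 Mya, rate 5×10⁻⁴
subs/site/Mya and 2000 sites, sizes at which the Poisson correction's
residual bias (it ignores the 19/20 saturation ceiling) stays at the
percent level for root-to-tip divergences ≈ 0.4 subs/site. The generator
does not emulate alignment error, indels, heterotachy, or compositional
bias — recoveries shown here bound estimator behavior under the model, not
real-alignment error.

## Imaging operators

Pixel coordinates are 0-based, x right, y down. Line profiles sample at
unit-pixel spacing with bilinear interpolation and average over a
perpendicular band of the requested width (odd widths center the band on
the line); kymograph row t is exactly the profile of frame t. Normalized
fluorescence divides per-frame mean contact intensity by mean reference
intensity, with optional per-frame background subtraction of both terms
(optional because whether subtraction was applied is an acquisition-side
choice, not derivable from the data model). Denominators below 10⁻⁶ × the
global mean yield NaN for that frame rather than an unstable spike. GP is
(I_o − I_d)/(I_o + I_d) per pixel, NaN below an absolute intensity floor.
Masks are explicit inputs: the synthetic generator emits geometric
ground-truth masks with a 15° angular guard band between the contact arc
and the reference arc so that blur does not leak enrichment into the
reference. The stack generator produces a blurred, Poisson-sampled annulus
— not a realistic cell: no membrane fluctuation, photobleaching, focus
drift or cytosolic background, so passing tests demonstrate operator
correctness, not robustness to real micrographs.

## Mechanics and statistics

Hertz model, spherical indenter: F = (4/3)·E/(1−ν²)·√R·δ^{3/2} with
ν = 0.33 (bulk polystyrene) and SI units internally (nm/nN converted and
logged at the I/O boundary). The fit estimates (E, δ₀) in
F = k(E)·max(δ−δ₀, 0)^{3/2}; because the model is linear in E at fixed
δ₀, E is profiled in closed form over a δ₀ grid to locate the global basin
before a joint trust-region refinement — the joint problem has local minima
when the planted contact offset is a sizeable fraction of the indentation
range. δ₀ can be pinned by flag. Defaults for synthetic curves mirror a
stiff-bead nanoindentation regime: R = 1.5 µm, indentation depths up to
10 nm.

The Spearman test computes r from midranks (for untied data this equals
1 − 6Σd²/(n(n²−1))) and an exact permutation p by full enumeration of the
n! rank permutations for n ≤ 9; beyond that a t approximation with n−2
degrees of freedom is used and noted. The one-sided p is the upper tail
P(statistic ≥ observed); the two-sided p doubles the smaller tail, capped
at 1, so perfect negative concordance reports the same two-sided p as
perfect positive concordance. Five strictly concordant groups give one-sided
p = 1/120 ≈ 0.0083, which is why a printed p of 0.0083 alongside r = 1
identifies the test as a one-sided exact permutation test with n = 5.
Exact p with ties is refused rather than silently approximated.

Phagocytosis efficiency from per-cell internalized/surface-bound counts is
reported both ways (fraction of cells with ≥ 1 internalized bead, and mean
internalized beads per cell) because the operational definition varies
between studies; bead geometry totals use V = (4/3)πr³ and S = 4πr² per
bead.

## Pipeline and reproducibility

A single global seed is expanded into per-stage streams via SeedSequence
spawn keys indexed by a fixed, append-only stage table, so adding a stage
never perturbs the others' randomness. Every run persists the resolved
config, a seed record and a manifest of SHA-256 content hashes; identical
(config, seed) runs produce identical manifests. Configs reject unknown
keys before execution.

## Problem sizes

Defaults used by the analysis scripts and the acceptance script: proteomes
of 300–550 proteins of length 300; 8-tip trees with 2000-site alignments
(10–20 replicate seeds for dating recovery); 96×96×40–50 image stacks at
100 counts/pixel base intensity; 20 force curves of 100 samples at 1%
multiplicative noise; 5 stiffness groups. These sizes keep the full
analysis reproducible in seconds while leaving estimator error well inside
the tolerances quoted in the tests.

## Known limitations

- Tree inference is distance-based; likelihood-based inference with
  empirical substitution matrices would be preferred for real protein
  families.
- The clock model is strict within each clade; rate variation inside a
  clade biases the age toward the calibrated pairs' average rate.
- The Poisson distance ignores the 20-state saturation ceiling; at deep
  divergences (p → 0.95) dates are increasingly underestimated.
- Imaging operators assume registered, flat-field frames and externally
  supplied masks; there is no segmentation.
- Published divergence dates and proteome hit counts depend on externally
  retrieved sequence sets, calibrations and database versions; this package
  validates the estimators by parameter recovery on synthetic data instead
  of reproducing those numbers.
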
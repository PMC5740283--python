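# Methods

This note documents the models behind `hzfootprint`, the parameter
choices that matter, what the synthetic data does and does not emulate,
and the numerical decisions a user re-deriving results will want to know.

## Admixture clustering

The sampler implements the admixture model: each allele copy of
individual *i* originates from genepool *z* with probability
Q<sub>ik</sub>, and genepool *k* carries its own allele frequencies per
locus. Conditionals are conjugate, so a plain Gibbs sweep updates (1)
allele-copy origins *z* categorically, (2) genepool allele frequencies
from Dirichlet(1 + counts), and (3) each Q row from Dirichlet(α + counts).

Choices and their reasons:

* **Independent allele-frequency prior.** Structure-style programs often
  use a correlated-frequency prior that borrows strength between
  genepools; for strongly diverged genepools the independent prior is
  adequate and removes a hierarchical layer. Consequence: the sampler
  needs more signal to separate weakly diverged genepools than a
  correlated-prior implementation would.
* **α fixed at 1.0** (symmetric, flat on the simplex), exposed in
  `AnalysisConfig`. Programs that *infer* α typically shrink it well
  below 1 for discrete populations, which pushes Q estimates toward the
  simplex corners. With α = 1 the posterior-mean max-Q of a pure
  individual from a Balding–Nichols population at F = 0.3 centres near
  0.9, not 0.99; clustering accuracy (argmax Q) is unaffected. Tests
  assert the argmax behaviour and the F1 point (0.5, 0.5) ± 0.1, not
  corner-sharp Q values.
* **Supervised mode** pins the allele origins of reference individuals to
  their species but still samples their Q, so the spread of reference Q
  values remains observable — that spread *is* the admixture threshold:
  `t = 1 − min(own-species Q over reference individuals)`. A locality is
  called admixed when two or more species exceed t in its mean Q.
* **Evidence and Δk.** The model evidence proxy is
  `mean(lnL) − var(lnL)/2` over the post-burn-in, thinned (every 10
  sweeps) data log-likelihood trace; Δk is its absolute second difference
  across k divided by the replicate standard deviation at k. Δk is
  undefined at the k-range endpoints and requires ≥ 2 replicates with
  non-zero variance.
* **Desk-scale defaults**: 20,000 sweeps / 5,000 burn-in. These are the
  package defaults for all headline computations; production-scale
  settings (10⁶/2.5·10⁵) remain available through the config. The hot
  loop is compiled with numba; one sweep over 120 × 50 diploid genotypes
  costs well under a millisecond.
* **Label switching** across replicates is undone by permuting columns to
  maximize the summed columnwise dot product with the first replicate
  (Hungarian assignment), then averaging.

## Diagnostic markers and hybrid index

A locus is diagnostic when *every* species' reference panel is fixed for
one allele (missing calls ignored) and the focal allele occurs in no
other species. Requiring fixation in all panels — not only the focal one —
keeps four-way comparisons consistent. The hybrid index of a locality is
(focal alleles)/(2 × scored genotypes) pooled over its individuals;
missing genotypes leave both numerator and denominator.

## mtDNA

Collapsing treats `N` as matching any base (gap `-` is a fifth state).
Sequences are processed most-complete-first and each joins the first
haplotype whose representative it matches; the representative is the
member with fewest Ns (ties by id). This makes collapsing idempotent, at
the cost of order-dependence in genuinely ambiguous chains (an N-bearing
sequence compatible with two distinct haplotypes joins the first by the
deterministic order). NJ trees use p-distances — no substitution model,
since at the divergence levels involved (intraspecific + congeners) the
distances are nearly linear anyway — with site-resampling bootstrap and
rooting on the designated outgroup. A query haplotype takes the species
of the smallest clade containing it and references of exactly one
species; short internal fragments are allocated only when every trimmed,
re-collapsed haplotype they match belongs to one species. Individuals
whose mtDNA type a human would infer from geography alone remain
UNASSIGNED here; no such manual step is automated.

## Triangle statistics

With fully diagnostic markers, the maximum-likelihood estimates of
ancestry S and interclass heterozygosity H reduce exactly to counting:
S = focal alleles / scored alleles, H = heterozygous(focal/other) loci /
scored loci. The identity H ≤ 2·min(S, 1−S) is an allele-count fact and
is asserted, not tolerated. A locality is *core* when every
Thiessen-neighbour shares its genetically dominant species; a locality
with no neighbours counts as core by the vacuous reading (configurable).

## Spatial stages

Thiessen polygons are Voronoi cells clipped to the bounding box expanded
by 10% per axis (the clipping extent is a presentation choice; adjacency
— shared edges of positive length — is insensitive to it for interior
cells). The hybrid-index surface is interpolated piecewise-linearly on
the Delaunay triangulation: linear, not spline, so the surface is
monotone between data and reproducible. Grid nodes falling in triangles
with an edge longer than 6× the median nearest-neighbour distance are
masked: such sliver triangles arise along the hull boundary between
distant localities, and interpolating across them smears the surface
over unsampled space and fabricates 0.5-contour lobes. The h = 0.5
contour comes from marching squares on the masked grid; each locality
then gets the minimum point-to-segment distance to any contour polyline,
signed positive where the focal species is dominant.

## Cline models

Centre sigmoid `p(x) = 1/(1+exp(−4(x−c)/w))`; left tail for x < c−δL:
`p = p(c−δL)·exp(4τL(x−c+δL)/w)`; right tail mirrored. Value continuity
at the junctions holds by construction. Two deliberate constraints:

* **Tail slope cap.** The effective tail slope is capped so the tail
  never decays *faster* than the sigmoid at its junction
  (τ<sub>eff</sub> = min(τ, 1−p<sub>L</sub>) on the left, min(τ, p<sub>R</sub>)
  on the right). Without the cap, a δ→0, τ→1 "tail" degenerates into a
  faster-than-sigmoid approach to the asymptote — the opposite of what a
  tail means — and wins AICc contests on the wrong side of noisy
  transects. A tail in this package always means *excess introgression*.
* **Ends fixed at 0 and 1**; free-end frequencies are out of scope.

The likelihood is binomial with n = scored genotypes (loci × individuals)
per locality — conservative, since alleles within a genotype are not
independent — with the observed hybrid index kept as a real fraction
(weighted-Bernoulli form; equal to the binomial up to a data-only
constant). Expected frequencies are clamped to [1e−9, 1−1e−9].

Fitting is multistart Nelder–Mead (adaptive simplex, box-projected
objective, f-tolerance 1e−8). Tail variants are additionally seeded from
the no-tail optimum — including starts at 0.6× its width, since a tail
absorbs part of the apparent width — because the (c, w, δ, τ) basin is a
narrow curved valley that axis-aligned searches and pure random
multistart miss. AICc uses K = 2, 4, 4, 4, 6 free parameters and n =
number of localities (not total genotypes; the alternative is a config
switch away and would only sharpen the penalty differences). Support
limits are profile likelihoods: the parameter is scanned, the others
re-optimized from the MLE, and the interval where the profile stays
within 2 log-likelihood units of the maximum is found by bisection to
1e−3; a limit that never drops below the threshold before its bound is
reported at the bound and flagged open-ended.

## Asymmetry tests

For a species pair, each retained locality contributes its foreign-allele
fraction (alleles diagnostic for the other species / scored diagnostic
alleles) and presence (fraction > 0). Third-species contamination is
excluded first: rule (a), the clustering shows third-species ancestry
above the admixture threshold; rule (b), the locality carries an allele
diagnostic for a third species *and* a neighbouring polygon is dominated
by that species. Rule (b) is this package's codification of a
neighbourhood-corroboration idea and is flagged as such in run manifests.

Fisher's exact test (two-sided) compares presence between sides. The
Mann–Whitney U test on fractions uses midranks; the one-tailed direction
is fixed a priori as "introgression into the putative invader is
greater". With no ties and n₁·n₂ ≤ 400 the p-value is exact (dynamic
programming over rank arrangements); otherwise a normal approximation
with tie-corrected variance and continuity correction is used (an exact
tie-aware enumeration is not implemented). The verdict "footprint
detected" requires Fisher p < 0.01 *and* an invaded-side tail (left,
mirror or both) in the selected cline model; both thresholds are package
conventions, configurable.

## Synthetic data

`simulate_structured_populations` draws ancestral frequencies from
Uniform(0.1, 0.9) and population frequencies from the Balding–Nichols
Beta with divergence F; genotypes are Binomial(2, p).

`simulate_contact_zone` places 60 localities (1–3 diploids each,
probabilities 0.10/0.15/0.75, mean 2.65) on a jittered 3-row quasi-grid
over a 200 × 40 km window — three rows because a single row of random-y
localities lets the interpolated 0.5 contour meander tens of km and
scrambles the transect. The focal-allele field is a sigmoid of width
30 km centred on the front; in moving scenarios an additive wake
`A·exp(−(x1−x)/λ)` (defaults A = 0.3, λ = 40 km) covers the invaded
strip, which spans the whole invader-side window (the old front sits at
the window edge: the emulated system's front crossed essentially the
entire inter-core region). 23 loci are diagnostic (fixed A/B between the
species) and 29 segregate everywhere — the 52/23 split of a realistic
marker panel. Reference panels (15 individuals per species, 3 × 5
localities) sit ≥ 3λ beyond the front on each side. The optional enclave
is a disc held at the pure focal value, by default 83 km behind the
front with radius 8 km; mtDNA labels are drawn from the same field with
the front displaced 25 km into the invaded range (the receding species'
mtDNA lags behind the re-centring nuclear cline). Wake amplitude and
decay are chosen for testability — the real system quantifies neither.

What the generator does *not* emulate: drift and dispersal dynamics (the
wake is imposed, not evolved), selection at markers, linkage,
genotyping error, or irregular real-world sampling. Passing tests
therefore demonstrate that the inference chain recovers the signals it
targets when they are present as modelled, and stays quiet when they are
absent — not that any particular empirical system behaves this way.

### A real limitation worth knowing

When an enclave sits inside the wake, the 0.5 contour includes the
enclave's own ring, and the signed-distance transect folds the wake
around it: localities deep in the invaded strip end up a few km from
*some* contour, compressing the x-axis and blurring the cline-tail
signature (the Fisher presence test is unaffected). At this map scale
(enclave radius ≈ 8 km in a 200 km window) the cline stage is therefore
exercised on enclave-free windows, and enclave-bearing scenarios are used
for the enclave-specific statistics. Real data with a small enclave in a
large map sit between these extremes.

## Problem sizes

Headline computations use desk-scale sizes chosen as package defaults:
clustering fixtures of 4 × 30 diploids × 50 loci with 20,000-sweep
chains; contact-zone fixtures of 60 localities (~160 diploids, 52 loci);
50-seed verdict-rate checks run the full pipeline per seed at reduced
settings (600 sweeps supervised, 1 replicate, 4 restarts, 80×80 grid),
which the fixed-seed examples show reproduce the full-setting verdicts.
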
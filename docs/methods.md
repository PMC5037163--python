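# Methods

## Model and definitions

The data are dual-labelled planar point patterns: for image i of a stack of
k, the coordinates (in nm) of nᵢᴬ particles of type A and nᵢᴮ of type B
inside a rectangular study window W, origin (0, 0), y increasing downward.
Particles are treated as centroids; section thickness is ignored and all
distances are Euclidean in the section plane.

A pair (A_j, B_q) **colocalizes** iff r′ ≤ d(A_j, B_q) < r″ for a chosen band
[r′, r″). The interval is half-open with *exact* floating-point comparison —
no epsilon. Coordinates are measurements, so ties at the boundary have
measure zero, and an exact rule keeps results deterministic and
order-independent. The KD-tree search only pre-filters candidates at d ≤ r″;
membership is always decided by recomputing the distance.

All coefficients are unweighted means over images of per-image ratios (the
outer 1/k), never ratios of pooled counts: the estimand is the "average
image", and pooling would let particle-rich images dominate.

### Undefined per-image terms

A per-image ratio with a zero denominator is *excluded* from that
coefficient's average rather than counted as zero, and the effective image
count per coefficient is recorded (`effective_counts`). If every image is
excluded the coefficient is reported as an explicit
`UndefinedCoefficientError`, never a silent 0. One asymmetry is deliberate:
the stage-3 densities run over all k images, with images lacking any
colocalizing particle contributing a zero *term* (their numerator is
necessarily zero) — the outer average there is defined over the whole stack.
When exclusions occur, the identity checker marks its report as approximate
(`exact=False`) since different stages then average over different image
subsets.

### Summary stage and identities

Aggregate summary fractions are products of aggregate stage-1 and stage-2
coefficients (coloc_A = CC₁ʳᵉˡ⁽ᴬ⁾·CC₂ᴬ etc.). Five identities follow
algebraically — the four fractions partition unity, coloc+noncoloc recovers
each stage-1 proportion, and coloc/CC₁ʳᵉˡ recovers each stage-2 value — and
`verify_identities` checks all residuals at tolerance 1e-12 (they are exact
up to rounding when no image is excluded). The per-image table also carries
per-image products for inspection; the identities are asserted on
aggregates.

## Edge correction

Particles near the window boundary have part of their annulus outside the
observed field. The optional weight w(x) is the fraction of the annulus
[r′, r″) area inside W, computed from the exact circle–rectangle
intersection (quadrant decomposition with the closed-form disc/quadrant
integral); a deterministic 3600-point angular midpoint quadrature is kept as
an independent numeric cross-check (they agree to ~5e-4 in tests, and to a
10⁶-sample Monte-Carlo estimate within 1e-3). Weights lie in (0, 1], exactly
0.25 at a corner.

Defaults: **weights off** for the coefficient stages, because the worked
example's arithmetic is unweighted and comparability with hand-computable
values comes first; stage-3 is the only coefficient stage that accepts the
weight (stage 2 is a pure fraction of particles, where up-weighting has no
natural place in the definition). Weighted CC₃ is reported exactly as the
formula yields it — no renormalisation to [0, 1] is applied, and the
weighted value can exceed the unweighted one by at most max(1/w). In the
PCCF the same weight (applied per A particle and per bin) makes the curve
unbiased at all distances; unweighted curves sag below 1 at long range in
small windows, which is visible in the tests.

## PCCF and envelopes

g_i(bin) = observed pair count / [nᵢᴬ·nᵢᴮ·area(bin annulus)/|W|]; g is the
unweighted mean over images with both labels present (others are skipped).
Defaults bin width 25 nm and r_max 500 nm match the granularity at which
colocalization distance ranges are conventionally reported; both are
overridable.

The null hypothesis is *no association*: each Monte-Carlo replicate redraws
the B points of every image uniformly in its window (same nᵢᴮ; A fixed),
conditioning on the observed A structure and counts. Envelopes are per-bin
empirical quantiles at (1−level)/2 and 1−(1−level)/2 over the simulated mean
curves, computed with the lower/higher order statistics so that 19
simulations at level 0.95 give the per-bin min/max. They are **pointwise,
not simultaneous** — each bin is tested at the nominal level on its own, and
outputs are labelled accordingly. Significant bands are maximal runs of bins
with g strictly above the upper envelope.

Randomness uses counter-based Philox generators with a mandatory integer
seed; every image draws from its own spawned substream, so results are
bit-reproducible and the simulation loop can be vectorised freely (the
envelope computation batches all replicates of an image into one distance
computation, chunked to bound memory).

## Synthetic generator

* `csr` — independent homogeneous Poisson processes for A and B (the null).
* `linked` — A Poisson; each B is, with probability p, attached to a
  uniformly chosen A parent at a uniform-in-area position in a link annulus
  (out-of-window positions are redrawn, preserving the drawn count and the
  annulus distance structure), else uniform. With p = 1 every B is forced
  into a colocalizing pair — the association alternative with a known
  distance band.
* `thomas` — shared Poisson parents; each parent gets Poisson(μ) offspring
  of *each* label, Gaussian-displaced (sd σ); offspring outside the window
  are discarded. Co-clustering without per-pair links.

Draw order is arranged so that `linked` with p = 0 is bit-identical to `csr`
under the same seed (the link decisions use a separate substream), making
the degenerate-limit equivalence testable exactly. A resource guard refuses
configurations expecting more than 10⁷ points.

What the generator does *not* emulate about real immunogold data: antibody
labelling efficiency differences between targets, steric exclusion between
gold particles (hard-core distances), within-image intensity inhomogeneity,
and section-thickness projection effects. Tests passing on these processes
therefore validate the estimators' arithmetic and statistical calibration,
not robustness to those acquisition artefacts.

### Packaged worked example

The single-image example stack (4 A, 3 B, 500 × 500 nm, band 25–125 nm)
realises a declared pair adjacency — pairs {A2–B1, A2–B3, A3–B1, A4–B1},
per-A partner counts (0, 2, 1, 1), per-B (3, 0, 1) — with coordinates chosen
so every pair distance keeps > 1 % clearance from both band boundaries
(in-band distances 60–70 nm; nearest excluded distance ≈ 143 nm), making the
expected coefficients exact small rationals: CC₁ = (7, 4/7, 3/7),
CC₂ = (3/4, 2/3), summary = (3/7, 1/7, 2/7, 1/7), CC₃ = (4/9, 1/2).
Note the summary non-coloc fractions follow the defining products
CC₁ʳᵉˡ·(1−CC₂) — (4/7)·(1/4) = 1/7 and (3/7)·(1/3) = 1/7 — which is the only
reading consistent with the partition-of-unity identity.

## Validation design and problem sizes

* **Brute-force oracles.** Pair finding, CC₂ and CC₃ are checked against
  literal double/triple-loop transcriptions of their definitions on 1000
  random instances (n ≤ 50 per label).
* **CSR calibration.** With band (0, r) and B intensity λ, the probability
  that an A particle colocalizes is the Poisson void probability
  1 − exp(−λπr²). With λ = 100 points per 2000 × 2000 nm window and
  r = 125 nm this is ≈ 0.707; the simulated 200-image mean CC₂ᴬ must fall
  within 0.03 below it (the unweighted statistic loses boundary neighbours;
  the expected deficit at these dimensions is ≈ 0.02).
* **Band recovery.** 20 seeded runs of the linked process (5 images,
  1500 × 1500 nm, ~40 particles per label per image, link annulus 25–75 nm,
  p = 1) are analysed with 25-nm bins to 300 nm and 999-replicate envelopes;
  at least 19 runs must yield a significant band overlapping 25–75 nm. These
  sizes keep the whole check under a minute while leaving the detection
  margin large (the in-annulus enrichment is severalfold).
* **Identity suite.** 50 seeded 5-image CSR stacks (mean 30 particles per
  label per image, so exclusions have negligible probability) must satisfy
  all five identities to 1e-12.
* **Property tests.** Exchange symmetry (swapping the A/B roles swaps every
  paired coefficient exactly), particle-order permutation invariance,
  common-scaling invariance (coordinates, window and band scaled together),
  monotonicity of CC₂ in r″, and the hypothesis-driven partition-of-unity
  property of the summary stage.

## Known limitations

* 2-D only; no account of section thickness or 3-D distances.
* Exactly two label types; multi-type analysis is out of scope.
* Envelopes are pointwise — a run of marginally significant bins is weaker
  evidence than a simultaneous (global rank) envelope would certify.
* The linked process redraws out-of-window positions, which slightly favours
  inward directions for parents near the boundary; the effect is confined to
  the boundary zone and irrelevant at the tested densities.
* Edge-weighted CC₃ is not renormalised and may exceed 1 for extreme
  edge-hugging configurations; interpret weighted values as densities per
  unit *observable* annulus.
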
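# Methods

## Code model

A Bitbow code is an ordered binary vector over (compartment, fluorophore)
slots. The digit order is fixed: fluorophores A, T, G, O, K (mAmetrine,
mTFP1, mNeonGreen, mKO2, tdKatushka2) within each group, groups ordered
membrane → nucleus → golgi, rendered as five-digit groups joined by `-`
(e.g. `01000-00000-00001`). This ordering is a package convention and is
never inferred from input data. Codes compare lexicographically on the
bit string; that ordering is the global tie-break everywhere (whitelist
construction, sorted output).

Capacity is 2^N − 1: the all-zero state is reserved for unlabeled cells,
which are invisible in imaging and never part of a code pool.

Shannon entropy of an observed code-count table is computed in base 2
(bits), consistent with the "bit" framing of the design; the entropy of a
design that generated its 31 five-bit codes uniformly would be
log2 31 ≈ 4.95, and recombination bias pushes observed values below that.

## Frequency model

Modules are assumed to recombine **independently** — the incompatible-FRT
construction is designed to prevent inter-module recombination — so
P(code) is a product of per-module Bernoulli factors, conditioned on at
least one ON bit. Correlated recombination models are out of scope.

Two conventions exist for a "module frequency" and the package keeps them
explicit:

* an **unconditional** rate p_i (probability the module flips ON), which
  is what `build_code_distribution` consumes; user-supplied frequency
  tables are interpreted this way by default, and
* a **conditional marginal** m_i (ON fraction among *observed, labeled*
  clusters), which is what `estimate_module_frequencies` measures from a
  cluster table. The two are related by m_i = p_i / (1 − Π_j (1 − p_j));
  `decondition_marginals` inverts this by fixed-point iteration
  (p ← m · labeled-mass, start p = m, tolerance 1e−9, capped iterations).
  Marginals with Σm < 1 are rejected as infeasible: a labeled cell carries
  at least one ON bit, so feasible conditional marginals sum to ≥ 1.

Whitelists ("exclude the m most frequent codes") break probability ties
lexicographically so the retained set is identical across runs and
platforms. By default, downstream collision and animal computations
**renormalize** the distribution onto the whitelist (drawing a code is
conditioned on it being usable); `simulate_collision_rate` also offers a
`filter` mode that draws from the full distribution and discards
non-whitelisted draws before scoring, since it is not obvious which
convention a given experiment's analysis used.

## Collision statistics

"Collision rate" is standardized as expected (draws − distinct)/draws
under i.i.d. sampling of n lineage codes:

* uniform pool of b codes: c = n − b(1 − ((b−1)/b)^n) (exact closed form);
* arbitrary distribution: c = n − Σ_i (1 − (1 − p_i)^n), which reduces to
  the closed form at p_i = 1/b and is verified against brute-force
  enumeration over all n-tuples for tiny pools;
* Monte Carlo: mean of per-repetition (n − distinct)/n with standard
  error; the default repetition schedule is 100,000 repeats for n < 100,
  1,000 for 100 ≤ n ≤ 1,000, and 10 above, trading precision for run time
  as n grows.

The *experimental* cluster statistic — the fraction of clusters in a brain
whose code is shared — is a different quantity and is kept under a
different name (`cluster_collision_summary`); both it and
`code_occupancy_summary` are computed per brain, with mean ± SD across
brains (SD reported as 0 for a single brain). Percentages for comparison
against printed values are rounded to one decimal, round-half-even.

## Animal-number estimation

Each animal labels each not-yet-sampled lineage independently with
probability q = activation_rate × whitelist mass; a labeling with a
non-whitelisted code does not count (the lineage identity cannot be
confidently assigned) but does not block future sampling of that lineage.
Under these assumptions each lineage's first valid observation is
geometric in q, and a trial's animal count is the maximum of L geometrics
— the simulation draws exactly that, which is distributionally identical
to looping over animals but much cheaper. Default 500 trials,
mean ± SD reported, fully seeded. The analytic expectation
E[A] = Σ_{a≥0} [1 − (1 − (1−q)^a)^L] is truncated when the tail term
drops below 1e−12 and is tested against an exact rational
inclusion-exclusion evaluation.

Activation-rate presets: 0.4808 for a Bitbow-style experiment (577
clusters over 6 brains × 200 lineages), and both 1% and 0.5% for the
single-color clonal (MARCM-style) baseline — the two figures circulate in
the literature and the package surfaces both rather than resolving them.

## Color calling

* **Unmixing** solves M·a ≈ y per pixel with nonnegative least squares
  (abundances are physical). Implementation note: the unconstrained
  least-squares solution is used wherever it is already nonnegative (there
  it *is* the NNLS solution); only pixels with negative components go
  through the iterative solver. Rank-deficient reference matrices are
  rejected with the condition number reported. Reference matrices are
  column-normalized to unit sum on construction; the number of detection
  channels C ≥ 5 is configurable.
* **Smoothing** is a 3×3×3 median (volumetric when a volume is supplied,
  a size-3 running median along the trace otherwise) followed by a
  centered 10-sample rolling mean along trace order, with the window
  shrunk at the ends so output length equals input length.
* **Normalization** divides each pixel's channel vector by its sum;
  pixels whose sum falls below a background floor (default 1% of the
  volume's 99th-percentile summed intensity) are flagged background and
  excluded from calling.
* **Bit calling** aggregates a cell's pixels per channel by the median
  (robust to soma/neurite brightness gradients; mean available) and sets
  a bit ON iff aggregate ≥ threshold — ties are ON. The default fixed
  threshold is 0.1 in normalized units. Auto mode fits per-channel Otsu
  splits across the cell population and uses the midpoint of the two
  class means as the cutoff (robust to outliers at the class boundary),
  falling back to the fixed threshold for channels without two classes
  separated by ≥ 0.1. Auto mode assumes each channel's ON population is
  unimodal; when cells mix very different ON-bit counts, sum-normalized
  ON levels spread widely and the fixed threshold is the more reliable
  choice — the end-to-end tests use it.
* **Consistency** between a neuron's soma and neurite series is the
  per-channel absolute difference of medians, summarized by its maximum;
  nearest-centroid assignment of neurites to somas gives a population
  accuracy.

## Synthetic data

Generators are pure functions of (config, seed); independent substreams
are derived per generator so outputs are stable regardless of call order.

* **Module frequencies**: the `bitbow-like` preset encodes the observed
  FRT-efficiency bias, G > A > K > T ≈ O, with baseline
  (0.40, 0.22, 0.55, 0.21, 0.32) in A,T,G,O,K order and ±0.02 seeded
  jitter per compartment group. The baseline values are a plausible
  realization of that ordering chosen once for this package; the
  experimentally measured per-module frequencies live in supplementary
  material that is not machine-readable here, so synthetic distributions
  emulate the *shape* of the bias, not the exact published numbers —
  which is why empirically-derived published rates (e.g. specific
  whitelist collision percentages) are covered by monotonicity and
  oracle-equivalence tests rather than value-for-value.
* **Cluster tables**: 6 brains × 200 lineages × 48.08% activation by
  default; each activated lineage draws one code (all progeny of a
  recombined neuroblast share it, so one lineage = one cluster), and the
  hidden lineage↔cluster map is returned for recovery tests.
* **Mixing matrices**: diagonal-dominant with off-target mass `bleed`
  spread with exponential spectral falloff; columns unit-sum, full rank
  enforced.
* **Volumes**: cells on a cubic grid (one per 14-voxel box), spherical
  soma (r = 2.5) plus a 3×3-cross-section neurite tube along +x, filled
  with the mixing-matrix forward model of the cell's 5-bit code; ON-bit
  amplitudes are log-normal (σ = 0.12) — variable enough to exercise
  sum-normalization, bounded so that expression-level variation alone can
  never push an ON bit's normalized share below the calling threshold,
  which is a stated property of the generator. Gaussian noise (default
  SD 5% of the unit mean amplitude) is added and clipped at zero.
  Geometry is deliberately minimal: enough to exercise the 3×3×3 median
  and along-trace smoothing, with no attempt at realistic neuroanatomy,
  expansion-microscopy distortion, or detector spectral response.

What passing tests on this synthetic data do **not** show: robustness to
tracing errors, antibody amplification artifacts, spatially varying
background, or overlapping neurites from different cells — real-data
performance depends on those.

## Problem sizes and determinism

Default test and acceptance problem sizes were chosen to make every
stochastic check decisive at 3-standard-error tolerance while keeping the
whole suite fast: 50,000-cluster tables for parameter recovery, 10,000
trials for coupon-collector oracle agreement, 200-cell volumes (the size
of a well-sampled imaging experiment) for end-to-end calling, and the
tiered repetition schedule for collision simulations. All stochastic
paths take explicit seeds; identical seeds give identical results.
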
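# Methods

## Model

Opinions are points in `[0, 1]^m`, one axis per survey item; ordinal Likert
codes `1..k` are mapped onto the unit interval by an equally spaced scheme
(`(j−1)/(k−1)`). Equal spacing is the minimal assumption: the subjective
metric below is invariant to any affine re-coding of the axes, because the
lens is refitted in the transformed coordinates (this invariance is tested).

Each respondent carries an identity label. A group's **lens** is the
eigendecomposition of its weighted in-group opinion covariance
`Σ_g = V Λ Vᵀ`: the basis vectors are `√λ_k · v_k`, and the induced squared
distance is the Mahalanobis form `Δᵀ Σ_g⁻¹ Δ`. We deliberately implement the
metric as the covariance inverse rather than via an explicit basis
inversion: the two are algebraically identical (`(L Lᵀ)⁻¹ = Σ⁻¹` for
`L = V √Λ`), the covariance route is numerically symmetric by construction,
and it makes the two stated reductions exact — identity covariance gives
Euclidean distance, and a 1D lens gives `|Δ|/σ`. Eigenvector sign and
ordering conventions therefore cannot affect any distance (tested by
rebuilding lenses from sign-flipped eigenbases).

The nonpartisan group `"None"` is fitted on the full sample — unaffiliated
respondents treat everyone as in-group — and also serves as the fallback
lens for groups too small to carry their own covariance and for labels that
appear in one wave but not in the other (fallbacks are recorded and logged).

**Disagreement** is the weighted mean over ordered pairs `(i, j)`, `i ≠ j`,
of the distance perceiver `i` measures to `j` through the lens of `i`'s
group, with pair weight `w_i·w_j` normalized over included pairs (the
standard U-statistic weighting; self-pairs excluded). Per-group values
restrict the perceiving side only, so the pair-mass-weighted combination of
per-group means reproduces the population mean exactly — an identity the
tests assert at 1e-10 relative tolerance.

**Decomposition.** Between waves `t1, t2`:
`P1 = d̄(X₂, L₁) − d̄(X₁, L₁)`, `P2 = d̄(X₂, L₂) − d̄(X₂, L₁)`,
`P = P1 + P2` (telescoping; the residual is checked at 1e-12 absolute).
With lenses held fixed, `P2 = 0` exactly — the implementation reuses the
cross report, so the equality is bitwise. The `instantaneous` mode refits
lenses on each wave's own data and its lens term is denoted `P2*`; the
`custom` mode takes caller-supplied lens sets, which is also the open door
to delayed-updating analyses without modeling a lag parameter explicitly.
Waves are independent cross-sections: lenses attach to groups, not persons.

## Estimators and parameters

- **Weighted covariance**: weights normalized to sum to the in-group count,
  denominator `n_g − 1` (unbiased frequency-weight convention; equal weights
  recover `numpy.cov`). Invariant to rescaling all weights. Survey analysis
  weights (e.g. ESS `anweight`) enter both the covariance and the pair
  weighting; weights default to 1 when none are configured.
- **Ridge** `ridge_epsilon` (default `1e-6`, dimensionless): the metric
  inverts `Σ + ε·(tr Σ/m)·I`. This keeps a rank-deficient lens finite — a
  perfectly unanimous group perceives very large but finite distances. For
  an all-zero covariance the relative scale `tr Σ/m` vanishes, so the ridge
  falls back to `ε·I`; without any ridge that case is a hard "singular
  lens" error. Exact closed-form checks (contraction law, σ-normalization)
  set the ridge to 0 on nondegenerate data.
- **`min_group_size`** (default 3): a covariance of fewer than 3 points is
  rank-deficient by construction; smaller groups fall back to the population
  lens. The covariance function itself accepts `min_members=2`, the
  mathematical minimum for an `n−1` denominator.
- **Pair computation**: exact `O(n²)` pairwise evaluation through a Cholesky
  whitening of each lens metric and blocked `cdist` calls (1024 perceiver
  rows per block), so memory stays modest at survey scale (`n ≈ 10⁴`).

## Synthetic data

The generator emulates what the analysis assumes about repeated
cross-sections: per-group Gaussian clouds in `[0, 1]^m` with configurable
means and covariances, truncated by rejection (resample-until-inside, 1000
retries per point) rather than clipping — clipping would put atoms on the
boundary and bias the very covariances the lenses are made of. Waves of a
scenario share their underlying standard-normal draws group by group
(common random numbers): a group whose spec is unchanged between waves
carries *identical* points, and `contraction_scenario(factor=f)` yields the
literal point-wise contraction `x ↦ μ + f·(x − μ)` of the first wave. That
choice makes the key qualitative experiment sharp: the non-contracted
group's lens and points are bit-identical across waves, so its `P2*` is
exactly 0 and its `P1` differs from 0 only through its view of the
contracted group.

Default study conditions used by the tests and the acceptance script:

- **two-lenses fixture**: red group at mean (0.30, 0.35) with isotropic
  SD 0.05; blue group at (0.72, 0.68) with anisotropic SDs (0.15, 0.11).
  Chosen so the groups are well separated relative to their spreads (the
  asymmetric-perception construction) while truncation is negligible.
- **contraction experiment**: factor 0.5 on the red group, 2000 respondents
  per group, 20 replicates.
- **self-calibration**: one group, `m ∈ {1, 2, 3}`, n = 5000, item variances
  around 0.01–0.02.

What the generator does *not* emulate: ordinal measurement error beyond
grid snapping, item nonresponse mechanisms, panel attrition, or any opinion
*dynamics* (waves are draws from specified laws, not model trajectories).
Passing tests therefore validate the measurement machinery, not any claim
about how real opinions evolve.

## Statistical checks

Two results used in testing deserve note.

1. **Self-calibration identity.** For any sample with unit weights, the mean
   *squared* pairwise Mahalanobis distance under the sample's own unbiased
   covariance is exactly `2m`: `Σ_{i,j}(x_i−x_j)(x_i−x_j)ᵀ = 2n(n−1)Σ̂`, so
   the mean over the `n(n−1)` ordered pairs of `Δᵀ Σ̂⁻¹ Δ` is
   `2·tr(Σ̂⁻¹Σ̂) = 2m`, independent of the distribution. Consequently a
   one-group society whose lens follows its own variation perceives (almost
   exactly) constant disagreement no matter how its variance changes — the
   mean unsquared distance depends only weakly on shape — and `P*` between
   two such waves is statistically indistinguishable from zero.
2. **Uncertainty bands.** Where a check asks whether a quantity is
   indistinguishable from zero, the standard error is the design-based
   U-statistic projection estimate `SE(d̄) ≈ 2·sd_w(d̄_i)/√n_eff`, with
   `d̄_i` the per-perceiver mean distance; differences across waves combine
   in quadrature (independent cross-sections). Under common random numbers
   this is conservative.

In the two-group contraction experiment the *population* pure component is
not zero: contraction mechanically shrinks old-lens within-group distances
by about `¼·(1−f)·E[d_in]` (≈ −0.23 lens units at `f = 0.5`), and that term
cannot be made small because lens units self-normalize. The claim the
experiment tests is the observer-side one: the non-contracted group's `P1`
is indistinguishable from zero while the contracted group's `P2*` is
strongly positive — perceived polarization without pure polarization, as
seen from outside the contracting group. The acceptance script reports the
population `P1` alongside so the distinction is visible in the numbers.

## Numerical conventions

- Eigenvalues are clipped at zero (tolerance-checked for PSD input) and
  sorted nonincreasing; repeated eigenvalues need no canonicalization since
  distances depend only on the covariance.
- Covariances and metrics are explicitly symmetrized after assembly.
- All simulation randomness flows through `numpy.random.default_rng` from a
  single seed; per-group streams are seeded `(seed, group index)` so common
  random numbers across waves are structural, not incidental.
- Serialization (lenses to JSON, waves to CSV) is lossless: JSON floats use
  shortest-round-trip representation and CSV reading uses pandas'
  `float_precision="round_trip"`.

## Known limitations

- The lens model is exactly the PCA construction: no shrinkage or sparse
  covariance estimation, and no lens families other than
  covariance-derived ones.
- Only the two extremes of lens updating are modeled (frozen and
  instantaneous); intermediate delays are reachable only through `custom`
  lens sets supplied by the caller.
- No inferential machinery (bootstrap CIs) on P itself; reported standard
  errors are the projection approximation used by the internal checks.
- Respondents with any invalid item answer are dropped listwise; no
  imputation.
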
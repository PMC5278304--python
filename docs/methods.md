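# Methods

## Model

Each recording channel (or, with a grouping table, each region) is a node
of a weighted undirected network whose edge weights are rectified
windowed-correlation functional connectivity. Node `k` carries a complex
state `z_k` governed by the subcritical-Hopf normal form

    dz_k/dt = (a|z_k|⁴ + b|z_k|² + λ + iω) z_k + β·coupling_k(z) + η(t).

With `a < 0 < b` and `λ ∈ (−b²/(4|a|), 0)` the radial dynamics
`dr/dt = r(a r⁴ + b r² + λ)` have three invariant circles: a stable fixed
point at `r = 0` (the interictal rest state), an unstable limit cycle at
`r_sep` (the separatrix) and a stable limit cycle at `r_lc` (the seizure
state), where `r_sep²`, `r_lc²` are the roots of `a x² + b x + λ = 0`.
Noise drives occasional escapes across the separatrix; coupling lets
strongly connected nodes pull each other over, so escape statistics probe
the network structure.

Assumptions worth making explicit: connectivity is static over the
recording (the windowed average is treated as a stationary coupling
parameter); all nodes share identical local parameters, so any
heterogeneity in seizure propensity comes from the network alone; noise is
white, complex, and independent across nodes.

### Coupling term

Two readings of the coupling are implemented. The `input_sum` form
`β Σ_j C_kj z_j` — the convention of the precursor bistable-network
models — is the default: it makes node `k` respond to its neighbours'
states, which is what gives resection its mechanism of action. The
`self_strength` form `β Σ_j C_kj z_k` (the node's own state scaled by its
strength) is available via `ModelParams.coupling_mode` for comparison;
under it a node's stability depends on its strength but not on its
neighbours' dynamics.

### Escape time and seizure likelihood

All nodes start at `z = 0`. The escape time `τ_k` of a realization is the
first grid time at which `|z_k| ≥ r_sep` — the deterministic separatrix
radius exactly, with no hysteresis band. Realizations that never escape
within the horizon `t_max` are censored at `τ = t_max` and flagged; they
enter means at the horizon value, which biases the likelihood of
slow nodes *upward* (a conservative choice: censoring can only shrink,
never inflate, apparent differences in epileptogenicity). Seizure
likelihood is `1/τ̄_k`; any strictly decreasing map would preserve the
ranking, and the reciprocal gives interpretable per-time-unit rates.

### Epileptogenic set

The node with the highest likelihood is the reference; its `M` escape
times are rank-sum tested against every other node's, with BH-FDR at 5%.
The delineated set is the reference plus every node *not* significantly
different from it — i.e. rejections exclude. The phrase "nodes having
significantly higher seizure likelihood" admits the opposite reading
(reference plus the significantly *different* nodes); that convention is
available via `include_rejected=True`, but only the default produces a
set of jointly-top nodes, which is what a resection target must be.
Ties for the highest likelihood break toward the lowest node index.

## Numerical integration

Fixed-step Euler–Maruyama with `dt = 0.05`. The noise increment is
`noise_mean·dt + noise_sd·√dt·(ξ₁ + iξ₂)` with standard-normal `ξ`
(defaults: mean `3·10⁻⁴`, per-component SD `0.05`).

The explicit scheme bounds the usable rotation rate: the linearized
per-step growth factor at rest is `|1 + dt(λ + iω)|`, which exceeds 1 —
i.e. every trajectory explodes — once `ω ≳ 5` at `dt = 0.05`, `λ = −0.75`.
The default is therefore `ω = 2.0` rad per model time unit. The same
analysis shows a discretization shift of the effective bistability
parameter, `λ_eff ≈ λ + dt(λ² + ω²)/2`; at the defaults this is ≈ +0.1 and
is absorbed into the calibration of `β` below. The integrator raises
(naming the first bad step) if the state ever becomes non-finite, rather
than silently producing censored garbage.

An ensemble run integrates all `M` realizations as one `(M, N)` complex
block and draws its noise from a single stream in fixed-size blocks keyed
only by `(seed, M, N)`. Consequently two runs with the same seed on two
connectivity matrices of the same size see *identical* noise: virtual
resections are common-random-number paired with their baseline by
default, which removes most Monte-Carlo variance from the paired
escape-time differences (independent streams are a flag away). Runs stop
early once every node of every realization has escaped.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `a`, `b` | −1, +2 | — | standard bistable normal form; only their ratios to λ matter |
| `λ` | −0.75 | — | mid-window bistability; barrier ≫ noise so isolated nodes essentially never seize and all escape structure comes from coupling |
| `ω` | 2.0 | rad/time | largest rate comfortably stable under Euler at `dt = 0.05` (see above) |
| `β` | 0.22 | — | calibrated once on the default planted network so that network escape times land at O(10–100) time units — the same order as published patient-level mean escape times — and focus/background contrast is resolvable at `M = 200` |
| `noise_mean`, `noise_sd` | 3·10⁻⁴, 0.05 | — | stated noise specification of the model |
| `dt` | 0.05 | time | stated integrator step |
| `t_max` | 4000 (API), 300 (cohort studies) | time | censoring horizon; desk-scale studies shorten it since all informative escapes happen well before |
| `M` | 200 (studies) | — | noise realizations; a desk-scale stand-in for m = 1000 |
| `n_instances` | 100 (API), 6 (cohort studies) | — | random resections per ensemble |

## Synthetic data: what it emulates, what it does not

`gen_correlated_recording` produces band-limited (1–70 Hz) Gaussian
channels with an exact target population correlation `R` (independently
filtered unit-variance noise mixed through a symmetric square root of
`R`); it validates the connectivity estimator, including rectification of
planted negative correlations. It does not emulate line noise, artifacts,
nonstationarity, 1/f spectra or epileptiform transients — passing
recovery tests shows the estimator is correct, not that it is robust to
clinical-grade data quality.

`gen_planted_network` plants a hyperconnected focus community:
`w_ff = 0.9` within the focus versus `w_bb = 0.08` in the background with
weak cross-weights `w_fb = 0.05` and 10% multiplicative jitter. The focus
thus owns the dominant coupling eigenmode (`λ + β·μ_focus ≈ −0.16` against
`≈ −0.49` for the background), which makes focus nodes escape first —
epileptogenicity is induced *purely through connectivity*, mirroring the
empirical correlation of simulated seizure likelihood with node strength
and clustering coefficient. A per-node `λ`-offset mode for planting
heterogeneity outside the connectivity is deliberately absent from the
defaults. After focus resection the background mode sits far below
threshold, so those runs censor at the horizon: "resecting the focus
prevents seizures on simulatable timescales" is a property of this
generator regime, not a theorem about patients.

`gen_cohort` labels a patient good iff the resection contains the whole
focus; non-covering resections are drawn from the background only,
emulating surgeries that missed the epileptogenic zone outright. Partial
focus overlap — the clinically gray zone — is not generated by default,
so cohort-level classification scores on synthetic data are an upper
bound on what mixed regimes would give.

Desk-scale study sizes (20 patients, N = 20 nodes, M = 200,
`t_max` = 300, 6 random resections per patient) are the package's own
choice of a surrogate for the published patient grids; all are
constructor arguments.

## Statistical kernels

* Rank-sum test: exact enumeration when the smaller sample has ≤ 8
  observations and the pooled sample is tie-free; otherwise the normal
  approximation with tie correction (escape times live on a `dt` grid
  with a censoring atom, so ties are the norm at scale). Completely tied
  samples return p = 1.
* BH-FDR: standard step-up.
* Effect size: `d = (X̄ − Ȳ)/mean(σ_X, σ_Y)` with (n−1)-denominator SDs.
  The mean-of-SDs denominator is kept deliberately — it is the variant
  used in the outcome-prediction analysis this package reproduces — and
  differs from the pooled-variance textbook form; both samples constant
  is an error rather than d = 0.
* ROC: candidate thresholds at midpoints between consecutive sorted
  unique feature values plus ±∞; decision rule is strictly
  `feature > threshold`; AUC by trapezoid (equal to the concordant-pair
  fraction with half-credit for ties). The operating point maximizes
  Youden's J, with ties broken toward higher specificity so the
  classifier errs away from promising seizure freedom. The threshold is
  chosen in-sample on the same cohort it classifies, reproducing the
  original retrospective procedure; the reported 81.3% accuracy therefore
  carries in-sample optimism and is not an out-of-sample estimate.

## Degenerate inputs and tie-breaks

Zero-variance channels within a correlation window contribute 0 for the
affected pairs (a neutral term in the window average) and are logged.
The connectivity diagonal is zeroed — self-coupling is indistinguishable
from a shift of `λ` and keeping it would double-count the node's own
dynamics. Resections keep ablated nodes in the state vector (they evolve,
uncoupled) but exclude them from every summary; random-resection
instances average over each instance's own survivors before pooling.
An all-equal feature column yields a degenerate ROC and a warning, not an
error.

## Known limitations

* Escape-based epileptogenicity inherits the model's assumption that
  transitions are noise-driven in a bistable system; oscillatory-onset or
  slow-drift seizure mechanisms are outside its scope.
* With the default `λ`, isolated nodes essentially never escape; all
  results live in the coupling-dominated regime, and `β` sets the overall
  time scale more strongly than any other parameter.
* The Euler scheme's `O(dt·ω²)` bias shifts escape times; halving `dt`
  changes single-node means by a few percent in the tested regimes, but
  quantitative escape times should be read as model-scale, not
  physical-scale, quantities.
* Channel-level nodes stand in for cortical regions; without electrode
  geometry the package cannot aggregate contacts anatomically (a
  label→region grouping table is accepted when one exists).
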
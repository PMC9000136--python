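# Methods

## Model structure and assumptions

Each cell is well mixed and of equal volume, so gap-junctional flux enters
`d[cAMP]/dt` directly with no volume factor. The intracellular circuit is
deliberately minimal, consistent with the first-order reporter dynamics
observed under spatially uniform stimulation:

* **cAMP.** Produced by bPAC in proportion to its expression level `b_i`
  and the light amplitude `u(t)` (rate `β_b·(b_i/[bPAC₀])·u`), plus an
  optional endogenous adenylyl-cyclase source `β₀` (zero by default; used
  by the undershoot variant, optionally inhibited by PKA with gain
  `g_AC`). Cleared by a first-order PDE term `γ_pde` and a smaller
  PDE-independent clearance `γ_ex` (membrane export, buffering, and PDE
  isoforms outside the inhibitor's reach). The split matters
  pharmacologically: full PDE inhibition zeroes `γ_pde` but leaves `γ_ex`,
  so the system stays dissipative and a basal steady state exists under
  the drug, while post-pulse decay still slows by the factor
  `(γ_pde + γ_ex)/γ_ex` = 6.
* **PKA.** cAMP binding frees the catalytic subunits fast relative to the
  minutes-scale dynamics of interest, so PKA activity is an instantaneous
  Hill read-out `camp^n/(K^n + camp^n)` with `n = 2`.
* **ERK.** Deactivated at rate `κ_erk·γ_erk·ψ(cAMP)` where `ψ` lumps the
  PKA and Epac drives with equal affinity (`ψ = (1 + epac_gain)·PKA_on`;
  the Epac term is removable by its inhibitor); reactivated first-order.
  `κ_erk ∈ {1, 0.5}` are the two deactivation presets studied.
* **ERK-KTR.** A single conserved reporter pool shuttles by linear mass
  action: import `k_in·KTR_cyt`, export `k_out·ERK·KTR_nuc`. The
  observable N/C ratio assumes equal-volume nuclear and cytosolic
  compartments. Conservation is structural (the cytosolic pool is
  `KTR_tot − KTR_nuc`).
* **Lagged PDE activation.** The optional PKA→PDE feedback acts through a
  first-order lag (`τ_fb = 8 min`) of PKA activity. An instantaneous
  feedback cannot overshoot; the lag is what lets this (rejected) circuit
  produce overshoot intracellularly, which is the point of the comparison:
  it makes receivers overshoot too, which is not observed.

## Gap-junction regulation

Inactive channels enter a chain of `N` first-order steps at rate
`k_act·f(PKA_on)` with the minimal monotone choice `f(x) = x`; each step
has rate `N/τ_gj`, so transit times are Erlang(N, N/τ_gj) with mean
`τ_gj` and variance `τ_gj²/N`. Active channels deactivate back to the
inactive pool at `γ_gj` (closed total pool, normalized to 1 per cell).
The closed-form oracle for the active amount (mass starting in the first
delay step, deactivation off) is `K·P(Erlang(N, N/τ_gj) ≤ t)`, which
reduces to `K(1 − e^{−t/τ})` at `N = 1` and to a step `K·u(t − τ)` as
`N → ∞`.

Effective permeability on interface (i, j):

```
ρᵢⱼ = coupling_scale · κ_gj · ωᵢⱼ · [k_gj + k_gj,gjf/(P̄·X_f³) · ([GJ_Ca]ᵢ/Pᵢ + [GJ_Ca]ⱼ/Pⱼ)]
```

Each cell's active pool is parsed equally among its `P_i` neighbors.
`P̄ = 5`; `X_f³ = 2/P̄²` is fixed so the parsed, normalized active
concentration is O(1) at full activation, making `k_gj,gjf` directly
comparable with the basal `k_gj`. Two independent chains ("near":
`τ_gj = 1`, fast entry; "far": `τ_gj = 15`) can share the pool; their
active amounts add before entering the permeability.

## Default parameters

| parameter | value | units | rationale |
|---|---|---|---|
| β_b | 0.4 | a.u./min | max-amplitude cAMP plateau `β_b/(γ_pde+γ_ex)` ≈ 0.67, near K so the reporter works in its sensitive range |
| β₀ | 0 (default); 0.08 receivers / 0.24 emitters (undershoot variant) | a.u./min | basal production only matters for the undershoot study |
| γ_pde | 0.5 | 1/min | reporter turn-off within minutes after shutoff |
| γ_ex | 0.1 (0.3 in the undershoot variant) | 1/min | PDE-independent clearance; sets the PDE-inhibited decay |
| K, n | 0.6, 2 | a.u., – | Hill PKA activation |
| γ_erk, κ_erk | 1.0, {1, 0.5} | 1/min | fitted deactivation rate and its two presets |
| k_react | 0.3 | 1/min | ERK reactivation |
| k_in, k_out | 0.3, 3.0 | 1/min | N/C range ≈ 0.1–0.7; ~5-min rise to near-steady reporter for a max pulse |
| k_gj | 0.01 | 1/min | basal permeability (0.1 for the constant-permeability model, swept by κ_gj) |
| k_gj,gjf | 0.6 (2.0 in the undershoot variant) | 1/min | regulated gain; fully open interfaces drain an emitter ~4× faster than degradation |
| τ_gj, N | 15, 4 (near pool 1, 4; undershoot 10, 7) | min, – | delayed-regulation presets |
| k_act | 0.5 (near pool 2.0; undershoot 0.1) | 1/min | entry-rate coefficient |
| γ_gj | 0.05 (undershoot 0.15) | 1/min | active-channel turnover |

The published material gives the model structure, the delay presets
(τ_gj/N values, κ_erk presets, P̄, the pharmacology scale factors) and
qualitative timescales, but not the full rate-constant table; the
remaining defaults above were calibrated once against those stated
timescales — a ~5-minute reporter rise at maximum amplitude, overshoot
completing within 8–15 minutes, and a clearly slower post-pulse decay
under PDE inhibition — and then frozen. The undershoot variant carries
its own auxiliary constants (stronger regulated gain, larger `γ_ex`,
per-role `β₀` with the emitter 3× the receivers) because the basal-state
physiology it probes is different; they are part of that variant's
definition, not runtime dials.

## Scenarios and geometry

Monolayers are hexagonal-lattice discs (planar, deterministic given the
seed): interior cells touch six neighbors, boundary cells three to four,
and seeded random edge thinning caps the mean degree at P̄ = 5 — matching
the observed degree statistics (most `P_i` between 4 and 7) without
claiming the exact published layouts, which are only available as figures.
Explicit edge lists are accepted for bespoke geometries. Scenario presets:
`all_emitter(n)`, `single_emitter_cluster` (1 emitter + 45 receivers;
10-receiver reduced variant), `small_emitter_cluster` (≤ 15 emitters, with
a warning beyond that). Emitters sit at the disc center.

## Numerics

Stiff-capable implicit BDF (`scipy.integrate.solve_ivp`) with an analytic
Jacobian sparsity pattern assembled from the cell graph; rtol 1e-6,
atol 1e-9. Integration restarts at every light switch and drug onset so
the piecewise-constant input is exact; per-pulse pool re-initializations
(the near/far heterogeneity protocol) are applied at those restarts.
Every run starts from the dark steady state obtained by 500 simulated
minutes of relaxation. Output cadence is 1 minute for model studies and
3 minutes when emulating microscopy. Single-cell simulation uses LSODA on
the 4-state intracellular system.

Metrics are computed on the sampled grid without interpolation (ties at
the maximum break to the earliest sample; the steady-state band is
two-sided, `|S − S_end| ≤ 0.3(S_max − S_end)`, with the one-sided variant
available). The degenerate-denominator guard is 1% of each trace's global
dynamic range. The post-pulse decay time interpolates linearly between
samples because the wild-type decay is faster than the output cadence.
Overshoot classification threshold: ratio > 1.1. Undershoot depth is
`max(0, S_start − min over the off period)`, classified against 5% of the
pulse amplitude. The near/far response classifier uses only
(time-to-max, overshoot ratio): no overshoot → "first-order"; overshoot
peaking at or after `0.55·τ_far` → "slow overshoot"; before `τ_far/2.5` →
"fast, no late overshoot"; between → "biphasic".

## Synthetic data

The generator emulates microscopy-extracted ERK-KTR N/C tables: model
ground truth plus log-normal bPAC expression across emitters (CV 0.3),
per-cell constant baseline offsets (sd 0.05), additive white measurement
noise (sd 0.02 ≈ 2% of a unit dynamic range), 3-minute sampling, and a
configurable fraction of flat non-responders (to be discarded downstream
via the metrics `valid` flag). Noise magnitudes are not published; these
defaults were chosen to resemble single-cell reporter roughness and are
configurable. The generator does **not** model correlated noise spectra,
segmentation/tracking artifacts, photobleaching, reporter saturation, or
cell movement — so passing tests demonstrate correctness of the analysis
chain under the stated noise model, not robustness to every pathology of
real imaging data. Every noisy table ships with its noiseless twin and
the exact seed.

## Statistics

Pooled groups concatenate per-cell-per-pulse records. Comparisons use the
paired one-tailed Student t-test when group sizes match and fall back to
one-tailed Welch otherwise (flagged — the published pooling makes the
pairing convention ambiguous for unequal groups, so both paired-within-
cell and unpaired variants are provided). Two 95% CI conventions are
reported side by side: the standard sem-based interval and an sd/N
convention for compatibility with analyses that quote error bars in the
mean as standard deviation divided by N; the latter is much tighter than
a true confidence interval and is flagged as such.

## Problem sizes

Model studies use the 46-cell single-emitter disc (45 receivers), its
11-cell reduction, and 46-cell all-emitter monolayers; parameter recovery
uses 6-minute-pulse traces (single cell, and a 20-cell noisy cohort);
statistical calibration uses 1000 null replicates and 10⁴ sign-flip
permutations. These sizes match the published experiments' scale and run
in seconds per simulation.

## Known limitations

* The exact published rate-constant tables and ODE appendix were not
  available; functional forms follow the stated design defaults (Hill
  PKA, lumped PKA/Epac drive, linear mass-action shuttling) and constants
  were calibrated to stated timescales, so quantitative trace shapes are
  not expected to match the published figures point-for-point — only the
  qualitative regime structure, which is what the acceptance checks
  assert.
* Receiver responses attenuate steeply with graph distance (the Hill
  nonlinearity suppresses sub-threshold cAMP), so propagation beyond the
  second shell is very weak under the defaults.
* `f(PKA_on)` is linear; entry-rate saturation or cooperativity in
  connexin recruitment is not modeled.
* H89 is mapped purely as frozen chain entry with basal permeability
  retained; any direct effect on the ERK drive is not modeled.
* Drug onset mid-run is an instantaneous parameter switch; the optional
  masked acquisition gap around drug addition is off by default.
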
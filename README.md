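# campnet

A multicellular model of cAMP/PKA/ERK signaling in epithelial monolayers
with dynamically regulated gap-junction coupling, together with the signal
analytics needed to study it: pulse-response metrics, a variability
decomposition, group statistics, and a synthetic single-cell reporter
trace generator.

## The scientific problem

In an epithelial monolayer, cells exchange the second messenger cAMP
through gap junctions. When cAMP production is switched on optogenetically
(blue light driving the bacterial adenylyl cyclase bPAC) in *every* cell,
the downstream ERK inhibition — read out as the nuclear/cytosolic ratio of
an ERK kinase translocation reporter (ERK-KTR N/C) — shows a simple,
over-damped first-order rise. But when only a *localized* cluster of
bPAC-expressing "emitter" cells is stimulated inside a lawn of
non-expressing "receivers", the emitters' ERK-KTR N/C signal frequently
*overshoots*: it peaks within ~10 minutes and partially relaxes despite
sustained illumination, while adjacent receivers rise monotonically.

A constant gap-junction permeability cannot reproduce this dichotomy, and
an intracellular negative feedback (PKA activating PDE) produces overshoot
in receivers as well — contrary to observation. The behavior is captured
by **cAMP/PKA-driven gap-junction regulation with a trafficking delay**:
inactive connexin channels are recruited by PKA activity through a chain
of `N` sequential first-order steps (the linear chain trick) with mean
delay `τ_gj`, so the emitter's cAMP is drained into its neighbors only
after a lag — a delayed negative regulation, the classic overshoot
mechanism.

## Model

Per cell `i` (time in minutes, concentrations in arbitrary units):

```
d[cAMP]ᵢ/dt = β_b (bᵢ/[bPAC₀]) u(t) + β₀(1 − g_AC·PKAᵢ)
              − (γ_pde·pde_scale·(1 + g_fb·PDE*ᵢ) + γ_ex)[cAMP]ᵢ
              + Σⱼ ρᵢⱼ ([cAMP]ⱼ − [cAMP]ᵢ)

PKAᵢ        = [cAMP]ᵢⁿ / (Kⁿ + [cAMP]ᵢⁿ)                  (Hill read-out)
ρᵢⱼ         = ωᵢⱼ κ_gj [ k_gj + (k_gj,gjf /(P̄·X_f³))([GJ_Ca]ᵢ/Pᵢ + [GJ_Ca]ⱼ/Pⱼ) ]
GJ_na → GJ_d1 → … → GJ_dN → GJ_Ca                          (entry k_act·PKA,
                                                            step rate N/τ_gj,
                                                            deactivation γ_gj)
dERKᵢ/dt    = −κ_erk γ_erk ψ([cAMP]ᵢ) ERKᵢ + k_react (ERK_tot − ERKᵢ)
dKTR_nucᵢ/dt = k_in (KTR_tot − KTR_nuc) − k_out ERKᵢ KTR_nuc
ERK-KTR N/C  = KTR_nuc / KTR_cyt
```

`u(t) ∈ [0, 1]` is the piecewise-constant blue-light input (standard
protocol: 40-min ON/OFF pulses); `ψ` lumps the PKA and Epac drives on ERK.
The activation chain gives an Erlang(N, N/τ_gj) transit-time distribution:
`N = 1` is a dispersed exponential, large `N` a sharp delayed switch.
Drugs map to parameter changes (IBMX → PDE rate 0; carbenoxolone →
coupling 0; CX43-NGFP → coupling ×0.2; Brefeldin-A → ×0.25; H89 → chain
entry frozen; ESI-09 → Epac term removed).

## Worked example

```python
import numpy as np
from campnet import build_scenario, run_model_variant, LightProtocol
from campnet.metrics import pulse_metrics_for_protocol

graph = build_scenario("single_emitter_cluster", seed=0)   # 1 emitter + 45 receivers
proto = LightProtocol.two_pulse(amplitudes=(1.0,))          # 40 min dark, 40 min light
ts = run_model_variant("delayed_regulation", graph=graph, protocol=proto)

e = int(graph.emitter_ids[0])
m = pulse_metrics_for_protocol(ts.time, ts.ktr_nc[e], proto.pulses)[0]
print(f"emitter overshoot ratio {m.overshoot_ratio:.3f}, "
      f"time-to-max {m.time_to_max:.0f} min, time-to-ss {m.time_to_ss:.0f} min")
recv = [pulse_metrics_for_protocol(ts.time, ts.ktr_nc[r], proto.pulses)[0]
        for r in graph.adjacent_receivers()]
print(f"adjacent receivers: mean ratio "
      f"{np.nanmean([x.overshoot_ratio for x in recv]):.3f}")
```

prints

```
emitter overshoot ratio 2.279, time-to-max 9 min, time-to-ss 20 min
adjacent receivers: mean ratio 1.026
```

The emitter N/C signal peaks at 9 minutes and relaxes (overshoot ratio
`(S_max − S_start)/(S_end − S_start)` ≈ 2.3, far above the 1.1
"overshooting" threshold) while the receivers rise first-order-like
(ratio ≈ 1.03). Re-running with `run_model_variant("constant_permeability",
...)` gives an emitter ratio of 1.000 with time-to-max 34 min — the
dichotomy that makes the delayed regulation necessary.

A command-line pipeline wraps the same operations:

```sh
campnet simulate --preset single_emitter_delayed --seed 0 --out out/
campnet metrics out/single_emitter_delayed_cells.csv --out out/metrics.csv
campnet compare out/metrics_a.csv out/metrics_b.csv --metric overshoot_ratio
campnet generate --seed 0 --out fixtures/        # synthetic fixture suite
campnet fit traces.csv --free gamma_pde,gamma_erk
```

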
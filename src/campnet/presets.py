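"""Named end-to-end run presets for every model variant studied.

Each preset bundles a scenario, a model variant, a pharmacology condition
and a light protocol, so the full pipeline (simulate -> metrics ->
compare) can be driven by name from the command line or from configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model_core import IntracellularParams, LightProtocol, NO_DRUG, PharmacologySpec
from .tissue import MonolayerGraph, TraceSet, build_scenario, drug_spec, run_model_variant

__all__ = ["RunPreset", "PRESETS", "get_preset", "run_preset"]


@dataclass(frozen=True)
class RunPreset:
    scenario: str
    variant: str
    scenario_options: dict = field(default_factory=dict)
    variant_options: dict = field(default_factory=dict)
    pharm: PharmacologySpec = NO_DRUG
    params: IntracellularParams = IntracellularParams()
    amplitudes: tuple[float, ...] = (1.0, 1.0)


PRESETS: dict[str, RunPreset] = {
    "all_emitter": RunPreset("all_emitter", "delayed_regulation"),
    "all_emitter_heterogeneous": RunPreset(
        "all_emitter", "delayed_regulation", {"bpac_cv": 0.3}
    ),
    "single_emitter_constant": RunPreset(
        "single_emitter_cluster", "constant_permeability"
    ),
    "single_emitter_feedback": RunPreset(
        "single_emitter_cluster", "pka_pde_feedback"
    ),
    "single_emitter_delayed": RunPreset(
        "single_emitter_cluster", "delayed_regulation"
    ),
    "single_emitter_delayed_small": RunPreset(
        "single_emitter_cluster", "delayed_regulation", {"n_receivers": 10}
    ),
    "near_far_far_only": RunPreset(
        "single_emitter_cluster", "near_far", {}, {"far_fraction": 1.0}
    ),
    "near_far_mixed": RunPreset(
        "single_emitter_cluster", "near_far", {}, {"far_fraction": 0.8}
    ),
    "near_far_near_only": RunPreset(
        "single_emitter_cluster", "near_far", {}, {"far_fraction": 0.0}
    ),
    "undershoot_gj_only": RunPreset(
        "single_emitter_cluster", "undershoot"
    ),
    "undershoot_gj_ac": RunPreset(
        "single_emitter_cluster", "undershoot",
        params=IntracellularParams(ac_pka_inhibition_gain=0.5),
    ),
    "undershoot_control": RunPreset(
        "single_emitter_cluster", "undershoot", {}, {"equal_basal": True}
    ),
    "ibmx": RunPreset(
        "single_emitter_cluster", "delayed_regulation", pharm=drug_spec("ibmx")
    ),
    "cx43_ngfp": RunPreset(
        "single_emitter_cluster", "delayed_regulation",
        pharm=drug_spec("cx43_ngfp"),
    ),
    "brefeldin_a": RunPreset(
        "single_emitter_cluster", "delayed_regulation",
        pharm=drug_spec("brefeldin_a"),
    ),
    "carbenoxolone": RunPreset(
        "single_emitter_cluster", "delayed_regulation",
        pharm=drug_spec("carbenoxolone"),
    ),
    "h89": RunPreset(
        "single_emitter_cluster", "delayed_regulation", pharm=drug_spec("h89")
    ),
}


def get_preset(name: str) -> RunPreset:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name]


def run_preset(
    name: str,
    seed: int = 0,
    graph: MonolayerGraph | None = None,
    protocol: LightProtocol | None = None,
) -> TraceSet:
    """Build the preset's scenario (seeded) and run its model variant."""
    preset = get_preset(name)
    if graph is None:
        graph = build_scenario(preset.scenario, dict(preset.scenario_options), seed)
    if protocol is None:
        protocol = LightProtocol.two_pulse(amplitudes=preset.amplitudes)
    ts = run_model_variant(
        preset.variant,
        graph=graph,
        protocol=protocol,
        params=preset.params,
        pharm=preset.pharm,
        **preset.variant_options,
    )
    ts.metadata["preset"] = name
    ts.metadata["seed"] = seed
    return ts
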
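"""Synthetic single-cell reporter trace tables.

Emulates the statistical structure of microscopy-extracted ERK-KTR N/C
time series without any imaging data: the multicellular model provides the
ground truth, on top of which the generator adds log-normal bPAC expression
heterogeneity across emitters, per-cell constant baseline offsets, additive
white measurement noise, a 3-minute sampling cadence, and a configurable
fraction of flat non-responder cells (which downstream metrics must discard
via the valid flag, mirroring the experimental discard rule).

Every noisy table ships with its noiseless twin (``ktr_nc_true`` and
``camp_true`` columns) and the exact seed, so ground truth is always
recoverable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import IntracellularParams, LightProtocol, NO_DRUG
from . import tissue as _tissue

__all__ = [
    "NoiseModel",
    "HeterogeneitySpec",
    "sample_expression_levels",
    "generate_trace_table",
    "make_fixture_suite",
]

#: Floor applied to noisy N/C ratios (the measured ratio of two positive
#: fluorescence medians cannot be non-positive).
NC_FLOOR = 1e-3


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for synthetic reporter tables.

    Defaults: measurement sd 2 percent and baseline-offset sd 5 percent of
    a unit dynamic range, values chosen to resemble single-cell reporter
    roughness at a 3-minute imaging cadence.
    """

    meas_sd: float = 0.02
    baseline_sd: float = 0.05
    sampling_period: float = 3.0
    nonresponder_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.meas_sd < 0 or self.baseline_sd < 0:
            raise ValueError("noise sds must be non-negative")
        if self.sampling_period <= 0:
            raise ValueError("sampling_period must be positive")
        if not 0.0 <= self.nonresponder_fraction <= 1.0:
            raise ValueError("nonresponder_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Cell-to-cell variability of the synthetic cohort."""

    bpac_cv: float = 0.3
    per_pulse_pool_splits: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bpac_cv < 0:
            raise ValueError("bpac_cv must be non-negative")
        if self.per_pulse_pool_splits is not None:
            for fr in self.per_pulse_pool_splits:
                if abs(sum(fr) - 1.0) > 1e-9:
                    raise ValueError("pool split fractions must sum to 1")


def sample_expression_levels(n: int, cv: float, seed: int) -> np.ndarray:
    """Log-normal bPAC expression levels with mean 1 and the given CV."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    mu = -0.5 * sigma2
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _resample(trace_set, period: float):
    t = trace_set.time
    step = t[1] - t[0]
    stride = max(1, int(round(period / step)))
    return np.arange(0, t.size, stride)


def generate_trace_table(
    scenario,
    params: IntracellularParams = IntracellularParams(),
    noise: NoiseModel = NoiseModel(),
    het: HeterogeneitySpec = HeterogeneitySpec(),
    protocol: LightProtocol | None = None,
    seed: int = 0,
    out_path: str | Path | None = None,
    variant: str = "delayed_regulation",
    **variant_kwargs,
):
    """Simulate a scenario and emit a noisy single-cell trace table.

    ``scenario`` is a scenario name (built with expression heterogeneity
    from ``het``) or a prebuilt :class:`~campnet.tissue.MonolayerGraph`.
    Returns ``(trace_set, table)``; the table has one row per cell per
    sample with both observed and ground-truth columns.  When ``out_path``
    is given the table is written as CSV with a JSON manifest sidecar
    (``<out_path>.json``) recording the seed, scenario and parameters; a
    fixed seed reproduces the files byte for byte.
    """
    rng = np.random.default_rng(seed)
    if protocol is None:
        protocol = LightProtocol.two_pulse()
    if isinstance(scenario, str):
        graph = _tissue.build_scenario(
            scenario, {"bpac_cv": het.bpac_cv}, seed=het.seed
        )
    else:
        graph = scenario
    if het.per_pulse_pool_splits is not None:
        variant_kwargs.setdefault("far_fraction",
                                  het.per_pulse_pool_splits[0][1])
    ts = _tissue.run_model_variant(
        variant, graph=graph, protocol=protocol, params=params,
        **variant_kwargs,
    )

    keep = _resample(ts, noise.sampling_period)
    time = ts.time[keep]
    n = ts.n_cells
    truth = ts.ktr_nc[:, keep]
    camp_true = ts.camp[:, keep]

    baseline = rng.normal(0.0, noise.baseline_sd, size=n)
    meas = rng.normal(0.0, noise.meas_sd, size=(n, time.size))
    flat = rng.random(n) < noise.nonresponder_fraction
    observed = truth + baseline[:, None] + meas
    if flat.any():
        base_vals = truth[flat, :1] + baseline[flat][:, None]
        observed[flat] = base_vals + meas[flat]
    clipped = observed < NC_FLOOR
    if clipped.any():
        warnings.warn(
            f"clipped {int(clipped.sum())} non-positive N/C sample(s) at "
            f"{NC_FLOOR}",
            stacklevel=2,
        )
        observed = np.maximum(observed, NC_FLOOR)

    table = pd.DataFrame(
        {
            "cell_id": np.repeat(np.arange(n), time.size),
            "role": np.repeat(ts.roles.astype(str), time.size),
            "time_min": np.tile(time, n),
            "ktr_nc": observed.ravel(),
            "ktr_nc_true": truth.ravel(),
            "camp_true": camp_true.ravel(),
            "nonresponder": np.repeat(flat, time.size),
        }
    )
    ts.metadata.update(
        seed=seed,
        noise=asdict(noise),
        heterogeneity={
            "bpac_cv": het.bpac_cv,
            "per_pulse_pool_splits": het.per_pulse_pool_splits,
            "seed": het.seed,
        },
    )
    if out_path is not None:
        out_path = Path(out_path)
        table.to_csv(out_path, index=False, float_format="%.10g")
        manifest = dict(ts.metadata)
        manifest["table_sha256"] = hashlib.sha256(
            out_path.read_bytes()
        ).hexdigest()
        out_path.with_suffix(out_path.suffix + ".json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n"
        )
    return ts, table


def make_fixture_suite(
    seed: int,
    out_dir: str | Path,
    n_receivers: int = 10,
    noise: NoiseModel | None = None,
) -> dict[str, Path]:
    """Emit the canonical named fixtures used by the test-suite and docs.

    Covers the all-emitter equal/increasing amplitude cohorts, the
    single-emitter constant-permeability / intracellular-feedback / delayed
    regulation trio, the near/far pool-split cases, the undershoot
    factorial, and the pharmacology variants.  Fixtures use a reduced
    monolayer (``n_receivers`` receivers) to stay small; each CSV has a
    JSON manifest sidecar.  Returns the name -> path manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    def sub() -> int:
        return int(rng.integers(2**31 - 1))

    single = _tissue.build_scenario(
        "single_emitter_cluster", {"n_receivers": n_receivers}, seed=seed % 2**16
    )
    specs: dict[str, dict] = {
        "all_emitter_equal_amplitude": dict(
            scenario="all_emitter", variant="delayed_regulation",
            het=HeterogeneitySpec(bpac_cv=0.3, seed=sub()),
            protocol=LightProtocol.two_pulse(),
        ),
        "all_emitter_increasing_amplitude": dict(
            scenario="all_emitter", variant="delayed_regulation",
            het=HeterogeneitySpec(bpac_cv=0.3, seed=sub()),
            protocol=LightProtocol.two_pulse(amplitudes=(0.5, 1.0)),
        ),
        "single_emitter_constant_permeability": dict(
            scenario=single, variant="constant_permeability"
        ),
        "single_emitter_pka_pde_feedback": dict(
            scenario=single, variant="pka_pde_feedback"
        ),
        "single_emitter_delayed": dict(
            scenario=single, variant="delayed_regulation"
        ),
        "near_far_far_only": dict(
            scenario=single, variant="near_far", far_fraction=1.0
        ),
        "near_far_mixed": dict(
            scenario=single, variant="near_far", far_fraction=0.8
        ),
        "near_far_near_only": dict(
            scenario=single, variant="near_far", far_fraction=0.0
        ),
        "undershoot_regulated_high_basal": dict(
            scenario=single, variant="undershoot"
        ),
        "undershoot_regulated_equal_basal": dict(
            scenario=single, variant="undershoot", equal_basal=True
        ),
        "undershoot_ac_feedback": dict(
            scenario=single, variant="undershoot",
            params=IntracellularParams(ac_pka_inhibition_gain=0.5),
        ),
        "pharm_ibmx_delayed": dict(
            scenario=single, variant="delayed_regulation",
            pharm=_tissue.drug_spec("ibmx"),
        ),
        "pharm_cx43_ngfp_delayed": dict(
            scenario=single, variant="delayed_regulation",
            pharm=_tissue.drug_spec("cx43_ngfp"),
        ),
        "pharm_brefeldin_a_delayed": dict(
            scenario=single, variant="delayed_regulation",
            pharm=_tissue.drug_spec("brefeldin_a"),
        ),
    }

    manifest: dict[str, Path] = {}
    for name, spec in specs.items():
        scenario = spec.pop("scenario")
        het = spec.pop("het", HeterogeneitySpec(bpac_cv=0.0, seed=0))
        protocol = spec.pop("protocol", None)
        params = spec.pop("params", IntracellularParams())
        path = out_dir / f"{name}.csv"
        generate_trace_table(
            scenario, params=params, noise=noise, het=het, protocol=protocol,
            seed=sub(), out_path=path, **spec,
        )
        manifest[name] = path
    index = {k: str(v.name) for k, v in manifest.items()}
    (out_dir / "manifest.json").write_text(json.dumps(index, indent=2) + "\n")
    return manifest
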
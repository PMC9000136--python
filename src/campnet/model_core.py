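"""Single-cell intracellular circuit: bPAC -> cAMP -> PKA/Epac -> ERK -> ERK-KTR.

The circuit is deliberately minimal, consistent with the first-order
dynamics observed in spatially uniform stimulation: light-driven cAMP
production by bPAC plus a small endogenous adenylyl-cyclase source, simple
first-order degradation by phosphodiesterases (rate ``gamma_pde``), a Hill
read-out of PKA activation by cAMP, cAMP-dependent deactivation of ERK
(PKA and Epac lumped into one drive), first-order ERK reactivation, and
linear mass-action nucleocytoplasmic shuttling of the ERK kinase
translocation reporter (ERK-KTR).  The observable is the nuclear-to-
cytosolic reporter ratio N/C, which rises when ERK is inhibited.

Optional gains support the model variants: PKA feedback onto PDE
(``pde_pka_feedback_gain``) and PKA inhibition of the endogenous cyclase
(``ac_pka_inhibition_gain``, used by the post-pulse undershoot variant).

Concentrations are in arbitrary units (reference bPAC expression
``bpac_ref = 1``, cAMP scale set by ``beta_b / gamma_pde``); time is in
minutes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "IntracellularParams",
    "LightProtocol",
    "CellTrace",
    "PharmacologySpec",
    "NO_DRUG",
    "light_input",
    "pka_activity",
    "erk_drive",
    "intracellular_derivatives",
    "simulate_single_cell",
    "fit_intracellular",
    "FitResult",
    "NonIdentifiableError",
    "IntegrationFailure",
]

#: Dark pre-equilibration span (minutes) used to reach the basal steady
#: state before t = 0.
RELAX_MINUTES = 500.0


class IntegrationFailure(RuntimeError):
    """Stiff integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float, cell_id: int | None = None):
        where = f" (cell {cell_id})" if cell_id is not None else ""
        super().__init__(f"{message}{where}; last good time t={last_time:.3f} min")
        self.last_time = last_time
        self.cell_id = cell_id


class NonIdentifiableError(ValueError):
    """Raised when fitting data carry no usable dynamic signal."""


@dataclass(frozen=True)
class IntracellularParams:
    beta_b: float = 0.4          # cAMP production per unit bPAC per unit light (a.u./min)
    bpac_ref: float = 1.0        # reference bPAC expression level
    beta_0: float = 0.0          # endogenous adenylyl-cyclase basal production (a.u./min)
    gamma_pde: float = 0.5       # PDE-driven first-order cAMP degradation rate (1/min)
    gamma_ex: float = 0.1        # PDE-independent cAMP clearance (efflux/buffering, 1/min)
    pde_pka_feedback_gain: float = 0.0
    tau_pde_fb: float = 8.0      # lag (min) of PKA-driven PDE activation
    ac_pka_inhibition_gain: float = 0.0
    K_pka: float = 0.6           # cAMP half-saturation of PKA activation (a.u.)
    n_pka: float = 2.0           # Hill exponent of PKA activation
    gamma_erk: float = 1.0       # fitted ERK deactivation rate (1/min)
    kappa_erk: float = 1.0       # scaling factor on the ERK deactivation rate
    k_erk_react: float = 0.3     # ERK reactivation rate (1/min)
    erk_tot: float = 1.0         # total ERK pool (a.u.)
    epac_gain: float = 1.0       # relative Epac contribution to the ERK drive
    k_ktr_in: float = 0.3        # basal nuclear import of ERK-KTR (1/min)
    k_ktr_out: float = 3.0       # ERK-driven nuclear export (1/min per unit ERK)
    ktr_tot: float = 1.0         # total ERK-KTR per cell (a.u.)

    def __post_init__(self) -> None:
        for name in (
            "beta_b", "bpac_ref", "beta_0", "gamma_pde", "gamma_ex", "K_pka",
            "gamma_erk", "k_erk_react", "erk_tot", "epac_gain",
            "k_ktr_in", "k_ktr_out",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_pka < 1:
            raise ValueError("n_pka must be >= 1")
        if self.kappa_erk <= 0:
            raise ValueError("kappa_erk must be positive")
        if self.ktr_tot <= 0:
            raise ValueError("ktr_tot must be positive")


@dataclass(frozen=True)
class PharmacologySpec:
    """Parameter-level mapping of a pharmacological or genetic condition.

    ``pde_scale`` multiplies the PDE degradation rate (0 for the PDE
    inhibitor IBMX); ``coupling_scale`` multiplies all gap-junction
    permeabilities (0.2 for receivers overexpressing flux-dead CX43-NGFP,
    0.25 for Brefeldin-A, 0 for carbenoxolone); ``regulation_enabled=False``
    freezes the delayed activation chains (PKA inhibition by H89), with the
    basal permeability retained; ``epac_enabled=False`` removes the Epac
    contribution to the ERK drive (ESI-09).  A finite ``onset_time``
    applies the condition only from that time on (drug added mid-run).
    """

    name: str = "none"
    pde_scale: float = 1.0
    regulation_enabled: bool = True
    coupling_scale: float = 1.0
    epac_enabled: bool = True
    onset_time: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pde_scale <= 1.0:
            raise ValueError("pde_scale must lie in [0, 1]")
        if not 0.0 <= self.coupling_scale <= 1.0:
            raise ValueError("coupling_scale must lie in [0, 1]")


NO_DRUG = PharmacologySpec()


@dataclass(frozen=True)
class LightProtocol:
    """Sequence of constant-amplitude blue-light pulses.

    ``pulses`` is an ordered list of (t_on, t_off, amplitude) with
    amplitudes in [0, 1]; the input is piecewise constant and right-open:
    the light is on for t in [t_on, t_off).
    """

    pulses: tuple[tuple[float, float, float], ...]
    t_end: float

    def __post_init__(self) -> None:
        pulses = tuple((float(a), float(b), float(u)) for a, b, u in self.pulses)
        object.__setattr__(self, "pulses", pulses)
        prev_off = -np.inf
        for t_on, t_off, amp in pulses:
            if t_off <= t_on:
                raise ValueError("each pulse needs t_off > t_on")
            if t_on < prev_off:
                raise ValueError("pulses must be sorted and non-overlapping")
            if not 0.0 <= amp <= 1.0:
                raise ValueError("amplitude must lie in [0, 1]")
            prev_off = t_off
        if pulses and self.t_end < pulses[-1][1]:
            raise ValueError("t_end must cover the last pulse")

    @classmethod
    def two_pulse(
        cls,
        on_minutes: float = 40.0,
        off_minutes: float = 40.0,
        amplitudes: Sequence[float] = (1.0, 1.0),
    ) -> "LightProtocol":
        """The standard experiment: dark lead-in, then ON/OFF pulses
        (default two 40-min pulses separated by 40-min dark periods)."""
        pulses = []
        t = off_minutes
        for amp in amplitudes:
            pulses.append((t, t + on_minutes, float(amp)))
            t += on_minutes + off_minutes
        return cls(pulses=tuple(pulses), t_end=t)

    @property
    def onsets(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.pulses)

    def breakpoints(self) -> np.ndarray:
        """Sorted switch times of the piecewise-constant input in [0, t_end]."""
        pts = {0.0, self.t_end}
        for t_on, t_off, _ in self.pulses:
            pts.update((t_on, t_off))
        return np.array(sorted(p for p in pts if 0.0 <= p <= self.t_end))


def light_input(protocol: LightProtocol, t: float) -> float:
    """Pulse amplitude at time t (0 outside all pulses; right-open)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    for t_on, t_off, amp in protocol.pulses:
        if t_on <= t < t_off:
            return amp
    return 0.0


def pka_activity(camp: float | np.ndarray, params: IntracellularParams):
    """Fraction of PKA activated by cAMP: Hill form c^n / (K^n + c^n)."""
    c = np.asarray(camp, dtype=float)
    if np.any(c < 0):
        raise ValueError("camp must be non-negative")
    cn = c**params.n_pka
    out = cn / (params.K_pka**params.n_pka + cn)
    return float(out) if np.isscalar(camp) else out


def erk_drive(
    camp: float | np.ndarray, params: IntracellularParams, epac_enabled: bool = True
):
    """Combined PKA + Epac deactivation drive psi(cAMP) on ERK.

    Both effectors are cAMP-activated and inhibit ERK; with no separate
    affinity data they share the PKA Hill curve, Epac entering with relative
    weight ``epac_gain`` and removable by the Epac inhibitor.
    """
    pka = pka_activity(camp, params)
    weight = 1.0 + (params.epac_gain if epac_enabled else 0.0)
    return weight * pka


def intracellular_derivatives(
    state: np.ndarray,
    t: float,
    params: IntracellularParams,
    protocol: LightProtocol,
    pharm: PharmacologySpec = NO_DRUG,
    camp_influx: float = 0.0,
    bpac_level: float | None = None,
    cell_id: int | None = None,
    light_override: float | None = None,
) -> np.ndarray:
    """Right-hand side of the single-cell circuit.

    ``state`` is (camp, erk_active, ktr_nuc, pde_act); the cytosolic
    reporter pool is ``ktr_tot - ktr_nuc`` by conservation, and ``pde_act``
    is the slow (lagged) PKA activity that drives the optional PDE
    feedback — negative feedback must lag the cAMP signal to produce
    overshoot.  ``camp_influx`` carries the net gap-junctional flux when
    the cell is embedded in a tissue.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise IntegrationFailure("non-finite state", t, cell_id)
    if np.any(state < -1e-6):
        raise IntegrationFailure("negative state", t, cell_id)
    camp, erk, ktr_nuc, pde_act = np.maximum(state, 0.0)
    if light_override is not None:
        u = light_override
    else:
        u = light_input(protocol, t) if t >= 0 else 0.0
    b = params.bpac_ref if bpac_level is None else bpac_level
    pka = pka_activity(camp, params)
    production = params.beta_b * (b / params.bpac_ref) * u
    basal = params.beta_0 * (1.0 - params.ac_pka_inhibition_gain * pka)
    degradation = (
        params.gamma_pde
        * pharm.pde_scale
        * (1.0 + params.pde_pka_feedback_gain * pde_act)
        + params.gamma_ex
    ) * camp
    d_camp = production + basal - degradation + camp_influx
    psi = erk_drive(camp, params, epac_enabled=pharm.epac_enabled)
    d_erk = (
        -params.kappa_erk * params.gamma_erk * psi * erk
        + params.k_erk_react * (params.erk_tot - erk)
    )
    d_ktr = (
        params.k_ktr_in * (params.ktr_tot - ktr_nuc)
        - params.k_ktr_out * erk * ktr_nuc
    )
    d_pde = (pka - pde_act) / params.tau_pde_fb
    return np.array([d_camp, d_erk, d_ktr, d_pde])


@dataclass
class CellTrace:
    """Time-gridded signals of one cell (minutes; a.u.)."""

    time: np.ndarray
    camp: np.ndarray
    pka_on: np.ndarray
    erk_active: np.ndarray
    ktr_nc: np.ndarray
    cell_id: int = 0

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("camp", "pka_on", "erk_active", "ktr_nc"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match the time grid")


def ktr_nc_ratio(ktr_nuc: np.ndarray, params: IntracellularParams) -> np.ndarray:
    """Nuclear/cytosolic reporter ratio from the nuclear pool (equal-volume
    compartments)."""
    nuc = np.clip(ktr_nuc, 1e-12, params.ktr_tot * (1 - 1e-12))
    return nuc / (params.ktr_tot - nuc)


def dark_steady_state(
    params: IntracellularParams,
    pharm: PharmacologySpec = NO_DRUG,
    bpac_level: float | None = None,
    relax_minutes: float = RELAX_MINUTES,
) -> np.ndarray:
    """Basal (dark) state obtained by relaxing the circuit with no light."""
    dark = LightProtocol(pulses=(), t_end=relax_minutes)
    y0 = np.array([0.0, params.erk_tot, 0.5 * params.ktr_tot, 0.0])
    sol = solve_ivp(
        lambda t, y: intracellular_derivatives(
            y, t, params, dark, pharm, bpac_level=bpac_level
        ),
        (0.0, relax_minutes),
        y0,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise IntegrationFailure("dark relaxation failed", sol.t[-1])
    return sol.y[:, -1]


def simulate_single_cell(
    params: IntracellularParams,
    protocol: LightProtocol,
    pharm: PharmacologySpec = NO_DRUG,
    t_grid: np.ndarray | None = None,
    bpac_level: float | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> CellTrace:
    """Integrate one uncoupled cell over a light protocol.

    The cell starts from its dark steady state (500 simulated minutes of
    relaxation).  Integration is restarted at every light switch time so the
    piecewise-constant input never crosses a solver step.  Default output
    grid: 1-minute cadence over [0, t_end].
    """
    if t_grid is None:
        t_grid = np.arange(0.0, protocol.t_end + 0.5, 1.0)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    pre = pharm if pharm.onset_time is None or pharm.onset_time <= 0 else NO_DRUG
    y = dark_steady_state(params, pre, bpac_level=bpac_level)
    breaks = set(protocol.breakpoints().tolist())
    breaks.update((float(t_grid[0]), float(t_grid[-1])))
    if pharm.onset_time is not None and 0 < pharm.onset_time < t_grid[-1]:
        breaks.add(float(pharm.onset_time))
    breaks = np.array(sorted(b for b in breaks if t_grid[0] <= b <= t_grid[-1]))

    out = np.empty((4, t_grid.size))
    filled = np.zeros(t_grid.size, dtype=bool)
    on_grid0 = np.isclose(t_grid, breaks[0])
    out[:, on_grid0] = y[:, None]
    filled |= on_grid0
    for a, b in zip(breaks[:-1], breaks[1:]):
        seg_pharm = pharm
        if pharm.onset_time is not None and a < pharm.onset_time:
            seg_pharm = NO_DRUG
        mask = (t_grid > a + 1e-12) & (t_grid <= b + 1e-12) & ~filled
        t_eval = t_grid[mask]
        u_seg = light_input(protocol, 0.5 * (a + b))
        sol = solve_ivp(
            lambda t, s: intracellular_derivatives(
                s, t, params, protocol, seg_pharm,
                bpac_level=bpac_level, light_override=u_seg,
            ),
            (a, b),
            y,
            method="LSODA",
            t_eval=t_eval if t_eval.size else None,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationFailure("single-cell integration failed", sol.t[-1])
        if t_eval.size:
            out[:, mask] = sol.y
            filled |= mask
        y = sol.y[:, -1]

    camp = np.maximum(out[0], 0.0)
    return CellTrace(
        time=t_grid,
        camp=camp,
        pka_on=pka_activity(camp, params),
        erk_active=out[1],
        ktr_nc=ktr_nc_ratio(out[2], params),
    )


@dataclass
class FitResult:
    estimates: dict[str, float]
    residual_norm: float
    success: bool
    identifiable: bool
    n_starts: int
    message: str


_FITTABLE = (
    "beta_b", "beta_0", "gamma_pde", "K_pka", "gamma_erk",
    "k_erk_react", "k_ktr_in", "k_ktr_out",
)


def fit_intracellular(
    traces: Sequence[CellTrace],
    free_params: Sequence[str],
    bounds: dict[str, tuple[float, float]],
    seed: int,
    protocol: LightProtocol,
    base_params: IntracellularParams = IntracellularParams(),
    pharm: PharmacologySpec = NO_DRUG,
    n_starts: int = 3,
) -> FitResult:
    """Least-squares fit of selected rate constants to ktr_nc traces.

    Minimizes the summed squared ktr_nc residual over all traces with
    seeded multi-start ``scipy.optimize.least_squares`` (TRF, log-spaced
    starts inside the bounds).  Traces must share the time grid and
    protocol.  Flat data raise :class:`NonIdentifiableError` rather than
    returning a silent fit.
    """
    if not traces:
        raise ValueError("need at least one trace")
    for name in free_params:
        if name not in _FITTABLE:
            raise ValueError(f"unknown or unsupported free parameter {name!r}")
        if name not in bounds:
            raise ValueError(f"missing bounds for {name!r}")
    grid = np.asarray(traces[0].time, dtype=float)
    data = np.stack([np.asarray(tr.ktr_nc, dtype=float) for tr in traces])
    if any(tr.time.shape != grid.shape or not np.allclose(tr.time, grid)
           for tr in traces):
        raise ValueError("all traces must share one time grid")
    dyn = float(data.max() - data.min())
    if dyn < 1e-9 * max(1.0, abs(float(data.mean()))) or dyn == 0.0:
        raise NonIdentifiableError(
            "traces carry no dynamic signal; parameters are not identifiable"
        )

    lo = np.array([bounds[n][0] for n in free_params])
    hi = np.array([bounds[n][1] for n in free_params])

    def residual(theta: np.ndarray) -> np.ndarray:
        p = replace(base_params, **dict(zip(free_params, theta)))
        model = simulate_single_cell(p, protocol, pharm, t_grid=grid).ktr_nc
        return (data - model[None, :]).ravel()

    rng = np.random.default_rng(seed)
    starts = [np.exp(rng.uniform(np.log(np.maximum(lo, 1e-6)), np.log(hi)))
              for _ in range(max(0, n_starts - 1))]
    base_start = np.clip(
        [getattr(base_params, n) for n in free_params], lo * 1.001, hi * 0.999
    )
    starts.insert(0, base_start)

    best = None
    for x0 in starts:
        try:
            res = least_squares(
                residual, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12
            )
        except IntegrationFailure:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return FitResult({}, np.inf, False, True, len(starts),
                         "all starts failed to integrate")
    return FitResult(
        estimates=dict(zip(free_params, best.x.tolist())),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        success=bool(best.status > 0),
        identifiable=True,
        n_starts=len(starts),
        message=best.message,
    )
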
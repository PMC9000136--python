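"""Delayed gap-junction regulation and intercellular cAMP flux.

Gap-junction channels (connexin 43 assemblies) are modeled as a closed pool
per cell: an inactive pool is recruited by cAMP/PKA activity into a chain of
``N`` sequential first-order delay steps (the linear chain trick) before
reaching the active, membrane-coupled state; active channels deactivate
(e.g. by endocytosis) back to the inactive pool.  The transit time through
the chain is Erlang(N, N/tau) distributed with mean ``tau_gj`` and variance
``tau_gj**2 / N``: N=1 gives a highly dispersed exponential activation,
large N a switch-like delayed step.

The active concentration on each side of a cell-cell interface, parsed
equally among that cell's coupled neighbors, modulates the effective
gap-junctional cAMP permeability ``rho_ij`` on top of a basal term; the flux
of cAMP into cell i across the interface is ``rho_ij * (camp_j - camp_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DelayChainParams",
    "GJPoolState",
    "CouplingParams",
    "delay_chain_derivatives",
    "delay_chain_response",
    "effective_permeability",
    "camp_flux",
]


@dataclass(frozen=True)
class DelayChainParams:
    """Rate constants of one delayed-activation chain (a connexin population).

    Parameters
    ----------
    tau_gj : float
        Mean delay (minutes) from entering the chain to becoming active.
    n_steps : int
        Number of intermediate delay steps N (>= 1).  Each step has rate
        ``n_steps / tau_gj`` so the mean transit time is ``tau_gj``.
    gamma_gj : float
        Deactivation rate (1/min) of the active pool back to inactive.
    k_act : float
        Entry-rate coefficient (1/min) multiplying f(PKA_on) = PKA_on.
    label : str
        Population name, e.g. ``"near"`` (membrane-proximal, short delay) or
        ``"far"`` (Golgi-located, long delay).
    """

    tau_gj: float = 15.0
    n_steps: int = 4
    gamma_gj: float = 0.05
    k_act: float = 0.5
    label: str = "far"

    def __post_init__(self) -> None:
        if self.tau_gj <= 0:
            raise ValueError("tau_gj must be positive")
        if int(self.n_steps) != self.n_steps or self.n_steps < 1:
            raise ValueError("n_steps must be an integer >= 1")
        if self.gamma_gj < 0 or self.k_act < 0:
            raise ValueError("gamma_gj and k_act must be non-negative")

    @property
    def step_rate(self) -> float:
        """Per-step transit rate N / tau_gj (1/min)."""
        return self.n_steps / self.tau_gj


@dataclass
class GJPoolState:
    """State of one chain: inactive pool, N delay pools, active pool."""

    gj_na: float
    gj_d: np.ndarray
    gj_ca: float

    def total(self) -> float:
        return float(self.gj_na + np.sum(self.gj_d) + self.gj_ca)


@dataclass(frozen=True)
class CouplingParams:
    """Constants of the effective-permeability model.

    ``rho_ij = kappa_gj * omega_ij * [k_gj + k_gj_gjf / (p_bar * x_f**3)
    * (gj_ca_i / P_i + gj_ca_j / P_j)]``.  ``p_bar`` and ``x_f**3`` are
    normalizing constants giving the regulated gain ``k_gj_gjf`` the same
    units as the basal permeability ``k_gj``; with the default pool size of
    one per cell and mean degree ``p_bar`` the normalized active
    concentration is O(1) at full activation.
    """

    k_gj: float = 0.01
    k_gj_gjf: float = 0.6
    x_f: float = 0.430886938006377  # x_f**3 == 2 / p_bar**2 for p_bar = 5
    p_bar: float = 5.0
    kappa_gj: float = 1.0

    def __post_init__(self) -> None:
        if min(self.k_gj, self.k_gj_gjf, self.x_f, self.kappa_gj) < 0:
            raise ValueError("coupling constants must be non-negative")
        if self.p_bar <= 0:
            raise ValueError("p_bar must be positive")

    @property
    def regulated_gain(self) -> float:
        """k_gj_gjf / (p_bar * x_f**3), the coefficient of the parsed
        active concentrations."""
        return self.k_gj_gjf / (self.p_bar * self.x_f**3)


def delay_chain_derivatives(
    pool: GJPoolState, pka_on: float, p: DelayChainParams
) -> GJPoolState:
    """Time derivatives of one delay chain driven by PKA activity.

    Entry from the inactive pool into the first delay step occurs at rate
    ``k_act * f(pka_on) * gj_na`` with the minimal monotone choice
    ``f(x) = x``; mass then transits the N steps at rate ``N / tau_gj`` each
    and deactivates from the active pool at ``gamma_gj``.  The chain is
    closed: the returned derivatives sum to zero exactly.
    """
    gj_d = np.asarray(pool.gj_d, dtype=float)
    if gj_d.shape != (p.n_steps,):
        raise ValueError(
            f"gj_d has length {gj_d.size}, expected n_steps={p.n_steps}"
        )
    r = p.step_rate
    entry = p.k_act * pka_on * pool.gj_na
    deact = p.gamma_gj * pool.gj_ca
    d_d = np.empty_like(gj_d)
    d_d[0] = entry - r * gj_d[0]
    if p.n_steps > 1:
        d_d[1:] = r * (gj_d[:-1] - gj_d[1:])
    return GJPoolState(
        gj_na=deact - entry,
        gj_d=d_d,
        gj_ca=r * gj_d[-1] - deact,
    )


def delay_chain_response(
    p: DelayChainParams, K: float, t: float | np.ndarray
) -> float | np.ndarray:
    """Closed-form active amount for a group of K molecules started in the
    first delay step at t=0 with deactivation off (gamma_gj = 0).

    The transit time through N sequential steps of rate N/tau is
    Erlang(N, N/tau) distributed, so the active amount is
    ``K * P(Erlang <= t)``.  For N=1 this is ``K * (1 - exp(-t/tau))``; for
    N -> infinity it approaches the perfect-delay step ``K * u(t - tau)``.
    """
    if p.gamma_gj != 0:
        raise ValueError("closed form requires gamma_gj = 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    out = K * stats.gamma.cdf(t_arr, a=p.n_steps, scale=p.tau_gj / p.n_steps)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def effective_permeability(
    gj_ca_i: float,
    gj_ca_j: float,
    P_i: int,
    P_j: int,
    cp: CouplingParams,
    omega_ij: int = 1,
    pharm_coupling_scale: float = 1.0,
) -> float:
    """Effective gap-junctional cAMP permeability rho_ij (1/min).

    Symmetric in (i, j); zero when the cells do not interface.  Each cell's
    active concentration is parsed equally among its P coupled neighbors.
    """
    if omega_ij not in (0, 1):
        raise ValueError("omega_ij must be 0 or 1")
    if omega_ij == 0:
        return 0.0
    if P_i < 1 or P_j < 1:
        raise ValueError("coupled cells must have degree >= 1")
    if gj_ca_i < 0 or gj_ca_j < 0:
        raise ValueError("active concentrations must be non-negative")
    reg = cp.regulated_gain * (gj_ca_i / P_i + gj_ca_j / P_j)
    return pharm_coupling_scale * cp.kappa_gj * (cp.k_gj + reg)


def camp_flux(camp_i: float, camp_j: float, rho_ij: float) -> float:
    """cAMP flux into cell i across the ij interface (a.u./min).

    ``F_ij = rho_ij * (camp_j - camp_i)``: positive when the neighbor has
    the higher concentration; antisymmetric under swapping i and j.
    """
    if rho_ij < 0:
        raise ValueError("rho_ij must be non-negative")
    return rho_ij * (camp_j - camp_i)
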
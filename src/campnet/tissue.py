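"""Monolayer scenarios and the coupled multicellular simulation.

Each cell runs the intracellular circuit of :mod:`campnet.model_core`;
cells exchange cAMP across gap junctions whose permeability is regulated by
the delayed activation chains of :mod:`campnet.gap_junctions`.  Emitters
carry bPAC (light-driven cAMP production), receivers do not; both carry the
ERK-KTR reporter.

Scenario geometry defaults to a hexagonal-lattice disc — a planar,
monolayer-like adjacency whose interior cells touch up to six neighbors,
seeded random edge thinning keeping the coupled-neighbor counts in the 4-7
range the experiments show (mean ~5).  Explicit edge lists are accepted for
bespoke layouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .gap_junctions import CouplingParams, DelayChainParams
from .model_core import (
    NO_DRUG,
    CellTrace,
    IntegrationFailure,
    IntracellularParams,
    LightProtocol,
    PharmacologySpec,
    RELAX_MINUTES,
    erk_drive,
    ktr_nc_ratio,
    light_input,
    pka_activity,
)

__all__ = [
    "MonolayerGraph",
    "TraceSet",
    "build_scenario",
    "drug_spec",
    "apply_pharmacology",
    "EffectiveCondition",
    "simulate_tissue",
    "run_model_variant",
    "DRUG_PRESETS",
    "MODEL_VARIANTS",
]

#: Basal permeability used by the constant-permeability (unregulated) model,
#: sized so receivers respond visibly at kappa_gj = 1.
CONSTANT_PERMEABILITY_K_GJ = 0.1

EMITTER = "emitter"
RECEIVER = "receiver"


@dataclass
class MonolayerGraph:
    """Cells with roles and bPAC levels plus a symmetric adjacency.

    ``edges`` stores each undirected interface once as (i, j) with i < j.
    ``beta_0`` optionally overrides the endogenous basal cAMP production
    per cell (used by the undershoot variant, where emitters have higher
    basal activity than receivers).
    """

    roles: np.ndarray
    bpac: np.ndarray
    edges: np.ndarray
    positions: np.ndarray | None = None
    beta_0: np.ndarray | None = None
    name: str = "custom"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.roles = np.asarray(self.roles, dtype=object)
        self.bpac = np.asarray(self.bpac, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int)
        n = self.roles.size
        if self.bpac.size != n:
            raise ValueError("bpac must have one entry per cell")
        if self.edges.ndim != 2 or self.edges.shape[1] != 2:
            raise ValueError("edges must be an (m, 2) array")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-edges are not allowed")
        self.edges = np.sort(self.edges, axis=1)
        self.edges = np.unique(self.edges, axis=0)
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= n):
            raise ValueError("edge endpoints out of range")
        for r, b in zip(self.roles, self.bpac):
            if r == EMITTER and b <= 0:
                raise ValueError("emitters must have bpac > 0")
            if r == RECEIVER and b != 0:
                raise ValueError("receivers must have bpac = 0")
        if not self._connected():
            raise ValueError("monolayer graph must be connected")

    def _connected(self) -> bool:
        n = self.n_cells
        if n == 1:
            return True
        adj = sparse.coo_matrix(
            (np.ones(len(self.edges)), (self.edges[:, 0], self.edges[:, 1])),
            shape=(n, n),
        )
        ncomp, _ = sparse.csgraph.connected_components(adj, directed=False)
        return ncomp == 1

    @property
    def n_cells(self) -> int:
        return int(self.roles.size)

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_cells, dtype=int)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    @property
    def emitter_ids(self) -> np.ndarray:
        return np.flatnonzero(self.roles == EMITTER)

    @property
    def receiver_ids(self) -> np.ndarray:
        return np.flatnonzero(self.roles == RECEIVER)

    def adjacency_matrix(self) -> np.ndarray:
        omega = np.zeros((self.n_cells, self.n_cells), dtype=int)
        omega[self.edges[:, 0], self.edges[:, 1]] = 1
        omega[self.edges[:, 1], self.edges[:, 0]] = 1
        return omega

    def graph_distances(self, source: int) -> np.ndarray:
        """Unweighted shortest-path (hop) distance of every cell from
        ``source``."""
        n = self.n_cells
        adj = sparse.coo_matrix(
            (np.ones(len(self.edges)), (self.edges[:, 0], self.edges[:, 1])),
            shape=(n, n),
        )
        d = sparse.csgraph.shortest_path(
            adj, method="BF", directed=False, unweighted=True, indices=source
        )
        return d.astype(int)

    def adjacent_receivers(self, emitter: int | None = None) -> np.ndarray:
        """Receivers sharing an interface with the given (or first) emitter."""
        if emitter is None:
            emitter = int(self.emitter_ids[0])
        nb = set()
        for i, j in self.edges:
            if i == emitter:
                nb.add(j)
            elif j == emitter:
                nb.add(i)
        return np.array(sorted(k for k in nb if self.roles[k] == RECEIVER))


def _hex_disc(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Positions and lattice edges of the n cells of a hexagonal disc
    closest to the origin (deterministic)."""
    radius = int(np.ceil(np.sqrt(n))) + 2
    cells = []
    for q in range(-radius, radius + 1):
        for r in range(-radius, radius + 1):
            x = q + 0.5 * r
            y = r * np.sqrt(3) / 2
            cells.append((x * x + y * y, q, r, x, y))
    cells.sort()
    chosen = cells[:n]
    index = {(q, r): k for k, (_, q, r, _, _) in enumerate(chosen)}
    pos = np.array([(x, y) for (_, _, _, x, y) in chosen])
    edges = []
    for (q, r), k in index.items():
        for dq, dr in ((1, 0), (0, 1), (1, -1)):
            other = index.get((q + dq, r + dr))
            if other is not None:
                edges.append((k, other))
    return pos, np.array(edges, dtype=int)


def _thin_edges(
    n: int, edges: np.ndarray, rng: np.random.Generator, target_mean: float = 5.0
) -> np.ndarray:
    """Randomly drop edges (seeded) while keeping degree >= 3 and
    connectivity, until the mean degree is at most ``target_mean``."""
    edges = [tuple(e) for e in edges]
    deg = np.zeros(n, dtype=int)
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1

    def connected(es: list[tuple[int, int]]) -> bool:
        if not es:
            return n == 1
        adj = sparse.coo_matrix(
            (np.ones(len(es)), tuple(np.array(es).T)), shape=(n, n)
        )
        ncomp, _ = sparse.csgraph.connected_components(adj, directed=False)
        return ncomp == 1

    attempts = 0
    while 2 * len(edges) / n > target_mean and attempts < 20 * len(edges):
        attempts += 1
        idx = int(rng.integers(len(edges)))
        i, j = edges[idx]
        if deg[i] <= 3 or deg[j] <= 3:
            continue
        trial = edges[:idx] + edges[idx + 1:]
        if connected(trial):
            deg[i] -= 1
            deg[j] -= 1
            edges = trial
    return np.array(edges, dtype=int)


def build_scenario(name: str, options: dict | None = None, seed: int = 0) -> MonolayerGraph:
    """Build a named monolayer scenario.

    ``all_emitter``: every cell carries bPAC (option ``n``, default 46;
    ``bpac_cv`` draws log-normal expression levels).
    ``single_emitter_cluster``: one central emitter surrounded by receivers
    (option ``n_receivers``, default 45; 10 for the reduced layout).
    ``small_emitter_cluster``: a concentrated central group of emitters
    (option ``n_emitters`` <= 15, default 5) surrounded by receivers.
    """
    options = dict(options or {})
    rng = np.random.default_rng(seed)

    if name == "all_emitter":
        n = int(options.pop("n", 46))
        n_emitters, n_receivers = n, 0
    elif name == "single_emitter_cluster":
        n_receivers = int(options.pop("n_receivers", 45))
        n_emitters = 1
        n = n_receivers + 1
    elif name == "small_emitter_cluster":
        n_emitters = int(options.pop("n_emitters", 5))
        if n_emitters > 15:
            warnings.warn(
                "a small emitter cluster is defined as 15 or fewer emitters",
                stacklevel=2,
            )
        n_receivers = int(options.pop("n_receivers", 46 - n_emitters))
        n = n_emitters + n_receivers
    else:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of all_emitter, "
            "single_emitter_cluster, small_emitter_cluster"
        )
    bpac_cv = float(options.pop("bpac_cv", 0.0))
    if options:
        raise ValueError(f"unknown scenario options: {sorted(options)}")

    pos, edges = _hex_disc(n)
    edges = _thin_edges(n, edges, rng)

    # emitters are the cells nearest the disc center (a concentrated cluster)
    center_order = np.argsort(np.einsum("ij,ij->i", pos, pos), kind="stable")
    roles = np.array([RECEIVER] * n, dtype=object)
    roles[center_order[:n_emitters]] = EMITTER
    bpac = np.zeros(n)
    if n_emitters:
        if bpac_cv > 0:
            from .synthetic import sample_expression_levels

            levels = sample_expression_levels(
                n_emitters, bpac_cv, seed=int(rng.integers(2**31 - 1))
            )
        else:
            levels = np.ones(n_emitters)
        bpac[center_order[:n_emitters]] = levels
    return MonolayerGraph(
        roles=roles, bpac=bpac, edges=edges, positions=pos, name=name, seed=seed
    )


DRUG_PRESETS: dict[str, PharmacologySpec] = {
    "none": NO_DRUG,
    "ibmx": PharmacologySpec(name="ibmx", pde_scale=0.0),
    "cx43_ngfp": PharmacologySpec(name="cx43_ngfp", coupling_scale=0.2),
    "brefeldin_a": PharmacologySpec(name="brefeldin_a", coupling_scale=0.25),
    "carbenoxolone": PharmacologySpec(name="carbenoxolone", coupling_scale=0.0),
    "h89": PharmacologySpec(name="h89", regulation_enabled=False),
    "esi09": PharmacologySpec(name="esi09", epac_enabled=False),
}


def drug_spec(name: str, onset_time: float | None = None) -> PharmacologySpec:
    """Pharmacology mapping by drug name; raises with the supported list."""
    key = name.lower().replace("-", "_")
    if key not in DRUG_PRESETS:
        raise ValueError(
            f"unknown drug {name!r}; supported: {sorted(DRUG_PRESETS)}"
        )
    spec = DRUG_PRESETS[key]
    if onset_time is not None:
        spec = replace(spec, onset_time=onset_time)
    return spec


@dataclass(frozen=True)
class EffectiveCondition:
    """Parameter set after applying a pharmacological condition."""

    params: IntracellularParams
    coupling_scale: float
    regulation_enabled: bool
    epac_enabled: bool


def apply_pharmacology(
    params: IntracellularParams,
    coupling: CouplingParams,
    pharm: PharmacologySpec,
) -> EffectiveCondition:
    """Fold a pharmacology spec into an effective parameter set.

    The PDE scale multiplies ``gamma_pde`` directly (zero under IBMX);
    coupling inhibitors scale every interface permeability; PKA inhibition
    freezes the delayed regulation chains (entry rate zero) while the basal
    permeability is retained.
    """
    eff_params = replace(params, gamma_pde=params.gamma_pde * pharm.pde_scale)
    return EffectiveCondition(
        params=eff_params,
        coupling_scale=pharm.coupling_scale,
        regulation_enabled=pharm.regulation_enabled,
        epac_enabled=pharm.epac_enabled,
    )


@dataclass
class TraceSet:
    """Time-gridded per-cell signals and per-interface permeability/flux."""

    time: np.ndarray
    roles: np.ndarray
    bpac: np.ndarray
    camp: np.ndarray        # (n_cells, n_t)
    pka_on: np.ndarray
    erk_active: np.ndarray
    ktr_nc: np.ndarray
    edges: np.ndarray       # (m, 2)
    rho: np.ndarray         # (m, n_t) effective permeability
    flux: np.ndarray        # (m, n_t) cAMP flux into edges[:, 0]
    gj_parsed_i: np.ndarray  # (m, n_t) parsed active concentration, side i
    gj_parsed_j: np.ndarray  # (m, n_t) parsed active concentration, side j
    gj_ca: np.ndarray       # (n_pops, n_cells, n_t) active pool per population
    pop_labels: tuple[str, ...]
    graph: MonolayerGraph | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.camp.shape[0]

    def cell_trace(self, i: int) -> CellTrace:
        return CellTrace(
            time=self.time,
            camp=self.camp[i],
            pka_on=self.pka_on[i],
            erk_active=self.erk_active[i],
            ktr_nc=self.ktr_nc[i],
            cell_id=i,
        )


def _chain_block(n: int, n_steps: int) -> int:
    return n * (n_steps + 2)


def _pack_layout(n: int, chains: Sequence[DelayChainParams]):
    """Offsets of each state block in the flat vector."""
    offsets = {"camp": 0, "erk": n, "ktr": 2 * n, "pde": 3 * n}
    cursor = 4 * n
    pops = []
    for p in chains:
        pops.append(cursor)
        cursor += _chain_block(n, p.n_steps)
    return offsets, pops, cursor


def _jac_sparsity(
    n: int, edges: np.ndarray, chains: Sequence[DelayChainParams], size: int,
    pops: Sequence[int],
) -> sparse.csr_matrix:
    rows, cols = [], []

    def dep(r, c):
        rows.append(r)
        cols.append(c)

    for i in range(n):
        dep(i, i)            # camp on camp
        dep(i, 3 * n + i)    # camp on lagged PDE activation
        dep(n + i, i)        # erk on camp
        dep(n + i, n + i)
        dep(2 * n + i, n + i)
        dep(2 * n + i, 2 * n + i)
        dep(3 * n + i, i)    # lagged PDE activation on camp
        dep(3 * n + i, 3 * n + i)
    for i, j in edges:
        dep(i, j)
        dep(j, i)
    for off, p in zip(pops, chains):
        N = p.n_steps
        for i in range(n):
            na = off + i
            d0 = off + n + i
            ca = off + (N + 1) * n + i
            dep(na, na); dep(na, ca); dep(na, i)
            dep(d0, na); dep(d0, d0); dep(d0, i)
            for k in range(1, N):
                dk = off + (k + 1) * n + i
                dep(dk, dk); dep(dk, dk - n)
            dep(ca, ca); dep(ca, off + N * n + i)
        # permeability regulation: camp of both edge ends depends on the
        # active pools of both cells
        for i, j in edges:
            dep(i, off + (N + 1) * n + i)
            dep(i, off + (N + 1) * n + j)
            dep(j, off + (N + 1) * n + i)
            dep(j, off + (N + 1) * n + j)
    data = np.ones(len(rows))
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(size, size)
    )


def simulate_tissue(
    graph: MonolayerGraph,
    params: IntracellularParams = IntracellularParams(),
    protocol: LightProtocol | None = None,
    pharm: PharmacologySpec = NO_DRUG,
    coupling: CouplingParams = CouplingParams(),
    chains: Sequence[DelayChainParams] = (DelayChainParams(),),
    pool_fractions: Sequence[float] | np.ndarray | None = None,
    pool_total: float = 1.0,
    pulse_reset_fractions: Sequence[Sequence[float]] | None = None,
    t_grid: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    metadata: dict | None = None,
) -> TraceSet:
    """Integrate the coupled multicellular system and return a TraceSet.

    All cells share ``params`` except the per-cell bPAC level (and optional
    per-cell basal production) carried by the graph.  ``chains`` lists the
    inactive gap-junction populations (e.g. near/far); ``pool_fractions``
    splits each cell's total inactive pool ``pool_total`` among them (all
    mass in the first population by default).  ``pulse_reset_fractions``
    optionally re-initializes the chains to fully inactive pools with the
    given per-pulse splits at each pulse onset, emulating inter-pulse
    connexin trafficking turnover.

    Stiff-capable integration: implicit BDF with an analytic Jacobian
    sparsity pattern built from the cell graph; integration restarts at
    every light switch so the piecewise-constant input is exact.
    """
    if protocol is None:
        protocol = LightProtocol.two_pulse()
    n = graph.n_cells
    edges = graph.edges
    n_pops = len(chains)
    if pool_fractions is None:
        pool_fractions = np.zeros(n_pops)
        pool_fractions[0] = 1.0
    pool_fractions = np.asarray(pool_fractions, dtype=float)
    if pool_fractions.ndim == 1:
        pool_fractions = np.tile(pool_fractions, (n, 1))
    if pool_fractions.shape != (n, n_pops):
        raise ValueError("pool_fractions must have shape (n_pops,) or (n, n_pops)")
    if np.any(pool_fractions < 0) or not np.allclose(pool_fractions.sum(axis=1), 1.0):
        raise ValueError("pool fractions must be non-negative and sum to 1")

    if t_grid is None:
        t_grid = np.arange(0.0, protocol.t_end + 0.5, 1.0)
    t_grid = np.asarray(t_grid, dtype=float)

    offsets, pops, size = _pack_layout(n, chains)
    sparsity = _jac_sparsity(n, edges, chains, size, pops)

    beta0 = (
        np.full(n, params.beta_0)
        if graph.beta_0 is None
        else np.asarray(graph.beta_0, dtype=float)
    )
    b_rel = graph.bpac / params.bpac_ref
    deg = graph.degrees.astype(float)
    if edges.size and np.any(deg[np.unique(edges)] < 1):
        raise ValueError("coupled cells must have degree >= 1")
    ei, ej = (edges[:, 0], edges[:, 1]) if edges.size else (np.array([], int),) * 2

    no_drug_cond = apply_pharmacology(params, coupling, NO_DRUG)
    drug_cond = apply_pharmacology(params, coupling, pharm)

    def rhs_factory(u: float, cond: EffectiveCondition):
        p = cond.params
        kact = np.array(
            [c.k_act if cond.regulation_enabled else 0.0 for c in chains]
        )
        gain = coupling.regulated_gain
        cscale = cond.coupling_scale * coupling.kappa_gj
        psi_weight = 1.0 + (p.epac_gain if cond.epac_enabled else 0.0)

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            camp = np.maximum(y[0:n], 0.0)
            erk = y[n: 2 * n]
            ktr = y[2 * n: 3 * n]
            pde_act = y[3 * n: 4 * n]
            pka = pka_activity(camp, p)
            dy = np.empty_like(y)

            # total active pool per cell and chain dynamics
            ca_tot = np.zeros(n)
            for off, cp, ka in zip(pops, chains, kact):
                N = cp.n_steps
                r = cp.step_rate
                na = y[off: off + n]
                d = y[off + n: off + (N + 1) * n].reshape(N, n)
                ca = y[off + (N + 1) * n: off + (N + 2) * n]
                ca_tot += ca
                entry = ka * pka * np.maximum(na, 0.0)
                deact = cp.gamma_gj * ca
                dy[off: off + n] = deact - entry
                dd = dy[off + n: off + (N + 1) * n].reshape(N, n)
                dd[0] = entry - r * d[0]
                if N > 1:
                    dd[1:] = r * (d[:-1] - d[1:])
                dy[off + (N + 1) * n: off + (N + 2) * n] = r * d[-1] - deact

            influx = np.zeros(n)
            if edges.size:
                parsed = ca_tot / np.maximum(deg, 1.0)
                rho = cscale * (coupling.k_gj + gain * (parsed[ei] + parsed[ej]))
                f = rho * (camp[ej] - camp[ei])  # flux into i
                np.add.at(influx, ei, f)
                np.add.at(influx, ej, -f)

            production = p.beta_b * b_rel * u
            basal = beta0 * (1.0 - p.ac_pka_inhibition_gain * pka)
            degr = (
                p.gamma_pde * (1.0 + p.pde_pka_feedback_gain * pde_act)
                + p.gamma_ex
            ) * camp
            dy[0:n] = production + basal - degr + influx
            psi = psi_weight * pka
            dy[n: 2 * n] = (
                -p.kappa_erk * p.gamma_erk * psi * erk
                + p.k_erk_react * (p.erk_tot - erk)
            )
            dy[2 * n: 3 * n] = (
                p.k_ktr_in * (p.ktr_tot - ktr) - p.k_ktr_out * erk * ktr
            )
            dy[3 * n: 4 * n] = (pka - pde_act) / p.tau_pde_fb
            return dy

        return rhs

    # ---- initial condition: dark relaxation to the basal steady state ----
    y0 = np.zeros(size)
    y0[n: 2 * n] = params.erk_tot
    y0[2 * n: 3 * n] = 0.5 * params.ktr_tot
    for off, frac in zip(pops, pool_fractions.T):
        y0[off: off + n] = pool_total * frac
    pre_cond = (
        drug_cond
        if (pharm.onset_time is None or pharm.onset_time <= 0)
        else no_drug_cond
    )
    relax = solve_ivp(
        rhs_factory(0.0, pre_cond),
        (0.0, RELAX_MINUTES),
        y0,
        method="BDF",
        jac_sparsity=sparsity,
        rtol=1e-7,
        atol=1e-10,
    )
    if not relax.success:
        raise IntegrationFailure("dark relaxation failed", relax.t[-1])
    y = relax.y[:, -1]

    # ---- piecewise integration over light switches / drug onset ----
    onset = pharm.onset_time
    breaks = set(protocol.breakpoints().tolist())
    breaks.update((float(t_grid[0]), float(t_grid[-1])))
    if onset is not None and t_grid[0] < onset < t_grid[-1]:
        breaks.add(float(onset))
    breaks = np.array(sorted(b for b in breaks if t_grid[0] <= b <= t_grid[-1]))
    reset_times = (
        {float(t): k for k, t in enumerate(protocol.onsets)}
        if pulse_reset_fractions is not None
        else {}
    )

    out = np.empty((size, t_grid.size))
    filled = np.zeros(t_grid.size, dtype=bool)
    first = np.isclose(t_grid, breaks[0])
    out[:, first] = y[:, None]
    filled |= first
    for a, b in zip(breaks[:-1], breaks[1:]):
        if float(a) in reset_times:
            k = min(reset_times[float(a)], len(pulse_reset_fractions) - 1)
            frac = np.asarray(pulse_reset_fractions[k], dtype=float)
            if frac.shape != (n_pops,) or not np.isclose(frac.sum(), 1.0):
                raise ValueError("pulse reset fractions must sum to 1 per pulse")
            for off, cp, f in zip(pops, chains, frac):
                blk = _chain_block(n, cp.n_steps)
                y[off: off + blk] = 0.0
                y[off: off + n] = pool_total * f
            at_a = np.isclose(t_grid, a)
            out[:, at_a] = y[:, None]
        cond = drug_cond if (onset is None or a >= onset) else no_drug_cond
        u_seg = light_input(protocol, 0.5 * (a + b))
        mask = (t_grid > a + 1e-12) & (t_grid <= b + 1e-12) & ~filled
        t_eval = t_grid[mask]
        sol = solve_ivp(
            rhs_factory(u_seg, cond),
            (a, b),
            y,
            method="BDF",
            jac_sparsity=sparsity,
            t_eval=t_eval if t_eval.size else None,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            worst = int(np.argmax(np.abs(sol.y[0:n, -1]))) if sol.y.size else -1
            raise IntegrationFailure(
                f"tissue integration failed ({sol.message})", sol.t[-1], worst
            )
        if t_eval.size:
            out[:, mask] = sol.y
            filled |= mask
        y = sol.y[:, -1]

    # ---- unpack and derive interface quantities on the output grid ----
    camp = np.maximum(out[0:n], 0.0)
    erk = out[n: 2 * n]
    ktr = out[2 * n: 3 * n]
    pka = pka_activity(camp, params)
    gj_ca = np.stack(
        [
            out[off + (cp.n_steps + 1) * n: off + (cp.n_steps + 2) * n]
            for off, cp in zip(pops, chains)
        ]
    )
    ca_tot = gj_ca.sum(axis=0)
    nt = t_grid.size
    m = len(edges)
    rho = np.zeros((m, nt))
    flux = np.zeros((m, nt))
    parsed_i = np.zeros((m, nt))
    parsed_j = np.zeros((m, nt))
    if m:
        # the applied coupling scale is time-dependent if the drug has an onset
        cscale_t = np.full(nt, drug_cond.coupling_scale * coupling.kappa_gj)
        if onset is not None:
            cscale_t[t_grid < onset] = (
                no_drug_cond.coupling_scale * coupling.kappa_gj
            )
        parsed = ca_tot / np.maximum(deg, 1.0)[:, None]
        parsed_i = parsed[ei]
        parsed_j = parsed[ej]
        rho = cscale_t[None, :] * (
            coupling.k_gj + coupling.regulated_gain * (parsed_i + parsed_j)
        )
        flux = rho * (camp[ej] - camp[ei])

    meta = {
        "scenario": graph.name,
        "seed": graph.seed,
        "pharm": pharm.name,
        "n_cells": n,
        "protocol_pulses": list(protocol.pulses),
    }
    meta.update(metadata or {})
    return TraceSet(
        time=t_grid,
        roles=graph.roles,
        bpac=graph.bpac,
        camp=camp,
        pka_on=pka,
        erk_active=erk,
        ktr_nc=ktr_nc_ratio(ktr, params),
        edges=edges,
        rho=rho,
        flux=flux,
        gj_parsed_i=parsed_i,
        gj_parsed_j=parsed_j,
        gj_ca=gj_ca,
        pop_labels=tuple(c.label for c in chains),
        graph=graph,
        metadata=meta,
    )


MODEL_VARIANTS = (
    "constant_permeability",
    "pka_pde_feedback",
    "delayed_regulation",
    "near_far",
    "undershoot",
)

#: Delay-chain presets: the default membrane-trafficking ("far") population,
#: a fast membrane-proximal ("near") population, and the sharper chain used
#: by the undershoot variant.
FAR_CHAIN = DelayChainParams(tau_gj=15.0, n_steps=4, label="far")
NEAR_CHAIN = DelayChainParams(tau_gj=1.0, n_steps=4, k_act=2.0, label="near")
UNDERSHOOT_CHAIN = DelayChainParams(
    tau_gj=10.0, n_steps=7, gamma_gj=0.15, k_act=0.1, label="far"
)

#: The undershoot variant carries its own auxiliary constants: emitters
#: have higher endogenous adenylyl-cyclase activity than receivers (3x),
#: the regulated permeability gain is stronger, and the PDE-independent
#: clearance is larger so a basal steady state in the reporter's sensitive
#: range survives full PDE inhibition.
UNDERSHOOT_RECEIVER_BETA0 = 0.08
UNDERSHOOT_EMITTER_FACTOR = 3.0
UNDERSHOOT_K_GJ_GJF = 2.0
UNDERSHOOT_GAMMA_EX = 0.3


def run_model_variant(
    variant: str,
    graph: MonolayerGraph | None = None,
    protocol: LightProtocol | None = None,
    params: IntracellularParams = IntracellularParams(),
    pharm: PharmacologySpec = NO_DRUG,
    kappa_gj: float = 1.0,
    kappa_erk: float = 1.0,
    far_fraction: float = 1.0,
    equal_basal: bool = False,
    regulation_enabled: bool = True,
    tau_gj: float | None = None,
    n_steps: int | None = None,
    per_pulse_reset: bool | None = None,
    t_grid: np.ndarray | None = None,
) -> TraceSet:
    """Configure a named model variant and run :func:`simulate_tissue`.

    ``constant_permeability``: unregulated coupling, ``rho = kappa_gj * k_gj``.
    ``pka_pde_feedback``: constant permeability plus strong intracellular
    PKA feedback on PDE (produces overshoot intracellularly; receivers
    mirror the emitter).
    ``delayed_regulation``: cAMP/PKA-driven delayed activation chain
    (default tau_gj = 15 min, N = 4).
    ``near_far``: two inactive populations with short and long delays;
    ``far_fraction`` sets the slow population's share of the pool, and the
    chains are re-initialized at each pulse onset.
    ``undershoot``: sharper delay chain (tau_gj = 10, N = 7) with emitter
    basal cAMP production above the receivers'; ``equal_basal=True`` is the
    no-undershoot control.  Use ``params.ac_pka_inhibition_gain > 0`` for
    the variant with endogenous adenylyl-cyclase feedback.
    """
    if variant not in MODEL_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {MODEL_VARIANTS}"
        )
    if graph is None:
        graph = build_scenario("single_emitter_cluster", seed=0)
    if protocol is None:
        protocol = LightProtocol.two_pulse()
    params = replace(params, kappa_erk=kappa_erk)
    chain_kw = {}
    if tau_gj is not None:
        chain_kw["tau_gj"] = tau_gj
    if n_steps is not None:
        chain_kw["n_steps"] = n_steps
    if not regulation_enabled:
        chain_kw["k_act"] = 0.0

    kwargs: dict = dict(
        graph=graph, params=params, protocol=protocol, pharm=pharm,
        t_grid=t_grid, metadata={"variant": variant},
    )
    if variant == "constant_permeability":
        kwargs["coupling"] = CouplingParams(
            k_gj=CONSTANT_PERMEABILITY_K_GJ, k_gj_gjf=0.0, kappa_gj=kappa_gj
        )
        kwargs["chains"] = (replace(FAR_CHAIN, k_act=0.0),)
    elif variant == "pka_pde_feedback":
        kwargs["params"] = replace(params, pde_pka_feedback_gain=6.0)
        kwargs["coupling"] = CouplingParams(
            k_gj=CONSTANT_PERMEABILITY_K_GJ, k_gj_gjf=0.0, kappa_gj=kappa_gj
        )
        kwargs["chains"] = (replace(FAR_CHAIN, k_act=0.0),)
    elif variant == "delayed_regulation":
        kwargs["coupling"] = CouplingParams(kappa_gj=kappa_gj)
        kwargs["chains"] = (replace(FAR_CHAIN, **chain_kw),)
    elif variant == "near_far":
        if not 0.0 <= far_fraction <= 1.0:
            raise ValueError("far_fraction must lie in [0, 1]")
        kwargs["coupling"] = CouplingParams(kappa_gj=kappa_gj)
        kwargs["chains"] = (NEAR_CHAIN, FAR_CHAIN)
        kwargs["pool_fractions"] = (1.0 - far_fraction, far_fraction)
        if per_pulse_reset is None or per_pulse_reset:
            kwargs["pulse_reset_fractions"] = [
                (1.0 - far_fraction, far_fraction)
            ] * max(1, len(protocol.pulses))
    elif variant == "undershoot":
        kwargs["params"] = replace(params, gamma_ex=UNDERSHOOT_GAMMA_EX)
        kwargs["coupling"] = CouplingParams(
            k_gj_gjf=UNDERSHOOT_K_GJ_GJF, kappa_gj=kappa_gj
        )
        kwargs["chains"] = (replace(UNDERSHOOT_CHAIN, **chain_kw),)
        beta0 = np.full(graph.n_cells, UNDERSHOOT_RECEIVER_BETA0)
        if not equal_basal:
            beta0[graph.roles == EMITTER] *= UNDERSHOOT_EMITTER_FACTOR
        graph = MonolayerGraph(
            roles=graph.roles, bpac=graph.bpac, edges=graph.edges,
            positions=graph.positions, beta_0=beta0, name=graph.name,
            seed=graph.seed,
        )
        kwargs["graph"] = graph
    return simulate_tissue(**kwargs)
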
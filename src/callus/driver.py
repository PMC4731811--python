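"""Coupled tissue–vasculature simulation over the healing horizon.

A run couples the continuum tissue model and the discrete vascular model on
the quarter-callus domain for 49 days (default), starting from a
post-haematoma granulation state: a sparse MSC population and a thin fibrous
matrix fill the callus, oxygen sits at an intermediate level, and the
pre-existing vasculature consists of perfused root vessels along the cortex
surfaces.  Each coupling interval the perfusion analysis refreshes the
oxygen source field seen by the tissue model, and the angiogenic
growth-factor field produced by hypoxic tissue drives the vascular agents.

Scenarios fix the eight NF1 study factors: the normal-healing column, the
NF1 (congenital pseudarthrosis) column, or any vector inside the NF1 ranges
used by the design-of-experiments pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DomainGrid, build_domain
from .tissue import ModelParams, TissueState, _Transport, apply_dirichlet, step_tissue
from .vasculature import (
    ECParams,
    VascularNetwork,
    detect_anastomosis,
    grow_and_branch,
    move_tip,
    oxygen_source_field,
    select_tips,
    update_intracellular,
)

FACTOR_NAMES = ("c_f_BC", "A_f0", "F_4", "Y_11", "Y_3cb", "P_mc", "P_mf", "G_gvc")

# normal-healing values, NF1-case values, and the NF1 design ranges
_NORMAL = (3.0, 0.1, 0.01, 20.0, 1000.0, 0.2, 0.2, 1e3)
_NF1 = (20.0, 2.0, 0.2, 1.0, 50.0, 0.02, 2.0, 5e4)
_RANGES = ((0.0, 50.0), (0.1, 10.0), (0.01, 1.0), (0.0, 20.0),
           (0.0, 1000.0), (0.0, 0.2), (0.2, 10.0), (1e3, 1e5))


@dataclass
class Scenario:
    """A named vector of the eight NF1 study factors."""

    factors: dict
    label: str = "custom"

    def __post_init__(self):
        missing = set(FACTOR_NAMES) - set(self.factors)
        if missing:
            raise ValueError(f"scenario missing factors: {sorted(missing)}")
        for k, v in self.factors.items():
            if v < 0:
                raise ValueError(f"factor {k} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.factors[k] for k in FACTOR_NAMES])


def normal_scenario() -> Scenario:
    """Factor values of unimpaired healing."""
    return Scenario(dict(zip(FACTOR_NAMES, _NORMAL)), label="normal")


def nf1_scenario() -> Scenario:
    """Factor values of the NF1 / congenital-pseudarthrosis case."""
    return Scenario(dict(zip(FACTOR_NAMES, _NF1)), label="nf1")


def nf1_ranges() -> dict:
    """Per-factor [lo, hi] intervals spanned by the NF1 design space."""
    return {name: tuple(rng) for name, rng in zip(FACTOR_NAMES, _RANGES)}


@dataclass
class SimulationResult:
    """Snapshots at the requested days plus run provenance."""

    snapshots: dict            # day -> {"tissue": TissueState, "network": edge df}
    scenario: Scenario
    seed: int
    log: dict = field(default_factory=dict)

    @property
    def days(self):
        return sorted(self.snapshots)


DEFAULT_SIM = {
    "dt": 0.25,                 # tissue step [days]
    "coupling_interval": 0.25,  # perfusion/oxygen refresh interval [days]
    "init_c_m": 0.05,
    "init_m_f": 0.05,
    "init_n": 0.4,
    "supply_per_length": 10.0,  # oxygen supply rate per perfused vessel length
    "root_spacing_cells": 2.0,  # root agent spacing, in grid spacings
}


def _initial_network(domain: DomainGrid, ec_params: ECParams,
                     spacing_cells: float) -> VascularNetwork:
    """Pre-existing perfused vasculature: root vessels along the periosteal
    and endosteal cortex surfaces, up to the degrading bone ends."""
    net = VascularNetwork(ec_params)
    cfg = domain.config
    z_end = domain.cortical_end_z
    spacing = spacing_cells * min(domain.h_z, domain.h_r)
    r_lines = (cfg["marrow_radius"] - 0.5 * domain.h_r,
               cfg["marrow_radius"] + cfg["cortex_thickness"] + 0.5 * domain.h_r)
    for r_line in r_lines:
        n_pts = max(2, int(np.floor(z_end / spacing)) + 1)
        zs = np.linspace(0.0, z_end, n_pts)
        prev = None
        for z in zs:
            ag = net.new_agent((z, r_line), "stalk")
            net.roots.add(ag.id)
            if prev is not None:
                net.add_edge(prev, ag.id)
            prev = ag.id
    return net


def _initial_state(domain: DomainGrid, params: ModelParams, sim_cfg: dict) -> TissueState:
    state = TissueState.zeros(domain)
    callus = domain.callus_mask
    state.c_m[callus] = sim_cfg["init_c_m"]
    state.m_f[callus] = sim_cfg["init_m_f"]
    state.n[callus] = sim_cfg["init_n"]
    return state


def _vascular_step(net: VascularNetwork, state: TissueState, domain: DomainGrid,
                   rng: np.random.Generator, dt: float) -> None:
    p = net.params
    spacing = min(domain.h_z, domain.h_r)
    # intracellular update from local angiogenic growth factor + neighbour Dll4
    from .vasculature import _bilinear
    new_ic = {}
    for aid in sorted(net.agents):
        ag = net.agents[aid]
        g_local = max(_bilinear(state.g_v, ag.position, domain.h_z, domain.h_r), 0.0)
        nbrs = net.neighbors(aid)
        nb_dll4 = max((net.agents[n].intracellular[3] for n in nbrs), default=0.0)
        new_ic[aid] = update_intracellular(ag, g_local, nb_dll4, dt, p).intracellular
    for aid, ic in new_ic.items():
        net.agents[aid].intracellular = ic

    select_tips(net, spacing)
    # mid-vessel and root winners sprout a daughter tip (the parent vessel
    # stays in place); free chain-end winners migrate themselves
    for tip in sorted(net.tips(), key=lambda a: a.id):
        if tip.id in net.roots or len(net.neighbors(tip.id)) >= 2:
            daughter = net.new_agent(tip.position + 1e-3 * spacing * rng.normal(size=2),
                                     "tip", tip.intracellular)
            net.add_edge(tip.id, daughter.id)
            tip.phenotype = "stalk"

    total_m = state.total_matrix()
    for tip in sorted(net.tips(), key=lambda a: a.id):
        tip.position = move_tip(tip, state.g_v, total_m, domain, rng, dt, p)
    grow_and_branch(net, spacing)
    detect_anastomosis(net, domain, spacing)


def run_simulation(scenario: Scenario, domain: DomainGrid | None = None,
                   params: ModelParams | None = None, seed: int = 0,
                   horizon: float = 49.0,
                   snapshot_days=(7, 21, 35, 49),
                   sim_config: dict | None = None,
                   ec_params: ECParams | None = None) -> SimulationResult:
    """Run the coupled model and return snapshots at the requested days.

    Identical ``(scenario, domain, params, seed)`` give bit-identical
    results.  ``horizon`` 0 returns only the initial condition (day 0).
    """
    if domain is None:
        domain = build_domain()
    base = params or ModelParams()
    p = base.with_factors(scenario.factors)
    cfg = dict(DEFAULT_SIM)
    if sim_config:
        cfg.update(sim_config)
    dt = cfg["dt"]
    rng = np.random.default_rng(seed)

    state = _initial_state(domain, p, cfg)
    net = _initial_network(domain, ec_params or ECParams(), cfg["root_spacing_cells"])
    transport = _Transport(domain)
    log = {"dt": dt, "seed": seed, "clipped_mass": 0.0, "scenario": scenario.label}

    snapshot_days = sorted(d for d in snapshot_days if d <= horizon)
    snapshots = {}

    def take(day):
        snapshots[day] = {"tissue": state.copy(), "network": net.edge_table()}

    state = apply_dirichlet(state, 0.0, domain, p)
    if horizon <= 0:
        take(0)
        return SimulationResult(snapshots, scenario, seed, log)
    if 0 in snapshot_days:
        take(0)

    n_steps = int(round(horizon / dt))
    oxy = oxygen_source_field(net, domain, cfg["supply_per_length"])
    next_coupling = cfg["coupling_interval"]
    next_snap_idx = 0
    while next_snap_idx < len(snapshot_days) and snapshot_days[next_snap_idx] <= 0:
        next_snap_idx += 1

    for k in range(1, n_steps + 1):
        t = k * dt
        state = step_tissue(state, domain, p, oxy, dt, transport, log)
        state = apply_dirichlet(state, t, domain, p)
        _vascular_step(net, state, domain, rng, dt)
        if t + 1e-9 >= next_coupling:
            oxy = oxygen_source_field(net, domain, cfg["supply_per_length"])
            next_coupling += cfg["coupling_interval"]
        while (next_snap_idx < len(snapshot_days)
               and t + 1e-9 >= snapshot_days[next_snap_idx]):
            take(snapshot_days[next_snap_idx])
            next_snap_idx += 1
    return SimulationResult(snapshots, scenario, seed, log)


def save_result(result: SimulationResult, path) -> None:
    """Write snapshots to an HDF5 container (one group per day)."""
    import h5py

    from .tissue import FIELD_NAMES
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = result.seed
        f.attrs["scenario"] = result.scenario.label
        for i, name in enumerate(FACTOR_NAMES):
            f.attrs[f"factor_{name}"] = result.scenario.factors[name]
        for day, snap in result.snapshots.items():
            g = f.create_group(f"day_{day}")
            for name in FIELD_NAMES:
                g.create_dataset(name, data=getattr(snap["tissue"], name))
            net = snap["network"]
            g.create_dataset("network_edges", data=net.to_records(index=False))
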
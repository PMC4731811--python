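"""Agent-based sprouting angiogenesis with tip/stalk lateral inhibition.

Each endothelial cell (EC) is an agent carrying exactly eight intracellular
variables in the lineage of the Bentley tip-selection model: sensed VEGF,
total VEGFR-2, active VEGFR-2, Dll4, total Notch, active Notch, actin
(filopodia) activity, and a tip-persistence timer.  VEGF sensing activates
VEGFR-2, which drives Dll4 expression; a neighbour's Dll4 activates Notch,
which in turn suppresses VEGFR-2 activation — the Dll4–Notch lateral
inhibition that patterns alternating tip/stalk phenotypes.

Tips migrate by chemotaxis up the angiogenic growth-factor gradient and
haptotaxis along the extracellular matrix, at a speed that saturates in
active VEGFR-2; stalk cells are laid down behind an advancing tip; a tip
that touches a foreign vessel segment or leaves the domain anastomoses and
loses its tip phenotype.  Only segments lying on a perfused loop — a cycle
through the root attachments or boundary anastomoses — deliver oxygen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .geometry import DomainGrid

IC_NAMES = ("vegf_sensed", "vegfr2_total", "vegfr2_active", "dll4",
            "notch_total", "notch_active", "actin", "tip_timer")
N_INTRACELLULAR = 8


@dataclass
class ECParams:
    """Endothelial-agent rate constants (first-order relaxation kinetics)."""

    k_sense: float = 5.0      # VEGF sensing relaxation [1/day]
    r2_total: float = 1.0     # homeostatic total VEGFR-2
    k_recept: float = 2.0     # receptor pool relaxation [1/day]
    k_act: float = 10.0       # VEGFR-2 activation [1/day]
    beta_notch: float = 10.0  # Notch suppression of VEGFR-2 activation (Hill-2)
    d_act: float = 2.0        # active VEGFR-2 decay [1/day]
    k_dll4: float = 4.0       # Dll4 expression from active VEGFR-2 [1/day]
    d_dll4: float = 2.0
    notch_total0: float = 1.0
    k_notch: float = 2.0
    k_nact: float = 8.0       # Notch activation by neighbour Dll4 [1/day]
    d_nact: float = 2.0
    k_actin: float = 4.0
    d_actin: float = 2.0
    ceiling: float = 10.0     # hard ceiling on every intracellular variable

    tip_threshold: float = 0.15  # active VEGFR-2 needed to become a tip
    min_tip_spacing: float = 2.0  # in grid spacings
    s_max: float = 0.5        # max tip speed [length/day]
    K_v: float = 0.5          # speed half-saturation in active VEGFR-2
    w_chemo: float = 1.0
    w_hapto: float = 0.3
    w_persist: float = 0.3
    noise: float = 0.1
    m_pref: float = 0.4       # preferred (intermediate) total matrix density
    ec_spacing: float = 1.0   # stalk spacing, in grid spacings
    capture_radius: float = 1.0  # anastomosis radius, in grid spacings
    max_substep: float = 0.02  # intracellular ODE sub-step cap (rate*dt)


@dataclass
class ECAgent:
    """One endothelial cell: position, phenotype, 8 intracellular scalars."""

    id: int
    position: np.ndarray            # (z, r) continuous coordinates
    phenotype: str = "stalk"        # "tip" | "stalk"
    intracellular: np.ndarray = field(
        default_factory=lambda: np.zeros(N_INTRACELLULAR))
    direction: np.ndarray = field(default_factory=lambda: np.zeros(2))
    boundary: bool = False          # anastomosed onto the domain boundary

    def __post_init__(self):
        self.position = np.asarray(self.position, float)
        self.intracellular = np.asarray(self.intracellular, float)
        if self.intracellular.shape != (N_INTRACELLULAR,):
            raise ValueError("intracellular state must have exactly 8 entries")


class VascularNetwork:
    """EC agents + vessel segments, with root attachments and perfusion flags."""

    def __init__(self, params: ECParams | None = None):
        self.params = params or ECParams()
        self.agents: dict[int, ECAgent] = {}
        self.edges: set[tuple[int, int]] = set()
        self.roots: set[int] = set()
        self._next_id = 0

    def new_agent(self, position, phenotype="stalk", intracellular=None) -> ECAgent:
        ag = ECAgent(
            id=self._next_id, position=np.asarray(position, float),
            phenotype=phenotype,
            intracellular=(np.zeros(N_INTRACELLULAR) if intracellular is None
                           else np.asarray(intracellular, float).copy()),
        )
        ag.intracellular[1] = max(ag.intracellular[1], self.params.r2_total)
        ag.intracellular[4] = max(ag.intracellular[4], self.params.notch_total0)
        self.agents[ag.id] = ag
        self._next_id += 1
        return ag

    def add_edge(self, a: int, b: int) -> None:
        if a == b:
            raise ValueError("self-edge")
        self.edges.add((min(a, b), max(a, b)))

    def has_edge(self, a: int, b: int) -> bool:
        return (min(a, b), max(a, b)) in self.edges

    def neighbors(self, aid: int) -> list[int]:
        out = []
        for (a, b) in self.edges:
            if a == aid:
                out.append(b)
            elif b == aid:
                out.append(a)
        return out

    def segment_length(self, edge) -> float:
        a, b = edge
        return float(np.linalg.norm(self.agents[a].position - self.agents[b].position))

    def tips(self) -> list[ECAgent]:
        return [a for a in self.agents.values() if a.phenotype == "tip"]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.agents)
        g.add_edges_from(self.edges)
        return g

    def edge_table(self):
        """Segments as a plain table (node ids, coordinates, perfusion)."""
        import pandas as pd
        perf = perfused_loops(self)
        rows = []
        for (a, b) in sorted(self.edges):
            pa, pb = self.agents[a].position, self.agents[b].position
            rows.append({"node_a": a, "node_b": b,
                         "za": pa[0], "ra": pa[1], "zb": pb[0], "rb": pb[1],
                         "perfused": bool(perf[(a, b)])})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# intracellular dynamics and tip selection
# ---------------------------------------------------------------------------


def update_intracellular(agent: ECAgent, local_g_v: float, neighbor_Dll4: float,
                         dt: float, params: ECParams | None = None) -> ECAgent:
    """Advance the 8-variable intracellular state by ``dt``.

    Relaxation ODEs implementing the Dll4–Notch lateral-inhibition loop:
    sensed VEGF tracks the local angiogenic growth factor; active VEGFR-2
    grows with sensed VEGF and free receptor, suppressed by active Notch;
    Dll4 follows active VEGFR-2; active Notch follows the *neighbour's* Dll4;
    actin follows active VEGFR-2.  All variables stay in [0, ceiling].
    """
    if local_g_v < 0 or neighbor_Dll4 < 0 or dt < 0:
        raise ValueError("inputs must be non-negative")
    p = params or ECParams()
    v = agent.intracellular.copy()
    stiff = max(p.k_sense, p.k_recept, p.k_act * max(local_g_v, 1.0), p.d_act,
                p.k_dll4, p.d_dll4, p.k_notch, p.k_nact * max(neighbor_Dll4, 1.0),
                p.d_nact, p.k_actin, p.d_actin)
    n_sub = max(1, int(np.ceil(stiff * dt / p.max_substep))) if dt > 0 else 1
    dts = dt / n_sub
    for _ in range(n_sub):
        sensed, r_tot, r_act, dll4, n_tot, n_act, actin, timer = v
        # Hill-2 suppression and cooperative Dll4 expression make the
        # symmetric two-cell state unstable, so lateral inhibition resolves
        # near-equal neighbours into a tip/stalk (winner/loser) pair
        suppression = 1.0 / (1.0 + (p.beta_notch * n_act) ** 2)
        dv = np.array([
            p.k_sense * (local_g_v - sensed),
            p.k_recept * (p.r2_total - r_tot),
            p.k_act * sensed * max(r_tot - r_act, 0.0) * suppression - p.d_act * r_act,
            p.k_dll4 * r_act ** 2 - p.d_dll4 * dll4,
            p.k_notch * (p.notch_total0 - n_tot),
            p.k_nact * neighbor_Dll4 * max(n_tot - n_act, 0.0) - p.d_nact * n_act,
            p.k_actin * r_act - p.d_actin * actin,
            0.0,
        ])
        v = np.clip(v + dts * dv, 0.0, p.ceiling)
    # tip-persistence timer: accumulates while tip, decays otherwise
    if agent.phenotype == "tip":
        v[7] = min(v[7] + dt, p.ceiling)
    else:
        v[7] = max(v[7] - dt, 0.0)
    return replace(agent, intracellular=v)


def tip_rule(network: VascularNetwork, aid: int, params: ECParams) -> bool:
    """The local tip-selection predicate: active VEGFR-2 above threshold and
    strictly above every segment-neighbour's (lateral-inhibition winner)."""
    ag = network.agents[aid]
    r_act = ag.intracellular[2]
    if r_act <= params.tip_threshold:
        return False
    for nid in network.neighbors(aid):
        if network.agents[nid].intracellular[2] >= r_act:
            return False
    return True


def select_tips(network: VascularNetwork, spacing: float) -> VascularNetwork:
    """Assign tip phenotypes by the lateral-inhibition winner rule.

    Candidate tips closer than ``min_tip_spacing`` (in units of the grid
    spacing ``spacing``) are thinned, keeping the higher active VEGFR-2; ties
    break on the lower agent id.  Boundary-anastomosed agents never become
    tips; a winning root agent sprouts a daughter tip instead of migrating
    (handled by the simulation driver).
    """
    p = network.params
    candidates = [aid for aid in sorted(network.agents)
                  if not network.agents[aid].boundary
                  and tip_rule(network, aid, p)]
    # spacing resolution: greedy by descending activity, id ascending
    candidates.sort(key=lambda aid: (-network.agents[aid].intracellular[2], aid))
    chosen: list[int] = []
    min_d = p.min_tip_spacing * spacing
    for aid in candidates:
        pos = network.agents[aid].position
        if all(np.linalg.norm(pos - network.agents[c].position) >= min_d
               for c in chosen):
            chosen.append(aid)
    chosen_set = set(chosen)
    for aid, ag in network.agents.items():
        ag.phenotype = "tip" if aid in chosen_set else "stalk"
    return network


# ---------------------------------------------------------------------------
# migration, growth, anastomosis
# ---------------------------------------------------------------------------


def _bilinear(field2d: np.ndarray, pos: np.ndarray, h_z: float, h_r: float) -> float:
    nz, nr = field2d.shape
    fz = np.clip(pos[0] / h_z - 0.5, 0, nz - 1)
    fr = np.clip(pos[1] / h_r - 0.5, 0, nr - 1)
    iz, ir = int(fz), int(fr)
    iz1, ir1 = min(iz + 1, nz - 1), min(ir + 1, nr - 1)
    tz, tr = fz - iz, fr - ir
    return float((1 - tz) * (1 - tr) * field2d[iz, ir]
                 + tz * (1 - tr) * field2d[iz1, ir]
                 + (1 - tz) * tr * field2d[iz, ir1]
                 + tz * tr * field2d[iz1, ir1])


def _grad(field2d: np.ndarray, pos, h_z, h_r) -> np.ndarray:
    gz = (_bilinear(field2d, pos + np.array([h_z, 0.0]), h_z, h_r)
          - _bilinear(field2d, pos - np.array([h_z, 0.0]), h_z, h_r)) / (2 * h_z)
    gr = (_bilinear(field2d, pos + np.array([0.0, h_r]), h_z, h_r)
          - _bilinear(field2d, pos - np.array([0.0, h_r]), h_z, h_r)) / (2 * h_r)
    return np.array([gz, gr])


def tip_speed(active_vegfr2: float, params: ECParams) -> float:
    """Saturating (Michaelis) speed law s_max * R / (K_v + R)."""
    return params.s_max * active_vegfr2 / (params.K_v + active_vegfr2)


def move_tip(agent: ECAgent, g_v: np.ndarray, total_matrix: np.ndarray,
             domain: DomainGrid, rng: np.random.Generator, dt: float,
             params: ECParams | None = None) -> np.ndarray:
    """New position of a tip agent after one migration step.

    Direction blends chemotaxis (up the angiogenic growth-factor gradient),
    haptotaxis (up the matrix gradient where the local matrix density is
    below the preferred intermediate level, down it above), persistence, and
    a small seeded isotropic noise; speed saturates in active VEGFR-2 and the
    step length is capped at one grid spacing.
    """
    p = params or ECParams()
    if agent.phenotype != "tip":
        raise ValueError("move_tip requires a tip agent")
    speed = tip_speed(agent.intracellular[2], p)
    if speed == 0.0:
        return agent.position.copy()
    h_z, h_r = domain.h_z, domain.h_r
    chemo = _grad(g_v, agent.position, h_z, h_r)
    m_local = _bilinear(total_matrix, agent.position, h_z, h_r)
    hapto = _grad(total_matrix, agent.position, h_z, h_r)
    hapto = hapto * np.sign(p.m_pref - m_local)  # prefer intermediate density
    noise = rng.normal(size=2) * p.noise if p.noise > 0 else np.zeros(2)
    direction = (p.w_chemo * chemo + p.w_hapto * hapto
                 + p.w_persist * agent.direction + noise)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        return agent.position.copy()
    direction = direction / norm
    step = min(speed * dt, min(h_z, h_r))
    agent.direction = direction
    return agent.position + step * direction


def grow_and_branch(network: VascularNetwork, spacing: float) -> VascularNetwork:
    """Insert stalk agents behind tips that advanced more than the EC spacing.

    The new stalk sits one spacing behind the tip along the tip's last
    direction, inherits an interpolated intracellular state, and takes over
    the tip's previous segment attachment, so segment lengths stay near one
    EC spacing.
    """
    p = network.params
    ds = p.ec_spacing * spacing
    for tip in list(network.tips()):
        nbrs = network.neighbors(tip.id)
        if not nbrs:
            continue
        anchor = min(nbrs, key=lambda nid: (
            np.linalg.norm(network.agents[nid].position - tip.position), nid))
        dist = np.linalg.norm(network.agents[anchor].position - tip.position)
        while dist > ds * (1 + 1e-9):
            vec = tip.position - network.agents[anchor].position
            vec = vec / np.linalg.norm(vec)
            new_pos = network.agents[anchor].position + ds * vec
            ic = 0.5 * (network.agents[anchor].intracellular + tip.intracellular)
            ic[7] = 0.0
            stalk = network.new_agent(new_pos, "stalk", ic)
            network.edges.discard((min(anchor, tip.id), max(anchor, tip.id)))
            network.add_edge(anchor, stalk.id)
            network.add_edge(stalk.id, tip.id)
            anchor = stalk.id
            dist = np.linalg.norm(network.agents[anchor].position - tip.position)
    return network


def _point_segment_distance(pt, a, b) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-24:
        return float(np.linalg.norm(pt - a))
    t = np.clip(float((pt - a) @ ab) / denom, 0.0, 1.0)
    return float(np.linalg.norm(pt - (a + t * ab)))


def detect_anastomosis(network: VascularNetwork, domain: DomainGrid,
                       spacing: float) -> VascularNetwork:
    """Fuse tips that touch foreign vessel or leave the domain.

    A tip within the capture radius of a segment not incident to itself fuses
    onto that segment's nearest endpoint; a tip outside the domain rectangle
    becomes a boundary anastomosis.  Either way the agent loses its tip
    phenotype.  Tips are processed in id order; a pair of tips meeting
    head-on therefore produces exactly one fusion.
    """
    p = network.params
    radius = p.capture_radius * spacing
    for tip in sorted(network.tips(), key=lambda a: a.id):
        if tip.phenotype != "tip":
            continue  # may have been fused by an earlier tip this pass
        z, r = tip.position
        if not (0.0 <= z <= domain.length and 0.0 <= r <= domain.radius):
            tip.phenotype = "stalk"
            tip.boundary = True
            tip.position = np.clip(tip.position, [0.0, 0.0],
                                   [domain.length, domain.radius])
            continue
        own = set(network.neighbors(tip.id)) | {tip.id}
        best = None
        for (a, b) in sorted(network.edges):
            if a in own or b in own:
                continue
            d = _point_segment_distance(tip.position,
                                        network.agents[a].position,
                                        network.agents[b].position)
            if d <= radius and (best is None or d < best[0]):
                best = (d, (a, b))
        if best is not None:
            a, b = best[1]
            target = min((a, b), key=lambda nid: np.linalg.norm(
                network.agents[nid].position - tip.position))
            if not network.has_edge(tip.id, target):
                network.add_edge(tip.id, target)
            tip.phenotype = "stalk"
    return network


# ---------------------------------------------------------------------------
# perfusion and oxygen sourcing
# ---------------------------------------------------------------------------

SUPER = -1  # virtual super-node tying roots and boundary anastomoses together


def perfused_loops(network: VascularNetwork) -> dict:
    """Per-segment perfusion flags.

    A segment carries flow iff it lies on a cycle of the augmented graph in
    which a virtual super-node connects every root and every boundary
    anastomosis — i.e. iff it is not a bridge of that graph and is connected
    to the supply.  Dead-end sprouts are never perfused.
    """
    g = network.graph()
    entry = sorted(network.roots | {a.id for a in network.agents.values() if a.boundary})
    for node in entry:
        g.add_edge(SUPER, node)
    flags = {e: False for e in network.edges}
    if not entry:
        return flags
    bridges = set()
    for (a, b) in nx.bridges(g):
        bridges.add((min(a, b), max(a, b)))
    comp = nx.node_connected_component(g, SUPER)
    for e in network.edges:
        a, b = e
        if a in comp and e not in bridges:
            flags[e] = True
    return flags


def oxygen_source_field(network: VascularNetwork, domain: DomainGrid,
                        supply_per_length: float = 1.0,
                        n_samples_per_cell: int = 4) -> np.ndarray:
    """Rasterize the perfused segments into a per-cell oxygen supply field.

    Each perfused segment deposits ``supply_per_length * length`` distributed
    over the grid cells it crosses (midpoint sampling); the total deposited
    rate equals the perfused length times the rate per length up to
    discretization.
    """
    flags = perfused_loops(network)
    out = np.zeros((domain.n_z, domain.n_r))
    for e, perf in flags.items():
        if not perf:
            continue
        a, b = e
        pa, pb = network.agents[a].position, network.agents[b].position
        length = float(np.linalg.norm(pb - pa))
        if length == 0.0:
            continue
        n_s = max(1, int(np.ceil(length / min(domain.h_z, domain.h_r)
                                 * n_samples_per_cell)))
        ts = (np.arange(n_s) + 0.5) / n_s
        w = supply_per_length * length / n_s
        for t in ts:
            p = pa + t * (pb - pa)
            iz = min(int(p[0] / domain.h_z), domain.n_z - 1)
            ir = min(int(p[1] / domain.h_r), domain.n_r - 1)
            out[iz, ir] += w
    return out
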
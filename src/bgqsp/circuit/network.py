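"""Fixed-topology multi-nucleus network builder.

The closed loop: cortical pyramidal cells drive both striatal MSN populations
and (hyperdirectly) the STN; D1+ MSNs inhibit GPi (direct pathway), D2+ MSNs
inhibit GPe (indirect pathway); GPe and STN are reciprocally coupled and both
project to GPi; GPi inhibits thalamocortical relay cells, which excite
reticular cells (reciprocal inhibition) and the cortex; basket cells close
the cortical E-I loop.  STN, GPe and GPi each contain 16 cells divided into
two groups of eight wired within-group; cross-group mixing happens only via
the striatal afferents.

In-degrees follow the printed wiring rules: each GPe cell receives inhibition
from three other GPe cells and excitation from three randomly chosen STN
cells; each STN cell receives inhibition from three GPe cells; each GPi cell
receives input from one GPe and one STN neuron; every TC cell is inhibited by
the eight GPi cells of its group; 60% of the basket cells synapse on
pyramidal cells and the remaining eight form the interneuron microcircuit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import circuit_params

__all__ = [
    "POPULATION_ORDER",
    "SynapseSpec",
    "Projection",
    "NetworkGraph",
    "build_network",
    "syn_conductance",
]

POPULATION_ORDER = (
    "MSN_D1", "MSN_D2", "GPe", "GPi", "STN", "TC", "Re", "Pyr", "BC",
)

GROUP_SIZE = 8          # STN/GPe/GPi sub-group size
TC_PER_GROUP = 2        # TC cells per pallidal output group


@dataclass(frozen=True)
class SynapseSpec:
    """Double-exponential synaptic conductance parameters."""

    kind: str               # AMPA | NMDA | GABA | mGluR
    gmax: float             # peak conductance <g>, mS/cm^2
    t_rise: float           # ms
    t_decay: float          # ms
    reversal: float         # mV (0 for excitatory)
    mg_block: bool = False  # voltage-dependent Mg block (NMDA)

    def __post_init__(self):
        if not 0.0 < self.t_rise < self.t_decay:
            raise ValueError(
                f"synapse requires 0 < t_rise < t_decay, got "
                f"({self.t_rise}, {self.t_decay})"
            )
        if self.gmax < 0:
            raise ValueError("gmax must be >= 0")

    @property
    def t_peak(self) -> float:
        """Time of peak conductance after a presynaptic spike."""
        tr, td = self.t_rise, self.t_decay
        return tr * td / (td - tr) * math.log(td / tr)

    @property
    def norm(self) -> float:
        """Normalization so the peak of the double exponential equals gmax."""
        tp = self.t_peak
        return 1.0 / (math.exp(-tp / self.t_decay) - math.exp(-tp / self.t_rise))


def syn_conductance(t_since_spike, spec: SynapseSpec, V: float = 0.0,
                    mg_mM: float = 1.0) -> np.ndarray | float:
    """Conductance ``t_since_spike`` ms after a presynaptic spike.

    The difference-of-exponentials g(t) = <g> N (exp(-t/t_decay) -
    exp(-t/t_rise)) with N normalizing the peak to <g>; NMDA conductances are
    additionally multiplied by the sigmoidal Mg-block factor evaluated at the
    postsynaptic voltage ``V``.
    """
    t = np.asarray(t_since_spike, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_spike must be >= 0")
    g = spec.gmax * spec.norm * (np.exp(-t / spec.t_decay) - np.exp(-t / spec.t_rise))
    if spec.mg_block:
        g = g / (1.0 + mg_mM / 3.57 * np.exp(-0.062 * V))
    return float(g) if np.isscalar(t_since_spike) else g


@dataclass
class Projection:
    """One afferent projection: parallel edge arrays plus synapse kinetics."""

    name: str
    pre_pop: str
    post_pop: str
    pre: np.ndarray          # global presynaptic indices (-1 = external)
    post: np.ndarray         # global postsynaptic indices
    delay_ms: np.ndarray
    spec: SynapseSpec
    comp: str = "soma"       # soma | dend
    target: str = ""         # coupling-table target name ("" = unmodulated)

    def __len__(self) -> int:
        return len(self.pre)


@dataclass
class NetworkGraph:
    """The wired circuit: population slices plus per-projection edge lists."""

    populations: dict            # name -> (start, count)
    family: dict                 # name -> cell family
    projections: dict            # name -> Projection
    bc_projecting: np.ndarray    # global indices of the 60% Pyr-projecting BCs
    seed: int
    params: dict = field(repr=False, default_factory=dict)

    @property
    def n_cells(self) -> int:
        return sum(c for _, c in self.populations.values())

    def slice(self, pop: str) -> slice:
        start, count = self.populations[pop]
        return slice(start, start + count)

    def population_of(self, idx: int) -> str:
        for name, (start, count) in self.populations.items():
            if start <= idx < start + count:
                return name
        raise IndexError(idx)

    def in_degree(self, proj_name: str, post_idx: int) -> int:
        proj = self.projections[proj_name]
        return int(np.sum(proj.post == post_idx))

    def edge_list(self) -> np.ndarray:
        """All (pre, post) edges over all projections, in a canonical order —
        byte-identical across builds with the same seed."""
        rows = []
        for name in sorted(self.projections):
            p = self.projections[name]
            rows.append(np.column_stack([p.pre, p.post]))
        return np.concatenate(rows, axis=0)


def _group_of(local_idx: int, group_size: int) -> int:
    return local_idx // group_size


def _choose(rng, pool, k, exclude=None):
    pool = [p for p in pool if p != exclude]
    if k > len(pool):
        raise ValueError("in-degree exceeds available presynaptic pool")
    return rng.choice(np.array(pool, dtype=np.int64), size=k, replace=False)


def build_network(seed: int) -> NetworkGraph:
    """Wire the circuit deterministically for a seed.

    Random choices (which STN cells excite a GPe cell, which Pyr cells drive
    an MSN, axonal delays) are drawn from a generator seeded with ``seed``;
    the in-degree rules themselves are fixed.
    """
    params = circuit_params()
    rng = np.random.default_rng(seed)

    populations = {}
    family = {}
    start = 0
    for name in POPULATION_ORDER:
        count = params["populations"][name]["count"]
        populations[name] = (start, count)
        family[name] = params["populations"][name]["family"]
        start += count

    def gidx(pop, local):
        return populations[pop][0] + int(local)

    def pop_range(pop):
        s, c = populations[pop]
        return list(range(s, s + c))

    # 60% of basket cells project to pyramidal cells; the remaining eight
    # form the inhibitory microcircuit.
    n_bc = populations["BC"][1]
    n_proj = int(round(params["bc_projecting_fraction"] * n_bc))
    perm = rng.permutation(n_bc)
    bc_projecting = np.sort(np.array([gidx("BC", i) for i in perm[:n_proj]]))
    bc_micro = np.sort(np.array([gidx("BC", i) for i in perm[n_proj:]]))

    d_lo, d_hi = params["integration"]["delay_range_ms"]
    shared_pre: dict = {}
    projections: dict = {}

    for name, cfg in params["projections"].items():
        pre_pop, post_pop = cfg["pre"], cfg["post"]
        k = cfg["in_degree"]
        post_start, post_count = populations[post_pop]

        if "share_pre" in cfg:
            base = projections[cfg["share_pre"]]
            pre = base.pre.copy()
            post = base.post.copy()
            delays = base.delay_ms.copy()
        elif pre_pop == "EXT":
            post = np.array(pop_range(post_pop), dtype=np.int64)
            pre = np.full(len(post), -1, dtype=np.int64)
            delays = np.zeros(len(post))
        else:
            pres, posts = [], []
            for local in range(post_count):
                post_idx = gidx(post_pop, local)
                if cfg.get("group_fanin"):
                    # every TC cell listens to all GPi cells of its group
                    g = local // TC_PER_GROUP
                    pool = [gidx(pre_pop, j) for j in range(populations[pre_pop][1])
                            if _group_of(j, GROUP_SIZE) == g]
                    chosen = np.array(pool, dtype=np.int64)
                    if k != len(pool):
                        raise ValueError(
                            f"{name}: group fan-in expects in_degree "
                            f"{len(pool)}, got {k}"
                        )
                else:
                    if cfg.get("within_group") and pre_pop in ("STN", "GPe", "GPi"):
                        g = _group_of(local, GROUP_SIZE)
                        pool = [gidx(pre_pop, j)
                                for j in range(populations[pre_pop][1])
                                if _group_of(j, GROUP_SIZE) == g]
                    elif cfg.get("pre_subset") == "projecting":
                        pool = list(bc_projecting)
                    elif cfg.get("pre_subset") == "microcircuit":
                        pool = list(bc_micro)
                    else:
                        pool = pop_range(pre_pop)
                    chosen = _choose(rng, pool, k,
                                     exclude=post_idx if pre_pop == post_pop else None)
                pres.append(chosen)
                posts.append(np.full(len(chosen), post_idx, dtype=np.int64))
            pre = np.concatenate(pres)
            post = np.concatenate(posts)
            lo, hi = cfg.get("delay_range_ms", (d_lo, d_hi))
            delays = rng.uniform(lo, hi, size=len(pre))

        spec = SynapseSpec(
            kind=cfg["kind"],
            gmax=cfg["gmax"],
            t_rise=cfg["t_rise"],
            t_decay=cfg["t_decay"],
            reversal=cfg["E"],
            mg_block=(cfg["kind"] == "NMDA"),
        )
        projections[name] = Projection(
            name=name, pre_pop=pre_pop, post_pop=post_pop,
            pre=pre, post=post, delay_ms=delays, spec=spec,
            comp=cfg.get("comp", "soma"), target=cfg.get("target", ""),
        )

    return NetworkGraph(
        populations=populations, family=family, projections=projections,
        bc_projecting=bc_projecting, seed=seed, params=params,
    )
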
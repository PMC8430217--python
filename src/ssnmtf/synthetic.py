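"""LFR-style benchmark networks with planted (possibly overlapping) modules.

The generator emulates the standard LFR benchmark family: node degrees
follow a truncated power law with a prescribed mean and maximum, module
sizes follow a truncated power law within given bounds, and each node
spends a fraction ``1 - mu`` of its edges inside its own module(s) and
``mu`` outside.  ``on`` nodes belong to ``om`` modules each (their
internal degree is split evenly among memberships); everyone else belongs
to exactly one.  Edges are realized by configuration-model stub matching
within modules and globally for the external stubs, followed by rewiring
sweeps that eliminate self-loops, multi-edges and (for external stubs)
within-module pairs; residual irreparable stubs are dropped with a logged
count.  The output is a simple undirected network plus the planted cover,
fully deterministic under a fixed seed.

This is a faithful re-implementation of the benchmark's *design*, not a
bit-compatible port of the original C++ generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .constraints import MustLinkConstraints, sample_mustlinks
from .io import ComplexCover, Network

logger = logging.getLogger(__name__)

__all__ = [
    "LFRConfig",
    "generate_lfr",
    "planted_partition",
    "mustlinks_from_truth",
    "PRESETS",
]


class GenerationError(RuntimeError):
    """Raised when a parameter set cannot be realized."""


@dataclass(frozen=True)
class LFRConfig:
    """Benchmark parameters.

    N: node count; ad: target average degree; d_max: maximum degree;
    m_min/m_max: module-size bounds; mu: mixing parameter (fraction of
    each node's edges leaving its modules); on: number of overlapping
    nodes; om: module memberships per overlapping node;
    degree_exponent/size_exponent: power-law exponents (standard LFR
    defaults 2 and 1); seed: RNG seed.
    """

    N: int = 1000
    ad: float = 15.0
    d_max: int = 50
    m_min: int = 20
    m_max: int = 50
    mu: float = 0.6
    on: int = 0
    om: int = 1
    degree_exponent: float = 2.0
    size_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.m_min <= self.m_max <= self.N):
            raise ValueError("need 1 <= m_min <= m_max <= N")
        if not 0 <= self.mu <= 1:
            raise ValueError("mu must lie in [0, 1]")
        if self.on > self.N:
            raise ValueError("on cannot exceed N")
        if self.om < 1:
            raise ValueError("om must be >= 1")
        if self.on > 0 and self.om < 2:
            raise ValueError("overlapping nodes need om >= 2")
        if self.ad > self.d_max:
            raise ValueError("average degree cannot exceed d_max")


# -- degree and size sampling ------------------------------------------------


def _truncated_powerlaw_mean(x_min: float, x_max: float, gamma: float) -> float:
    """Mean of a continuous power law p(x) ~ x^-gamma on [x_min, x_max]."""
    if gamma == 1.0:
        z = np.log(x_max / x_min)
        return (x_max - x_min) / z
    if gamma == 2.0:
        z = 1.0 / x_min - 1.0 / x_max
        return np.log(x_max / x_min) / z
    z = (x_min ** (1 - gamma) - x_max ** (1 - gamma)) / (gamma - 1)
    m = (x_min ** (2 - gamma) - x_max ** (2 - gamma)) / (gamma - 2)
    return m / z


def _sample_truncated_powerlaw(
    rng: np.random.Generator, size: int, x_min: float, x_max: float, gamma: float
) -> np.ndarray:
    """Inverse-CDF sampling of the continuous truncated power law."""
    u = rng.uniform(size=size)
    if gamma == 1.0:
        return x_min * (x_max / x_min) ** u
    a = x_min ** (1 - gamma)
    b = x_max ** (1 - gamma)
    return (a + u * (b - a)) ** (1 / (1 - gamma))


def _sample_degrees(rng: np.random.Generator, cfg: LFRConfig) -> np.ndarray:
    """Integer degrees with mean ~ ad and max <= d_max.

    The continuous lower cutoff is solved by bisection so that the mean of
    the floored sample is the target (flooring shifts the continuous mean
    by about one half, hence the ad + 0.5 target)."""
    target = cfg.ad + 0.5
    lo, hi = 1.0, float(cfg.d_max)
    if _truncated_powerlaw_mean(lo, cfg.d_max + 1.0, cfg.degree_exponent) > target:
        raise GenerationError("average degree unreachable: ad too small for d_max")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _truncated_powerlaw_mean(mid, cfg.d_max + 1.0, cfg.degree_exponent) < target:
            lo = mid
        else:
            hi = mid
    x = _sample_truncated_powerlaw(
        rng, cfg.N, 0.5 * (lo + hi), cfg.d_max + 1.0, cfg.degree_exponent
    )
    deg = np.clip(np.floor(x).astype(int), 1, cfg.d_max)
    if deg.sum() % 2:  # stub parity
        i = int(np.argmin(deg))
        deg[i] += 1 if deg[i] < cfg.d_max else -1
    return deg


def _sample_module_sizes(rng: np.random.Generator, cfg: LFRConfig) -> list[int]:
    """Module sizes from the truncated power law, summing to the total
    number of memberships N + on * (om - 1)."""
    total = cfg.N + cfg.on * (cfg.om - 1)
    sizes: list[int] = []
    acc = 0
    while acc < total:
        s = int(
            np.floor(
                _sample_truncated_powerlaw(
                    rng, 1, cfg.m_min, cfg.m_max + 1.0, cfg.size_exponent
                )[0]
            )
        )
        s = min(s, cfg.m_max)
        sizes.append(s)
        acc += s
    excess = acc - total
    # shave the excess off modules that stay above m_min
    i = 0
    guard = 0
    while excess > 0:
        if sizes[i] > cfg.m_min:
            sizes[i] -= 1
            excess -= 1
        i = (i + 1) % len(sizes)
        guard += 1
        if guard > 100 * len(sizes) + 100:
            # all modules at m_min: drop one and re-add its slots
            sizes.pop()
            return _distribute_remainder(sizes, total, cfg)
    if len(sizes) < max(2, cfg.om):
        raise GenerationError("parameter set yields too few modules")
    return sizes


def _distribute_remainder(sizes: list[int], total: int, cfg: LFRConfig) -> list[int]:
    deficit = total - sum(sizes)
    i = 0
    while deficit > 0:
        if sizes[i] < cfg.m_max:
            sizes[i] += 1
            deficit -= 1
        i = (i + 1) % len(sizes)
    return sizes


# -- stub matching -----------------------------------------------------------


def _match_stubs(
    rng: np.random.Generator,
    stubs: np.ndarray,
    forbidden: set[tuple[int, int]],
    same_group: list[set[int]] | None,
    sweeps: int = 100,
) -> tuple[list[tuple[int, int]], int]:
    """Pair a shuffled stub list into edges, then rewire bad pairs.

    A pair is bad if it is a self-loop, duplicates an existing or already
    formed edge, or (when ``same_group`` is given, mapping node -> module
    set) joins two nodes sharing a module.  Up to ``sweeps`` rewiring
    passes swap endpoints of bad pairs with random partners; survivors are
    dropped.  Returns the accepted edges and the number of dropped pairs.
    """
    stubs = stubs.copy()
    rng.shuffle(stubs)
    if len(stubs) % 2:
        stubs = stubs[:-1]
    pairs = stubs.reshape(-1, 2)

    def is_bad(u: int, v: int, edgeset: set[tuple[int, int]]) -> bool:
        if u == v:
            return True
        key = (u, v) if u < v else (v, u)
        if key in forbidden or key in edgeset:
            return True
        if same_group is not None and same_group[u] & same_group[v]:
            return True
        return False

    n_pairs = len(pairs)
    for _ in range(sweeps):
        edgeset: set[tuple[int, int]] = set()
        bad_idx = []
        for idx in range(n_pairs):
            u, v = int(pairs[idx, 0]), int(pairs[idx, 1])
            if is_bad(u, v, edgeset):
                bad_idx.append(idx)
            else:
                edgeset.add((u, v) if u < v else (v, u))
        if not bad_idx:
            break
        # swap one endpoint of each bad pair with a random other pair
        for idx in bad_idx:
            j = int(rng.integers(n_pairs))
            side = int(rng.integers(2))
            pairs[idx, 1], pairs[j, side] = pairs[j, side], pairs[idx, 1]

    edges: list[tuple[int, int]] = []
    edgeset = set()
    dropped = 0
    for idx in range(n_pairs):
        u, v = int(pairs[idx, 0]), int(pairs[idx, 1])
        if is_bad(u, v, edgeset):
            dropped += 1
        else:
            key = (u, v) if u < v else (v, u)
            edgeset.add(key)
            edges.append(key)
    return edges, dropped


# -- main generator ----------------------------------------------------------


def generate_lfr(config: LFRConfig) -> tuple[Network, ComplexCover]:
    """Generate one benchmark network and its planted module cover."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    degrees = _sample_degrees(rng, cfg)
    sizes = _sample_module_sizes(rng, cfg)
    n_mod = len(sizes)
    if cfg.om > n_mod:
        raise GenerationError(f"om={cfg.om} exceeds the number of modules {n_mod}")

    overlapping = rng.choice(cfg.N, size=cfg.on, replace=False) if cfg.on else np.array([], int)
    is_overlap = np.zeros(cfg.N, dtype=bool)
    is_overlap[overlapping] = True
    memberships_needed = np.where(is_overlap, cfg.om, 1)

    # assign memberships: high-degree nodes first, into modules with room
    # that can host their internal degree (internal degree < module size)
    capacity = np.array(sizes)
    modules_of: list[set[int]] = [set() for _ in range(cfg.N)]
    d_int_total = np.round((1.0 - cfg.mu) * degrees).astype(int)
    order = np.lexsort((np.arange(cfg.N), -degrees))
    for node in order:
        need = memberships_needed[node]
        per_mod_int = int(np.ceil(d_int_total[node] / need))
        open_mods = np.flatnonzero(capacity > 0)
        if len(open_mods) < need:
            raise GenerationError("ran out of module capacity during assignment")
        fits = open_mods[np.array(sizes)[open_mods] - 1 >= per_mod_int]
        pool = fits if len(fits) >= need else open_mods
        # prefer fitting modules; fill up from the largest remaining ones
        if len(pool) < need:
            pool = open_mods
        probs = capacity[pool] / capacity[pool].sum()
        pick = rng.choice(pool, size=need, replace=False, p=probs)
        for m in pick:
            modules_of[node].add(int(m))
            capacity[m] -= 1

    members: list[list[int]] = [[] for _ in range(n_mod)]
    for node in range(cfg.N):
        for m in modules_of[node]:
            members[m].append(node)

    # split internal degree across memberships, capped at module size - 1
    internal: dict[tuple[int, int], int] = {}
    for node in range(cfg.N):
        mods = sorted(modules_of[node])
        base, rem = divmod(d_int_total[node], len(mods))
        for r, m in enumerate(mods):
            want = base + (1 if r < rem else 0)
            internal[(node, m)] = min(want, len(members[m]) - 1)

    # intra-module configuration model, one module at a time
    all_edges: list[tuple[int, int]] = []
    dropped_total = 0
    for m in range(n_mod):
        stubs_list: list[int] = []
        for node in members[m]:
            stubs_list.extend([node] * internal[(node, m)])
        if len(stubs_list) % 2:
            # give the parity stub back to the external pool
            victim = stubs_list.pop()
            internal[(victim, m)] -= 1
        if not stubs_list:
            continue
        existing = set(all_edges)
        edges, dropped = _match_stubs(
            rng, np.array(stubs_list), forbidden=existing, same_group=None
        )
        all_edges.extend(edges)
        dropped_total += dropped

    # external stubs: whatever degree is not realized internally
    deg_count = np.zeros(cfg.N, dtype=int)
    for u, v in all_edges:
        deg_count[u] += 1
        deg_count[v] += 1
    d_ext = np.maximum(degrees - deg_count, 0)
    if cfg.mu == 0.0:
        # pure-intra limit: residual stubs (saturated modules, parity) are
        # dropped rather than wired across modules
        if d_ext.sum():
            logger.info("mu=0: dropped %d residual external stubs", int(d_ext.sum()))
        d_ext[:] = 0
    ext_stubs: list[int] = []
    for node in range(cfg.N):
        ext_stubs.extend([node] * int(d_ext[node]))
    if ext_stubs:
        existing = set(all_edges)
        edges, dropped = _match_stubs(
            rng,
            np.array(ext_stubs),
            forbidden=existing,
            same_group=modules_of,
        )
        all_edges.extend(edges)
        dropped_total += dropped
    if dropped_total:
        logger.info("stub matching dropped %d irreparable pairs", dropped_total)

    labels = [f"v{i}" for i in range(cfg.N)]
    a = np.zeros((cfg.N, cfg.N))
    for u, v in all_edges:
        a[u, v] = a[v, u] = 1.0
    net = Network(nodes=labels, adjacency=a, weighted=False)
    cover = ComplexCover(
        complexes=[{labels[i] for i in mem} for mem in members if mem],
        name=f"lfr-truth(mu={cfg.mu},seed={cfg.seed})",
    )
    return net, cover


def empirical_mixing(net: Network, truth: ComplexCover) -> float:
    """Mean over nodes of (edges leaving all own modules) / degree."""
    idx = {lab: i for i, lab in enumerate(net.nodes)}
    own: list[set[int]] = [set() for _ in net.nodes]
    for c_id, c in enumerate(truth.complexes):
        for lab in c:
            own[idx[lab]].add(c_id)
    node_mods = own
    a = net.adjacency
    fracs = []
    for i in range(net.n_nodes):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size == 0:
            continue
        ext = sum(1 for j in nbrs if not (node_mods[i] & node_mods[j]))
        fracs.append(ext / nbrs.size)
    return float(np.mean(fracs)) if fracs else 0.0


def planted_partition(
    n_blocks: int, block_size: int, p_in: float, p_out: float, seed: int = 0
) -> tuple[Network, ComplexCover]:
    """Small planted-partition fixture: Erdos-Renyi blocks with
    intra-probability p_in and inter-probability p_out."""
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("need 0 <= p_out < p_in <= 1")
    g = nx.planted_partition_graph(n_blocks, block_size, p_in, p_out, seed=seed)
    n = n_blocks * block_size
    labels = [f"v{i}" for i in range(n)]
    a = np.zeros((n, n))
    for u, v in g.edges():
        if u != v:
            a[u, v] = a[v, u] = 1.0
    net = Network(nodes=labels, adjacency=a, weighted=False)
    cover = ComplexCover(
        complexes=[
            {labels[i] for i in range(b * block_size, (b + 1) * block_size)}
            for b in range(n_blocks)
        ],
        name="planted-partition",
    )
    return net, cover


def mustlinks_from_truth(
    truth: ComplexCover, fraction: float, alpha: float = 10.0, seed: int = 0
) -> MustLinkConstraints:
    """Sample ground-truth must-links (single-membership rule applies, so
    overlapping nodes contribute no pairs)."""
    if fraction == 0:
        return MustLinkConstraints(pairs=set(), alpha=alpha)
    return sample_mustlinks(truth, fraction=fraction, alpha=alpha, rng_seed=seed)


def _preset(mu: float, overlap: bool) -> LFRConfig:
    base = LFRConfig(N=1000, ad=15.0, d_max=50, m_min=20, m_max=50, mu=mu)
    if overlap:
        base = replace(base, on=200, om=2)
    return base


PRESETS: dict[str, LFRConfig] = {
    f"lfr-{kind}-mu{int(round(mu * 100)):02d}": _preset(mu, kind == "overlap")
    for kind in ("nonoverlap", "overlap")
    for mu in (0.6, 0.65, 0.7)
}
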
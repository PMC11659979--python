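"""Synthetic networks, pathways, cohorts and survival for end-to-end testing.

Everything the scoring and subtyping pipeline consumes can be generated here
without any download: a connected scale-free gene network, random gene sets
with optionally "planted" network-localized pathways, cohorts whose samples
mutate planted-pathway genes at an elevated rate, and exponential survival
times tied to the planted subgroup. Planted pathways are grown by short
restarting random walks so their members are topologically coherent — the
propagation step only concentrates signal on a pathway whose mutated genes
cluster in the network, which is the mechanism under test.

All generators are fully deterministic given ``FixtureSpec.seed``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace

import networkx as nx
import numpy as np

from .io import MutationProfile, PathwayCollection
from .network import PPINetwork, build_network, edge_pairs
from .subtyping import SurvivalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SubgroupSpec",
    "FixtureSpec",
    "single_program_spec",
    "two_program_spec",
    "make_network",
    "make_pathways",
    "make_cohort",
    "perturb_network",
]

#: Baseline event hazard, events/day: median overall survival of 500 days.
BASELINE_HAZARD = math.log(2) / 500.0


@dataclass(frozen=True)
class SubgroupSpec:
    """One cohort subgroup tied to a planted pathway program.

    ``enrichment`` multiplies the background per-gene mutation probability for
    the planted pathway's genes; ``hazard_rate`` is the exponential event rate
    (events/day) of the subgroup.
    """

    pathway_id: str
    enrichment: float = 10.0
    n_samples: int = 50
    hazard_rate: float = BASELINE_HAZARD


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults describe a desk-scale cohort: a 500-gene scale-free network with
    mean degree ~14 (matching the edge density of curated human PPI networks),
    20 pathways of 20-40 genes, a background per-gene mutation probability of
    0.04 (a few dozen mutated genes per sample, mirroring typical nonsilent
    per-tumor counts on a network this size), 10x enrichment on planted
    pathways, and exponential survival with ~18% censoring.
    """

    n_nodes: int = 500
    graph_model: str = "preferential_attachment"  # or "planted_community"
    attachment_edges: int = 7
    n_communities: int = 4
    p_within: float = 0.2
    p_between: float = 0.01
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (20, 40)
    subgroups: tuple[SubgroupSpec, ...] = (SubgroupSpec("PW01"),)
    background_mutation_rate: float = 0.04
    censoring_rate: float = 3e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_mutation_rate <= 1.0:
            raise ValueError("background_mutation_rate must be in [0, 1]")
        lo, hi = self.pathway_size_range
        if lo < 3 or hi < lo:
            raise ValueError("pathway_size_range must satisfy 3 <= lo <= hi")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "FixtureSpec":
        data = dict(data)
        if "subgroups" in data:
            data["subgroups"] = tuple(
                sg if isinstance(sg, SubgroupSpec) else SubgroupSpec(**sg)
                for sg in data["subgroups"]
            )
        if "pathway_size_range" in data:
            data["pathway_size_range"] = tuple(data["pathway_size_range"])
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "FixtureSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def single_program_spec(seed: int = 0, n_samples: int = 100) -> FixtureSpec:
    """One subgroup with a single 10x-enriched planted pathway."""
    return FixtureSpec(subgroups=(SubgroupSpec("PW01", 10.0, n_samples),), seed=seed)


def two_program_spec(
    seed: int = 0, n_per_group: int = 50, rate_ratio: float = 3.0
) -> FixtureSpec:
    """Two subgroups with distinct planted programs and a survival rate ratio.

    Subgroup 1 (program PW01) carries ``rate_ratio`` times the baseline event
    hazard of subgroup 2 (program PW02).
    """
    return FixtureSpec(
        subgroups=(
            SubgroupSpec("PW01", 10.0, n_per_group, BASELINE_HAZARD * rate_ratio),
            SubgroupSpec("PW02", 10.0, n_per_group, BASELINE_HAZARD),
        ),
        seed=seed,
    )


def _gene_name(i: int, n_nodes: int) -> str:
    width = max(4, len(str(n_nodes - 1)))
    return f"G{i:0{width}d}"


def make_network(spec: FixtureSpec) -> PPINetwork:
    """Generate a connected simple gene graph per ``spec.graph_model``."""
    if spec.n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    if spec.graph_model == "preferential_attachment":
        graph = nx.barabasi_albert_graph(spec.n_nodes, spec.attachment_edges, seed=spec.seed)
    elif spec.graph_model == "planted_community":
        size = spec.n_nodes // spec.n_communities
        graph = None
        for attempt in range(50):
            candidate = nx.planted_partition_graph(
                spec.n_communities, size, spec.p_within, spec.p_between,
                seed=spec.seed + attempt,
            )
            if nx.is_connected(candidate):
                graph = candidate
                break
        if graph is None:
            raise RuntimeError("could not generate a connected planted-community graph")
    else:
        raise ValueError(f"unknown graph_model {spec.graph_model!r}")
    pairs = [
        (_gene_name(a, spec.n_nodes), _gene_name(b, spec.n_nodes)) for a, b in graph.edges()
    ]
    net = build_network(pairs)
    if net.n_nodes != graph.number_of_nodes():
        raise RuntimeError("generated graph unexpectedly disconnected")
    return net


def _localized_gene_set(
    net: PPINetwork, size: int, rng: np.random.Generator, exclude: set[str]
) -> tuple[set[str], str]:
    """Grow a gene set by a restarting random walk from a well-connected start."""
    candidates = [
        g for g in net.nodes if g not in exclude and net.degree(g) >= np.median(net.degrees)
    ]
    if not candidates:
        candidates = [g for g in net.nodes if g not in exclude]
    start = candidates[int(rng.integers(len(candidates)))]
    members = {start}
    current = start
    for _ in range(200 * size):
        if len(members) >= size:
            break
        if rng.random() < 0.3:  # restart keeps the walk local to `start`
            current = start
            continue
        nbrs = net.neighbors(current)
        current = nbrs[int(rng.integers(len(nbrs)))]
        if current not in exclude:
            members.add(current)
    if len(members) < size:  # fall back to BFS fill around the start
        for g in nx.bfs_tree(nx.from_scipy_sparse_array(net.adjacency), net.index[start]):
            gene = net.nodes[g]
            if gene not in exclude:
                members.add(gene)
            if len(members) >= size:
                break
    return members, start


def make_pathways(
    net: PPINetwork, spec: FixtureSpec
) -> tuple[PathwayCollection, dict[str, str]]:
    """Generate the pathway collection; returns (collection, planted start nodes).

    Pathways named by the subgroups are planted (network-localized and mutually
    disjoint); the rest are gene sets sampled uniformly from the genes outside
    every planted program, so recovery of a planted program is not confounded
    by background sets sharing its genes.
    """
    rng = np.random.default_rng([spec.seed, 1])
    ids = [f"PW{i + 1:02d}" for i in range(spec.n_pathways)]
    planted_ids = [sg.pathway_id for sg in spec.subgroups]
    missing = [pid for pid in planted_ids if pid not in ids]
    if missing:
        raise ValueError(f"planted pathway ids {missing} not among generated ids")
    lo, hi = spec.pathway_size_range
    if hi > net.n_nodes // 2:
        raise ValueError("pathway sizes must stay below half the network")
    sizes = {pid: int(rng.integers(lo, hi + 1)) for pid in ids}

    pathways: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    starts: dict[str, str] = {}
    exclude: set[str] = set()
    for pid in planted_ids:
        members, start = _localized_gene_set(net, sizes[pid], rng, exclude)
        pathways[pid] = frozenset(members)
        descriptions[pid] = f"planted network-localized program around {start}"
        starts[pid] = start
        exclude |= members
    allowed = np.array([i for i, g in enumerate(net.nodes) if g not in exclude])
    for pid in ids:
        if pid in pathways:
            continue
        chosen = rng.choice(allowed, size=sizes[pid], replace=False)
        pathways[pid] = frozenset(net.nodes[i] for i in chosen)
        descriptions[pid] = "background gene set"
    ordered = {pid: pathways[pid] for pid in ids}
    return PathwayCollection(pathways=ordered, descriptions=descriptions), starts


def make_cohort(
    net: PPINetwork, pathways: PathwayCollection, spec: FixtureSpec
) -> tuple[list[MutationProfile], list[SurvivalRecord], dict[str, int]]:
    """Simulate mutation profiles, survival and truth labels per subgroup.

    Each sample of subgroup g mutates each network gene independently at the
    background rate, multiplied by g's enrichment factor for genes of its
    planted pathway (probabilities clipped at 1 with a warning). Survival is
    exponential with the subgroup hazard, censored by an independent
    exponential clock.
    """
    rng = np.random.default_rng([spec.seed, 2])
    profiles: list[MutationProfile] = []
    survival: list[SurvivalRecord] = []
    truth: dict[str, int] = {}
    counter = 1
    for g_index, subgroup in enumerate(spec.subgroups, start=1):
        rates = np.full(net.n_nodes, spec.background_mutation_rate)
        mask = np.fromiter(
            (g in pathways[subgroup.pathway_id] for g in net.nodes),
            dtype=bool,
            count=net.n_nodes,
        )
        rates[mask] *= subgroup.enrichment
        if np.any(rates > 1.0):
            logger.warning(
                "subgroup %d: %d per-gene mutation probabilities clipped at 1",
                g_index,
                int((rates > 1.0).sum()),
            )
            rates = np.minimum(rates, 1.0)
        for _ in range(subgroup.n_samples):
            sid = f"S{counter:04d}"
            counter += 1
            mutated = rng.random(net.n_nodes) < rates
            profiles.append(
                MutationProfile(sid, frozenset(np.asarray(net.nodes)[mutated]))
            )
            t_event = rng.exponential(1.0 / subgroup.hazard_rate)
            if spec.censoring_rate > 0:
                t_cens = rng.exponential(1.0 / spec.censoring_rate)
            else:
                t_cens = math.inf
            survival.append(
                SurvivalRecord(sid, min(t_event, t_cens), bool(t_event <= t_cens))
            )
            truth[sid] = g_index
    return profiles, survival, truth


def perturb_network(net: PPINetwork, fraction: float, seed: int) -> PPINetwork:
    """Remove a random fraction of edges while keeping the graph connected.

    The node set is unchanged; edge count becomes round((1 - fraction) * E).
    The removed set is resampled (bounded retries) until connectivity holds.
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    edges = edge_pairs(net)
    n_remove = round(fraction * len(edges))
    if n_remove == 0:
        return net
    rng = np.random.default_rng(seed)
    for _ in range(200):
        removed = set(rng.choice(len(edges), size=n_remove, replace=False).tolist())
        kept = [e for i, e in enumerate(edges) if i not in removed]
        graph = nx.Graph(kept)
        if graph.number_of_nodes() == net.n_nodes and nx.is_connected(graph):
            return build_network(kept)
    raise RuntimeError(
        f"could not remove {n_remove} edges while keeping the graph connected"
    )
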
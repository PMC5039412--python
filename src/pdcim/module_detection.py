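"""Overlapping dense-module detection by greedy cohesiveness growth.

The clusterer follows the overlapping neighborhood-expansion scheme used
for protein-complex detection in weighted graphs: grow a candidate set
from a seed node by single-node additions and removals, always taking the
move that most increases the cohesiveness objective

    coh(S) = w_in(S) / (w_in(S) + w_bound(S) + penalty * |S|)

where ``w_in`` is the total weight of edges inside ``S`` and ``w_bound``
the total weight of edges crossing its boundary; the size penalty models
unobserved connectivity and discourages sprawling low-density sets. Seeds
are taken in descending weighted-degree order (ties broken
lexicographically), skipping nodes already absorbed by an earlier module,
so the procedure is deterministic. Candidate sets whose pairwise overlap
score ``|A∩B|^2 / (|A||B|)`` reaches the merge threshold are unioned;
survivors below the size or density floor are discarded.

Each reported module carries its weighted density, its cohesiveness, and a
one-sided Mann-Whitney U p-value comparing internal against boundary edge
weights (internal stochastically larger => small p), the significance
notion used to call a module "meaningful".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
from scipy import stats

from .io_formats import WeightedNetwork


@dataclass(frozen=True)
class Module:
    """A (possibly overlapping) dense node set of a weighted network."""

    members: frozenset
    density: float
    cohesiveness: float
    p_value: float

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ModuleSet:
    """Ordered collection of modules detected in one network."""

    modules: tuple[Module, ...]
    source_network: WeightedNetwork = field(compare=False, default=None)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def __getitem__(self, i):
        return self.modules[i]


def _boundary_weights(network: WeightedNetwork, node_set) -> tuple[list, list]:
    """Internal and boundary edge-weight multisets of a node set."""
    node_set = set(node_set)
    internal, boundary = [], []
    seen = set()
    for u in node_set:
        if u not in network:
            continue
        for v, data in network[u].items():
            if v in node_set:
                key = (u, v) if u <= v else (v, u)
                if key not in seen:
                    seen.add(key)
                    internal.append(data["weight"])
            else:
                boundary.append(data["weight"])
    return internal, boundary


def cohesiveness(network: WeightedNetwork, node_set, penalty: float = 2.0) -> float:
    """Cohesiveness of a node set: w_in / (w_in + w_bound + penalty*|S|)."""
    node_set = set(node_set)
    if not node_set:
        raise ValueError("cohesiveness of an empty node set is undefined")
    internal, boundary = _boundary_weights(network, node_set)
    w_in = sum(internal)
    denom = w_in + sum(boundary) + penalty * len(node_set)
    return w_in / denom if denom > 0 else 0.0


def weighted_density(network: WeightedNetwork, node_set) -> float:
    """Sum of internal edge weights over the number of possible pairs."""
    node_set = set(node_set)
    n = len(node_set)
    if n < 2:
        return 0.0
    internal, _ = _boundary_weights(network, node_set)
    return sum(internal) / (n * (n - 1) / 2)


def module_pvalue(network: WeightedNetwork, members) -> float:
    """One-sided Mann-Whitney U p-value: internal vs boundary edge weights.

    Small p means the module's internal weights are stochastically larger
    than the weights on edges leaving it. A module with no internal or no
    boundary edges offers no contrast and gets p = 1 by convention.
    """
    internal, boundary = _boundary_weights(network, members)
    if not internal or not boundary:
        return 1.0
    tie_free = len(set(internal) | set(boundary)) == len(internal) + len(boundary)
    method = "exact" if (max(len(internal), len(boundary)) <= 20 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(internal, boundary, alternative="greater", method=method)
    return float(res.pvalue)


class _CohesivenessState:
    """Incremental cohesiveness bookkeeping for one growing candidate set."""

    def __init__(self, network: WeightedNetwork, seed, penalty: float):
        self.network = network
        self.penalty = penalty
        self.members: set = set()
        self.w_in = 0.0
        self.w_bound = 0.0
        self.add(seed)

    def value(self) -> float:
        denom = self.w_in + self.w_bound + self.penalty * len(self.members)
        return self.w_in / denom if denom > 0 else 0.0

    def peek(self, node, adding: bool) -> float:
        """Cohesiveness after the hypothetical move, without applying it."""
        to_in = 0.0
        to_out = 0.0
        others = self.members - {node}
        for v, data in self.network[node].items():
            if v in others:
                to_in += data["weight"]
            else:
                to_out += data["weight"]
        if adding:
            w_in = self.w_in + to_in
            w_bound = self.w_bound - to_in + to_out
            n = len(self.members) + 1
        else:
            w_in = self.w_in - to_in
            w_bound = self.w_bound + to_in - to_out
            n = len(self.members) - 1
        denom = w_in + w_bound + self.penalty * n
        return w_in / denom if denom > 0 else 0.0

    def add(self, node) -> None:
        to_in = to_out = 0.0
        for v, data in self.network[node].items():
            if v in self.members:
                to_in += data["weight"]
            else:
                to_out += data["weight"]
        self.members.add(node)
        self.w_in += to_in
        self.w_bound += to_out - to_in

    def remove(self, node) -> None:
        self.members.discard(node)
        to_in = to_out = 0.0
        for v, data in self.network[node].items():
            if v in self.members:
                to_in += data["weight"]
            else:
                to_out += data["weight"]
        self.w_in -= to_in
        self.w_bound += to_in - to_out


def _grow_from_seed(network: WeightedNetwork, seed, penalty: float) -> frozenset:
    """Greedy grow/shrink until cohesiveness is locally maximal."""
    state = _CohesivenessState(network, seed, penalty)
    eps = 1e-12
    while True:
        current = state.value()
        frontier = sorted(
            {v for u in state.members for v in network[u]} - state.members
        )
        best_move, best_val = None, current
        for node in frontier:
            val = state.peek(node, adding=True)
            if val > best_val + eps:
                best_val, best_move = val, ("add", node)
        if len(state.members) > 1:
            for node in sorted(state.members):
                val = state.peek(node, adding=False)
                if val > best_val + eps:
                    best_val, best_move = val, ("remove", node)
        if best_move is None:
            break
        op, node = best_move
        if op == "add":
            state.add(node)
        else:
            state.remove(node)
        if not state.members:  # pragma: no cover - removal guard
            break
    return frozenset(state.members)


def _overlap_score(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def _merge_overlapping(candidates: list[frozenset], merge_overlap: float) -> list[frozenset]:
    """Union connected components of the candidate-overlap graph."""
    overlap = nx.Graph()
    overlap.add_nodes_from(range(len(candidates)))
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if _overlap_score(candidates[i], candidates[j]) >= merge_overlap:
                overlap.add_edge(i, j)
    merged = []
    for comp in nx.connected_components(overlap):
        union: set = set()
        for idx in comp:
            union |= candidates[idx]
        merged.append(frozenset(union))
    merged.sort(key=lambda s: (-len(s), tuple(sorted(s))))
    return merged


def detect_modules(
    network: WeightedNetwork,
    penalty: float = 2.0,
    min_size: int = 3,
    min_density: float = 0.5,
    merge_overlap: float = 0.8,
) -> ModuleSet:
    """Detect overlapping dense modules in a weighted network.

    Parameters mirror the published defaults of the neighborhood-expansion
    clusterer: size penalty 2, minimum module size 3, minimum weighted
    density 0.5, overlap-merge threshold 0.8. Output order and content are
    fully determined by the network.
    """
    if network.number_of_nodes() == 0:
        warnings.warn("empty network: no modules to detect", stacklevel=2)
        return ModuleSet(modules=(), source_network=network)

    wdeg = {n: sum(d["weight"] for d in network[n].values()) for n in network}
    seeds = sorted(network.nodes, key=lambda n: (-wdeg[n], n))

    covered: set = set()
    candidates: list[frozenset] = []
    seen: set[frozenset] = set()
    for seed in seeds:
        if seed in covered:
            continue
        grown = _grow_from_seed(network, seed, penalty)
        covered |= grown
        if grown not in seen:
            seen.add(grown)
            candidates.append(grown)

    merged = _merge_overlapping(candidates, merge_overlap)

    modules = []
    for members in merged:
        if len(members) < min_size:
            continue
        density = weighted_density(network, members)
        if density < min_density:
            continue
        modules.append(
            Module(
                members=members,
                density=density,
                cohesiveness=cohesiveness(network, members, penalty),
                p_value=module_pvalue(network, members),
            )
        )
    modules.sort(key=lambda m: (-len(m.members), tuple(sorted(m.members))))
    return ModuleSet(modules=tuple(modules), source_network=network)
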
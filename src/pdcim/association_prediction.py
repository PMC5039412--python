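"""Per-pair drug-disease scoring inside a linked module pair.

Two-step procedure. Step 1 rescores every node pair *within* a module from
the module's own subgraph topology: for nodes ``a, b`` let ``avg*(i)`` be
the best per-edge average weight over simple paths from ``a`` to ``b``
with exactly ``i`` edges (0 when no such path exists); then

    sim(a, b) = sum_{i=1}^{n-1} avg*(i)

with ``n`` the module size. Short, heavy paths dominate; an adjacent pair
recovers at least its edge weight. By default the best path per length is
the maximum-weight one (order-independent and bounded); averaging over all
simple paths of a length is available as an alternative. Paths are simple
— on weighted cycles an unrestricted length-indexed sum would diverge.

Step 2 propagates these within-module similarities across the curated
links that cross the module pair. For disease ``v`` and drug ``w``,

    corr(v, w) =   sum_{p in N_DI(v)} sim(v, p) * [ (w, p) curated ]
                 + sum_{q in N_DR(w)} sim(w, q) * [ (q, v) curated ]

where ``N_DI(v)`` holds the direct neighbors of ``v`` in the disease
module that carry at least one curated link into the drug module, and
``N_DR(w)`` symmetrically. A candidate pair thus inherits support from
curated associations of its close, topologically similar neighbors. The
scores are unnormalized sums; all module cells (curated and novel alike)
are ranked together in descending order, and precision-at-n simply labels
each ranked cell by its curated mark.

Step 1 is computed exactly with a dynamic program over node subsets
(bitmask states), tractable because modules are small (about a dozen
nodes); an exhaustive path enumeration serves as an independent check in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io_formats import CuratedAssociationSet, KNOWN_MARKS, WeightedNetwork

_MAX_DP_NODES = 26  # 2^n subset states; modules are far smaller in practice


def path_similarity(
    subgraph: WeightedNetwork,
    a,
    b,
    max_len: int | None = None,
    aggregate: str = "max",
) -> float:
    """Length-indexed path similarity between two nodes of a module subgraph.

    Parameters
    ----------
    subgraph : networkx.Graph
        The module-induced weighted subgraph.
    a, b : node
        Distinct nodes of ``subgraph``.
    max_len : int, optional
        Longest path length (edge count) considered; defaults to n-1,
        the longest possible simple path.
    aggregate : {"max", "mean"}
        Per-length aggregation over the simple paths of that length:
        weight of the maximum-weight path (default) or the mean weight
        over all such paths.
    """
    if a == b:
        raise ValueError("path similarity of a node with itself is undefined")
    if a not in subgraph or b not in subgraph:
        missing = [x for x in (a, b) if x not in subgraph]
        raise ValueError(f"node(s) not in subgraph: {missing}")
    if aggregate not in ("max", "mean"):
        raise ValueError(f"aggregate must be 'max' or 'mean', got {aggregate!r}")
    n = subgraph.number_of_nodes()
    if n > _MAX_DP_NODES:
        raise ValueError(
            f"module too large for exact path similarity ({n} > {_MAX_DP_NODES} nodes)"
        )
    if max_len is None:
        max_len = n - 1
    if max_len < 1:
        return 0.0

    nodes = sorted(subgraph.nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    adj = [
        [(idx[v], data["weight"]) for v, data in subgraph[u].items()]
        for u in nodes
    ]
    ai, bi = idx[a], idx[b]

    # dp maps (visited-mask) -> {endpoint: stats}; stats is the best path
    # weight for "max", or (count, total weight) for "mean". Paths never
    # extend through b, which only ever terminates them.
    if aggregate == "max":
        init: object = 0.0
    else:
        init = (1, 0.0)
    frontier: dict[int, dict[int, object]] = {1 << ai: {ai: init}}
    best_per_len: dict[int, object] = {}

    for length in range(1, max_len + 1):
        nxt: dict[int, dict[int, object]] = {}
        for mask, ends in frontier.items():
            for v, stat in ends.items():
                if v == bi:
                    continue
                for u, w in adj[v]:
                    if mask & (1 << u):
                        continue
                    nmask = mask | (1 << u)
                    slot = nxt.setdefault(nmask, {})
                    if aggregate == "max":
                        cand = stat + w
                        if u not in slot or cand > slot[u]:
                            slot[u] = cand
                    else:
                        cnt, tot = stat
                        pc, pt = slot.get(u, (0, 0.0))
                        slot[u] = (pc + cnt, pt + tot + cnt * w)
        for mask, ends in nxt.items():
            if bi in ends:
                stat = ends[bi]
                if aggregate == "max":
                    prev = best_per_len.get(length)
                    if prev is None or stat > prev:
                        best_per_len[length] = stat
                else:
                    cnt, tot = stat
                    pc, pt = best_per_len.get(length, (0, 0.0))
                    best_per_len[length] = (pc + cnt, pt + tot)
        frontier = nxt
        if not frontier:
            break

    total = 0.0
    for length, stat in best_per_len.items():
        if aggregate == "max":
            total += stat / length
        else:
            cnt, tot = stat
            total += tot / (cnt * length)
    return total


@dataclass(frozen=True)
class AssociationPrediction:
    """One ranked drug-disease cell of a module pair."""

    drug_id: str
    disease_id: str
    corr: float
    curated_mark: str
    rank: int


@dataclass(frozen=True)
class BipartiteContext:
    """Precomputed state for scoring one drug-module / disease-module pair."""

    drug_subgraph: WeightedNetwork = field(compare=False)
    disease_subgraph: WeightedNetwork = field(compare=False)
    known_links: frozenset  # curated (drug, disease) pairs crossing the modules
    drug_sims: dict  # sim over unordered drug pairs, keyed (min, max)
    disease_sims: dict
    drug_neighbors: dict  # N_DR(w): qualifying module neighbors per drug
    disease_neighbors: dict  # N_DI(v): qualifying module neighbors per disease

    @property
    def drugs(self) -> tuple:
        return tuple(sorted(self.drug_subgraph.nodes))

    @property
    def diseases(self) -> tuple:
        return tuple(sorted(self.disease_subgraph.nodes))


def _pairwise_sims(subgraph: WeightedNetwork, aggregate: str) -> dict:
    sims = {}
    nodes = sorted(subgraph.nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            sims[(u, v)] = path_similarity(subgraph, u, v, aggregate=aggregate)
    return sims


def _sim(sims: dict, a, b) -> float:
    return sims[(a, b) if a <= b else (b, a)]


def build_bipartite_context(
    drug_module,
    disease_module,
    drug_network: WeightedNetwork,
    disease_network: WeightedNetwork,
    curated: CuratedAssociationSet,
    aggregate: str = "max",
) -> BipartiteContext:
    """Assemble the heterogeneous-network context for one module pair.

    Induces the two module subgraphs, collects the curated links crossing
    the pair (marks M, T, M&T), precomputes all within-module path
    similarities, and derives the qualifying neighbor sets: a disease
    neighbor of ``v`` qualifies if it carries at least one curated link
    into the drug module (drugs symmetrically).
    """
    drugs = set(getattr(drug_module, "members", drug_module))
    diseases = set(getattr(disease_module, "members", disease_module))
    if not drugs or not diseases:
        raise ValueError("empty module in bipartite context")

    drug_sub = nx.Graph()
    drug_sub.add_nodes_from(drugs)
    drug_sub.add_edges_from(
        (u, v, d) for u, v, d in drug_network.edges(data=True) if u in drugs and v in drugs
    )
    dis_sub = nx.Graph()
    dis_sub.add_nodes_from(diseases)
    dis_sub.add_edges_from(
        (u, v, d)
        for u, v, d in disease_network.edges(data=True)
        if u in diseases and v in diseases
    )

    known = frozenset(
        (chem, dis)
        for (chem, dis), mark in curated.records.items()
        if mark in KNOWN_MARKS and chem in drugs and dis in diseases
    )
    linked_drugs = {chem for chem, _ in known}
    linked_diseases = {dis for _, dis in known}

    disease_neighbors = {
        v: frozenset(p for p in dis_sub[v] if p in linked_diseases) for v in diseases
    }
    drug_neighbors = {
        w: frozenset(q for q in drug_sub[w] if q in linked_drugs) for w in drugs
    }

    return BipartiteContext(
        drug_subgraph=drug_sub,
        disease_subgraph=dis_sub,
        known_links=known,
        drug_sims=_pairwise_sims(drug_sub, aggregate),
        disease_sims=_pairwise_sims(dis_sub, aggregate),
        drug_neighbors=drug_neighbors,
        disease_neighbors=disease_neighbors,
    )


def cross_module_score(
    context: BipartiteContext,
    v,
    w,
    side: str = "both",
    direct_bonus: bool = False,
) -> float:
    """Score a (disease v, drug w) cell by neighbor-propagated curated support.

    ``side`` restricts propagation to one half of the sum ("disease" or
    "drug"); ``direct_bonus`` adds 1 when (w, v) itself is a curated link.
    """
    if v not in context.disease_neighbors:
        raise ValueError(f"disease {v!r} not in context")
    if w not in context.drug_neighbors:
        raise ValueError(f"drug {w!r} not in context")
    if side not in ("both", "disease", "drug"):
        raise ValueError(f"side must be 'both', 'disease' or 'drug', got {side!r}")
    score = 0.0
    if side in ("both", "disease"):
        for p in context.disease_neighbors[v]:
            if (w, p) in context.known_links:
                score += _sim(context.disease_sims, v, p)
    if side in ("both", "drug"):
        for q in context.drug_neighbors[w]:
            if (q, v) in context.known_links:
                score += _sim(context.drug_sims, w, q)
    if direct_bonus and (w, v) in context.known_links:
        score += 1.0
    return score


def rank_predictions(
    context: BipartiteContext,
    scores: dict,
    curated: CuratedAssociationSet,
) -> list[AssociationPrediction]:
    """Order all module-pair cells by descending score with stable tie-break.

    ``scores`` maps every (drug, disease) cell of the pair to its corr
    value; marks (including "inferred"/"none") come from the full curated
    table. Curated cells are ranked together with novel ones.
    """
    cells = [(w, v) for w in context.drugs for v in context.diseases]
    if set(scores) != set(cells):
        raise ValueError("scores must cover exactly the module-pair cells")
    ordered = sorted(cells, key=lambda cell: (-scores[cell], cell[0], cell[1]))
    return [
        AssociationPrediction(
            drug_id=w,
            disease_id=v,
            corr=scores[(w, v)],
            curated_mark=curated.mark(w, v),
            rank=r,
        )
        for r, (w, v) in enumerate(ordered, start=1)
    ]


def score_module_pair(
    drug_module,
    disease_module,
    drug_network: WeightedNetwork,
    disease_network: WeightedNetwork,
    curated: CuratedAssociationSet,
    aggregate: str = "max",
    side: str = "both",
    direct_bonus: bool = False,
) -> list[AssociationPrediction]:
    """Full Step-1 + Step-2 scoring of one module pair, ranked."""
    context = build_bipartite_context(
        drug_module, disease_module, drug_network, disease_network, curated, aggregate
    )
    scores = {
        (w, v): cross_module_score(context, v, w, side=side, direct_bonus=direct_bonus)
        for w in context.drugs
        for v in context.diseases
    }
    return rank_predictions(context, scores, curated)


def evaluate_precision(predictions, top_n: int = 20) -> float:
    """Fraction of the top-n ranked predictions carrying a curated mark.

    Marks M, T and M&T count as known; "inferred" and "none" count as
    potential (unverified) associations. Accepts a sequence of
    :class:`AssociationPrediction` or any iterable of objects/rows with a
    ``curated_mark`` attribute or key.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    marks = []
    for p in predictions:
        mark = getattr(p, "curated_mark", None)
        if mark is None:
            mark = p["curated_mark"]
        marks.append(mark)
    if top_n > len(marks):
        raise ValueError(f"top_n = {top_n} exceeds {len(marks)} predictions")
    head = marks[:top_n]
    return sum(1 for m in head if m in KNOWN_MARKS) / top_n
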
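"""End-to-end convenience wrappers over the pipeline stages.

These glue the stages together for scripted runs and benchmarks: build
both similarity networks, detect modules, link module pairs through the
curated table, and score every drug-disease cell of the linked pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .association_prediction import build_bipartite_context, cross_module_score
from .io_formats import CuratedAssociationSet, WeightedNetwork
from .module_detection import ModuleSet, detect_modules
from .module_linking import link_modules, rank_module_pairs
from .profile_similarity import build_similarity_network, filter_network, tfidf_weight
from .synthetic import Fixture


@dataclass(frozen=True)
class PipelineResult:
    drug_network: WeightedNetwork = field(compare=False)
    disease_network: WeightedNetwork = field(compare=False)
    drug_modules: ModuleSet
    disease_modules: ModuleSet
    module_pairs: tuple
    cell_scores: dict  # (drug, disease) -> max corr over linked module pairs


def score_linked_pairs(
    drug_network: WeightedNetwork,
    disease_network: WeightedNetwork,
    drug_modules,
    disease_modules,
    curated: CuratedAssociationSet,
    min_score: float = 0.0,
    top_k: int | None = None,
    aggregate: str = "max",
) -> tuple[tuple, dict]:
    """Rank module pairs, then score every cell of the retained pairs.

    A cell covered by several retained module pairs keeps its maximum
    score. Returns (ranked pairs, cell-score map).
    """
    links = link_modules(drug_modules, disease_modules, curated)
    if top_k is None:
        top_k = max(len(links), 1)
    ranked = rank_module_pairs(links, min_score=min_score, top_k=top_k)
    mods_d = list(drug_modules)
    mods_x = list(disease_modules)
    scores: dict = {}
    for link in ranked:
        dm = mods_d[link.drug_module_id - 1]
        xm = mods_x[link.disease_module_id - 1]
        context = build_bipartite_context(
            dm, xm, drug_network, disease_network, curated, aggregate=aggregate
        )
        for w in context.drugs:
            for v in context.diseases:
                s = cross_module_score(context, v, w)
                key = (w, v)
                if s > scores.get(key, -1.0):
                    scores[key] = s
    return tuple(ranked), scores


def run_pipeline(
    occurrences,
    disease_edges: WeightedNetwork,
    curated: CuratedAssociationSet,
    drug_cutoff: float = 0.4,
    disease_cutoff: float = 0.5,
    min_pair_score: float = 0.0,
    top_k: int | None = None,
) -> PipelineResult:
    """Occurrence table + disease network + curated table -> scored cells."""
    drug_network = build_similarity_network(tfidf_weight(occurrences), drug_cutoff)
    disease_network = filter_network(disease_edges, disease_cutoff)
    drug_modules = detect_modules(drug_network)
    disease_modules = detect_modules(disease_network)
    pairs, cell_scores = score_linked_pairs(
        drug_network,
        disease_network,
        drug_modules,
        disease_modules,
        curated,
        min_score=min_pair_score,
        top_k=top_k,
    )
    return PipelineResult(
        drug_network=drug_network,
        disease_network=disease_network,
        drug_modules=drug_modules,
        disease_modules=disease_modules,
        module_pairs=pairs,
        cell_scores=cell_scores,
    )


def heldout_recovery(fixture: Fixture) -> tuple[list[int], list[float]]:
    """Labels and scores for held-out planted-link recovery on a fixture.

    Runs the full pipeline on the fixture's tables, scores every cell of
    every (drug module, disease module) combination — including pairs with
    no curated support, whose cells all score 0 and supply the negatives —
    and labels each cell: 1 if it is a planted link held out of the
    curated table, 0 if it is not planted at all. Exposed (curated)
    planted cells are excluded — they are inputs, not predictions.
    Held-out cells missed by module detection score 0, so poor module
    recovery is penalized rather than hidden.
    """
    result = run_pipeline(fixture.occurrences, fixture.disease_network, fixture.curated)
    cell_scores: dict = {}
    for dm in result.drug_modules:
        for xm in result.disease_modules:
            context = build_bipartite_context(
                dm, xm, result.drug_network, result.disease_network, fixture.curated
            )
            for w in context.drugs:
                for v in context.diseases:
                    s = cross_module_score(context, v, w)
                    if s > cell_scores.get((w, v), -1.0):
                        cell_scores[(w, v)] = s
    held_out = fixture.held_out_links()
    exposed = set(fixture.curated.records)
    cells = (set(cell_scores) | held_out) - exposed
    y_true, y_score = [], []
    for cell in sorted(cells):
        y_true.append(1 if cell in held_out else 0)
        y_score.append(cell_scores.get(cell, 0.0))
    return y_true, y_score
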
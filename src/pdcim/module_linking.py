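"""Scoring and ranking of (drug module, disease module) pairs.

A drug module and a disease module are linked through the curated
chemical-disease associations that cross them: with ``M_ij`` the number of
curated drug-disease pairs spanning the two modules and ``N_i``, ``N_j``
the module sizes, the pair strength is

    w(i, j) = M_ij / (N_i * N_j)

i.e. the fraction of possible cross-module cells backed by curated
evidence, bounded in [0, 1]. Alternative normalizations (``sum``:
M/(N_i+N_j); ``geomean``: M/sqrt(N_i*N_j)) are selectable. Pairs are
ranked by descending score, those below a floor (default 0.2) dropped,
and the list truncated to the top-k (default 3) for downstream per-pair
prediction.

Which curated marks qualify for ``M_ij`` is configurable: the default
counts every directly curated mark {M, T, M&T}; restricted variants
{T, M&T} and {M, M&T} are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io_formats import CuratedAssociationSet, KNOWN_MARKS

#: Selectable mark sets for counting cross-module curated associations.
MARK_SETS = {
    "curated": frozenset(KNOWN_MARKS),  # {M, T, M&T}
    "therapeutic": frozenset({"T", "M&T"}),
    "marker": frozenset({"M", "M&T"}),
}

_FORMULAS = ("product", "sum", "geomean")


@dataclass(frozen=True)
class ModulePairLink:
    """A scored (drug module, disease module) pair."""

    drug_module_id: int
    disease_module_id: int
    m_ij: int
    n_i: int
    n_j: int
    score: float


def count_cross_associations(
    drug_module,
    disease_module,
    curated: CuratedAssociationSet,
    mark_set: str = "curated",
) -> int:
    """Count curated associations crossing a drug module / disease module pair.

    Each (drug, disease) cell is counted at most once; only records whose
    mark falls in the chosen ``mark_set`` qualify.
    """
    marks = MARK_SETS[mark_set]
    drugs = set(getattr(drug_module, "members", drug_module))
    diseases = set(getattr(disease_module, "members", disease_module))
    return sum(
        1
        for (chem, dis), mark in curated.records.items()
        if mark in marks and chem in drugs and dis in diseases
    )


def module_pair_score(m_ij: int, n_i: int, n_j: int, formula: str = "product") -> float:
    """Strength of a module pair from its cross-association count and sizes."""
    if n_i < 1 or n_j < 1:
        raise ValueError("module sizes must be >= 1")
    if not 0 <= m_ij <= n_i * n_j:
        raise ValueError(f"M_ij = {m_ij} outside [0, {n_i * n_j}]")
    if formula == "product":
        return m_ij / (n_i * n_j)
    if formula == "sum":
        return m_ij / (n_i + n_j)
    if formula == "geomean":
        return m_ij / math.sqrt(n_i * n_j)
    raise ValueError(f"formula must be one of {_FORMULAS}, got {formula!r}")


def link_modules(
    drug_modules,
    disease_modules,
    curated: CuratedAssociationSet,
    formula: str = "product",
    mark_set: str = "curated",
) -> list[ModulePairLink]:
    """Score every (drug module, disease module) pair.

    Module ids are 1-based positions within each input collection, matching
    the module TSV written by :func:`pdcim.io_formats.write_modules`.
    """
    links = []
    for i, dm in enumerate(drug_modules, start=1):
        drugs = getattr(dm, "members", dm)
        for j, xm in enumerate(disease_modules, start=1):
            diseases = getattr(xm, "members", xm)
            m_ij = count_cross_associations(drugs, diseases, curated, mark_set)
            links.append(
                ModulePairLink(
                    drug_module_id=i,
                    disease_module_id=j,
                    m_ij=m_ij,
                    n_i=len(drugs),
                    n_j=len(diseases),
                    score=module_pair_score(m_ij, len(drugs), len(diseases), formula),
                )
            )
    return links


def rank_module_pairs(
    links,
    min_score: float = 0.2,
    top_k: int = 3,
) -> list[ModulePairLink]:
    """Rank pairs by descending score, drop those below the floor, keep top-k.

    The floor is inclusive (score >= min_score survives); ties are broken
    by (drug_module_id, disease_module_id) so the result is deterministic
    under input shuffling.
    """
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    kept = [l for l in links if l.score >= min_score and l.score > 0]
    kept.sort(key=lambda l: (-l.score, l.drug_module_id, l.disease_module_id))
    return kept[:top_k]
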
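"""TF-IDF weighting of binary occurrence profiles and cosine-similarity networks.

A drug is represented by the set of side effects it displays (a disease by
its symptoms). Raw co-occurrence over-weights ubiquitous features — e.g.
abdominal pain is reported for a large fraction of marketed drugs — so each
incidence ``W_ij`` is reweighted by inverse document frequency:

    w_ij = W_ij * log(N / n_i)

with ``N`` the number of entities and ``n_i`` the number of entities
displaying feature ``i``. The logarithm base only rescales every weight of
a feature uniformly and cancels in the cosine, so natural log is used.
Pairwise cosine similarity of the weighted columns then yields a weighted
network, thresholded at a cutoff (0.4 for the drug network, 0.5 for the
disease network in the reference analysis); entities left without an edge
drop out of the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .io_formats import OccurrenceProfile, WeightedNetwork


@dataclass(frozen=True)
class TfidfProfile:
    """TF-IDF-weighted occurrence profile.

    ``weights[i, j] = W_ij * ln(N / n_i)``; zero wherever the binary
    incidence is zero, and zero for any feature present in every entity.
    """

    entity_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    weights: sparse.csr_matrix  # shape (n_features, n_entities)
    n_entities: int
    feature_counts: np.ndarray  # n_i per feature

    def entity_vector(self, entity_id: str) -> np.ndarray:
        j = self.entity_ids.index(entity_id)
        return np.asarray(self.weights[:, j].todense()).ravel()


def tfidf_weight(profile: OccurrenceProfile) -> TfidfProfile:
    """Apply inverse-document-frequency weighting to a binary profile.

    Raises
    ------
    ValueError
        If any feature has no associated entity (n_i = 0), which the
        incidence invariants rule out for well-formed inputs.
    """
    incidence = profile.incidence.tocsr()
    n_i = np.asarray(incidence.sum(axis=1)).ravel()
    if np.any(n_i == 0):
        dead = [profile.feature_ids[i] for i in np.flatnonzero(n_i == 0)]
        raise ValueError(f"features with no associated entity: {dead[:5]}")
    idf = np.log(profile.n_entities / n_i)
    weights = sparse.diags(idf) @ incidence
    weights.eliminate_zeros()
    return TfidfProfile(
        entity_ids=profile.entity_ids,
        feature_ids=profile.feature_ids,
        weights=weights.tocsr(),
        n_entities=profile.n_entities,
        feature_counts=n_i.astype(int),
    )


def cosine_similarity(u, v) -> float:
    """Cosine similarity of two weight vectors, clipped into [0, 1].

    Raises
    ------
    ValueError
        If either vector is all-zero (undefined angle).
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), 0.0, 1.0))


def build_similarity_network(profile: TfidfProfile, cutoff: float = 0.4) -> WeightedNetwork:
    """Threshold pairwise cosine similarities into a weighted network.

    An edge (a, b) is present iff cosine(a, b) >= cutoff; entities with no
    surviving edge are dropped. Entities whose weight vector is all-zero
    (every feature ubiquitous) cannot enter the network and are excluded
    with a warning rather than aborting.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    cols = profile.weights.T.tocsr()  # entities as rows
    norms = sparse.linalg.norm(cols, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        names = [profile.entity_ids[j] for j in zero]
        warnings.warn(
            f"excluding {zero.size} entit(ies) with all-zero weight vectors "
            f"(every feature ubiquitous): {names[:5]}",
            stacklevel=2,
        )
    keep = np.flatnonzero(norms > 0)
    sims = _sk_cosine(cols[keep])
    np.clip(sims, 0.0, 1.0, out=sims)
    graph = nx.Graph()
    ii, jj = np.nonzero(np.triu(sims >= cutoff, k=1))
    for a, b in zip(ii, jj):
        graph.add_edge(
            profile.entity_ids[keep[a]],
            profile.entity_ids[keep[b]],
            weight=float(sims[a, b]),
        )
    return graph


def filter_network(network: WeightedNetwork, cutoff: float) -> WeightedNetwork:
    """Keep edges with weight >= cutoff; drop nodes left isolated."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    out = nx.Graph()
    for a, b, data in network.edges(data=True):
        if data["weight"] >= cutoff:
            out.add_edge(a, b, weight=data["weight"])
    return out
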
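"""Seeded synthetic corpora with planted module and cross-layer structure.

The generator emulates the three pipeline inputs without any download:

* a drug x side-effect occurrence table in which the drugs of each planted
  module share a block of module-exclusive side effects (plus optional
  noise side effects from a common low-specificity pool), so their TF-IDF
  cosine similarity is high within a module and near zero across modules;
* a weighted disease-disease network whose planted modules are cliques
  with heavy intra-module weights and sparse light inter-module noise
  edges;
* a curated chemical-disease table: the k-th drug module is paired with
  the k-th disease module, every cell of that pairing is a planted
  association, and a ``link_coverage`` fraction of the cells is exposed
  with mark M&T — the remainder is held out in the ground-truth manifest
  for recovery evaluation.

Background drugs carry a few private side effects plus one draw from the
common pool, which bounds any background pairwise cosine well below the
0.4 network cutoff. All randomness flows from the single integer seed; no
global generator state is touched. The generator mimics sparsity and
block structure only — it makes no attempt to match real pharmacovigilance
marginals, reporting biases or mark composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import CuratedAssociationSet, OccurrenceProfile, WeightedNetwork

_BG_PRIVATE_FEATURES = 4  # private side effects per background drug
_INTER_EDGE_PROB = 0.1  # density of inter-module disease noise edges


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic corpus; fully determines it with a seed."""

    n_drug_modules: int = 3
    n_disease_modules: int = 3
    module_size_range: tuple[int, int] = (4, 8)
    n_background_entities: int = 20
    n_features: int = 120
    shared_feature_count: int = 8
    noise_feature_prob: float = 0.05
    intra_weight_range: tuple[float, float] = (0.8, 1.0)
    inter_weight_range: tuple[float, float] = (0.05, 0.2)
    link_coverage: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.intra_weight_range, self.inter_weight_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("weight ranges must lie within [0, 1]")
        if not 0.0 <= self.link_coverage <= 1.0:
            raise ValueError("link_coverage must lie in [0, 1]")
        if not 0.0 <= self.noise_feature_prob <= 1.0:
            raise ValueError("noise_feature_prob must lie in [0, 1]")
        if min(
            self.n_drug_modules,
            self.n_disease_modules,
            self.n_background_entities,
            self.n_features,
            self.shared_feature_count,
            self.module_size_range[0],
        ) < 1:
            raise ValueError("all counts must be >= 1")
        needed = (
            self.n_drug_modules * self.shared_feature_count
            + self.n_background_entities * _BG_PRIVATE_FEATURES
            + 2
        )
        if self.n_features < needed:
            raise ValueError(
                f"n_features = {self.n_features} cannot host "
                f"{self.n_drug_modules} x {self.shared_feature_count} module "
                f"features plus background features (need >= {needed})"
            )


@dataclass(frozen=True)
class Fixture:
    """One generated corpus plus its ground truth."""

    spec: FixtureSpec
    occurrences: OccurrenceProfile
    disease_network: WeightedNetwork = field(compare=False)
    curated: CuratedAssociationSet
    drug_modules: tuple[frozenset, ...]
    disease_modules: tuple[frozenset, ...]
    manifest: pd.DataFrame = field(compare=False)

    def held_out_links(self) -> set[tuple[str, str]]:
        rows = self.manifest[self.manifest["status"] == "held_out"]
        return set(zip(rows["drug"], rows["disease"]))

    def write(self, out_dir) -> dict[str, Path]:
        """Emit the three input TSVs plus the manifest TSV, deterministically."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "occurrences": out_dir / "occurrences.tsv",
            "disease_network": out_dir / "disease_network.tsv",
            "curated": out_dir / "curated.tsv",
            "manifest": out_dir / "manifest.tsv",
        }
        with open(paths["occurrences"], "w", encoding="utf-8") as fh:
            for feat, ent in sorted(self.occurrences.pairs()):
                fh.write(f"{feat}\t{ent}\n")
        with open(paths["disease_network"], "w", encoding="utf-8") as fh:
            for a, b, d in sorted(
                (min(u, v), max(u, v), d)
                for u, v, d in self.disease_network.edges(data=True)
            ):
                fh.write(f"{a}\t{b}\t{d['weight']:.6f}\n")
        with open(paths["curated"], "w", encoding="utf-8") as fh:
            for (chem, dis), mark in sorted(self.curated.records.items()):
                fh.write(f"{chem}\t{dis}\t{mark}\n")
        self.manifest.to_csv(paths["manifest"], sep="\t", index=False)
        return paths


def _module_sizes(rng: np.random.Generator, k: int, size_range) -> list[int]:
    lo, hi = size_range
    return [int(s) for s in rng.integers(lo, hi + 1, size=k)]


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate one synthetic corpus from a spec (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)

    # --- feature universe -------------------------------------------------
    module_feats = [
        [f"se_m{k:02d}_{t:02d}" for t in range(spec.shared_feature_count)]
        for k in range(spec.n_drug_modules)
    ]
    n_private = spec.n_background_entities * _BG_PRIVATE_FEATURES
    private_feats = [f"se_p{t:04d}" for t in range(n_private)]
    n_common = (
        spec.n_features
        - spec.n_drug_modules * spec.shared_feature_count
        - n_private
    )
    common_feats = [f"se_c{t:03d}" for t in range(n_common)]

    # --- drugs ------------------------------------------------------------
    drug_sizes = _module_sizes(rng, spec.n_drug_modules, spec.module_size_range)
    pairs: set[tuple[str, str]] = set()
    drug_modules: list[frozenset] = []
    for k, size in enumerate(drug_sizes):
        members = [f"drug_m{k:02d}_{i:02d}" for i in range(size)]
        drug_modules.append(frozenset(members))
        for drug in members:
            for feat in module_feats[k]:
                pairs.add((feat, drug))
            noisy = rng.random(n_common) < spec.noise_feature_prob
            for feat, hit in zip(common_feats, noisy):
                if hit:
                    pairs.add((feat, drug))
    for i in range(spec.n_background_entities):
        drug = f"drug_bg{i:03d}"
        start = i * _BG_PRIVATE_FEATURES
        for feat in private_feats[start: start + _BG_PRIVATE_FEATURES]:
            pairs.add((feat, drug))
        pairs.add((str(rng.choice(common_feats)), drug))
    occurrences = OccurrenceProfile.from_pairs(pairs)

    # --- disease network --------------------------------------------------
    disease_sizes = _module_sizes(rng, spec.n_disease_modules, spec.module_size_range)
    graph = nx.Graph()
    disease_modules: list[frozenset] = []
    lo_in, hi_in = spec.intra_weight_range
    lo_out, hi_out = spec.inter_weight_range
    for k, size in enumerate(disease_sizes):
        members = [f"dis_m{k:02d}_{i:02d}" for i in range(size)]
        disease_modules.append(frozenset(members))
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                graph.add_edge(a, b, weight=float(rng.uniform(lo_in, hi_in)))
    for k1 in range(spec.n_disease_modules):
        for k2 in range(k1 + 1, spec.n_disease_modules):
            for a in sorted(disease_modules[k1]):
                for b in sorted(disease_modules[k2]):
                    if rng.random() < _INTER_EDGE_PROB:
                        w = float(rng.uniform(lo_out, hi_out))
                        if w > 0.0:
                            graph.add_edge(a, b, weight=w)

    # --- planted cross-layer links ----------------------------------------
    records: dict[tuple[str, str], str] = {}
    manifest_rows = []
    n_pairings = min(spec.n_drug_modules, spec.n_disease_modules)
    for k in range(n_pairings):
        cells = [
            (drug, dis)
            for drug in sorted(drug_modules[k])
            for dis in sorted(disease_modules[k])
        ]
        n_exposed = int(round(spec.link_coverage * len(cells)))
        exposed_idx = set(
            rng.choice(len(cells), size=n_exposed, replace=False).tolist()
        )
        for idx, (drug, dis) in enumerate(cells):
            status = "exposed" if idx in exposed_idx else "held_out"
            if status == "exposed":
                records[(drug, dis)] = "M&T"
            manifest_rows.append(
                {
                    "drug": drug,
                    "disease": dis,
                    "drug_module": k,
                    "disease_module": k,
                    "status": status,
                }
            )
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["drug", "disease", "drug_module", "disease_module", "status"],
    )

    return Fixture(
        spec=spec,
        occurrences=occurrences,
        disease_network=graph,
        curated=CuratedAssociationSet(records),
        drug_modules=tuple(drug_modules),
        disease_modules=tuple(disease_modules),
        manifest=manifest,
    )


@dataclass(frozen=True)
class ToyModulePair:
    """The hand-sized 4-drug x 4-disease worked example."""

    drug_module: frozenset
    disease_module: frozenset
    drug_network: WeightedNetwork = field(compare=False)
    disease_network: WeightedNetwork = field(compare=False)
    curated: CuratedAssociationSet = None


def worked_toy() -> ToyModulePair:
    """A 4-drug / 4-disease module pair with 5 curated cross links.

    Both modules are cliques with fixed weights, and exactly five of the
    sixteen cross cells carry a curated M&T mark, so M_ij = 5 and
    N(i) = N(j) = 4 with the default pair score 5/16.
    """
    drugs = [f"drug{i}" for i in range(1, 5)]
    diseases = [f"disease{i}" for i in range(1, 5)]
    drug_net = nx.Graph()
    for i, a in enumerate(drugs):
        for b in drugs[i + 1:]:
            drug_net.add_edge(a, b, weight=0.8)
    dis_net = nx.Graph()
    for i, a in enumerate(diseases):
        for b in diseases[i + 1:]:
            dis_net.add_edge(a, b, weight=0.7)
    curated = CuratedAssociationSet(
        {
            ("drug1", "disease1"): "M&T",
            ("drug1", "disease2"): "M&T",
            ("drug2", "disease2"): "M&T",
            ("drug3", "disease3"): "M&T",
            ("drug4", "disease4"): "M&T",
        }
    )
    return ToyModulePair(
        drug_module=frozenset(drugs),
        disease_module=frozenset(diseases),
        drug_network=drug_net,
        disease_network=dis_net,
        curated=curated,
    )
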
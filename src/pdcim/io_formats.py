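"""Readers and writers for the tabular formats the pipeline touches.

All external inputs are plain delimited text (TSV by default, ``#`` comment
lines skipped): a two-column entity/feature occurrence table (SIDER-style
drug x side-effect, or disease x symptom), a three-column weighted edge
list (symptom-based disease network), and a three-column curated
chemical-disease association table (CTD-style, with marks ``M``, ``T``,
``M&T``, ``inferred`` or ``none``).

Identifiers are opaque, case-sensitive strings; no synonym resolution is
attempted. Entity and feature orderings are sorted lexicographically so a
given file always yields the same in-memory object.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

#: Closed vocabulary of curated-association marks, plus accepted aliases.
CURATED_MARKS = frozenset({"M", "T", "M&T", "inferred", "none"})

#: Marks that denote a directly curated ("known") association.
KNOWN_MARKS = frozenset({"M", "T", "M&T"})

_MARK_ALIASES = {
    "marker/mechanism": "M",
    "therapeutic": "T",
    "marker/mechanism|therapeutic": "M&T",
    "therapeutic|marker/mechanism": "M&T",
    "marker/mechanism&therapeutic": "M&T",
    "m&t": "M&T",
    "m": "M",
    "t": "T",
    "inferred": "inferred",
    "none": "none",
}


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


def normalize_mark(raw: str) -> str:
    """Map a raw mark string onto the closed vocabulary.

    Accepts the canonical tokens (``M``, ``T``, ``M&T``, ``inferred``,
    ``none``) and the long-form aliases used by curated extracts
    (``therapeutic``, ``marker/mechanism``, pipe-joined combinations).

    Raises
    ------
    ValueError
        If the string maps to nothing in the vocabulary.
    """
    token = raw.strip()
    if token in CURATED_MARKS:
        return token
    alias = _MARK_ALIASES.get(token.lower())
    if alias is None:
        raise ValueError(f"unknown curated mark {raw!r}")
    return alias


@dataclass(frozen=True)
class OccurrenceProfile:
    """Binary incidence of features (rows) against entities (columns).

    ``incidence[i, j] == 1`` iff entity ``j`` displays feature ``i`` — e.g.
    drug ``j`` displays side effect ``i``. Every entity has at least one
    feature and vice versa.
    """

    entity_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    incidence: sparse.csr_matrix  # shape (n_features, n_entities), values {0,1}

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_incidences(self) -> int:
        return int(self.incidence.nnz)

    @classmethod
    def from_pairs(cls, pairs) -> "OccurrenceProfile":
        """Build a profile from an iterable of (feature_id, entity_id)."""
        pairs = set(pairs)
        if not pairs:
            raise ValueError("empty occurrence set")
        features = sorted({f for f, _ in pairs})
        entities = sorted({e for _, e in pairs})
        fidx = {f: i for i, f in enumerate(features)}
        eidx = {e: j for j, e in enumerate(entities)}
        rows = [fidx[f] for f, e in pairs]
        cols = [eidx[e] for f, e in pairs]
        mat = sparse.csr_matrix(
            ([1] * len(pairs), (rows, cols)),
            shape=(len(features), len(entities)),
            dtype=float,
        )
        return cls(tuple(entities), tuple(features), mat)

    def pairs(self) -> set[tuple[str, str]]:
        """Return the (feature_id, entity_id) incidence pairs."""
        coo = self.incidence.tocoo()
        return {
            (self.feature_ids[i], self.entity_ids[j])
            for i, j in zip(coo.row, coo.col)
        }


@dataclass(frozen=True)
class CuratedAssociationSet:
    """Curated chemical-disease associations with a closed mark vocabulary."""

    records: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self):
        bad = {m for m in self.records.values() if m not in CURATED_MARKS}
        if bad:
            raise ValueError(f"marks outside vocabulary: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    def mark(self, chemical: str, disease: str) -> str:
        """The mark for a pair, or ``"none"`` when the pair is absent."""
        return self.records.get((chemical, disease), "none")

    def is_known(self, chemical: str, disease: str) -> bool:
        return self.mark(chemical, disease) in KNOWN_MARKS

    def known_pairs(self) -> set[tuple[str, str]]:
        return {p for p, m in self.records.items() if m in KNOWN_MARKS}


# A weighted undirected network is carried as a networkx Graph with float
# 'weight' attributes in (0, 1]; the alias exists for signature readability.
WeightedNetwork = nx.Graph


def _data_rows(path, delimiter: str):
    """Yield (lineno, fields) for non-comment, non-blank lines."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n").rstrip("\r")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            yield lineno, stripped.split(delimiter)


def read_occurrence_table(path, delimiter: str = "\t") -> OccurrenceProfile:
    """Read a two-column (feature_id, entity_id) occurrence table.

    Duplicate rows are dropped with a single summary warning. Entities and
    features are ordered lexicographically.
    """
    pairs: list[tuple[str, str]] = []
    for lineno, fields in _data_rows(path, delimiter):
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(f"{path}: line {lineno}: expected two non-empty columns")
        pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise ParseError(f"{path}: empty occurrence table")
    unique = set(pairs)
    n_dup = len(pairs) - len(unique)
    if n_dup:
        warnings.warn(
            f"{path}: dropped {n_dup} duplicate occurrence row(s)", stacklevel=2
        )
    return OccurrenceProfile.from_pairs(unique)


def read_weighted_edgelist(path, delimiter: str = "\t") -> WeightedNetwork:
    """Read a three-column (node, node, weight) undirected edge list.

    ``(a, b)`` and ``(b, a)`` rows must carry equal weights; conflicting
    duplicates raise. Self-loops are dropped with a warning.
    """
    graph = nx.Graph()
    n_loops = 0
    for lineno, fields in _data_rows(path, delimiter):
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected three columns")
        a, b = fields[0].strip(), fields[1].strip()
        try:
            w = float(fields[2])
        except ValueError as exc:
            raise ParseError(
                f"{path}: line {lineno}: non-numeric weight {fields[2]!r}"
            ) from exc
        if a == b:
            n_loops += 1
            continue
        if graph.has_edge(a, b) and graph[a][b]["weight"] != w:
            raise ParseError(
                f"{path}: line {lineno}: conflicting weights for edge "
                f"({a}, {b}): {graph[a][b]['weight']} vs {w}"
            )
        graph.add_edge(a, b, weight=w)
    if n_loops:
        warnings.warn(f"{path}: dropped {n_loops} self-loop(s)", stacklevel=2)
    return graph


def read_curated_associations(path, delimiter: str = "\t") -> CuratedAssociationSet:
    """Read a (chemical, disease, mark) association table.

    Marks are normalized to the closed vocabulary; unknown mark strings and
    duplicate pairs with conflicting marks raise.
    """
    records: dict[tuple[str, str], str] = {}
    offenders: list[str] = []
    for lineno, fields in _data_rows(path, delimiter):
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected three columns")
        chem, dis = fields[0].strip(), fields[1].strip()
        try:
            mark = normalize_mark(fields[2])
        except ValueError:
            offenders.append(f"line {lineno}: {fields[2]!r}")
            continue
        key = (chem, dis)
        if key in records and records[key] != mark:
            raise ParseError(
                f"{path}: line {lineno}: conflicting marks for {key}: "
                f"{records[key]} vs {mark}"
            )
        records[key] = mark
    if offenders:
        raise ParseError(f"{path}: unknown curated marks: " + "; ".join(offenders))
    return CuratedAssociationSet(records)


MODULE_COLUMNS = ["module_id", "member_ids", "size", "density", "cohesiveness", "p_value"]
PREDICTION_COLUMNS = ["rank", "drug", "disease", "score", "curated_mark"]


def write_modules(modules, path, delimiter: str = "\t") -> None:
    """Write a module collection as TSV (members pipe-joined, sorted)."""
    modules = list(modules)
    if not modules:
        raise ValueError("refusing to write an empty module collection")
    rows = [
        {
            "module_id": i + 1,
            "member_ids": "|".join(sorted(m.members)),
            "size": len(m.members),
            "density": m.density,
            "cohesiveness": m.cohesiveness,
            "p_value": m.p_value,
        }
        for i, m in enumerate(modules)
    ]
    pd.DataFrame(rows, columns=MODULE_COLUMNS).to_csv(path, sep=delimiter, index=False)


def read_modules(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a module TSV back into a DataFrame (member_ids pipe-separated)."""
    df = pd.read_csv(path, sep=delimiter, comment="#")
    missing = set(MODULE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing module columns {sorted(missing)}")
    return df


def write_predictions(predictions, path, delimiter: str = "\t") -> None:
    """Write ranked drug-disease predictions as TSV."""
    predictions = list(predictions)
    if not predictions:
        raise ValueError("refusing to write an empty prediction collection")
    rows = [
        {
            "rank": p.rank,
            "drug": p.drug_id,
            "disease": p.disease_id,
            "score": p.corr,
            "curated_mark": p.curated_mark,
        }
        for p in predictions
    ]
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(
        path, sep=delimiter, index=False
    )


def read_predictions(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a prediction TSV; rows come back in written (rank) order."""
    df = pd.read_csv(path, sep=delimiter, comment="#", dtype={"curated_mark": str})
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing prediction columns {sorted(missing)}")
    return df
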
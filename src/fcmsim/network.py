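"""Signed concept networks with determinate and indeterminate influences.

A :class:`ConceptNetwork` is a sparse signed weighted directed graph.  Nodes
("concepts") are genes, proteins, phenotypes, cell types, brain regions,
conditions or media components; their activity lives in [-1, 1] around a 0
baseline.  Edges ("influences") carry a weight in [-1, 1] excluding 0
(absence of an edge *is* weight 0), or the indeterminate marker ``"I"`` for
relationships known to exist but of unknown sign/strength.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

import numpy as np
import scipy.sparse as sp

from .errors import (
    DuplicateEdgeError,
    MalformedWeightError,
    NetworkFormatError,
    UndefinedFractionError,
    UnknownConceptError,
)

INDETERMINATE = "I"

CATEGORIES = frozenset(
    {"gene", "protein", "phenotype", "cell_type", "region", "condition",
     "media_component"}
)

Weight = Union[float, str]


@dataclass(frozen=True)
class Concept:
    """A node in the map. Baseline activity is 0 by convention."""

    id: str
    label: str = ""
    category: str = "gene"

    def __post_init__(self):
        if not self.id:
            raise NetworkFormatError("concept id must be non-empty")
        if self.category not in CATEGORIES:
            raise NetworkFormatError(
                f"unknown concept category {self.category!r} for {self.id!r}"
            )


@dataclass(frozen=True)
class Influence:
    """A directed signed influence source -> target.

    ``weight`` is a real in [-1, 1] \\ {0}, or :data:`INDETERMINATE`.
    """

    source: str
    target: str
    weight: Weight

    def __post_init__(self):
        if self.source == self.target:
            raise NetworkFormatError(
                f"self-loop {self.source!r}: memory is an engine parameter, "
                "not an edge"
            )
        w = self.weight
        if isinstance(w, str):
            if w.upper() != INDETERMINATE:
                raise MalformedWeightError(
                    f"weight {w!r} on {self.source}->{self.target} is neither "
                    "a number nor 'I'"
                )
            object.__setattr__(self, "weight", INDETERMINATE)
        else:
            w = float(w)
            if not math.isfinite(w) or not (-1.0 <= w <= 1.0):
                raise MalformedWeightError(
                    f"weight {w} on {self.source}->{self.target} outside [-1, 1]"
                )
            if w == 0.0:
                raise MalformedWeightError(
                    f"zero weight on {self.source}->{self.target}: absence of "
                    "an edge encodes 'no relationship'"
                )
            object.__setattr__(self, "weight", w)

    @property
    def is_indeterminate(self) -> bool:
        return isinstance(self.weight, str)


class ConceptNetwork:
    """Concepts plus signed weighted directed influences.

    Concept order is insertion order and defines the engine's state-vector
    layout.  At most one influence per ordered (source, target) pair.
    """

    def __init__(self, concepts: Iterable[Concept] = (),
                 influences: Iterable[Influence] = ()):
        self._concepts: dict[str, Concept] = {}
        self._influences: dict[tuple[str, str], Influence] = {}
        for c in concepts:
            self.add_concept(c)
        for e in influences:
            self.add_influence(e)

    # -- construction -----------------------------------------------------

    def add_concept(self, concept: Concept) -> None:
        if concept.id in self._concepts:
            raise NetworkFormatError(f"duplicate concept id {concept.id!r}")
        self._concepts[concept.id] = concept

    def ensure_concept(self, cid: str, category: str = "gene") -> None:
        if cid not in self._concepts:
            self._concepts[cid] = Concept(cid, category=category)

    def add_influence(self, influence: Influence,
                      auto_register: bool = False) -> None:
        key = (influence.source, influence.target)
        if key in self._influences:
            raise DuplicateEdgeError(
                f"duplicate influence {key[0]} -> {key[1]}"
            )
        for cid in key:
            if cid not in self._concepts:
                if auto_register:
                    self.ensure_concept(cid)
                else:
                    raise UnknownConceptError(
                        f"influence endpoint {cid!r} names no concept"
                    )
        self._influences[key] = influence

    # -- views ------------------------------------------------------------

    @property
    def concepts(self) -> list[Concept]:
        return list(self._concepts.values())

    @property
    def concept_ids(self) -> list[str]:
        return list(self._concepts)

    @property
    def influences(self) -> list[Influence]:
        return list(self._influences.values())

    @property
    def n_concepts(self) -> int:
        return len(self._concepts)

    @property
    def n_influences(self) -> int:
        return len(self._influences)

    def __contains__(self, cid: str) -> bool:
        return cid in self._concepts

    def has_indeterminate(self) -> bool:
        return any(e.is_indeterminate for e in self._influences.values())

    def index_of(self, cid: str) -> int:
        try:
            return self.concept_ids.index(cid)
        except ValueError:
            raise UnknownConceptError(f"unknown concept {cid!r}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConceptNetwork):
            return NotImplemented
        return (set(self._concepts) == set(other._concepts)
                and self._influences == other._influences)

    def adjacency(self) -> sp.csr_matrix:
        """Sparse weight matrix W with W[i, j] = weight of concept_i -> concept_j.

        Raises :class:`EnginePreconditionError` via the engine if
        indeterminate weights remain; here indeterminates raise directly.
        """
        from .errors import EnginePreconditionError

        idx = {cid: i for i, cid in enumerate(self._concepts)}
        rows, cols, vals = [], [], []
        for e in self._influences.values():
            if e.is_indeterminate:
                raise EnginePreconditionError(
                    f"unresolved indeterminate weight {e.source}->{e.target}; "
                    "call resolve_indeterminates first"
                )
            rows.append(idx[e.source])
            cols.append(idx[e.target])
            vals.append(e.weight)
        n = len(idx)
        return sp.csr_matrix(
            (np.asarray(vals, dtype=float), (rows, cols)), shape=(n, n)
        )


# -- edge-list dialect ----------------------------------------------------
#
# Whitespace- or comma-delimited; '#' starts a comment; optional header line
# "source target weight"; 'I'/'i' is the only indeterminate token.

_HEADER_TOKENS = {"source", "src", "from"}


def _split(line: str) -> list[str]:
    if "," in line:
        return [tok.strip() for tok in line.split(",")]
    return line.split()


def parse_network(text: str,
                  concepts: Mapping[str, Concept] | Iterable[Concept] | None = None,
                  ) -> ConceptNetwork:
    """Parse an edge-list text into a :class:`ConceptNetwork`.

    Each record is ``source target weight`` where weight is a decimal
    literal in [-1, 1] \\ {0} or the token ``I`` (case-insensitive).
    Concepts are auto-registered from edge endpoints unless a concept table
    is supplied, in which case endpoints must name known concepts.
    """
    net = ConceptNetwork()
    strict = concepts is not None
    if concepts is not None:
        it = concepts.values() if isinstance(concepts, Mapping) else concepts
        for c in it:
            net.add_concept(c)
    seen_data = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = _split(line)
        if len(fields) != 3:
            raise NetworkFormatError(
                f"line {lineno}: expected 3 fields (source target weight), "
                f"got {len(fields)}"
            )
        src, tgt, wtok = fields
        if not seen_data and src.lower() in _HEADER_TOKENS:
            continue
        seen_data = True
        if wtok.upper() == INDETERMINATE:
            weight: Weight = INDETERMINATE
        else:
            try:
                weight = float(wtok)
            except ValueError:
                raise MalformedWeightError(
                    f"line {lineno}: weight {wtok!r} is not a number or 'I'"
                ) from None
        try:
            inf = Influence(src, tgt, weight)
            net.add_influence(inf, auto_register=not strict)
        except (MalformedWeightError, DuplicateEdgeError, NetworkFormatError,
                UnknownConceptError) as exc:
            raise type(exc)(f"line {lineno}: {exc}") from None
    return net


def write_network(net: ConceptNetwork) -> str:
    """Serialize to the edge-list dialect, sorted by (source, target).

    ``parse_network(write_network(net))`` reproduces the network (up to
    concept metadata, which lives in the optional concept table).
    """
    buf = io.StringIO()
    buf.write("source\ttarget\tweight\n")
    for e in sorted(net.influences, key=lambda e: (e.source, e.target)):
        w = INDETERMINATE if e.is_indeterminate else repr(e.weight)
        buf.write(f"{e.source}\t{e.target}\t{w}\n")
    return buf.getvalue()


def read_network(path, concepts_path=None) -> ConceptNetwork:
    """Read an edge-list file, optionally with a concept table.

    The concept table is TSV/CSV with columns id, label, category.
    """
    concepts = None
    if concepts_path is not None:
        concepts = []
        with open(concepts_path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                # tab-first split so labels may contain spaces and commas
                fields = ([f.strip() for f in line.split("\t")]
                          if "\t" in line else _split(line))
                if lineno == 1 and fields[0].lower() in {"id", "concept"}:
                    continue
                if len(fields) < 3:
                    raise NetworkFormatError(
                        f"{concepts_path}: line {lineno}: expected id, label, "
                        "category"
                    )
                concepts.append(Concept(fields[0], fields[1], fields[2]))
    with open(path, encoding="utf-8") as fh:
        return parse_network(fh.read(), concepts=concepts)


def save_network(net: ConceptNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_network(net))


def to_graphml(net: ConceptNetwork, path) -> None:
    """Export for graph viewers; indeterminate edges get weight 0 and an
    ``indeterminate`` attribute."""
    import networkx as nx

    g = nx.DiGraph()
    for c in net.concepts:
        g.add_node(c.id, label=c.label, category=c.category)
    for e in net.influences:
        g.add_edge(
            e.source, e.target,
            weight=0.0 if e.is_indeterminate else float(e.weight),
            indeterminate=e.is_indeterminate,
        )
    nx.write_graphml(g, path)


# -- summary statistics ----------------------------------------------------

def positive_fraction(net: ConceptNetwork) -> float:
    """Share of determinate influences with positive weight.

    Indeterminate influences are excluded from numerator and denominator.
    """
    det = [e for e in net.influences if not e.is_indeterminate]
    if not det:
        raise UndefinedFractionError(
            "positive fraction undefined: no determinate influences"
        )
    return sum(1 for e in det if e.weight > 0) / len(det)


def degree_summary(net: ConceptNetwork) -> tuple[float, float]:
    """(mean in-degree, mean out-degree); the two are equal by construction
    since every influence contributes one of each."""
    if net.n_concepts == 0:
        raise NetworkFormatError("degree summary undefined on empty network")
    mean = net.n_influences / net.n_concepts
    return mean, mean
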
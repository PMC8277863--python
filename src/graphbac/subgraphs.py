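"""Connected-subgraph enumeration and the molecule x pattern frequency matrix.

Every connected subset of 1..max_edges edges of a master graph is a
"group": a molecular fragment in the group-additivity sense.  Fragments
are identified up to isomorphism by the canonical key of their labeled
graph, so rotations, reflections and atom-numbering choices collapse to
one column.  Zeroth-order groups are the heavy-atom element counts plus
one special descriptor for the lumped hydrogens.

The counting unit is the distinct connected *edge subset*: a symmetric
pattern is counted once per subset, not once per automorphic embedding,
which keeps coefficients interpretable as per-occurrence group energies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .molgraph import MasterGraph, canonical_key, render_label, total_hydrogens

#: Default fragment size cutoff, in edges ("linkages").
DEFAULT_MAX_EDGES = 4

#: Canonical key of the lumped-hydrogen zeroth-order descriptor.
HYDROGEN_KEY = "H"


@dataclass(frozen=True)
class SubgraphPattern:
    """Canonical representative of an isomorphism class of fragments."""

    key: str
    n_edges: int
    label: str

    def __lt__(self, other: "SubgraphPattern") -> bool:
        return (self.n_edges, self.key) < (other.n_edges, other.key)


HYDROGEN_PATTERN = SubgraphPattern(HYDROGEN_KEY, 0, "H")


def _atom_pattern(element: str) -> SubgraphPattern:
    return SubgraphPattern(canonical_key((element,), ()), 0, element)


def _connected_edge_subsets(
    edges: Sequence[tuple[int, int, int]], max_edges: int
) -> set[frozenset[int]]:
    """All connected subsets of 1..max_edges edge indices.

    Grown breadth-first: a subset of size k+1 is some size-k subset plus
    an incident edge, so extending every frontier subset by every
    incident edge (deduplicated as frozensets) is exhaustive.
    """
    m = len(edges)
    incident: list[set[int]] = [set() for _ in range(m)]
    for a in range(m):
        ia, ja, _ = edges[a]
        for b in range(a + 1, m):
            ib, jb, _ = edges[b]
            if len({ia, ja} & {ib, jb}) > 0:
                incident[a].add(b)
                incident[b].add(a)
    frontier: set[frozenset[int]] = {frozenset([i]) for i in range(m)}
    results: set[frozenset[int]] = set(frontier)
    for _ in range(max_edges - 1):
        nxt: set[frozenset[int]] = set()
        for subset in frontier:
            reachable: set[int] = set()
            for e in subset:
                reachable |= incident[e]
            for e in reachable - subset:
                nxt.add(subset | {e})
        nxt -= results
        results |= nxt
        frontier = nxt
    return results


def _subset_pattern(
    g: MasterGraph, subset: Iterable[int]
) -> SubgraphPattern:
    picked = [g.edges[e] for e in sorted(subset)]
    nodes = sorted({v for i, j, _ in picked for v in (i, j)})
    relabel = {v: k for k, v in enumerate(nodes)}
    labels = tuple(g.elements[v] for v in nodes)
    sub_edges = tuple(
        (min(relabel[i], relabel[j]), max(relabel[i], relabel[j]), o)
        for i, j, o in picked
    )
    key = canonical_key(labels, sub_edges)
    return SubgraphPattern(key, len(sub_edges), render_label(labels, sub_edges))


def enumerate_subgraphs(
    g: MasterGraph, max_edges: int = DEFAULT_MAX_EDGES
) -> dict[SubgraphPattern, int]:
    """Count every connected fragment of ``g`` up to ``max_edges`` edges.

    Returns a mapping from pattern to frequency.  Zeroth-order entries
    are one pattern per element present (count = number of such nodes)
    plus the hydrogen descriptor (count = total lumped hydrogens, present
    only when the molecule contains hydrogen).
    """
    if max_edges < 0:
        raise ValueError("max_edges must be nonnegative")
    counts: dict[SubgraphPattern, int] = {}
    for element in sorted(set(g.elements)):
        counts[_atom_pattern(element)] = g.elements.count(element)
    n_h = total_hydrogens(g)
    if n_h:
        counts[HYDROGEN_PATTERN] = n_h
    if max_edges == 0:
        return counts
    for subset in _connected_edge_subsets(g.edges, max_edges):
        pattern = _subset_pattern(g, subset)
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def count_pattern(g: MasterGraph, p: SubgraphPattern) -> int:
    """Frequency of one pattern in one molecule (0 if absent)."""
    counts = enumerate_subgraphs(g, max_edges=p.n_edges)
    for pattern, c in counts.items():
        if pattern.key == p.key:
            return c
    return 0


@dataclass(frozen=True)
class FeatureTable:
    """Molecule x pattern frequency matrix with its pattern registry.

    ``frame`` holds the nonnegative integer frequencies d_ij with
    molecule ids as the index and canonical keys as columns; ``patterns``
    is the column registry in the same (deterministic) order: ascending
    edge count, then lexicographic key.
    """

    frame: pd.DataFrame
    patterns: tuple[SubgraphPattern, ...]

    @property
    def molecule_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def keys(self) -> tuple[str, ...]:
        return tuple(p.key for p in self.patterns)

    def pattern_by_key(self, key: str) -> SubgraphPattern:
        for p in self.patterns:
            if p.key == key:
                return p
        raise KeyError(key)

    def to_csv(self, path: str) -> None:
        self.frame.to_csv(path, index_label="id")

    def registry_to_json(self, path: str) -> None:
        payload = {p.key: {"n_edges": p.n_edges, "label": p.label} for p in self.patterns}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_csv(cls, table_path: str, registry_path: str) -> "FeatureTable":
        frame = pd.read_csv(table_path, index_col="id")
        with open(registry_path, encoding="utf-8") as fh:
            registry = json.load(fh)
        patterns = tuple(
            SubgraphPattern(key, registry[key]["n_edges"], registry[key]["label"])
            for key in frame.columns
        )
        return cls(frame, patterns)


def build_feature_table(
    molecules: Sequence[MasterGraph], max_edges: int = DEFAULT_MAX_EDGES
) -> FeatureTable:
    """Assemble the frequency matrix over a molecule set.

    Columns are the union of patterns observed anywhere in the set, in
    registry order; a pattern absent from a molecule has frequency 0.
    Molecule ids must be unique.
    """
    if len(molecules) == 0:
        raise ValueError("molecule sequence must be non-empty")
    ids = [g.id for g in molecules]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate molecule ids: {dup}")
    per_mol: list[dict[str, int]] = []
    registry: dict[str, SubgraphPattern] = {}
    for g in molecules:
        counts = enumerate_subgraphs(g, max_edges=max_edges)
        per_mol.append({p.key: c for p, c in counts.items()})
        for p in counts:
            registry.setdefault(p.key, p)
    patterns = tuple(sorted(registry.values()))
    frame = pd.DataFrame(
        [[row.get(p.key, 0) for p in patterns] for row in per_mol],
        index=pd.Index(ids, name="id"),
        columns=[p.key for p in patterns],
        dtype=int,
    )
    return FeatureTable(frame, patterns)


def pattern_from_fragment(fragment: str) -> SubgraphPattern:
    """Build a pattern from chain notation, e.g. ``"C-C=O"`` or ``"C"``.

    Only linear fragments (and single atoms, including the hydrogen
    descriptor ``"H"``) are expressible this way; it is a convenience for
    specifying truth models and reading coefficients, not a SMILES parser.
    """
    frag = fragment.strip()
    if frag == "H":
        return HYDROGEN_PATTERN
    labels: list[str] = []
    orders: list[int] = []
    token = ""
    bond_of = {"-": 1, "=": 2, "#": 3}
    for ch in frag:
        if ch in bond_of:
            if not token:
                raise ValueError(f"malformed fragment {fragment!r}")
            labels.append(token)
            orders.append(bond_of[ch])
            token = ""
        else:
            token += ch
    if not token:
        raise ValueError(f"malformed fragment {fragment!r}")
    labels.append(token)
    edges = tuple((i, i + 1, o) for i, o in enumerate(orders))
    key = canonical_key(tuple(labels), edges)
    return SubgraphPattern(key, len(edges), render_label(tuple(labels), edges))


def registry_counts(
    counts: Mapping[SubgraphPattern, int]
) -> dict[str, int]:
    """Collapse a pattern->count mapping to canonical-key->count."""
    return {p.key: c for p, c in counts.items()}
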
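"""Hydrogen-lumped labeled molecular graphs ("master graphs").

A molecule is represented as a labeled graph whose nodes are the heavy
atoms (C, N, O, P by default) and whose edges carry covalent bond orders
1, 2 or 3.  Hydrogens are never nodes: each heavy atom records the number
of hydrogens bonded to it (``implicit_h``), and a molecule with no heavy
atoms at all (H2) records its hydrogens in ``free_hydrogens``.  Aromatic
systems are kekulized before graph construction so that every edge fits
the {single, double, triple} alphabet.

Canonical keys for small labeled graphs are computed by exhaustive
permutation search, which is exact and cheap for the graph sizes that
arise from subgraph enumeration (at most ``max_edges + 1`` nodes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

from rdkit import Chem

#: Heavy-atom alphabet. Hydrogen is handled by lumping, never as a node.
DEFAULT_ELEMENTS: frozenset[str] = frozenset({"C", "N", "O", "P"})

#: Rendering characters for bond orders.
BOND_CHARS = {1: "-", 2: "=", 3: "#"}

# Permutation canonicalization is exact but factorial; subgraph patterns
# never exceed max_edges + 1 nodes, and whole-molecule keys are only used
# on small test molecules.
_MAX_CANON_NODES = 9


class MoleculeError(ValueError):
    """Raised when a structure cannot be represented as a master graph."""


@dataclass(frozen=True)
class MasterGraph:
    """Hydrogen-lumped molecular graph.

    Parameters
    ----------
    id
        Text label for the molecule.
    elements
        Element symbol per node; node ids are positions in this tuple.
    implicit_h
        Number of lumped hydrogens per node, aligned with ``elements``.
    edges
        Bonds as ``(i, j, order)`` with ``i < j`` and order in {1, 2, 3}.
    free_hydrogens
        Hydrogens not attached to any heavy atom; nonzero only for
        hydrogen-only species such as H2 (which has zero nodes).
    """

    id: str
    elements: tuple[str, ...]
    implicit_h: tuple[int, ...]
    edges: tuple[tuple[int, int, int], ...]
    free_hydrogens: int = 0
    allowed_elements: frozenset[str] = field(default=DEFAULT_ELEMENTS, compare=False)

    def __post_init__(self) -> None:
        n = len(self.elements)
        if len(self.implicit_h) != n:
            raise MoleculeError("implicit_h must align with elements")
        if any(h < 0 for h in self.implicit_h):
            raise MoleculeError("negative implicit hydrogen count")
        if self.free_hydrogens < 0:
            raise MoleculeError("negative free hydrogen count")
        if n > 0 and self.free_hydrogens:
            raise MoleculeError("free hydrogens only allowed on hydrogen-only species")
        bad = set(self.elements) - self.allowed_elements
        if bad:
            raise MoleculeError(f"unsupported element(s): {sorted(bad)}")
        seen: set[tuple[int, int]] = set()
        for i, j, order in self.edges:
            if not (0 <= i < n and 0 <= j < n):
                raise MoleculeError("edge endpoint out of range")
            if i == j:
                raise MoleculeError("self-loops are not allowed")
            if i > j:
                raise MoleculeError("edges must be stored with i < j")
            if (i, j) in seen:
                raise MoleculeError("duplicate edge")
            if order not in (1, 2, 3):
                raise MoleculeError(f"bond order {order} outside {{1,2,3}}")
            seen.add((i, j))
        if not _is_connected(n, [(i, j) for i, j, _ in self.edges]):
            raise MoleculeError(f"molecule {self.id!r} is not a single connected species")

    @property
    def n_nodes(self) -> int:
        return len(self.elements)

    def neighbors(self, node: int) -> list[tuple[int, int]]:
        """``(neighbor, bond order)`` pairs of ``node``."""
        out = []
        for i, j, order in self.edges:
            if i == node:
                out.append((j, order))
            elif j == node:
                out.append((i, order))
        return out

    def molecule_key(self) -> str:
        """Canonical key of the whole graph with H counts in the labels.

        Two master graphs get the same key exactly when they describe the
        same hydrogen-lumped structure, regardless of input atom order.
        """
        if self.n_nodes == 0:
            return f"H{self.free_hydrogens}"
        labels = tuple(
            f"{el}H{h}" if h else el for el, h in zip(self.elements, self.implicit_h)
        )
        return canonical_key(labels, self.edges)


def total_hydrogens(g: MasterGraph) -> int:
    """Total hydrogen count of the molecule (all hydrogens are lumped)."""
    return sum(g.implicit_h) + g.free_hydrogens


def _is_connected(n_nodes: int, edges: Iterable[tuple[int, int]]) -> bool:
    if n_nodes <= 1:
        return True
    adj: dict[int, list[int]] = {i: [] for i in range(n_nodes)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == n_nodes


def canonical_key(
    labels: Sequence[str], edges: Iterable[tuple[int, int, int]]
) -> str:
    """Canonical text key of a small connected labeled graph.

    The key is the lexicographic minimum, over all node orderings, of
    ``"<labels>|<upper-triangle bond orders>"`` where absent edges encode
    as 0.  Two graphs share a key iff a node bijection preserves labels
    and bond orders.  Only orderings that sort the labels are searched,
    which prunes the permutation space without losing the minimum.
    """
    labels = tuple(labels)
    edges = tuple(edges)
    n = len(labels)
    if n == 0:
        raise MoleculeError("empty graph has no canonical key")
    if n > _MAX_CANON_NODES:
        raise MoleculeError(f"graph too large for permutation canonicalization ({n} nodes)")
    if not _is_connected(n, [(i, j) for i, j, _ in edges]):
        raise MoleculeError("canonical_key requires a connected graph")
    return _canonical_key_cached(labels, edges)


@lru_cache(maxsize=200_000)
def _canonical_key_cached(
    labels: tuple[str, ...], edges: tuple[tuple[int, int, int], ...]
) -> str:
    n = len(labels)
    order_of: dict[tuple[int, int], int] = {}
    for i, j, o in edges:
        order_of[(i, j)] = o
        order_of[(j, i)] = o
    sorted_labels = tuple(sorted(labels))
    best: str | None = None
    for perm in itertools.permutations(range(n)):
        if tuple(labels[v] for v in perm) != sorted_labels:
            continue
        adj = "".join(
            str(order_of.get((perm[a], perm[b]), 0))
            for a in range(n)
            for b in range(a + 1, n)
        )
        cand = ",".join(sorted_labels) + "|" + adj
        if best is None or cand < best:
            best = cand
    assert best is not None
    return best


def render_label(labels: Sequence[str], edges: Sequence[tuple[int, int, int]]) -> str:
    """Human-readable rendering of a small labeled graph.

    Simple paths render in the field's chain notation (``C-C=O``); other
    topologies (rings, branches) fall back to the canonical key.
    """
    labels = tuple(labels)
    if len(labels) == 1:
        return labels[0]
    degree = [0] * len(labels)
    for i, j, _ in edges:
        degree[i] += 1
        degree[j] += 1
    ends = [v for v, d in enumerate(degree) if d == 1]
    is_path = len(ends) == 2 and all(d <= 2 for d in degree)
    if not is_path:
        return canonical_key(labels, edges)
    order_of = {}
    adj: dict[int, list[int]] = {v: [] for v in range(len(labels))}
    for i, j, o in edges:
        order_of[(i, j)] = order_of[(j, i)] = o
        adj[i].append(j)
        adj[j].append(i)

    def walk(start: int) -> str:
        out = [labels[start]]
        prev, cur = None, start
        while True:
            nxt = [v for v in adj[cur] if v != prev]
            if not nxt:
                return "".join(out)
            out.append(BOND_CHARS[order_of[(cur, nxt[0])]])
            out.append(labels[nxt[0]])
            prev, cur = cur, nxt[0]

    return min(walk(ends[0]), walk(ends[1]))


def _structure_to_mol(structure: str) -> Chem.Mol:
    text = structure.strip()
    if "\n" in structure or "V2000" in structure or "V3000" in structure:
        mol = Chem.MolFromMolBlock(structure, sanitize=True, removeHs=False)
    else:
        mol = Chem.MolFromSmiles(text, sanitize=True)
    if mol is None:
        raise MoleculeError(f"could not parse structure: {text[:60]!r}")
    return mol


def parse_molecule(
    structure: str,
    id: str | None = None,
    elements: frozenset[str] = DEFAULT_ELEMENTS,
) -> MasterGraph:
    """Parse a SMILES string or MOL/SDF block into a :class:`MasterGraph`.

    The species must be a single-component neutral molecule over
    C/H/O/N/P.  Aromatic systems are kekulized so every bond maps onto
    the {single, double, triple} alphabet; explicit hydrogens are folded
    into their heavy-atom neighbor's lumped count.  Radicals are allowed:
    hydrogen counts follow the input's explicit valence, not a standard
    valence table.

    Raises
    ------
    MoleculeError
        For unsupported elements (named in the message), multi-component
        structures, net formal charge, or unkekulizable aromatic input.
    """
    mol = _structure_to_mol(structure)
    label = id if id is not None else structure.strip()

    if len(Chem.GetMolFrags(mol)) > 1:
        raise MoleculeError(f"{label}: multi-component (disconnected) structure")
    if Chem.GetFormalCharge(mol) != 0:
        raise MoleculeError(f"{label}: net formal charge {Chem.GetFormalCharge(mol)} (only neutral species supported)")
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym != "H" and sym not in elements:
            raise MoleculeError(f"{label}: unsupported element {sym}")
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Chem.KekulizeException as exc:  # pragma: no cover - rdkit message varies
        raise MoleculeError(f"{label}: unkekulizable aromatic system") from exc

    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    if not heavy:
        n_h = sum(1 + a.GetTotalNumHs() for a in mol.GetAtoms())
        return MasterGraph(label, (), (), (), free_hydrogens=n_h, allowed_elements=elements)

    index = {a.GetIdx(): k for k, a in enumerate(heavy)}
    node_elements = tuple(a.GetSymbol() for a in heavy)
    node_h = tuple(a.GetTotalNumHs(includeNeighbors=True) for a in heavy)
    graph_edges = []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        order = bond.GetBondTypeAsDouble()
        if order not in (1.0, 2.0, 3.0):
            raise MoleculeError(f"{label}: bond order {order} outside {{1,2,3}}")
        i, j = sorted((index[a.GetIdx()], index[b.GetIdx()]))
        graph_edges.append((i, j, int(order)))
    return MasterGraph(
        label,
        node_elements,
        node_h,
        tuple(sorted(graph_edges)),
        allowed_elements=elements,
    )


def parse_smiles_file(path: str, elements: frozenset[str] = DEFAULT_ELEMENTS) -> list[MasterGraph]:
    """Parse a one-SMILES-per-line text file."""
    graphs = []
    with open(path, encoding="utf-8") as fh:
        for k, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            graphs.append(parse_molecule(line, id=f"line{k + 1}", elements=elements))
    return graphs
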
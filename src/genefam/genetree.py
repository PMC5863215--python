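"""Gene-tree construction, species-tree reconciliation and NHX io.

Per family, five candidate trees are built by neighbor joining on five
distance estimators over the protein and codon alignments.  Every
candidate is rooted on every edge and reconciled against the species
tree by standard last-common-ancestor mapping; the (candidate, root)
pair minimizing (duplications, losses, total branch length, serialized
form) wins.  Internal nodes are annotated as speciation (S) or
duplication (D); duplication nodes carry a duplication consistency
score (DCS), the Jaccard overlap of the species sets under the two
children.  Trees serialize to Newick with NHX comments.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .msa import CodonAlignment, ProteinAlignment
from .preparation import demangle_id

#: ceiling applied when a distance correction is undefined (p too large)
MAX_DISTANCE = 10.0


class TreeError(ValueError):
    pass


class Node:
    """Rooted tree node; leaves carry a sequence id and a species label."""

    __slots__ = ("name", "length", "children", "species", "event", "dcs")

    def __init__(
        self,
        name: str = "",
        length: float | None = None,
        children: list["Node"] | None = None,
        species: str = "",
    ) -> None:
        self.name = name
        self.length = length
        self.children: list[Node] = children or []
        self.species = species
        self.event: str | None = None  # 'S' or 'D' on internal nodes
        self.dcs: float | None = None

    # -- traversal ------------------------------------------------------

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterable["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def min_leaf(self) -> str:
        return min(self.leaf_names())

    def copy(self) -> "Node":
        n = Node(self.name, self.length, [c.copy() for c in self.children], self.species)
        n.event = self.event
        n.dcs = self.dcs
        return n

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n.length is not None)

    # -- serialization --------------------------------------------------

    def _nhx_comment(self) -> str:
        if self.is_leaf():
            return f"[&&NHX:S={self.species}]" if self.species else ""
        if self.event is None:
            return ""
        parts = [f"D={'Y' if self.event == 'D' else 'N'}"]
        if self.species:
            parts.append(f"S={self.species}")
        if self.event == "D" and self.dcs is not None:
            parts.append("DCS=" + _fmt_float(self.dcs))
        return "[&&NHX:" + ":".join(parts) + "]"

    def to_newick(self, nhx: bool = False, _root: bool = True) -> str:
        if self.is_leaf():
            s = self.name
        else:
            inner = ",".join(c.to_newick(nhx, _root=False) for c in self.children)
            s = f"({inner}){self.name}"
        if self.length is not None and not _root:
            s += ":" + _fmt_float(self.length)
        if nhx:
            s += self._nhx_comment()
        return s + (";" if _root else "")


def _fmt_float(x: float) -> str:
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


# -- Newick / NHX parsing -----------------------------------------------

_TOKEN = re.compile(r"\s*(\(|\)|,|;|\[&&NHX:[^\]]*\]|:[-0-9.eE+]+|[^():,;\[\]]+)")


def parse_newick(text: str) -> Node:
    """Parse a Newick string, interpreting ``[&&NHX:...]`` annotations."""
    pos = 0
    tokens: list[str] = []
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise TreeError(f"unparseable Newick near index {pos}: {text[pos:pos+20]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    if not tokens or tokens[-1] != ";":
        raise TreeError("Newick string must end with ';'")

    idx = 0

    def parse_node() -> Node:
        nonlocal idx
        node = Node()
        if tokens[idx] == "(":
            idx += 1
            while True:
                node.children.append(parse_node())
                if tokens[idx] == ",":
                    idx += 1
                    continue
                if tokens[idx] == ")":
                    idx += 1
                    break
                raise TreeError(f"expected ',' or ')', got {tokens[idx]!r}")
        # optional label, branch length, NHX comment (in that order)
        if idx < len(tokens) and tokens[idx] not in "(),;" and not tokens[idx].startswith(
            (":", "[")
        ):
            node.name = tokens[idx].strip()
            idx += 1
        if idx < len(tokens) and tokens[idx].startswith(":"):
            node.length = float(tokens[idx][1:])
            idx += 1
        if idx < len(tokens) and tokens[idx].startswith("[&&NHX:"):
            _apply_nhx(node, tokens[idx][7:-1])
            idx += 1
        return node

    root = parse_node()
    if tokens[idx] != ";":
        raise TreeError(f"trailing content after tree: {tokens[idx:]!r}")
    return root


def _apply_nhx(node: Node, body: str) -> None:
    fields: dict[str, str] = {}
    for item in body.split(":"):
        if not item:
            continue
        key, _, val = item.partition("=")
        fields[key] = val
    if node.is_leaf():
        node.species = fields.get("S", "")
    else:
        if "D" in fields:
            node.event = "D" if fields["D"] == "Y" else "S"
        node.species = fields.get("S", "")
        if "DCS" in fields:
            node.dcs = float(fields["DCS"])


def write_nhx(tree: Node, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick(nhx=True) + "\n")


def read_nhx(path: str | Path) -> Node:
    return parse_newick(Path(path).read_text().strip())


# -- species tree -------------------------------------------------------

class SpeciesTree:
    """Rooted species tree; multifurcations are resolved on load.

    Polytomies are resolved deterministically (children ordered by their
    smallest leaf label, folded left into zero-length binary nodes), and
    unnamed internal nodes are labelled ``<smallest leaf>.<leaf count>``
    so every reconciliation target has a stable name.
    """

    def __init__(self, root: Node) -> None:
        self.root = root
        _resolve_polytomies(self.root)
        self._autolabel()
        leaves = self.root.leaf_names()
        if len(set(leaves)) != len(leaves):
            raise TreeError("duplicate species labels in species tree")
        self.parent: dict[int, Node | None] = {id(self.root): None}
        self.depth: dict[int, int] = {id(self.root): 0}
        self.by_label: dict[str, Node] = {}
        for node in self.root.postorder():
            if node.name:
                self.by_label[node.name] = node
            for c in node.children:
                self.parent[id(c)] = node
                self.depth[id(c)] = 0
        # recompute depths top-down
        def set_depth(n: Node, d: int) -> None:
            self.depth[id(n)] = d
            for c in n.children:
                set_depth(c, d + 1)

        set_depth(self.root, 0)

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        return cls(parse_newick(text))

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesTree":
        return cls.from_newick(Path(path).read_text().strip())

    def _autolabel(self) -> None:
        for node in self.root.postorder():
            if not node.is_leaf() and not node.name:
                node.name = f"{node.min_leaf()}.{len(node.leaves())}"

    @property
    def species(self) -> list[str]:
        return sorted(self.root.leaf_names())

    def node_of(self, label: str) -> Node:
        node = self.by_label.get(label)
        if node is None:
            raise TreeError(f"species label {label!r} not in species tree")
        return node

    def lca(self, labels: Iterable[str]) -> Node:
        nodes = [self.node_of(l) for l in set(labels)]
        if not nodes:
            raise TreeError("lca of empty label set")
        current = nodes[0]
        for other in nodes[1:]:
            a, b = current, other
            while id(a) != id(b):
                da, db = self.depth[id(a)], self.depth[id(b)]
                if da >= db:
                    a = self.parent[id(a)]
                else:
                    b = self.parent[id(b)]
            current = a
        return current

    def to_newick(self) -> str:
        return self.root.to_newick()


def _resolve_polytomies(node: Node) -> None:
    for c in node.children:
        _resolve_polytomies(c)
    node.children.sort(key=lambda c: c.min_leaf())
    while len(node.children) > 2:
        a, b = node.children[0], node.children[1]
        merged = Node(length=0.0, children=[a, b])
        node.children = [merged] + node.children[2:]
        node.children.sort(key=lambda c: c.min_leaf())


def species_tree_from_taxonomy(taxa: Iterable[tuple[str, str]]) -> SpeciesTree:
    """Build a species tree from (label, parent_label) rows.

    Labels never used as a parent become the leaves.  Unary internal
    nodes are collapsed; the single remaining root anchors the tree.
    """
    rows = list(taxa)
    children: dict[str, list[str]] = {}
    labels: set[str] = set()
    parent_of: dict[str, str] = {}
    for label, parent in rows:
        if label in parent_of:
            raise TreeError(f"label {label!r} listed twice")
        parent_of[label] = parent
        labels.add(label)
        if parent:
            labels.add(parent)
            children.setdefault(parent, []).append(label)

    roots = sorted(l for l in labels if not parent_of.get(l))
    if len(roots) != 1:
        raise TreeError(f"taxonomy must have exactly one root, found {roots}")

    # cycle check: every label must reach the root
    for label in labels:
        seen = set()
        cur = label
        while parent_of.get(cur):
            if cur in seen:
                raise TreeError(f"cycle in taxonomy involving {cur!r}")
            seen.add(cur)
            cur = parent_of[cur]
        if cur != roots[0]:
            raise TreeError(f"label {label!r} does not reach the root")

    def build(label: str) -> Node:
        kids = sorted(children.get(label, []))
        if not kids:
            return Node(name=label, length=1.0)
        built = [build(k) for k in kids]
        if len(built) == 1:  # collapse unary nodes
            return built[0]
        return Node(name=label, length=1.0, children=built)

    return SpeciesTree(build(roots[0]))


# -- distance estimation ------------------------------------------------

def _pairwise_sites(a: str, b: str, stride: int = 1, offset: int = 0) -> tuple[int, int]:
    """(differing, compared) site counts with pairwise deletion of gaps."""
    diff = comp = 0
    for i in range(offset, len(a), stride):
        x, y = a[i], b[i]
        if x == "-" or y == "-" or x == "X" or y == "X" or x == "N" or y == "N":
            continue
        comp += 1
        if x != y:
            diff += 1
    return diff, comp


def _p_distance(a: str, b: str, stride: int = 1, offset: int = 0) -> float:
    diff, comp = _pairwise_sites(a, b, stride, offset)
    if comp == 0:
        raise TreeError("all-gap pairwise overlap")
    return diff / comp


def _poisson(p: float) -> float:
    if p >= 1.0 - math.exp(-MAX_DISTANCE):
        return MAX_DISTANCE
    return -math.log(1.0 - p)


def _jukes_cantor(p: float) -> float:
    limit = 0.75 * (1.0 - math.exp(-4.0 * MAX_DISTANCE / 3.0))
    if p >= limit:
        return MAX_DISTANCE
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _matrix(ids: list[str], rows: dict[str, str], fn: Callable[[str, str], float]) -> DistanceMatrix:
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = fn(rows[ids[i]], rows[ids[j]])
            except TreeError as exc:
                raise TreeError(f"pair ({ids[i]}, {ids[j]}): {exc}") from exc
            m[i, j] = m[j, i] = d
    return DistanceMatrix(m, ids)


def _from_skbio(sk_node) -> Node:
    node = Node(
        name=sk_node.name or "",
        length=None if sk_node.length is None else max(0.0, float(sk_node.length)),
    )
    node.children = [_from_skbio(c) for c in sk_node.children]
    return node


def neighbor_joining(dm: DistanceMatrix) -> Node:
    """Neighbor joining; negative branch lengths clamped to zero."""
    if len(dm.ids) < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    tree = _skbio_nj(dm)
    root = _from_skbio(tree.root())
    # drop skbio's zero-length internal bookkeeping nodes of degree 2
    def collapse(n: Node) -> None:
        for c in n.children:
            collapse(c)
        if len(n.children) == 1 and not n.children[0].is_leaf():
            only = n.children[0]
            n.children = only.children
    collapse(root)
    return root


def build_candidate_trees(
    codon_aln: CodonAlignment, prot_aln: ProteinAlignment
) -> list[Node]:
    """Five unrooted NJ trees from five distance estimators.

    Estimators: protein p-distance, Poisson-corrected protein distance,
    nucleotide p-distance, Jukes-Cantor nucleotide distance, and a
    synonymous proxy (p-distance at third codon positions).  Sites with
    a gap or ambiguity in either row are excluded pairwise; undefined
    corrections are clamped at ``MAX_DISTANCE``.
    """
    ids = sorted(prot_aln.rows)
    if sorted(codon_aln.rows) != ids:
        raise TreeError("protein and codon alignments disagree on sequence ids")
    if len(ids) < 3:
        raise TreeError("gene tree needs at least 3 sequences")
    p_rows, c_rows = prot_aln.rows, codon_aln.rows
    estimators: list[DistanceMatrix] = [
        _matrix(ids, p_rows, lambda a, b: _p_distance(a, b)),
        _matrix(ids, p_rows, lambda a, b: _poisson(_p_distance(a, b))),
        _matrix(ids, c_rows, lambda a, b: _p_distance(a, b)),
        _matrix(ids, c_rows, lambda a, b: _jukes_cantor(_p_distance(a, b))),
        _matrix(ids, c_rows, lambda a, b: _p_distance(a, b, stride=3, offset=2)),
    ]
    return [neighbor_joining(dm) for dm in estimators]


# -- rooting ------------------------------------------------------------

def _adjacency(root: Node) -> tuple[dict[int, list[tuple[int, float]]], dict[int, Node]]:
    nodes: dict[int, Node] = {}
    adj: dict[int, list[tuple[int, float]]] = {}
    def visit(n: Node) -> None:
        nodes[id(n)] = n
        adj.setdefault(id(n), [])
        for c in n.children:
            visit(c)
            w = c.length if c.length is not None else 0.0
            adj[id(n)].append((id(c), w))
            adj.setdefault(id(c), []).append((id(n), w))
    visit(root)
    return adj, nodes


def all_rootings(unrooted: Node) -> list[Node]:
    """Root the tree on every edge, splitting the edge length in half."""
    adj, nodes = _adjacency(unrooted)

    def build(nid: int, parent: int, length: float) -> Node:
        src = nodes[nid]
        fresh = Node(name=src.name, length=length, species=src.species)
        for other, w in adj[nid]:
            if other != parent:
                fresh.children.append(build(other, nid, w))
        fresh.children.sort(key=lambda c: c.min_leaf())
        return fresh

    rootings = []
    for nid, neighbors in adj.items():
        for other, w in neighbors:
            if nid < other:  # one rooting per undirected edge
                left = build(nid, other, w / 2.0)
                right = build(other, nid, w / 2.0)
                kids = sorted([left, right], key=lambda c: c.min_leaf())
                rootings.append(Node(children=kids))
    # suppress any degree-2 passthrough introduced when rooting next to
    # the original trifurcation
    cleaned = []
    for r in rootings:
        for node in r.postorder():
            node.children = [
                c if len(c.children) != 1 else _lift(c) for c in node.children
            ]
        cleaned.append(r)
    return cleaned


def _lift(n: Node) -> Node:
    only = n.children[0]
    only.length = (only.length or 0.0) + (n.length or 0.0)
    return only


# -- reconciliation -----------------------------------------------------

def leaf_species_map(leaf_ids: Iterable[str], species_labels: Iterable[str]) -> dict[str, str]:
    """Species of each mangled leaf id, by longest-suffix demangling."""
    labels = list(species_labels)
    out = {}
    for lid in leaf_ids:
        try:
            out[lid] = demangle_id(lid, labels)[1]
        except Exception as exc:
            raise TreeError(f"leaf {lid!r}: species unresolvable ({exc})") from exc
    return out


def reconcile(
    tree: Node, sp: SpeciesTree, species_of: dict[str, str] | None = None
) -> tuple[Node, int, int]:
    """Annotate a rooted gene tree with S/D events and count duplications/losses.

    Each node maps to the species-tree LCA of its leaf species.  A node
    is a duplication when it maps to the same species-tree node as
    either child; otherwise a speciation.  Losses follow the standard
    path-depth count: a speciation child contributes depth(child map) -
    depth(node map) - 1, a duplication child contributes the full depth
    difference.  Duplication nodes get DCS = |A intersect B| / |A union B|
    over the child species sets.
    """
    annotated = tree.copy()
    if species_of is None:
        species_of = leaf_species_map(annotated.leaf_names(), sp.species)

    mapping: dict[int, Node] = {}
    species_sets: dict[int, frozenset[str]] = {}
    for node in annotated.postorder():
        if node.is_leaf():
            label = species_of.get(node.name, node.species)
            if not label:
                raise TreeError(f"leaf {node.name!r}: species unresolvable")
            node.species = label
            mapping[id(node)] = sp.node_of(label)
            species_sets[id(node)] = frozenset([label])
        else:
            if len(node.children) != 2:
                raise TreeError("reconciliation requires a binary gene tree")
            species_sets[id(node)] = frozenset().union(
                *(species_sets[id(c)] for c in node.children)
            )
            mapping[id(node)] = sp.lca(species_sets[id(node)])

    dup_count = loss_count = 0
    for node in annotated.postorder():
        if node.is_leaf():
            continue
        m = mapping[id(node)]
        is_dup = any(id(mapping[id(c)]) == id(m) for c in node.children)
        node.event = "D" if is_dup else "S"
        node.species = m.name
        if is_dup:
            dup_count += 1
            a, b = (species_sets[id(c)] for c in node.children)
            node.dcs = len(a & b) / len(a | b)
        for c in node.children:
            d = sp.depth[id(mapping[id(c)])] - sp.depth[id(m)]
            loss_count += d if is_dup else max(d - 1, 0)
    return annotated, dup_count, loss_count


def select_and_root(
    candidates: list[Node], sp: SpeciesTree, species_of: dict[str, str] | None = None
) -> Node:
    """Best (candidate, rooting) by (duplications, losses, tree length, text)."""
    if not candidates:
        raise TreeError("no candidate trees")
    best_key = None
    best_tree = None
    for cand in candidates:
        for rooted in all_rootings(cand):
            annotated, dups, losses = reconcile(rooted, sp, species_of)
            key = (
                dups,
                losses,
                round(annotated.total_branch_length(), 9),
                annotated.to_newick(nhx=True),
            )
            if best_key is None or key < best_key:
                best_key = key
                best_tree = annotated
    return best_tree
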
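"""Tree I/O and per-species phylogenetic quantities.

Implements a small rooted-phylogeny model with branch lengths in time
units (Myr by convention), a Newick reader/writer, and the per-species
quantities used downstream:

* terminal branch lengths ("species ages"),
* fair-proportion evolutionary distinctiveness (ED),
* patristic distance matrices,
* the Brownian phylogenetic covariance matrix.

Polytomies are preserved everywhere; a root edge, if present in the
Newick string, is ignored by ED, distances and covariances since it is
shared by all tips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "Node",
    "Phylogeny",
    "DistanceMatrix",
    "PhyloCovariance",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "write_newick_file",
    "terminal_branch_lengths",
    "fair_proportion_ed",
    "patristic_distances",
    "phylo_vcv",
    "write_metrics_csv",
]


class NewickParseError(ValueError):
    """Malformed Newick input; carries the offending character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates a Phylogeny invariant."""


@dataclass
class Node:
    """A tree node; ``length`` is the edge above the node (None at an
    unrooted-style root with no root edge)."""

    label: str | None = None
    length: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)


class Phylogeny:
    """A rooted phylogeny with nonnegative branch lengths and unique
    tip labels."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self._validate()
        self._warn_zero_pendants()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        labels = self.tip_labels
        if len(labels) < 2:
            raise TreeValidationError(
                f"a phylogeny needs at least 2 tips, found {len(labels)}"
            )
        seen: set[str] = set()
        dupes = set()
        for lab in labels:
            if lab in seen:
                dupes.add(lab)
            seen.add(lab)
        if dupes:
            raise TreeValidationError(
                f"duplicate tip labels: {sorted(dupes)}"
            )
        if any(lab is None or lab == "" for lab in labels):
            raise TreeValidationError("unlabeled tip encountered")
        for node in self.root.preorder():
            if node is not self.root and node.length is not None and node.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.length} above "
                    f"{node.label or 'internal node'}"
                )

    def _warn_zero_pendants(self) -> None:
        zero = [t.label for t in self.tips if (t.length or 0.0) == 0.0]
        if zero:
            warnings.warn(
                f"zero-length pendant edges for {sorted(zero)}: species age is 0 "
                "and covariance matrices may be ill-conditioned",
                stacklevel=3,
            )

    # -- basic structure -----------------------------------------------

    @property
    def tips(self) -> list[Node]:
        return [n for n in self.root.preorder() if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def edge_lengths(self) -> list[float]:
        """Lengths of all edges below the root (the root edge excluded)."""
        return [
            n.length or 0.0 for n in self.root.preorder() if n is not self.root
        ]

    @property
    def total_length(self) -> float:
        return float(sum(self.edge_lengths()))

    def depths(self) -> dict[int, float]:
        """Root-to-node path length for every node, keyed by ``id(node)``.

        The root sits at depth 0; its own edge (if any) is ignored.
        """
        depth = {id(self.root): 0.0}
        for node in self.root.preorder():
            d = depth[id(node)]
            for child in node.children:
                depth[id(child)] = d + (child.length or 0.0)
        return depth

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depth = self.depths()
        tip_depths = [depth[id(t)] for t in self.tips]
        span = max(tip_depths) - min(tip_depths)
        scale = max(tip_depths) or 1.0
        return span <= rel_tol * scale

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<Phylogeny with {self.n_tips} tips, length {self.total_length:.4g}>"


# ---------------------------------------------------------------------
# Newick parsing
# ---------------------------------------------------------------------

_LABEL_TERMINATORS = set("(),:;[]'")


def _strip_comments(text: str) -> str:
    """Remove square-bracket comments, preserving character positions by
    replacing them with spaces so error offsets refer to the input."""
    out = []
    depth = 0
    in_quote = False
    for ch in text:
        if in_quote:
            out.append(ch)
            if ch == "'":
                in_quote = False
            continue
        if ch == "'" and depth == 0:
            in_quote = True
            out.append(ch)
            continue
        if ch == "[":
            depth += 1
            out.append(" ")
            continue
        if ch == "]":
            if depth == 0:
                raise NewickParseError("unbalanced ']'", len(out))
            depth -= 1
            out.append(" ")
            continue
        out.append(" " if depth > 0 else ch)
    if depth != 0:
        raise NewickParseError("unterminated '[' comment", len(text) - 1)
    return "".join(out)


class _NewickCursor:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        self.skip_ws()
        if self.pos >= len(self.text):
            raise NewickParseError("unexpected end of input", self.pos)
        return self.text[self.pos]

    def expect(self, ch: str) -> None:
        got = self.peek()
        if got != ch:
            raise NewickParseError(f"expected '{ch}', found '{got}'", self.pos)
        self.pos += 1

    def read_label(self) -> str | None:
        self.skip_ws()
        if self.pos >= len(self.text):
            return None
        if self.text[self.pos] == "'":
            start = self.pos
            self.pos += 1
            parts: list[str] = []
            while True:
                if self.pos >= len(self.text):
                    raise NewickParseError("unterminated quoted label", start)
                ch = self.text[self.pos]
                if ch == "'":
                    if self.pos + 1 < len(self.text) and self.text[self.pos + 1] == "'":
                        parts.append("'")  # '' escapes a quote
                        self.pos += 2
                        continue
                    self.pos += 1
                    return "".join(parts)
                parts.append(ch)
                self.pos += 1
        start = self.pos
        while self.pos < len(self.text) and not (
            self.text[self.pos].isspace() or self.text[self.pos] in _LABEL_TERMINATORS
        ):
            self.pos += 1
        label = self.text[start : self.pos]
        return label or None

    def read_length(self) -> float | None:
        self.skip_ws()
        if self.pos >= len(self.text) or self.text[self.pos] != ":":
            return None
        self.pos += 1
        self.skip_ws()
        start = self.pos
        while self.pos < len(self.text) and (
            self.text[self.pos] in "+-.eE0123456789"
        ):
            self.pos += 1
        token = self.text[start : self.pos]
        try:
            return float(token)
        except ValueError:
            raise NewickParseError(f"invalid branch length '{token}'", start) from None


def _parse_clade(cur: _NewickCursor) -> Node:
    node = Node()
    if cur.peek() == "(":
        cur.expect("(")
        node.children.append(_parse_clade(cur))
        while cur.peek() == ",":
            cur.expect(",")
            node.children.append(_parse_clade(cur))
        cur.expect(")")
        node.label = cur.read_label()
    else:
        label = cur.read_label()
        if label is None:
            raise NewickParseError("expected a taxon label", cur.pos)
        node.label = label
    node.length = cur.read_length()
    return node


def parse_newick(text: str, validate: bool = True) -> Phylogeny:
    """Parse a single Newick tree.

    Quoted labels and ``[...]`` comments are accepted (comments are
    stripped); polytomies are preserved. Raises :class:`NewickParseError`
    with the offending position on malformed input and
    :class:`TreeValidationError` on duplicate labels or < 2 tips.
    """
    cur = _NewickCursor(_strip_comments(text))
    root = _parse_clade(cur)
    cur.expect(";")
    cur.skip_ws()
    if cur.pos < len(cur.text):
        raise NewickParseError("trailing characters after ';'", cur.pos)
    return Phylogeny(root, validate=validate)


def _format_label(label: str) -> str:
    if label and not (set(label) & _LABEL_TERMINATORS) and " " not in label:
        return label
    return "'" + label.replace("'", "''") + "'"


def _write_clade(node: Node, parts: list[str], precision: int) -> None:
    if node.children:
        parts.append("(")
        for i, child in enumerate(node.children):
            if i:
                parts.append(",")
            _write_clade(child, parts, precision)
        parts.append(")")
        if node.label:
            parts.append(_format_label(node.label))
    else:
        parts.append(_format_label(node.label or ""))
    if node.length is not None:
        parts.append(f":{node.length:.{precision}g}")


def write_newick(tree: Phylogeny, precision: int = 12) -> str:
    parts: list[str] = []
    _write_clade(tree.root, parts, precision)
    parts.append(";")
    return "".join(parts)


def read_newick_file(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick_file(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------
# Labeled matrices
# ---------------------------------------------------------------------


@dataclass
class _LabeledMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def subset(self, labels) -> "_LabeledMatrix":
        labels = list(labels)
        idx = [self._index[lab] for lab in labels]
        return type(self)(labels, self.values[np.ix_(idx, idx)])


class DistanceMatrix(_LabeledMatrix):
    """Symmetric patristic distances with a zero diagonal."""


class PhyloCovariance(_LabeledMatrix):
    """Shared root-to-tip path lengths; the Brownian-motion covariance
    structure (diagonal = tip depths)."""


# ---------------------------------------------------------------------
# Per-species quantities
# ---------------------------------------------------------------------


def terminal_branch_lengths(tree: Phylogeny) -> dict[str, float]:
    """Pendant edge length per species (the "species age" proxy)."""
    return {t.label: float(t.length or 0.0) for t in tree.tips}


def fair_proportion_ed(tree: Phylogeny) -> dict[str, float]:
    """Fair-proportion evolutionary distinctiveness.

    Each edge's length is divided equally among the tips that descend
    from it; a tip's ED is the sum of its shares along the root path.
    The root edge (shared by every tip) is excluded, so
    ``sum(ED) == tree.total_length`` exactly.
    """
    ed = {t.label: 0.0 for t in tree.tips}

    def walk(node: Node) -> list[str]:
        if node.is_leaf:
            below = [node.label]
        else:
            below = []
            for child in node.children:
                below.extend(walk(child))
        if node is not tree.root and node.length:
            share = node.length / len(below)
            for lab in below:
                ed[lab] += share
        return below

    walk(tree.root)
    return ed


def patristic_distances(tree: Phylogeny) -> DistanceMatrix:
    """Pairwise path-length distances between tips.

    Computed by accumulating, at every internal node, the tip-to-node
    path lengths of each child subtree and summing across child pairs —
    independent of :func:`phylo_vcv`.
    """
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    dist = np.zeros((n, n))

    def walk(node: Node) -> dict[int, float]:
        """Map tip index -> path length from the tip up to ``node``."""
        if node.is_leaf:
            up = {index[node.label]: 0.0}
        else:
            child_maps = [walk(c) for c in node.children]
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for i, di in child_maps[a].items():
                        for j, dj in child_maps[b].items():
                            d = di + dj
                            dist[i, j] = d
                            dist[j, i] = d
            up = {}
            for m in child_maps:
                up.update(m)
        if node is not tree.root and node.length:
            for i in up:
                up[i] += node.length
        return up

    walk(tree.root)
    return DistanceMatrix(labels, dist)


def phylo_vcv(tree: Phylogeny) -> PhyloCovariance:
    """Brownian phylogenetic covariance: entry (i, j) is the root-to-MRCA
    depth; the diagonal holds root-to-tip depths. The root edge is
    excluded (depth 0 at the root)."""
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    cov = np.zeros((n, n))
    depth = tree.depths()

    def walk(node: Node) -> list[int]:
        if node.is_leaf:
            i = index[node.label]
            cov[i, i] = depth[id(node)]
            return [i]
        child_sets = [walk(c) for c in node.children]
        d = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        cov[i, j] = d
                        cov[j, i] = d
        return [i for s in child_sets for i in s]

    walk(tree.root)
    return PhyloCovariance(labels, cov)


def write_metrics_csv(path, tree: Phylogeny) -> None:
    """Export per-species ED and terminal branch length as CSV
    (columns ``species,ed,bl``, units follow the tree's edge lengths)."""
    ed = fair_proportion_ed(tree)
    bl = terminal_branch_lengths(tree)
    with open(path, "w") as fh:
        fh.write("species,ed,bl\n")
        for lab in tree.tip_labels:
            fh.write(f"{lab},{ed[lab]:.10g},{bl[lab]:.10g}\n")
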
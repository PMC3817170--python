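"""Dot-bracket parsing and decomposition into a secondary-structure element tree.

A non-pseudoknotted secondary structure decomposes into helices (maximal
stacks of perfectly nested base pairs) and non-helical elements: hairpin
loops, internal loops, bulges, multi-branch junctions and the external
(unpaired tail) region.  The elements form a rooted tree whose edges
follow nesting; replacing the 3D geometry of one element only affects
the placement of elements below it in the tree.  The number of
non-helical elements is the low-resolution degree-of-freedom count used
by the sampling algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_BASES = set("AUGCaugc")


class ParseError(ValueError):
    """Malformed sequence/structure input."""


class PseudoknotError(ValueError):
    """Pseudoknotted (non-nested) structure; the element-tree model requires nesting."""


@dataclass(frozen=True)
class SecondaryStructure:
    """RNA sequence with a set of nested base pairs (0-based, i < j)."""

    sequence: str
    pairs: frozenset

    def __post_init__(self):
        n = len(self.sequence)
        seen = set()
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise ParseError(f"pair ({i},{j}) out of range for length {n}")
            if i in seen or j in seen:
                raise ParseError("an index appears in more than one pair")
            seen.add(i)
            seen.add(j)

    def __len__(self):
        return len(self.sequence)

    def partner(self) -> dict:
        """Map each paired index to its partner."""
        out = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def to_dotbracket(self) -> str:
        chars = ["."] * len(self.sequence)
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)


def parse_dotbracket(sequence: str, structure: str) -> SecondaryStructure:
    """Parse a dot-bracket string against its sequence.

    Only '.', '(' and ')' are accepted; extended bracket alphabets
    (pseudoknot notation) are rejected.  Unbalanced brackets raise
    :class:`ParseError` naming the offending index.
    """
    if len(sequence) != len(structure):
        raise ParseError(
            f"sequence length {len(sequence)} != structure length {len(structure)}")
    bad = set(sequence) - VALID_BASES
    if bad:
        raise ParseError(f"invalid nucleotides: {sorted(bad)}")
    pairs = set()
    stack = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at index {idx}")
            pairs.add((stack.pop(), idx))
        elif ch != ".":
            if ch in "[]{}<>" or ch.isalpha():
                raise PseudoknotError(
                    f"extended bracket '{ch}' at index {idx}: pseudoknots unsupported")
            raise ParseError(f"invalid structure character '{ch}' at index {idx}")
    if stack:
        raise ParseError(f"unbalanced '(' at index {stack[-1]}")
    return SecondaryStructure(sequence.upper().replace("T", "U"), frozenset(pairs))


HELIX = "helix"
HAIRPIN = "hairpin_loop"
INTERNAL = "internal_loop"
BULGE = "bulge"
JUNCTION = "junction"
EXTERNAL = "external_loop"

NON_HELIX_KINDS = (HAIRPIN, INTERNAL, BULGE, JUNCTION, EXTERNAL)


@dataclass
class Element:
    """One secondary-structure element.

    ``strands`` are (start, end) inclusive 0-based residue ranges in
    chain order; an empty strand (the missing side of a bulge, or an
    absent inter-helix segment in junctions/external loops) is encoded
    as (start, start - 1).  ``closing_pairs`` lists the helix base pairs
    bounding the element, parent side first.
    """

    kind: str
    strands: list
    closing_pairs: list = field(default_factory=list)
    index: int = -1  # position in ElementTree.nodes, set by decompose

    @property
    def strand_lengths(self) -> tuple:
        return tuple(e - s + 1 for s, e in self.strands)

    @property
    def key(self) -> tuple:
        """Fragment-library key: (kind, strand lengths)."""
        return (self.kind, self.strand_lengths)

    def residues(self) -> list:
        out = []
        for s, e in self.strands:
            out.extend(range(s, e + 1))
        return out

    def sequences(self, sequence: str) -> tuple:
        return tuple(sequence[s:e + 1] for s, e in self.strands)


@dataclass
class ElementTree:
    """Rooted tree of secondary-structure elements."""

    secondary: SecondaryStructure
    nodes: list
    root: int
    children: dict  # node index -> list of child node indices
    parent: dict  # node index -> parent node index (root absent)

    def __iter__(self):
        return iter(self.nodes)

    def node(self, i: int) -> Element:
        return self.nodes[i]

    def preorder(self, start: int | None = None):
        """Yield node indices in pre-order from ``start`` (default root)."""
        stack = [self.root if start is None else start]
        while stack:
            i = stack.pop()
            yield i
            stack.extend(reversed(self.children.get(i, [])))

    def subtree_residues(self, start: int) -> list:
        out = []
        for i in self.preorder(start):
            out.extend(self.nodes[i].residues())
        return sorted(out)

    def non_helix_nodes(self) -> list:
        return [i for i, n in enumerate(self.nodes) if n.kind != HELIX]


def _helices(ss: SecondaryStructure) -> list:
    """Maximal stacks of consecutive nested pairs, sorted by outer 5' index."""
    pairs = sorted(ss.pairs)
    pair_set = set(pairs)
    helices = []
    used = set()
    for p in pairs:
        if p in used:
            continue
        stack = [p]
        used.add(p)
        i, j = p
        while (i + 1, j - 1) in pair_set:
            i, j = i + 1, j - 1
            stack.append((i, j))
            used.add((i, j))
        helices.append(stack)
    return helices


def decompose(ss: SecondaryStructure) -> ElementTree:
    """Decompose a nested secondary structure into its element tree.

    Every residue belongs to exactly one element: paired residues to
    their helix, unpaired residues to the loop/junction/external element
    that contains them.
    """
    n = len(ss)
    partner = ss.partner()
    # nesting check (pseudoknots cannot arise from single-bracket input,
    # but pair sets may be constructed directly)
    opened = []
    for idx in range(n):
        j = partner.get(idx)
        if j is None:
            continue
        if j > idx:
            opened.append(j)
        else:
            if not opened or opened[-1] != idx:
                raise PseudoknotError("crossing base pairs: structure is pseudoknotted")
            opened.pop()

    helices = _helices(ss)
    nodes: list[Element] = []

    def add(elem: Element) -> int:
        elem.index = len(nodes)
        nodes.append(elem)
        return elem.index

    helix_by_outer = {}
    for stack in helices:
        strands = [(stack[0][0], stack[-1][0]), (stack[-1][1], stack[0][1])]
        e = Element(HELIX, strands, closing_pairs=[stack[0], stack[-1]])
        helix_by_outer[stack[0]] = add(e)

    children: dict[int, list] = {}
    parent: dict[int, int] = {}

    def top_level_pairs(lo: int, hi: int) -> list:
        """Outermost pairs fully inside [lo, hi], left to right."""
        out = []
        idx = lo
        while idx <= hi:
            j = partner.get(idx)
            if j is not None and j > idx:
                out.append((idx, j))
                idx = j + 1
            else:
                idx += 1
        return out

    def build_loop(helix_idx: int) -> None:
        """Create the element enclosed by a helix and recurse."""
        helix = nodes[helix_idx]
        (i_in, j_in) = helix.closing_pairs[1]
        lo, hi = i_in + 1, j_in - 1
        child_pairs = top_level_pairs(lo, hi)
        # strand segments between consecutive child helices
        cursor = lo
        segs = []
        for k in range(len(child_pairs) + 1):
            seg_start = cursor
            seg_end = (child_pairs[k][0] - 1) if k < len(child_pairs) else hi
            segs.append((seg_start, seg_end))
            if k < len(child_pairs):
                cursor = child_pairs[k][1] + 1
        m = len(child_pairs)
        if m == 0:
            kind = HAIRPIN
        elif m == 1:
            lens = [e - s + 1 for s, e in segs]
            kind = BULGE if min(lens) == 0 else INTERNAL
        else:
            kind = JUNCTION
        elem = Element(kind, segs, closing_pairs=[helix.closing_pairs[1]]
                       + child_pairs)
        ei = add(elem)
        children.setdefault(helix_idx, []).append(ei)
        parent[ei] = helix_idx
        for p in child_pairs:
            hi_child = helix_by_outer[p]
            children.setdefault(ei, []).append(hi_child)
            parent[hi_child] = ei
            build_loop(hi_child)

    ext_pairs = top_level_pairs(0, n - 1)
    ext_segs = []
    cursor = 0
    for k in range(len(ext_pairs) + 1):
        seg_start = cursor
        seg_end = (ext_pairs[k][0] - 1) if k < len(ext_pairs) else n - 1
        ext_segs.append((seg_start, seg_end))
        if k < len(ext_pairs):
            cursor = ext_pairs[k][1] + 1
    ext_residues = sum(e - s + 1 for s, e in ext_segs)

    if len(ext_pairs) == 1 and ext_residues == 0:
        root = helix_by_outer[ext_pairs[0]]
        build_loop(root)
    else:
        ext = Element(EXTERNAL, ext_segs, closing_pairs=list(ext_pairs))
        root = add(ext)
        for p in ext_pairs:
            hi_child = helix_by_outer[p]
            children.setdefault(root, []).append(hi_child)
            parent[hi_child] = root
            build_loop(hi_child)

    return ElementTree(ss, nodes, root, children, parent)


def degrees_of_freedom(tree: ElementTree) -> int:
    """Low-resolution degrees of freedom: the number of non-helix elements."""
    return len(tree.non_helix_nodes())


def read_dotbracket(path) -> SecondaryStructure:
    """Read a two-line dot-bracket file (FASTA-style header tolerated)."""
    from pathlib import Path
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith((">", ";", "#"))]
    if len(lines) < 2:
        raise ParseError(f"{path}: need sequence and structure lines")
    return parse_dotbracket(lines[0], lines[1])


def write_dotbracket(path, ss: SecondaryStructure, name: str = "rna") -> None:
    from pathlib import Path
    Path(path).write_text(f">{name}\n{ss.sequence}\n{ss.to_dotbracket()}\n")
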
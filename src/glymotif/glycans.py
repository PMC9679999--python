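"""Parsing, canonicalization and traversal of condensed glycan structure strings.

Glycans on arrays are written in the CFG/IUPAC-condensed dialect: a linear
string read child-to-parent (non-reducing to reducing end), with branches in
parentheses and an optional spacer/linker suffix, e.g.

    Galb1-4GlcNAcb1-2Mana1-3(Galb1-4GlcNAcb1-2Mana1-6)Manb1-4GlcNAcb1-4GlcNAc-Sp12

Each residue token is ``[substituents]Sugar[anomer][child-carbon][-][parent-carbon]``.
Both ASCII ("b1-4") and Greek/comma ("β1,4") linkage spellings are accepted and
normalized to ASCII internally. Sulfate/phosphate/acetyl decorations written as
parenthesized prefixes — ``(3S)Gal``, ``(6OSO3)GlcNAc`` — become substituents on
the node. The parsed form is a rooted labeled tree (:class:`GlycanGraph`); the
root is the reducing-end residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator

__all__ = [
    "GlycanParseError",
    "UnknownSugarError",
    "MonosaccharideNode",
    "LinkageEdge",
    "GlycanGraph",
    "SugarRegistry",
    "DEFAULT_REGISTRY",
    "parse_condensed",
    "to_canonical",
    "terminal_nodes",
    "enumerate_kmers",
]

WILDCARD_SUGAR = "*"


class GlycanParseError(ValueError):
    """Malformed condensed string; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)


class UnknownSugarError(GlycanParseError):
    """Syntactically valid residue token whose sugar symbol is not registered."""


# ---------------------------------------------------------------------------
# Sugar registry
# ---------------------------------------------------------------------------

_DEFAULT_SUGARS: dict[str, tuple[str, ...]] = {
    # canonical symbol -> aliases
    "Glc": (),
    "Gal": (),
    "Man": (),
    "GlcNAc": (),
    "GalNAc": (),
    "ManNAc": (),
    "Fuc": (),
    "Xyl": (),
    "Rha": (),
    "Ara": (),
    "GlcN": (),
    "GalN": (),
    "Neu5Ac": ("NeuAc", "NeuNAc"),
    "Neu5Gc": ("NeuGc",),
    "Neu5,9Ac2": (),
    "KDN": ("Kdn",),
    "MurNAc": (),
    "GlcA": ("GlcUA",),
    "IdoA": ("IdoUA",),
    "GalA": (),
}


class SugarRegistry:
    """Extensible monosaccharide vocabulary with alias resolution.

    A registry maps every accepted spelling to a canonical symbol. Symbols can
    be loaded from a plain-text file with one canonical symbol per line,
    optionally followed by whitespace-separated aliases.
    """

    def __init__(self, sugars: dict[str, tuple[str, ...]] | None = None):
        self._canonical: dict[str, str] = {}
        for symbol, aliases in (sugars or _DEFAULT_SUGARS).items():
            self.add(symbol, aliases)

    def add(self, symbol: str, aliases: tuple[str, ...] = ()) -> None:
        self._canonical[symbol] = symbol
        for a in aliases:
            self._canonical[a] = symbol

    def resolve(self, token: str) -> str | None:
        return self._canonical.get(token)

    def spellings(self) -> list[str]:
        # longest-first so e.g. "Neu5,9Ac2" wins over "Neu5" prefixes
        return sorted(self._canonical, key=len, reverse=True)

    def symbols(self) -> set[str]:
        return set(self._canonical.values())

    @classmethod
    def from_file(cls, path: str) -> "SugarRegistry":
        reg = cls(sugars={})
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.split()
                reg.add(parts[0], tuple(parts[1:]))
        return reg


DEFAULT_REGISTRY = SugarRegistry()


# ---------------------------------------------------------------------------
# Graph types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonosaccharideNode:
    """A single monosaccharide with optional substituents.

    ``substituents`` is a sorted tuple of ``(position, group)`` pairs with
    group in {"S" (sulfate), "P" (phosphate), "Ac" (acetyl)}; positions are
    distinct per node.
    """

    node_id: int
    sugar: str
    substituents: tuple[tuple[int, str], ...] = ()

    def token(self) -> str:
        """Residue token with substituent prefixes, e.g. ``(3S)Gal``."""
        prefix = "".join(f"({p}{g})" for p, g in self.substituents)
        return prefix + self.sugar


@dataclass(frozen=True)
class LinkageEdge:
    """Glycosidic bond: child residue attached to a carbon of its parent.

    ``anomer`` is "a", "b" or "?"; carbons are 1-9 or None for unknown ("?").
    """

    child: int
    parent: int
    anomer: str = "?"
    child_carbon: int | None = None
    parent_carbon: int | None = None

    def linkage_str(self) -> str:
        c1 = "?" if self.child_carbon is None else str(self.child_carbon)
        c2 = "?" if self.parent_carbon is None else str(self.parent_carbon)
        return f"{self.anomer}{c1}-{c2}"


@dataclass
class GlycanGraph:
    """Rooted tree of monosaccharides; root is the reducing-end residue."""

    nodes: dict[int, MonosaccharideNode]
    edges: list[LinkageEdge]
    root: int
    linker: str | None = None
    _children: dict[int, list[LinkageEdge]] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        self._children = {nid: [] for nid in self.nodes}
        seen_children = set()
        for e in self.edges:
            if e.child == e.parent:
                raise ValueError("self-loop edge")
            if e.child in seen_children:
                raise ValueError(f"node {e.child} has two parents")
            seen_children.add(e.child)
            self._children[e.parent].append(e)
        if self.root in seen_children:
            raise ValueError("root must not be a child")
        if len(seen_children) != len(self.nodes) - 1:
            raise ValueError("graph is not a connected tree")
        reached, stack = {self.root}, [self.root]
        while stack:
            for e in self._children[stack.pop()]:
                reached.add(e.child)
                stack.append(e.child)
        if len(reached) != len(self.nodes):
            raise ValueError("graph is not connected from the root")

    def children(self, node_id: int) -> list[LinkageEdge]:
        return self._children[node_id]

    def parent_edge(self, node_id: int) -> LinkageEdge | None:
        for e in self.edges:
            if e.child == node_id:
                return e
        return None

    def __len__(self) -> int:
        return len(self.nodes)

    def iter_nodes(self) -> Iterator[MonosaccharideNode]:
        return iter(self.nodes.values())

    def is_leaf(self, node_id: int) -> bool:
        return not self._children[node_id]

    def without_linker(self) -> "GlycanGraph":
        return replace(self, linker=None) if self.linker else self


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

_SUBST_RE = re.compile(r"\((\d)(S|Ac|P|OSO3|OPO3)\)")
_SUBST_GROUPS = {"S": "S", "OSO3": "S", "Ac": "Ac", "P": "P", "OPO3": "P"}
_LINKAGE_RE = re.compile(r"([abαβ?]?)(\d|\?)[-,](\d|\?)")
_LINKER_RE = re.compile(r"-(Sp\d+|[A-Z][a-z]{2})$")
_ANOMER_MAP = {"a": "a", "α": "a", "b": "b", "β": "b", "?": "?", "": "?"}


def _carbon(tok: str) -> int | None:
    return None if tok == "?" else int(tok)


class _Parser:
    def __init__(self, text: str, registry: SugarRegistry):
        self.text = text
        self.pos = 0
        self.registry = registry
        self.spellings = registry.spellings()
        self.next_id = 0
        self.nodes: dict[int, MonosaccharideNode] = {}
        self.edges: list[LinkageEdge] = []

    def error(self, msg: str) -> GlycanParseError:
        return GlycanParseError(msg, self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def parse(self) -> GlycanGraph:
        text = self.text.strip()
        if not text:
            raise GlycanParseError("empty glycan string", 0)
        linker = None
        m = _LINKER_RE.search(text)
        if m:
            linker = m.group(1)
            text = text[: m.start()]
        self.text = text
        root, link = self._parse_chain(top=True)
        if link is not None:
            raise self.error("dangling linkage on root residue")
        if self.pos != len(self.text):
            raise self.error("unexpected trailing text")
        return GlycanGraph(nodes=self.nodes, edges=self.edges, root=root, linker=linker)

    def _parse_chain(self, top: bool) -> tuple[int, tuple[str, int | None, int | None] | None]:
        """Parse residues/branches until chain end; return (sub-root id, its linkage)."""
        pending: list[tuple[int, tuple[str, int | None, int | None]]] = []
        while self.pos < len(self.text) and self.peek() != ")":
            if self.peek() == "(" and not _SUBST_RE.match(self.text, self.pos):
                self.pos += 1  # consume "("
                croot, clink = self._parse_chain(top=False)
                if self.peek() != ")":
                    raise self.error("unbalanced parenthesis: missing ')'")
                self.pos += 1
                if clink is None:
                    raise self.error("branch lacks a linkage to its parent")
                pending.append((croot, clink))
                continue
            node_id = self._parse_residue()
            link = self._parse_linkage_opt()
            for child, (an, c1, c2) in pending:
                self.edges.append(LinkageEdge(child=child, parent=node_id, anomer=an,
                                              child_carbon=c1, parent_carbon=c2))
            pending = []
            if link is None:
                # reducing-end residue of this (sub)chain
                if self.pos < len(self.text) and self.peek() != ")":
                    raise self.error("residue without linkage followed by more residues")
                return node_id, None
            pending = [(node_id, link)]
        if len(pending) == 1:
            return pending[0]
        raise self.error("truncated glycan string" if not pending else "malformed branch")

    def _parse_residue(self) -> int:
        subs: list[tuple[int, str]] = []
        while True:
            m = _SUBST_RE.match(self.text, self.pos)
            if not m:
                break
            pos_c, grp = int(m.group(1)), _SUBST_GROUPS[m.group(2)]
            if any(p == pos_c for p, _ in subs):
                raise self.error(f"duplicate substituent position {pos_c}")
            subs.append((pos_c, grp))
            self.pos = m.end()
        if self.text.startswith(WILDCARD_SUGAR, self.pos):
            sugar = WILDCARD_SUGAR
            self.pos += 1
        else:
            sugar = None
            for spelling in self.spellings:
                if self.text.startswith(spelling, self.pos):
                    sugar = self.registry.resolve(spelling)
                    self.pos += len(spelling)
                    break
            if sugar is None:
                token = re.match(r"[A-Za-z][A-Za-z0-9,]*", self.text[self.pos:])
                if token:
                    raise UnknownSugarError(
                        f"unknown sugar symbol {token.group(0)!r}", self.pos)
                raise self.error("expected a residue token")
        node_id = self.next_id
        self.next_id += 1
        self.nodes[node_id] = MonosaccharideNode(
            node_id=node_id, sugar=sugar, substituents=tuple(sorted(subs)))
        return node_id

    def _parse_linkage_opt(self) -> tuple[str, int | None, int | None] | None:
        m = _LINKAGE_RE.match(self.text, self.pos)
        if m:
            self.pos = m.end()
            return _ANOMER_MAP[m.group(1)], _carbon(m.group(2)), _carbon(m.group(3))
        # a lone anomer or half-linkage is a truncated token, not a chain end
        if re.match(r"[abαβ](\d|\?)?(?![A-Za-z])", self.text[self.pos:]):
            raise self.error("truncated linkage token")
        return None


def parse_condensed(text: str, registry: SugarRegistry = DEFAULT_REGISTRY) -> GlycanGraph:
    """Parse a condensed-dialect glycan string into a :class:`GlycanGraph`.

    Raises :class:`GlycanParseError` (with offset) for malformed syntax and
    :class:`UnknownSugarError` for unregistered sugar symbols.
    """
    return _Parser(text, registry).parse()


# ---------------------------------------------------------------------------
# Canonical serialization
# ---------------------------------------------------------------------------

def _canonical_subtree(g: GlycanGraph, node_id: int) -> str:
    """Serialize the subtree rooted at node_id, children in canonical order."""
    node = g.nodes[node_id]
    rendered = []
    for e in g.children(node_id):
        sub = _canonical_subtree(g, e.child) + e.linkage_str()
        key = (e.parent_carbon if e.parent_carbon is not None else 10, sub)
        rendered.append((key, sub))
    rendered.sort(key=lambda kv: kv[0])
    parts = [sub for _, sub in rendered]
    if not parts:
        return node.token()
    # first sibling stays on the main chain, the rest are parenthesized
    return parts[0] + "".join(f"({p})" for p in parts[1:]) + node.token()


def to_canonical(g: GlycanGraph) -> str:
    """Deterministic condensed string; sibling branches ordered by
    (parent carbon, canonical subtree string), independent of input order."""
    s = _canonical_subtree(g, g.root)
    if g.linker:
        s += f"-{g.linker}"
    return s


def isomorphic(a: GlycanGraph, b: GlycanGraph) -> bool:
    """Structural equality up to node ids and sibling order (linker included)."""
    return to_canonical(a) == to_canonical(b)


# ---------------------------------------------------------------------------
# Traversal and k-mer enumeration
# ---------------------------------------------------------------------------

def terminal_nodes(g: GlycanGraph) -> set[int]:
    """Leaf node ids (non-reducing termini); the root only for a 1-node graph."""
    return {nid for nid in g.nodes if g.is_leaf(nid)}


def enumerate_kmers(g: GlycanGraph, k: int) -> dict[str, int]:
    """Multiset of canonical mono- (k=1) or disaccharide (k=2) motif strings.

    k=1 counts residue tokens (substituents retained, e.g. ``(3S)Gal``); k=2
    yields one ``Child<linkage>Parent`` entry per edge. The linker is excluded.
    """
    if k == 1:
        out: dict[str, int] = {}
        for node in g.iter_nodes():
            t = node.token()
            out[t] = out.get(t, 0) + 1
        return out
    if k == 2:
        out = {}
        for e in g.edges:
            t = g.nodes[e.child].token() + e.linkage_str() + g.nodes[e.parent].token()
            out[t] = out.get(t, 0) + 1
        return out
    raise ValueError("k must be 1 or 2")
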
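"""Glycan featurization: curated motif catalog + systematic mono/disaccharide counts.

Two feature families feed the rule miner, mirroring common practice for
glycan-array analysis:

* a curated catalog of named motifs (Lewis and blood-group antigens, O-glycan
  cores, high-mannose classes, terminal residues, sialylation/sulfation, ...),
  scored as binary presence via subtree-embedding matching;
* systematic features: the count of every observed monosaccharide and linked
  disaccharide (with linkage) in the library.

The array linker/spacer is exposed as a one-hot categorical, never as a sugar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .glycans import (
    DEFAULT_REGISTRY,
    GlycanGraph,
    LinkageEdge,
    MonosaccharideNode,
    SugarRegistry,
    WILDCARD_SUGAR,
    enumerate_kmers,
    parse_condensed,
)

__all__ = [
    "MotifPattern",
    "FeatureMatrix",
    "match_motif",
    "systematic_motifs",
    "build_feature_matrix",
    "default_catalog",
    "load_catalog",
    "DEFAULT_CATALOG_SPEC",
]


@dataclass(frozen=True)
class MotifPattern:
    """A glycan subtree template with anchoring and optional context constraints.

    ``template`` may carry wildcards: sugar ``*`` matches any residue; anomer
    or carbon ``?`` in the pattern matches any value in the target. A ``?`` in
    the *target* glycan is an unknown and never satisfies a specified pattern
    carbon. Anchors:

    - ``terminal``: every template leaf must map onto a leaf of the glycan
      (the motif caps a non-reducing terminus);
    - ``root``: the template root must map onto the reducing-end residue;
    - ``internal``: every template leaf must map onto a non-leaf residue;
    - ``anywhere``: unconstrained.

    ``forbidden_context`` lists (template node_id, spec) pairs that must be
    absent on the matched image node: ``"child"`` (no children at all),
    ``"child@N"`` (no child attached at parent carbon N), ``"sub@NS"`` (no
    substituent, e.g. ``sub@3S``). ``required_linker`` restricts matches to
    glycans presented on one of the named spacers.
    """

    name: str
    template: GlycanGraph
    anchor: str = "anywhere"
    forbidden_context: tuple[tuple[int, str], ...] = ()
    required_linker: frozenset[str] | None = None

    def __post_init__(self):
        if self.anchor not in {"terminal", "internal", "root", "anywhere"}:
            raise ValueError(f"unknown anchor {self.anchor!r}")

    @classmethod
    def from_string(
        cls,
        name: str,
        pattern: str,
        anchor: str = "anywhere",
        forbidden_context: tuple[tuple[int, str], ...] = (),
        required_linker: frozenset[str] | None = None,
        registry: SugarRegistry = DEFAULT_REGISTRY,
    ) -> "MotifPattern":
        template = parse_condensed(pattern, registry).without_linker()
        return cls(name=name, template=template, anchor=anchor,
                   forbidden_context=tuple(forbidden_context),
                   required_linker=required_linker)


# ---------------------------------------------------------------------------
# Subtree-embedding matching
# ---------------------------------------------------------------------------

def _node_compatible(tnode: MonosaccharideNode, gnode: MonosaccharideNode) -> bool:
    if tnode.sugar != WILDCARD_SUGAR and tnode.sugar != gnode.sugar:
        return False
    # pattern substituents must be present; extra decorations on the target allowed
    return all(sub in gnode.substituents for sub in tnode.substituents)


def _edge_compatible(tedge: LinkageEdge, gedge: LinkageEdge) -> bool:
    if tedge.anomer != "?" and tedge.anomer != gedge.anomer:
        return False
    if tedge.child_carbon is not None and tedge.child_carbon != gedge.child_carbon:
        return False
    if tedge.parent_carbon is not None and tedge.parent_carbon != gedge.parent_carbon:
        return False
    return True


def _extend(g: GlycanGraph, t: GlycanGraph, tnode: int, gnode: int,
            used: set[int]) -> list[dict[int, int]]:
    """All injective embeddings of the template subtree at tnode onto gnode."""
    if not _node_compatible(t.nodes[tnode], g.nodes[gnode]):
        return []
    tchildren = t.children(tnode)
    if not tchildren:
        return [{tnode: gnode}]
    gchildren = g.children(gnode)

    results: list[dict[int, int]] = []

    def assign(i: int, mapping: dict[int, int], taken: frozenset[int]) -> None:
        if i == len(tchildren):
            results.append(mapping)
            return
        te = tchildren[i]
        for ge in gchildren:
            if ge.child in taken or ge.child in used or not _edge_compatible(te, ge):
                continue
            for sub in _extend(g, t, te.child, ge.child, used | taken):
                subvals = frozenset(sub.values())
                if subvals & taken:
                    continue
                assign(i + 1, {**mapping, **sub}, taken | subvals)

    assign(0, {tnode: gnode}, frozenset({gnode}))
    return results


def _mapping_ok(g: GlycanGraph, m: MotifPattern, mapping: dict[int, int]) -> bool:
    t = m.template
    if m.anchor == "root" and mapping[t.root] != g.root:
        return False
    if m.anchor in ("terminal", "internal"):
        for tnid in t.nodes:
            if t.is_leaf(tnid):
                img_is_leaf = g.is_leaf(mapping[tnid])
                if m.anchor == "terminal" and not img_is_leaf:
                    return False
                if m.anchor == "internal" and img_is_leaf:
                    return False
    for tnid, spec in m.forbidden_context:
        img = mapping[tnid]
        if spec == "child":
            if not g.is_leaf(img):
                return False
        elif spec.startswith("child@"):
            carbon = int(spec.split("@", 1)[1])
            if any(e.parent_carbon == carbon for e in g.children(img)):
                return False
        elif spec.startswith("sub@"):
            tok = spec.split("@", 1)[1]
            pos, grp = int(tok[0]), tok[1:]
            if (pos, grp) in g.nodes[img].substituents:
                return False
        else:
            raise ValueError(f"unknown forbidden-context spec {spec!r}")
    return True


def match_motif(g: GlycanGraph, m: MotifPattern) -> int:
    """Number of distinct embeddings of the motif template into the glycan.

    Embeddings are counted by their *image* (the set of matched residues), so
    template automorphisms — e.g. two symmetric wildcard branches — are not
    double-counted.
    """
    if m.required_linker is not None and g.linker not in m.required_linker:
        return 0
    t = m.template
    images: set[frozenset[int]] = set()
    for gnid in g.nodes:
        for mapping in _extend(g, t, t.root, gnid, set()):
            if len(set(mapping.values())) != len(t.nodes):
                continue
            if _mapping_ok(g, m, mapping):
                images.add(frozenset(mapping.values()))
    return len(images)


# ---------------------------------------------------------------------------
# Systematic features and the feature matrix
# ---------------------------------------------------------------------------

def systematic_motifs(library: list[GlycanGraph]) -> list[str]:
    """Sorted union of all observed mono- and disaccharide motif strings."""
    if not library:
        raise ValueError("empty glycan library")
    names: set[str] = set()
    for g in library:
        names.update(enumerate_kmers(g, 1))
        names.update(enumerate_kmers(g, 2))
    return sorted(names)


@dataclass
class FeatureMatrix:
    """Glycans × features count matrix (curated features binary)."""

    glycan_ids: list[str]
    feature_names: list[str]
    values: pd.DataFrame
    curated_names: list[str] = field(default_factory=list)

    def to_csv(self, path: str) -> None:
        self.values.to_csv(path, index_label="glycan_id")

    @classmethod
    def from_csv(cls, path: str) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="glycan_id")
        df.index = df.index.astype(str)
        return cls(glycan_ids=list(df.index), feature_names=list(df.columns), values=df)


def build_feature_matrix(
    library: list[GlycanGraph],
    catalog: list[MotifPattern] | None = None,
    glycan_ids: list[str] | None = None,
) -> FeatureMatrix:
    """Assemble the feature matrix: curated motifs, then systematic k-mers,
    then linker one-hot columns. Curated features are 0/1 presence; systematic
    features are counts.
    """
    if not library:
        raise ValueError("empty glycan library")
    catalog = catalog or []
    if glycan_ids is None:
        glycan_ids = [f"G{i + 1:04d}" for i in range(len(library))]
    curated_names = [m.name for m in catalog]
    sys_names = systematic_motifs(library)
    linkers = sorted({g.linker or "none" for g in library})
    linker_names = [f"linker:{lk}" for lk in linkers]
    all_names = curated_names + sys_names + linker_names
    if len(set(all_names)) != len(all_names):
        dupes = sorted({n for n in all_names if all_names.count(n) > 1})
        raise ValueError(f"duplicate feature names: {dupes}")

    rows = []
    for g in library:
        row = [1 if match_motif(g, m) > 0 else 0 for m in catalog]
        k1, k2 = enumerate_kmers(g, 1), enumerate_kmers(g, 2)
        row += [k1.get(n, 0) + k2.get(n, 0) for n in sys_names]
        row += [1 if (g.linker or "none") == lk else 0 for lk in linkers]
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(glycan_ids, name="glycan_id"),
                      columns=all_names, dtype=int)
    return FeatureMatrix(glycan_ids=list(glycan_ids), feature_names=all_names,
                         values=df, curated_names=curated_names)


# ---------------------------------------------------------------------------
# Default curated catalog
# ---------------------------------------------------------------------------

# (name, pattern, anchor[, options]); the catalog is deliberately a plain table
# so users can export, edit and reload it as YAML via load_catalog().
DEFAULT_CATALOG_SPEC: list[dict] = [
    # Lewis antigens
    {"name": "Lewis a", "pattern": "Galb1-3(Fuca1-4)GlcNAc", "anchor": "terminal"},
    {"name": "Lewis x", "pattern": "Galb1-4(Fuca1-3)GlcNAc", "anchor": "terminal"},
    {"name": "Lewis b", "pattern": "Fuca1-2Galb1-3(Fuca1-4)GlcNAc", "anchor": "terminal"},
    {"name": "Lewis y", "pattern": "Fuca1-2Galb1-4(Fuca1-3)GlcNAc", "anchor": "terminal"},
    # Blood groups
    {"name": "blood group H type 1", "pattern": "Fuca1-2Galb1-3GlcNAc", "anchor": "terminal"},
    {"name": "blood group H type 2", "pattern": "Fuca1-2Galb1-4GlcNAc", "anchor": "terminal"},
    {"name": "blood group H type 3/4", "pattern": "Fuca1-2Galb1-3GalNAc", "anchor": "terminal"},
    {"name": "blood group A", "pattern": "GalNAca1-3(Fuca1-2)Gal", "anchor": "terminal"},
    {"name": "blood group B", "pattern": "Gala1-3(Fuca1-2)Gal", "anchor": "terminal"},
    {"name": "alpha-Gal (Gala1-3Gal)", "pattern": "Gala1-3Gal", "anchor": "anywhere"},
    {"name": "Forssman (GalNAca1-3GalNAc)", "pattern": "GalNAca1-3GalNAc", "anchor": "terminal"},
    # LacNAc family
    {"name": "type 1 LacNAc", "pattern": "Galb1-3GlcNAc", "anchor": "anywhere"},
    {"name": "type 2 LacNAc", "pattern": "Galb1-4GlcNAc", "anchor": "anywhere"},
    {"name": "LacdiNAc", "pattern": "GalNAcb1-4GlcNAc", "anchor": "terminal"},
    {"name": "polyLacNAc (n>=2)",
     "pattern": "Galb1-4GlcNAcb1-3Galb1-4GlcNAc", "anchor": "anywhere"},
    {"name": "polyLacNAc (n>=3)",
     "pattern": "Galb1-4GlcNAcb1-3Galb1-4GlcNAcb1-3Galb1-4GlcNAc", "anchor": "anywhere"},
    # Chitin
    {"name": "chitobiose", "pattern": "GlcNAcb1-4GlcNAc", "anchor": "anywhere"},
    {"name": "chitin (n>=4)",
     "pattern": "GlcNAcb1-4GlcNAcb1-4GlcNAcb1-4GlcNAc", "anchor": "anywhere"},
    # N-glycan core decorations
    {"name": "bisecting GlcNAc",
     "pattern": "Mana1-3(Mana1-6)(GlcNAcb1-4)Man", "anchor": "anywhere"},
    {"name": "core fucose", "pattern": "Fuca1-6GlcNAc", "anchor": "root"},
    {"name": "N-glycan core (trimannosyl)",
     "pattern": "Mana1-3(Mana1-6)Manb1-4GlcNAcb1-4GlcNAc", "anchor": "root"},
    # High-mannose classes (terminal anchoring keeps the classes disjoint)
    {"name": "high mannose Man3",
     "pattern": "Mana1-3(Mana1-6)Manb1-4GlcNAcb1-4GlcNAc", "anchor": "terminal"},
    {"name": "high mannose Man4",
     "pattern": "Mana1-2Mana1-3(Mana1-6)Manb1-4GlcNAcb1-4GlcNAc", "anchor": "terminal"},
    {"name": "high mannose Man5",
     "pattern": "Mana1-3(Mana1-6)Mana1-6(Mana1-3)Manb1-4GlcNAcb1-4GlcNAc",
     "anchor": "terminal"},
    {"name": "high mannose Man6",
     "pattern": "Mana1-3(Mana1-6)Mana1-6(Mana1-2Mana1-3)Manb1-4GlcNAcb1-4GlcNAc",
     "anchor": "terminal"},
    {"name": "high mannose Man7",
     "pattern": "Mana1-3(Mana1-6)Mana1-6(Mana1-2Mana1-2Mana1-3)Manb1-4GlcNAcb1-4GlcNAc",
     "anchor": "terminal"},
    {"name": "high mannose Man8",
     "pattern": "Mana1-2Mana1-3(Mana1-6)Mana1-6(Mana1-2Mana1-2Mana1-3)Manb1-4GlcNAcb1-4GlcNAc",
     "anchor": "terminal"},
    {"name": "high mannose Man9",
     "pattern": "Mana1-2Mana1-3(Mana1-2Mana1-6)Mana1-6(Mana1-2Mana1-2Mana1-3)Manb1-4GlcNAcb1-4GlcNAc",
     "anchor": "terminal"},
    # Terminal residues
    {"name": "terminal Mana1-2", "pattern": "Mana1-2Man", "anchor": "terminal"},
    {"name": "terminal Mana1-3", "pattern": "Mana1-3Man", "anchor": "terminal"},
    {"name": "terminal Mana1-6", "pattern": "Mana1-6Man", "anchor": "terminal"},
    {"name": "terminal GlcNAca", "pattern": "GlcNAca?-?*", "anchor": "terminal"},
    {"name": "terminal GlcNAcb", "pattern": "GlcNAcb?-?*", "anchor": "terminal"},
    {"name": "terminal GalNAca", "pattern": "GalNAca?-?*", "anchor": "terminal"},
    {"name": "terminal GalNAcb", "pattern": "GalNAcb?-?*", "anchor": "terminal"},
    {"name": "terminal Gala", "pattern": "Gala?-?*", "anchor": "terminal"},
    {"name": "terminal Galb", "pattern": "Galb?-?*", "anchor": "terminal"},
    # O-glycan cores (reducing-end anchored, Ser/Thr presentation)
    {"name": "Tn antigen", "pattern": "GalNAc", "anchor": "root",
     "forbidden_context": [[0, "child"]], "required_linker": ["Ser", "Thr"]},
    {"name": "T antigen / core 1", "pattern": "Galb1-3GalNAc", "anchor": "root",
     "required_linker": ["Ser", "Thr"]},
    {"name": "sialyl-Tn", "pattern": "Neu5Aca2-6GalNAc", "anchor": "root",
     "required_linker": ["Ser", "Thr"]},
    {"name": "core 2", "pattern": "Galb1-3(GlcNAcb1-6)GalNAc", "anchor": "root",
     "required_linker": ["Ser", "Thr"]},
    {"name": "core 3", "pattern": "GlcNAcb1-3GalNAc", "anchor": "root",
     "required_linker": ["Ser", "Thr"]},
    {"name": "core 4", "pattern": "GlcNAcb1-3(GlcNAcb1-6)GalNAc", "anchor": "root",
     "required_linker": ["Ser", "Thr"]},
    # Sialylation and rarer sialic acids
    {"name": "alpha2-3 sialylation", "pattern": "Neu5Aca2-3Gal", "anchor": "anywhere"},
    {"name": "alpha2-6 sialylation", "pattern": "Neu5Aca2-6*", "anchor": "anywhere"},
    {"name": "alpha2-8 sialylation", "pattern": "Neu5Aca2-8Neu5Ac", "anchor": "anywhere"},
    {"name": "Neu5Gc present", "pattern": "Neu5Gc", "anchor": "anywhere"},
    {"name": "KDN present", "pattern": "KDN", "anchor": "anywhere"},
    # Sulfation
    {"name": "3-O-sulfation", "pattern": "(3S)*", "anchor": "anywhere"},
    {"name": "6-O-sulfation", "pattern": "(6S)*", "anchor": "anywhere"},
]


def _pattern_from_entry(entry: dict, registry: SugarRegistry) -> MotifPattern:
    return MotifPattern.from_string(
        name=entry["name"],
        pattern=entry["pattern"],
        anchor=entry.get("anchor", "anywhere"),
        forbidden_context=tuple((int(n), s) for n, s in entry.get("forbidden_context", [])),
        required_linker=(frozenset(entry["required_linker"])
                         if entry.get("required_linker") else None),
        registry=registry,
    )


def default_catalog(registry: SugarRegistry = DEFAULT_REGISTRY) -> list[MotifPattern]:
    return [_pattern_from_entry(e, registry) for e in DEFAULT_CATALOG_SPEC]


def load_catalog(path: str, registry: SugarRegistry = DEFAULT_REGISTRY) -> list[MotifPattern]:
    """Load a curated catalog from a YAML file (list of entries with keys
    name, pattern, anchor, forbidden_context, required_linker)."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return [_pattern_from_entry(e, registry) for e in entries]


def save_catalog(path: str, spec: list[dict] | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec or DEFAULT_CATALOG_SPEC, fh, sort_keys=False,
                       allow_unicode=True)
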
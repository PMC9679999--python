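import itertools

import pytest

import glymotif as gm

MAN9 = ("Mana1-2Mana1-3(Mana1-2Mana1-6)Mana1-6"
        "(Mana1-2Mana1-2Mana1-3)Manb1-4GlcNAcb1-4GlcNAc")

BIANTENNARY = ("Galb1-4GlcNAcb1-2Mana1-3(Galb1-4GlcNAcb1-2Mana1-6)"
               "Manb1-4GlcNAcb1-4GlcNAc")

BIANTENNARY_COREFUC = ("Galb1-4GlcNAcb1-2Mana1-3(Galb1-4GlcNAcb1-2Mana1-6)"
                       "Manb1-4GlcNAcb1-4(Fuca1-6)GlcNAc")

BIANTENNARY_BISECT = ("Galb1-4GlcNAcb1-2Mana1-3(Galb1-4GlcNAcb1-2Mana1-6)"
                      "(GlcNAcb1-4)Manb1-4GlcNAcb1-4GlcNAc")


@pytest.fixture(scope="session")
def man9():
    return gm.parse_condensed(MAN9)


@pytest.fixture(scope="session")
def chitobiose():
    return gm.parse_condensed("GlcNAcb1-4GlcNAc")


@pytest.fixture(scope="session")
def trimannosyl():
    return gm.parse_condensed("Mana1-6(Mana1-3)Man")


@pytest.fixture(scope="session")
def small_library():
    strings = [
        "GlcNAcb1-4GlcNAc",
        "Mana1-6(Mana1-3)Man",
        "Galb1-4(Fuca1-3)GlcNAc-Sp8",
        MAN9,
        BIANTENNARY,
        BIANTENNARY_COREFUC,
        BIANTENNARY_BISECT,
        "Neu5Aca2-6Galb1-4GlcNAc-Sp0",
        "(3S)Galb1-4GlcNAc-Sp0",
        "Galb1-3GalNAc-Thr",
    ]
    return [gm.parse_condensed(s) for s in strings]


def brute_force_embeddings(g: gm.GlycanGraph, m: gm.MotifPattern) -> int:
    """Independent motif-count oracle: try every injective node assignment and
    check node/edge/anchor/context constraints directly. Exponential; fixtures
    stay small."""
    from glymotif.features import _edge_compatible, _node_compatible, _mapping_ok

    if m.required_linker is not None and g.linker not in m.required_linker:
        return 0
    t = m.template
    tnodes = list(t.nodes)
    gnodes = list(g.nodes)
    tedges = [(e.child, e.parent, e) for e in t.edges]
    images = set()
    for combo in itertools.permutations(gnodes, len(tnodes)):
        mapping = dict(zip(tnodes, combo))
        if not all(_node_compatible(t.nodes[tn], g.nodes[mapping[tn]])
                   for tn in tnodes):
            continue
        ok = True
        for child, parent, te in tedges:
            ge = g.parent_edge(mapping[child])
            if ge is None or ge.parent != mapping[parent] or not _edge_compatible(te, ge):
                ok = False
                break
        if ok and _mapping_ok(g, m, mapping):
            images.add(frozenset(mapping.values()))
    return len(images)
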
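"""Synthetic glycan libraries, lectins and array scans with known ground truth.

The generator emulates the composition of a CFG-style printed array — a mix of
N-glycans (bi/tri/tetra-antennary and high-mannose, with optional bisecting
GlcNAc, core fucose, sialylation and polyLacNAc), O-glycan cores 1-4, and
free-standing terminal epitopes (Lewis, blood group, LacdiNAc, chitin, ...)
on aliphatic spacers — together with lectins defined by a predominant motif
plus enhancer/inhibitor features. Binding follows a one-site saturation curve
over a concentration series with multiplicative lognormal spot noise, and six
replicate spots per glycan, so every processing stage can be exercised against
a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import MotifPattern
from .glycans import GlycanGraph, parse_condensed, to_canonical

__all__ = [
    "SimulationConfig",
    "SyntheticLectin",
    "generate_library",
    "simulate_scans",
    "simulate_dataset",
    "ground_truth",
    "synthetic_metadata",
    "example_lectins",
]

_SP_LINKERS = ("Sp0", "Sp8", "Sp12", "Sp21", "Sp24", "Sp25")

# terminal caps for complex N-glycan antennae (joined to Man via b1-2/4/6)
_ANTENNA_CAPS = (
    "GlcNAc",
    "Galb1-4GlcNAc",
    "Neu5Aca2-3Galb1-4GlcNAc",
    "Neu5Aca2-6Galb1-4GlcNAc",
    "Galb1-4(Fuca1-3)GlcNAc",
    "Galb1-4GlcNAcb1-3Galb1-4GlcNAc",
    "GalNAcb1-4GlcNAc",
)

_HIGH_MANNOSE = (
    "Mana1-3(Mana1-6)Manb1-4GlcNAcb1-4GlcNAc",
    "Mana1-2Mana1-3(Mana1-6)Manb1-4GlcNAcb1-4GlcNAc",
    "Mana1-3(Mana1-6)Mana1-6(Mana1-3)Manb1-4GlcNAcb1-4GlcNAc",
    "Mana1-3(Mana1-6)Mana1-6(Mana1-2Mana1-3)Manb1-4GlcNAcb1-4GlcNAc",
    "Mana1-3(Mana1-6)Mana1-6(Mana1-2Mana1-2Mana1-3)Manb1-4GlcNAcb1-4GlcNAc",
    "Mana1-2Mana1-3(Mana1-6)Mana1-6(Mana1-2Mana1-2Mana1-3)Manb1-4GlcNAcb1-4GlcNAc",
    "Mana1-2Mana1-3(Mana1-2Mana1-6)Mana1-6(Mana1-2Mana1-2Mana1-3)Manb1-4GlcNAcb1-4GlcNAc",
)

# free-standing terminal epitopes, optionally extended on a lactosamine stem
_EPITOPES = (
    "Fuca1-2Galb1-4GlcNAc",
    "Fuca1-2Galb1-3GlcNAc",
    "Galb1-3(Fuca1-4)GlcNAc",
    "Galb1-4(Fuca1-3)GlcNAc",
    "Fuca1-2Galb1-3(Fuca1-4)GlcNAc",
    "Fuca1-2Galb1-4(Fuca1-3)GlcNAc",
    "GalNAca1-3(Fuca1-2)Galb1-4GlcNAc",
    "Gala1-3(Fuca1-2)Galb1-4GlcNAc",
    "GalNAca1-3(Fuca1-2)Galb1-3GlcNAc",
    "Gala1-3Galb1-4GlcNAc",
    "GalNAca1-3GalNAcb1-3Gala1-4Galb1-4Glc",
    "GalNAcb1-4GlcNAc",
    "GlcNAcb1-4GlcNAc",
    "GlcNAcb1-4GlcNAcb1-4GlcNAc",
    "GlcNAcb1-4GlcNAcb1-4GlcNAcb1-4GlcNAc",
    "GlcNAcb1-4GlcNAcb1-4GlcNAcb1-4GlcNAcb1-4GlcNAc",
    "Neu5Aca2-3Galb1-4GlcNAc",
    "Neu5Aca2-6Galb1-4GlcNAc",
    "Neu5Aca2-8Neu5Aca2-3Galb1-4GlcNAc",
    "Neu5Gca2-3Galb1-4GlcNAc",
    "KDNa2-3Galb1-4GlcNAc",
    "(3S)Galb1-4GlcNAc",
    "(6S)Galb1-4GlcNAc",
    "Galb1-4(6S)GlcNAc",
    "Galb1-3GlcNAc",
    "Galb1-4GlcNAcb1-3Galb1-4GlcNAc",
    "Galb1-4GlcNAcb1-3Galb1-4GlcNAcb1-3Galb1-4GlcNAc",
    "Mana1-3Man",
    "Mana1-6Man",
    "Mana1-2Man",
)

_O_CORES = {
    1: "Galb1-3GalNAc",
    2: "Galb1-3(GlcNAcb1-6)GalNAc",
    3: "GlcNAcb1-3GalNAc",
    4: "GlcNAcb1-3(GlcNAcb1-6)GalNAc",
}


@dataclass
class SimulationConfig:
    """Array-simulation conditions: 4-point concentration series spanning
    0.1-100 µg/mL, six replicate spots, 15% multiplicative spot noise over a
    100-RFU baseline."""

    n_glycans: int = 200
    concentrations: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    spots_per_glycan: int = 6
    spot_noise_cv: float = 0.15
    baseline_rfu: float = 100.0
    n_glycan_fraction: float = 0.223
    o_glycan_fraction: float = 0.185
    seed: int = 0

    def __post_init__(self):
        if len(self.concentrations) < 2:
            raise ValueError("need >=2 concentrations")
        if self.spots_per_glycan < 4:
            raise ValueError("need >=4 spots per glycan")


@dataclass
class SyntheticLectin:
    """Generative binding model: a predominant motif gates binding; enhancers
    multiply and inhibitors suppress the bound-state affinity (fold 0 = hard
    knockout). ``label_noise`` flips the bound state of a random glycan
    fraction."""

    name: str
    predominant: MotifPattern
    enhancers: tuple[tuple[MotifPattern, float], ...] = ()
    inhibitors: tuple[tuple[MotifPattern, float], ...] = ()
    kd_scale: float = 1.0       # µg/mL at half-saturation
    max_rfu: float = 30000.0
    label_noise: float = 0.0

    def __post_init__(self):
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        for _, fold in self.enhancers + self.inhibitors:
            if fold < 0:
                raise ValueError("fold factors must be >= 0")

    def affinity(self, g: GlycanGraph) -> float:
        from .features import match_motif
        a = 1.0 if match_motif(g, self.predominant) > 0 else 0.0
        if a == 0.0:
            return 0.0
        for motif, fold in self.enhancers:
            if match_motif(g, motif) > 0:
                a *= fold
        for motif, fold in self.inhibitors:
            if match_motif(g, motif) > 0:
                a *= fold
        return a


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

def _allocate(n: int, fractions: list[float]) -> list[int]:
    """Deterministic largest-remainder allocation summing exactly to n."""
    raw = [n * f for f in fractions]
    base = [int(x) for x in raw]
    rem = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:rem]:
        base[i] += 1
    return base


def _sample_n_glycan(rng: np.random.Generator) -> str:
    if rng.random() < 0.30:
        return str(rng.choice(_HIGH_MANNOSE)) + "-" + str(rng.choice(_SP_LINKERS))
    n_ant = int(rng.integers(2, 5))
    caps = [str(rng.choice(_ANTENNA_CAPS)) for _ in range(n_ant)]
    arm3 = f"{caps[0]}b1-2"
    if n_ant >= 3:
        arm3 = f"{caps[0]}b1-2({caps[2]}b1-4)"
    arm6 = f"{caps[1]}b1-2"
    if n_ant == 4:
        arm6 = f"{caps[1]}b1-2({caps[3]}b1-6)"
    bisect = "(GlcNAcb1-4)" if rng.random() < 0.25 else ""
    core_fuc = "(Fuca1-6)" if rng.random() < 0.35 else ""
    linker = str(rng.choice(_SP_LINKERS))
    return (f"{arm3}Mana1-3({arm6}Mana1-6){bisect}"
            f"Manb1-4GlcNAcb1-4{core_fuc}GlcNAc-{linker}")


_O_GAL_CAPS = ("", "Neu5Aca2-3", "Fuca1-2")
_O_ARM6 = ("GlcNAcb1-6", "Galb1-4GlcNAcb1-6", "Neu5Aca2-3Galb1-4GlcNAcb1-6",
           "Galb1-4(Fuca1-3)GlcNAcb1-6", "Galb1-4GlcNAcb1-3Galb1-4GlcNAcb1-6")
_O_ARM3 = ("GlcNAcb1-3", "Galb1-4GlcNAcb1-3", "Galb1-3GlcNAcb1-3",
           "Neu5Aca2-3Galb1-4GlcNAcb1-3")


def _sample_o_glycan(rng: np.random.Generator) -> str:
    r = rng.random()
    if r < 0.10:
        core = "GalNAc"            # Tn
    elif r < 0.20:
        core = "Neu5Aca2-6GalNAc"  # sialyl-Tn
    else:
        which = int(rng.integers(1, 5))
        cap = str(rng.choice(_O_GAL_CAPS))
        sia6 = "(Neu5Aca2-6)" if rng.random() < 0.3 else ""
        arm6 = str(rng.choice(_O_ARM6))
        arm3 = str(rng.choice(_O_ARM3))
        if which == 1:
            core = f"{cap}Galb1-3{sia6}GalNAc"
        elif which == 2:
            core = f"{cap}Galb1-3({arm6})GalNAc"
        elif which == 3:
            core = f"{arm3}GalNAc"
        else:
            core = f"{arm3}({arm6})GalNAc"
    linker = "Thr" if rng.random() < 0.5 else "Ser"
    return f"{core}-{linker}"


def _sample_epitope(rng: np.random.Generator) -> str:
    epi = str(rng.choice(_EPITOPES))
    if epi.endswith("GlcNAc") and rng.random() < 0.4:
        epi = f"{epi}b1-3Galb1-4Glc"  # presented on a lactosamine-lactose stem
    linker = str(rng.choice(_SP_LINKERS))
    return f"{epi}-{linker}"


def generate_library(config: SimulationConfig) -> list[tuple[str, str]]:
    """Generate ``n_glycans`` unique structures as (glycan_id, canonical
    string) pairs. Category counts follow the configured fractions via exact
    largest-remainder allocation; duplicates (up to canonical form) are
    rejected and resampled. Raises when a category's template space cannot
    supply the requested unique count."""
    if config.n_glycans < 20:
        raise ValueError("n_glycans must be >= 20")
    rng = np.random.default_rng(config.seed)
    f_n, f_o = config.n_glycan_fraction, config.o_glycan_fraction
    n_n, n_o, n_epi = _allocate(config.n_glycans, [f_n, f_o, 1.0 - f_n - f_o])
    samplers = [(_sample_n_glycan, n_n), (_sample_o_glycan, n_o),
                (_sample_epitope, n_epi)]
    seen: set[str] = set()
    structures: list[str] = []
    for sampler, quota in samplers:
        got, attempts = 0, 0
        limit = 500 * max(quota, 1)
        while got < quota:
            attempts += 1
            if attempts > limit:
                raise ValueError(
                    f"template space exhausted: {sampler.__name__} produced "
                    f"{got}/{quota} unique structures")
            canon = to_canonical(parse_condensed(sampler(rng)))
            if canon in seen:
                continue
            seen.add(canon)
            structures.append(canon)
            got += 1
    return [(f"G{i + 1:04d}", s) for i, s in enumerate(structures)]


# ---------------------------------------------------------------------------
# Scan simulation and ground truth
# ---------------------------------------------------------------------------

def _bound_state(lectin: SyntheticLectin, g: GlycanGraph) -> tuple[bool, float]:
    a = lectin.affinity(g)
    return a >= 0.5, a


def simulate_scans(
    lectin: SyntheticLectin,
    library: list[tuple[str, str]],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Long-format scan table for one lectin over the concentration series.

    Mean RFU = baseline + max_rfu · affinity · c/(c + kd); replicate spots get
    i.i.d. mean-preserving multiplicative lognormal noise of the configured CV.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    graphs = {gid: parse_condensed(s) for gid, s in library}
    affinities = {gid: _bound_state(lectin, g)[1] for gid, g in graphs.items()}
    cv = config.spot_noise_cv
    sigma = float(np.sqrt(np.log1p(cv * cv))) if cv > 0 else 0.0
    rows = []
    spot_names = [f"spot{i + 1}" for i in range(config.spots_per_glycan)]
    for conc in config.concentrations:
        frac = conc / (conc + lectin.kd_scale)
        for gid, structure in library:
            a = affinities[gid]
            # label noise: per-array binding artifact (spot dropout or spurious
            # capture) flipping this glycan's bound state on this scan only
            if lectin.label_noise > 0 and rng.random() < lectin.label_noise:
                a = 0.0 if a >= 0.5 else 1.0
            mean = config.baseline_rfu + lectin.max_rfu * a * frac
            if sigma > 0:
                factors = np.exp(rng.normal(-0.5 * sigma * sigma, sigma,
                                            size=config.spots_per_glycan))
            else:
                factors = np.ones(config.spots_per_glycan)
            spots = mean * factors
            rows.append({"glycan_id": gid, "structure": structure,
                         "lectin_id": lectin.name, "concentration": conc,
                         **dict(zip(spot_names, spots))})
    return pd.DataFrame(rows)


def simulate_dataset(
    lectins: list[SyntheticLectin],
    config: SimulationConfig,
    library: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]], dict[str, pd.Series]]:
    """Full experiment: one library, scans for every lectin, plus per-lectin
    ground-truth labels. Returns (scans, library, truth)."""
    if library is None:
        library = generate_library(config)
    rng = np.random.default_rng(config.seed + 1)
    frames = [simulate_scans(lc, library, config, rng) for lc in lectins]
    truth = {lc.name: ground_truth(lc, library)[0] for lc in lectins}
    return pd.concat(frames, ignore_index=True), library, truth


def ground_truth(
    lectin: SyntheticLectin, library: list[tuple[str, str]]
) -> tuple[pd.Series, list[str]]:
    """Noise-free expected labels plus the feature names a correct rule miner
    should recover (the predominant pattern's name)."""
    labels = {}
    for gid, s in library:
        bound, _ = _bound_state(lectin, parse_condensed(s))
        labels[gid] = int(bound)
    return pd.Series(labels, name=lectin.name), pattern_feature_aliases(lectin.predominant)


def pattern_feature_aliases(pattern: MotifPattern) -> list[str]:
    """Feature-matrix column names equivalent to a motif pattern: its catalog
    name plus, for plain unanchored mono/disaccharide templates, the matching
    systematic k-mer string (those columns carry identical presence calls)."""
    from .glycans import WILDCARD_SUGAR
    names = [pattern.name]
    t = pattern.template
    plain = (pattern.anchor == "anywhere"
             and not pattern.forbidden_context
             and pattern.required_linker is None
             and all(n.sugar != WILDCARD_SUGAR for n in t.iter_nodes()))
    if plain and len(t) == 1:
        names.append(t.nodes[t.root].token())
    elif plain and len(t) == 2:
        e = t.edges[0]
        if e.anomer != "?" and e.child_carbon is not None and e.parent_carbon is not None:
            names.append(t.nodes[e.child].token() + e.linkage_str()
                         + t.nodes[e.parent].token())
    return names


# ---------------------------------------------------------------------------
# Metadata fixture
# ---------------------------------------------------------------------------

def synthetic_metadata(
    n_preparations: int = 116,
    n_duplicates: int = 42,
    n_low_activity: int = 15,
    n_incongruent: int = 2,
) -> pd.DataFrame:
    """Synthetic lectin-preparation metadata table.

    Encodes a realistic commercial-panel accounting — some preparations are
    the same lectin from a second vendor (duplicate_of), some show too little
    binding activity, and a couple bind in a way incongruent with the
    literature — with the default counts yielding 57 unique annotated lectins.
    Column layout matches the processing module's metadata contract.
    """
    n_unique = n_preparations - n_duplicates
    if n_unique <= n_low_activity + n_incongruent:
        raise ValueError("exclusions exceed unique preparations")
    rows = []
    for i in range(n_unique):
        reason = ""
        if i < n_low_activity:
            reason = "low_binding_activity"
        elif i < n_low_activity + n_incongruent:
            reason = "literature_incongruent"
        rows.append({"lectin_id": f"LEC{i + 1:03d}_vendorA", "vendor": "vendorA",
                     "lot": f"A{i + 1:04d}", "duplicate_of": "",
                     "exclude_reason": reason})
    for j in range(n_duplicates):
        base = f"LEC{(j % n_unique) + 1:03d}"
        rows.append({"lectin_id": f"{base}_vendorB_{j + 1}", "vendor": "vendorB",
                     "lot": f"B{j + 1:04d}", "duplicate_of": f"{base}_vendorA",
                     "exclude_reason": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ready-made lectin panel for demos and end-to-end tests
# ---------------------------------------------------------------------------

def epitope_decoy_panel() -> list[SyntheticLectin]:
    """Decoy lectins whose motifs live on free epitopes and O-glycans only —
    orthogonal to N-glycan-core motifs, so a core-directed target lectin's
    binders are bound by the target alone (as in a large diverse panel)."""
    mk = MotifPattern.from_string
    return [
        SyntheticLectin("DEC-H", mk("Fuca1-2Gal", "Fuca1-2Gal")),
        SyntheticLectin("DEC-aGal", mk("Gala1-3Gal", "Gala1-3Gal")),
        SyntheticLectin("DEC-3S", mk("3-O-sulfation", "(3S)*")),
        SyntheticLectin("DEC-T", mk("core 1", "Galb1-3GalNAc", anchor="root",
                                    required_linker=frozenset({"Ser", "Thr"}))),
        SyntheticLectin("DEC-sTn", mk("sialyl-Tn", "Neu5Aca2-6GalNAc", anchor="root",
                                      required_linker=frozenset({"Ser", "Thr"}))),
    ]


def diverse_decoy_panel() -> list[SyntheticLectin]:
    """Epitope decoys plus N-/O-glycan-directed binders: a panel whose joint
    coverage keeps most of the library in the analysis after the never-bound
    drop, so any one lectin's binders stay a minority of the analyzed pool —
    the regime a many-lectin array experiment operates in."""
    mk = MotifPattern.from_string
    return epitope_decoy_panel() + [
        SyntheticLectin("DEC-aMan", mk("terminal alpha-Man", "Mana?-?*",
                                       anchor="terminal")),
        SyntheticLectin("DEC-Sia3", mk("alpha2-3 sialylation", "Neu5Aca2-3Gal")),
        SyntheticLectin("DEC-Sia6", mk("alpha2-6 sialylation", "Neu5Aca2-6*")),
        SyntheticLectin("DEC-Lex", mk("Lewis x", "Galb1-4(Fuca1-3)GlcNAc",
                                      anchor="terminal")),
        SyntheticLectin("DEC-T1", mk("type 1 LacNAc", "Galb1-3GlcNAc")),
        SyntheticLectin("DEC-LDN", mk("LacdiNAc", "GalNAcb1-4GlcNAc",
                                      anchor="terminal")),
        SyntheticLectin("DEC-Lea", mk("Lewis a", "Galb1-3(Fuca1-4)GlcNAc",
                                      anchor="terminal")),
        SyntheticLectin("DEC-Tn", mk("Tn antigen", "GalNAc", anchor="root",
                                     forbidden_context=((0, "child"),),
                                     required_linker=frozenset({"Ser", "Thr"}))),
        SyntheticLectin("DEC-6S", mk("6-O-sulfation", "(6S)*")),
        SyntheticLectin("DEC-Gc", mk("Neu5Gc", "Neu5Gc")),
        SyntheticLectin("DEC-KDN", mk("KDN", "KDN")),
        SyntheticLectin("DEC-pLN", mk("polyLacNAc",
                                      "Galb1-4GlcNAcb1-3Galb1-4GlcNAc")),
        SyntheticLectin("DEC-P1", mk("Gala1-4Gal", "Gala1-4Gal")),
    ]


def planted_rule_panel(label_noise: float = 0.05) -> list[SyntheticLectin]:
    """Ground-truth-recovery experiment: a chitobiose-directed target lectin
    among decoys that bind epitope/O-glycan motifs only. No decoy binds
    N-glycans, so target binders that fail the Z-score call drop out of the
    analysis rather than polluting it; the polyLacNAc decoy keeps multi-GlcNAc
    non-carriers in the pool so GlcNAc counts cannot proxy for the motif."""
    mk = MotifPattern.from_string
    target = SyntheticLectin("TGT", mk("chitobiose", "GlcNAcb1-4GlcNAc"),
                             label_noise=label_noise)
    extras = [
        SyntheticLectin("DEC-Lea", mk("Lewis a", "Galb1-3(Fuca1-4)GlcNAc",
                                      anchor="terminal")),
        SyntheticLectin("DEC-Tn", mk("Tn antigen", "GalNAc", anchor="root",
                                     forbidden_context=((0, "child"),),
                                     required_linker=frozenset({"Ser", "Thr"}))),
        SyntheticLectin("DEC-6S", mk("6-O-sulfation", "(6S)*")),
        SyntheticLectin("DEC-Gc", mk("Neu5Gc", "Neu5Gc")),
        SyntheticLectin("DEC-KDN", mk("KDN", "KDN")),
        SyntheticLectin("DEC-P1", mk("Gala1-4Gal", "Gala1-4Gal")),
        SyntheticLectin("DEC-T1", mk("type 1 LacNAc", "Galb1-3GlcNAc")),
        SyntheticLectin("DEC-pLN", mk("polyLacNAc",
                                      "Galb1-4GlcNAcb1-3Galb1-4GlcNAc")),
    ]
    return [target] + epitope_decoy_panel() + extras


PLANTED_RULE_FEATURES = ("chitobiose", "GlcNAcb1-4GlcNAc")

BISECT_PATTERN = "Mana1-3(Mana1-6)(GlcNAcb1-4)Man"


def planted_inhibitor_panel(label_noise: float = 0.0) -> list[SyntheticLectin]:
    """Two-stage target (binds chitobiose-cored glycans unless the core
    carries a bisecting GlcNAc) in a diverse panel; the bisect-directed decoy
    keeps the inhibited glycans in the analysis."""
    mk = MotifPattern.from_string
    target = SyntheticLectin(
        "TGT", mk("chitobiose", "GlcNAcb1-4GlcNAc"),
        inhibitors=((mk("bisecting GlcNAc", BISECT_PATTERN), 0.0),),
        label_noise=label_noise)
    bis_binder = SyntheticLectin("DEC-BIS", mk("bisecting GlcNAc", BISECT_PATTERN))
    return [target, bis_binder] + diverse_decoy_panel()


def lectin_family_panels() -> list[SyntheticLectin]:
    """Two five-member lectin families sharing a predominant motif within the
    family (chitobiose vs Fucα1-2Gal) with varied affinity and dynamic range,
    for clustering-separation experiments."""
    mk = MotifPattern.from_string
    params = [(0.5, 25000.0), (1.0, 30000.0), (2.0, 35000.0),
              (1.5, 20000.0), (0.8, 40000.0)]
    fam_a = [SyntheticLectin(f"FamA{i}", mk("chitobiose", "GlcNAcb1-4GlcNAc"),
                             kd_scale=kd, max_rfu=mr)
             for i, (kd, mr) in enumerate(params)]
    fam_b = [SyntheticLectin(f"FamB{i}", mk("Fuca1-2Gal", "Fuca1-2Gal"),
                             kd_scale=kd, max_rfu=mr)
             for i, (kd, mr) in enumerate(params)]
    return fam_a + fam_b


def example_lectins() -> list[SyntheticLectin]:
    """Five lectins spanning the motif families the generator plants."""
    mk = MotifPattern.from_string
    return [
        SyntheticLectin(
            name="SynL-Man",
            predominant=mk("terminal alpha-mannose", "Mana?-?*", anchor="terminal")),
        SyntheticLectin(
            name="SynL-LacNAc",
            predominant=mk("type 2 LacNAc", "Galb1-4GlcNAc"),
            inhibitors=((mk("alpha2-6 sialylation", "Neu5Aca2-6*"), 0.0),)),
        SyntheticLectin(
            name="SynL-Fuc",
            predominant=mk("Fuca1-2Gal", "Fuca1-2Gal")),
        SyntheticLectin(
            name="SynL-Chitin",
            predominant=mk("chitobiose", "GlcNAcb1-4GlcNAc")),
        SyntheticLectin(
            name="SynL-Sia",
            predominant=mk("alpha2-3 sialylation", "Neu5Aca2-3Gal"),
            enhancers=((mk("polyLacNAc", "Galb1-4GlcNAcb1-3Galb1-4GlcNAc"), 2.0),)),
    ]
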
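"""Synthetic sequence generator for RNR annotation pipelines.

Real RNR subunits carry a handful of diagnostic residues (metal-binding
sites, the tyrosyl-radical site, the radical-transfer tyrosine pair,
catalytic sites) embedded in a mutable background.  This module emulates
exactly that structure:

* shared per-role "segment blocks" give every generated sequence of a role a
  common homologous scaffold, so alignment-based site projection works;
* diagnostic residues are planted at controlled 1-based coordinates taken
  from the published per-representative numbering (D85/E116/... on the Ia β
  representative, Y730/Y731 on α, and so on);
* substitution noise is applied outside planted sites — a ±3 window around
  every planted position is protected, so "sequence divergence" and "loss of
  a functional site" are separate dials (the knockout switch is the only way
  to destroy a site);
* toy genomes place one annotated α gene and one *hypothetical* β gene at a
  controlled offset among decoy hypothetical proteins, for discovery tests.

Everything is reproducible from (spec, seed).

The bundled reference panel is also built here
(:func:`build_reference_fixture`): it is a synthetic stand-in for the real
subclass representatives (see ``refdata`` module docstring), constructed so
that all published residue/position pairs hold exactly.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np

from .align import AMINO_ACIDS
from .discover import GenomeProtein, GenomeProteinSet
from .refdata import AnnotatedReference, SiteAnnotation, SubclassPattern

_BLOCK_SEED = 90_121_144  # fixes the shared per-role scaffolds, never user-facing

# ---------------------------------------------------------------------------
# Published coordinates used for layout
# ---------------------------------------------------------------------------

# β-subunit metal-site layouts: (site1, site2, site4, site5, length).
# Derived positions are structural across all known representatives:
# site3 = site2+3, site6 = site5+3, site7 = site2-1, site8 = site5-1,
# tyrosyl-radical site = site3+3 (Y122 on the Ia representative).
BETA_LAYOUTS: dict[str, tuple[int, int, int, int, int]] = {
    "Ia": (85, 116, 205, 239, 376),
    "Ib": (67, 98, 158, 192, 330),
    "Ic": (89, 120, 193, 227, 346),
    "Id": (67, 97, 160, 195, 320),
    "Ie": (85, 116, 176, 210, 330),
    # phage-like compact layout (site1 at 42, as on the Cyano SP clade rep)
    "phage": (42, 71, 117, 147, 315),
}

# β-subunit residues per subclass representative: metal sites 1-8 + radical site.
BETA_REF_RESIDUES: dict[str, tuple[str, ...]] = {
    #      1    2    3    4    5    6    7    8   rad
    "Ia": ("D", "E", "H", "E", "E", "H", "S", "D", "Y"),
    "Ib": ("D", "E", "H", "E", "E", "H", "M", "D", "Y"),
    "Ic": ("E", "E", "H", "E", "E", "H", "E", "D", "F"),
    "Id": ("E", "E", "H", "E", "E", "H", "C", "D", "Y"),
    "Ie": ("D", "V", "H", "P", "K", "H", "M", "D", "Y"),
}

BETA_REF_LABELS = {
    "Ia": "E. coli-like Ia beta (synthetic)",
    "Ib": "S. typhimurium-like Ib beta (synthetic)",
    "Ic": "C. trachomatis-like Ic beta (synthetic)",
    "Id": "F. johnsoniae-like Id beta (synthetic)",
    "Ie": "A. urinae-like Ie beta (synthetic)",
}

# Group pattern table: allowed residues at metal sites 1-8 per RNRdb group
# plus the Cyano SP clade, with subclass membership.
GROUP_PATTERNS_RAW: list[tuple[str, str, tuple[str, ...]]] = [
    ("NrdBe", "Ia", ("D", "E", "H", "E", "E", "H", "M/I/V", "D")),
    ("NrdBg", "Ia", ("D", "E", "H", "E", "E", "H", "S", "D")),
    ("NrdBh", "Ia_presumed", ("D", "E", "H", "E", "E", "H", "E/Q", "D")),
    ("NrdBk", "Ia_presumed", ("D", "E", "H", "E", "E", "H", "M/R/I", "D/E")),
    ("NrdBn", "Ia_presumed", ("D", "E", "H", "E", "E", "H", "E", "D")),
    ("NrdBza", "Ia_presumed", ("D", "E", "H", "E", "E", "H", "E", "D")),
    ("NrdFb", "Ib", ("D", "E", "H", "E", "E", "H", "M", "D")),
    ("NrdBzc", "Ic", ("E", "E", "H", "E", "E", "H", "E", "D")),
    ("NrdBi", "Id", ("E", "E", "H", "E", "E", "H", "C/S", "D/E")),
    ("NrdFe", "Ie", ("D", "Q/V", "H", "S/P", "K", "H", "M", "D")),
    ("CyanoSP", "If", ("E", "E", "H", "E", "E", "H", "D", "D")),
]

# radical-site residue planted in generated sequences per group
_GROUP_RADICAL = {"NrdBzc": "F", "CyanoSP": "M"}  # default otherwise: Y

# α-subunit layout (shared by all α references and the Class II reference,
# *E. coli* α numbering): catalytic C225-region anchor, N437 / C439 / E441 /
# C462 catalytic block, S625, radical-transfer pair Y730/Y731.
ALPHA_LENGTH = 745
ALPHA_CATALYTIC = {225: "C", 437: "N", 439: "C", 441: "E", 462: "C", 625: "S"}
ALPHA_YY = {730: "Y", 731: "Y"}


def group_patterns() -> list[SubclassPattern]:
    return [
        SubclassPattern(
            group=g, subclass=sc,
            allowed=tuple(frozenset(c.split("/")) for c in cells),
        )
        for g, sc, cells in GROUP_PATTERNS_RAW
    ]


# ---------------------------------------------------------------------------
# Shared scaffolds
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


@functools.lru_cache(maxsize=1)
def _blocks() -> dict[str, str]:
    """Shared homologous scaffold segments, fixed for the package version."""
    rng = np.random.default_rng(_BLOCK_SEED)
    blocks = {
        "b_head": _rand_seq(rng, 90),
        "b_seg12": _rand_seq(rng, 30),
        "b_seg23": _rand_seq(rng, 2),
        "b_seg3r": _rand_seq(rng, 2),
        "b_segr4": _rand_seq(rng, 85),
        "b_seg45": _rand_seq(rng, 35),
        "b_seg56": _rand_seq(rng, 2),
        "b_tail": _rand_seq(rng, 170),
        "a_core": _rand_seq(rng, ALPHA_LENGTH),
    }
    # β trim anchors on the Ia (E. coli-like) representative: W48 and Y356.
    # head is taken as a suffix: position 48 of an 84-residue head = index 53.
    bh = list(blocks["b_head"]); bh[53] = "W"; blocks["b_head"] = "".join(bh)
    bt = list(blocks["b_tail"]); bt[113] = "Y"; blocks["b_tail"] = "".join(bt)
    return blocks


def _beta_positions(layout: tuple[int, int, int, int, int]) -> dict[str, int]:
    p1, p2, p4, p5, length = layout
    return {
        "metal_1": p1,
        "metal_7": p2 - 1,
        "metal_2": p2,
        "metal_3": p2 + 3,
        "tyr_radical": p2 + 6,
        "metal_4": p4,
        "metal_8": p5 - 1,
        "metal_5": p5,
        "metal_6": p5 + 3,
        "_length": length,
    }


def _assemble_beta(layout: tuple[int, int, int, int, int],
                   residues: dict[str, str]) -> tuple[str, dict[str, int]]:
    """Build a β scaffold with the given site residues planted; returns
    (sequence, site positions)."""
    b = _blocks()
    pos = _beta_positions(layout)
    p1, p2, p4, p5, length = layout
    p3, rad, p6 = p2 + 3, p2 + 6, p5 + 3
    parts = [
        b["b_head"][len(b["b_head"]) - (p1 - 1):],
        residues["metal_1"],
        b["b_seg12"][: p2 - p1 - 2],
        residues["metal_7"],
        residues["metal_2"],
        b["b_seg23"],
        residues["metal_3"],
        b["b_seg3r"],
        residues["tyr_radical"],
        b["b_segr4"][: p4 - p3 - 4],
        residues["metal_4"],
        b["b_seg45"][: p5 - p4 - 2],
        residues["metal_8"],
        residues["metal_5"],
        b["b_seg56"],
        residues["metal_6"],
        b["b_tail"][: length - p6],
    ]
    seq = "".join(parts)
    assert len(seq) == length, (len(seq), length)
    del pos["_length"]
    for kind, p in pos.items():
        assert seq[p - 1] == residues[kind]
    return seq, pos


def _assemble_alpha(yy: bool = True) -> tuple[str, dict[int, str]]:
    core = list(_blocks()["a_core"])
    planted = dict(ALPHA_CATALYTIC)
    planted.update(ALPHA_YY if yy else {730: "G", 731: "A"})
    for p, r in planted.items():
        core[p - 1] = r
    return "".join(core), planted


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            protected: set[int]) -> str:
    """Substitute background positions at the given rate; 1-based positions in
    `protected` (and a ±3 window handled by the caller) are never touched."""
    chars = list(seq)
    for i in range(len(chars)):
        if (i + 1) in protected:
            continue
        if rng.random() < rate:
            choices = [c for c in AMINO_ACIDS if c != chars[i]]
            chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _protect(positions, window: int = 3) -> set[int]:
    out: set[int] = set()
    for p in positions:
        out.update(range(p - window, p + window + 1))
    return out


# ---------------------------------------------------------------------------
# Bundled reference fixture
# ---------------------------------------------------------------------------

def build_reference_fixture() -> list[AnnotatedReference]:
    """Deterministically build the 11-member synthetic reference panel.

    Five β and five α Class I subclass representatives (Ia-Ie) plus one
    Class II representative.  β references carry the published metal-site
    residue/position pairs; the Ia pair additionally carries the trim
    anchors (W48/Y356 on β; C225, N437, S625 on α).  The α/Class II
    catalytic-site list is curator-supplied (no published table enumerates
    it); it is a fixture choice, not ground truth.
    """
    refs: list[AnnotatedReference] = []
    mut_rng = np.random.default_rng(_BLOCK_SEED + 1)

    for subclass in ("Ia", "Ib", "Ic", "Id", "Ie"):
        res = BETA_REF_RESIDUES[subclass]
        residues = {f"metal_{i}": res[i - 1] for i in range(1, 9)}
        residues["tyr_radical"] = res[8]
        seq, pos = _assemble_beta(BETA_LAYOUTS[subclass], residues)
        protected = _protect(pos.values())
        if subclass == "Ia":
            protected |= _protect([48, 356])
        seq = _mutate(seq, 0.10, mut_rng, protected)
        sites = [SiteAnnotation(k, p, seq[p - 1]) for k, p in sorted(pos.items(), key=lambda x: x[1])]
        if subclass == "Ia":
            sites.append(SiteAnnotation("trim_anchor_start", 48, "W"))
            sites.append(SiteAnnotation("trim_anchor_end", 356, "Y"))
        refs.append(AnnotatedReference(
            id=f"BETA_{subclass.upper()}_SYN", label=BETA_REF_LABELS[subclass],
            role="class1_beta", subclass=subclass, sequence=seq, sites=sites,
        ))

    for subclass in ("Ia", "Ib", "Ic", "Id", "Ie"):
        seq, planted = _assemble_alpha(yy=True)
        seq = _mutate(seq, 0.10, mut_rng, _protect(planted))
        sites = [
            SiteAnnotation("other_catalytic", 225, "C"),
            SiteAnnotation("other_catalytic", 437, "N"),
            SiteAnnotation("catalytic_cys", 439, "C"),
            SiteAnnotation("other_catalytic", 441, "E"),
            SiteAnnotation("other_catalytic", 462, "C"),
            SiteAnnotation("other_catalytic", 625, "S"),
            SiteAnnotation("radical_transfer_tyr1", 730, "Y"),
            SiteAnnotation("radical_transfer_tyr2", 731, "Y"),
        ]
        if subclass == "Ia":
            sites += [
                SiteAnnotation("trim_anchor_start", 437, "N"),
                SiteAnnotation("trim_anchor_end", 625, "S"),
            ]
        refs.append(AnnotatedReference(
            id=f"ALPHA_{subclass.upper()}_SYN",
            label=f"Class I alpha {subclass} representative (synthetic)",
            role="class1_alpha", subclass=subclass, sequence=seq, sites=sites,
        ))

    seq, planted = _assemble_alpha(yy=False)
    seq = _mutate(seq, 0.15, mut_rng, _protect(planted))
    refs.append(AnnotatedReference(
        id="NRDJ_SYN", label="Class II (NrdJ) representative (synthetic)",
        role="class2", subclass=None, sequence=seq,
        sites=[
            SiteAnnotation("other_catalytic", 225, "C"),
            SiteAnnotation("other_catalytic", 437, "N"),
            SiteAnnotation("catalytic_cys", 439, "C"),
            SiteAnnotation("other_catalytic", 441, "E"),
            SiteAnnotation("other_catalytic", 462, "C"),
            SiteAnnotation("other_catalytic", 625, "S"),
        ],
    ))
    return refs


# ---------------------------------------------------------------------------
# Query generators
# ---------------------------------------------------------------------------

@dataclass
class SynthSpec:
    """Controls for the generator; defaults are the package's study conditions."""

    seed: int = 0
    noise: float = 0.05          # substitution rate outside protected windows
    layout: str = "phage"        # β metal-site layout key in BETA_LAYOUTS
    knockout: str | None = None  # site_kind whose planted residue is destroyed
    insert_length: int = 0       # planted intein-mimic insert (0 = none)
    insert_after: str = "metal_3"  # site after whose +5 offset the insert goes
    # family-set controls
    n_families: int = 3
    members_per_family: int = 4
    family_length: int = 300
    within_identity: float = 0.95
    between_identity: float = 0.40
    # genome controls
    beta_group: str = "CyanoSP"
    beta_offset: int = 1         # genes downstream of α (negative = upstream)
    beta_strand: int = 1
    decoy_lengths: tuple[int, ...] = (150, 250, 480, 600)


@dataclass
class PlantedSequence:
    sequence: str
    sites: dict[str, int]        # site_kind -> 1-based position (ground truth)
    group: str | None = None
    insert_span: tuple[int, int] | None = None  # 1-based inclusive, if planted


def make_beta(spec: SynthSpec, group: str) -> PlantedSequence:
    """Generate a β-subunit-like sequence carrying one group's metal pattern.

    Site residues are drawn from the group's allowed sets; the radical site
    gets Y except for groups defined by its loss/mutation.  With
    ``spec.knockout`` set to a metal site kind, that site's residue is
    replaced by one outside every group's allowed set.
    """
    rng = np.random.default_rng(spec.seed)
    pat = {g: allowed for g, _, allowed in (
        (p.group, p.subclass, p.allowed) for p in group_patterns())}
    if group not in pat:
        raise ValueError(f"unknown group {group!r}")
    allowed = pat[group]
    residues = {
        f"metal_{i}": sorted(allowed[i - 1])[rng.integers(len(allowed[i - 1]))]
        for i in range(1, 9)
    }
    residues["tyr_radical"] = _GROUP_RADICAL.get(group, "Y")
    seq, pos = _assemble_beta(BETA_LAYOUTS[spec.layout], residues)
    seq = _mutate(seq, spec.noise, rng, _protect(pos.values()))
    if spec.knockout is not None:
        p = pos[spec.knockout]
        seq = seq[: p - 1] + "G" + seq[p:]  # G is in no group's allowed set
    insert_span = None
    if spec.insert_length > 0:
        at = pos[spec.insert_after] + 20  # insert after this residue, clear of site windows
        ins = _rand_seq(rng, spec.insert_length)
        seq = seq[:at] + ins + seq[at:]
        insert_span = (at + 1, at + spec.insert_length)
        pos = {k: (p if p <= at else p + spec.insert_length) for k, p in pos.items()}
    return PlantedSequence(sequence=seq, sites=pos, group=group, insert_span=insert_span)


def make_alpha(spec: SynthSpec, with_yy: bool = True) -> PlantedSequence:
    """Generate an α-like (with_yy) or Class II-like (not with_yy) sequence."""
    rng = np.random.default_rng(spec.seed)
    seq, planted = _assemble_alpha(yy=with_yy)
    seq = _mutate(seq, spec.noise, rng, _protect(planted))
    sites = {"catalytic_cys": 439, "radical_transfer_tyr1": 730,
             "radical_transfer_tyr2": 731}
    return PlantedSequence(sequence=seq, sites=sites)


def make_family_set(spec: SynthSpec) -> tuple[dict[str, str], dict[str, str]]:
    """Sequence families at controlled within/between identities.

    Returns (sequences keyed by id, family label per id).  Identities are
    targeted by mutation counts from a shared ancestor (gapless), so realized
    pairwise identity lands within a few percentage points of the targets.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.family_length
    k = max(0, round(L * (1.0 - spec.within_identity) / 2))
    mf = max(0, round(L * (1.0 - spec.between_identity) / 2) - k)
    ancestor = _rand_seq(rng, L)

    def mutate_n(s: str, n: int) -> str:
        chars = list(s)
        for i in rng.choice(L, size=min(n, L), replace=False):
            choices = [c for c in AMINO_ACIDS if c != chars[i]]
            chars[i] = choices[rng.integers(len(choices))]
        return "".join(chars)

    seqs: dict[str, str] = {}
    labels: dict[str, str] = {}
    for f in range(spec.n_families):
        founder = mutate_n(ancestor, mf)
        for m in range(spec.members_per_family):
            sid = f"fam{f}_m{m}"
            seqs[sid] = mutate_n(founder, k)
            labels[sid] = f"fam{f}"
    return seqs, labels


def make_genome(spec: SynthSpec) -> tuple[GenomeProteinSet, dict[str, str]]:
    """Toy phage genome: one annotated α, one hidden (hypothetical) β at a
    controlled gene offset, plus decoy hypothetical proteins in and out of
    the 200-500 aa discovery window.

    Returns (genome, truth) with truth = {"alpha": id, "beta": id}.
    """
    rng = np.random.default_rng(spec.seed)
    alpha = make_alpha(replace(spec, seed=int(rng.integers(2**31))))
    beta = make_beta(replace(spec, seed=int(rng.integers(2**31))), spec.beta_group)

    entries: list[tuple[str, str, int, str]] = []  # (id, seq, strand, status)
    for i, dl in enumerate(spec.decoy_lengths):
        entries.append((f"decoy_{i}", _rand_seq(rng, dl), 1, "hypothetical"))
    # place α among the decoys, β at the requested gene offset from α
    mid = len(entries) // 2
    entries.insert(mid, ("alpha_gene", alpha.sequence, 1, "annotated"))
    # after the α insertion, α sits at index mid; offset +1 = directly after
    beta_idx = mid + spec.beta_offset if spec.beta_offset > 0 else mid + spec.beta_offset + 1
    beta_idx = max(0, min(len(entries), beta_idx))
    entries.insert(beta_idx, ("beta_gene", beta.sequence, spec.beta_strand, "hypothetical"))

    proteins = []
    start = 100
    for pid, seq, strand, status in entries:
        end = start + 3 * len(seq) + 2
        proteins.append(GenomeProtein(
            protein_id=pid, sequence=seq, start=start, end=end,
            strand=strand, status=status,
        ))
        start = end + 50
    genome = GenomeProteinSet(genome_id=f"synth_genome_{spec.seed}", proteins=proteins)
    return genome, {"alpha": "alpha_gene", "beta": "beta_gene"}
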
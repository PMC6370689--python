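"""β-subunit discovery in an annotated phage genome.

A Class I α subunit without a partner β is a red flag: either the genome
truly lacks one (and the enzyme is misclassified) or the β gene is hiding
among the hypothetical proteins.  Discovery proceeds in three stages:

1. **length filter** — unannotated proteins within a size window (Class I β
   subunits run ~350-400 aa; the default window 200-500 is deliberately
   generous);
2. **residue screen** — candidates are aligned to the annotated β
   representatives and must carry the full first sphere of metal-binding
   residues;
3. **adjacency ranking** — surviving candidates are ordered by genomic
   context, favouring the gene directly downstream of the α subunit on the
   same strand, the arrangement typical of Class I operons.

Strand handling for "directly downstream" is not settled usage; the default
requires the same strand and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import sites as sites_mod
from .align import ScoringConfig, align_to_profile


@dataclass(frozen=True)
class GenomeProtein:
    protein_id: str
    sequence: str
    start: int            # 1-based inclusive, GenBank convention
    end: int
    strand: int           # +1 / -1
    status: str           # "annotated" | "hypothetical"

    def __post_init__(self):
        if self.start < 0 or self.end < 0:
            raise ValueError(f"{self.protein_id}: negative coordinates")
        if self.status not in ("annotated", "hypothetical"):
            raise ValueError(f"{self.protein_id}: unknown status {self.status!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeProteinSet:
    genome_id: str
    proteins: list[GenomeProtein]

    def __post_init__(self):
        self.proteins = sorted(self.proteins, key=lambda p: (p.start, p.protein_id))

    def index_of(self, protein_id: str) -> int:
        for i, p in enumerate(self.proteins):
            if p.protein_id == protein_id:
                return i
        raise KeyError(protein_id)

    def get(self, protein_id: str) -> GenomeProtein:
        return self.proteins[self.index_of(protein_id)]


@dataclass
class BetaCandidate:
    protein_id: str
    length: int
    passed_length: bool = True
    passed_residues: bool | None = None
    adjacency: str | None = None     # downstream_of_alpha | upstream | distant
    gene_distance: int | None = None
    rank: int | None = None
    missing_sites: list[str] = field(default_factory=list)


def read_genbank(path: str | Path) -> GenomeProteinSet:
    """Read an annotated genome from a GenBank flat file (CDS features with
    translations).  A product/annotation of 'hypothetical protein' marks a
    protein as unannotated."""
    from Bio import SeqIO

    record = SeqIO.read(str(path), "genbank")
    proteins = []
    for feat in record.features:
        if feat.type != "CDS" or "translation" not in feat.qualifiers:
            continue
        pid = feat.qualifiers.get("protein_id", feat.qualifiers.get("locus_tag", ["?"]))[0]
        product = " ".join(feat.qualifiers.get("product", [""])).lower()
        status = "hypothetical" if "hypothetical" in product or not product else "annotated"
        proteins.append(GenomeProtein(
            protein_id=pid,
            sequence=feat.qualifiers["translation"][0],
            start=int(feat.location.start) + 1,
            end=int(feat.location.end),
            strand=1 if (feat.location.strand or 1) >= 0 else -1,
            status=status,
        ))
    return GenomeProteinSet(genome_id=record.id, proteins=proteins)


def length_filter(genome: GenomeProteinSet, min_len: int = 200,
                  max_len: int = 500) -> list[BetaCandidate]:
    """Unannotated proteins with min_len <= length <= max_len (inclusive)."""
    return [
        BetaCandidate(protein_id=p.protein_id, length=p.length)
        for p in genome.proteins
        if p.status == "hypothetical" and min_len <= p.length <= max_len
    ]


def residue_screen(candidates: list[BetaCandidate], genome: GenomeProteinSet,
                   refs, config: ScoringConfig | None = None) -> list[BetaCandidate]:
    """Mark candidates carrying the full essential β residue complement.

    A candidate passes iff profile extraction against the β references finds
    every first-sphere metal site present (mapped, correct residue class).
    """
    beta_refs = [r for r in refs if r.role == "class1_beta"]
    if not beta_refs:
        raise ValueError("no class1_beta references supplied")
    for cand in candidates:
        seq = genome.get(cand.protein_id).sequence
        prof_aln = align_to_profile(seq, beta_refs, query_id=cand.protein_id, config=config)
        profile = sites_mod.extract_profile(seq, beta_refs, prof_aln)
        missing = sites_mod.missing_essential(profile, "class1_beta")
        cand.missing_sites = missing
        cand.passed_residues = not missing
    return candidates


def adjacency_rank(candidates: list[BetaCandidate], alpha_id: str,
                   genome: GenomeProteinSet, same_strand: bool = True) -> list[BetaCandidate]:
    """Rank candidates: residue survivors first, then directly-downstream
    adjacency to the α gene, then gene distance; id breaks ties."""
    ai = genome.index_of(alpha_id)
    alpha = genome.proteins[ai]
    for cand in candidates:
        ci = genome.index_of(cand.protein_id)
        # orientation relative to transcription of the α gene
        delta = (ci - ai) * alpha.strand
        cand.gene_distance = abs(ci - ai)
        strand_ok = (genome.proteins[ci].strand == alpha.strand) or not same_strand
        if delta == 1 and strand_ok:
            cand.adjacency = "downstream_of_alpha"
        elif delta == -1 and strand_ok:
            cand.adjacency = "upstream"
        else:
            cand.adjacency = "distant"
    order = {"downstream_of_alpha": 0, "upstream": 1, "distant": 2}
    ranked = sorted(
        candidates,
        key=lambda c: (
            not c.passed_residues,
            order[c.adjacency],
            c.gene_distance,
            c.protein_id,
        ),
    )
    for i, c in enumerate(ranked, start=1):
        c.rank = i
    return ranked


def discover_beta(genome: GenomeProteinSet, alpha_id: str, refs,
                  min_len: int = 200, max_len: int = 500,
                  config: ScoringConfig | None = None) -> list[BetaCandidate]:
    """Full pipeline: length filter, residue screen, adjacency ranking."""
    cands = length_filter(genome, min_len, max_len)
    cands = residue_screen(cands, genome, refs, config)
    return adjacency_rank(cands, alpha_id, genome)
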
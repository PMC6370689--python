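"""Pairwise and query-to-reference-panel alignment with coordinate mapping.

Annotated active sites live in 1-based ungapped *reference* coordinates
(the field's "D85"-style numbering).  Everything downstream — residue
extraction, classification, trimming, intein excision — needs those
coordinates projected onto a query sequence.  This module provides global
alignment under BLOSUM62 with affine gaps and a :class:`PositionMap` that
formalises "the query residue aligning with reference position p".
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass(frozen=True)
class ScoringConfig:
    """Scoring for protein alignment.

    Gap penalty convention: a gap run of length k costs ``open + k * extend``
    (so the first gapped residue costs ``open + extend``).  ``x_neutral``
    rescores every substitution involving X to 0: an X is alignable but
    carries no evidence, and it never satisfies a residue rule.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    x_neutral: bool = True
    mode: str = "global"
    illegal: str = "reject"  # or "as_x"

    def substitution_matrix(self):
        return _load_matrix(self.matrix_name, self.x_neutral)


@functools.lru_cache(maxsize=8)
def _load_matrix(name: str, x_neutral: bool):
    m = substitution_matrices.load(name)
    if x_neutral and "X" in m.alphabet:
        m = m.copy()
        xi = m.alphabet.index("X")
        m[xi, :] = 0.0
        m[:, xi] = 0.0
    return m


@functools.lru_cache(maxsize=8)
def _aligner(config: ScoringConfig) -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.substitution_matrix = config.substitution_matrix()
    # Biopython charges open_gap_score for the first gapped position and
    # extend_gap_score per further position; translate our convention.
    aln.open_gap_score = -(config.gap_open + config.gap_extend)
    aln.extend_gap_score = -config.gap_extend
    if config.mode == "semiglobal":
        # free end gaps on the query side: fragments align into the
        # reference without paying for the reference overhangs
        aln.mode = "global"
        try:
            aln.end_deletion_score = 0.0
        except AttributeError:  # older Biopython naming
            aln.query_end_gap_score = 0.0
    else:
        aln.mode = config.mode
    return aln


def _clean(seq: str, config: ScoringConfig, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    seq = seq.upper()
    alphabet = set(AMINO_ACIDS + "X")
    bad = set(seq) - alphabet
    if bad:
        if config.illegal == "as_x":
            seq = "".join(c if c in alphabet else "X" for c in seq)
        else:
            raise ValueError(f"{name}: illegal residue(s) {sorted(bad)}")
    return seq


@dataclass
class Alignment:
    """A gapped alignment: equal-length rows over residues plus ``-``."""

    rows: list[str]
    row_ids: list[str]
    score: float | None = None

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        if len(self.rows) != len(self.row_ids):
            raise ValueError("row_ids/rows length mismatch")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def row(self, row_id: str) -> str:
        return self.rows[self.row_ids.index(row_id)]


@dataclass
class PositionMap:
    """Partial map from ungapped reference positions to query positions.

    Both sides are 1-based.  Undefined where the query has a gap under a
    reference residue.  Strictly increasing on its domain (colinearity).
    """

    mapping: dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_alignment(cls, ref_row: str, query_row: str) -> "PositionMap":
        mapping: dict[int, int] = {}
        rpos = qpos = 0
        for rc, qc in zip(ref_row, query_row):
            if rc != GAP:
                rpos += 1
            if qc != GAP:
                qpos += 1
            if rc != GAP and qc != GAP:
                mapping[rpos] = qpos
        return cls(mapping)

    def get(self, ref_pos: int) -> int | None:
        return self.mapping.get(ref_pos)

    def is_monotonic(self) -> bool:
        items = sorted(self.mapping.items())
        return all(b[1] > a[1] for a, b in zip(items, items[1:]))


def global_align(
    a: str, b: str, config: ScoringConfig | None = None, ids: tuple[str, str] = ("a", "b")
) -> Alignment:
    """Optimal global alignment of two protein sequences.

    Deterministic: when co-optimal alignments exist, Biopython's first
    traceback is taken.
    """
    config = config or ScoringConfig()
    a = _clean(a, config, ids[0])
    b = _clean(b, config, ids[1])
    result = _aligner(config).align(a, b)
    best = result[0]
    return Alignment(rows=[str(best[0]), str(best[1])], row_ids=list(ids), score=best.score)


def local_align_score(a: str, b: str, config: ScoringConfig | None = None) -> float:
    """Smith-Waterman score under the same scoring config (for SSN edges)."""
    config = config or ScoringConfig(mode="local")
    if config.mode != "local":
        config = ScoringConfig(
            config.matrix_name, config.gap_open, config.gap_extend, config.x_neutral, "local",
            config.illegal,
        )
    a = _clean(a, config, "a")
    b = _clean(b, config, "b")
    return float(_aligner(config).score(a, b))


def percent_identity(
    a: str, b: str, mode: str = "over-shorter", config: ScoringConfig | None = None
) -> float:
    """Pairwise identity in [0, 1] from the emitted global alignment.

    mode="over-shorter" divides match columns by the shorter ungapped length
    (the CD-HIT convention, and the default); "over-alignment" divides by the
    number of alignment columns.
    """
    aln = global_align(a, b, config)
    matches = sum(
        1 for x, y in zip(aln.rows[0], aln.rows[1]) if x == y and x != GAP
    )
    if mode == "over-shorter":
        denom = min(len(aln.ungapped(0)), len(aln.ungapped(1)))
    elif mode == "over-alignment":
        denom = aln.column_count
    else:
        raise ValueError(f"unknown identity mode {mode!r}")
    return matches / denom if denom else 0.0


@dataclass
class ProfileAlignment:
    """A query aligned against a panel of annotated references.

    One global pairwise alignment (and its PositionMap) per reference;
    annotated-site consistency across references of a role is checked at
    extraction time, with conflicts resolved toward the highest-scoring
    reference.  ``unalignable(role)`` is the no-shared-region signal: every
    annotated site of every reference of that role fails to map.
    """

    query_id: str
    query: str
    alignments: dict[str, Alignment] = field(default_factory=dict)
    maps: dict[str, PositionMap] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)
    references: dict[str, object] = field(default_factory=dict)  # ref_id -> AnnotatedReference

    def refs_with_role(self, role: str) -> list:
        return [r for r in self.references.values() if r.role == role]

    def unalignable(self, role: str) -> bool:
        refs = self.refs_with_role(role)
        if not refs:
            return True
        for ref in refs:
            pm = self.maps[ref.id]
            if any(pm.get(s.position) is not None for s in ref.sites):
                return False
        return True


def align_to_profile(
    query: str,
    refs: Iterable,
    query_id: str = "query",
    config: ScoringConfig | None = None,
) -> ProfileAlignment:
    """Align a query against each annotated reference in a panel.

    The references of one role stay mutually consistent because their site
    annotations name homologous positions (site kinds); per-kind column
    agreement is assessed downstream when residues are extracted.
    """
    config = config or ScoringConfig()
    prof = ProfileAlignment(query_id=query_id, query=query)
    for ref in refs:
        aln = global_align(ref.sequence, query, config, ids=(ref.id, query_id))
        prof.alignments[ref.id] = aln
        prof.maps[ref.id] = PositionMap.from_alignment(aln.rows[0], aln.rows[1])
        prof.scores[ref.id] = aln.score if aln.score is not None else 0.0
        prof.references[ref.id] = ref
    return prof
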
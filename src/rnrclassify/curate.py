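"""Reference-set curation: dereplication, intein excision, functionality
filtering, region-of-interest trimming and greedy identity clustering.

These are the standard preparation steps applied before building large-scale
alignments, trees and similarity networks from curated RNR sequence sets:

* drop exact duplicates and sub-strings;
* excise long query-only insertions (inteins are mobile self-splicing
  elements that confound phylogenetics) relative to the annotated role
  profile, refusing any excision that would disturb an annotated site;
* remove sequences lacking essential catalytic residues (likely
  pseudogenes);
* trim to shared regions of interest defined by anchor residues on the
  reference (N437-S625 for the α+Class II combined region, from C225 for
  α-only, W48-Y356 for β), which also strips mobile ATP-cone and fused
  glutaredoxin domains;
* cluster greedily at fixed identity thresholds (longest-first seeding, the
  CD-HIT strategy) with a coverage constraint on the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import sites as sites_mod
from .align import GAP, ScoringConfig, align_to_profile, global_align, percent_identity
from .refdata import AnnotatedReference


@dataclass(frozen=True)
class TrimSpec:
    """Anchor intervals, in 1-based reference coordinates, per trimming mode.

    ``end = None`` means "to the end of whatever aligns" (used by the
    α-only mode, anchored only at its start).
    """

    ref_id: str
    start: int
    end: int | None

    def __post_init__(self):
        if self.end is not None and self.start >= self.end:
            raise ValueError("start anchor must precede end anchor")


def default_trimspecs(refs: list[AnnotatedReference]) -> dict[str, TrimSpec]:
    """The three standard modes, validated against the reference panel:
    combined (N437-S625 on the Ia α reference), alpha_only (from C225),
    beta (W48-Y356 on the Ia β reference)."""
    alpha = next(r for r in refs if r.role == "class1_alpha" and r.subclass == "Ia")
    beta = next(r for r in refs if r.role == "class1_beta" and r.subclass == "Ia")
    for ref, pos, letter in ((alpha, 437, "N"), (alpha, 625, "S"), (alpha, 225, "C"),
                             (beta, 48, "W"), (beta, 356, "Y")):
        if ref.sequence[pos - 1] != letter:
            raise ValueError(
                f"{ref.id}: expected {letter} at anchor position {pos}, "
                f"found {ref.sequence[pos - 1]}"
            )
    return {
        "combined": TrimSpec(alpha.id, 437, 625),
        "alpha_only": TrimSpec(alpha.id, 225, None),
        "beta": TrimSpec(beta.id, 48, 356),
    }


@dataclass
class Cluster:
    representative: str
    members: list[str]            # includes the representative
    threshold: float
    coverage: float
    identities: dict[str, float] = field(default_factory=dict)


@dataclass
class InteinReport:
    excised: list[tuple[int, int]] = field(default_factory=list)  # 1-based inclusive spans
    flagged: bool = False
    reason: str = ""


def dereplicate(seqs: dict[str, str]) -> dict[str, str]:
    """Remove exact duplicates and sub-string matches; the longest sequence
    of each redundant set is retained (ties broken by id)."""
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    kept: dict[str, str] = {}
    for sid in order:
        s = seqs[sid]
        if any(s in ks for ks in kept.values()):
            continue
        kept[sid] = s
    return {k: seqs[k] for k in seqs if k in kept}


def remove_inteins(seq: str, refs: list[AnnotatedReference], min_insert: int = 50,
                   config: ScoringConfig | None = None,
                   query_id: str = "query",
                   site_margin: int = 3) -> tuple[str, InteinReport]:
    """Excise contiguous query-only insertions >= min_insert columns
    relative to the best-aligning reference of the panel.

    Excision is refused (sequence returned unchanged, flagged for manual
    review) when an insertion overlaps or directly abuts the ±site_margin
    context window of an extracted diagnostic site — insert boundaries are
    an approximation, and cutting into a site's context risks destroying the
    evidence the pipeline runs on — or when re-extraction after excision
    would change any site call.
    """
    report = InteinReport()
    prof = align_to_profile(seq, refs, query_id=query_id, config=config)
    best = max(refs, key=lambda r: (prof.scores[r.id], r.id))
    aln = prof.alignments[best.id]
    ref_row, q_row = aln.rows

    spans: list[tuple[int, int]] = []  # 1-based inclusive query spans
    qpos = 0
    run_start = None
    run_len = 0
    for rc, qc in zip(ref_row, q_row):
        if qc != GAP:
            qpos += 1
        if rc == GAP and qc != GAP:
            if run_start is None:
                run_start = qpos
            run_len += 1
        else:
            if run_start is not None and run_len >= min_insert:
                spans.append((run_start, run_start + run_len - 1))
            run_start, run_len = None, 0
    if run_start is not None and run_len >= min_insert:
        spans.append((run_start, run_start + run_len - 1))
    if not spans:
        return seq, report

    role_refs = [r for r in refs if r.role == best.role]
    before = sites_mod.extract_profile(seq, role_refs, prof)
    for call in before.calls.values():
        if not call.present:
            continue
        for s, e in spans:
            if s - site_margin <= call.query_position <= e + site_margin:
                report.flagged = True
                report.reason = (
                    f"insertion ({s}-{e}) overlaps context of site "
                    f"{call.site_key} at {call.query_position}"
                )
                return seq, report
    trimmed = []
    last = 0
    for s, e in spans:
        trimmed.append(seq[last:s - 1])
        last = e
    trimmed.append(seq[last:])
    new_seq = "".join(trimmed)

    # realign and verify no site call was disturbed
    prof2 = align_to_profile(new_seq, refs, query_id=query_id, config=config)
    after = sites_mod.extract_profile(new_seq, role_refs, prof2)
    for key, call in before.calls.items():
        call2 = after.call(key)
        if call.present and (call2 is None or not call2.present
                             or call2.residue != call.residue):
            report.flagged = True
            report.reason = f"excision would disturb site {key}"
            return seq, report
    report.excised = spans
    return new_seq, report


def filter_functional(seqs: dict[str, str], refs: list[AnnotatedReference],
                      role: str, config: ScoringConfig | None = None) -> dict[str, str]:
    """Keep only sequences whose profile carries every essential site for the
    role (present, with the expected residue class)."""
    role_refs = [r for r in refs if r.role == role]
    kept = {}
    for sid, s in seqs.items():
        prof_aln = align_to_profile(s, role_refs, query_id=sid, config=config)
        profile = sites_mod.extract_profile(s, role_refs, prof_aln)
        if not sites_mod.missing_essential(profile, role):
            kept[sid] = s
    return kept


def trim_roi(seq: str, trimspec: TrimSpec, refs: list[AnnotatedReference],
             config: ScoringConfig | None = None, min_cover: float = 0.3) -> str:
    """Return the query residues mapping within the anchor interval of the
    trim reference.  The query is aligned semi-globally (reference overhangs
    are free), so re-trimming a trimmed sequence is a no-op.  When fewer
    than ``min_cover`` of the interval's reference positions map, the query
    is unalignable in the region of interest and the result is empty."""
    ref = next(r for r in refs if r.id == trimspec.ref_id)
    config = config or ScoringConfig(mode="semiglobal")
    prof = align_to_profile(seq, [ref], config=config)
    pm = prof.maps[ref.id]
    end = trimspec.end if trimspec.end is not None else len(ref.sequence)
    qpos = [q for p in range(trimspec.start, end + 1) if (q := pm.get(p)) is not None]
    if len(qpos) < min_cover * (end - trimspec.start + 1):
        return ""
    return seq[min(qpos) - 1: max(qpos)]


def greedy_cluster(seqs: dict[str, str], threshold: float,
                   coverage: float = 0.8, identity_mode: str = "over-shorter",
                   config: ScoringConfig | None = None,
                   skip: bool = False) -> list[Cluster]:
    """CD-HIT-style greedy clustering.

    Sequences are sorted longest-first (ties by id); each is assigned to the
    first existing representative with identity >= threshold whose alignment
    covers >= coverage of the alignment length (columns where both rows have
    residues / total columns); otherwise it seeds a new cluster.  With
    ``skip`` every sequence passes through as its own singleton cluster
    (used for sets that must not be collapsed before phylogenetics).
    """
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    if skip:
        return [Cluster(sid, [sid], threshold, coverage) for sid in order]
    clusters: list[Cluster] = []
    for sid in order:
        placed = False
        for cl in clusters:
            rep_seq = seqs[cl.representative]
            aln = global_align(rep_seq, seqs[sid], config)
            both = sum(1 for a, b in zip(*aln.rows) if a != GAP and b != GAP)
            cov = both / aln.column_count if aln.column_count else 0.0
            ident = percent_identity(rep_seq, seqs[sid], identity_mode, config)
            if ident >= threshold and cov >= coverage:
                cl.members.append(sid)
                cl.identities[sid] = ident
                placed = True
                break
        if not placed:
            clusters.append(Cluster(sid, [sid], threshold, coverage, {sid: 1.0}))
    return clusters


def write_clusters(clusters: list[Cluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("representative\tmember\tidentity\n")
        for cl in clusters:
            for m in cl.members:
                fh.write(f"{cl.representative}\t{m}\t{cl.identities.get(m, 1.0):.4f}\n")
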
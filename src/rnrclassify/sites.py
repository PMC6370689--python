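"""Diagnostic-residue extraction: project annotated reference sites onto a query.

The unit of evidence downstream is a :class:`ResidueProfile`: for every
annotated site kind of a reference role, either the (query position, residue)
pair sitting in the aligned column, or "absent" when the query has a gap
there.  Multi-instance site kinds (the catalytic set on α/Class II
references) are indexed by their order along the reference, which is how
homology across references of a role is expressed.

When two references of the same role disagree about where a site lands on
the query, the site is reported with a ``conflict`` flag and the residue
from the highest-scoring reference alignment is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .align import ProfileAlignment
from .refdata import FIRST_SPHERE, METAL_SITES

_MULTI_KINDS = {"other_catalytic"}

# Residue classes seen at each first-sphere metal site across characterised
# groups; used as the "expected residue class" in essentiality checks.
METAL_SITE_CLASSES: dict[str, frozenset[str]] = {
    "metal_1": frozenset("DE"),
    "metal_2": frozenset("EQV"),
    "metal_3": frozenset("H"),
    "metal_4": frozenset("ESP"),
    "metal_5": frozenset("EK"),
    "metal_6": frozenset("H"),
}

ESSENTIAL_SITES: dict[str, tuple[str, ...]] = {
    "class1_beta": FIRST_SPHERE,
    # catalytic complement shared by Class I α and Class II
    "class1_alpha": ("catalytic_cys", "other_catalytic#0", "other_catalytic#1",
                     "other_catalytic#2", "other_catalytic#3", "other_catalytic#4"),
    "class2": ("catalytic_cys", "other_catalytic#0", "other_catalytic#1",
               "other_catalytic#2", "other_catalytic#3", "other_catalytic#4"),
}


@dataclass
class SiteCall:
    site_key: str                 # e.g. "metal_1" or "other_catalytic#2"
    site_kind: str
    query_position: int | None    # None = absent
    residue: str | None
    ref_id: str | None = None
    ref_position: int | None = None
    ref_residue: str | None = None
    flag: str = ""                # "", "conflict"

    @property
    def present(self) -> bool:
        return self.query_position is not None


@dataclass
class ResidueProfile:
    query_id: str
    role: str
    calls: dict[str, SiteCall] = field(default_factory=dict)

    def call(self, site_key: str) -> SiteCall | None:
        return self.calls.get(site_key)

    def residue(self, site_key: str) -> str | None:
        c = self.calls.get(site_key)
        return c.residue if c and c.present else None

    def position(self, site_key: str) -> int | None:
        c = self.calls.get(site_key)
        return c.query_position if c and c.present else None

    def metal_residues(self) -> list[str | None]:
        """Residues at metal sites 1..8 in order (None where absent)."""
        return [self.residue(k) for k in METAL_SITES]

    def to_rows(self) -> list[dict]:
        return [
            {
                "query_id": self.query_id, "site_key": c.site_key,
                "site_kind": c.site_kind, "ref_id": c.ref_id or "",
                "ref_position": c.ref_position or "",
                "query_position": c.query_position if c.present else "absent",
                "residue": c.residue or "", "flag": c.flag,
            }
            for c in self.calls.values()
        ]


def _site_keys(ref) -> list[tuple[str, object]]:
    """(site_key, SiteAnnotation) pairs; multi-instance kinds indexed by
    position order within the reference."""
    keyed = []
    counters: dict[str, int] = {}
    for s in sorted(ref.sites, key=lambda x: x.position):
        if s.site_kind.startswith("trim_anchor"):
            continue
        if s.site_kind in _MULTI_KINDS:
            i = counters.get(s.site_kind, 0)
            counters[s.site_kind] = i + 1
            keyed.append((f"{s.site_kind}#{i}", s))
        else:
            keyed.append((s.site_kind, s))
    return keyed


def extract_profile(query: str, refs, alignment: ProfileAlignment,
                    role: str | None = None) -> ResidueProfile:
    """Assemble the ResidueProfile of a query from a profile alignment.

    ``refs`` selects which references contribute (they must be present in the
    alignment); when ``role`` is None it is taken from the references, which
    must then share one role.
    """
    refs = list(refs)
    roles = {r.role for r in refs}
    if role is None:
        if len(roles) != 1:
            raise ValueError(f"references span roles {sorted(roles)}; pass role=")
        role = next(iter(roles))
    chosen = [r for r in refs if r.role == role]
    if not chosen:
        raise ValueError(f"no reference with role {role!r} in alignment")

    # candidates per site key across references of the role
    candidates: dict[str, list[tuple[float, str, object, int | None]]] = {}
    kinds: dict[str, str] = {}
    for ref in chosen:
        pm = alignment.maps[ref.id]
        score = alignment.scores.get(ref.id, 0.0)
        for key, site in _site_keys(ref):
            kinds[key] = site.site_kind
            candidates.setdefault(key, []).append(
                (score, ref.id, site, pm.get(site.position))
            )

    profile = ResidueProfile(query_id=alignment.query_id, role=role)
    for key, cands in candidates.items():
        mapped = [(sc, rid, site, qp) for sc, rid, site, qp in cands if qp is not None]
        if not mapped:
            sc, rid, site, _ = min(cands, key=lambda c: (-c[0], c[1]))
            profile.calls[key] = SiteCall(
                site_key=key, site_kind=kinds[key], query_position=None,
                residue=None, ref_id=rid, ref_position=site.position,
                ref_residue=site.residue,
            )
            continue
        flag = "conflict" if len({qp for _, _, _, qp in mapped}) > 1 else ""
        sc, rid, site, qp = min(mapped, key=lambda c: (-c[0], c[1]))
        profile.calls[key] = SiteCall(
            site_key=key, site_kind=kinds[key], query_position=qp,
            residue=query[qp - 1], ref_id=rid, ref_position=site.position,
            ref_residue=site.residue, flag=flag,
        )
    return profile


def has_radical_transfer_pair(profile: ResidueProfile) -> bool:
    """True iff the radical-transfer tyrosine pair is intact: both sites map,
    both query residues are Y, and the two positions are consecutive in the
    peptide (query coordinates, not alignment columns)."""
    t1 = profile.call("radical_transfer_tyr1")
    t2 = profile.call("radical_transfer_tyr2")
    return bool(
        t1 and t2 and t1.present and t2.present
        and t1.residue == "Y" and t2.residue == "Y"
        and t2.query_position == t1.query_position + 1
    )


def missing_essential(profile: ResidueProfile, role: str) -> list[str]:
    """Essential sites absent or outside the expected residue class.

    β: the six first-sphere metal sites must be present with residues in the
    class seen across characterised groups.  α/Class II: the shared catalytic
    complement must be present with the reference residue.
    """
    missing = []
    for key in ESSENTIAL_SITES[role]:
        c = profile.call(key)
        if c is None or not c.present:
            missing.append(key)
            continue
        if key in METAL_SITE_CLASSES:
            if c.residue not in METAL_SITE_CLASSES[key]:
                missing.append(key)
        elif c.residue != c.ref_residue:
            missing.append(key)
    return missing


def profile_from_metal_residues(residues, tyr_radical: str | None = None,
                                query_id: str = "q") -> ResidueProfile:
    """Build a β-role profile directly from an 8-tuple of metal residues
    (None = absent), for rule-only use without sequences or alignments."""
    p = ResidueProfile(query_id=query_id, role="class1_beta")
    for i, r in enumerate(residues, start=1):
        if r is not None:
            key = f"metal_{i}"
            p.calls[key] = SiteCall(key, key, 10 * i, r)
    if tyr_radical is not None:
        p.calls["tyr_radical"] = SiteCall("tyr_radical", "tyr_radical", 95, tyr_radical)
    return p


def write_profile_report(profiles: list[ResidueProfile], path: str | Path) -> None:
    cols = ["query_id", "site_key", "site_kind", "ref_id", "ref_position",
            "query_position", "residue", "flag"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in profiles:
            for row in p.to_rows():
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")
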
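"""Rule-based RNR class and Class I subclass assignment.

Class call
----------
* A full first sphere of metal-binding residues (plus the tyrosyl-radical
  region covered by the β references) marks a **Class I β** subunit.
* The catalytic complement shared by Class I α and Class II, *with* the
  intact consecutive radical-transfer tyrosine pair (Y730/Y731 in the Ia
  representative's numbering), marks a **Class I α** subunit; the same
  complement *without* the pair marks a **Class II** enzyme — the pair is
  the single discriminating feature between the two.
* Anything else is unassigned (a value, not an error).

Subclass call (β only, inherited by paired α)
---------------------------------------------
The eight metal-site residues are matched by exact set membership against
the per-group allowed-residue table.  A unique full-pattern match gives that
group's subclass; no match at all is the "novel" outcome (the evidence that
first motivated erecting a new subclass for the Cyano SP clade); multiple
matches are reported, not arbitrated — overlapping groups are resolved
phylogenetically, which is a separate evidence channel.

Mixed-subclass groups have their own splitting rules: NrdBz splits on the
tyrosyl-radical residue (Y -> NrdBza/Ia, F/L/V -> NrdBzc/Ic), NrdF on
whether the carboxylates at metal sites 2, 4 and 5 are conserved (-> NrdFb/Ib)
or all replaced (-> NrdFe/Ie).

α subunits cannot be subclassed from primary sequence; they inherit the
subclass of their genome's β partner, and an α with zero or multiple β
partners is excluded from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import sites as sites_mod
from .align import ScoringConfig, align_to_profile
from .refdata import FIRST_SPHERE, METAL_SITES, SubclassPattern
from .sites import ResidueProfile

CARBOXYLATE = frozenset("DE")


@dataclass
class ClassificationResult:
    query_id: str
    class_call: str = "unassigned"        # class1_alpha | class1_beta | class2 | unassigned
    subclass_call: str = "unassigned"     # Ia | Ia_presumed | Ib | Ic | Id | Ie | If | novel | unassigned
    matched_groups: list[str] = field(default_factory=list)
    evidence: list[tuple[str, str]] = field(default_factory=list)

    def add(self, rule: str, outcome: str) -> None:
        self.evidence.append((rule, outcome))


@dataclass
class SubunitPairing:
    alpha_id: str
    beta_ids: list[str] = field(default_factory=list)
    status: str = "unpaired"              # paired | unpaired | ambiguous
    inherited_subclass: str | None = None


def call_class(profiles: dict[str, ResidueProfile]) -> tuple[str, list[tuple[str, str]]]:
    """Class call from per-role residue profiles.

    ``profiles`` maps role -> ResidueProfile for the same query extracted
    against class1_beta, class1_alpha and class2 references.
    Returns (class_call, evidence).
    """
    evidence: list[tuple[str, str]] = []
    beta = profiles.get("class1_beta")
    if beta is not None:
        missing = sites_mod.missing_essential(beta, "class1_beta")
        evidence.append(("beta_first_sphere", "complete" if not missing
                         else f"missing:{','.join(missing)}"))
        if not missing:
            return "class1_beta", evidence

    alpha = profiles.get("class1_alpha")
    if alpha is not None:
        missing = sites_mod.missing_essential(alpha, "class1_alpha")
        evidence.append(("shared_catalytic", "complete" if not missing
                         else f"missing:{','.join(missing)}"))
        if not missing:
            has_pair = sites_mod.has_radical_transfer_pair(alpha)
            evidence.append(("radical_transfer_pair", "present" if has_pair else "absent"))
            return ("class1_alpha" if has_pair else "class2"), evidence
    return "unassigned", evidence


def match_metal_pattern(profile: ResidueProfile, patterns: list[SubclassPattern],
                        first_sphere_only: bool = False) -> list[str]:
    """Groups whose allowed-residue sets admit the profile's metal residues.

    Exact set membership at every site (1-6 in first-sphere mode, 1-8
    otherwise); an absent site matches nothing.
    """
    residues = profile.metal_residues()
    return [p.group for p in patterns if p.matches(residues, first_sphere_only)]


def match_first_sphere_references(profile: ResidueProfile, refs) -> list[str]:
    """Subclasses of the β representatives whose first-sphere residues equal
    the profile's, site for site (the representative-matching mode)."""
    residues = profile.metal_residues()[:6]
    out = []
    for ref in refs:
        if ref.role != "class1_beta":
            continue
        ref_res = [s.residue if (s := ref.site(k)) else None for k in FIRST_SPHERE]
        if all(r is not None and r == q for r, q in zip(ref_res, residues)):
            out.append(ref.subclass)
    return out


def split_nrdbz(profile: ResidueProfile) -> str:
    """NrdBz subgroup from the tyrosyl-radical residue: Y -> NrdBza (Ia);
    F/L/V -> NrdBzc (Ic); anything else, including absent -> unassigned."""
    r = profile.residue("tyr_radical")
    if r == "Y":
        return "NrdBza"
    if r in ("F", "L", "V"):
        return "NrdBzc"
    return "unassigned"


def split_nrdf(profile: ResidueProfile) -> str:
    """NrdF subgroup from carboxylate conservation at metal sites 2, 4, 5:
    all carboxylate -> NrdFb (Ib); all non-carboxylate -> NrdFe (Ie);
    mixed or incomplete -> unassigned."""
    res = [profile.residue(k) for k in ("metal_2", "metal_4", "metal_5")]
    if any(r is None for r in res):
        return "unassigned"
    carbox = [r in CARBOXYLATE for r in res]
    if all(carbox):
        return "NrdFb"
    if not any(carbox):
        return "NrdFe"
    return "unassigned"


def call_subclass(profile: ResidueProfile, patterns: list[SubclassPattern],
                  result: ClassificationResult | None = None) -> ClassificationResult:
    """Subclass call for a β profile by full 8-site pattern matching.

    Unique match -> that group's subclass (the Ia-presumed label is kept
    distinct).  Zero matches -> "novel".  Multiple matches -> all reported,
    subclass unassigned with ambiguity evidence.
    """
    result = result or ClassificationResult(query_id=profile.query_id)
    groups = match_metal_pattern(profile, patterns)
    result.matched_groups = groups
    residues = profile.metal_residues()
    if any(r is None for r in residues):
        absent = [METAL_SITES[i] for i, r in enumerate(residues) if r is None]
        result.add("metal_sites", f"absent:{','.join(absent)}")
        result.subclass_call = "unassigned"
        return result
    if len(groups) == 1:
        by_group = {p.group: p.subclass for p in patterns}
        result.subclass_call = by_group[groups[0]]
        result.add("full_pattern", f"unique:{groups[0]}")
    elif not groups:
        result.subclass_call = "novel"
        result.add("full_pattern", "no_group_matched")
    else:
        result.subclass_call = "unassigned"
        result.add("full_pattern", f"ambiguous:{','.join(groups)}")
    return result


def classify_sequence(query: str, refs, patterns: list[SubclassPattern],
                      query_id: str = "query",
                      config: ScoringConfig | None = None) -> ClassificationResult:
    """End-to-end classification of one protein sequence.

    Aligns the query to the full reference panel, extracts per-role residue
    profiles, calls the class, and (for β calls) the subclass.
    """
    refs = list(refs)
    prof_aln = align_to_profile(query, refs, query_id=query_id, config=config)
    profiles = {}
    for role in ("class1_beta", "class1_alpha", "class2"):
        role_refs = [r for r in refs if r.role == role]
        if role_refs and not prof_aln.unalignable(role):
            profiles[role] = sites_mod.extract_profile(query, role_refs, prof_aln)
    result = ClassificationResult(query_id=query_id)
    if not profiles:
        result.add("alignment", "unalignable")
        return result
    class_call, evidence = call_class(profiles)
    result.class_call = class_call
    result.evidence.extend(evidence)
    if class_call == "class1_beta":
        call_subclass(profiles["class1_beta"], patterns, result)
    return result


def pair_subunits(alphas: list[ClassificationResult],
                  betas: list[ClassificationResult],
                  correspondence: dict[str, list[str]]) -> list[SubunitPairing]:
    """Pair α subunits with β subunits and apply the exclusion rule.

    ``correspondence`` maps alpha_id -> candidate beta_ids (e.g. the β genes
    of the same genome).  An α paired with exactly one β inherits that β's
    subclass; zero or multiple partners -> excluded (unpaired / ambiguous).
    """
    beta_by_id = {b.query_id: b for b in betas}
    pairings = []
    for a in alphas:
        partner_ids = [i for i in correspondence.get(a.query_id, []) if i in beta_by_id]
        p = SubunitPairing(alpha_id=a.query_id, beta_ids=partner_ids)
        if len(partner_ids) == 1:
            p.status = "paired"
            p.inherited_subclass = beta_by_id[partner_ids[0]].subclass_call
        elif not partner_ids:
            p.status = "unpaired"
        else:
            p.status = "ambiguous"
        pairings.append(p)
    return pairings
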
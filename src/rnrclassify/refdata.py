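"""Domain model for annotated subclass representatives and residue-pattern tables.

The classification rules operate on two curated inputs:

* **Annotated references** — one biochemically characterised representative
  per Class I subclass (a-e) for each subunit role (α and β) plus a Class II
  representative, each carrying 1-based site annotations: the tyrosyl-radical
  site, the six first-sphere and two second-sphere metal-binding sites (β),
  the radical-transfer tyrosine pair Y730/Y731 (α, *E. coli* numbering),
  catalytic sites shared between Class I α and Class II, and trim anchors for
  region-of-interest extraction.

* **Group patterns** — per RNRdb group (NrdBe, NrdBg, ..., plus the Cyano SP
  clade), the allowed residue set at each of the eight metal-binding sites,
  and the group's Class I subclass.

The bundled fixture (``data/references_synthetic.*``) is a synthetic
stand-in reference set: deterministic sequences constructed so that every
diagnostic residue sits at its published coordinate (e.g. D85/E116/H119/
E205/E239/H242 with S115/D238 on the Ia β representative).  The catalytic
site list for α/Class II references is curator-supplied, not a published
table.  A fetch helper can refresh the set from live accessions, but nothing
in the package requires network access.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

ROLES = ("class1_alpha", "class1_beta", "class2")

METAL_SITES = tuple(f"metal_{i}" for i in range(1, 9))
FIRST_SPHERE = METAL_SITES[:6]
SECOND_SPHERE = METAL_SITES[6:]

SITE_KINDS = (
    "tyr_radical",
    *METAL_SITES,
    "radical_transfer_tyr1",
    "radical_transfer_tyr2",
    "catalytic_cys",
    "other_catalytic",
    "trim_anchor_start",
    "trim_anchor_end",
)

_BETA_ONLY = {"tyr_radical", *METAL_SITES}
_ALPHA_ONLY = {"radical_transfer_tyr1", "radical_transfer_tyr2"}

SUBCLASSES = ("Ia", "Ia_presumed", "Ib", "Ic", "Id", "Ie", "If")


class SchemaError(ValueError):
    """A malformed row in a reference or pattern file."""


class IntegrityError(ValueError):
    """Annotation disagrees with the sequence it annotates."""


@dataclass(frozen=True)
class SiteAnnotation:
    site_kind: str
    position: int  # 1-based, ungapped reference coordinates
    residue: str

    def __post_init__(self):
        if self.site_kind not in SITE_KINDS:
            raise SchemaError(f"unknown site_kind {self.site_kind!r}")
        if self.position < 1:
            raise SchemaError(f"position must be >= 1, got {self.position}")
        if len(self.residue) != 1:
            raise SchemaError(f"residue must be one letter, got {self.residue!r}")


@dataclass
class AnnotatedReference:
    id: str
    label: str
    role: str
    sequence: str
    sites: list[SiteAnnotation] = field(default_factory=list)
    subclass: str | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise SchemaError(f"{self.id}: unknown role {self.role!r}")
        self.validate()

    def validate(self) -> None:
        for s in self.sites:
            if s.position > len(self.sequence):
                raise IntegrityError(
                    f"{self.id}: site {s.site_kind} position {s.position} beyond "
                    f"sequence length {len(self.sequence)}"
                )
            letter = self.sequence[s.position - 1]
            if letter != s.residue:
                raise IntegrityError(
                    f"{self.id}: site {s.site_kind} records {s.residue}{s.position} "
                    f"but sequence has {letter} at position {s.position}"
                )
            if s.site_kind in _BETA_ONLY and self.role != "class1_beta":
                raise IntegrityError(
                    f"{self.id}: {s.site_kind} only valid on class1_beta references"
                )
            if s.site_kind in _ALPHA_ONLY and self.role != "class1_alpha":
                raise IntegrityError(
                    f"{self.id}: {s.site_kind} only valid on class1_alpha references"
                )

    def site(self, kind: str) -> SiteAnnotation | None:
        for s in self.sites:
            if s.site_kind == kind:
                return s
        return None

    def sites_of_kind(self, kind: str) -> list[SiteAnnotation]:
        return [s for s in self.sites if s.site_kind == kind]

    def metal_sites(self) -> dict[str, SiteAnnotation]:
        return {k: s for k in METAL_SITES if (s := self.site(k)) is not None}


@dataclass
class SubclassPattern:
    """Allowed residues at metal sites 1-8 for one RNRdb group / clade."""

    group: str
    subclass: str
    allowed: tuple[frozenset[str], ...]  # length 8, sites 1..8

    def __post_init__(self):
        if len(self.allowed) != 8:
            raise SchemaError(f"{self.group}: need 8 allowed-residue sets")
        if any(not a for a in self.allowed):
            raise SchemaError(f"{self.group}: empty allowed set")
        if self.subclass not in SUBCLASSES:
            raise SchemaError(f"{self.group}: unknown subclass {self.subclass!r}")
        # Sites 3 and 6 are the invariant histidines in every known group.
        for idx in (2, 5):
            if self.allowed[idx] != frozenset("H"):
                raise SchemaError(
                    f"{self.group}: site {idx + 1} must allow only H"
                )

    def matches(self, residues: Iterable[str | None], first_sphere_only: bool = False) -> bool:
        residues = list(residues)
        n = 6 if first_sphere_only else 8
        if len(residues) < n:
            return False
        return all(
            residues[i] is not None and residues[i] in self.allowed[i] for i in range(n)
        )


def _read_fasta(path: Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def load_references(
    table_path: str | Path,
    fasta_path: str | Path | None = None,
    require_full_set: bool = False,
) -> list[AnnotatedReference]:
    """Load annotated references from a site table plus companion FASTA.

    The table is TSV with columns (ref_id, label, role, subclass, site_kind,
    position, residue); one row per annotated site.  Sequences come from the
    companion FASTA keyed by ref_id (default: same stem, ``.faa`` suffix).

    With ``require_full_set`` the bundled-set invariant is enforced: exactly
    one α and one β representative per Class I subclass a-e.
    """
    table_path = Path(table_path)
    fasta_path = Path(fasta_path) if fasta_path else table_path.with_suffix(".faa")
    if not table_path.exists():
        raise FileNotFoundError(table_path)
    seqs = _read_fasta(fasta_path)

    meta: dict[str, dict] = {}
    sites: dict[str, list[SiteAnnotation]] = {}
    with open(table_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"ref_id", "label", "role", "subclass", "site_kind", "position", "residue"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise SchemaError(f"{table_path}: expected columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            try:
                rid = row["ref_id"].strip()
                ann = SiteAnnotation(
                    site_kind=row["site_kind"].strip(),
                    position=int(row["position"]),
                    residue=row["residue"].strip(),
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise SchemaError(f"{table_path} line {i}: {exc}") from exc
            meta.setdefault(
                rid,
                {
                    "label": row["label"].strip(),
                    "role": row["role"].strip(),
                    "subclass": row["subclass"].strip() or None,
                },
            )
            sites.setdefault(rid, []).append(ann)

    refs = []
    for rid, m in meta.items():
        if rid not in seqs:
            raise SchemaError(f"{table_path}: no sequence for {rid} in {fasta_path}")
        refs.append(
            AnnotatedReference(
                id=rid, label=m["label"], role=m["role"], subclass=m["subclass"],
                sequence=seqs[rid], sites=sites[rid],
            )
        )
    if require_full_set:
        for role in ("class1_alpha", "class1_beta"):
            have = sorted(r.subclass for r in refs if r.role == role)
            if have != ["Ia", "Ib", "Ic", "Id", "Ie"]:
                raise IntegrityError(
                    f"reference set must carry exactly one {role} representative per "
                    f"subclass Ia-Ie, got {have}"
                )
    return refs


def load_patterns(path: str | Path) -> list[SubclassPattern]:
    """Load the group residue-pattern table.

    TSV columns: group, subclass, site1..site8; alternatives separated by
    ``/`` (``M/I/V`` means {M, I, V}).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    patterns = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = {"group", "subclass", *(f"site{i}" for i in range(1, 9))}
        if reader.fieldnames is None or not cols.issubset(reader.fieldnames):
            raise SchemaError(f"{path}: expected columns {sorted(cols)}")
        for i, row in enumerate(reader, start=2):
            try:
                allowed = tuple(
                    frozenset(x.strip() for x in row[f"site{j}"].split("/") if x.strip())
                    for j in range(1, 9)
                )
                patterns.append(
                    SubclassPattern(
                        group=row["group"].strip(),
                        subclass=row["subclass"].strip(),
                        allowed=allowed,
                    )
                )
            except SchemaError as exc:
                raise SchemaError(f"{path} line {i}: {exc}") from exc
    return patterns


def serialize_references(refs: list[AnnotatedReference], table_path: str | Path,
                         fasta_path: str | Path | None = None) -> None:
    """Write references back to the TSV + FASTA schema (round-trip safe)."""
    table_path = Path(table_path)
    fasta_path = Path(fasta_path) if fasta_path else table_path.with_suffix(".faa")
    with open(table_path, "w") as fh:
        fh.write("ref_id\tlabel\trole\tsubclass\tsite_kind\tposition\tresidue\n")
        for r in refs:
            for s in r.sites:
                fh.write(
                    f"{r.id}\t{r.label}\t{r.role}\t{r.subclass or ''}\t"
                    f"{s.site_kind}\t{s.position}\t{s.residue}\n"
                )
    with open(fasta_path, "w") as fh:
        for r in refs:
            fh.write(f">{r.id} {r.label}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i:i + 60] + "\n")


def serialize_patterns(patterns: list[SubclassPattern], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group\tsubclass\t" + "\t".join(f"site{i}" for i in range(1, 9)) + "\n")
        for p in patterns:
            cells = ["/".join(sorted(a)) for a in p.allowed]
            fh.write(f"{p.group}\t{p.subclass}\t" + "\t".join(cells) + "\n")


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("rnrclassify") / "data" / name))


def bundled_references() -> list[AnnotatedReference]:
    """The bundled synthetic stand-in reference panel (11 references)."""
    return load_references(
        _data_path("references_synthetic.tsv"),
        _data_path("references_synthetic.faa"),
        require_full_set=True,
    )


def bundled_patterns() -> list[SubclassPattern]:
    """The bundled group pattern table (11 groups incl. Cyano SP)."""
    return load_patterns(_data_path("group_patterns.tsv"))
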
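# Methods

## Scope and model

The package implements residue-rule annotation of ribonucleotide reductase
(RNR) class and Class I subclass, plus the curation, clustering, network
and phylogeny steps that surround it.  The underlying model is the standard
one in RNR biochemistry: a small number of diagnostic residues — the six
first-sphere and two second-sphere metal-binding sites of the β subunit,
the tyrosyl-radical site, the consecutive radical-transfer tyrosine pair of
the α subunit, and a shared α/Class II catalytic complement — carry the
class and subclass signal, while the rest of the sequence is free to
diverge.  Class III enzymes share no usable sequence similarity with
Classes I/II and are outside scope by construction: the reference panel has
no Class III role, so such sequences come back `unassigned`.

All rules operate on residues projected from annotated references onto the
query through explicit alignments, never on absolute query positions.

## Reference panel (synthetic stand-in)

The bundled panel (`data/references_synthetic.*`) contains one α and one β
representative per subclass Ia–Ie plus one Class II representative.  The
sequences are *synthetic*: each role has a shared set of randomly generated
scaffold segments, and each representative is assembled from those segments
with per-representative segment lengths chosen so that every published
residue lands on its published coordinate — e.g. the Ia β row
D85/E116/H119/E205/E239/H242 with second sphere S115/D238 and the radical
tyrosine at 122, the Ie β row with V116/P176/K210, the trim anchors W48 and
Y356 on the Ia β and C225/N437/S625 on the Ia α, and the Y730/Y731 pair on
every α.  A further 10% background substitution rate (15% for the Class II
representative) is applied outside ±3-residue windows around planted
positions, so the panel members are homologous but not identical
(pairwise ~80–85% identity).

Two consequences matter for interpretation:

* Real subclass representatives are far more divergent (often 25–45%
  identity).  Passing tests on this panel demonstrates the correctness of
  the *rules and plumbing* (coordinate mapping, extraction, pattern
  matching, trimming, clustering, discovery logic), not the alignment
  difficulty of real RNR data; with real references the alignment stage
  inherits MAFFT-class difficulty that the synthetic scaffolds do not pose.
* The α/Class II catalytic-site list (C225-analog, N437, C439, E441, C462,
  S625, with Y730/Y731 on α only) is curator-supplied — no published table
  in the source material enumerates it — and is flagged as a fixture
  choice, not ground truth.

The panel is regenerated bit-identically by
`rnrclassify.synth.build_reference_fixture()`; a test asserts the shipped
files match the builder's output.  Real reference sets load through the
same schema (TSV of per-site annotations + FASTA), with integrity checks
that every recorded residue equals the sequence letter at its position.

## Alignment

Pairwise global alignment uses BLOSUM62 with affine gaps; a gap run of
length k costs `open + k·extend` with defaults open = 10, extend = 1.  The
gap penalties are a community default and are exposed in `ScoringConfig`;
the downstream rules depend only on site columns, which are robust to small
penalty changes at the conservation levels involved.  `X` is rescored to 0
against everything and never satisfies a residue rule: a rule asserts the
identity of a specific amino acid, which an `X` cannot attest.

`align_to_profile` replaces manual alignment curation: the query is aligned
pairwise against every reference in the panel, and annotated site kinds
express homology across references of a role (multi-instance kinds are
indexed by their order along the reference).  When two same-role references
place a site at different query positions, the site is reported with a
`conflict` flag and the residue from the highest-scoring reference is used
— a deterministic stand-in for manual resolution.  A query on which no site
of a role maps is reported `unalignable` for that role, not an error.  This
per-reference-pairwise design was chosen over a literal query-into-MSA
threading because it keeps every coordinate map exact and the conflict
channel explicit; the observable contract (position maps, anchoring,
conflict handling) is the same.

Region-of-interest trimming aligns semi-globally (reference overhangs
free), which makes trimming idempotent; a query mapping fewer than 30% of
the interval's reference positions is "unalignable in the ROI" and returns
empty.

## Classification rules

* **Essential β complement**: metal sites 1–6 present, residues within the
  classes seen across characterised groups (site 1 ∈ {D,E}, site 2 ∈
  {E,Q,V}, sites 3/6 = H, site 4 ∈ {E,S,P}, site 5 ∈ {E,K}).  Second-sphere
  sites are diagnostic but not essential.
* **Class call order**: β evidence first, then α/Class II.  The
  radical-transfer pair must be two tyrosines at *consecutive query
  positions* — the biological statement is about the peptide, so adjacency
  is enforced in query coordinates, not alignment columns.
* **Pattern matching** is exact set membership at all 8 sites (or 1–6 in
  first-sphere mode); no partial credit.  "Carboxylate" in the NrdF split
  means {D, E}.  Multiple full-pattern matches are reported rather than
  resolved by precedence, because group rows overlap (NrdBn and NrdBza are
  identical; NrdBh's E/Q covers both) and such cases are resolved
  phylogenetically, a separate evidence channel.  The "Ia presumed" label
  is kept distinct from Ia to preserve the epistemic difference.

## Curation

Dereplication removes exact and substring duplicates, keeping the longest
(ties by id).  Intein-like excision removes contiguous query-only
insertions of ≥ 50 alignment columns (configurable) relative to the
best-scoring reference; excision is refused and flagged when an insertion
overlaps or abuts (±3 residues) the context of any extracted site, or when
re-extraction after excision would change a site call.  The 50-column
threshold and the refusal margin are artifact decisions — the original
procedure was manual — and every excision is reported, never silent.
Greedy clustering is CD-HIT-style: longest-first seeding (ties by id),
first-fit assignment at identity ≥ threshold under a coverage constraint
(fraction of alignment columns where both rows have residues).  Identity
defaults to matches over the shorter sequence (the CD-HIT convention);
matches over alignment length is available.  A `skip` flag passes a set
through uncollapsed, for collections that must not be clustered before
phylogenetics.

## Networks and trees

SSN nodes are 90%-identity greedy clusters; edges join node representatives
whose optimal local alignment converts to an alignment score
−log₁₀E ≥ 90, with E = K·m·n·e^(−λS) under fixed gapped BLOSUM62 constants
λ = 0.267, K = 0.041 (documented so the threshold is interpretable).
Neighbor joining is implemented directly with a fixed tie-break (lowest
index pair on equal Q), clamping negative length estimates to zero; on
additive matrices it recovers the generating metric exactly, which is the
correctness oracle, and it is cross-checked against scikit-bio's NJ in a
test.  It stands in for approximate-ML tree building deliberately:
desk-scale determinism, topology-level claims only.  Clade queries answer
unrooted monophyly by edge-split enumeration and report the label
composition of the subtrees adjacent to the attachment point.

## Discovery

Candidate β genes are unannotated proteins of 200–500 aa (inclusive; real
β subunits run ~350–400, the window is deliberately generous), screened for
the full essential β complement, then ranked: residue survivors first, then
adjacency (directly downstream of the α gene > directly upstream > distant,
ties by gene distance then id).  "Directly downstream" requires the same
strand by default — the operonic α–β arrangement — and is configurable,
since usage varies.  Genome coordinates follow the GenBank 1-based
inclusive convention.

## Synthetic data

The generator emulates exactly the structure the rules assume: shared
scaffolds with planted diagnostic residues, substitution noise (default
5%) that never touches ±3-residue windows around planted sites — so
divergence and loss-of-function are separate dials, with `knockout` the
only way to destroy a site — optional intein-mimic inserts, families at
mutation-count-controlled identities, and toy genomes with one annotated α,
one hypothetical β at a controlled gene offset, and decoys inside and
outside the length window.  Background residues are uniform over the
20-letter alphabet; diagnostic sites carry all the signal.  What the
generator does *not* emulate: indel processes along a phylogeny,
composition bias, and realistic inter-family divergence — see the caveat
under the reference panel.

## Problem sizes and numerical choices

The shipped checks run at desk scale: 10,000 random residue tuples for
rule-engine equivalence, 1,000 random additive matrices (3–8 taxa, branch
lengths U(0.1, 1)) for NJ recovery at 1e-9, 200 random sequence sets (≤ 8
sequences, 20–40 aa) for clustering equivalence, and 100 synthetic genomes
for discovery.  Determinism throughout: fixed seeds, lexicographic
tie-breaks, and first-traceback selection among co-optimal alignments.

## Known limitations

* The synthetic reference panel understates real alignment difficulty (see
  above); accession-anchored checks against real proteins require network
  access and are not part of the offline suite.
* Excision boundaries for intein-like inserts are approximate (co-optimal
  alignments can shift a boundary by a residue); all excisions are
  reported with coordinates.
* The SSN "fraction" parameter of the original network protocol has no
  closed-form meaning here and is not functional; the E-value constants
  are fixed, not fitted.
* No bootstrap support, ML model selection, or visualization.
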
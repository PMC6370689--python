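# rnrclassify

Rule-based (re)annotation of ribonucleotide reductases (RNRs) from conserved
residues, with the supporting curation, similarity-network and phylogeny
machinery needed to place divergent clades.

## The problem

RNRs catalyze the rate-limiting step of DNA synthesis and are split into
three classes by their radical-generation chemistry: Class I (O₂-dependent,
two subunits — a catalytic α and a radical-generating β), Class II
(B₁₂-dependent, single *nrdJ* gene) and Class III (O₂-sensitive).  Class I
is further divided into subclasses (Ia–Ie) by the β subunit's
metallocofactor and use of the tyrosyl-radical site.  Because Class I α and
Class II share catalytic machinery but differ sharply in biology, and
because a Class I annotation rests on finding *both* subunits,
misannotation is rampant — most notoriously in phage genomes, where highly
divergent β subunits hide among "hypothetical proteins".  For viral
ecologists using RNR as a marker gene, a wrong class call propagates into
wrong inferences about oxygen, B₁₂ and metal requirements.

This package turns the residue-level evidence used by RNR specialists into
an explicit, testable rule engine:

* **Class call.**  A full first coordination sphere of metal-binding
  residues (six sites, with invariant histidines at sites 3 and 6) marks a
  Class I β subunit.  The shared α/Class II catalytic complement *plus* the
  consecutive radical-transfer tyrosine pair (Y730/Y731 in *E. coli* α
  numbering) marks Class I α; the same complement without the pair marks
  Class II.
* **Subclass call.**  The eight metal-site residues (first sphere 1–6,
  second sphere 7–8) are matched by exact set membership against per-group
  allowed-residue patterns (NrdBe, NrdBg, …, plus the Cyano SP clade).  A
  unique match yields that group's subclass; *no* match is the "novel
  subclass" signal; multiple matches are reported, not arbitrated.
  Mixed groups split by their own rules: NrdBz on the tyrosyl-radical
  residue (Y → Ia, F/L/V → Ic), NrdF on carboxylate conservation at metal
  sites 2/4/5 (conserved → Ib, all lost → Ie).  α subunits inherit the
  subclass of their unique β partner; α with zero or several partners is
  excluded.
* **β discovery.**  Hidden β genes are found by a length window (200–500
  aa) over unannotated proteins, an essential-residue screen against
  annotated subclass representatives, and ranking by genomic adjacency
  (directly downstream of the α gene, same strand).
* **Supporting analyses.**  CD-HIT-style greedy identity clustering,
  region-of-interest trimming anchored on reference coordinates
  (N437–S625 / from C225 / W48–Y356), intein-like insert excision,
  EFI-EST-style sequence similarity networks (edge = −log₁₀ E-value of the
  local alignment ≥ 90), and neighbor-joining trees with clade-placement
  queries.

Site positions are always 1-based ungapped reference coordinates ("D85"),
projected onto queries through explicit alignment position maps.

The bundled reference panel is a **synthetic stand-in**: deterministic
sequences constructed so every published diagnostic residue sits at its
published coordinate (see `docs/methods.md`).  Real reference sets load
through the same TSV + FASTA schema.

## Worked example

```python
from rnrclassify import bundled_references, bundled_patterns, classify_sequence, synth

refs, patterns = bundled_references(), bundled_patterns()
beta = synth.make_beta(synth.SynthSpec(seed=1), "CyanoSP")
result = classify_sequence(beta.sequence, refs, patterns, query_id="cyano_sp_beta")
print(result.class_call, result.subclass_call, result.matched_groups)
```

prints

```
class1_beta If ['CyanoSP']
```

the query carries a complete first sphere (→ Class I β) and its eight
metal-site residues (E,E,H,E,E,H,D,D) match exactly one group pattern — the
Cyano SP clade row, i.e. the proposed novel subclass If.  Running
`python examples/02_discover_hidden_beta.py` shows the discovery pipeline
ranking a hidden β gene first in a toy phage genome:

```
rank  protein     len  residues  adjacency
1     beta_gene   315  True      downstream_of_alpha
2     decoy_1     250  False     upstream
3     decoy_2     480  False     distant
```

The other scripts under `examples/` walk through curation/clustering and
network/tree placement.  A thin CLI mirrors the library
(`rnr-classify classify|curate|ssn|tree|discover-beta|synth`).

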
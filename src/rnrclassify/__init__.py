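"""rnrclassify: residue-rule annotation of ribonucleotide reductase (RNR)
class and Class I subclass, with the supporting curation, similarity-network
and phylogeny machinery needed to place divergent clades.

Typical entry points:

* :func:`rnrclassify.classify.classify_sequence` — class + subclass call for
  one protein against the bundled reference panel;
* :func:`rnrclassify.discover.discover_beta` — find a hidden β subunit gene
  in an annotated phage genome;
* :mod:`rnrclassify.curate` / :mod:`rnrclassify.graphs` — dereplication,
  trimming, clustering, similarity networks, neighbor-joining trees;
* :mod:`rnrclassify.synth` — reproducible synthetic data with ground truth.
"""

from . import align, classify, curate, discover, graphs, refdata, sites, synth
from .classify import ClassificationResult, classify_sequence
from .discover import discover_beta
from .refdata import bundled_patterns, bundled_references

__version__ = "0.1.0"

__all__ = [
    "align", "classify", "curate", "discover", "graphs", "refdata", "sites",
    "synth", "ClassificationResult", "classify_sequence", "discover_beta",
    "bundled_patterns", "bundled_references", "__version__",
]
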
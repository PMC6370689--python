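import pytest

from rnrclassify import bundled_patterns, bundled_references


@pytest.fixture(scope="session")
def refs():
    return bundled_references()


@pytest.fixture(scope="session")
def beta_refs(refs):
    return [r for r in refs if r.role == "class1_beta"]


@pytest.fixture(scope="session")
def alpha_refs(refs):
    return [r for r in refs if r.role == "class1_alpha"]


@pytest.fixture(scope="session")
def patterns():
    return bundled_patterns()


# Published β-representative metal-site rows: subclass -> residues at metal
# sites 1..8 and their 1-based positions.  Frozen independently of the
# fixture builder; the bundled references must reproduce these exactly.
TABLE3 = {
    "Ia": (("D", 85), ("E", 116), ("H", 119), ("E", 205), ("E", 239), ("H", 242),
           ("S", 115), ("D", 238)),
    "Ib": (("D", 67), ("E", 98), ("H", 101), ("E", 158), ("E", 192), ("H", 195),
           ("M", 97), ("D", 191)),
    "Ic": (("E", 89), ("E", 120), ("H", 123), ("E", 193), ("E", 227), ("H", 230),
           ("E", 119), ("D", 226)),
    "Id": (("E", 67), ("E", 97), ("H", 100), ("E", 160), ("E", 195), ("H", 198),
           ("C", 96), ("D", 194)),
    "Ie": (("D", 85), ("V", 116), ("H", 119), ("P", 176), ("K", 210), ("H", 213),
           ("M", 115), ("D", 209)),
}

# Independent copy of the group pattern table (allowed residues at metal
# sites 1..8), used by brute-force oracles.  Kept separate from the package's
# bundled TSV on purpose.
GROUP_TABLE = {
    "NrdBe":  ("D", "E", "H", "E", "E", "H", "MIV", "D"),
    "NrdBg":  ("D", "E", "H", "E", "E", "H", "S", "D"),
    "NrdBh":  ("D", "E", "H", "E", "E", "H", "EQ", "D"),
    "NrdBk":  ("D", "E", "H", "E", "E", "H", "MRI", "DE"),
    "NrdBn":  ("D", "E", "H", "E", "E", "H", "E", "D"),
    "NrdBza": ("D", "E", "H", "E", "E", "H", "E", "D"),
    "NrdFb":  ("D", "E", "H", "E", "E", "H", "M", "D"),
    "NrdBzc": ("E", "E", "H", "E", "E", "H", "E", "D"),
    "NrdBi":  ("E", "E", "H", "E", "E", "H", "CS", "DE"),
    "NrdFe":  ("D", "QV", "H", "SP", "K", "H", "M", "D"),
    "CyanoSP": ("E", "E", "H", "E", "E", "H", "D", "D"),
}


def oracle_group_match(residues, first_sphere_only=False):
    """Brute-force membership check against GROUP_TABLE."""
    n = 6 if first_sphere_only else 8
    out = []
    for group, allowed in GROUP_TABLE.items():
        if all(residues[i] is not None and residues[i] in allowed[i] for i in range(n)):
            out.append(group)
    return out
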
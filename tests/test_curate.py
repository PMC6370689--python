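"""Dereplication, intein excision, functionality filter, trimming, clustering."""

import numpy as np
import pytest

from rnrclassify import synth
from rnrclassify.align import percent_identity
from rnrclassify.curate import (
    default_trimspecs, dereplicate, filter_functional, greedy_cluster,
    remove_inteins, trim_roi,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def rand_seq(rng, n):
    return "".join(rng.choice(list(AA), n))


class TestDereplicate:
    def test_substring_removed(self):
        assert dereplicate({"a": "ACDEF", "b": "CDE"}) == {"a": "ACDEF"}

    def test_exact_duplicate_keeps_one(self):
        out = dereplicate({"a": "ACDEF", "b": "ACDEF"})
        assert list(out.values()) == ["ACDEF"]

    def test_agrees_with_all_pairs_scan(self):
        """Output equals the brute-force O(n^2) substring scan: a sequence
        survives iff it is not a substring of any distinct longer/equal
        survivor."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            seqs = {}
            for i in range(8):
                s = rand_seq(rng, int(rng.integers(4, 12)))
                seqs[f"s{i}"] = s
            # randomly make some entries substrings of others
            for i in range(3):
                src = f"s{rng.integers(8)}"
                dst = f"s{rng.integers(8)}"
                if src != dst and len(seqs[src]) > 2:
                    a = int(rng.integers(0, len(seqs[src]) - 1))
                    b = int(rng.integers(a + 1, len(seqs[src]) + 1))
                    seqs[dst] = seqs[src][a:b]
            got = set(dereplicate(seqs))
            order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
            expect = []
            for sid in order:
                if not any(seqs[sid] in seqs[k] for k in expect):
                    expect.append(sid)
            assert got == set(expect)


class TestTrimROI:
    def test_combined_roi_length_on_anchor_reference(self, refs):
        spec = default_trimspecs(refs)["combined"]
        alpha = next(r for r in refs if r.id == spec.ref_id)
        roi = trim_roi(alpha.sequence, spec, refs)
        assert len(roi) == 625 - 437 + 1 == 189
        assert roi[0] == "N" and roi[-1] == "S"

    def test_beta_roi_length_on_anchor_reference(self, refs):
        spec = default_trimspecs(refs)["beta"]
        beta = next(r for r in refs if r.id == spec.ref_id)
        roi = trim_roi(beta.sequence, spec, refs)
        assert len(roi) == 356 - 48 + 1 == 309
        assert roi[0] == "W" and roi[-1] == "Y"

    def test_alpha_only_removes_n_terminal_extension(self, refs):
        """An ATP-cone-like N-terminal extension is excised by the
        from-C225 trim mode."""
        spec = default_trimspecs(refs)["alpha_only"]
        alpha = synth.make_alpha(synth.SynthSpec(seed=61))
        extension = rand_seq(np.random.default_rng(0), 90)
        extended = extension + alpha.sequence
        roi = trim_roi(extended, spec, refs)
        assert extension not in roi
        assert roi == trim_roi(alpha.sequence, spec, refs)

    def test_trim_is_idempotent(self, refs):
        spec = default_trimspecs(refs)["beta"]
        ps = synth.make_beta(synth.SynthSpec(seed=62, layout="Ia"), "NrdBg")
        once = trim_roi(ps.sequence, spec, refs)
        assert trim_roi(once, spec, refs) == once

    def test_unalignable_query_yields_empty(self, refs):
        spec = default_trimspecs(refs)["beta"]
        assert trim_roi("WAWAWAWA", spec, refs) == ""


class TestRemoveInteins:
    def test_planted_insert_excised_and_sites_survive(self, beta_refs):
        ps = synth.make_beta(
            synth.SynthSpec(seed=7, layout="Ia", insert_length=120), "NrdBg")
        new, report = remove_inteins(ps.sequence, beta_refs)
        assert not report.flagged
        assert len(report.excised) == 1
        assert len(ps.sequence) - len(new) == 120
        # every planted site is still extractable with the same residue
        from rnrclassify.align import align_to_profile
        from rnrclassify.sites import extract_profile
        p = extract_profile(new, beta_refs, align_to_profile(new, beta_refs))
        ps0 = synth.make_beta(synth.SynthSpec(seed=7, layout="Ia"), "NrdBg")
        for kind, pos in ps0.sites.items():
            assert p.residue(kind) == ps0.sequence[pos - 1], kind

    def test_short_insert_untouched(self, beta_refs):
        ps = synth.make_beta(
            synth.SynthSpec(seed=7, layout="Ia", insert_length=10), "NrdBg")
        new, report = remove_inteins(ps.sequence, beta_refs, min_insert=50)
        assert new == ps.sequence
        assert report.excised == [] and not report.flagged

    def test_insert_abutting_a_site_is_refused(self, beta_refs):
        ps = synth.make_beta(synth.SynthSpec(seed=7, layout="Ia", noise=0.0), "NrdBg")
        p4 = ps.sites["metal_4"]
        ins = rand_seq(np.random.default_rng(1), 120)
        seq = ps.sequence[:p4] + ins + ps.sequence[p4:]
        new, report = remove_inteins(seq, beta_refs)
        assert report.flagged
        assert new == seq
        assert "metal_4" in report.reason


class TestFilterFunctional:
    def test_references_retain_themselves(self, refs, beta_refs):
        seqs = {r.id: r.sequence for r in beta_refs}
        assert set(filter_functional(seqs, refs, "class1_beta")) == set(seqs)

    def test_zero_noise_set_fully_retained_knockouts_fully_removed(self, refs):
        intact = {f"ok{i}": synth.make_beta(
            synth.SynthSpec(seed=70 + i, noise=0.0), "NrdBg").sequence
            for i in range(3)}
        dead = {f"ko{i}": synth.make_beta(
            synth.SynthSpec(seed=70 + i, noise=0.0, knockout="metal_3"),
            "NrdBg").sequence for i in range(3)}
        assert set(filter_functional(intact, refs, "class1_beta")) == set(intact)
        assert filter_functional(dead, refs, "class1_beta") == {}


def oracle_greedy(seqs, threshold, coverage, identity_mode="over-shorter"):
    """Independent reimplementation of the greedy assignment logic."""
    from rnrclassify.align import GAP, global_align

    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    clusters = []  # (rep, [members])
    for sid in order:
        for entry in clusters:
            rep = entry[0]
            aln = global_align(seqs[rep], seqs[sid])
            both = sum(1 for a, b in zip(*aln.rows) if a != GAP and b != GAP)
            cov = both / aln.column_count
            ident = percent_identity(seqs[rep], seqs[sid], identity_mode)
            if ident >= threshold and cov >= coverage:
                entry[1].append(sid)
                break
        else:
            clusters.append((sid, [sid]))
    return {rep: sorted(mem) for rep, mem in clusters}


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        seqs = {f"s{i}": "MKLVNNPQRSTW" for i in range(4)}
        for t in (0.7, 0.9, 1.0):
            assert len(greedy_cluster(seqs, t)) == 1

    def test_pair_at_72_percent_splits_between_thresholds(self):
        """Two length-100 sequences differing at exactly 28 positions sit at
        72% identity: together at 0.70, apart at 0.75."""
        rng = np.random.default_rng(9)
        a = rand_seq(rng, 100)
        positions = rng.choice(100, size=28, replace=False)
        chars = list(a)
        for i in positions:
            chars[i] = next(c for c in AA if c != a[i])
        b = "".join(chars)
        assert percent_identity(a, b) == pytest.approx(0.72)
        seqs = {"a": a, "b": b}
        assert len(greedy_cluster(seqs, 0.70)) == 1
        assert len(greedy_cluster(seqs, 0.75)) == 2

    def test_partition_property(self):
        seqs, _ = synth.make_family_set(synth.SynthSpec(
            seed=81, n_families=3, members_per_family=3, family_length=60))
        clusters = greedy_cluster(seqs, 0.8)
        seen = [m for cl in clusters for m in cl.members]
        assert sorted(seen) == sorted(seqs)

    def test_agrees_with_greedy_oracle_on_random_sets(self):
        rng = np.random.default_rng(13)
        for trial in range(15):
            base = rand_seq(rng, int(rng.integers(20, 40)))
            seqs = {}
            for i in range(int(rng.integers(3, 8))):
                chars = list(base)
                for j in range(len(chars)):
                    if rng.random() < rng.uniform(0.0, 0.4):
                        chars[j] = AA[rng.integers(20)]
                seqs[f"s{i}"] = "".join(chars)
            got = {cl.representative: sorted(cl.members)
                   for cl in greedy_cluster(seqs, 0.75, coverage=0.8)}
            assert got == oracle_greedy(seqs, 0.75, 0.8)

    def test_skip_flag_passes_sequences_through(self):
        seqs = {f"s{i}": "MKLVNNPQRSTW" for i in range(4)}
        clusters = greedy_cluster(seqs, 0.7, skip=True)
        assert len(clusters) == 4
        assert all(len(cl.members) == 1 for cl in clusters)
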
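"""Diagnostic markers, hybrid index, haplotype collapsing, NJ trees and
fragment allocation."""

import numpy as np
import pytest

from hzfootprint.core import GenotypeMatrix, LocalityTable, ReferencePanel, SequenceSet
from hzfootprint.markers import (
    AMBIGUOUS,
    UNASSIGNED,
    assign_haplotype_species,
    assign_internal_fragment,
    build_nj_tree,
    collapse_haplotypes,
    find_diagnostic_markers,
    hybrid_index,
    individual_hybrid_index,
    p_distance_matrix,
)


def _matrix(calls_by_ind, loci):
    ids = tuple(calls_by_ind)
    return GenotypeMatrix(ids, tuple(loci), tuple(tuple(calls_by_ind[i]) for i in ids))


class TestDiagnosticMarkers:
    def test_segregating_focal_panel_excluded(self):
        """Five loci, one with a segregating focal panel: four diagnostic."""
        loci = [f"L{j}" for j in range(5)]
        calls = {
            "f1": [("A", "A")] * 5,
            "f2": [("A", "A")] * 4 + [("A", "B")],   # L4 segregates in focal
            "o1": [("B", "B")] * 5,
            "o2": [("B", "B")] * 5,
        }
        G = _matrix(calls, loci)
        panel = ReferencePanel({"focal": {"f1", "f2"}, "other": {"o1", "o2"}})
        diag = find_diagnostic_markers(G, panel, "focal")
        assert set(diag.loci) == {"L0", "L1", "L2", "L3"}
        assert diag.focal_allele("L0") == "A"

    def test_identical_panels_give_empty_set(self):
        G = _matrix({"f1": [("A", "A")], "o1": [("A", "A")]}, ["L0"])
        panel = ReferencePanel({"focal": {"f1"}, "other": {"o1"}})
        assert find_diagnostic_markers(G, panel, "focal").loci == ()

    def test_recovers_simulated_diagnostic_loci_exactly(self, moving_sim):
        diag = find_diagnostic_markers(
            moving_sim.genotypes, moving_sim.reference_panel,
            moving_sim.scenario.focal_species,
        )
        assert set(diag.loci) == set(moving_sim.diagnostic_loci)


class TestHybridIndex:
    def _pair_matrix(self):
        loci = ["L1", "L2", "L3", "L4"]
        calls = {
            "pure": [("A", "A")] * 4,
            "f1": [("A", "B")] * 4,
            "mix": [("A", "A"), ("A", "B"), ("B", "B"), ("A", "A")],
        }
        G = _matrix(calls, loci)
        refG = _matrix({"rf": [("A", "A")] * 4, "ro": [("B", "B")] * 4}, loci)
        panel = ReferencePanel({"focal": {"rf"}, "other": {"ro"}})
        merged = GenotypeMatrix(
            G.individual_ids + refG.individual_ids, tuple(loci),
            G.calls + refG.calls,
        )
        diag = find_diagnostic_markers(merged, panel, "focal")
        return merged, diag

    def test_individual_values(self):
        G, diag = self._pair_matrix()
        h = individual_hybrid_index(G, diag)
        assert h["pure"][0] == 1.0
        assert h["f1"][0] == 0.5
        assert h["mix"][0] == pytest.approx(5 / 8)

    def test_locality_mean_and_missing_exclusion(self):
        G, diag = self._pair_matrix()
        locs = LocalityTable(
            ("La",), (0.0,), (0.0,), {"La": ("pure", "mix")}
        )
        tab = hybrid_index(G, diag, locs)
        assert tab.h["La"] == pytest.approx((8 + 5) / 16)
        assert tab.n_genotypes["La"] == 8

    def test_reference_individuals_at_corners(self, moving_sim):
        diag = find_diagnostic_markers(
            moving_sim.genotypes, moving_sim.reference_panel,
            moving_sim.scenario.focal_species,
        )
        h = individual_hybrid_index(moving_sim.genotypes, diag)
        for sp, ids in moving_sim.reference_panel.members.items():
            target = 1.0 if sp == moving_sim.scenario.focal_species else 0.0
            for iid in ids:
                assert h[iid][0] == target


class TestCollapse:
    def test_identical_merge(self):
        H = collapse_haplotypes(SequenceSet({"a": "ACGT", "b": "ACGT"}))
        assert len(H) == 1
        assert H["a"].multiplicity == 2

    def test_n_matches_anything(self):
        H = collapse_haplotypes(SequenceSet({"x": "ACGT", "y": "ACGN"}))
        assert len(H) == 1
        rep = next(iter(H.haplotypes.values()))
        assert rep.sequence == "ACGT"  # fewest Ns is canonical

    def test_real_difference_kept(self):
        H = collapse_haplotypes(SequenceSet({"x": "ACGT", "y": "ACCT"}))
        assert len(H) == 2

    def test_idempotent(self):
        S = SequenceSet({
            "a": "ACGTACGT", "b": "ACGTACGN", "c": "ACGTACGT",
            "d": "TCGTACGA", "e": "NNGTACGA",
        })
        H1 = collapse_haplotypes(S)
        H2 = collapse_haplotypes(H1.as_sequence_set())
        assert {h.sequence for h in H1.haplotypes.values()} == \
               {h.sequence for h in H2.haplotypes.values()}
        assert H1.total_multiplicity() == len(S)


def _clade_alignment():
    """Two clades 50 fixed differences apart, plus a distant outgroup."""
    rng = np.random.default_rng(0)
    base = rng.choice(list("ACGT"), size=200)
    cladeB = base.copy()
    cladeB[:50] = np.where(cladeB[:50] == "A", "C", "A")
    out = base.copy()
    out[::2] = np.where(out[::2] == "G", "T", "G")

    def mut(seq, pos):
        s = seq.copy()
        s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
        return s

    return SequenceSet({
        "A1": "".join(base), "A2": "".join(mut(base, 150)),
        "B1": "".join(cladeB), "B2": "".join(mut(cladeB, 151)),
        "OUT": "".join(out),
    })


class TestNJTree:
    def test_p_distance(self):
        S = SequenceSet({"a": "AAAA", "b": "AAAT", "c": "NTTT"})
        d = p_distance_matrix(S)
        assert d["a", "b"] == pytest.approx(0.25)
        assert d["a", "c"] == pytest.approx(1.0)  # N site excluded

    def test_zero_comparable_sites_rejected(self):
        S = SequenceSet({"a": "ANN", "b": "NAN"})
        with pytest.raises(ValueError, match="comparable"):
            p_distance_matrix(S)

    def test_two_clades_full_support(self):
        """50 fixed differences cannot be erased by site resampling."""
        tree, support = build_nj_tree(_clade_alignment(), ["OUT"], bootstrap_n=100, seed=0)
        tips = {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}
        assert any(s == {"A1", "A2"} or s == {"B1", "B2"} for s in tips)
        # the unrooted tree has exactly the two clade edges; 50 fixed
        # differences survive any site resampling, so support is total
        assert support and all(sup == 1.0 for sup in support.values())

    def test_four_point_topology(self):
        """Additive distances d(AB)=d(CD)=small, cross=large give ((A,B),(C,D))."""
        tree, _ = build_nj_tree(_clade_alignment(), ["OUT"], bootstrap_n=0)
        a1 = tree.find("A1")
        siblings = {t.name for t in a1.parent.tips()}
        assert "A2" in siblings and "B1" not in siblings


class TestAssignment:
    def test_query_matches_reference_clade(self):
        S = _clade_alignment()
        rng_seq = list(S["A1"])
        rng_seq[100] = "C" if rng_seq[100] != "C" else "G"
        S2 = SequenceSet({**S.sequences, "Q": "".join(rng_seq)})
        H = collapse_haplotypes(S2)
        tree, _ = build_nj_tree(S2, ["OUT"], bootstrap_n=0)
        out = assign_haplotype_species(
            H, {"A1": "spA", "A2": "spA", "B1": "spB", "B2": "spB"}, tree
        )
        assert out["Q"].species == "spA"

    def test_missing_query_rejected(self):
        S = _clade_alignment()
        q = list(S["A1"])
        q[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[10]]
        H = collapse_haplotypes(SequenceSet({**S.sequences, "Q": "".join(q)}))
        tree, _ = build_nj_tree(S, ["OUT"], bootstrap_n=0)  # tree lacks Q
        with pytest.raises(ValueError, match="absent"):
            assign_haplotype_species(
                H, {"A1": "spA", "B1": "spB"}, tree
            )


class TestInternalFragment:
    def _assigned(self):
        from hzfootprint.markers import Haplotype, HaplotypeSet
        return HaplotypeSet({
            "hA": Haplotype("hA", "AAAACCCC", 3, ("hA",), "spA"),
            "hB": Haplotype("hB", "TTTTCCCC", 2, ("hB",), "spB"),
            "hB2": Haplotype("hB2", "TTTTCCGG", 1, ("hB2",), "spB"),
        })

    def test_unique_species_window(self):
        assert assign_internal_fragment("AAAA", self._assigned(), (0, 4)) == "spA"

    def test_shared_window_is_ambiguous(self):
        # both species collapse to "CCCC" in the window -> ambiguous
        assert assign_internal_fragment("CCCC", self._assigned(), (4, 8)) == AMBIGUOUS

    def test_no_match_unassigned(self):
        assert assign_internal_fragment("GGGG", self._assigned(), (0, 4)) == UNASSIGNED

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="fit window"):
            assign_internal_fragment("AA", self._assigned(), (0, 4))


def test_newick_roundtrip(tmp_path):
    from skbio import TreeNode

    from hzfootprint.markers import write_newick

    tree, _ = build_nj_tree(_clade_alignment(), ["OUT"], bootstrap_n=0)
    p = tmp_path / "tree.nwk"
    write_newick(tree, p)
    back = TreeNode.read(str(p), format="newick")
    assert {t.name for t in back.tips()} == {"A1", "A2", "B1", "B2", "OUT"}
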
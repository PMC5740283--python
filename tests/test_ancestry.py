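"""Admixture sampler, evidence estimate, Evanno delta-k, replicate
alignment and the admixture-threshold locality rule."""


import numpy as np
import pytest

from hzfootprint.ancestry import (
    AncestryMatrix,
    admixture_threshold,
    align_replicates,
    estimate_evidence,
    evanno_delta_k,
    mean_ancestry,
    run_admixture_sampler,
    summarize_localities,
)
from hzfootprint.core import GenotypeMatrix, LocalityTable, ReferencePanel


def _ancestry(ids, Q, labels=None):
    Q = np.asarray(Q, float)
    return AncestryMatrix(
        tuple(ids), Q.shape[1], Q, np.array([-1.0, -1.0]),
        np.array([0, 10]), burnin=0, column_labels=labels,
    )


class TestSampler:
    def test_k1_gives_unit_column(self, tiny_genotypes):
        am = run_admixture_sampler(tiny_genotypes, k=1, iters=50, burnin=10, seed=0)
        assert np.allclose(am.Q, 1.0)

    def test_k_exceeding_individuals_rejected(self, tiny_genotypes):
        with pytest.raises(ValueError, match="exceeds"):
            run_admixture_sampler(tiny_genotypes, k=5, iters=10, burnin=1)

    def test_all_missing_locus_dropped(self):
        G = GenotypeMatrix(
            ("i1", "i2"), ("L1", "L2"),
            ((("A", "A"), (None, None)), (("A", "B"), (None, None))),
        )
        with pytest.warns(UserWarning, match="all-missing"):
            am = run_admixture_sampler(G, k=1, iters=20, burnin=5)
        assert np.allclose(am.Q, 1.0)

    def test_two_populations_separated(self, two_pop_sim):
        """Pure individuals from diverged genepools cluster correctly and
        confidently."""
        G, labels = two_pop_sim
        am = run_admixture_sampler(G, k=2, iters=4000, burnin=1000, seed=5)
        assign = am.Q.argmax(axis=1)
        pops = np.array([labels[i] for i in am.individual_ids])
        # dominant cluster reproduces the truth for every individual
        # (up to label switching)
        acc = max(
            (assign == (pops == "pop1")).mean(),
            (assign == (pops == "pop2")).mean(),
        )
        assert acc == 1.0
        assert np.median(am.Q.max(axis=1)) > 0.8

    def test_constructed_f1_near_half(self, two_pop_sim):
        G, labels = two_pop_sim
        arr, table = G.encode()
        pops = np.array([labels[i] for i in G.individual_ids])
        # build an F1: one allele from each population's majority at every locus
        calls = []
        for j, locus in enumerate(G.locus_ids):
            maj = []
            for p in ("pop1", "pop2"):
                sub = arr[pops == p, j, :]
                sub = sub[sub >= 0]
                maj.append(table[locus][np.bincount(sub).argmax()])
            calls.append(tuple(sorted(maj)))
        G2 = GenotypeMatrix(
            G.individual_ids + ("f1",), G.locus_ids, G.calls + (tuple(calls),)
        )
        am = run_admixture_sampler(G2, k=2, iters=4000, burnin=1000, seed=2)
        assert am.q_of("f1") == pytest.approx((0.5, 0.5), abs=0.1)

    def test_supervised_pins_reference_columns(self, two_pop_sim):
        G, labels = two_pop_sim
        panel = ReferencePanel({
            "pop1": frozenset(i for i in G.individual_ids[:5]),
            "pop2": frozenset(i for i in G.individual_ids[-5:]),
        })
        am = run_admixture_sampler(G, k=2, iters=2000, burnin=500, seed=1,
                                   supervised=panel)
        assert am.column_labels == ("pop1", "pop2")
        for iid in G.individual_ids:
            expected = 0 if labels[iid] == "pop1" else 1
            assert am.q_of(iid).argmax() == expected


class TestEvidence:
    def test_constant_trace(self):
        assert estimate_evidence([-5.0, -5.0, -5.0]) == -5.0

    def test_hand_arithmetic(self):
        # mean -11, sample variance 2 -> -11 - 1 = -12
        assert estimate_evidence([-10.0, -12.0]) == pytest.approx(-12.0)

    def test_noise_lowers_estimate(self):
        rng = np.random.default_rng(0)
        base = np.full(200, -100.0)
        noisy = base + rng.normal(0, 3, 200)
        assert estimate_evidence(noisy) < estimate_evidence(base) + 1e-9

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_evidence([-1.0])


class TestEvanno:
    def test_hand_example(self):
        d = 1 / np.sqrt(2)  # two replicates m +- d have sample sd 1
        table = evanno_delta_k({
            1: [-100 - d, -100 + d],
            2: [-50 - d, -50 + d],
            3: [-48 - d, -48 + d],
            4: [-47 - d, -47 + d],
        })
        assert table.delta_k[2] == pytest.approx(48.0)
        assert table.delta_k[3] == pytest.approx(1.0)
        assert table.best_k == 2

    def test_linear_evidence_gives_zero_deltas(self):
        d = 0.5
        table = evanno_delta_k({k: [-10.0 * k - d, -10.0 * k + d] for k in range(1, 5)})
        assert all(v == pytest.approx(0.0) for v in table.delta_k.values())

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero replicate variance"):
            evanno_delta_k({1: [-3.0, -2.0], 2: [-1.0, -1.0], 3: [-0.5, -0.4]})

    def test_nonconsecutive_k_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            evanno_delta_k({1: [-1, -2], 3: [-1, -2], 5: [-1, -2]})


class TestAlignment:
    def test_permutation_undone_exactly(self):
        rng = np.random.default_rng(0)
        Q = rng.dirichlet(np.ones(3), size=8)
        ref = _ancestry([f"i{j}" for j in range(8)], Q)
        perm = [2, 0, 1]
        swapped = _ancestry(ref.individual_ids, Q[:, perm])
        aligned = align_replicates([ref, swapped])
        assert np.allclose(aligned[1].Q, Q)

    def test_identical_unchanged(self):
        Q = np.array([[0.7, 0.3], [0.2, 0.8]])
        ref = _ancestry(["a", "b"], Q)
        aligned = align_replicates([ref, ref])
        assert np.allclose(aligned[1].Q, Q)

    def test_alignment_reduces_frobenius_distance(self):
        rng = np.random.default_rng(42)
        Q = rng.dirichlet(np.ones(4), size=20)
        ref = _ancestry([f"i{j}" for j in range(20)], Q)
        reps = [ref]
        for _ in range(5):
            perm = rng.permutation(4)
            noisy = np.clip(Q[:, perm] + rng.normal(0, 0.02, Q.shape), 1e-6, None)
            noisy /= noisy.sum(axis=1, keepdims=True)
            reps.append(_ancestry(ref.individual_ids, noisy))
        pre = np.mean([np.linalg.norm(r.Q - ref.Q) for r in reps[1:]])
        aligned = align_replicates(reps)
        post = np.mean([np.linalg.norm(r.Q - ref.Q) for r in aligned[1:]])
        assert post <= pre
        mean = mean_ancestry(aligned)
        assert np.allclose(mean.Q.sum(axis=1), 1.0)

    def test_mismatched_k_rejected(self):
        a = _ancestry(["x"], [[1.0]])
        b = _ancestry(["x"], [[0.5, 0.5]])
        with pytest.raises(ValueError):
            align_replicates([a, b])


class TestLocalitySummaries:
    def _setup(self):
        ids = ("r1", "r2", "r3", "r4", "q1", "q2")
        Q = np.array([
            [0.9794, 0.0206 / 3, 0.0206 / 3, 0.0206 / 3],   # weakest reference
            [0.001, 0.997, 0.001, 0.001],
            [0.001, 0.001, 0.997, 0.001],
            [0.001, 0.001, 0.001, 0.997],
            [1.0, 0.0, 0.0, 0.0],
            [0.6, 0.39, 0.01, 0.0],
        ])
        am = _ancestry(ids, Q, labels=("sp1", "sp2", "sp3", "sp4"))
        panel = ReferencePanel({f"sp{j + 1}": {f"r{j + 1}"} for j in range(4)})
        locs = LocalityTable(
            ("La", "Lb"), (0.0, 1.0), (0.0, 0.0), {"La": ("q1",), "Lb": ("q2",)}
        )
        return am, panel, locs

    def test_threshold_from_weakest_reference(self):
        am, panel, _ = self._setup()
        # threshold = 1 - 0.9794 = 0.0206
        assert admixture_threshold(am, panel) == pytest.approx(0.0206, abs=1e-12)

    def test_pure_locality_not_admixed(self):
        am, panel, locs = self._setup()
        out = {s.locality_id: s for s in summarize_localities(am, locs, panel)}
        assert out["La"].dominant_species == "sp1"
        assert not out["La"].admixed

    def test_two_species_over_threshold_is_admixed(self):
        am, panel, locs = self._setup()
        out = {s.locality_id: s for s in summarize_localities(am, locs, panel)}
        assert out["Lb"].admixed
        assert out["Lb"].dominant_species == "sp1"

    def test_empty_panel_rejected(self):
        am, _, _ = self._setup()
        with pytest.raises(ValueError, match="empty reference panel"):
            admixture_threshold(am, ReferencePanel({}))


def test_noise_loci_lower_evidence(two_pop_sim):
    """Adding uninformative loci adds likelihood cost without adding
    structure, so the evidence estimate drops."""
    import numpy as np

    from hzfootprint.core import GenotypeMatrix

    G, _ = two_pop_sim
    rng = np.random.default_rng(0)
    extra = tuple(f"noise{j}" for j in range(10))
    calls = []
    for row in G.calls:
        noise = tuple(
            tuple(sorted(rng.choice(["A", "B"], size=2))) for _ in extra
        )
        calls.append(row + noise)
    G2 = GenotypeMatrix(G.individual_ids, G.locus_ids + extra, tuple(calls))
    e1 = estimate_evidence(
        run_admixture_sampler(G, 2, iters=1500, burnin=400, seed=3).post_burnin_trace
    )
    e2 = estimate_evidence(
        run_admixture_sampler(G2, 2, iters=1500, burnin=400, seed=3).post_burnin_trace
    )
    assert e2 < e1
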
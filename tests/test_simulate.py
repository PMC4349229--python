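import numpy as np
import pytest

from sweepscan.core import nucleotide_diversity
from sweepscan.io import QTL_CATEGORIES
from sweepscan.simulate import (
    DemographyModel,
    GroundTruth,
    SweepSpec,
    make_toy_annotations,
    simulate_forward_wf,
    simulate_neutral_coalescent,
)

SAMPLES = {"breed1": 5, "breed2": 5, "outgroup": 5}

FAST_MODEL = DemographyModel(
    N_anc=80, T_dom=60, T_split=25, N_bottleneck1=50, D_bottleneck1=8,
    N_bottleneck2=30, D_bottleneck2=4, N_breed=60, m=0.002,
    mu=1e-6, r=1e-6,
)


class TestDemographyModel:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DemographyModel(T_dom=10, T_split=20)
        with pytest.raises(ValueError):
            DemographyModel(m=1.5)
        with pytest.raises(ValueError):
            DemographyModel(N_anc=0)
        with pytest.raises(ValueError):
            DemographyModel(T_split=5, D_bottleneck2=10)

    def test_rescaling_preserves_products(self):
        m = DemographyModel()
        r = m.rescaled(10)
        assert r.N_anc * r.mu == pytest.approx(m.N_anc * m.mu, rel=0.01)
        assert r.N_breed * r.m == pytest.approx(m.N_breed * m.m, rel=0.01)
        assert r.T_dom == m.T_dom / 10


class TestCoalescent:
    def test_panmictic_pi_matches_theta(self):
        # E(pi) = theta for a panmictic coalescent; check within 3 SE
        model = DemographyModel.panmictic(500)
        reps = simulate_neutral_coalescent(
            model, {"breed1": 0, "breed2": 0, "outgroup": 1},
            theta=1.0, n_replicates=3000, seed=5,
        )
        pis = [
            nucleotide_diversity(r.alleles) if r.n_sites else 0.0 for r in reps
        ]
        se = np.std(pis) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - 1.0) < 3 * se + 0.02

    def test_watterson_segregating_sites(self):
        # E(S) = theta * sum(1/i) for n haplotypes
        model = DemographyModel.panmictic(500)
        n_dip = 3
        reps = simulate_neutral_coalescent(
            model, {"breed1": n_dip, "breed2": 0, "outgroup": 0},
            theta=2.0, n_replicates=2000, seed=6,
        )
        s = [r.n_sites for r in reps]
        harmonic = sum(1 / i for i in range(1, 2 * n_dip))
        se = np.std(s) / np.sqrt(len(s))
        assert abs(np.mean(s) - 2.0 * harmonic) < 3 * se + 0.05

    def test_nonpositive_theta_rejected(self):
        with pytest.raises(ValueError):
            simulate_neutral_coalescent(FAST_MODEL, SAMPLES, 0.0, 1, 1)

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError, match="sample count"):
            simulate_neutral_coalescent(
                FAST_MODEL, {"breed1": 100, "breed2": 2, "outgroup": 2},
                theta=1.0, n_replicates=1, seed=0,
            )

    def test_determinism(self):
        a = simulate_neutral_coalescent(FAST_MODEL, SAMPLES, 8.0, 3, seed=9)
        b = simulate_neutral_coalescent(FAST_MODEL, SAMPLES, 8.0, 3, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.alleles, y.alleles)
            np.testing.assert_array_equal(x.positions, y.positions)

    def test_three_population_structure(self):
        reps = simulate_neutral_coalescent(FAST_MODEL, SAMPLES, 10.0, 2, seed=3)
        for r in reps:
            assert r.n_hap == 30
            assert r.population_labels == ["breed1", "breed2", "outgroup"]

    def test_breed_diversity_below_outgroup(self):
        # bottlenecked breeds should carry less diversity than the outgroup
        model = DemographyModel(
            N_anc=800, T_dom=400, T_split=100, N_bottleneck1=60,
            D_bottleneck1=80, N_bottleneck2=30, D_bottleneck2=40,
            N_breed=100, m=0.001, mu=1e-6, r=0.0,
        )
        reps = simulate_neutral_coalescent(model, SAMPLES, 20.0, 60, seed=17)
        wins = 0
        for r in reps:
            if r.n_sites == 0:
                continue
            pi_b = nucleotide_diversity(r.rows_for("breed1"))
            pi_o = nucleotide_diversity(r.rows_for("outgroup"))
            wins += pi_b < pi_o
        assert wins >= 0.8 * len(reps)


class TestForwardWf:
    def test_no_sweep_basic_shapes_and_determinism(self):
        h1, t1 = simulate_forward_wf(FAST_MODEL, [], 50_000, SAMPLES, seed=4)
        h2, t2 = simulate_forward_wf(FAST_MODEL, [], 50_000, SAMPLES, seed=4)
        np.testing.assert_array_equal(h1.alleles, h2.alleles)
        assert h1.n_hap == 30
        assert t1.n_rejections == 0
        assert t1.events == t2.events

    def test_mu_zero_monomorphic_except_sweep(self):
        model = DemographyModel(
            N_anc=60, T_dom=40, T_split=20, N_bottleneck1=40, D_bottleneck1=5,
            N_bottleneck2=30, D_bottleneck2=3, N_breed=50, m=0.0,
            mu=0.0, r=1e-6,
        )
        sweep = SweepSpec("breed1", 25_000, s=0.8, onset_generation=15)
        haps, truth = simulate_forward_wf(model, [sweep], 50_000, SAMPLES, seed=8)
        assert haps.n_sites <= 1  # only the selected site can segregate

    def test_complete_sweep_fixes_in_target(self):
        sweep = SweepSpec("breed1", 25_000, s=0.8, onset_generation=20)
        haps, truth = simulate_forward_wf(
            FAST_MODEL, [sweep], 50_000, SAMPLES, seed=12
        )
        freqs = truth.sweeps[0]["final_frequency"]
        assert freqs["breed1"] == 1.0
        assert freqs["outgroup"] == 0.0

    def test_partial_sweep_segregates_near_target(self):
        sweep = SweepSpec(
            "breed2", 25_000, s=1.0, onset_generation=10,
            mode="partial", target_frequency=0.5,
        )
        haps, truth = simulate_forward_wf(
            FAST_MODEL, [sweep], 50_000, SAMPLES, seed=13, freq_tolerance=0.15
        )
        f = truth.sweeps[0]["final_frequency"]["breed2"]
        assert 0.35 <= f <= 0.65

    def test_sweep_before_breed_exists_rejected(self):
        sweep = SweepSpec("breed1", 25_000, s=0.5, onset_generation=30)
        with pytest.raises(ValueError, match="onset"):
            simulate_forward_wf(FAST_MODEL, [sweep], 50_000, SAMPLES, seed=1)

    def test_ground_truth_records_each_sweep_once(self):
        sweep = SweepSpec("breed1", 25_000, s=0.8, onset_generation=20)
        _, truth = simulate_forward_wf(FAST_MODEL, [sweep], 50_000, SAMPLES, seed=21)
        assert isinstance(truth, GroundTruth)
        assert len(truth.sweeps) == 1
        assert truth.sweeps[0]["position"] == 25_000

    def test_neutral_forward_frequency_change_mean_zero(self):
        # s = 0 reduces to neutrality: mean frequency change ~ 0
        model = DemographyModel(
            N_anc=100, T_dom=12, T_split=6, N_bottleneck1=100,
            D_bottleneck1=2, N_bottleneck2=100, D_bottleneck2=1,
            N_breed=100, m=0.0, mu=5e-6, r=0.0,
        )
        deltas = []
        for seed in range(8):
            haps, _ = simulate_forward_wf(
                model, [], 30_000, {"breed1": 30, "breed2": 2, "outgroup": 30},
                seed=100 + seed,
            )
            f_out = haps.rows_for("outgroup").mean(axis=0)
            f_b = haps.rows_for("breed1").mean(axis=0)
            keep = (f_out > 0) & (f_out < 1)
            deltas.extend((f_b - f_out)[keep].tolist())
        assert abs(np.mean(deltas)) < 0.02

    def test_region_too_short_rejected(self):
        with pytest.raises(ValueError, match="1 kb"):
            simulate_forward_wf(FAST_MODEL, [], 500, SAMPLES, seed=0)

    def test_desk_scale_guard(self):
        big = DemographyModel(N_anc=5000)
        with pytest.raises(ValueError, match="desk-scale"):
            simulate_forward_wf(big, [], 10_000, SAMPLES, seed=0)


class TestToyAnnotations:
    def test_single_gene_inside_region(self):
        genes, qtls = make_toy_annotations(10_000, 1, 0, seed=1)
        assert len(genes) == 1
        assert 0 <= genes[0].start < genes[0].stop <= 10_000

    def test_genes_do_not_overlap(self):
        genes, _ = make_toy_annotations(200_000, 25, 10, seed=2)
        spans = sorted((g.start, g.stop) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_categories_from_fixed_set(self):
        _, qtls = make_toy_annotations(100_000, 5, 12, seed=3)
        assert {q.category for q in qtls} <= set(QTL_CATEGORIES)
        assert len(qtls) == 12

    def test_deterministic(self):
        a = make_toy_annotations(50_000, 8, 4, seed=7)
        b = make_toy_annotations(50_000, 8, 4, seed=7)
        assert a == b

    def test_zero_qtl_gives_empty_table(self):
        _, qtls = make_toy_annotations(50_000, 3, 0, seed=1)
        assert qtls == []

    def test_too_many_genes_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            make_toy_annotations(1_000, 50, 0, seed=1)
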
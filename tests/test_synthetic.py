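import numpy as np
import pytest

import magicqtl as m
from magicqtl.io_qc import GeneticMap
from magicqtl.synthetic import _meiosis, _recomb_probs

from conftest import FIXTURE_SEED, random_genotypes


def flat_map(p, chrom="1H", spacing=0.0):
    return GeneticMap(
        tuple(f"S{j}" for j in range(p)),
        tuple(chrom for _ in range(p)),
        np.arange(p, dtype=float) * spacing,
    )


class TestFounders:
    def test_allele_frequency_within_binomial_bound(self):
        founders = m.simulate_founders(flat_map(1000, spacing=1.0), 0.5, seed=3)
        frac = (founders.values == 1).mean()
        assert 0.45 < frac < 0.55  # 8000 draws at p=0.5

    @pytest.mark.parametrize("freq", [0.0, 1.0, -0.2, 1.5])
    def test_degenerate_frequency_rejected(self, freq):
        with pytest.raises(ValueError):
            m.simulate_founders(flat_map(10), freq, seed=0)

    def test_deterministic_given_seed(self):
        gmap = flat_map(50, spacing=2.0)
        a = m.simulate_founders(gmap, 0.5, seed=11)
        b = m.simulate_founders(gmap, 0.5, seed=11)
        assert np.array_equal(a.values, b.values)

    def test_monomorphic_markers_dropped(self):
        # extreme frequency forces many monomorphic draws; survivors segregate
        founders = m.simulate_founders(flat_map(400, spacing=1.0), 0.05, seed=4)
        assert founders.p <= 400
        assert (founders.values.min(axis=0) < founders.values.max(axis=0)).all()
        assert founders.map.p == founders.p


class TestMagicDh:
    def test_zero_map_distance_gives_intact_founder_haplotypes(self):
        founders = m.simulate_founders(flat_map(40, spacing=0.0), 0.5, seed=5)
        G = m.simulate_magic_dh(founders, n_lines=60, seed=6)
        founder_rows = {tuple(row) for row in founders.values.tolist()}
        for row in G.values.tolist():
            assert tuple(row) in founder_rows

    def test_haldane_recombination_fraction_at_50_cm(self):
        gmap = GeneticMap(("a", "b"), ("1H", "1H"), np.array([0.0, 50.0]))
        rec = _recomb_probs(gmap)
        expected = 0.5 * (1 - np.exp(-1.0))
        assert rec[0] == pytest.approx(expected)
        rng = np.random.default_rng(7)
        hap_a = np.array([1, 1], dtype=np.int8)
        hap_b = np.array([-1, -1], dtype=np.int8)
        n_meioses = 10_000
        recombinant = sum(
            g[0] != g[1] for g in (_meiosis(hap_a, hap_b, rec, rng) for _ in range(n_meioses))
        )
        se = np.sqrt(expected * (1 - expected) / n_meioses)
        assert abs(recombinant / n_meioses - expected) < 3 * se

    def test_output_coded_plus_minus_one(self):
        founders = m.simulate_founders(flat_map(30, spacing=2.0), 0.5, seed=8)
        G = m.simulate_magic_dh(founders, n_lines=25, seed=9)
        assert set(np.unique(G.values)) <= {-1, 1}

    def test_chromosomes_segregate_independently(self):
        p = 40
        gmap = GeneticMap(
            tuple(f"S{j}" for j in range(p)),
            tuple("1H" if j < p // 2 else "2H" for j in range(p)),
            np.array([float(j % (p // 2)) for j in range(p)]),
        )
        rec = _recomb_probs(gmap)
        assert rec[p // 2 - 1] == 0.5

    def test_ld_decays_with_map_distance(self):
        # one long chromosome: adjacent 1 cM pairs vs pairs >= 50 cM apart
        gmap = flat_map(60, spacing=1.0)
        founders = m.simulate_founders(gmap, 0.5, seed=10)
        G = m.simulate_magic_dh(founders, n_lines=10_000, seed=11)
        x = G.values.astype(float)
        xc = x - x.mean(axis=0)
        norm = np.sqrt((xc * xc).sum(axis=0))
        z = xc / norm
        corr = z.T @ z
        pos = founders.map.positions_cm
        near, far = [], []
        for a in range(founders.p):
            for b in range(a + 1, founders.p):
                d = pos[b] - pos[a]
                if d <= 1.0:
                    near.append(corr[a, b] ** 2)
                elif d >= 50.0:
                    far.append(corr[a, b] ** 2)
        assert np.mean(near) > np.mean(far)


class TestPhenotype:
    def test_no_effects_no_noise_is_constant_intercept(self):
        G = random_genotypes(20, 5, seed=12)
        truth = m.SimTruth(80.0, (), (), (), noise_sd=0.0)
        y = m.simulate_phenotype(G, truth, seed=13)
        assert np.allclose(y.values, 80.0)

    def test_main_effect_contrast(self):
        G = random_genotypes(1000, 4, seed=14)
        truth = m.SimTruth(0.0, ((2, 2.0),), (), (), noise_sd=1.0)
        y = m.simulate_phenotype(G, truth, seed=15).values
        x = G.values[:, 2]
        contrast = y[x == 1].mean() - y[x == -1].mean()
        assert abs(contrast - 4.0) < 0.3

    def test_pure_trio_effect_has_no_marginal_contrast(self):
        G = random_genotypes(4000, 5, seed=16)
        truth = m.SimTruth(0.0, (), (), (((0, 2, 4), 2.0),), noise_sd=0.5)
        y = m.simulate_phenotype(G, truth, seed=17).values
        for j in (0, 2, 4):
            x = G.values[:, j]
            assert abs(y[x == 1].mean() - y[x == -1].mean()) < 0.25
        prod = np.prod(G.values[:, [0, 2, 4]].astype(float), axis=1)
        trio_contrast = y[prod == 1].mean() - y[prod == -1].mean()
        assert abs(trio_contrast - 4.0) < 0.25

    def test_variance_decomposition(self):
        # var(y) ~ sum of squared effects + noise variance for iid ±1 markers
        G = random_genotypes(20_000, 10, seed=18)
        truth = m.SimTruth(
            50.0,
            ((0, 1.0), (3, -2.0)),
            (((5, 7), 1.5),),
            (((1, 4, 8), 1.0),),
            noise_sd=1.0,
        )
        y = m.simulate_phenotype(G, truth, seed=19).values
        expected = 1.0 + 4.0 + 2.25 + 1.0 + 1.0
        assert abs(np.var(y) / expected - 1.0) < 0.1


class TestFixtures:
    def test_null_preset_has_empty_truth(self):
        ds = m.make_fixture("null", seed=FIXTURE_SEED)
        assert ds.truth.main_effects == ()
        assert ds.truth.pair_effects == ()
        assert ds.truth.trio_effects == ()
        assert ds.genotypes.n == 300

    def test_bit_exact_reproducibility(self):
        a = m.make_fixture("recovery_epistasis", seed=FIXTURE_SEED)
        b = m.make_fixture("recovery_epistasis", seed=FIXTURE_SEED)
        assert np.array_equal(a.genotypes.values, b.genotypes.values)
        assert np.array_equal(a.phenotypes.values, b.phenotypes.values)
        assert a.truth == b.truth

    def test_recovery_main_effect_sizes(self):
        ds = m.make_fixture("recovery_main", seed=FIXTURE_SEED)
        assert [e for _, e in ds.truth.main_effects] == [2.0, -1.5, 1.0]
        chroms = {ds.map.chromosomes[j] for j, _ in ds.truth.main_effects}
        assert len(chroms) == 3

    def test_recovery_epistasis_architecture_disjoint(self):
        ds = m.make_fixture("recovery_epistasis", seed=FIXTURE_SEED)
        mains = {j for j, _ in ds.truth.main_effects}
        inter = set()
        for pair, _ in ds.truth.pair_effects:
            inter |= set(pair)
        for trio, _ in ds.truth.trio_effects:
            inter |= set(trio)
        assert mains.isdisjoint(inter)
        assert [e for _, e in ds.truth.pair_effects] == [1.5, -1.5]
        assert [e for _, e in ds.truth.trio_effects] == [2.0]

    def test_duplicates_preset_removes_exactly_twenty(self):
        ds = m.make_fixture("duplicates", seed=FIXTURE_SEED)
        _, rep = m.remove_duplicate_markers(ds.genotypes, 0.99)
        assert len(rep.removed_marker_ids) == 20
        assert all(mid.endswith("_dup") for mid in rep.removed_marker_ids)

    def test_duplicates_preset_truth_indices_track_inserted_columns(self):
        ds = m.make_fixture("duplicates", seed=FIXTURE_SEED)
        base = m.make_fixture("recovery_main", seed=FIXTURE_SEED)
        dup_ids = [ds.genotypes.marker_ids[j] for j, _ in ds.truth.main_effects]
        base_ids = [base.genotypes.marker_ids[j] for j, _ in base.truth.main_effects]
        assert dup_ids == base_ids

    def test_phenotype_reproducible_from_genotypes_truth_seed(self):
        ds = m.make_fixture("recovery_main", seed=FIXTURE_SEED)
        again = m.make_fixture("recovery_main", seed=FIXTURE_SEED)
        assert np.array_equal(ds.phenotypes.values, again.phenotypes.values)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            m.make_fixture("nope", seed=0)
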
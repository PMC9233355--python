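"""Population simulator: map construction, Haldane meiosis, pooling."""

import numpy as np
import pandas as pd
import pytest

from poolrr import popsim
from poolrr.popsim import (
    GenotypeMatrix,
    MapError,
    make_synthetic_map,
    pool_allele_frequency,
    simulate_f2_population,
    simulate_gamete,
    simulate_ril,
    subsample_markers,
)


def haldane_recombinant_fraction(d_morgan):
    """Closed-form oracle: P(odd crossovers in d Morgans)."""
    return (1.0 - np.exp(-2.0 * d_morgan)) / 2.0


class TestSyntheticMap:
    def test_uniform_equal_spacing(self):
        tmap = make_synthetic_map(1, 11, 10_000_000, 100.0, "uniform")
        np.testing.assert_allclose(tmap["cM"], np.arange(0, 101, 10), atol=1e-9)

    def test_barley_like_pericentromeric_suppression(self):
        tmap = make_synthetic_map(2, 300, 300_000_000, 300.0, "barley_like")
        for _, grp in tmap.groupby("chrom"):
            bp = grp["pos_bp"].to_numpy()
            cm = grp["cM"].to_numpy()
            rel = (bp - bp[0]) / (bp[-1] - bp[0])
            rr = np.diff(cm) / np.diff(bp)
            mid = (rel[:-1] >= 1 / 3) & (rel[:-1] < 2 / 3)
            assert np.median(rr[mid]) < np.median(rr[~mid])
            # outer thirds hold at least 70% of the genetic length
            mid_cm = cm[np.searchsorted(rel, 2 / 3)] - cm[np.searchsorted(rel, 1 / 3)]
            assert mid_cm / cm[-1] < 0.30
            assert np.all(np.diff(cm) >= 0)

    def test_per_chromosome_length(self):
        tmap = make_synthetic_map(4, 50, 50_000_000, 600.0, "uniform")
        lengths = tmap.groupby("chrom")["cM"].max()
        np.testing.assert_allclose(lengths, 150.0)

    @pytest.mark.parametrize(
        "args",
        [
            (0, 10, 1_000_000, 100.0, "uniform"),
            (1, 1, 1_000_000, 100.0, "uniform"),
            (1, 10, 1_000_000, 0.0, "uniform"),
            (1, 10, 1_000_000, 100.0, "weird"),
            (1, 10, 5, 100.0, "uniform"),
        ],
    )
    def test_invalid_sizes_rejected(self, args):
        with pytest.raises(MapError):
            make_synthetic_map(*args)


class TestGamete:
    def test_recombinant_fraction_matches_haldane(self, rng):
        """Switch fraction between marker pairs equals the Haldane closed form."""
        tmap = make_synthetic_map(1, 11, 10_000_000, 100.0, "uniform")
        n = 4000
        origins = np.stack([simulate_gamete(tmap, rng) for _ in range(n)])
        cm = tmap["cM"].to_numpy()
        checked = 0
        for i in range(len(cm)):
            for j in range(i + 1, len(cm)):
                d = (cm[j] - cm[i]) / 100.0
                expected = haldane_recombinant_fraction(d)
                observed = np.mean(origins[:, i] != origins[:, j])
                se = np.sqrt(max(expected * (1 - expected), 1e-6) / n)
                assert abs(observed - expected) < 3.5 * se
                checked += 1
        assert checked >= 10

    def test_zero_distance_markers_share_origin(self, rng):
        tmap = pd.DataFrame(
            {"chrom": ["c1"] * 3, "pos_bp": [1, 500, 1000], "cM": [0.0, 0.0, 0.0]}
        )
        for _ in range(50):
            g = simulate_gamete(tmap, rng)
            assert len(set(g)) == 1

    def test_chromosomes_independent_starts(self, rng):
        tmap = make_synthetic_map(2, 2, 1_000_000, 0.0002, "uniform")
        starts = np.stack([simulate_gamete(tmap, rng)[[0, 2]] for _ in range(500)])
        # both-parent combinations all occur for two ~unlinked chromosomes
        combos = {tuple(row) for row in starts}
        assert combos == {(0, 0), (0, 1), (1, 0), (1, 1)}


class TestF2:
    def test_dosage_values_and_mean(self, uniform_map, rng):
        g = simulate_f2_population(uniform_map, 3000, rng)
        assert set(np.unique(g.dosage)) <= {0, 1, 2}
        # per-locus mean dosage ~ 1.0 (allele frequency ~ 0.5)
        np.testing.assert_allclose(g.dosage.mean(axis=0), 1.0, atol=0.08)

    def test_af_half_normal_law(self):
        """|AF - 0.5| follows the Binomial(2n, 1/2) half-normal approximation."""
        tmap = make_synthetic_map(10, 20, 50_000_000, 1000.0, "uniform")
        n = 200
        devs = []
        for rep in range(10):
            g = simulate_f2_population(tmap, n, np.random.default_rng([77, rep]))
            af = pool_allele_frequency(g)["af"].to_numpy()
            devs.append(np.abs(af - 0.5))
        devs = np.concatenate(devs)
        sigma = 0.5 / np.sqrt(2 * n)
        exp_mean = sigma * np.sqrt(2 / np.pi)
        exp_sd = sigma * np.sqrt(1 - 2 / np.pi)
        assert abs(devs.mean() - exp_mean) < 4 * exp_sd / np.sqrt(200)  # ~indep loci
        assert abs(devs.std(ddof=1) - exp_sd) < 0.15 * exp_sd

    def test_af_deviation_shrinks_with_population_size(self):
        tmap = make_synthetic_map(10, 20, 50_000_000, 1000.0, "uniform")
        means = []
        for n in (50, 100, 500, 1000, 2000, 4000, 10000):
            devs = []
            for rep in range(2):
                g = simulate_f2_population(tmap, n, np.random.default_rng([n, rep]))
                devs.append(np.abs(pool_allele_frequency(g)["af"].to_numpy() - 0.5))
            means.append(np.concatenate(devs).mean())
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_same_seed_bit_identical(self, uniform_map):
        a = simulate_f2_population(uniform_map, 40, np.random.default_rng(3))
        b = simulate_f2_population(uniform_map, 40, np.random.default_rng(3))
        assert np.array_equal(a.dosage, b.dosage)


class TestRIL:
    def test_one_selfing_generation_is_f2(self, uniform_map):
        f2 = simulate_f2_population(uniform_map, 30, np.random.default_rng(11))
        ril1 = simulate_ril(uniform_map, 30, 1, np.random.default_rng(11))
        assert np.array_equal(f2.dosage, ril1.dosage)

    def test_infinite_selfing_fixes_all_loci(self, uniform_map, rng):
        g = simulate_ril(uniform_map, 200, None, rng)
        assert set(np.unique(g.dosage)) <= {0, 2}

    def test_haldane_waddington_expansion(self):
        """At full inbreeding R = 2r/(1+2r) — Haldane-Waddington oracle."""
        from poolrr.haldane import haldane_distance

        for r in (0.05, 0.2):
            d = haldane_distance(r)
            tmap = pd.DataFrame(
                {"chrom": ["c1", "c1"], "pos_bp": [1, 1_000_000], "cM": [0.0, d]}
            )
            g = simulate_ril(tmap, 4000, None, np.random.default_rng(int(r * 1000)))
            observed = np.mean(g.dosage[:, 0] != g.dosage[:, 1])
            expected = 2 * r / (1 + 2 * r)
            se = np.sqrt(expected * (1 - expected) / 4000)
            assert abs(observed - expected) < 3.5 * se


class TestSubsample:
    def test_full_depth_identity_without_rng_draw(self, uniform_map):
        rng = np.random.default_rng(0)
        state_before = rng.bit_generator.state
        sub = subsample_markers(uniform_map, len(uniform_map), rng)
        assert rng.bit_generator.state == state_before
        pd.testing.assert_frame_equal(sub, uniform_map.reset_index(drop=True))

    def test_subset_size_and_order(self, barley_map, rng):
        sub = subsample_markers(barley_map, 100, rng)
        assert len(sub) == 100
        for _, grp in sub.groupby("chrom"):
            assert grp["pos_bp"].is_monotonic_increasing

    def test_depth_exceeding_markers_rejected(self, uniform_map, rng):
        with pytest.raises(ValueError, match="exceeds"):
            subsample_markers(uniform_map, len(uniform_map) + 1, rng)

    def test_different_seeds_differ(self, barley_map):
        a = subsample_markers(barley_map, 50, np.random.default_rng(1))
        b = subsample_markers(barley_map, 50, np.random.default_rng(2))
        assert not a["pos_bp"].equals(b["pos_bp"])


class TestPooling:
    def test_af_arithmetic(self):
        markers = pd.DataFrame(
            {"chrom": ["c1"] * 2, "pos_bp": [1, 2000], "cM": [0.0, 1.0]}
        )
        g = GenotypeMatrix(markers=markers, dosage=np.array([[0, 1], [1, 1], [2, 1]]))
        af = pool_allele_frequency(g)
        np.testing.assert_allclose(af["af"], [0.5, 0.5])
        np.testing.assert_allclose(af["missing_frac"], [0.0, 0.0])

    def test_missing_calls_excluded_from_denominator(self):
        markers = pd.DataFrame({"chrom": ["c1"], "pos_bp": [1], "cM": [0.0]})
        g = GenotypeMatrix(
            markers=markers, dosage=np.array([[2], [2], [popsim.MISSING], [0]])
        )
        af = pool_allele_frequency(g)
        assert af["af"].iloc[0] == pytest.approx(4 / 6)
        assert af["missing_frac"].iloc[0] == pytest.approx(0.25)

    def test_all_missing_marker_dropped_with_warning(self):
        markers = pd.DataFrame(
            {"chrom": ["c1"] * 2, "pos_bp": [1, 2000], "cM": [0.0, 1.0]}
        )
        g = GenotypeMatrix(
            markers=markers,
            dosage=np.array([[popsim.MISSING, 1], [popsim.MISSING, 1]]),
        )
        with pytest.warns(UserWarning, match="no non-missing"):
            af = pool_allele_frequency(g)
        assert list(af["pos_bp"]) == [2000]
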
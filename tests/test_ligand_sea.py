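"""Ligand-set raw scores, background calibration, EVD fit and E-values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import gumbel_r

from polypharm import synthetic_data as sd
from polypharm.ligand_sea import (
    FingerprintSet,
    SeaCalibration,
    calibrate_evd,
    e_value,
    fit_background,
    fit_evd,
    hashed_fingerprint,
    raw_score,
    tanimoto,
    z_score,
)


def bits(on, n=16):
    fp = np.zeros(n, dtype=bool)
    fp[list(on)] = True
    return fp


class TestTanimoto:
    def test_identical_and_disjoint(self):
        a = bits({1, 2, 3})
        assert tanimoto(a, a) == 1.0
        assert tanimoto(a, bits({5, 6})) == 0.0

    def test_half_overlap(self):
        assert tanimoto(bits({1, 2, 3}), bits({2, 3, 4})) == 0.5

    def test_both_empty_defined_zero(self):
        assert tanimoto(bits(set()), bits(set())) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            tanimoto(bits({1}, 8), bits({1}, 16))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.booleans(), min_size=4, max_size=32), st.data())
    def test_symmetry_and_bounds(self, a, data):
        b = data.draw(st.lists(st.booleans(), min_size=len(a), max_size=len(a)))
        a, b = np.array(a), np.array(b)
        t = tanimoto(a, b)
        assert t == tanimoto(b, a)
        assert 0.0 <= t <= 1.0


class TestRawScore:
    def test_sums_only_above_cutoff(self):
        # Three ligand pairs engineered to Tc = 0.6, 0.5, 0.9 with all
        # cross terms bit-disjoint; only the pairs strictly above 0.55
        # count, so the raw score is 0.6 + 0.9 = 1.5.
        A = np.stack([bits({0, 1, 2, 3}, 40), bits(range(10, 16), 40), bits(range(21, 30), 40)])
        B = np.stack([
            bits({0, 1, 2, 4}, 40),
            bits(range(12, 18), 40),
            bits(range(21, 30), 40) | bits({39}, 40),
        ])
        assert tanimoto(A[0], B[0]) == pytest.approx(0.6)
        assert tanimoto(A[1], B[1]) == pytest.approx(0.5)   # <= 0.55, excluded
        assert tanimoto(A[2], B[2]) == pytest.approx(0.9)
        assert tanimoto(A[0], B[1]) == 0.0  # cross terms vanish
        assert raw_score(A, B) == pytest.approx(1.5)

    def test_zero_when_all_below_cutoff(self):
        A = np.stack([bits(range(0, 10), 40)])
        B = np.stack([bits(range(5, 15), 40)])  # Tc = 5/15 = 1/3
        assert raw_score(A, B) == 0.0

    def test_self_score_counts_diagonal(self):
        fps = np.stack([bits({1, 2, 3}, 16)] * 4)
        s = FingerprintSet("X", fps)
        assert raw_score(s, s) >= 4.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 500))
    def test_symmetric_and_monotone_under_addition(self, seed):
        rng = np.random.default_rng(seed)
        uni = sd.ScaffoldUniverse(n_bits=256, n_scaffolds=5, bits_per_scaffold=40,
                                  n_flips=4, rng_seed=seed)
        A = uni.draw_ligands(4, rng)
        B = uni.draw_ligands(3, rng)
        extra = uni.draw_ligands(1, rng)
        assert raw_score(A, B) == pytest.approx(raw_score(B, A))
        assert raw_score(A, B) >= 0.0
        assert raw_score(np.vstack([A, extra]), B) >= raw_score(A, B)


@pytest.fixture(scope="module")
def universe():
    return sd.ScaffoldUniverse(rng_seed=11)


@pytest.fixture(scope="module")
def calibration(universe):
    grid = [(5, 5), (8, 8), (12, 12), (16, 16)]
    return fit_background(universe.draw_ligands, grid, n_samples_per_cell=300, rng_seed=1)


class TestBackgroundFit:
    def test_mean_increases_with_size_product(self, calibration):
        assert calibration.mean_at(256) > calibration.mean_at(25)

    def test_background_z_standardized(self, universe, calibration):
        rng = np.random.default_rng(2)
        zs = []
        for i in range(2000):
            n1, n2 = [(5, 5), (8, 8), (12, 12), (16, 16)][i % 4]
            r = raw_score(universe.draw_ligands(n1, rng), universe.draw_ligands(n2, rng))
            zs.append(z_score(r, n1, n2, calibration))
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.1
        assert 0.9 < zs.std() < 1.1

    def test_degenerate_background_raises(self):
        def zeros(n, rng):
            return np.zeros((n, 64), dtype=bool)

        with pytest.raises(ValueError, match="degenerate"):
            fit_background(zeros, [(5, 5), (10, 10)], n_samples_per_cell=30)

    def test_requires_two_size_products(self, universe):
        with pytest.raises(ValueError, match="distinct size products"):
            fit_background(universe.draw_ligands, [(5, 5), (5, 5)], n_samples_per_cell=30)

    def test_z_at_fitted_mean_is_zero(self, calibration):
        m = calibration.mean_at(100)
        s = calibration.sd_at(100)
        assert z_score(m, 10, 10, calibration) == pytest.approx(0.0, abs=1e-12)
        assert z_score(m + 2 * s, 10, 10, calibration) == pytest.approx(2.0, abs=1e-12)

    def test_json_round_trip(self, calibration, tmp_path):
        calibration.to_json(tmp_path / "cal.json")
        back = SeaCalibration.from_json(tmp_path / "cal.json")
        assert back.mean_coef == calibration.mean_coef
        assert back.sd_coef == calibration.sd_coef


class TestEvd:
    def test_gumbel_parameter_recovery(self):
        rng = np.random.default_rng(5)
        z = gumbel_r.rvs(loc=0.0, scale=1.0, size=10_000, random_state=rng)
        fit = fit_evd(z)
        assert -0.1 <= fit.mu <= 0.1
        assert 0.9 <= fit.sigma <= 1.1

    def test_location_equivariance(self):
        rng = np.random.default_rng(6)
        z = gumbel_r.rvs(size=5000, random_state=rng)
        f0 = fit_evd(z)
        f1 = fit_evd(z + 2.5)
        assert f1.mu == pytest.approx(f0.mu + 2.5, abs=1e-6)

    def test_rejects_nonfinite(self):
        z = np.full(2000, np.nan)
        with pytest.raises(ValueError):
            fit_evd(z)

    def test_e_value_at_location(self):
        cal = SeaCalibration(evd_mu=1.0, evd_sigma=0.5, n_comparisons=1)
        assert e_value(1.0, cal) == pytest.approx(1 - np.exp(-1), rel=1e-12)

    def test_e_value_vanishes_in_tail(self):
        cal = SeaCalibration(evd_mu=0.0, evd_sigma=1.0, n_comparisons=1000)
        assert e_value(50.0, cal) < 1e-18
        assert e_value(100.0, cal) < e_value(50.0, cal) + 1e-30

    def test_uncalibrated_raises(self):
        with pytest.raises(ValueError, match="calibrated"):
            e_value(1.0, SeaCalibration())


def test_hashed_fingerprint_deterministic_and_discriminating():
    f1 = hashed_fingerprint("CCOCCN")
    f2 = hashed_fingerprint("CCOCCN")
    f3 = hashed_fingerprint("c1ccccc1O")
    assert np.array_equal(f1, f2)
    assert tanimoto(f1, f3) < tanimoto(f1, f2)


def test_planted_pair_beats_background_end_to_end():
    lig = sd.gen_ligand_sets(12, n_shared_scaffold_pairs=1, rng_seed=9)
    uni = lig.universe
    cal = fit_background(uni.draw_ligands, [(5, 5), (10, 10), (15, 15), (20, 20)],
                         n_samples_per_cell=200, rng_seed=3, n_comparisons=66)
    rng = np.random.default_rng(4)
    zs = np.array([
        z_score(raw_score(uni.draw_ligands(10, rng), uni.draw_ligands(10, rng)), 10, 10, cal)
        for _ in range(2000)
    ])
    calibrate_evd(cal, zs)
    a, b = lig.shared_pairs[0]
    A, B = lig.sets[a], lig.sets[b]
    z = z_score(raw_score(A, B), len(A), len(B), cal)
    assert e_value(z, cal) <= 1e-4
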
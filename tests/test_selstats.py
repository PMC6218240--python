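"""FST, EHH and XP-EHH against independent oracles and analytic anchors."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sweepenrich as se
from sweepenrich.selstats import XpehhConfig, _ies_chromosome

from conftest import POP_A, POP_B, make_panel, study_config


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def fst_reference(p_a, p_b, n_a, n_b):
    """Independent scalar re-evaluation of the haploid two-population
    variance-components estimator (plain math, no arrays)."""
    r = 2.0
    nbar = (n_a + n_b) / r
    nc = (r * nbar - (n_a * n_a + n_b * n_b) / (r * nbar)) / (r - 1.0)
    pbar = (n_a * p_a + n_b * p_b) / (r * nbar)
    s2 = (n_a * (p_a - pbar) ** 2 + n_b * (p_b - pbar) ** 2) / ((r - 1.0) * nbar)
    t1 = s2 - (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r) / (nbar - 1.0)
    t2 = ((nc - 1.0) / (nbar - 1.0)) * pbar * (1.0 - pbar) \
        + (1.0 + (r - 1.0) * (nbar - nc) / (nbar - 1.0)) * s2 / r
    return t1 / t2


def ehh_enumeration(alleles, core, direction):
    """Exhaustive pairwise-identity EHH values site by site from the core."""
    n_sites, n = alleles.shape
    n_pairs = n * (n - 1) // 2
    order = range(core + 1, n_sites) if direction == "downstream" \
        else range(core - 1, -1, -1)
    values = []
    for x in order:
        lo, hi = (core + 1, x + 1) if direction == "downstream" else (x, core)
        ident = sum(
            1 for i, j in itertools.combinations(range(n), 2)
            if np.array_equal(alleles[lo:hi, i], alleles[lo:hi, j])
        )
        values.append(ident / n_pairs)
    return values


def panel_from_matrix(alleles, pos=None):
    return make_panel(alleles, pos=pos)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("alleles,expected", [
    ([0, 0, 1, 1], 0.5),
    ([0, 0, 0, 0], 0.0),
    ([1, 1, 1, 0, 0], 0.6),
])
def test_allele_frequency_counts(alleles, expected):
    panel = make_panel(np.array([alleles]))
    assert se.allele_frequencies(panel, "pop")[0] == pytest.approx(expected)


def test_all_missing_site_is_an_error():
    panel = make_panel(np.full((1, 4), se.MISSING))
    with pytest.raises(se.PanelError, match="missing"):
        se.allele_frequencies(panel, "pop")


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

class TestFstWeirHaploid:
    def test_fixed_difference_gives_theta_one(self):
        for n_a, n_b in [(5, 5), (41, 21), (7, 31)]:
            alleles = np.array([[1] * n_a + [0] * n_b])
            panel = make_panel(alleles, pops=["A"] * n_a + ["B"] * n_b)
            track = se.fst_weir_haploid(panel, "A", "B")
            assert track.values[0] == pytest.approx(1.0, abs=1e-12)

    def test_equal_frequencies_give_retained_negative(self):
        # p_A = p_B = 0.5, n = 4 each: estimator is slightly negative
        alleles = np.array([[0, 0, 1, 1, 1, 1, 0, 0]])
        panel = make_panel(alleles, pops=["A"] * 4 + ["B"] * 4)
        theta = se.fst_weir_haploid(panel, "A", "B").values[0]
        assert theta < 0
        assert theta == pytest.approx(fst_reference(0.5, 0.5, 4, 4), abs=1e-12)

    def test_matches_independent_reference_on_real_counts(self):
        # realizable frequencies at the study sample sizes
        rng = np.random.default_rng(5)
        n_a, n_b = 41, 21
        for _ in range(25):
            k_a = rng.integers(0, n_a + 1)
            k_b = rng.integers(0, n_b + 1)
            if (k_a + k_b == 0) or (k_a + k_b == n_a + n_b):
                continue
            alleles = np.array([[1] * k_a + [0] * (n_a - k_a)
                                + [1] * k_b + [0] * (n_b - k_b)])
            panel = make_panel(alleles, pops=["A"] * n_a + ["B"] * n_b)
            theta = se.fst_weir_haploid(panel, "A", "B").values[0]
            expected = fst_reference(k_a / n_a, k_b / n_b, n_a, n_b)
            assert theta == pytest.approx(expected, abs=1e-12)
            assert theta <= 1.0 + 1e-12

    def test_monomorphic_sites_excluded_with_log(self, caplog):
        alleles = np.array([[1, 1, 1, 1], [0, 1, 0, 1]])
        panel = make_panel(alleles, pops=["A", "A", "B", "B"])
        with caplog.at_level("INFO", logger="sweepenrich"):
            track = se.fst_weir_haploid(panel, "A", "B")
        assert len(track) == 1
        assert "monomorphic" in caplog.text


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

class TestEhhCurve:
    def test_worked_four_haplotype_example(self):
        # extensions beyond the core: 00, 00, 01, 11
        alleles = np.array([
            [0, 1, 0, 1],  # core site (alleles irrelevant to EHH definition)
            [0, 0, 0, 1],
            [0, 0, 1, 1],
        ])
        panel = make_panel(alleles, pos=[100, 200, 300])
        curve = se.ehh_curve(panel, "pop", 0, "downstream")
        np.testing.assert_allclose(curve.distance_bp, [0, 100, 200])
        assert curve.ehh[0] == 1.0
        assert curve.ehh[1] == pytest.approx(0.5)       # C(3,2)/C(4,2)
        assert curve.ehh[2] == pytest.approx(1 / 6)     # C(2,2)/C(4,2)

    def test_identical_haplotypes_keep_ehh_one_to_chromosome_end(self):
        alleles = np.tile(np.array([[0], [1], [0], [1]]), (1, 5))
        panel = make_panel(alleles)
        curve = se.ehh_curve(panel, "pop", 0, "downstream")
        assert curve.ehh.size == 4
        assert np.all(curve.ehh == 1.0)

    def test_single_haplotype_pair_required(self):
        panel = make_panel(np.array([[0], [1]]))
        with pytest.raises(se.PanelError, match="2 haplotypes"):
            se.ehh_curve(panel, "pop", 0, "downstream")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_curve_matches_exhaustive_enumeration_and_is_monotone(self, data):
        n = data.draw(st.integers(2, 12))
        s = data.draw(st.integers(2, 20))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        alleles = rng.integers(0, 2, size=(s, n)).astype(np.int8)
        core = int(data.draw(st.integers(0, s - 1)))
        direction = data.draw(st.sampled_from(["downstream", "upstream"]))
        panel = make_panel(alleles)
        curve = se.ehh_curve(panel, "pop", core, direction)
        expected = ehh_enumeration(alleles, core, direction)
        # identical floats: both are integer pair counts over C(n,2)
        for k, v in enumerate(curve.ehh[1:]):
            assert v == expected[k]
            if v < 0.05:
                break
        assert np.all(np.diff(curve.ehh) <= 1e-15)  # non-increasing


class TestIntegrateEhh:
    def test_hand_trapezoid(self):
        down = se.EHHCurve(0, "downstream", np.array([0.0, 100.0, 200.0]),
                           np.array([1.0, 0.5, 1 / 6]))
        ies = se.integrate_ehh(None, down)
        assert ies == pytest.approx(100 * 1.5 / 2 + 100 * (0.5 + 1 / 6) / 2)

    def test_long_gap_is_down_weighted_to_scale(self):
        down = se.EHHCurve(0, "downstream", np.array([0.0, 100.0, 50_100.0]),
                           np.array([1.0, 0.5, 1 / 6]))
        ies = se.integrate_ehh(None, down)
        # 50 kb gap contributes as if it were 20 kb long
        assert ies == pytest.approx(100 * 1.5 / 2 + 20_000 * (0.5 + 1 / 6) / 2)

    def test_truncated_at_cutoff_crossing(self):
        down = se.EHHCurve(0, "downstream", np.array([0.0, 100.0, 200.0]),
                           np.array([1.0, 0.5, 0.01]))
        ies = se.integrate_ehh(None, down)
        assert ies == pytest.approx(100 * 1.5 / 2)  # second interval excluded

    def test_isolated_core_is_unscored(self):
        lone = se.EHHCurve(0, "downstream", np.array([0.0]), np.array([1.0]))
        assert se.integrate_ehh(lone, None) == 0.0


def test_fast_scan_equals_curve_integration():
    rng = np.random.default_rng(21)
    for _ in range(10):
        n = int(rng.integers(2, 10))
        s = int(rng.integers(3, 25))
        alleles = rng.integers(0, 2, size=(s, n)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 200_000), s, replace=False))
        panel = make_panel(alleles, pos=pos)
        cfg = XpehhConfig()
        fast = _ies_chromosome(alleles, pos, cfg)
        for core in range(s):
            up = se.ehh_curve(panel, "pop", core, "upstream")
            down = se.ehh_curve(panel, "pop", core, "downstream")
            assert fast[core] == pytest.approx(se.integrate_ehh(up, down, cfg),
                                               abs=1e-9)


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_panel():
    cfg = se.SweepSimConfig(chrom_length_bp=2_000_000, n_sites=800,
                            n_a=20, n_b=12)
    panel, _ = se.simulate_two_pop_sweep(cfg, seed=3)
    return se.complete_data_subset(panel, (POP_A, POP_B))


class TestXpehhScan:
    def test_population_swap_negates_raw_scores_exactly(self, small_panel):
        fwd = se.xpehh_scan(small_panel, POP_A, POP_B, normalize=False)
        rev = se.xpehh_scan(small_panel, POP_B, POP_A, normalize=False)
        np.testing.assert_array_equal(fwd.df["raw"].to_numpy(),
                                      -rev.df["raw"].to_numpy())

    def test_normalized_track_has_zero_mean_unit_sd(self, small_panel):
        track = se.xpehh_scan(small_panel, POP_A, POP_B)
        assert abs(track.values.mean()) < 1e-9
        assert abs(track.values.std(ddof=0) - 1.0) < 1e-9
        assert track.normalization is not None and track.normalization["sd"] > 0

    def test_identical_populations_are_degenerate(self):
        alleles = np.array([[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1]])
        panel = make_panel(alleles, pops=["A", "A", "B", "B"],
                           pos=[100, 200, 300])
        with pytest.raises(se.PanelError, match="degenerate"):
            se.xpehh_scan(panel, "A", "B")

    def test_full_sweep_core_scores_in_lowest_percentile(self):
        cfg = se.SweepSimConfig(
            chrom_length_bp=8_000_000, n_sites=2000, n_a=25, n_b=15,
            sweeps=[se.SweepSpec("1", 4_000_000, 200_000, 1.0)])
        panel, _ = se.simulate_two_pop_sweep(cfg, seed=9)
        panel = se.complete_data_subset(panel, (POP_A, POP_B))
        track = se.xpehh_scan(panel, POP_A, POP_B)
        pos = track.df["pos"].to_numpy()
        centre_score = track.values[np.argmin(np.abs(pos - 4_000_000))]
        assert centre_score < 0
        assert centre_score <= np.quantile(track.values, 0.025)
        # the entire lowest-1% tail of the track sits inside the sweep
        tail = pos[track.values <= np.quantile(track.values, 0.01)]
        assert np.all(np.abs(tail - 4_000_000) <= 120_000)


def test_sweep_detection_fst_and_xpehh_medians():
    """f >= 0.8 sweeps: XP-EHH lower and FST higher inside swept windows
    than outside, in >= 18 of 20 seeds."""
    hits_xp = hits_fst = 0
    for seed in range(20):
        cfg = se.SweepSimConfig(
            chrom_length_bp=4_000_000, n_sites=1200, n_a=25, n_b=15,
            sweeps=[se.SweepSpec("1", 2_000_000, 300_000, 0.8)])
        panel, truth = se.simulate_two_pop_sweep(cfg, seed=seed)
        panel = se.complete_data_subset(panel, (POP_A, POP_B))
        swept = [w for _, w in truth.swept_windows]
        xp = se.xpehh_scan(panel, POP_A, POP_B)
        fst = se.fst_weir_haploid(panel, POP_A, POP_B)
        for track, store in ((xp, "xp"), (fst, "fst")):
            ws = se.window_start(track.df["pos"].to_numpy())
            inside = np.isin(ws, swept)
            med_in = np.median(track.values[inside])
            med_out = np.median(track.values[~inside])
            if store == "xp" and med_in < med_out:
                hits_xp += 1
            if store == "fst" and med_in > med_out:
                hits_fst += 1
    assert hits_xp >= 18
    assert hits_fst >= 18
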
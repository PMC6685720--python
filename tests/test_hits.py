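"""Exposure features: binning, summaries, thresholds, fingerprints."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from headimpact import (FingerprintBinner, bin_index, canonicalize_angles,
                        cohort_sd_threshold, compute_fingerprint,
                        count_exclusive, count_suprathreshold,
                        decile_thresholds, summarize_hit_log)
from headimpact.hits import read_hit_log

from conftest import make_hit_log


def brute_force_bin(az, el):
    """Independent oracle: scan all 648 bin rectangles for the one containing
    the canonicalized angle pair (top elevation edge closed)."""
    az, el = canonicalize_angles(az, el)
    for ia in range(36):
        lo_a = -180.0 + 10.0 * ia
        if not (lo_a <= az < lo_a + 10.0):
            continue
        for ie in range(18):
            lo_e = -90.0 + 10.0 * ie
            hi_e = lo_e + 10.0
            if lo_e <= el < hi_e or (ie == 17 and el == 90.0):
                return ia * 18 + ie
    raise AssertionError("no rectangle contains the angle pair")


class TestBinIndex:
    def test_first_bin_convention(self):
        assert bin_index(-180.0, -90.0) == 0

    def test_right_side_equator(self):
        # azimuth bin [90, 100) is the 28th (index 27), elevation [0, 10) the 10th
        assert bin_index(90.0, 0.0) == 27 * 18 + 9 == 495

    def test_top_elevation_edge_closed(self):
        assert bin_index(0.0, 90.0) % 18 == 17

    def test_matches_rectangle_oracle_on_random_angles(self):
        rng = np.random.default_rng(0)
        az = rng.uniform(-720.0, 720.0, 10_000)
        el = rng.uniform(-90.0, 90.0, 10_000)
        got = bin_index(az, el)
        sample = rng.choice(10_000, 400, replace=False)  # oracle is slow
        for i in sample:
            assert got[i] == brute_force_bin(az[i], el[i])
        assert got.min() >= 0 and got.max() <= 647

    def test_nonfinite_angle_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            bin_index(np.nan, 0.0)

    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_total_on_canonicalized_angles(self, az, el):
        idx = bin_index(az, el)
        assert 0 <= idx <= 647
        ca, ce = canonicalize_angles(az, el)
        assert -180.0 <= ca < 180.0
        assert -90.0 <= ce <= 90.0
        # canonicalization is idempotent and preserves the bin
        assert bin_index(ca, ce) == idx


class TestFingerprint:
    def test_single_hit_single_bin(self):
        log = pd.DataFrame({"azimuth_deg": [45.0], "elevation_deg": [12.0]})
        fp = compute_fingerprint(log)
        assert fp.n_bins == 648 and fp.n_hits == 1
        assert fp.weights.sum() == 1.0
        assert (fp.weights > 0).sum() == 1

    def test_empty_input_flagged_zero_vector(self):
        fp = compute_fingerprint(pd.DataFrame({"azimuth_deg": [], "elevation_deg": []}))
        assert fp.n_hits == 0 and not fp.weights.any()

    def test_matches_per_hit_accumulation(self, rng):
        log = make_hit_log(rng, 1000)
        fp = compute_fingerprint(log)
        expected = np.zeros(648)
        for az, el in zip(log.azimuth_deg, log.elevation_deg):
            expected[bin_index(az, el)] += 1 / 1000
        np.testing.assert_allclose(fp.weights, expected)
        assert abs(fp.weights.sum() - 1.0) < 1e-12
        assert (fp.weights >= 0).all()

    def test_binner_roster_and_row_normalization(self, random_log):
        binner = FingerprintBinner(roster=["A", "B", "C", "Z"]).fit(random_log)
        F = binner.transform(random_log)
        assert F.shape == (4, 648)
        np.testing.assert_allclose(F[:3].sum(axis=1), 1.0, atol=1e-12)
        assert not F[3].any()  # player Z has no hits

    def test_reduced_resolution_bin_count(self):
        assert FingerprintBinner(az_bin_deg=30, el_bin_deg=30).n_bins == 72


class TestSummary:
    def test_session_percentages(self):
        log = pd.DataFrame({
            "player_id": ["A"] * 4,
            "session_type": ["practice", "practice", "game", "scrimmage"],
            "linear_g": [10.0, 20.0, 30.0, 40.0],
            "rotational_rad_s2": [1.0, 2.0, 3.0, 4.0],
            "azimuth_deg": [0.0] * 4, "elevation_deg": [0.0] * 4,
        })
        s = summarize_hit_log(log)
        assert s.loc["practice", "percent"] == 50.0
        assert s.loc["game", "percent"] == 25.0
        assert s.loc["other", "percent"] == 25.0  # scrimmage grouped as other
        assert s.loc["practice", "linear_median"] == 15.0
        assert s.loc["practice", "linear_mean"] == 15.0

    def test_matches_naive_loop(self, random_log):
        s = summarize_hit_log(random_log)
        for st_name in ("practice", "game", "other"):
            vals = [r.linear_g for r in random_log.itertuples()
                    if r.session_type == st_name]
            assert s.loc[st_name, "n_hits"] == len(vals)
            if vals:
                assert s.loc[st_name, "linear_mean"] == pytest.approx(np.mean(vals))
                assert s.loc[st_name, "linear_median"] == pytest.approx(np.median(vals))
        assert s.percent.sum() == pytest.approx(100.0)

    def test_empty_log_zero_counts(self):
        empty = pd.DataFrame(columns=["player_id", "session_type", "linear_g",
                                      "rotational_rad_s2", "azimuth_deg",
                                      "elevation_deg"])
        s = summarize_hit_log(empty)
        assert (s.n_hits == 0).all()
        assert s.linear_median.isna().all()


class TestThresholds:
    def test_mean_plus_sample_sd(self):
        log = pd.DataFrame({"linear_g": [1.0, 2.0, 3.0]})
        assert cohort_sd_threshold(log, "linear") == pytest.approx(3.0)

    def test_zero_variance(self):
        log = pd.DataFrame({"rotational_rad_s2": [5.0] * 7})
        assert cohort_sd_threshold(log, "rotational") == 5.0

    def test_matches_brute_force(self, random_log):
        got = cohort_sd_threshold(random_log, "rotational")
        v = random_log.rotational_rad_s2.to_numpy()
        mean = sum(v) / len(v)
        sd = (sum((x - mean) ** 2 for x in v) / (len(v) - 1)) ** 0.5
        assert got == pytest.approx(mean + sd)

    def test_too_few_hits(self):
        with pytest.raises(ValueError, match="at least 2"):
            cohort_sd_threshold(pd.DataFrame({"linear_g": [1.0]}), "linear")


class TestCounts:
    def test_examples(self):
        log = pd.DataFrame({"linear_g": [10.0, 20.0, 30.0]})
        assert count_suprathreshold(log, "linear", 25.0) == 1
        assert count_suprathreshold(log, "linear", 0.0) == 3

    def test_matches_naive_filter(self, rng, random_log):
        thr = float(rng.uniform(20, 60))
        got = count_suprathreshold(random_log, "linear", thr)
        assert got == sum(1 for x in random_log.linear_g if x >= thr)

    def test_non_increasing_in_threshold(self, random_log):
        thrs = np.linspace(1, 200, 50)
        counts = [count_suprathreshold(random_log, "linear", t) for t in thrs]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_exclusive_examples(self):
        both = pd.DataFrame({"linear_g": [60.0], "rotational_rad_s2": [3000.0]})
        assert count_exclusive(both, 2782.0, 50.0, "rot_only") == 0
        rot = pd.DataFrame({"linear_g": [20.0], "rotational_rad_s2": [3000.0]})
        assert count_exclusive(rot, 2782.0, 50.0, "rot_only") == 1

    def test_exclusive_partition_identity(self, random_log):
        rt, lt = 2000.0, 35.0
        rot_only = count_exclusive(random_log, rt, lt, "rot_only")
        lin_only = count_exclusive(random_log, rt, lt, "lin_only")
        both = sum(1 for r in random_log.itertuples()
                   if r.rotational_rad_s2 >= rt and r.linear_g >= lt)
        neither = sum(1 for r in random_log.itertuples()
                      if r.rotational_rad_s2 < rt and r.linear_g < lt)
        assert rot_only + lin_only + both + neither == len(random_log)


class TestDeciles:
    def test_linear_interpolation_rule(self):
        log = pd.DataFrame({"linear_g": np.arange(1.0, 101.0)})
        got = decile_thresholds(log, "linear")
        v = np.sort(log.linear_g.to_numpy())
        for k, q in enumerate(range(10, 100, 10)):
            # independent sort-and-index oracle for the linear rule
            h = (len(v) - 1) * q / 100.0
            lo = int(np.floor(h))
            expected = v[lo] + (h - lo) * (v[lo + 1] - v[lo])
            assert got[k] == pytest.approx(expected)

    def test_constant_values(self):
        log = pd.DataFrame({"linear_g": [7.0] * 12})
        assert (decile_thresholds(log, "linear") == 7.0).all()

    def test_counts_monotone_over_deciles(self, random_log):
        thrs = decile_thresholds(random_log, "rotational")
        assert (np.diff(thrs) >= 0).all()
        counts = [count_suprathreshold(random_log, "rotational", t) for t in thrs]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_too_few_hits(self):
        with pytest.raises(ValueError, match="at least 10"):
            decile_thresholds(pd.DataFrame({"linear_g": np.arange(5.0)}), "linear")


def test_read_hit_log_roundtrip(tmp_path, random_log):
    path = tmp_path / "hits.csv"
    random_log.to_csv(path, index=False)
    back = read_hit_log(path)
    assert len(back) == len(random_log)
    assert set(back.session_type) <= {"practice", "game", "other"}
    with pytest.raises(ValueError, match="missing columns"):
        pd.DataFrame({"player_id": []}).to_csv(tmp_path / "bad.csv", index=False)
        read_hit_log(tmp_path / "bad.csv")
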
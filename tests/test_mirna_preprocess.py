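"""Spot-level preprocessing: formula examples, oracles, pipeline properties."""

import numpy as np
import pandas as pd
import pytest

from concordx.mirna_preprocess import (
    DetectionThreshold,
    ProbeIntensityMatrix,
    collapse_triplicates,
    detection_filter,
    detection_threshold,
    log2_transform,
    normalization_factor,
    normalize,
    preprocess_mirna,
    spot_intensity,
)
from concordx.synthetic_data import SimConfig, SpotTable, simulate_spot_arrays


def brute_trimmed_mean(x, trim):
    """Sort, drop floor(n*trim) from each tail, average the rest."""
    x = sorted(x)
    k = int(len(x) * trim)
    kept = x[k : len(x) - k] if k > 0 else x
    return sum(kept) / len(kept)


def make_array(ctrl_intensities, bg_sd, array_id="a0", probe_spots=None):
    rows = []
    for i, v in enumerate(ctrl_intensities):
        rows.append((1, 0, i + 1, f"neg_{i}", 1000.0 + v, 1000.0, 0, 1))
    for name, vals, flags in probe_spots or []:
        for j, (v, fl) in enumerate(zip(vals, flags)):
            rows.append((1, 1, j + 1, name, 1000.0 + v, 1000.0, fl, 0))
    spots = pd.DataFrame(
        rows, columns=["Block", "Row", "Column", "Name", "F_Median", "B_Median", "Flags", "ControlType"]
    )
    return SpotTable(array_id=array_id, group="g", spots=spots, background_sd=bg_sd)


class TestSpotIntensity:
    @pytest.mark.parametrize("f, b, expected", [(500, 100, 400), (100, 100, 0), (90, 100, -10)])
    def test_background_subtraction(self, f, b, expected):
        spots = pd.DataFrame({"F_Median": [f], "B_Median": [b]})
        assert spot_intensity(spots).iloc[0] == expected

    def test_non_positive_becomes_missing_in_log2(self):
        assert np.isnan(log2_transform(np.array([-10.0]))[0])
        assert np.isnan(log2_transform(np.array([0.0]))[0])


class TestDetectionThreshold:
    def test_constant_controls_plus_sd_margin(self):
        arr = make_array([10, 10, 10, 10], bg_sd=2.0)
        t = detection_threshold(arr)
        assert t.t_raw == pytest.approx(10 + 5 * 2)
        assert t.t_log2 == pytest.approx(np.log2(20), abs=1e-9)

    def test_trimming_drops_one_value_per_tail(self):
        arr = make_array([1] + [10] * 8 + [100], bg_sd=0.0)
        t = detection_threshold(arr, trim=0.10, k_sd=5.0)
        assert t.t_raw == pytest.approx(10.0)

    def test_zero_trim_zero_ksd_reduces_to_plain_mean(self):
        vals = [3, 5, 7, 9, 11]
        arr = make_array(vals, bg_sd=4.0)
        t = detection_threshold(arr, trim=0.0, k_sd=0.0)
        assert t.t_raw == pytest.approx(np.mean(vals))

    def test_no_negative_controls_is_hard_error(self):
        arr = make_array([10], bg_sd=1.0)
        arr.spots["ControlType"] = 0
        with pytest.raises(ValueError, match="negative-control"):
            detection_threshold(arr)

    def test_nonpositive_threshold_is_hard_error(self):
        arr = make_array([-50, -50], bg_sd=0.0)
        with pytest.raises(ValueError, match="log-transform"):
            detection_threshold(arr)


class TestLog2Transform:
    @pytest.mark.parametrize("x, expected", [(8.0, 3.0), (1.0, 0.0)])
    def test_values(self, x, expected):
        assert log2_transform(np.array([x]))[0] == pytest.approx(expected)

    def test_preserves_pandas_containers(self):
        s = pd.Series([4.0, -1.0], index=["a", "b"])
        out = log2_transform(s)
        assert isinstance(out, pd.Series) and list(out.index) == ["a", "b"]
        assert out["a"] == 2.0 and np.isnan(out["b"])


def two_identical_arrays(intensities):
    """Two arrays whose probes each have one spot at 2**v raw intensity."""
    arrays = []
    for aid in ("a0", "a1"):
        spots = [(f"p{i}", [2.0**v - 0.0], [0]) for i, v in enumerate(intensities)]
        arr = make_array([0.5, 0.5], bg_sd=0.0, array_id=aid, probe_spots=spots)
        arrays.append(arr)
    return arrays


class TestNormalization:
    def test_trimmed_mean_over_common_detected_set(self):
        arrays = two_identical_arrays(list(range(1, 11)))  # log2 spot values 1..10
        thresholds = {a.array_id: DetectionThreshold(a.array_id, 1.0, 0.0) for a in arrays}
        n = normalization_factor(arrays, thresholds, trim=0.20)
        assert n["a0"] == pytest.approx(5.5)  # mean of {3..8}
        assert n["a0"] == n["a1"]

    def test_zero_trim_is_plain_mean(self):
        arrays = two_identical_arrays([2, 4, 6])
        thresholds = {a.array_id: DetectionThreshold(a.array_id, 1.0, 0.0) for a in arrays}
        n = normalization_factor(arrays, thresholds, trim=0.0)
        assert n["a0"] == pytest.approx(4.0)

    def test_empty_common_detected_set_is_hard_error(self):
        arrays = two_identical_arrays([2, 3])
        thresholds = {a.array_id: DetectionThreshold(a.array_id, 1.0, 99.0) for a in arrays}
        with pytest.raises(ValueError, match="detected"):
            normalization_factor(arrays, thresholds)

    def test_identical_factors_make_normalize_identity(self):
        arrays = two_identical_arrays([2, 4, 6, 8])
        thresholds = {a.array_id: DetectionThreshold(a.array_id, 1.0, 0.0) for a in arrays}
        factors = {"a0": 3.0, "a1": 3.0}
        normed, t_norm = normalize(arrays, thresholds, factors)
        for aid in ("a0", "a1"):
            pd.testing.assert_series_equal(
                normed[aid]["normalized"], normed[aid]["log2_intensity"], check_names=False
            )
            assert t_norm[aid] == thresholds[aid].t_log2

    def test_two_array_shift_arithmetic(self):
        # value 5 on an array with N=4, grand mean N=5 -> 6
        arrays = two_identical_arrays([5.0])
        thresholds = {a.array_id: DetectionThreshold(a.array_id, 1.0, 0.0) for a in arrays}
        normed, _ = normalize(arrays, thresholds, {"a0": 4.0, "a1": 6.0})
        assert normed["a0"]["normalized"].iloc[0] == pytest.approx(5 - 4 + 5)

    def test_experiment_wide_mean_shift_is_zero(self):
        cfg = SimConfig(n_probes=50, groups=[("DM", 3), ("MW", 3)], noise_sd=0.3, seed=13)
        arrays, _ = simulate_spot_arrays(cfg)
        thresholds = {a.array_id: detection_threshold(a) for a in arrays}
        factors = normalization_factor(arrays, thresholds)
        normed, _ = normalize(arrays, thresholds, factors)
        shifts = []
        for aid, spots in normed.items():
            shifts.append((spots["normalized"] - spots["log2_intensity"]).mean())
        # each array shifts by (grand - N_a); these average to zero exactly
        assert np.mean(shifts) == pytest.approx(0.0, abs=1e-9)


class TestCollapseTriplicates:
    def _matrix(self, vals, flags):
        spots = pd.DataFrame(
            {
                "Name": ["p"] * 3,
                "Flags": flags,
                "normalized": vals,
            }
        )
        return collapse_triplicates({"a0": spots}, {"a0": 0.0})

    def test_plain_mean(self):
        m = self._matrix([4.0, 4.2, 4.4], [0, 0, 0])
        assert m.values.loc["p", "a0"] == pytest.approx(4.2)
        assert m.n_spots.loc["p", "a0"] == 3

    def test_flagged_spot_omitted(self):
        m = self._matrix([4.0, 4.2, 4.4], [0, 1, 0])
        assert m.values.loc["p", "a0"] == pytest.approx(4.2)
        assert m.n_spots.loc["p", "a0"] == 2

    def test_all_flagged_is_missing(self):
        m = self._matrix([4.0, 4.2, 4.4], [1, 1, 1])
        assert np.isnan(m.values.loc["p", "a0"])
        assert m.n_spots.loc["p", "a0"] == 0


class TestDetectionFilter:
    def _random_case(self, rng, n_probes=20, n_arrays=6):
        values = pd.DataFrame(
            rng.normal(5, 2, (n_probes, n_arrays)),
            index=[f"p{i}" for i in range(n_probes)],
            columns=[f"a{j}" for j in range(n_arrays)],
        )
        thresholds = {f"a{j}": float(rng.uniform(3, 7)) for j in range(n_arrays)}
        design = {f"a{j}": ("g1" if j < n_arrays // 2 else "g2") for j in range(n_arrays)}
        m = ProbeIntensityMatrix(values=values, n_spots=(values * 0 + 3).astype(int), thresholds=thresholds)
        return m, design

    def test_retained_iff_above_in_all_samples_of_some_group(self, rng):
        values = pd.DataFrame(
            [[5, 5, 5, 1, 1, 1], [5, 5, 1, 5, 5, 1]],
            index=["hit", "miss"],
            columns=[f"a{j}" for j in range(6)],
            dtype=float,
        )
        m = ProbeIntensityMatrix(values, (values * 0 + 3).astype(int), {f"a{j}": 3.0 for j in range(6)})
        design = {f"a{j}": ("g1" if j < 3 else "g2") for j in range(6)}
        assert detection_filter(m, design) == ["hit"]

    def test_matches_brute_force_rule(self, rng):
        for _ in range(25):
            m, design = self._random_case(rng)
            expected = []
            groups = {}
            for a, g in design.items():
                groups.setdefault(g, []).append(a)
            for p in m.values.index:
                ok = False
                for g, members in groups.items():
                    if all(m.values.loc[p, a] > m.thresholds[a] for a in members):
                        ok = True
                if ok:
                    expected.append(p)
            assert detection_filter(m, design) == expected

    def test_missing_counts_as_not_above(self, rng):
        values = pd.DataFrame([[5.0, np.nan]], index=["p"], columns=["a0", "a1"])
        m = ProbeIntensityMatrix(values, (values * 0).fillna(0).astype(int), {"a0": 1.0, "a1": 1.0})
        assert detection_filter(m, {"a0": "g", "a1": "g"}) == []

    def test_empty_design_is_configuration_error(self, rng):
        m, _ = self._random_case(rng)
        with pytest.raises(ValueError, match="empty"):
            detection_filter(m, {})

    def test_unknown_array_in_design_is_configuration_error(self, rng):
        m, design = self._random_case(rng)
        design["phantom_array"] = "g1"
        with pytest.raises(ValueError, match="phantom_array"):
            detection_filter(m, design)

    def test_output_monotone_non_increasing_in_threshold(self, rng):
        m, design = self._random_case(rng, n_probes=30)
        retained_prev = None
        for bump in (0.0, 0.5, 1.0, 2.0):
            m2 = ProbeIntensityMatrix(
                m.values, m.n_spots, {a: t + bump for a, t in m.thresholds.items()}
            )
            retained = set(detection_filter(m2, design))
            if retained_prev is not None:
                assert retained <= retained_prev
            retained_prev = retained


class TestEndToEnd:
    def test_planted_high_signal_kept_and_control_level_removed(self, small_arrays, small_spot_config):
        arrays, _ = small_arrays
        matrix, retained, qc = preprocess_mirna(arrays)
        # planted high-signal probe survives the detection filter
        assert "probe_00007" in retained
        # probes demoted to negative-control signal level are removed
        n_low = int(round(small_spot_config.frac_undetectable * small_spot_config.n_probes))
        low = {f"probe_{i:05d}" for i in range(n_low)}
        assert not (low & set(retained))
        assert set(qc.columns) == {"T_raw", "T_log2", "N", "n_detected"}
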
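"""Composite records and derived statistics."""

import numpy as np
import pandas as pd
import pytest

from nbox import (
    RecordScenario,
    SedimentRecord,
    bin_series,
    corg_accumulation,
    delta15N_gap,
    make_records,
    nstar,
    splice_records,
    windowed_correlation,
)
from nbox.records import record_statistics


def _record(site, env, ages, d15N, **cols):
    data = {"age": ages, "d15N": d15N}
    data.update(cols)
    return SedimentRecord(site=site, environment=env, data=pd.DataFrame(data))


class TestSplice:
    def test_single_record_is_identity(self):
        r = _record("A", "deep-margin", [1.0, 2.0, 3.0], [3.0, 3.5, 4.0])
        comp = splice_records([r])
        assert comp.diagnostics == []
        assert np.allclose(comp.data["value"], [3.0, 3.5, 4.0])
        assert list(comp.data["site"]) == ["A"] * 3

    def test_shared_curve_offset_below_noise(self):
        """Two sites drawn from one curve agree within 3 standard errors."""
        rng = np.random.default_rng(3)
        ages = np.linspace(10, 60, 80)
        curve = 3.0 + 0.02 * ages
        sd = 0.4
        a = _record("A", "distal", ages, curve + rng.normal(0, sd, ages.size))
        b = _record("B", "distal", ages + 0.01, curve + rng.normal(0, sd, ages.size))
        comp = splice_records([a, b], overlap_tol=0.5)
        (diag,) = comp.diagnostics
        se = sd * np.sqrt(2.0 / diag.n_pairs)
        assert abs(diag.mean_offset) < 3 * se

    def test_constant_offset_is_flagged(self):
        ages = np.linspace(0, 50, 40)
        a = _record("A", "deep-margin", ages, np.full(ages.size, 3.0))
        b = _record("B", "deep-margin", ages + 0.01, np.full(ages.size, 5.0))
        comp = splice_records([a, b], overlap_tol=0.5)
        (diag,) = comp.diagnostics
        assert diag.flagged
        assert diag.mean_offset == pytest.approx(-2.0, abs=1e-9)

    def test_mixed_environments_rejected(self):
        a = _record("A", "deep-margin", [1.0], [3.0])
        b = _record("B", "distal", [1.0], [7.0])
        with pytest.raises(ValueError, match="environment"):
            splice_records([a, b])

    def test_splice_then_split_reproduces_inputs(self, deep_records):
        comp = splice_records(deep_records)
        split = comp.split_by_site()
        for r in deep_records:
            got = split[r.site].sort_values("age")
            assert np.allclose(got["value"].to_numpy(), r.data["d15N"].to_numpy())
            assert np.allclose(got["age"].to_numpy(), r.data["age"].to_numpy())

    def test_nonmonotone_ages_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            _record("A", "deep-margin", [2.0, 1.0], [3.0, 3.0])


class TestCorgAccumulation:
    def test_unit_arithmetic(self):
        assert corg_accumulation(1.0, 1.0, 1.0) == pytest.approx(0.01)

    def test_zero_toc_gives_zero(self):
        assert corg_accumulation(0.0, 3.0, 1.2) == 0.0

    def test_margin_like_inputs_inside_reported_envelope(self):
        """Typical margin TOC/rates produce 0.003-0.20 g C/kyr/cm2."""
        rng = np.random.default_rng(8)
        toc = rng.uniform(0.5, 3.0, 200)  # wt%
        rate = rng.uniform(0.8, 5.0, 200)  # cm/kyr
        acc = corg_accumulation(toc, rate, 1.0)
        assert acc.min() >= 0.003 and acc.max() <= 0.20

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            corg_accumulation(-1.0, 1.0, 1.0)


class TestDelta15NGap:
    def test_self_difference_is_zero(self, deep_records):
        comp = splice_records(deep_records)
        grid = np.linspace(5, 100, 30)
        gap = delta15N_gap(comp, comp, grid)
        finite = gap["delta15N"].dropna()
        assert len(finite) > 0
        assert np.allclose(finite, 0.0, atol=1e-12)

    def test_constructed_gap_recovered(self):
        ages = np.linspace(0, 100, 400)
        g = 2.0 + 0.03 * ages  # the constructed gap g(age)
        deep = splice_records([_record("D", "deep-margin", ages, np.full(ages.size, 3.0))])
        distal = splice_records([_record("X", "distal", ages + 1e-4, 3.0 + g)])
        grid = np.linspace(1, 99, 50)
        gap = delta15N_gap(deep, distal, grid)
        expect = 2.0 + 0.03 * grid
        assert np.allclose(gap["delta15N"], expect, atol=0.01)

    def test_well_mixed_scenario_mean_near_zero(self):
        rng = np.random.default_rng(9)
        ages = np.linspace(0, 100, 300)
        base = 4.0 + np.sin(ages / 15.0)
        deep = splice_records([_record("D", "deep-margin", ages, base + rng.normal(0, 0.3, ages.size))])
        distal = splice_records([_record("X", "distal", ages + 1e-4, base + rng.normal(0, 0.3, ages.size))])
        gap = delta15N_gap(deep, distal, np.linspace(1, 99, 60))
        assert abs(np.nanmean(gap["delta15N"])) < 0.2

    def test_antisymmetric_under_swap(self, deep_records, distal_records):
        deep = splice_records(deep_records)
        distal = splice_records(distal_records)
        grid = np.linspace(2, 88, 40)
        ab = delta15N_gap(deep, distal, grid)["delta15N"].to_numpy()
        ba = delta15N_gap(distal, deep, grid)["delta15N"].to_numpy()
        assert np.allclose(ab, -ba, equal_nan=True)

    def test_points_outside_span_masked_and_empty_overlap_rejected(self):
        deep = splice_records([_record("D", "deep-margin", [10.0, 20.0], [3.0, 3.0])])
        distal = splice_records([_record("X", "distal", [15.0, 25.0], [7.0, 7.0])])
        gap = delta15N_gap(deep, distal, np.array([5.0, 17.0, 30.0]))
        assert np.isnan(gap["delta15N"][0]) and np.isnan(gap["delta15N"][2])
        assert np.isfinite(gap["delta15N"][1])
        with pytest.raises(ValueError, match="overlap"):
            delta15N_gap(deep, distal, np.array([50.0, 60.0]))


class TestNstar:
    @pytest.mark.parametrize(
        "no3, po4, expected",
        [(32.0, 2.0, 0.0), (12.0, 2.0, -20.0), (42.0, 2.0, 10.0)],
    )
    def test_redfield_deficit_scale(self, no3, po4, expected):
        assert nstar(no3, po4) == pytest.approx(expected)


class TestBinSeries:
    def test_constant_series(self):
        ages = np.arange(0.5, 20, 1.0)
        out = bin_series(ages, np.full(ages.size, 4.2), bin_width=5.0)
        assert np.allclose(out["mean"], 4.2)
        assert np.allclose(out["sd"].dropna(), 0.0)

    def test_counting_two_bins(self):
        out = bin_series(np.arange(10.0), np.arange(10.0), bin_width=5.0)
        assert list(out["n"]) == [5, 5]
        assert list(out["bin_centre"]) == [2.5, 7.5]

    def test_brute_force_oracle(self):
        """Explicit per-point assignment matches the implementation exactly."""
        rng = np.random.default_rng(10)
        ages = rng.uniform(0, 163, 300)
        vals = rng.normal(5, 2, 300)
        width = 5.0
        out = bin_series(ages, vals, bin_width=width)
        for _, row in out.iterrows():
            lo = row["bin_centre"] - width / 2
            sel = [v for a, v in zip(ages, vals) if lo <= a < lo + width]
            assert row["n"] == len(sel)
            if len(sel) >= 2:
                assert row["mean"] == pytest.approx(np.mean(sel))
                assert row["sd"] == pytest.approx(np.std(sel, ddof=1))
            elif len(sel) == 1:
                assert np.isnan(row["sd"])

    def test_empty_bins_emitted_and_sd_undefined_for_singletons(self):
        out = bin_series([1.0, 12.0], [3.0, 4.0], bin_width=5.0)
        assert list(out["n"]) == [1, 0, 1]
        assert out["sd"].isna().all()

    def test_mean_invariant_to_within_bin_permutation(self):
        rng = np.random.default_rng(11)
        ages = rng.uniform(0, 25, 60)
        vals = rng.normal(0, 1, 60)
        a = bin_series(ages, vals)
        order = rng.permutation(60)
        b = bin_series(ages[order], vals[order])
        pd.testing.assert_frame_equal(a, b)


class TestWindowedCorrelation:
    def _series(self, ages, values):
        return pd.DataFrame({"age": ages, "value": values})

    def test_perfect_anticorrelation(self):
        ages = np.linspace(0, 100, 50)
        x = self._series(ages, ages * 0.1)
        y = self._series(ages, -ages * 0.1)
        out = windowed_correlation(x, y, windows=((0, 50), (50, 100)))
        assert np.allclose(out["r"], -1.0)
        assert list(out["sign"]) == ["negative", "negative"]

    def test_constructed_sign_flip_at_28_Ma(self):
        """Negative coupling before 28 Ma, positive after, is recovered."""
        rng = np.random.default_rng(12)
        ages = np.sort(rng.uniform(0, 165, 240))
        x = rng.normal(5, 1.5, ages.size)
        y = np.where(ages > 28.0, -0.8 * x, 0.8 * x) + rng.normal(0, 0.3, ages.size)
        out = windowed_correlation(
            self._series(ages, x), self._series(ages, y),
            windows=((28.0, 165.0), (0.0, 28.0)),
        )
        old = out[out["age_min"] == 28.0].iloc[0]
        young = out[out["age_min"] == 0.0].iloc[0]
        assert old["sign"] == "negative" and old["r"] < -0.5
        assert young["r"] >= 0

    def test_independent_series_have_small_r(self):
        rng = np.random.default_rng(13)
        ages = np.sort(rng.uniform(0, 100, 200))
        x = self._series(ages, rng.normal(0, 1, 200))
        y = self._series(ages, rng.normal(0, 1, 200))
        out = windowed_correlation(x, y, windows=((0, 50), (50, 100)))
        assert (out["r"].abs() < 0.2).all()

    def test_insufficient_pairs_marked_not_raised(self):
        x = self._series([1.0, 2.0], [1.0, 2.0])
        y = self._series([90.0], [1.0])
        out = windowed_correlation(x, y, windows=((0, 10),))
        assert not out["sufficient"].iloc[0]
        assert np.isnan(out["r"].iloc[0])


class TestRecordStatistics:
    def test_statistics_on_constructed_composites(self):
        ages = np.linspace(0, 160, 400)
        deep = splice_records([_record("D", "deep-margin", ages, np.full(ages.size, 3.0))])
        distal = splice_records([_record("X", "distal", ages + 1e-4, np.full(ages.size, 7.0))])
        stats = record_statistics(deep, distal)
        assert stats["deep_mean"] == pytest.approx(3.0)
        assert stats["distal_mean"] == pytest.approx(7.0)
        assert stats["deep_median"] == pytest.approx(3.0)
        assert stats["deep_frac_outside"] == 0.0
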
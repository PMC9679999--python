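"""Spot averaging, Z-scoring, filters, Stouffer combination, binder calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import glymotif as gm
from glymotif.arrays import ProcessingConfig


class TestSpotAverage:
    def test_drops_one_min_one_max(self):
        assert gm.robust_spot_average([100, 200, 300, 400, 500, 600]) == 350

    def test_constant_invariance(self):
        assert gm.robust_spot_average([5] * 6) == 5

    def test_outlier_spike_removed(self):
        assert gm.robust_spot_average([0, 0, 0, 0, 0, 10000]) == 0

    def test_requires_four_spots(self):
        with pytest.raises(ValueError):
            gm.robust_spot_average([1.0, 2.0, 3.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e5), min_size=4, max_size=8))
    def test_bounded_by_trimmed_range(self, spots):
        avg = gm.robust_spot_average(spots)
        s = sorted(spots)
        assert s[1] - 1e-9 <= avg <= s[-2] + 1e-9


class TestZScore:
    def test_hand_computed_value(self):
        rfu = pd.Series([0, 0, 0, 0, 10], index=list("abcde"), dtype=float)
        z = gm.zscore_array(rfu)
        assert z["e"] == pytest.approx((10 - 2) / np.std([0, 0, 0, 0, 10], ddof=1))
        assert z["e"] == pytest.approx(1.7889, abs=1e-4)

    def test_mean_centering(self):
        rng = np.random.default_rng(0)
        z = gm.zscore_array(pd.Series(rng.gamma(2, 500, size=50)))
        assert z.sum() == pytest.approx(0, abs=1e-9)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError, match="zero spread"):
            gm.zscore_array(pd.Series([7.0, 7.0, 7.0]))


class TestExclusions:
    def _scans(self, peaks_by_conc):
        idx = [f"G{i}" for i in range(5)]
        out = {}
        for conc, peak in peaks_by_conc.items():
            vals = [10.0] * 4 + [peak]
            out[conc] = pd.Series(vals, index=idx)
        return out

    def test_lectin_below_4000_everywhere_excluded(self):
        qc = gm.QCLog()
        scans = {"L1": self._scans({1.0: 3999, 10.0: 3999})}
        kept = gm.exclude_low_signal(scans, qc=qc)
        assert kept == {}
        assert any(e["rule"] == "no_glycan_ge_4000_rfu" for e in qc.events)

    def test_array_below_1000_dropped_lectin_kept(self):
        scans = {"L1": self._scans({0.1: 999, 1.0: 5000, 10.0: 6000})}
        kept = gm.exclude_low_signal(scans)
        assert set(kept["L1"]) == {1.0, 10.0}

    def test_single_surviving_array_excludes_lectin(self):
        qc = gm.QCLog()
        scans = {"L1": self._scans({0.1: 900, 1.0: 5000})}
        assert gm.exclude_low_signal(scans, qc=qc) == {}
        assert any(e["rule"] == "single_surviving_array" for e in qc.events)


class TestStouffer:
    def test_single_array_identity(self):
        z = pd.Series([2.5, -1.0], index=["a", "b"])
        assert gm.stouffer_combine([z]).tolist() == [2.5, -1.0]

    def test_four_equal_arrays(self):
        z = pd.Series([3.0], index=["a"])
        assert gm.stouffer_combine([z] * 4)["a"] == pytest.approx(6.0)

    def test_antisymmetry(self):
        z = pd.Series([1.7], index=["a"])
        assert gm.stouffer_combine([z, -z])["a"] == pytest.approx(0.0)

    def test_mismatched_glycans_rejected(self):
        a = pd.Series([1.0], index=["g1"])
        b = pd.Series([1.0], index=["g2"])
        with pytest.raises(ValueError, match="mismatched"):
            gm.stouffer_combine([a, b])

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_conc = int(rng.integers(2, 7))
            n_gly = int(rng.integers(3, 30))
            mats = [pd.Series(rng.normal(size=n_gly)) for _ in range(n_conc)]
            zs = gm.stouffer_combine(mats)
            for g in range(n_gly):
                expect = sum(m.iloc[g] for m in mats) / np.sqrt(n_conc)
                assert abs(zs.iloc[g] - expect) < 1e-12


class TestNonVaryingFlags:
    def _tables(self, rfu_rows, z_rows, glycans):
        concs = [0.1, 1.0, 10.0, 100.0][: len(rfu_rows)]
        rfu = pd.DataFrame(rfu_rows, index=concs, columns=glycans, dtype=float)
        z = pd.DataFrame(z_rows, index=concs, columns=glycans, dtype=float)
        return z, rfu

    def test_constant_weak_signal_is_nonspecific(self):
        glycans = ["flat", "titrating"]
        z, rfu = self._tables(
            rfu_rows=[[500, 2800], [500, 15000], [500, 27000], [500, 29000]],
            z_rows=[[2.0, 2.0]] * 4, glycans=glycans)
        zs = pd.Series([4.0, 4.0], index=glycans)
        adjusted, flags = gm.flag_nonvarying(z, rfu, zs)
        assert flags["flat"] == "nonvarying+nonspecific"
        assert adjusted["flat"] == pytest.approx(2.0)  # plain average of Z
        assert flags["titrating"] == ""
        assert adjusted["titrating"] == 4.0

    def test_variance_boundary_strict(self):
        # variance exactly 10% of the max stays unflagged (strict <)
        glycans = ["a", "b"]
        base = np.array([0.0, 10.0, 0.0, 10.0])
        rfu = np.stack([base * np.sqrt(0.1) + 20000, base + 20000], axis=1)
        z, rfu_df = self._tables(rfu.tolist(), [[2.0, 2.0]] * 4, glycans)
        zs = pd.Series([4.0, 4.0], index=glycans)
        _, flags = gm.flag_nonvarying(z, rfu_df, zs)
        assert flags["a"] == "" and flags["b"] == ""

    def test_below_threshold_never_flagged(self):
        glycans = ["dim", "max"]
        z, rfu = self._tables(
            rfu_rows=[[100, 2800], [100, 15000], [100, 27000], [100, 29000]],
            z_rows=[[0.1, 2.0]] * 4, glycans=glycans)
        zs = pd.Series([0.2, 4.0], index=glycans)
        adjusted, flags = gm.flag_nonvarying(z, rfu, zs)
        assert flags["dim"] == "" and adjusted["dim"] == 0.2


class TestBackgroundAndCalls:
    def test_constant_row_zeroes(self):
        zs = pd.DataFrame({"L1": [3.0], "L2": [3.0], "L3": [3.0]})
        assert (gm.subtract_background(zs).iloc[0] == 0).all()

    def test_row_example(self):
        zs = pd.DataFrame([[4.0, 0.0, 0.0, 0.0]], columns=list("ABCD"))
        out = gm.subtract_background(zs)
        assert out.iloc[0].tolist() == [3.0, -1.0, -1.0, -1.0]

    def test_rows_sum_zero(self):
        rng = np.random.default_rng(1)
        zs = pd.DataFrame(rng.normal(size=(20, 5)))
        assert np.allclose(gm.subtract_background(zs).sum(axis=1), 0, atol=1e-9)

    def test_single_lectin_rejected(self):
        with pytest.raises(ValueError):
            gm.subtract_background(pd.DataFrame({"L1": [1.0, 2.0]}))

    def test_threshold_boundaries_inclusive(self):
        processed = pd.DataFrame({"L1": [1.645, 1.644, 3.0]},
                                 index=["at", "below", "flagged"])
        flags = pd.DataFrame({"L1": ["", "", "nonvarying+nonspecific"]},
                             index=processed.index)
        labels = gm.call_binders(processed, flags)
        assert labels.loc["at", "L1"] == 1
        assert labels.loc["below", "L1"] == 0
        assert labels.loc["flagged", "L1"] == 0  # nonspecific overrides score

    def test_drop_never_bound(self):
        labels = pd.DataFrame({"L1": [1, 0], "L2": [0, 0]}, index=["keep", "drop"])
        qc = gm.QCLog()
        kept = gm.drop_never_bound_glycans(labels, qc)
        assert list(kept) == ["keep"]
        assert labels.loc[kept].sum().tolist() == labels.sum().tolist()


class TestPipelineProperties:
    def test_glycan_row_order_invariance(self):
        panel = gm.example_lectins()[:3]
        cfg = gm.SimulationConfig(n_glycans=40, seed=5)
        scans, lib, _ = gm.simulate_dataset(panel, cfg)
        m1, _ = gm.process_arrays(scans)
        shuffled = scans.sample(frac=1.0, random_state=0).reset_index(drop=True)
        m2, _ = gm.process_arrays(shuffled)
        pd.testing.assert_frame_equal(m1.zs, m2.zs)
        pd.testing.assert_frame_equal(m1.labels, m2.labels)

    def test_inverse_normal_threshold(self):
        assert round(gm.binding_threshold(0.05), 3) == 1.645

    def test_metadata_exclusions_accounted(self):
        meta = gm.synthetic_metadata()
        qc = gm.QCLog()
        summary = gm.account_exclusions(meta, qc)
        assert summary["preparations"] == 116
        assert summary["duplicates"] == 42
        assert summary["excluded:low_binding_activity"] == 15
        assert summary["excluded:literature_incongruent"] == 2
        assert summary["unique_annotated_lectins"] == 57
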
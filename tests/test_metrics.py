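import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegident as ei
from eegident.evaluation import OpennessAccuracy


def loop_lrl(v):
    total = 0.0
    for j in range(1, len(v)):
        if v[j - 1] > v[j]:
            total += (v[j - 1] - v[j]) / v[j - 1]
    return 100.0 * total / (len(v) - 1)


def loop_grl(v):
    total = 0.0
    for j in range(1, len(v)):
        if v[0] > v[j]:
            total += (v[0] - v[j]) / v[0]
    return 100.0 * total / (len(v) - 1)


accuracy_vectors = st.lists(
    st.floats(0.01, 1.0, allow_nan=False), min_size=2, max_size=30
)


class TestLossMetrics:
    def test_lrl_hand_example(self):
        assert ei.lrl([1.0, 0.9, 0.9]) == pytest.approx(5.0)

    def test_grl_hand_examples(self):
        assert ei.grl([1.0, 0.9, 0.8]) == pytest.approx(15.0)
        assert ei.grl([0.5, 0.25]) == pytest.approx(50.0)

    @pytest.mark.parametrize("metric", [ei.lrl, ei.grl])
    def test_constant_and_increasing_trajectories_have_zero_loss(self, metric):
        assert metric([0.7, 0.7, 0.7]) == 0.0
        assert metric([0.5, 0.6, 0.9]) == 0.0

    @settings(max_examples=300, deadline=None)
    @given(accuracy_vectors)
    def test_matches_bruteforce_loop(self, v):
        assert ei.lrl(v) == pytest.approx(loop_lrl(v), abs=1e-10)
        assert ei.grl(v) == pytest.approx(loop_grl(v), abs=1e-10)

    @settings(max_examples=200, deadline=None)
    @given(accuracy_vectors, st.floats(0.05, 1.0))
    def test_scale_invariance(self, v, c):
        np.testing.assert_allclose(ei.lrl(v), ei.lrl([c * x for x in v]), atol=1e-8)
        np.testing.assert_allclose(ei.grl(v), ei.grl([c * x for x in v]), atol=1e-8)

    @settings(max_examples=300, deadline=None)
    @given(accuracy_vectors)
    def test_both_zero_iff_nondecreasing(self, v):
        nondecreasing = all(a <= b for a, b in zip(v, v[1:]))
        assert (ei.lrl(v) == 0.0 and ei.grl(v) == 0.0) == nondecreasing

    def test_degrading_only_mode_averages_fewer_terms(self):
        v = [1.0, 0.9, 0.9]
        assert ei.lrl(v, mode="degrading_only") == pytest.approx(10.0)
        assert ei.lrl(v, mode="clamped") == pytest.approx(5.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            ei.grl([0.0, 0.5])


class TestPowerAndDMM:
    def test_equal_values_give_unit_power(self):
        assert ei.power([2.5, 2.5, 2.5]) == 1.0

    def test_power_invariant_to_common_rescaling(self):
        values = [5.03, 3.19, 4.12, 3.65, 6.15]
        assert ei.power(values) == pytest.approx(ei.power([10 * v for v in values]))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            ei.power([1.0, 0.0])

    def test_dmm_examples(self):
        assert ei.dmm(0.9, 1.0) == pytest.approx(0.9)
        assert ei.dmm(0.8, 2.0) == pytest.approx(0.4)

    def test_dmm_undefined_without_degradation(self):
        with pytest.raises(ei.DegradationUndefined, match="no degradation"):
            ei.dmm(0.9, 0.0)


class TestGridReport:
    @staticmethod
    def report_for(oams, sweep):
        results = {
            cid: OpennessAccuracy(np.asarray([v]), np.asarray(v))
            for cid, v in oams.items()
        }
        return ei.grid_report(results, sweep)

    def test_structure_of_2x3_grid(self):
        sweep = ei.SweepSpec(orders=(1, 2), bands=((4, 8), (8, 13), (30, 50)))
        oams = {}
        rng = np.random.default_rng(0)
        for order in sweep.orders:
            for band in sweep.bands:
                v = np.sort(rng.uniform(0.5, 1.0, 4))[::-1]
                oams[ei.config_id(order, band)] = v
        report = self.report_for(oams, sweep)
        assert len(report.table) == 6
        assert len(report.order_marginals) == 2
        assert len(report.band_marginals) == 3
        assert report.order_power >= 1.0 and report.band_power >= 1.0

    def test_best_config_maximises_dmm(self):
        sweep = ei.SweepSpec(orders=(1,), bands=((4, 8), (30, 50)))
        oams = {
            ei.config_id(1, (4, 8)): [0.9, 0.5, 0.4],     # heavy degradation
            ei.config_id(1, (30, 50)): [0.95, 0.94, 0.93],  # stable
        }
        report = self.report_for(oams, sweep)
        assert report.best_band == (30.0, 50.0)
        assert report.best_order == 1

    def test_perfectly_stable_cell_outranks_degrading_cells(self):
        sweep = ei.SweepSpec(orders=(1,), bands=((4, 8), (30, 50)))
        oams = {
            ei.config_id(1, (4, 8)): [0.99, 0.98, 0.97],
            ei.config_id(1, (30, 50)): [0.9, 0.9, 0.9],  # GRL = 0
        }
        report = self.report_for(oams, sweep)
        assert report.best_band == (30.0, 50.0)
        assert np.isinf(
            report.table.set_index("config_id").loc[
                ei.config_id(1, (30, 50)), "dmm_last"
            ]
        )

    def test_single_cell_grid_has_undefined_power(self):
        sweep = ei.SweepSpec(orders=(1,), bands=((30, 50),))
        report = self.report_for({ei.config_id(1, (30, 50)): [0.9, 0.8]}, sweep)
        assert np.isnan(report.order_power) and np.isnan(report.band_power)

    def test_missing_cells_listed(self):
        sweep = ei.SweepSpec(orders=(1, 2), bands=((4, 8),))
        with pytest.raises(KeyError, match=ei.config_id(2, (4, 8))):
            self.report_for({ei.config_id(1, (4, 8)): [0.9, 0.8]}, sweep)

    def test_report_files_written(self, tmp_path):
        sweep = ei.SweepSpec(orders=(1,), bands=((4, 8), (30, 50)))
        report = self.report_for(
            {
                ei.config_id(1, (4, 8)): [0.9, 0.8],
                ei.config_id(1, (30, 50)): [0.95, 0.94],
            },
            sweep,
        )
        report.write(tmp_path)
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "grl_by_order.csv").exists()
        assert (tmp_path / "grl_by_band.csv").exists()
        assert (tmp_path / "summary.json").exists()
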
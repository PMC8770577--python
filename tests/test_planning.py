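"""Metrics, threshold sweeps, minimum yield, composite trigger, gating."""

import math

import numpy as np
import pytest

from sortcyte import (ConfusionMatrix, SortTriggerConfig, SyntheticConfig,
                      TimingGate, confusion, gated_fraction,
                      make_two_class_dataset, metrics, sorting_trigger, sweep,
                      yield_min)


class TestConfusion:
    def test_perfect_scores(self):
        y = [1, 1, 0, 0]
        s = [0.9, 0.8, 0.1, 0.2]
        cm = confusion(y, s, 0.5)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (2, 0, 2, 0)

    def test_zero_threshold_predicts_all_positive(self):
        cm = confusion([1, 0, 1], [0.2, 0.3, 0.9], 0.0)
        assert cm.fn == 0 and cm.tn == 0
        assert cm.tp == 2 and cm.fp == 1

    def test_matches_per_event_tally(self, rng):
        """Vectorised counts equal an explicit per-event loop."""
        for _ in range(10):
            y = rng.integers(0, 2, 50)
            s = rng.random(50)
            th = rng.random()
            cm = confusion(y, s, th)
            tp = fp = tn = fn = 0
            for yi, si in zip(y, s):
                if si >= th:
                    tp, fp = tp + (yi == 1), fp + (yi == 0)
                else:
                    tn, fn = tn + (yi == 0), fn + (yi == 1)
            assert (cm.tp, cm.fp, cm.tn, cm.fn) == (tp, fp, tn, fn)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion([1, 0], [0.5], 0.5)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            confusion([1], [1.5], 0.5)


class TestMetrics:
    def test_sensitivity_is_yield(self):
        m = metrics(ConfusionMatrix(tp=40, fp=0, tn=0, fn=60))
        assert m.sensitivity == pytest.approx(0.40)
        assert m.yield_ == m.sensitivity

    def test_perfect_accuracy(self):
        m = metrics(ConfusionMatrix(tp=50, fp=0, tn=50, fn=0))
        assert m.accuracy == 1.0

    def test_precision_is_concentration(self):
        m = metrics(ConfusionMatrix(tp=77, fp=23, tn=0, fn=0))
        assert m.precision == pytest.approx(0.77)
        assert m.concentration == m.precision

    def test_zero_denominators_flagged_not_zero(self):
        m = metrics(ConfusionMatrix(tp=0, fp=0, tn=10, fn=0))
        assert math.isnan(m.sensitivity) and math.isnan(m.precision)
        assert set(m.undefined) == {"sensitivity", "precision"}

    def test_complementary_identities(self, rng):
        """sensitivity + FNR = 1 and specificity + FPR = 1."""
        for _ in range(20):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 50, 4))
            m = metrics(ConfusionMatrix(tp, fp, tn, fn))
            assert m.sensitivity + fn / (tp + fn) == pytest.approx(1.0)
            assert m.specificity + fp / (tn + fp) == pytest.approx(1.0)


class TestSweep:
    def test_threshold_zero_full_yield_prevalence_concentration(self, rng):
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        sw = sweep(y, s, [0.0])
        assert sw.yields[0] == 1.0
        assert sw.concentration[0] == pytest.approx(y.mean())

    def test_threshold_above_max_score_zero_yield(self):
        sw = sweep([1, 0, 1], [0.4, 0.2, 0.6], [1.0])
        assert sw.yields[0] == 0.0

    def test_yield_monotone_non_increasing(self, rng):
        y = rng.integers(0, 2, 300)
        s = rng.random(300)
        sw = sweep(y, s)
        assert np.all(np.diff(sw.yields) <= 1e-12)

    def test_separated_scores_concentration_non_decreasing(self, rng):
        """Fully separated score supports make precision monotone by
        construction (it steps from prevalence to 1 and stays there)."""
        y = np.repeat([0, 1], 200)
        s = np.concatenate([rng.uniform(0.0, 0.45, 200),
                            rng.uniform(0.55, 1.0, 200)])
        sw = sweep(y, s, np.linspace(0, 0.95, 40))
        conc = sw.concentration[~np.isnan(sw.concentration)]
        assert np.all(np.diff(conc) >= -1e-9)

    def test_frame_export(self, rng):
        sw = sweep([0, 1], [0.2, 0.9], [0.0, 0.5, 1.0])
        df = sw.to_frame()
        assert list(df.columns) == ["threshold", "concentration", "yield"]
        assert len(df) == 3


class TestYieldMin:
    def test_transplantation_budget(self):
        """100,000 cells at 75 cells/s in one hour needs 37.0% yield."""
        assert 100 * yield_min(100_000, 75.0, 3600.0) == pytest.approx(37.0, abs=0.05)

    def test_zero_required_zero_yield(self):
        assert yield_min(0, 75.0, 3600.0) == 0.0

    def test_exact_capacity(self):
        assert yield_min(270_000, 75.0, 3600.0) == pytest.approx(1.0)

    def test_over_capacity_capped_with_warning(self):
        with pytest.warns(UserWarning, match="unreachable"):
            assert yield_min(500_000, 75.0, 3600.0) == 1.0

    def test_linearity(self):
        base = yield_min(10_000, 100.0, 1000.0)
        assert yield_min(20_000, 100.0, 1000.0) == pytest.approx(2 * base)
        assert yield_min(10_000, 200.0, 1000.0) == pytest.approx(base / 2)
        assert yield_min(10_000, 100.0, 2000.0) == pytest.approx(base / 2)


class TestSortingTrigger:
    CFG = SortTriggerConfig(p_threshold=0.5)

    def _fire(self, area=28.0, n_contours=1, t=1.0, score=0.9,
              gate=None):
        gate = gate or TimingGate()
        return sorting_trigger(area, n_contours, t, score, self.CFG, gate)

    def test_all_gates_pass(self):
        sort, _ = self._fire()
        assert sort

    @pytest.mark.parametrize("area", [40.0, 15.0])
    def test_size_band_rejects(self, area):
        sort, _ = self._fire(area=area)
        assert not sort

    def test_multiple_contours_reject(self):
        sort, _ = self._fire(n_contours=2)
        assert not sort

    def test_low_score_rejects_and_ties_sort(self):
        assert not self._fire(score=0.49)[0]
        assert self._fire(score=0.5)[0]  # score comparison is >= threshold

    def test_timing_gate_integrated(self):
        gate = TimingGate()
        _, gate = sorting_trigger(28.0, 1, 1.0, 0.9, self.CFG, gate)
        sort, _ = sorting_trigger(28.0, 1, 1.0 + 1 / 3000, 0.9, self.CFG, gate)
        assert not sort


class TestGatedFraction:
    def test_reference_fractions_from_counts(self, rng):
        """Known in-gate counts reproduce the printed percentages."""
        for n_in, n_total, expected in [(3957, 7428, 53.2), (1516, 2180, 69.5)]:
            fluor = np.concatenate([rng.uniform(1000, 5000, n_in),
                                    rng.uniform(0, 400, n_total - n_in)])
            area = np.full(n_total, 27.0)
            pct, num, den = gated_fraction(area, fluor, (20.0, 35.0),
                                           (500.0, 1e6))
            assert (num, den) == (n_in, n_total)
            assert pct == pytest.approx(100.0 * n_in / n_total, abs=1e-9)
            assert pct == pytest.approx(expected, abs=0.1)  # printed truncation

    def test_empty_gate_zero_percent(self):
        pct, num, den = gated_fraction([25.0, 30.0], [10.0, 20.0],
                                       (20.0, 35.0), (100.0, 200.0))
        assert pct == 0.0 and num == 0 and den == 2

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            gated_fraction([], [], (0, 1), (0, 1))


class TestEndToEndSort:
    def test_sorting_enriches_target_class(self, config):
        """Any scorer with AUC > 0.5 concentrates the target fraction."""
        rng = np.random.default_rng(17)
        data = make_two_class_dataset(config, 250, rng)
        # crude intensity scorer: normalised crop mean (imperfect, AUC > .5)
        raw = data.images.mean(axis=(1, 2))
        score = (raw - raw.min()) / (raw.max() - raw.min())
        if raw[data.labels == 1].mean() < raw[data.labels == 0].mean():
            score = 1.0 - score
        # verify AUC > 0.5 by rank statistic
        r = np.argsort(np.argsort(score))
        n1 = int(data.labels.sum())
        n0 = len(data.labels) - n1
        auc = (r[data.labels == 1].sum() - n1 * (n1 - 1) / 2) / (n0 * n1)
        assert auc > 0.55

        areas = rng.uniform(21.0, 34.0, len(data))  # all inside the size band
        times = 1.0 + 0.005 * np.arange(len(data))
        cfg = SortTriggerConfig(p_threshold=float(np.median(score)))
        gate = TimingGate()
        sorted_mask = np.zeros(len(data), bool)
        for i in range(len(data)):
            sorted_mask[i], gate = sorting_trigger(
                areas[i], 1, times[i], score[i], cfg, gate)
        assert sorted_mask.sum() > 30
        fluor_gate = (500.0, 1e7)
        init_pct, _, _ = gated_fraction(areas, data.fluorescence,
                                        (20, 35), fluor_gate)
        targ_pct, _, _ = gated_fraction(areas[sorted_mask],
                                        data.fluorescence[sorted_mask],
                                        (20, 35), fluor_gate)
        assert targ_pct > init_pct
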
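"""Lesion metrics: extents, rates, arrest and edge diagnostics."""

import numpy as np
import pandas as pd
import pytest

from dcisim import metrics
from dcisim.cells import (ACTIVE, CALCIFIED, DIFFERENTIATED, PROGENITOR,
                          QUIESCENT, STEM)


class TestAxialExtent:
    def test_summed_two_direction_measure(self):
        assert metrics.axial_extent(np.array([-30.0, 0.0, 50.0]), 0.0) == 80.0

    def test_all_at_initiation_site(self):
        assert metrics.axial_extent(np.zeros(5), 0.0) == 0.0

    def test_matches_brute_force_scan(self, rng):
        x = rng.normal(scale=40.0, size=300)
        assert metrics.axial_extent(x, 0.0) == pytest.approx(
            (x.max() - 0.0) + (0.0 - x.min()))

    def test_empty_population_raises(self):
        with pytest.raises(ValueError):
            metrics.axial_extent(np.array([]), 0.0)


class TestAdvanceRate:
    def test_flat_series_zero(self):
        t = np.linspace(0, 10, 50)
        assert metrics.advance_rate(t, np.full(50, 42.0)) == pytest.approx(0.0)

    def test_exact_line_recovered(self):
        t = np.linspace(0, 10, 50)
        assert metrics.advance_rate(t, 5.0 + 10.0 * t) == pytest.approx(10.0)

    def test_noisy_line_within_ci(self, rng):
        t = np.linspace(0, 20, 200)
        y = 3.0 * t + rng.normal(0, 2.0, 200)
        slope = metrics.advance_rate(t, y)
        # OLS slope SE = sigma / (sd(t) * sqrt(n))
        se = 2.0 / (t.std() * np.sqrt(200))
        assert abs(slope - 3.0) < 4 * se

    def test_window_restriction(self):
        t = np.linspace(0, 30, 100)
        y = np.where(t < 15, 0.0, (t - 15) * 2.0)
        assert metrics.advance_rate(t, y, t_min=15.0) == pytest.approx(2.0)

    def test_degenerate_window_raises(self):
        with pytest.raises(ValueError):
            metrics.advance_rate(np.array([1.0]), np.array([2.0]))


class TestStemFraction:
    def test_two_of_fifty(self):
        lineage = np.array([STEM] * 2 + [PROGENITOR] * 48)
        status = np.full(50, ACTIVE)
        assert metrics.stem_fraction(lineage, status) == pytest.approx(4.0)

    def test_all_stem(self):
        assert metrics.stem_fraction(np.full(7, STEM),
                                     np.full(7, ACTIVE)) == 100.0

    def test_dead_cells_excluded_from_denominator(self, rng):
        n = 200
        lineage = rng.integers(0, 3, n)
        status = rng.choice([ACTIVE, QUIESCENT, CALCIFIED], n)
        live = status != CALCIFIED
        want = 100.0 * ((lineage == STEM) & live).sum() / live.sum()
        assert metrics.stem_fraction(lineage, status) == pytest.approx(want)

    def test_empty_live_population_raises(self):
        with pytest.raises(ValueError):
            metrics.stem_fraction(np.array([STEM]), np.array([CALCIFIED]))


class TestCalcification:
    def test_none_calcified(self):
        ext, n = metrics.calcification_metrics(np.array([0.0, 5.0]),
                                               np.array([ACTIVE, ACTIVE]))
        assert (ext, n) == (0.0, 0)

    def test_two_calcified_span(self):
        x = np.array([-10.0, 40.0, 0.0])
        status = np.array([CALCIFIED, CALCIFIED, ACTIVE])
        assert metrics.calcification_metrics(x, status) == (50.0, 2)

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=100)
        status = rng.choice([ACTIVE, CALCIFIED], 100)
        ext, n = metrics.calcification_metrics(x, status)
        assert n == (status == CALCIFIED).sum()
        if n:
            assert ext == pytest.approx(np.ptp(x[status == CALCIFIED]))


class TestEdges:
    def _line(self, n=21, span=200.0):
        return np.linspace(-span / 2, span / 2, n)

    def test_differentiated_edges_are_incompetent(self):
        x = self._line()
        lineage = np.where(np.abs(x) > 60, DIFFERENTIATED, PROGENITOR)
        status = np.full_like(lineage, ACTIVE)
        div = np.zeros_like(lineage)
        assert not metrics.edges_competent(x, lineage, status, div, 18, 25.0)

    def test_stem_at_edge_is_competent(self):
        x = self._line()
        lineage = np.where(np.abs(x) > 60, DIFFERENTIATED, PROGENITOR)
        lineage[0] = lineage[-1] = STEM
        status = np.full_like(lineage, ACTIVE)
        div = np.zeros_like(lineage)
        assert metrics.edges_competent(x, lineage, status, div, 18, 25.0)

    def test_capped_progenitors_not_competent(self):
        x = self._line()
        lineage = np.full_like(x, PROGENITOR, dtype=int)
        status = np.full_like(lineage, ACTIVE)
        div = np.full_like(lineage, 18)
        assert not metrics.edges_competent(x, lineage, status, div, 18, 25.0)

    def test_edge_quiescence_flag(self):
        x = self._line()
        lineage = np.full_like(x, PROGENITOR, dtype=int)
        status = np.where(np.abs(x) > 60, QUIESCENT, ACTIVE)
        assert metrics.edges_all_quiescent(x, lineage, status, 25.0)
        status[0] = ACTIVE
        assert not metrics.edges_all_quiescent(x, lineage, status, 25.0)


class TestArrestDetection:
    def _record(self, t, extent, competent):
        return pd.DataFrame({"t_d": t, "extent_um": extent,
                             "edge_competent": competent})

    def test_sustained_incompetence_with_flat_extent_arrests(self):
        t = np.arange(0, 20, 0.5)
        rec = self._record(t, np.where(t < 10, 10 * t, 100.0), t < 10)
        at, crit = metrics.detect_arrest(rec, persistence_days=2.0)
        assert crit == "edge-incompetent"
        assert at == pytest.approx(10.0)

    def test_growing_lesion_not_arrested(self):
        t = np.arange(0, 20, 0.5)
        rec = self._record(t, 10 * t, np.zeros_like(t, dtype=bool))
        at, crit = metrics.detect_arrest(rec, persistence_days=2.0)
        assert at is None

    def test_advancing_competent_lesion_never_arrests(self):
        t = np.arange(0, 20, 0.5)
        rec = self._record(t, 10 * t, np.ones_like(t, dtype=bool))
        assert metrics.detect_arrest(rec)[0] is None

    def test_dormant_flat_lesion_is_arrested(self):
        # competent edges but permanently flat extent: progression stopped
        t = np.arange(0, 20, 0.5)
        rec = self._record(t, np.full_like(t, 50.0),
                           np.ones_like(t, dtype=bool))
        at, crit = metrics.detect_arrest(rec)
        assert crit == "flat-extent" and at == 0.0

    def test_transient_stall_with_recovery_not_arrested(self):
        t = np.arange(0, 30, 0.5)
        ext = np.where(t < 10, 8 * t,
                       np.where(t < 18, 80.0, 80.0 + 8 * (t - 18)))
        competent = (t < 10) | (t >= 18)
        rec = self._record(t, ext, competent)
        assert metrics.detect_arrest(rec, persistence_days=2.0)[0] is None

    def test_flat_extent_fallback_for_bare_series(self):
        t = np.arange(0, 20, 0.5)
        ext = np.where(t < 8, 10 * t, 80.0)
        rec = pd.DataFrame({"t_d": t, "extent_um": ext})
        at, crit = metrics.detect_arrest(rec, flat_eps_um=5.0)
        assert crit == "flat-extent"
        assert 7.0 <= at <= 8.5

    def test_fixture_arrested_duct_fires_immediately(self):
        from dcisim.io import make_fixture
        rec = make_fixture("arrested-duct")
        at, crit = metrics.detect_arrest(rec, persistence_days=2.0)
        assert at is not None and at <= 0.5


class TestQuiescenceTime:
    def test_first_flag_time_reported(self):
        rec = pd.DataFrame({"t_d": [0.0, 1.0, 2.0, 3.0],
                            "edge_quiescent": [False, False, True, True]})
        assert metrics.leading_edge_quiescence_time(rec) == 2.0

    def test_none_when_never_quiescent(self):
        rec = pd.DataFrame({"t_d": [0.0, 1.0],
                            "edge_quiescent": [False, False]})
        assert metrics.leading_edge_quiescence_time(rec) is None


class TestRunOutputs:
    def test_truncation_at_arrest(self):
        t = np.arange(0, 20.5, 0.5)
        rec = pd.DataFrame({
            "t_d": t, "extent_um": np.minimum(10 * t, 100.0),
            "edge_competent": t < 10, "edge_quiescent": False,
            "stem_pct": 1.0, "prolif_cum": (10 * t).astype(int),
            "n_calcified": 0, "calc_extent_um": 0.0,
            "n_live": 100, "n_er_pos": 60, "n_er_neg": 40,
        })
        out = metrics.run_outputs(rec, arrest_time_d=10.0)
        assert out["t_end_d"] == pytest.approx(10.0)
        assert out["advance_rate_um_d"] == pytest.approx(10.0, rel=0.05)

    def test_advance_uses_monotone_reach(self):
        t = np.arange(0, 10.5, 0.5)
        ext = np.where(t < 5, 20 * t, 100.0 - 10 * (t - 5))  # regressing mass
        rec = pd.DataFrame({
            "t_d": t, "extent_um": ext, "edge_competent": True,
            "edge_quiescent": False, "stem_pct": 1.0,
            "prolif_cum": 0, "n_calcified": 0, "calc_extent_um": 0.0,
            "n_live": 10, "n_er_pos": 5, "n_er_neg": 5,
        })
        out = metrics.run_outputs(rec, window_t_min=5.0)
        assert out["advance_rate_um_d"] == pytest.approx(0.0, abs=1e-9)
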
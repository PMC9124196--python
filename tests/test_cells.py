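"""Cell state machine: gates, daughter phenotypes, dedifferentiation, death."""

import numpy as np
import pytest

from dcisim import cells
from dcisim.cells import (ACTIVE, CALCIFIED, DIFFERENTIATED, ER_NA, ER_NEG,
                          ER_POS, HYPOXIC, NECROTIC, PROGENITOR, QUIESCENT,
                          STEM, CellAgent, Population, apoptosis_check,
                          assign_cycle_time, attempt_dedifferentiation,
                          choose_daughter_phenotypes, hypoxia_update,
                          proliferation_gate, quiescence_update)
from dcisim.params import ParameterSet, per_step_probability


def _cell(lineage=PROGENITOR, status=ACTIVE, er=ER_POS, divisions=0,
          cycle_time=20.0, cycle_clock=20.0):
    return CellAgent(id=0, pos=np.zeros(3), radius=5.0, lineage=lineage,
                     status=status, er=er, cycle_clock=cycle_clock,
                     cycle_time=cycle_time, divisions=divisions)


class TestCycleTime:
    def test_zero_spread_returns_mean(self, rng):
        p = ParameterSet(tau_sigma=0.0)
        assert assign_cycle_time(p, rng) == 20.0

    def test_floor_at_minimum(self, baseline, rng):
        p = baseline.replace(tau_sigma=8.0)
        draws = np.array([assign_cycle_time(p, rng) for _ in range(5000)])
        assert draws.min() >= p.tau_min

    def test_mean_matches_clipped_lognormal_oracle(self, baseline, rng):
        draws = assign_cycle_time(baseline, rng, size=10 ** 5)
        # oracle: clipped-mean of the same lognormal, brute-force Monte Carlo
        from dcisim.params import lognormal_underlying
        mu, sig = lognormal_underlying(baseline.tau_p, baseline.tau_sigma)
        ref = np.clip(np.random.default_rng(99).lognormal(mu, sig, 10 ** 6),
                      baseline.tau_min, None)
        assert draws.mean() == pytest.approx(ref.mean(), abs=3 * 2.0 / 300)


class TestProliferationGate:
    def test_baseline_er_pos_progenitor_passes(self, baseline):
        c = _cell(er=ER_POS, divisions=3)
        assert proliferation_gate(c, 0.90, 0.0, 0.5, baseline)

    def test_er_neg_below_fgf_threshold_fails(self, baseline):
        c = _cell(er=ER_NEG)
        assert not proliferation_gate(c, 1.0, 0.60, 0.5, baseline)

    def test_division_cap_blocks(self, baseline):
        c = _cell(divisions=baseline.p_max)
        assert not proliferation_gate(c, 1.0, 1.0, 0.0, baseline)

    def test_density_quiesces(self, baseline):
        c = _cell()
        assert not proliferation_gate(c, 1.0, 1.0, 0.75, baseline)

    def test_stem_follows_estrogen_gate(self, baseline):
        c = _cell(lineage=STEM, er=ER_NA)
        assert proliferation_gate(c, 0.9, 0.0, 0.0, baseline)
        assert not proliferation_gate(c, 0.5, 0.0, 0.0, baseline)
        ungated = baseline.replace(stem_er_gated=False)
        assert proliferation_gate(c, 0.5, 0.0, 0.0, ungated)

    def test_non_proliferative_phenotype_rejected(self, baseline):
        with pytest.raises(ValueError):
            proliferation_gate(_cell(lineage=DIFFERENTIATED), 1, 1, 0, baseline)


class TestDaughterPhenotypes:
    def test_certain_stem_daughter(self, rng):
        p = ParameterSet(omega_sc=1.0)
        lin, er = choose_daughter_phenotypes([STEM], [ER_NA], p, rng)
        assert lin[0] == STEM and er[0] == ER_NA

    def test_stem_daughter_fraction_matches_omega_sc(self, baseline, rng):
        n = 10 ** 5
        lin, er = choose_daughter_phenotypes(np.full(n, STEM),
                                             np.full(n, ER_NA), baseline, rng)
        frac = (lin == STEM).mean()
        sigma = np.sqrt(0.12 * 0.88 / n)
        assert abs(frac - 0.12) < 3 * sigma
        # ER split of non-stem daughters
        er_pos = (er[lin == PROGENITOR] == ER_POS).mean()
        assert abs(er_pos - 0.50) < 3 * np.sqrt(0.25 / (lin == PROGENITOR).sum())

    def test_progenitor_daughter_fraction_matches_omega_p(self, baseline, rng):
        n = 10 ** 5
        lin, er = choose_daughter_phenotypes(np.full(n, PROGENITOR),
                                             np.full(n, ER_NEG), baseline, rng)
        frac = (lin == PROGENITOR).mean()
        assert abs(frac - 0.75) < 3 * np.sqrt(0.75 * 0.25 / n)
        # progenitor daughters inherit the mother's receptor status
        assert (er == ER_NEG).all()


class TestDedifferentiation:
    def test_disabled_pathway_never_fires(self, rng):
        p = ParameterSet(omega_dd=0.0)
        c = _cell()
        assert not any(attempt_dedifferentiation(c, p, rng, False)
                       for _ in range(1000))

    @pytest.mark.parametrize("status,lineage", [
        (QUIESCENT, PROGENITOR),    # quiescent cells do not dedifferentiate
        (ACTIVE, STEM),             # stems cannot dedifferentiate
        (ACTIVE, DIFFERENTIATED),   # terminal cells do not revert
        (HYPOXIC, PROGENITOR),
    ])
    def test_ineligible_phenotypes(self, rng, status, lineage):
        p = ParameterSet(omega_dd=0.007)
        c = _cell(lineage=lineage, status=status)
        assert not any(attempt_dedifferentiation(c, p, rng, False)
                       for _ in range(2000))

    def test_dividing_cells_excluded(self, rng):
        p = ParameterSet(omega_dd=1.0)
        assert not attempt_dedifferentiation(_cell(), p, rng,
                                             dividing_this_step=True)

    def test_success_converts_to_stem(self, rng):
        p = ParameterSet(omega_dd=1.0)
        c = _cell(divisions=7)
        assert attempt_dedifferentiation(c, p, rng, False)
        assert c.lineage == STEM and c.er == ER_NA and c.divisions == 0

    def test_per_step_rate_matches_oracle(self, baseline):
        p_step = per_step_probability(0.004, 0.5, 20.0)
        rng = np.random.default_rng(5)
        n = 10 ** 6
        hits = (rng.random(n) < p_step).mean()
        sigma = np.sqrt(p_step * (1 - p_step) / n)
        assert abs(hits - 1.002e-4) < 3 * sigma + 1e-8


class TestApoptosis:
    def test_zero_probability_never_kills(self, rng):
        p = ParameterSet(omega_apop=0.0)
        assert not any(apoptosis_check(_cell(), p, rng) for _ in range(1000))

    def test_certain_probability_always_kills(self, rng):
        p = ParameterSet(omega_apop=1.0)
        assert apoptosis_check(_cell(), p, rng)

    def test_rate_matches_baseline(self, baseline):
        rng = np.random.default_rng(6)
        n = 10 ** 6
        hits = (rng.random(n) < baseline.omega_apop).mean()
        assert abs(hits - 0.00705) < 3 * np.sqrt(0.00705 * 0.993 / n)

    def test_dead_cells_rejected(self, baseline, rng):
        with pytest.raises(ValueError):
            apoptosis_check(_cell(status=NECROTIC), baseline, rng)

    def test_non_cycling_scope_spares_active_cells(self, rng):
        p = ParameterSet(omega_apop=1.0, apoptosis_scope="non_cycling")
        assert not apoptosis_check(_cell(status=ACTIVE), p, rng)
        assert apoptosis_check(_cell(status=QUIESCENT), p, rng)
        assert apoptosis_check(_cell(lineage=DIFFERENTIATED), p, rng)


class TestQuiescence:
    def test_threshold_crossing(self, baseline):
        c = _cell()
        assert quiescence_update(c, 0.71, baseline) == "quiescent"
        assert c.status == QUIESCENT

    def test_zero_occupancy_stays_active(self, baseline):
        c = _cell()
        assert quiescence_update(c, 0.0, baseline) == "progenitor"

    def test_oscillating_occupancy_toggles(self, baseline):
        c = _cell()
        trace = [quiescence_update(c, occ, baseline)
                 for occ in (0.75, 0.5, 0.9, 0.1)]
        assert trace == ["quiescent", "progenitor", "quiescent", "progenitor"]


class TestHypoxia:
    def test_normoxia_is_a_no_op(self, baseline):
        c = _cell()
        assert hypoxia_update(c, 1.0, baseline) == "progenitor"
        assert c.hypoxia_h == 0.0

    def test_sustained_hypoxia_calcifies(self, baseline):
        c = _cell()
        steps = int((baseline.t_necrosis + baseline.t_calcify) / baseline.dt) + 3
        for _ in range(steps):
            hypoxia_update(c, 0.05, baseline)
        assert c.status == CALCIFIED

    def test_recovery_resets_clock(self, baseline):
        c = _cell()
        for _ in range(4):
            hypoxia_update(c, 0.05, baseline)
        assert c.status == HYPOXIC
        hypoxia_update(c, 0.9, baseline)
        assert c.status == ACTIVE and c.hypoxia_h == 0.0

    def test_necrosis_is_irreversible(self, baseline):
        c = _cell(status=NECROTIC)
        hypoxia_update(c, 1.0, baseline)
        assert c.status in (NECROTIC, CALCIFIED)


class TestPopulation:
    def test_add_remove_compaction(self):
        pop = Population(capacity=2)
        ids = pop.add(np.zeros((5, 3)), 5.0, PROGENITOR, ER_POS, 20.0)
        assert pop.n == 5 and list(ids) == [0, 1, 2, 3, 4]
        keep = pop.remove(np.array([True, False, True, False, False]))
        assert pop.n == 3
        assert list(pop.col("ids")) == [1, 3, 4]
        assert keep.sum() == 3

    def test_dataframe_round_trip(self, rng):
        pop = Population()
        pop.add(rng.normal(size=(4, 3)), 5.0,
                np.array([STEM, PROGENITOR, DIFFERENTIATED, PROGENITOR]),
                np.array([ER_NA, ER_POS, ER_NEG, ER_NEG]),
                np.array([20.0, 18.0, 22.0, 16.0]))
        pop.status[1] = QUIESCENT
        df = pop.to_dataframe()
        back = Population.from_dataframe(df)
        np.testing.assert_array_equal(back.col("pos"), pop.col("pos"))
        np.testing.assert_array_equal(back.col("lineage"), pop.col("lineage"))
        np.testing.assert_array_equal(back.col("status"), pop.col("status"))
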
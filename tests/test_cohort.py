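"""Cohort engine: occupancy, mortality floor, discounting, accrual rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psmcea.cohort import (
    CycleSpec,
    DrugComponent,
    LifeTable,
    StrategyConfig,
    apply_mortality_floor,
    discount_factor,
    first_cycle_ae_burden,
    run_cohort,
    state_occupancy,
)
from psmcea.economics import EconParams
from psmcea.survival import survival_at

FAMILY_POOL = [
    ("exponential", (0.08,)),
    ("weibull", (1.4, 11.0)),
    ("log-logistic", (2.0, 9.0)),
    ("log-normal", (2.1, 0.8)),
    ("gompertz", (0.06, 0.04)),
    ("generalized-gamma", (2.0, 0.7, 0.8)),
]


def _econ(**kw):
    defaults = dict(
        u_pfs=0.84,
        u_pd=0.47,
        ae_costs={"neutropenia": 16619.16, "hypertension": 14.45},
        ae_disutilities={"neutropenia": 0.09, "hypertension": 0.04},
        followup_costs={"ct": 447.02, "cbc": 2.70},
        followup_frequency_cycles=3,
        bsc_cost_per_cycle=1543.46,
    )
    defaults.update(kw)
    return EconParams(**defaults)


def _strategy(**kw):
    defaults = dict(
        name="X",
        drug_components=(
            DrugComponent("chemo", 209.03, max_cycles=4),
            DrugComponent("targeted", 563.24, max_cycles=None),
        ),
        ae_probabilities={"neutropenia": 0.5, "hypertension": 0.1},
    )
    defaults.update(kw)
    return StrategyConfig(**defaults)


def brute_force_outcome(fits, strategy, econ, spec, life_table):
    """Independent per-cycle accumulation with plain Python loops."""
    dm = spec.cycle_length_days / 30.4375
    dy = spec.cycle_length_days / 365.25
    # survival at boundaries
    s_os, s_pfs = [], []
    for k in range(spec.n_cycles + 1):
        s_pfs.append(survival_at(fits["PFS"][0], fits["PFS"][1], k * dm))
        s_os.append(survival_at(fits["OS"][0], fits["OS"][1], k * dm))
    # mortality floor, hazard scale, cycle by cycle
    if life_table is not None and life_table.annual_rate > 0:
        adj = [s_os[0]]
        for k in range(spec.n_cycles):
            cond = 0.0 if s_os[k] <= 0 else min(s_os[k + 1] / s_os[k], 1.0)
            h = -math.log(cond) if cond > 0 else math.inf
            h = max(h, life_table.annual_rate * dy)
            adj.append(adj[-1] * (math.exp(-h) if math.isfinite(h) else 0.0))
        s_os = adj
    total_cost = 0.0
    total_qaly = 0.0
    total_ly = 0.0
    for k in range(spec.n_cycles):
        pfs = min(s_pfs[k], s_os[k])
        pd = max(0.0, s_os[k] - s_pfs[k])
        df = (1.0 + spec.annual_discount_rate) ** (-(k * dy))
        cost = 0.0
        for comp in strategy.drug_components:
            if comp.max_cycles is None or k < comp.max_cycles:
                cost += comp.cost_per_cycle * pfs
        if k % econ.followup_frequency_cycles == 0:
            cost += sum(econ.followup_costs.values()) * pfs
        cost += econ.bsc_cost_per_cycle * pd
        total_cost += cost * df
        total_qaly += (pfs * econ.u_pfs + pd * econ.u_pd) * dy * df
        total_ly += (pfs + pd) * dy
    for ae, p in strategy.ae_probabilities.items():
        total_cost += p * econ.ae_costs[ae]
        total_qaly -= p * econ.ae_disutilities[ae] * dy
    return total_cost, total_qaly, total_ly


class TestStateOccupancy:
    @pytest.mark.parametrize(
        "s_pfs,s_os,expected",
        [
            (0.5, 0.8, (0.5, 0.3, 0.2)),
            (0.9, 0.8, (0.8, 0.0, 0.2)),  # crossing curves clipped
            (1.0, 1.0, (1.0, 0.0, 0.0)),
        ],
    )
    def test_partition(self, s_pfs, s_os, expected):
        out = state_occupancy(s_pfs, s_os)
        assert out == pytest.approx(expected)
        assert sum(out) == pytest.approx(1.0)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=100, derandomize=True)
    def test_always_sums_to_one(self, s_pfs, s_os):
        assert sum(state_occupancy(s_pfs, s_os)) == pytest.approx(1.0)


class TestDiscounting:
    @pytest.mark.parametrize(
        "rate,t,expected",
        [(0.05, 0.0, 1.0), (0.0, 7.0, 1.0), (0.05, 1.0, 1 / 1.05)],
    )
    def test_known_values(self, rate, t, expected):
        assert discount_factor(rate, t) == pytest.approx(expected, abs=1e-5)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1.0)


class TestMortalityFloor:
    def setup_method(self):
        self.spec = CycleSpec()

    def test_zero_rate_identity(self):
        s = np.exp(-0.05 * self.spec.boundary_times_months())
        out = apply_mortality_floor(s, LifeTable(annual_rate=0.0), self.spec)
        np.testing.assert_array_equal(out, s)

    def test_floor_binds_on_flat_survival(self):
        # immortal model cohort + 1% annual background -> S(1y) = exp(-0.01)
        n_year = math.ceil(365.25 / 21)  # cycles covering one year
        s = np.ones(self.spec.n_cycles + 1)
        out = apply_mortality_floor(s, LifeTable(annual_rate=0.01), self.spec)
        t_years = n_year * self.spec.cycle_length_years
        assert out[n_year] == pytest.approx(math.exp(-0.01 * t_years), rel=1e-9)
        assert out[n_year] == pytest.approx(0.99, abs=5e-4)

    def test_adjusted_below_input_and_monotone(self):
        s = 1.0 / (1.0 + (self.spec.boundary_times_months() / 15.0) ** 2)
        out = apply_mortality_floor(s, LifeTable(annual_rate=0.2), self.spec)
        assert np.all(out <= s + 1e-12)
        assert np.all(np.diff(out) <= 1e-12)

    def test_extreme_rate_collapses_but_stays_monotone(self):
        s = np.ones(20)
        out = apply_mortality_floor(s, LifeTable(annual_rate=1 - 1e-9), self.spec)
        assert np.all(np.diff(out) <= 0)
        assert out[-1] < out[0]


class TestAEBurden:
    def test_single_ae(self):
        spec = CycleSpec()
        cost, dec = first_cycle_ae_burden(
            {"hypertension": 0.16}, {"hypertension": 14.45}, {"hypertension": 0.04}, spec
        )
        assert cost == pytest.approx(0.16 * 14.45)
        assert dec == pytest.approx(0.16 * 0.04 * spec.cycle_length_years)

    def test_empty_map(self):
        assert first_cycle_ae_burden({}, {}, {}, CycleSpec()) == (0.0, 0.0)

    def test_triple_arm_published_set(self):
        probs = {
            "neutropenia": 0.70,
            "leukopenia": 0.38,
            "thrombocytopenia": 0.50,
            "anemia": 0.24,
            "hypertension": 0.16,
        }
        costs = {
            "neutropenia": 16619.16,
            "leukopenia": 16619.16,
            "thrombocytopenia": 2674.01,
            "anemia": 510.35,
            "hypertension": 14.45,
        }
        dis = dict.fromkeys(probs, 0.1)
        cost, _ = first_cycle_ae_burden(probs, costs, dis, CycleSpec())
        assert cost == pytest.approx(19410.4938, abs=0.01)

    def test_missing_entry_names_the_ae(self):
        with pytest.raises(KeyError, match="anemia"):
            first_cycle_ae_burden({"anemia": 0.2}, {}, {"anemia": 0.07}, CycleSpec())


class TestRunCohort:
    def test_occupancy_conserved_and_monotone(self):
        fits = {"PFS": ("log-normal", (1.6, 0.8)), "OS": ("log-logistic", (2.0, 12.0))}
        trace, _ = run_cohort(fits, _strategy(), _econ(), CycleSpec(), LifeTable())
        np.testing.assert_allclose(trace.pfs + trace.pd + trace.dead, 1.0, atol=1e-12)
        assert np.all(np.diff(trace.dead) >= -1e-12)
        assert np.all(np.diff(trace.pfs) <= 1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            pfs_fam = FAMILY_POOL[rng.integers(len(FAMILY_POOL))]
            os_fam = FAMILY_POOL[rng.integers(len(FAMILY_POOL))]
            fits = {"PFS": pfs_fam, "OS": os_fam}
            n_cycles = int(rng.integers(5, 40))
            spec = CycleSpec(n_cycles=n_cycles, horizon_years=n_cycles * 21 / 365.25)
            lt = LifeTable(annual_rate=float(rng.uniform(0, 0.05)))
            strat = _strategy()
            econ = _econ()
            _, outcome = run_cohort(fits, strat, econ, spec, lt)
            cost, qaly, ly = brute_force_outcome(fits, strat, econ, spec, lt)
            assert outcome.total_cost == pytest.approx(cost, abs=1e-9)
            assert outcome.total_qaly == pytest.approx(qaly, abs=1e-9)
            assert outcome.total_ly == pytest.approx(ly, abs=1e-9)

    def test_qaly_conservation_at_full_survival(self):
        # no costs, utility ~1, no discount, immortal cohort -> QALY = horizon
        fits = {"PFS": ("exponential", (1e-12,)), "OS": ("exponential", (1e-12,))}
        strat = _strategy(drug_components=(), ae_probabilities={})
        econ = _econ(u_pfs=1.0, u_pd=0.5, followup_costs={}, bsc_cost_per_cycle=0.0)
        spec = CycleSpec(annual_discount_rate=0.0)
        _, out = run_cohort(fits, strat, econ, spec, None)
        assert out.total_cost == 0.0
        assert out.total_qaly == pytest.approx(5.0, abs=spec.cycle_length_years + 1e-6)

    def test_bsc_accrues_per_cycle_in_pd(self):
        # PFS collapses immediately: all alive time after cycle 0 is PD
        fits = {"PFS": ("weibull", (8.0, 1e-3)), "OS": ("exponential", (1e-12,))}
        strat = _strategy(drug_components=(), ae_probabilities={})
        econ = _econ(followup_costs={}, bsc_cost_per_cycle=1543.46)
        spec = CycleSpec(n_cycles=10, horizon_years=10 * 21 / 365.25, annual_discount_rate=0.0)
        trace, out = run_cohort(fits, strat, econ, spec, None)
        assert out.cost_breakdown["bsc"] == pytest.approx(1543.46 * trace.pd.sum())
        assert trace.pd.sum() == pytest.approx(9.0, abs=1e-6)  # cycle 0 starts in PFS
        # ten full PD cycles would charge exactly 10 x 1543.46 under this rule
        assert 1543.46 * 10 == pytest.approx(15434.60)

    def test_discounted_constant_cost_matches_geometric_sum(self):
        fits = {"PFS": ("exponential", (1e-12,)), "OS": ("exponential", (1e-12,))}
        strat = _strategy(
            drug_components=(DrugComponent("d", 100.0, None),), ae_probabilities={}
        )
        econ = _econ(followup_costs={}, bsc_cost_per_cycle=0.0)
        spec = CycleSpec(annual_discount_rate=0.05)
        _, out = run_cohort(fits, strat, econ, spec, None)
        expected = 100.0 * sum(
            1.05 ** (-(k * spec.cycle_length_years)) for k in range(spec.n_cycles)
        )
        # rate 1e-12 stands in for S==1; allow the matching slack
        assert out.total_cost == pytest.approx(expected, rel=1e-9)

    def test_chemo_cap_limits_accrual(self):
        fits = {"PFS": ("exponential", (1e-12,)), "OS": ("exponential", (1e-12,))}
        strat = _strategy(
            drug_components=(DrugComponent("chemo", 100.0, max_cycles=4),),
            ae_probabilities={},
        )
        econ = _econ(followup_costs={}, bsc_cost_per_cycle=0.0)
        spec = CycleSpec(annual_discount_rate=0.0)
        _, out = run_cohort(fits, strat, econ, spec, None)
        assert out.cost_breakdown["drug:chemo"] == pytest.approx(400.0)

    def test_cost_and_qaly_monotonicity(self):
        fits = {"PFS": ("log-normal", (1.8, 0.8)), "OS": ("log-logistic", (2.0, 13.0))}
        spec = CycleSpec()
        base_strat = _strategy()
        _, base = run_cohort(fits, base_strat, _econ(), spec, None)
        richer = _strategy(
            drug_components=(
                DrugComponent("chemo", 250.0, max_cycles=4),
                DrugComponent("targeted", 563.24, max_cycles=None),
            )
        )
        _, up = run_cohort(fits, richer, _econ(), spec, None)
        assert up.total_cost >= base.total_cost
        _, better = run_cohort(fits, base_strat, _econ(u_pfs=0.9), spec, None)
        assert better.total_qaly >= base.total_qaly

    def test_exponential_closed_form_life_years(self):
        # zero discount: QALY at u=1 equals the geometric sum of S_OS over cycles
        rate = 0.05
        fits = {"PFS": ("exponential", (rate,)), "OS": ("exponential", (rate,))}
        strat = _strategy(drug_components=(), ae_probabilities={})
        econ = _econ(u_pfs=1.0, u_pd=0.5, followup_costs={}, bsc_cost_per_cycle=0.0)
        spec = CycleSpec(annual_discount_rate=0.0)
        _, out = run_cohort(fits, strat, econ, spec, None)
        r = math.exp(-rate * spec.cycle_length_months)
        closed = spec.cycle_length_years * (1 - r**spec.n_cycles) / (1 - r)
        assert out.total_qaly == pytest.approx(closed, rel=1e-12)

    def test_missing_curve_is_configuration_error(self):
        with pytest.raises(KeyError):
            run_cohort(
                {"PFS": ("exponential", (0.1,))}, _strategy(), _econ(), CycleSpec(), None
            )

    def test_half_cycle_correction_flag(self):
        fits = {"PFS": ("log-normal", (1.8, 0.8)), "OS": ("log-logistic", (2.0, 13.0))}
        spec_hc = CycleSpec(half_cycle_correction=True)
        _, plain = run_cohort(fits, _strategy(), _econ(), CycleSpec(), None)
        _, hc = run_cohort(fits, _strategy(), _econ(), spec_hc, None)
        # averaging start/end occupancy lowers accruals for declining curves
        assert hc.total_qaly < plain.total_qaly


class TestCycleSpec:
    def test_default_cycle_count_covers_horizon(self):
        spec = CycleSpec()
        assert spec.n_cycles == math.ceil(5 * 365.25 / 21) == 87

    def test_insufficient_cycles_rejected(self):
        with pytest.raises(ValueError):
            CycleSpec(n_cycles=50)  # 50 x 21d < 5y

    def test_month_conversion(self):
        assert CycleSpec().cycle_length_months == pytest.approx(21 / 30.4375)
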
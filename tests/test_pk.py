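import numpy as np
import pytest

from vbesim import (
    CompoundParams,
    DosingRegimen,
    InhibitorSpec,
    WeibullParams,
    effective_clint,
    hepatic_clearance,
    simulate_subject,
    steady_state_auc_ratio,
    total_clearance,
)
from vbesim.errors import ConfigError, DataError
from vbesim.nca import compute_endpoints


class TestClearanceAlgebra:
    def test_no_inhibitor_leaves_clint(self, simple_compound):
        inh = InhibitorSpec(ki_cyp1a2=2.0, ki_cyp3a4=1.5, unbound_concentration=0.0)
        assert effective_clint(simple_compound, inh) == simple_compound.clint_total
        assert effective_clint(simple_compound, None) == simple_compound.clint_total

    def test_single_pathway_halved(self):
        comp = CompoundParams(volume_of_distribution=50, clint_total=10,
                              fm_cyp1a2=1.0)
        # Iu/(Ki*fu_inc) = 1 halves a fully CYP1A2-metabolized clearance
        inh = InhibitorSpec(ki_cyp1a2=2.0, ki_cyp3a4=1.5, fu_inc_cyp1a2=1.0,
                            unbound_concentration=2.0)
        assert effective_clint(comp, inh) == pytest.approx(5.0)

    def test_static_ddi_hand_case(self):
        """fm 0.5/0.4, both inhibition ratios 9 -> CLint scale 0.19."""
        comp = CompoundParams(volume_of_distribution=50, clint_total=10,
                              fm_cyp1a2=0.5, fm_cyp3a4=0.4)
        inh = InhibitorSpec(ki_cyp1a2=1.0, ki_cyp3a4=1.0, unbound_concentration=9.0)
        assert effective_clint(comp, inh) / comp.clint_total == pytest.approx(0.19)

    def test_well_stirred_limits(self):
        # fu*CLint << Q: CLh ~ fu*CLint
        low = CompoundParams(volume_of_distribution=50, clint_total=1.0,
                             fu_plasma=0.5, hepatic_blood_flow=90)
        assert hepatic_clearance(low) == pytest.approx(0.5, rel=0.01)
        # fu*CLint >> Q: CLh -> Q
        high = CompoundParams(volume_of_distribution=50, clint_total=1e5,
                              hepatic_blood_flow=90)
        assert hepatic_clearance(high) == pytest.approx(90.0, rel=0.01)

    def test_invariant_validation(self):
        with pytest.raises(DataError):
            CompoundParams(volume_of_distribution=50, clint_total=10,
                           fm_cyp1a2=0.7, fm_cyp3a4=0.5)
        with pytest.raises(DataError):
            InhibitorSpec(ki_cyp1a2=-1.0, ki_cyp3a4=1.0)


class TestDosingRegimen:
    def test_constructors(self):
        assert DosingRegimen.single(2.0).events == ((0.0, 2.0),)
        bid = DosingRegimen.bid(500.0, days=2)
        assert [t for t, _ in bid.events] == [0.0, 12.0, 24.0, 36.0]
        tid = DosingRegimen.tid(2.0, days=1)
        assert [t for t, _ in tid.events] == [0.0, 8.0, 16.0]

    def test_weekly_titration(self):
        reg = DosingRegimen.weekly_titration_tid()
        doses = sorted({d for _, d in reg.events})
        assert doses == [0.5, 1.0, 1.5, 2.0]
        assert len(reg.events) == 5 * 7 * 3  # 35 days TID, final week held at 2 mg
        assert reg.events[-1] == (34 * 24.0 + 16.0, 2.0)

    def test_validation(self):
        with pytest.raises(DataError):
            DosingRegimen(events=((-1.0, 2.0),))
        with pytest.raises(ConfigError):
            DosingRegimen.repeated(2.0, interval_h=0.0, n_doses=3)


class TestSimulateSubject:
    def test_zero_dose_gives_zero_profile(self, simple_compound, mr_release,
                                          dense_grid):
        prof = simulate_subject(simple_compound, mr_release,
                                DosingRegimen.single(0.0), grid=dense_grid)
        assert np.all(prof.concentrations == 0.0)

    def test_mass_conservation_without_clearance(self, mr_release):
        """With negligible clearance all released-and-absorbed drug
        accumulates: A_central(inf) = Fa * Fmax/100 * dose."""
        comp = CompoundParams(volume_of_distribution=50, clint_total=1e-9,
                              ka=2.0, fraction_absorbed=0.8, renal_cl=0.0)
        grid = np.linspace(0, 400, 1601)
        prof = simulate_subject(comp, mr_release, DosingRegimen.single(2.0),
                                grid=grid)
        a_central = prof.concentrations[-1] / 1000.0 * 50.0  # ng/mL -> mg
        expected = 0.8 * mr_release.fmax / 100.0 * 2.0
        assert a_central == pytest.approx(expected, rel=1e-4)

    def test_bateman_oracle(self, simple_compound, dense_grid):
        """Near-instantaneous release reduces to the oral Bateman equation."""
        release = WeibullParams(fmax=100, lag=0, alpha=1e-5, beta=1.0)
        prof = simulate_subject(simple_compound, release,
                                DosingRegimen.single(2.0), grid=dense_grid)
        ka = simple_compound.ka
        ke = total_clearance(simple_compound) / simple_compound.volume_of_distribution
        t = dense_grid
        bateman = (2.0 * ka / (simple_compound.volume_of_distribution * (ka - ke))
                   * (np.exp(-ke * t) - np.exp(-ka * t)) * 1000.0)
        err = np.max(np.abs(prof.concentrations - bateman)) / bateman.max()
        assert err < 1e-4

    def test_auc_inf_mass_balance(self, simple_compound, mr_release, single_dose,
                                  dense_grid):
        """AUC0-inf = Fa * (Fmax/100) * dose / CL_total within 0.5%."""
        prof = simulate_subject(simple_compound, mr_release, single_dose,
                                grid=dense_grid)
        ep = compute_endpoints(prof)
        expected = (mr_release.fmax / 100.0) * 2.0 / total_clearance(
            simple_compound) * 1000.0
        assert ep.auc_0_inf == pytest.approx(expected, rel=0.005)

    def test_dose_linearity(self, simple_compound, mr_release, dense_grid):
        one = simulate_subject(simple_compound, mr_release,
                               DosingRegimen.single(1.0), grid=dense_grid)
        two = simulate_subject(simple_compound, mr_release,
                               DosingRegimen.single(2.0), grid=dense_grid)
        # agreement to solver tolerance (atol ~ 2e-9 ng/mL from atol=1e-10 mg)
        np.testing.assert_allclose(two.concentrations, 2 * one.concentrations,
                                   rtol=1e-5, atol=1e-8)

    def test_superposition(self, simple_compound, mr_release):
        """A multi-dose profile equals the sum of shifted single-dose profiles."""
        grid = np.linspace(0, 96, 769)
        multi = simulate_subject(simple_compound, mr_release,
                                 DosingRegimen.repeated(2.0, 12.0, 3), grid=grid)
        total = np.zeros_like(grid)
        for shift in (0.0, 12.0, 24.0):
            single = simulate_subject(simple_compound, mr_release,
                                      DosingRegimen.single(2.0, time=shift),
                                      grid=grid)
            total += single.concentrations
        np.testing.assert_allclose(multi.concentrations, total,
                                   rtol=1e-5, atol=1e-6)

    def test_slower_release_lowers_cmax_not_auc(self, simple_compound,
                                                single_dose, dense_grid):
        slow = WeibullParams(fmax=92, lag=0.5, alpha=14, beta=1.15)
        fast = WeibullParams(fmax=92, lag=0.5, alpha=7, beta=1.15)
        eps = {}
        for name, rel in (("slow", slow), ("fast", fast)):
            prof = simulate_subject(simple_compound, rel, single_dose,
                                    grid=dense_grid)
            eps[name] = compute_endpoints(prof)
        assert eps["slow"].cmax < eps["fast"].cmax
        assert eps["slow"].auc_0_inf == pytest.approx(eps["fast"].auc_0_inf,
                                                      rel=0.005)

    def test_grid_must_cover_doses(self, simple_compound, mr_release):
        with pytest.raises(DataError):
            simulate_subject(simple_compound, mr_release,
                             DosingRegimen.single(2.0, time=50.0),
                             grid=np.linspace(0, 24, 97))


class TestSteadyStateAUCRatio:
    def test_no_inhibitor_ratio_is_one(self, simple_compound, mr_release):
        inh = InhibitorSpec(ki_cyp1a2=2.0, ki_cyp3a4=1.5, unbound_concentration=0.0)
        comp = CompoundParams(volume_of_distribution=50, clint_total=10,
                              fm_cyp1a2=0.6, fm_cyp3a4=0.3)
        ratio = steady_state_auc_ratio(comp, mr_release, inh,
                                       regimen=DosingRegimen.tid(2.0, 5))
        assert ratio == pytest.approx(1.0, abs=1e-12)

    def test_linear_limit_matches_static_equation(self, mr_release):
        """fu*CLint << Q: simulated SS AUC ratio = CLint / CLint_eff."""
        comp = CompoundParams(volume_of_distribution=50, clint_total=2.0,
                              fu_plasma=1.0, hepatic_blood_flow=90,
                              fm_cyp1a2=0.6, fm_cyp3a4=0.3, renal_cl=0.0)
        inh = InhibitorSpec(ki_cyp1a2=2.0, ki_cyp3a4=1.5,
                            fu_inc_cyp1a2=0.92, fu_inc_cyp3a4=1.0,
                            unbound_concentration=3.0)
        ratio = steady_state_auc_ratio(comp, mr_release, inh)
        static = comp.clint_total / effective_clint(comp, inh)
        assert ratio == pytest.approx(static, rel=0.02)

    def test_non_steady_regimen_warns(self, mr_release):
        comp = CompoundParams(volume_of_distribution=50, clint_total=2.0)
        inh = InhibitorSpec(ki_cyp1a2=2.0, ki_cyp3a4=1.5,
                            unbound_concentration=3.0)
        with pytest.warns(UserWarning, match="steady state"):
            steady_state_auc_ratio(comp, mr_release, inh,
                                   regimen=DosingRegimen.tid(2.0, 1))
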
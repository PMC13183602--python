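"""Steady-state solver correctness: convergence, conservation laws,
oracle agreement, and physiological response directions."""

import math

import numpy as np
import pytest

from episurf.cellmodel import (ConfigurationError, ConvergenceError,
                               apply_parameter_fractions, cold_start_state,
                               load_variant, relax_to_steady_state, residuals,
                               solve_steady_state, transcellular_fluxes)

VARIANTS = ("pct_male", "pct_female", "mtal_male", "mtal_female")


@pytest.fixture(scope="module")
def solved(variants):
    return {name: solve_steady_state(variants[name]) for name in VARIANTS}


@pytest.mark.parametrize("name", VARIANTS)
class TestBaselineSolutions:
    def test_cold_start_converges_below_tolerance(self, variants, solved, name):
        st = solved[name]
        assert st.converged
        assert st.residual_norm < 1e-10

    def test_plausibility_window(self, variants, solved, name):
        st = solved[name]
        assert 10.0 <= st.cytosol.concentrations["Na"] <= 25.0
        assert 100.0 <= st.cytosol.concentrations["K"] <= 145.0
        assert -90.0 <= st.Va <= -40.0

    def test_electroneutrality(self, variants, solved, name):
        v, st = variants[name], solved[name]
        charge = sum(s.z * st.cytosol.concentrations[s.name] for s in v.solutes)
        charge += v.geometry.impermeant_valence * v.geometry.impermeant_amount / st.volume
        assert abs(charge) < 1e-8

    def test_per_solute_mass_conservation(self, variants, solved, name):
        fx = transcellular_fluxes(solved[name])
        for sol in fx.apical:
            imbalance = fx.apical[sol] + fx.sources[sol] - fx.basolateral[sol]
            assert abs(imbalance) < 1e-10

    def test_open_circuit_current_balance(self, variants, solved, name):
        v, st = variants[name], solved[name]
        fx = st.fluxes
        zmap = {s.name: s.z for s in v.solutes}
        total = sum(zmap[sol] * (fx.basolateral[sol] + fx.paracellular[sol])
                    for sol in zmap)
        assert abs(total) < 1e-10

    def test_water_balance_for_water_permeable_variant(self, variants, solved, name):
        st = solved[name]
        if variants[name].water_permeable:
            assert abs(st.fluxes.Jv_apical - st.fluxes.Jv_basolateral) < 1e-12
        else:
            assert st.fluxes.Jv_apical == st.fluxes.Jv_basolateral == 0.0

    def test_sodium_reabsorbed_at_baseline(self, variants, solved, name):
        assert solved[name].fluxes.basolateral["Na"] > 0


class TestSolverBehavior:
    def test_warm_restart_is_a_fixed_point(self, variants):
        v = variants["pct_male"]
        st = solve_steady_state(v)
        st2 = solve_steady_state(v, initial_guess=st)
        assert st2.iterations <= 2
        for sol, c in st.cytosol.concentrations.items():
            assert st2.cytosol.concentrations[sol] == pytest.approx(c, rel=1e-9)

    def test_residuals_vanish_at_converged_state(self, variants):
        v = variants["mtal_male"]
        st = solve_steady_state(v)
        res = residuals(v, state=st)
        assert np.max(np.abs(res)) < 1e-10

    def test_sodium_perturbation_moves_mass_balance_monotonically(self, variants):
        from dataclasses import replace
        v = variants["pct_male"]
        st = solve_steady_state(v)
        vals = []
        for d in (0.0, 0.5, 1.0, 2.0):
            conc = dict(st.cytosol.concentrations)
            conc["Na"] += d
            cyt = replace(st.cytosol, concentrations=conc)
            res = residuals(v, state=replace(st, cytosol=cyt))
            vals.append(res[0])          # Na mass balance is the first entry
        diffs = np.diff(vals)
        assert np.all(diffs < 0) or np.all(diffs > 0)

    def test_pump_inhibition_raises_na_and_lowers_k(self, variants):
        # reduced basolateral Na+/K+-ATPase activity lets Na+ accumulate
        # and K+ leak away
        for name in ("pct_male", "mtal_female"):
            v = variants[name]
            base = solve_steady_state(v)
            act, mem = apply_parameter_fractions(v, {"NaKATPase": 0.75})
            low = solve_steady_state(v, act, mem, initial_guess=base)
            assert low.cytosol.concentrations["Na"] > base.cytosol.concentrations["Na"]
            assert low.cytosol.concentrations["K"] < base.cytosol.concentrations["K"]

    def test_unconverged_state_rejected_by_flux_accessor(self, variants):
        st = cold_start_state(variants["pct_male"])
        with pytest.raises(ValueError):
            transcellular_fluxes(st)

    def test_unknown_parameter_name_rejected(self, variants):
        with pytest.raises(ConfigurationError):
            apply_parameter_fractions(variants["pct_male"], {"AQP1": 0.5})

    def test_failure_carries_last_iterate(self, variants):
        v = variants["pct_male"]
        with pytest.raises(ConvergenceError) as exc:
            solve_steady_state(v, max_iter=1)
        assert exc.value.last_state is not None
        assert exc.value.residual_norm is not None


class TestRelaxationOracle:
    def _agree(self, v, st, rx, tol=1e-6):
        for s in v.solutes:
            a = st.cytosol.concentrations[s.name]
            b = rx.cytosol.concentrations[s.name]
            assert abs(a - b) / a < tol
        assert abs(st.V_cell - rx.V_cell) / abs(st.V_cell) < tol
        assert abs(st.volume - rx.volume) / st.volume < tol

    @pytest.mark.parametrize("name", ("pct_male", "mtal_female"))
    def test_baseline_agreement(self, variants, name):
        v = variants[name]
        self._agree(v, solve_steady_state(v), relax_to_steady_state(v))

    @pytest.mark.parametrize("name", ("pct_female", "mtal_male"))
    def test_random_parameter_agreement(self, variants, name):
        rng = np.random.default_rng(11)
        v = variants[name]
        for _ in range(2):
            fr = {p: float(np.exp(rng.uniform(math.log(0.5), math.log(2.0))))
                  for p in v.varied_parameters}
            act, mem = apply_parameter_fractions(v, fr)
            self._agree(v, solve_steady_state(v, act, mem),
                        relax_to_steady_state(v, act, mem))

    def test_result_independent_of_initial_step_size(self, variants):
        v = variants["mtal_male"]
        a = relax_to_steady_state(v, dt=1.0)
        b = relax_to_steady_state(v, dt=0.5)
        for s in v.solutes:
            assert (a.cytosol.concentrations[s.name]
                    == pytest.approx(b.cytosol.concentrations[s.name], rel=1e-8))

    def test_no_driving_forces_equilibrates_toward_boundary(self, variants):
        # zero transporter activities and equal boundary compositions: the
        # cytosol relaxes toward a passive (Donnan-limited) equilibrium much
        # closer to the boundary composition than the cold start
        from dataclasses import replace
        v = variants["mtal_male"]
        act = replace(v.baseline_activities, x_NKCC2=0.0, pump_Jmax=1e-30)
        rx = relax_to_steady_state(v, act)
        start = cold_start_state(v)
        # the charged intracellular impermeant shifts the passive endpoint
        # away from the exact boundary values (Donnan), so require a clear
        # move toward the boundary rather than coincidence with it
        for sol in ("Na", "K"):
            target = v.interstitium.concentrations[sol]
            d_end = abs(rx.cytosol.concentrations[sol] - target)
            d_start = abs(start.cytosol.concentrations[sol] - target)
            assert d_end < 0.6 * d_start

    def test_rejects_nonpositive_step(self, variants):
        from episurf.cellmodel import DomainError
        with pytest.raises(DomainError):
            relax_to_steady_state(variants["mtal_male"], dt=0.0)
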
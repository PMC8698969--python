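import numpy as np
import pytest

from gdeastem import (
    GDEAConfig,
    MOLPProblem,
    PayoffTable,
    PreferenceDirective,
    PreferenceScriptError,
    Relaxation,
    ScriptedOracle,
    STEMState,
    StemInfeasibleError,
    load_preference_script,
    payoff_table,
    run_stem,
    stem_step,
    stem_weights,
    to_molp,
)


def toy_molp(obj_rows, input_bound=0.0, n=None):
    obj_rows = np.asarray(obj_rows, dtype=float)
    n = n or obj_rows.shape[1]
    return MOLPProblem(
        focal=0,
        labels=tuple(str(i + 1) for i in range(n)),
        obj_rows=obj_rows,
        in_rows=np.zeros((1, n)),
        const_out=np.zeros(obj_rows.shape[0]),
        const_in=np.zeros(1),
        alpha=1.0,
        input_bound=input_bound,
    )


@pytest.fixture(scope="module")
def unit1_molp(norm_hospitals, raw_hospitals):
    cfg = GDEAConfig.fdh(dtilde_convention="zero")
    return to_molp(norm_hospitals, 0, cfg, raw_panel=raw_hospitals)


class TestPayoffTable:
    def test_single_objective(self):
        molp = toy_molp([[1.0, -1.0, 0.5]])
        pay = payoff_table(molp)
        assert pay.ideal.shape == (1,) and pay.payoff.shape == (1, 1)
        assert pay.ideal[0] == pytest.approx(-1.0)

    def test_two_objective_vertices(self):
        # objectives over a 3-vertex simplex: minima read off the vertices
        molp = toy_molp([[1.0, 0.0, 2.0], [0.0, 1.0, 2.0]])
        pay = payoff_table(molp)
        np.testing.assert_allclose(pay.ideal, [0.0, 0.0], atol=1e-9)
        np.testing.assert_allclose(sorted(pay.payoff.ravel()), [0, 0, 1, 1])

    def test_ideal_bounds_every_payoff_entry(self, unit1_molp):
        pay = payoff_table(unit1_molp)
        assert (pay.ideal[None, :] <= pay.payoff + 1e-9).all()

    def test_unreachable_input_bound_raises(self, norm_hospitals):
        molp = to_molp(norm_hospitals, 0, GDEAConfig.fdh(), input_bound=-10.0)
        with pytest.raises(StemInfeasibleError):
            payoff_table(molp)


class TestStemWeights:
    def test_symmetric_objectives_get_uniform_weights(self):
        pay = PayoffTable(
            ideal=np.array([1.0, 1.0]),
            payoff=np.array([[1.0, 3.0], [3.0, 1.0]]),
            argmins=np.zeros((2, 2)),
        )
        np.testing.assert_allclose(stem_weights(pay), [0.5, 0.5])

    def test_zero_range_objective_gets_zero_weight(self):
        pay = PayoffTable(
            ideal=np.array([2.0, 1.0]),
            payoff=np.array([[2.0, 3.0], [2.0, 1.0]]),
            argmins=np.zeros((2, 2)),
        )
        np.testing.assert_allclose(stem_weights(pay), [0.0, 1.0])

    def test_stated_formula(self):
        # ranges (2, 1), |nadir| (4, 4) -> weights (2/3, 1/3)
        pay = PayoffTable(
            ideal=np.array([2.0, 3.0]),
            payoff=np.array([[2.0, 4.0], [4.0, 3.0]]),
            argmins=np.zeros((2, 2)),
        )
        np.testing.assert_allclose(stem_weights(pay), [2 / 3, 1 / 3])

    def test_all_zero_ranges_fall_back_to_uniform(self):
        pay = PayoffTable(
            ideal=np.zeros(3), payoff=np.zeros((3, 3)), argmins=np.zeros((3, 3))
        )
        np.testing.assert_allclose(stem_weights(pay), 1 / 3)


class TestStemStep:
    def test_first_iterate_matches_grid_search(self):
        """Tchebychev minimiser agrees with a fine simplex grid scan."""
        molp = toy_molp([[1.0, 0.0, 2.0], [0.0, 1.5, 2.0]])
        pay = payoff_table(molp)
        w = stem_weights(pay)
        st = stem_step(molp, pay)
        best = np.inf
        for a in np.linspace(0, 1, 101):
            for b in np.linspace(0, 1 - a, int(101 * (1 - a)) + 1):
                lam = np.array([a, b, 1 - a - b])
                f = molp.obj_rows @ lam
                best = min(best, max(w * (f - pay.ideal)))
        assert st.tcheb == pytest.approx(best, abs=1e-2)
        assert st.tcheb == pytest.approx(max(w * (st.f - pay.ideal)), abs=1e-9)

    def test_directive_required_after_first_step(self, unit1_molp):
        pay = payoff_table(unit1_molp)
        st = stem_step(unit1_molp, pay)
        with pytest.raises(ValueError, match="adjust"):
            stem_step(unit1_molp, pay, st, None)

    def test_relaxed_bound_and_maintenance(self, unit1_molp):
        pay = payoff_table(unit1_molp)
        st1 = stem_step(unit1_molp, pay)
        directive = PreferenceDirective(
            "adjust",
            relax=(Relaxation(0, 10.0, "raw_output"), Relaxation(2, 40.0, "raw_output")),
            improve=(1,),
        )
        st2 = stem_step(unit1_molp, pay, st1, directive)
        d0 = 10.0 * unit1_molp.alpha / unit1_molp.out_divisors[0]
        d2 = 40.0 * unit1_molp.alpha / unit1_molp.out_divisors[2]
        assert st2.f[0] <= st1.f[0] + d0 + 1e-8
        assert st2.f[2] <= st1.f[2] + d2 + 1e-8
        assert st2.f[1] <= st1.f[1] + 1e-8  # maintained objective cannot worsen
        assert st2.weights[0] == 0.0 and st2.weights[2] == 0.0
        assert st2.iteration == 2 and st2.ever_relaxed == {0, 2}

    def test_empty_relaxation_cannot_worsen_anything(self, unit1_molp):
        pay = payoff_table(unit1_molp)
        st1 = stem_step(unit1_molp, pay)
        st2 = stem_step(unit1_molp, pay, st1, PreferenceDirective("adjust"))
        assert (st2.f <= st1.f + 1e-8).all()

    def test_raw_scale_needs_divisors(self, norm_hospitals):
        molp = to_molp(norm_hospitals, 0, GDEAConfig.fdh(dtilde_convention="zero"))
        pay = payoff_table(molp)
        st1 = stem_step(molp, pay)
        with pytest.raises(ValueError, match="raw panel"):
            stem_step(
                molp, pay, st1,
                PreferenceDirective("adjust", relax=(Relaxation(0, 1.0, "raw_output"),)),
            )


class TestRunStem:
    def test_immediate_accept_returns_first_iterate(self, unit1_molp):
        lam, history = run_stem(unit1_molp, ScriptedOracle([]))
        assert len(history) == 1
        assert history[0].accepted and history[0].iteration == 1
        np.testing.assert_allclose(lam, history[0].lam)

    def test_scripted_three_iteration_walk(self, unit1_molp, raw_hospitals):
        directives = [
            PreferenceDirective(
                "adjust",
                relax=(Relaxation(0, 10.0, "raw_output"), Relaxation(2, 40.0, "raw_output")),
                improve=(1,),
            ),
            PreferenceDirective("adjust", relax=(Relaxation(1, 20.0, "raw_output"),)),
        ]
        lam, history = run_stem(
            unit1_molp, ScriptedOracle(directives), raw_panel=raw_hospitals
        )
        assert history[-1].accepted
        assert history[-1].iteration == 3
        induced = [abs(st.induced) for st in history]
        assert all(b <= a + 1e-9 for a, b in zip(induced, induced[1:]))

    def test_deterministic_replay(self, unit1_molp):
        d = [PreferenceDirective("adjust", relax=(Relaxation(0, 0.01),))]
        lam1, h1 = run_stem(unit1_molp, ScriptedOracle(list(d)))
        lam2, h2 = run_stem(unit1_molp, ScriptedOracle(list(d)))
        np.testing.assert_array_equal(lam1, lam2)
        assert [st.tcheb for st in h1] == [st.tcheb for st in h2]

    def test_persistent_relaxation_keeps_other_objective_monotone(self):
        molp = toy_molp([[1.0, 0.0, 2.0], [0.0, 1.5, 2.0]])
        oracle = ScriptedOracle(
            [PreferenceDirective("adjust", relax=(Relaxation(0, 0.05),))] * 3
        )
        _, history = run_stem(molp, oracle)
        f2 = [st.f[1] for st in history]
        assert all(b <= a + 1e-8 for a, b in zip(f2, f2[1:]))

    def test_max_iter_exhaustion_flags_unaccepted(self, unit1_molp):
        class NeverAccept:
            def __call__(self, state, projection):
                return PreferenceDirective("adjust")

        _, history = run_stem(unit1_molp, NeverAccept(), max_iter=2)
        assert not history[-1].accepted


class TestDirectivesAndScripts:
    def test_accept_carries_no_lists(self):
        with pytest.raises(ValueError, match="accept"):
            PreferenceDirective("accept", relax=(Relaxation(0, 1.0),))

    def test_relax_improve_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            PreferenceDirective("adjust", relax=(Relaxation(0, 1.0),), improve=(0,))

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            Relaxation(0, -1.0)

    def test_yaml_script_round_trip(self, tmp_path):
        path = tmp_path / "prefs.yaml"
        path.write_text(
            "- relax:\n"
            "    - {objective: 1, delta: 10, scale: raw_output}\n"
            "    - {objective: 3, delta: 40, scale: raw_output}\n"
            "  improve: [2]\n"
            "- accept\n"
        )
        directives = load_preference_script(path)
        assert len(directives) == 2
        assert directives[0].relax[0] == Relaxation(0, 10.0, "raw_output")
        assert directives[0].improve == (1,)
        assert directives[1].action == "accept"

    def test_malformed_script_reports_position(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("- relax:\n    - {delta: 1}\n")
        with pytest.raises(PreferenceScriptError, match="directive 1"):
            load_preference_script(path)
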
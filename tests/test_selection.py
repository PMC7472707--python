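"""WAIC and the model-comparison machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spatlogit as sl
from spatlogit.selection import compute_waic


def waic_loop_oracle(pointwise):
    """Literal two-loop WAIC: lppd and the variance penalty, observation by
    observation, draw by draw."""
    S, n = pointwise.shape
    lppd = 0.0
    p_d = 0.0
    for i in range(n):
        col = [pointwise[s, i] for s in range(S)]
        lppd += np.log(np.mean([np.exp(v) for v in col]))
        mean = sum(col) / S
        p_d += sum((v - mean) ** 2 for v in col) / (S - 1)
    return lppd, p_d, -2.0 * (lppd - p_d)


class TestComputeWAIC:
    def test_constant_half_model_closed_form(self):
        """Ten Bernoulli observations under a fixed p = 0.5 draw: lppd is
        10 log 0.5, no effective parameters, WAIC = -20 log 0.5."""
        pointwise = np.full((4, 10), np.log(0.5))
        w = compute_waic(pointwise)
        assert np.isclose(w.lppd, 10 * np.log(0.5))
        assert np.isclose(w.p_d, 0.0)
        assert np.isclose(w.waic, -20 * np.log(0.5))
        assert np.isclose(w.waic, 13.8629, atol=1e-4)

    def test_duplicating_observations_doubles_everything(self):
        rng = np.random.default_rng(0)
        pw = -rng.exponential(1.0, size=(8, 6))
        doubled = np.concatenate([pw, pw], axis=1)
        w1, w2 = compute_waic(pw), compute_waic(doubled)
        assert np.isclose(w2.lppd, 2 * w1.lppd)
        assert np.isclose(w2.p_d, 2 * w1.p_d)
        assert np.isclose(w2.waic, 2 * w1.waic)

    def test_matches_loop_oracle_small(self):
        rng = np.random.default_rng(3)
        pw = -rng.exponential(1.0, size=(4, 5))
        w = compute_waic(pw)
        lppd, p_d, waic = waic_loop_oracle(pw)
        assert abs(w.lppd - lppd) < 1e-10
        assert abs(w.p_d - p_d) < 1e-10
        assert abs(w.waic - waic) < 1e-10

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 12), st.integers(1, 9))
    def test_matches_loop_oracle_property(self, seed, S, n):
        rng = np.random.default_rng(seed)
        pw = rng.normal(-1.0, 1.0, size=(S, n))
        w = compute_waic(pw)
        lppd, p_d, waic = waic_loop_oracle(pw)
        assert abs(w.lppd - lppd) < 1e-10
        assert abs(w.p_d - p_d) < 1e-10
        assert abs(w.waic - waic) < 1e-10

    def test_nonfinite_rejected(self):
        pw = np.zeros((3, 2))
        pw[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            compute_waic(pw)

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError):
            compute_waic(np.zeros((1, 5)))


@pytest.fixture(scope="module")
def tiny_survey():
    truth = sl.TrueParameters(
        intercept=-1.0,
        beta={"residence": {"urban": 0.6}},
        smooth_age_survey=lambda t: 0.0 * np.asarray(t),
        smooth_age_cohab=lambda t: 0.0 * np.asarray(t),
        sigma_b=0.5, sigma_h=0.0,
    )
    return sl.simulate_survey(
        graph=sl.generate_lattice_graph(3, 3), truth=truth, n_per_district=80,
        covariate_mix={"residence": {"rural": 0.5, "urban": 0.5}}, seed=17,
    )


TINY_SAMPLER = {"draws": 120, "warmup": 80, "chains": 1}


@pytest.fixture(scope="module")
def tiny_spec():
    return sl.ModelSpec(
        fixed_effects=[sl.FixedEffect("residence", "rural")],
        smooth_terms=[], random_structure="CAR",
    )


class TestStructureLadder:
    def test_all_four_structures_reported_and_deterministic(self, tiny_survey, tiny_spec):
        r1 = sl.structure_ladder(tiny_survey.data, tiny_survey.graph, tiny_spec,
                                 sampler=TINY_SAMPLER, seed=5)
        r2 = sl.structure_ladder(tiny_survey.data, tiny_survey.graph, tiny_spec,
                                 sampler=TINY_SAMPLER, seed=5)
        df1, df2 = r1.to_dataframe(), r2.to_dataframe()
        assert list(df1.index) == ["NO", "IID", "CAR", "CAR_IID"]
        pd.testing.assert_frame_equal(df1, df2)
        assert r1.best == r2.best
        assert r1.best in df1.index
        assert df1.loc[r1.best, "delta_waic"] == 0.0

    def test_trace_carries_two_unit_rule(self, tiny_survey, tiny_spec):
        r = sl.structure_ladder(tiny_survey.data, tiny_survey.graph, tiny_spec,
                                sampler=TINY_SAMPLER, seed=5)
        ok = [t for t in r.decision_trace if t["status"] == "ok"]
        assert all("within_2_of_best" in t for t in ok)

    def test_column_order_invariance(self, tiny_survey, tiny_spec):
        shuffled = tiny_survey.data[list(tiny_survey.data.columns)[::-1]]
        r1 = sl.structure_ladder(tiny_survey.data, tiny_survey.graph, tiny_spec,
                                 sampler=TINY_SAMPLER, seed=5)
        r2 = sl.structure_ladder(shuffled, tiny_survey.graph, tiny_spec,
                                 sampler=TINY_SAMPLER, seed=5)
        pd.testing.assert_frame_equal(r1.to_dataframe(), r2.to_dataframe())


class TestBackwardSelect:
    def test_single_informative_covariate_retained(self, tiny_survey, tiny_spec):
        r = sl.backward_select(tiny_survey.data, tiny_survey.graph, tiny_spec,
                               sampler=TINY_SAMPLER, seed=6)
        assert [f.name for f in r.selected_spec.fixed_effects] == ["residence"]

    def test_requires_a_covariate(self, tiny_survey):
        spec = sl.ModelSpec(fixed_effects=[], smooth_terms=[],
                            random_structure="NO")
        with pytest.raises(ValueError):
            sl.backward_select(tiny_survey.data, tiny_survey.graph, spec)


class TestSensitivitySweep:
    def test_rows_per_family_and_determinism(self, tiny_survey, tiny_spec):
        fams = ["gamma", "half_normal", "pc"]
        t1 = sl.sensitivity_sweep(tiny_survey.data, tiny_survey.graph, tiny_spec,
                                  families=fams, sampler=TINY_SAMPLER, seed=8)
        t2 = sl.sensitivity_sweep(tiny_survey.data, tiny_survey.graph, tiny_spec,
                                  families=fams, sampler=TINY_SAMPLER, seed=8)
        # one variance component (CAR) per family
        assert len(t1) == 3
        assert set(t1["family"]) == set(fams)
        pd.testing.assert_frame_equal(t1, t2)

    def test_six_families_supported(self, tiny_survey, tiny_spec):
        fams = ["gamma", "half_normal", "half_cauchy", "half_t", "uniform", "pc"]
        small = {"draws": 60, "warmup": 40, "chains": 1}
        t = sl.sensitivity_sweep(tiny_survey.data, tiny_survey.graph, tiny_spec,
                                 families=fams, sampler=small, seed=9)
        assert len(t) == 6

    def test_unknown_family_rejected(self, tiny_survey, tiny_spec):
        with pytest.raises(ValueError, match="unknown precision-prior family"):
            sl.sensitivity_sweep(tiny_survey.data, tiny_survey.graph, tiny_spec,
                                 families=["laplace"], sampler=TINY_SAMPLER)


def test_noise_covariate_does_not_hurt_training_lppd(tiny_survey):
    """Adding a pure-noise covariate leaves the training-fit lppd no worse
    than Monte-Carlo noise (richer models fit the training data at least as
    well)."""
    rng = np.random.default_rng(13)
    df = tiny_survey.data.copy()
    df["noise"] = rng.choice(["p", "q"], size=len(df))
    base = sl.ModelSpec(fixed_effects=[sl.FixedEffect("residence", "rural")],
                        smooth_terms=[], random_structure="NO")
    rich = sl.ModelSpec(fixed_effects=[sl.FixedEffect("residence", "rural"),
                                       sl.FixedEffect("noise", "p")],
                        smooth_terms=[], random_structure="NO")
    g = tiny_survey.graph
    w0 = sl.SpatialLogit.from_dataframe(df, base, g).fit(
        draws=200, warmup=120, chains=1, seed=14).waic()
    w1 = sl.SpatialLogit.from_dataframe(df, rich, g).fit(
        draws=200, warmup=120, chains=1, seed=15).waic()
    assert w1.lppd >= w0.lppd - 1.0  # MC slack on ~700 obs


class TestLinearityComparison:
    def test_identical_specs_give_identical_columns(self, tiny_survey):
        """When the spec's smooths are already linear both arms coincide."""
        spec = sl.ModelSpec(
            fixed_effects=[sl.FixedEffect("residence", "rural")],
            smooth_terms=[sl.SmoothTerm("age_survey", "linear")],
            random_structure="CAR",
        )
        t = sl.linearity_comparison(tiny_survey.data, tiny_survey.graph, spec,
                                    sampler=TINY_SAMPLER, seed=11)
        # same model in both arms, different seeds: ORs close, intervals overlap
        assert t["intervals_overlap"].all()
        np.testing.assert_allclose(t["or_nonlinear"], t["or_linear"], rtol=0.2)

    def test_paired_table_shape(self, tiny_survey, tiny_spec):
        spec = sl.ModelSpec(
            fixed_effects=tiny_spec.fixed_effects,
            smooth_terms=[sl.SmoothTerm("age_survey", 1)],
            random_structure="CAR",
        )
        t = sl.linearity_comparison(tiny_survey.data, tiny_survey.graph, spec,
                                    sampler=TINY_SAMPLER, seed=12)
        assert set(t.columns) >= {
            "or_nonlinear", "or_nonlinear2.5", "or_nonlinear97.5",
            "or_linear", "or_linear2.5", "or_linear97.5",
            "intervals_overlap", "same_direction",
        }
        assert "residence[urban]" in t.index
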
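"""Descriptive tables, GVIF screening, exceedance and risk maps."""

import numpy as np
import pandas as pd
import pytest

import spatlogit as sl
from spatlogit.diagnostics import compute_gvif, descriptive_table, exceedance


def table1_frame():
    """Rebuild an individual-level frame from the survey's printed marginal
    counts (outcome x residence and outcome x occupation cross-tables)."""
    rows = []
    # residence: rural 2176 yes / 9483 no; urban 1290 yes / 4873 no
    for lev, yes, no in (("rural", 2176, 9483), ("urban", 1290, 4873)):
        rows += [{"residence": lev, "outcome": 1}] * yes
        rows += [{"residence": lev, "outcome": 0}] * no
    df = pd.DataFrame(rows)
    # occupation: not working 2220/9994; working 1246/4362 -- attach aligned by
    # outcome strata so both margins are exact
    occ = []
    for lev, yes, no in (("not_working", 2220, 9994), ("working", 1246, 4362)):
        occ += [(lev, 1)] * yes + [(lev, 0)] * no
    occ.sort(key=lambda t: -t[1])
    df = df.sort_values("outcome", ascending=False, kind="stable").reset_index(drop=True)
    df["occupation"] = [t[0] for t in occ]
    return df


class TestDescriptiveTable:
    def test_toy_row_percent(self):
        df = pd.DataFrame({"outcome": [1, 0, 0, 1],
                           "residence": ["rural"] * 4})
        t = descriptive_table(df, categorical=["residence"], continuous=[])
        row = t.loc[("residence", "rural")]
        assert row["total"] == 4
        assert row["yes_row_pct"] == 50.00
        assert row["no_row_pct"] == 50.00

    def test_printed_survey_margins(self):
        """The printed counts reproduce the published prevalence and shares:
        3,466/17,822 terminated (19.45%), 11,659 rural (65.42%),
        5,608 working (31.47%)."""
        df = table1_frame()
        assert len(df) == 17822
        t = descriptive_table(df, categorical=["residence", "occupation"],
                              continuous=[])
        assert t.loc[("outcome", "prevalence_pct"), "column_pct"] == pytest.approx(
            19.45, abs=0.01)
        assert t.loc[("residence", "rural"), "column_pct"] == pytest.approx(
            65.42, abs=0.01)
        assert t.loc[("occupation", "working"), "column_pct"] == pytest.approx(
            31.47, abs=0.01)

    def test_row_percentages_sum_to_hundred(self):
        ds = sl.simulate_survey(n_per_district=40, seed=3)
        t = descriptive_table(ds.data)
        cat = t[t["yes_row_pct"].notna()]
        sums = cat["yes_row_pct"] + cat["no_row_pct"]
        assert (abs(sums - 100.0) <= 0.011).all()

    def test_continuous_median_iqr(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"outcome": rng.integers(0, 2, 200),
                           "age": rng.uniform(15, 49, 200)})
        t = descriptive_table(df, categorical=[], continuous=["age"])
        med = t.loc[("age", "median/IQR (overall)"), "yes"]
        assert med == pytest.approx(np.median(df["age"]), abs=0.01)


class TestGVIF:
    def test_orthogonal_binary_covariates_unit_gvif(self):
        # full 2x2 factorial: exactly orthogonal dummies
        df = pd.DataFrame({
            "a": ["x", "x", "y", "y"] * 50,
            "b": ["u", "v", "u", "v"] * 50,
        })
        rep = compute_gvif(df, ["a", "b"])
        np.testing.assert_allclose(rep.table["gvif"], 1.0, atol=1e-10)
        assert rep.flagged == []

    def test_correlated_continuous_closed_form(self):
        """Two continuous covariates with sample correlation r have
        GVIF = 1 / (1 - r^2) each."""
        rng = np.random.default_rng(1)
        n = 20_000
        x = rng.standard_normal(n)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "y": y})
        r = np.corrcoef(x, y)[0, 1]
        expected = 1.0 / (1.0 - r**2)
        rep = compute_gvif(df, ["x", "y"])
        np.testing.assert_allclose(rep.table["gvif"], expected, rtol=1e-8)
        assert rep.table["gvif"].round(2).iloc[0] == pytest.approx(2.78, abs=0.05)

    def test_near_duplicate_parity_pair_flagged(self):
        """A children-ever-born / children-alive style near-duplicate pair is
        flagged on the adjusted scale; dropping one clears all flags."""
        rng = np.random.default_rng(2)
        n = 5000
        born = rng.integers(0, 5, n)
        alive = np.where(rng.uniform(size=n) < 0.97, born,
                         np.maximum(born - 1, 0))
        other = rng.integers(0, 2, n)
        df = pd.DataFrame({
            "born": pd.Categorical(born.astype(str)),
            "alive": pd.Categorical(alive.astype(str)),
            "other": pd.Categorical(other.astype(str)),
        })
        rep = compute_gvif(df, ["born", "alive", "other"])
        assert {"born", "alive"} <= set(rep.flagged)
        assert "other" not in rep.flagged
        rep2 = compute_gvif(df, ["born", "other"])
        assert rep2.flagged == []

    def test_exact_duplicate_reported_infinite(self):
        df = pd.DataFrame({
            "a": ["x", "y"] * 100,
            "b": ["x", "y"] * 100,
            "c": ["u", "u", "v", "v"] * 50,
        })
        rep = compute_gvif(df, ["a", "b", "c"])
        assert np.isinf(rep.table.loc["a", "gvif"])
        assert rep.collinear_sets and {"a", "b"} <= set(rep.collinear_sets[0])

    def test_df1_adjusted_is_sqrt(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.standard_normal(500),
                           "y": rng.standard_normal(500)})
        rep = compute_gvif(df, ["x", "y"])
        for _, row in rep.table.iterrows():
            if row["df"] == 1:
                assert row["adjusted"] ** 2 == pytest.approx(row["gvif"], rel=1e-9)

    def test_reference_level_invariance(self):
        """GVIF of each covariate does not depend on which level is dropped."""
        rng = np.random.default_rng(4)
        n = 400
        for trial in range(10):
            a = rng.choice(["p", "q", "r"], n)
            z = rng.standard_normal(n)
            b = np.where(z + (a == "p") > 0.5, "hi", "lo")
            df = pd.DataFrame({"a": a, "b": b, "z": z})
            g1 = compute_gvif(df, ["a", "b", "z"], references={"a": "p"})
            g2 = compute_gvif(df, ["a", "b", "z"], references={"a": "r"})
            np.testing.assert_allclose(g1.table["gvif"], g2.table["gvif"],
                                       atol=1e-8)


class _FakeResults:
    """Minimal stand-in carrying b draws for exceedance tests (synthetic)."""

    def __init__(self, b_draws, unit_ids, structure="CAR"):
        self._b = b_draws

        class _Spec:
            random_structure = structure

        class _Bundle:
            pass

        class _Model:
            spec = _Spec()
            bundle = _Bundle()

        _Model.bundle.unit_ids = unit_ids
        self.model = _Model()

    @property
    def b_draws(self):
        return self._b if self.model.spec.random_structure in ("CAR", "CAR_IID") else None


class TestExceedance:
    def test_all_positive_draws(self):
        b = np.abs(np.random.default_rng(0).standard_normal((50, 1))) + 0.01
        res = _FakeResults(b, ["d0"])
        t = exceedance(res).table
        assert t.loc["d0", "q"] == 1.0
        assert bool(t.loc["d0", "elevated"])

    def test_counting_example(self):
        b = np.array([[-0.1], [0.2], [0.3], [0.4]])
        t = exceedance(_FakeResults(b, ["d0"])).table
        assert t.loc["d0", "q"] == 0.75
        assert not bool(t.loc["d0", "elevated"])

    def test_symmetric_draws_near_half(self):
        rng = np.random.default_rng(5)
        b = rng.standard_normal((2000, 3))
        t = exceedance(_FakeResults(b, ["a", "b", "c"])).table
        se = 0.5 / np.sqrt(2000)
        assert (abs(t["q"] - 0.5) < 3 * se).all()

    def test_matches_sorting_oracle(self):
        rng = np.random.default_rng(6)
        b = rng.normal(0.1, 0.5, size=(400, 4))
        t = exceedance(_FakeResults(b, list("abcd"))).table
        for j, uid in enumerate("abcd"):
            col = np.sort(b[:, j])
            q_oracle = 1.0 - np.searchsorted(col, 0.0, side="right") / col.size
            assert t.loc[uid, "q"] == pytest.approx(q_oracle, abs=1e-12)

    def test_without_car_unsupported(self):
        res = _FakeResults(np.zeros((10, 2)), ["a", "b"], structure="IID")
        with pytest.raises(ValueError, match="CAR"):
            exceedance(res)

    def test_bad_cutoff_rejected(self):
        res = _FakeResults(np.zeros((10, 1)), ["a"])
        with pytest.raises(ValueError):
            exceedance(res, cutoff=1.5)


class TestDistrictRiskMap:
    def test_groupby_oracle_and_zero_record_district(self, small_fit):
        risk = sl.district_risk_map(small_fit)
        pred = small_fit.predict()
        idx = small_fit.model.bundle.district_index
        series = pd.Series(pred.mean)
        for j, uid in enumerate(small_fit.model.bundle.unit_ids):
            sub = series[idx == j]
            row = risk.table.loc[uid]
            if len(sub) == 0:
                assert np.isnan(row["p_mean"])
            else:
                assert row["p_mean"] == pytest.approx(sub.mean(), abs=1e-12)
                if len(sub) > 1:
                    assert row["p_sd"] == pytest.approx(sub.std(ddof=1), rel=1e-9)

    def test_b_columns_present_and_finite(self, small_fit):
        risk = sl.district_risk_map(small_fit)
        assert np.isfinite(risk.table[["b_mean", "b_sd", "q"]]).all().all()
        assert risk.table["q"].between(0, 1).all()

    def test_geojson_join(self, small_fit):
        sq = lambda x, y: {
            "type": "Polygon",
            "coordinates": [[[x, y], [x + 1, y], [x + 1, y + 1], [x, y + 1], [x, y]]],
        }
        uid = small_fit.model.bundle.unit_ids[0]
        fc = {"type": "FeatureCollection",
              "features": [{"type": "Feature", "properties": {"id": uid},
                            "geometry": sq(0, 0)}]}
        risk = sl.district_risk_map(small_fit)
        out = risk.to_geojson(fc, id_property="id")
        props = out["features"][0]["properties"]
        assert props["b_mean"] == pytest.approx(risk.table.loc[uid, "b_mean"])
        assert "q" in props


def test_hotspot_district_attains_max_posterior_mean():
    """A designed +0.8 hot-spot district gets the largest posterior-mean b
    (single-replicate version of the detection property)."""
    g = sl.generate_lattice_graph(3, 3)
    truth = sl.TrueParameters(
        intercept=-1.2, beta={},
        smooth_age_survey=lambda t: 0.0 * np.asarray(t),
        smooth_age_cohab=lambda t: 0.0 * np.asarray(t),
        sigma_b=0.0, sigma_h=0.0,
    )
    ds = sl.simulate_survey(graph=g, truth=truth, n_per_district=400,
                            covariate_mix={"residence": {"rural": 1.0}},
                            weight_scheme="uniform", seed=90)
    df = ds.data.copy()
    hot = g.unit_ids[4]
    # inject the hot spot: re-draw that district's outcomes at logit +0.8
    mask = (df["district"] == hot).to_numpy()
    rng = np.random.default_rng(91)
    p_hot = 1 / (1 + np.exp(1.2 - 0.8))
    df["outcome"] = df["outcome"].astype(int)
    df.loc[mask, "outcome"] = (rng.uniform(size=mask.sum()) < p_hot).astype(int)
    spec = sl.ModelSpec(fixed_effects=[], smooth_terms=[], random_structure="CAR")
    res = sl.SpatialLogit.from_dataframe(df, spec, g, weight=None).fit(
        draws=200, warmup=120, chains=1, seed=92)
    risk = sl.district_risk_map(res)
    assert risk.table["b_mean"].idxmax() == hot
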
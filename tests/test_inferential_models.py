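import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from migstops.glmm import fit_binomial_glmm
from migstops.inferential_models import (fit_activity_glmm,
                                         fit_stopover_count_model,
                                         prune_correlated_predictors)
from migstops.synthetic_data import simulate_glmm_dataset


def _corr_table(rng, spec):
    """Build columns with approximately the requested correlation structure."""
    n = 4000
    z = {k: rng.normal(size=n) for k in "xyzw"}
    cols = {}
    for name, expr in spec.items():
        cols[name] = expr(z, rng)
    return pd.DataFrame(cols)


class TestPruning:
    def test_high_correlation_keeps_priority(self):
        rng = np.random.default_rng(0)
        df = _corr_table(rng, {
            "a": lambda z, r: z["x"],
            "b": lambda z, r: 0.95 * z["x"] + 0.1 * r.normal(size=4000),
        })
        assert prune_correlated_predictors(df, ["a", "b"]) == ["a"]
        assert prune_correlated_predictors(df, ["b", "a"]) == ["b"]

    def test_independent_all_retained(self):
        rng = np.random.default_rng(1)
        df = _corr_table(rng, {
            "a": lambda z, r: z["x"], "b": lambda z, r: z["y"],
            "c": lambda z, r: z["z"]})
        assert prune_correlated_predictors(df, ["a", "b", "c"]) == \
            ["a", "b", "c"]

    def test_chain_keeps_a_and_c(self):
        # A-B r~0.7, B-C r~0.7, A-C r~0.1, priority A>B>C -> {A, C}
        rng = np.random.default_rng(2)
        n = 20000
        a = rng.normal(size=n)
        c = 0.1 * a + np.sqrt(1 - 0.01) * rng.normal(size=n)
        resid = rng.normal(size=n)
        b = 0.65 * a + 0.65 * c + 0.35 * resid
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        r_ab = abs(np.corrcoef(a, b)[0, 1])
        r_bc = abs(np.corrcoef(b, c)[0, 1])
        r_ac = abs(np.corrcoef(a, c)[0, 1])
        assert r_ab > 0.6 and r_bc > 0.6 and r_ac < 0.6
        assert prune_correlated_predictors(df, ["a", "b", "c"]) == ["a", "c"]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        df = _corr_table(rng, {
            "a": lambda z, r: z["x"],
            "b": lambda z, r: 0.8 * z["x"] + 0.3 * z["y"],
            "c": lambda z, r: z["z"]})
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        assert prune_correlated_predictors(df, ["a", "b", "c"]) == \
            prune_correlated_predictors(shuffled, ["a", "b", "c"])

    def test_constant_dropped_with_warning(self):
        df = pd.DataFrame({"a": np.arange(10.0), "k": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            out = prune_correlated_predictors(df, ["k", "a"])
        assert out == ["a"]

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            prune_correlated_predictors(pd.DataFrame({"a": [1.0, 2.0]}),
                                        ["a"], threshold=1.5)


def _count_dataset(rng, pop_offset=0.0, season_offset=0.0, n_ind=32):
    rows = []
    pops = ["p1", "p2", "p3", "p4"]
    for i in range(n_ind):
        pop = pops[i % 4]
        u = rng.normal(0, 1.0)
        for season in ("spring", "fall"):
            mu = (3.0 + u + (pop_offset if pop == "p2" else 0.0)
                  + (season_offset if season == "spring" else 0.0))
            for _ in range(3):
                rows.append({"individual_id": f"i{i}", "population": pop,
                             "season": season,
                             "count": max(0.0, rng.normal(mu, 1.0))})
    return pd.DataFrame(rows)


class TestCountModel:
    def test_recovers_population_offset(self):
        rng = np.random.default_rng(7)
        res = fit_stopover_count_model(_count_dataset(rng, pop_offset=5.0))
        term = next(t for t in res.terms if "p2" in t[0] and ":" not in t[0])
        beta, se = term[1], term[2]
        assert abs(beta - 5.0) < 2.5 * se + 0.5

    def test_duplicated_data_same_estimates(self):
        rng = np.random.default_rng(8)
        df = _count_dataset(rng)
        r1 = fit_stopover_count_model(df)
        r2 = fit_stopover_count_model(pd.concat([df, df], ignore_index=True))
        for (n1, b1, *_), (n2, b2, *_) in zip(r1.terms, r2.terms):
            assert n1 == n2
            assert b1 == pytest.approx(b2, abs=1e-4)

    def test_single_season_drops_term(self):
        rng = np.random.default_rng(9)
        df = _count_dataset(rng)
        df = df[df["season"] == "fall"]
        with pytest.warns(UserWarning, match="season"):
            res = fit_stopover_count_model(df)
        assert not any("season" in t[0] for t in res.terms)

    def test_zero_effect_type_one_rate(self):
        rng = np.random.default_rng(10)
        hits = total = 0
        for _ in range(20):
            res = fit_stopover_count_model(_count_dataset(rng, n_ind=24))
            for name, beta, se, _ in res.terms:
                if name == "Intercept":
                    continue
                total += 1
                hits += abs(beta) <= 2.0 * se
        assert hits / total >= 0.85

    def test_random_effect_sd_reported(self):
        rng = np.random.default_rng(11)
        res = fit_stopover_count_model(_count_dataset(rng))
        assert res.random_effect_sd["individual_id"] > 0.3


NAMES = ["precipitation_fraction", "thermal_updraft_velocity", "temperature"]


class TestActivityGLMM:
    def test_recovery_single_replicate(self):
        df = simulate_glmm_dataset(seed=5)
        res = fit_activity_glmm(df, NAMES)
        truth = {"Intercept": -1.7, "precipitation_fraction": -3.8,
                 "thermal_updraft_velocity": 9.2, "temperature": 3.0}
        for name, (lo, hi) in res.ci95().items():
            tv = truth[name]
            assert lo - 0.5 < tv < hi + 0.5  # generous single-rep check

    def test_aggregated_equals_disaggregated(self):
        df = simulate_glmm_dataset(n_stopovers=60, n_individuals=8,
                                   n_populations=2, seed=3)
        agg = fit_activity_glmm(df, NAMES)
        rows = []
        for _, r in df.iterrows():
            k = int(r["n_active_h"])
            for j in range(int(r["n_daytime_h"])):
                row = r.copy()
                row["n_active_h"] = 1 if j < k else 0
                row["n_daytime_h"] = 1
                rows.append(row)
        dis = fit_activity_glmm(pd.DataFrame(rows), NAMES)
        for (n1, b1, s1, *_), (n2, b2, s2, *_) in zip(agg.terms, dis.terms):
            assert b1 == pytest.approx(b2, abs=5e-3)
            assert s1 == pytest.approx(s2, rel=5e-3)

    def test_single_individual_raises(self):
        df = simulate_glmm_dataset(n_stopovers=40, n_individuals=1,
                                   n_populations=1, seed=1)
        with pytest.raises(ValueError, match="individual"):
            fit_activity_glmm(df, NAMES)

    def test_null_simulation_sign_balance(self):
        rng = np.random.default_rng(0)
        pos = 0
        reps = 16
        for rep in range(reps):
            df = simulate_glmm_dataset(n_stopovers=200, n_individuals=20,
                                       n_populations=4,
                                       betas=(-1.0, 0.0, 0.0, 0.0),
                                       seed=300 + rep)
            res = fit_activity_glmm(df, NAMES)
            beta = dict((t[0], t[1]) for t in res.terms)
            pos += beta["precipitation_fraction"] > 0
        assert 2 <= pos <= reps - 2

    def test_missing_column_raises(self):
        df = simulate_glmm_dataset(seed=2).drop(columns=["temperature"])
        with pytest.raises(ValueError, match="temperature"):
            fit_activity_glmm(df, NAMES)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
class TestAgainstLme4:
    def test_matches_glmer_fit(self, tmp_path):
        df = simulate_glmm_dataset(n_stopovers=300, n_individuals=20,
                                   n_populations=4, seed=77)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
fit <- suppressWarnings(suppressMessages(
  glmer(cbind(n_active_h, n_daytime_h - n_active_h) ~
        precipitation_fraction + thermal_updraft_velocity + temperature +
        (1|population/individual_id), data=d, family=binomial)))
co <- summary(fit)$coefficients
write.csv(data.frame(term=rownames(co), beta=co[,1], se=co[,2]),
          "{tmp_path / 'out.csv'}", row.names=FALSE)
""")
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv")
        res = fit_activity_glmm(df, NAMES)
        ours = {t[0]: (t[1], t[2]) for t in res.terms}
        for _, row in ref.iterrows():
            name = row["term"].replace("(Intercept)", "Intercept")
            beta, se = ours[name]
            assert beta == pytest.approx(row["beta"], abs=0.02)
            assert se == pytest.approx(row["se"], rel=0.05)


class TestGLMMCore:
    def test_invalid_inputs(self):
        X = np.ones((5, 1))
        with pytest.raises(ValueError):
            fit_binomial_glmm(X, [0, 1, 1, 0, 1], [0, 2, 2, 2, 2],
                              {"g": [0, 0, 1, 1, 1]})
        with pytest.raises(ValueError):
            fit_binomial_glmm(X, [3, 1, 1, 0, 1], [2, 2, 2, 2, 2],
                              {"g": [0, 0, 1, 1, 1]})
        with pytest.raises(ValueError, match="single level"):
            fit_binomial_glmm(X, [1, 1, 1, 0, 1], [2, 2, 2, 2, 2],
                              {"g": [0, 0, 0, 0, 0]})
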
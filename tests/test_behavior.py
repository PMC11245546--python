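"""State-conditioned behavioral statistics."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from phasestates import (
    GeneratorConfig,
    arcsine,
    block_pattern_occupancy,
    compare_to_baseline,
    detection_rates,
    fdr_bh,
    fit_rate_model,
    fit_rt_model,
    join_patterns,
    make_latent_states,
    make_ratings,
    make_schedule,
    poststim_occupancy,
    ratings_correlation,
    simulate_coupled_block,
    simulate_dataset,
    simulate_observer,
    time_resolved_occupancy,
)
from phasestates.behavior import _design, fit_weighted_lmm, signed_rank
from phasestates.states import StateSequence
from phasestates.synth import LatentStateSequence


def make_state_seq(labels, tr=1.0, subject="sub-01"):
    labels = np.asarray(labels)
    return StateSequence(labels=labels, distances=np.zeros(len(labels)),
                         tr=tr, subject_id=subject)


def toy_trials():
    return pd.DataFrame({
        "subject": "sub-01", "block": 1, "trial": [1, 2, 3],
        "onset_s": [10.2, 11.0, 25.7],
        "snr": ["-9", "-7", "catch"],
        "detected": [True, False, False],
        "rt_s": [0.8, np.nan, np.nan],
        "prev_detected": [None, True, False],
    })


class TestJoinPatterns:
    def test_floor_and_boundary_rules(self):
        labels = np.arange(1, 41) % 5 + 1
        seq = make_state_seq(labels)
        out = join_patterns(toy_trials(), seq)
        assert out.loc[0, "pattern"] == labels[10]   # onset 10.2 -> volume 10
        assert out.loc[1, "pattern"] == labels[11]   # onset 11.0 -> volume 11

    def test_constant_sequence_gives_single_pattern(self):
        out = join_patterns(toy_trials(), make_state_seq(np.full(40, 3)))
        assert (out["pattern"] == 3).all()

    def test_onset_outside_run_raises(self):
        with pytest.raises(ValueError, match="outside"):
            join_patterns(toy_trials(), make_state_seq(np.full(20, 1)))


class TestDetectionRates:
    def test_exact_proportions(self):
        trials = pd.DataFrame({
            "subject": "s1", "block": 1, "trial": range(1, 5),
            "onset_s": np.arange(4) * 14.0,
            "snr": ["-9"] * 4, "detected": [True, True, True, False],
            "rt_s": np.nan, "prev_detected": None, "pattern": 1,
        })
        rt = detection_rates(trials)
        assert rt.cells.loc[0, "rate"] == 0.75

    def test_weighted_cell_mean_equals_marginal(self):
        """Pooling check on a random table: the n-weighted mean of cell
        rates reproduces the overall per-SNR rate (direct-count oracle)."""
        rng = np.random.default_rng(0)
        rows = []
        for s, pat, snr in product(range(4), range(1, 4), ["-7", "-9"]):
            n = rng.integers(1, 9)
            for i in range(n):
                rows.append({"subject": f"s{s}", "block": 1, "trial": i,
                             "onset_s": 0.0, "snr": snr,
                             "detected": bool(rng.random() < 0.5),
                             "rt_s": np.nan, "prev_detected": True,
                             "pattern": pat})
        trials = pd.DataFrame(rows)
        rt = detection_rates(trials)
        for snr in ["-7", "-9"]:
            cells = rt.cells[rt.cells.snr == snr]
            pooled = (cells.rate * cells.n_trials).sum() / cells.n_trials.sum()
            direct = trials.loc[trials.snr == snr, "detected"].mean()
            assert pooled == pytest.approx(direct, abs=1e-12)

    def test_catch_false_alarm_in_marginal_only(self):
        rt = detection_rates(toy_trials().assign(pattern=1))
        assert "catch" in set(rt.marginal.snr)
        assert "catch" not in set(rt.cells.snr)


class TestArcsine:
    @pytest.mark.parametrize("p,expected", [
        (0.0, 0.0), (1.0, np.pi / 2), (0.5, np.pi / 4),
    ])
    def test_known_values(self, p, expected):
        assert arcsine(p) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            arcsine(1.2)


class TestSignedRank:
    def test_three_positive_differences(self):
        v, p, n = signed_rank(np.array([0.1, 0.2, 0.3]), alternative="greater")
        assert v == 6
        assert p == pytest.approx(0.125, abs=1e-12)

    def test_all_zero_differences_skipped(self):
        v, p, n = signed_rank(np.zeros(5))
        assert n == 0 and np.isnan(p)

    def test_antisymmetric_data_not_significant(self):
        d = np.array([0.2, 0.4, 0.6, -0.2, -0.4, -0.6])
        _, p, _ = signed_rank(d, alternative="greater")
        assert p > 0.4

    def test_exact_path_matches_sign_pattern_enumeration(self):
        """Enumerate all 2^n sign assignments of |d| ranks: the exact
        one-sided p equals the fraction of assignments with V+ >= observed."""
        rng = np.random.default_rng(1)
        for _ in range(60):
            n = rng.integers(3, 11)
            d = rng.normal(size=n)
            d = d[d != 0]
            n = len(d)
            ranks = pd.Series(np.abs(d)).rank().to_numpy()
            v_obs = ranks[d > 0].sum()
            count = 0
            for signs in product([0, 1], repeat=n):
                v = ranks[np.array(signs, bool)].sum()
                if v >= v_obs - 1e-9:
                    count += 1
            expected_p = count / 2**n
            _, p, _ = signed_rank(d, alternative="greater")
            assert p == pytest.approx(expected_p, abs=1e-10)


class TestFdrBh:
    def test_textbook_example(self):
        adj = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04, 0.05]))
        assert np.allclose(adj, 0.05)

    def test_single_and_degenerate(self):
        assert fdr_bh(np.array([0.3]))[0] == pytest.approx(0.3)
        assert np.allclose(fdr_bh(np.ones(4)), 1.0)
        assert fdr_bh(np.array([])).size == 0

    def test_matches_brute_force_step_up(self):
        """Direct step-up definition: adj_(i) = min over j >= i of
        min(1, m p_(j) / j)."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            m = rng.integers(1, 12)
            p = rng.uniform(size=m)
            order = np.argsort(p)
            sorted_p = p[order]
            adj_sorted = np.minimum.accumulate(
                (m * sorted_p / np.arange(1, m + 1))[::-1])[::-1]
            adj = np.empty(m)
            adj[order] = np.minimum(adj_sorted, 1.0)
            assert np.allclose(fdr_bh(p), adj, atol=1e-12)


class TestWeightedLmm:
    def _toy(self, seed=0, n_subj=10, equal_weights=False):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subj):
            b = rng.normal(0, 0.3)
            for pat in range(1, 4):
                for snr in ["-7", "-9"]:
                    w = 1.0 if equal_weights else float(rng.integers(2, 20))
                    mu = 1.0 + 0.2 * pat + (0.5 if snr == "-7" else 0.0)
                    rows.append({"subject": f"s{s}", "pattern": pat, "snr": snr,
                                 "n_trials": w,
                                 "y": mu + b + rng.normal(0, 0.4 / np.sqrt(w))})
        return pd.DataFrame(rows)

    def test_agrees_with_statsmodels_on_equal_weights(self):
        """Dual-route check: with unit weights the model reduces to a
        standard random-intercept LMM, which statsmodels fits independently."""
        import statsmodels.formula.api as smf
        df = self._toy(equal_weights=True)
        factors = {"pattern": [1, 2, 3], "snr": ["-7", "-9"]}
        x, names, _ = _design(df, factors, [])
        fit = fit_weighted_lmm(df["y"].to_numpy(), x, df["subject"].to_numpy(),
                               df["n_trials"].to_numpy(), colnames=names)
        sm_fit = smf.mixedlm("y ~ C(pattern) + C(snr)", df,
                             groups=df["subject"]).fit(reml=True)
        assert np.allclose(fit.beta, sm_fit.fe_params.to_numpy(), atol=1e-4)
        assert fit.tau2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=0.01, abs=1e-4)
        assert fit.sigma2 == pytest.approx(float(sm_fit.scale), rel=0.01)
        se = np.sqrt(np.diag(fit.cov_beta))
        assert np.allclose(se, sm_fit.bse_fe.to_numpy(), rtol=0.02)

    def test_zero_random_variance_reduces_to_wls(self):
        """With tau^2 pinned at 0 the GLS solution equals closed-form
        weighted least squares."""
        df = self._toy(seed=3)
        factors = {"pattern": [1, 2, 3], "snr": ["-7", "-9"]}
        x, names, _ = _design(df, factors, [])
        w = df["n_trials"].to_numpy()
        fit = fit_weighted_lmm(df["y"].to_numpy(), x, df["subject"].to_numpy(),
                               w, colnames=names, fixed_tau2=0.0)
        beta_wls = np.linalg.solve(x.T @ (w[:, None] * x), x.T @ (w * df["y"]))
        assert np.allclose(fit.beta, beta_wls, atol=1e-10)


class TestRateModel:
    def test_planted_interaction_detected(self):
        cfg = GeneratorConfig(rng_seed=1)
        ds = simulate_dataset(cfg, include_bold=False)
        trials = ds.trials.copy()
        trials["pattern"] = trials["pattern_true"]
        report = fit_rate_model(detection_rates(trials).cells)
        terms = report.term_tests.set_index("term")
        assert terms.loc["snr", "p"] < 1e-10
        assert terms.loc["pattern:snr", "p"] < 0.05
        assert report.transform == "arcsine"
        # Pattern 1 vs others contrasts exist within the threshold SNR family
        at9 = report.contrasts[report.contrasts.family == "-9"]
        assert {"p_fdr", "cohens_d"} <= set(at9.columns)

    def test_previous_detection_effect_recovered(self):
        cfg = GeneratorConfig(rng_seed=2, gamma=0.15, delta=0.0)
        ds = simulate_dataset(cfg, include_bold=False)
        trials = ds.trials.copy()
        trials["pattern"] = trials["pattern_true"]
        cells = detection_rates(trials, by_prev=True).cells
        report = fit_rate_model(cells, include_prev=True)
        terms = report.term_tests.set_index("term")
        assert terms.loc["prev_detected", "p"] < 0.01


class TestBaselineComparison:
    def test_spec_example_and_flags(self):
        cells = pd.DataFrame({
            "subject": ["s1", "s2", "s3"], "pattern": 1, "snr": "-9",
            "n_trials": 10, "n_detected": [7, 8, 9],
        })
        cells["rate"] = cells["n_detected"] / cells["n_trials"]
        out = compare_to_baseline(cells, baseline=0.58)
        row = out.iloc[0]
        assert row["V"] == 6
        assert row["p"] == pytest.approx(0.125)
        assert not row["unreliable"]

    def test_all_zero_differences_flagged(self):
        cells = pd.DataFrame({
            "subject": ["s1", "s2"], "pattern": 1, "snr": "-9",
            "n_trials": 10, "n_detected": 5, "rate": 0.5,
        })
        out = compare_to_baseline(cells, baseline=0.5)
        assert out.iloc[0]["unreliable"]
        assert np.isnan(out.iloc[0]["p"])


class TestRtModel:
    def _trials_with_rts(self, rts, snr="-9"):
        n = len(rts)
        return pd.DataFrame({
            "subject": ["s1", "s2"] * (n // 2) if n % 2 == 0 else ["s1"] * n,
            "block": 1, "trial": range(1, n + 1),
            "onset_s": np.arange(n) * 14.0, "snr": snr,
            "detected": True, "rt_s": rts, "prev_detected": True, "pattern": 1,
        })

    def test_filter_interval_closed_at_both_ends(self):
        # RTs exactly at 0.4 s and 2.0 s are retained...
        boundary = pd.concat([
            self._trials_with_rts([0.4, 2.0, 0.6, 1.4]),
            self._trials_with_rts([0.5, 1.1, 0.4, 2.0], snr="-7"),
        ], ignore_index=True)
        report = fit_rt_model(boundary)
        assert report.term_tests.shape[0] == 3
        # ...while RTs strictly outside are all excluded
        outside = self._trials_with_rts([0.1, 0.39, 3.0, 2.01])
        with pytest.raises(ValueError, match="RT filter"):
            fit_rt_model(outside)

    def test_snr_ordering_recovered(self):
        """The generator plants slower RTs at lower SNR; the model should
        find a main effect of SNR with the correct direction on 1/RT."""
        cfg = GeneratorConfig(rng_seed=3)
        ds = simulate_dataset(cfg, include_bold=False)
        trials = ds.trials.copy()
        trials["pattern"] = trials["pattern_true"]
        report = fit_rt_model(trials)
        terms = report.term_tests.set_index("term")
        assert terms.loc["snr", "p"] < 1e-6
        snr_con = report.contrasts[report.contrasts.family == "snr"]
        row = snr_con[snr_con[["a", "b"]].apply(set, axis=1) == {"-7", "-11"}].iloc[0]
        t_fast_minus_slow = row["t"] if row["a"] == "-7" else -row["t"]
        assert t_fast_minus_slow > 0  # 1/RT larger (faster) at SNR -7


def _coupled_dataset(seed=0, n_subjects=12, bias=0.3):
    cfg = GeneratorConfig(n_subjects=n_subjects, post_detection_bias=bias,
                          rng_seed=seed)
    ds = simulate_dataset(cfg, include_bold=False)
    seqs = {}
    for (sid, block), lat in ds.task_latent.items():
        seqs[(sid, block)] = make_state_seq(lat.states, subject=sid)
    return cfg, ds, seqs


class TestOccupancy:
    def test_constant_labels_full_occupancy(self):
        trials = toy_trials()
        seqs = {("sub-01", 1): make_state_seq(np.full(40, 2))}
        occ, tests = poststim_occupancy(trials, seqs, k=3)
        two = occ[occ.pattern == 2]
        assert (two["prob"] == 1.0).all()
        assert occ.groupby(["subject", "condition"])["prob"].sum().eq(1).all()

    def test_per_condition_probabilities_sum_to_one(self):
        _, ds, seqs = _coupled_dataset(seed=1, n_subjects=3)
        occ, _ = poststim_occupancy(ds.trials, seqs, k=5)
        sums = occ.groupby(["subject", "condition"])["prob"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_detection_coupled_dynamics_raise_poststim_occupancy(self):
        """With a planted post-detection transition bias, the favorable
        pattern occupies more of the 9-s post-stimulus window after
        detected than undetected threshold stimuli (paired Wilcoxon)."""
        cfg, ds, seqs = _coupled_dataset(seed=2, n_subjects=25)
        occ, tests = poststim_occupancy(ds.trials, seqs, k=5)
        fav = cfg.favorable_state
        wide = occ[occ.pattern == fav].pivot_table(
            index="subject", columns="condition", values="prob")
        assert wide["detected"].mean() > wide["undetected"].mean()
        assert tests.set_index("pattern").loc[fav, "p"] < 0.05


class TestTimeResolved:
    def test_grid_has_thirteen_offsets(self):
        _, ds, seqs = _coupled_dataset(seed=3, n_subjects=3)
        profile, tests = time_resolved_occupancy(ds.trials, seqs, k=5)
        assert sorted(profile["offset"].unique().tolist()) == list(range(-3, 10))
        assert tests.groupby("pattern")["offset"].count().eq(13).all()

    def test_identical_sequences_give_no_differences(self):
        trials = pd.DataFrame({
            "subject": ["s1"] * 6, "block": 1, "trial": range(1, 7),
            "onset_s": np.arange(6) * 14.0 + 14.0, "snr": "-9",
            "detected": [True, False] * 3, "rt_s": np.nan,
            "prev_detected": True, "pattern": 1,
        })
        seqs = {("s1", 1): make_state_seq(np.full(120, 1), subject="s1")}
        _, tests = time_resolved_occupancy(trials, seqs, k=2)
        assert tests["p"].isna().all() or (tests["n_subjects"] <= 1).all()

    def test_onset_locked_effect_localized_in_time(self):
        """A state effect present only at the onset volume produces a
        detected/undetected difference at offset 0 and none pre-stimulus."""
        rng = np.random.default_rng(4)
        rows, seqs = [], {}
        for s in range(20):
            sid = f"s{s:02d}"
            labels = rng.integers(1, 3, size=400)
            seqs[(sid, 1)] = make_state_seq(labels, subject=sid)
            for i in range(24):
                onset = 14.0 * (i + 1)
                state = labels[int(onset)]
                p = 0.8 if state == 1 else 0.2
                rows.append({"subject": sid, "block": 1, "trial": i + 1,
                             "onset_s": onset, "snr": "-9",
                             "detected": bool(rng.random() < p),
                             "rt_s": np.nan, "prev_detected": True,
                             "pattern": state})
        trials = pd.DataFrame(rows)
        _, tests = time_resolved_occupancy(trials, seqs, k=2)
        t1 = tests[tests.pattern == 1].set_index("offset")
        assert t1.loc[0, "p"] < 0.01
        assert (t1.loc[[-3, -2, -1], "p"] > 0.05).all()


class TestRatingsCorrelation:
    def _occ_frame(self, occ_values):
        rows = []
        for i, v in enumerate(occ_values):
            rows.append({"subject": f"s{i % 5}", "block": i // 5 + 1,
                         "pattern": 1, "occupancy": v})
        return pd.DataFrame(rows)

    def test_perfect_monotone(self):
        occ = self._occ_frame(np.linspace(0, 1, 20))
        ratings = occ[["subject", "block"]].copy()
        ratings["tiredness"] = np.arange(20)
        out = ratings_correlation(occ, ratings, rating_cols=("tiredness",))
        assert out.iloc[0]["rho"] == pytest.approx(1.0)
        out_rev = ratings_correlation(occ, ratings.assign(tiredness=-np.arange(20)),
                                      rating_cols=("tiredness",))
        assert out_rev.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_constant_rating_reported_missing(self):
        occ = self._occ_frame(np.linspace(0, 1, 20))
        ratings = occ[["subject", "block"]].copy()
        ratings["tiredness"] = 4
        out = ratings_correlation(occ, ratings, rating_cols=("tiredness",))
        assert np.isnan(out.iloc[0]["rho"])

    def test_generator_tiredness_association_significant(self):
        """Block tiredness ratings correlate with planted tired-state
        occupancy across 150 subject-blocks, surviving FDR."""
        cfg = GeneratorConfig(n_subjects=25, rng_seed=5)
        ds = simulate_dataset(cfg, include_bold=False)
        seqs = {key: make_state_seq(lat.states, subject=key[0])
                for key, lat in ds.task_latent.items()}
        occ = block_pattern_occupancy(seqs, k=5)
        out = ratings_correlation(occ, ds.ratings)
        row = out[(out.pattern == cfg.tired_state) & (out.rating == "tiredness")]
        assert row["rho"].iloc[0] > 0.2
        assert row["p_fdr"].iloc[0] < 0.05
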
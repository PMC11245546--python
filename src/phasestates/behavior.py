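"""State-conditioned behavioral statistics.

Joins the per-volume brain-pattern labels to the trial table (the pattern
of the volume whose acquisition interval contains the stimulus onset),
builds subject-level detection-rate and reaction-time cells, and runs the
study's statistical battery:

* linear mixed models with a subject random intercept on arcsine-transformed
  detection rates (or inverse reaction times), observations weighted by
  trial counts, factors tested with Type-II Wald chi-square statistics;
* pairwise pattern contrasts within each SNR (paired t on subject-level
  transformed rates, BH-FDR corrected, paired Cohen's d);
* one-sided Wilcoxon signed-rank comparisons of per-pattern threshold
  detection rates against the staircase baseline;
* post-stimulus pattern-occupancy comparisons between detected and
  undetected threshold trials (paired two-sided Wilcoxon), both aggregated
  over a 9-s window and time-resolved on a -3..+9 s offset grid;
* Spearman correlations between block-level pattern occupancy and
  subjective ratings.

The mixed model is implemented directly (profiled (RE)ML with a
Sherman-Morrison inverse per subject) because the residual variance must
scale as sigma^2 / n_trials for trial-count weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from statsmodels.stats.multitest import multipletests

from .states import StateSequence

__all__ = [
    "join_patterns",
    "detection_rates",
    "arcsine",
    "fit_rate_model",
    "fit_rt_model",
    "compare_to_baseline",
    "poststim_occupancy",
    "time_resolved_occupancy",
    "block_pattern_occupancy",
    "ratings_correlation",
    "fdr_bh",
    "signed_rank",
    "ModelReport",
    "LmmFit",
    "fit_weighted_lmm",
]

logger = logging.getLogger(__name__)

SNR_ORDER = ["-7", "-9", "-11"]
THRESHOLD_SNR = "-9"
RT_WINDOW = (0.4, 2.0)   # seconds, closed interval


# ---------------------------------------------------------------------------
# joining patterns to trials
# ---------------------------------------------------------------------------

def join_patterns(trials: pd.DataFrame,
                  state_seq: StateSequence | dict[tuple[str, int], StateSequence],
                  column: str = "pattern") -> pd.DataFrame:
    """Attach the brain pattern active at each stimulus onset.

    The pattern of a trial is the label of the volume whose acquisition
    interval [k*TR, (k+1)*TR) contains the onset (floor rule; an onset
    exactly on a volume boundary belongs to that volume).  ``state_seq``
    is either a single sequence or a dict keyed by (subject, block).
    """
    out = trials.copy()
    patterns = np.empty(len(out), dtype=int)
    for pos, rec in enumerate(out.itertuples()):
        seq = (state_seq if isinstance(state_seq, StateSequence)
               else state_seq[(rec.subject, rec.block)])
        k = int(np.floor(rec.onset_s / seq.tr))
        if not (0 <= k < seq.n_volumes):
            raise ValueError(
                f"trial (subject={rec.subject}, block={rec.block}, trial={rec.trial}): "
                f"onset {rec.onset_s} s outside the labeled run")
        patterns[pos] = seq.labels[k]
    out[column] = patterns
    return out


# ---------------------------------------------------------------------------
# detection-rate cells
# ---------------------------------------------------------------------------

@dataclass
class RateTable:
    """Per-(subject, pattern, SNR) detection-rate cells plus marginals."""

    cells: pd.DataFrame        # subject, pattern, snr[, prev_detected], n_trials, n_detected, rate
    marginal: pd.DataFrame     # snr (incl. "catch"), n_trials, n_detected, rate


def detection_rates(trials: pd.DataFrame, pattern_col: str = "pattern",
                    by_prev: bool = False) -> RateTable:
    """Exact detection counts and proportions.

    Cells are (subject, pattern, SNR) — optionally further split by the
    previous-trial detection status, dropping block-initial trials with no
    previous trial — and the marginals pool everything per SNR level,
    including the catch-trial false-alarm rate.
    """
    if trials.empty:
        raise ValueError("empty trial table")
    marg = (trials.groupby("snr", sort=False)
            .agg(n_trials=("detected", "size"), n_detected=("detected", "sum"))
            .reset_index())
    marg["rate"] = marg["n_detected"] / marg["n_trials"]
    stim = trials[trials["snr"] != "catch"].copy()
    keys = ["subject", pattern_col, "snr"]
    if by_prev:
        stim = stim[stim["prev_detected"].notna()].copy()
        stim["prev_detected"] = stim["prev_detected"].astype(bool)
        keys.append("prev_detected")
    cells = (stim.groupby(keys, sort=False)
             .agg(n_trials=("detected", "size"), n_detected=("detected", "sum"))
             .reset_index())
    cells["rate"] = cells["n_detected"] / cells["n_trials"]
    cells = cells.rename(columns={pattern_col: "pattern"})
    return RateTable(cells=cells, marginal=marg)


def arcsine(p):
    """Variance-stabilizing transform for proportions: asin(sqrt(p))."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(p))


# ---------------------------------------------------------------------------
# weighted random-intercept linear mixed model
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    colnames: list[str]
    sigma2: float              # residual variance (for unit weight)
    tau2: float                # random-intercept variance
    loglik: float
    singular: bool
    term_cols: dict[str, list[int]] = field(default_factory=dict)


def fit_weighted_lmm(y: np.ndarray, x: np.ndarray, groups: np.ndarray,
                     weights: np.ndarray, colnames: list[str] | None = None,
                     reml: bool = True, fixed_tau2: float | None = None) -> LmmFit:
    """Random-intercept LMM with heteroscedastic residuals sigma^2 / w.

    y_ij = x_ij' beta + b_i + e_ij,  b_i ~ N(0, tau^2),
    e_ij ~ N(0, sigma^2 / w_ij).

    The two variance components are estimated by (RE)ML on a 2-parameter
    log scale; beta is the GLS solution at the optimum and its covariance
    the inverse weighted information.  Per-group covariance inverses use
    the Sherman-Morrison identity, so the fit is O(n) per evaluation.
    """
    y = np.asarray(y, float)
    x = np.atleast_2d(np.asarray(x, float))
    w = np.asarray(weights, float)
    n, p = x.shape
    if colnames is None:
        colnames = [f"x{j}" for j in range(p)]
    codes = pd.factorize(groups)[0]
    n_groups = codes.max() + 1
    # sufficient statistics: everything the likelihood needs, computed once
    wx = w[:, None] * x
    a0 = x.T @ wx                                     # X' W X
    b0 = x.T @ (w * y)                                # X' W y
    q0 = float(y @ (w * y))                           # y' W y
    s_wx = np.zeros((n_groups, p))                    # per-group sums of W X
    for j in range(p):
        s_wx[:, j] = np.bincount(codes, weights=wx[:, j], minlength=n_groups)
    s_wy = np.bincount(codes, weights=w * y, minlength=n_groups)
    s_w = np.bincount(codes, weights=w, minlength=n_groups)
    sum_log_w = float(np.sum(np.log(w)))
    var_y = max(float(np.var(y)), 1e-12)

    def profile(params):
        log_s2, log_t2 = params
        s2, t2 = np.exp(log_s2), np.exp(log_t2)
        c = t2 / (s2 * (s2 + t2 * s_w))               # Sherman-Morrison factors
        a = a0 / s2 - (s_wx * c[:, None]).T @ s_wx
        b = b0 / s2 - s_wx.T @ (c * s_wy)
        quad_y = q0 / s2 - float(c @ s_wy**2)
        logdet = n * np.log(s2) - sum_log_w + float(np.sum(np.log1p(t2 * s_w / s2)))
        beta = np.linalg.solve(a, b)
        quad = quad_y - b @ beta                      # r' V^-1 r at the GLS beta
        neg2ll = logdet + quad + n * np.log(2 * np.pi)
        if reml:
            _, ld = np.linalg.slogdet(a)
            neg2ll += ld - p * np.log(2 * np.pi)
        return neg2ll, beta, a

    if fixed_tau2 is not None:
        log_t2_fixed = np.log(max(fixed_tau2, 1e-300))

        def objective(log_s2):
            return profile([log_s2[0], log_t2_fixed])[0]

        res = minimize(objective, [np.log(var_y)], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        params = np.array([res.x[0], log_t2_fixed])
    else:
        def objective(params):
            return profile(params)[0]

        x0 = np.array([np.log(var_y), np.log(var_y / 2)])
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        params = res.x
    log_s2, log_t2 = params
    s2, t2 = float(np.exp(log_s2)), float(np.exp(log_t2))
    neg2ll, beta, a = profile(params)
    cov = np.linalg.inv(a)
    singular = t2 < 1e-6 * s2
    return LmmFit(beta=beta, cov_beta=cov, colnames=list(colnames),
                  sigma2=s2, tau2=t2, loglik=-0.5 * neg2ll, singular=singular)


def _design(df: pd.DataFrame, factors: dict[str, list],
            interactions: list[tuple[str, str]]) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Treatment-coded design matrix with intercept; tracks term -> columns."""
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["Intercept"]
    term_cols: dict[str, list[int]] = {}
    dummies: dict[str, dict[object, np.ndarray]] = {}
    for f, levels in factors.items():
        dummies[f] = {lv: (df[f].to_numpy() == lv).astype(float) for lv in levels}
        term_cols[f] = []
        for lv in levels[1:]:
            term_cols[f].append(len(cols))
            cols.append(dummies[f][lv])
            names.append(f"{f}[{lv}]")
    for fa, fb in interactions:
        term = f"{fa}:{fb}"
        term_cols[term] = []
        for la in factors[fa][1:]:
            for lb in factors[fb][1:]:
                col = dummies[fa][la] * dummies[fb][lb]
                if not col.any():
                    continue             # structurally empty cell combination
                term_cols[term].append(len(cols))
                cols.append(col)
                names.append(f"{fa}[{la}]:{fb}[{lb}]")
    return np.column_stack(cols), names, term_cols


def _wald(fit: LmmFit, idx: list[int]) -> tuple[float, int, float]:
    b = fit.beta[idx]
    v = fit.cov_beta[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(v, b))
    df = len(idx)
    return stat, df, float(stats.chi2.sf(stat, df))


@dataclass
class ModelReport:
    """Wald term tests and FDR-corrected contrasts for one mixed model."""

    term_tests: pd.DataFrame    # term, chi2, df, p
    contrasts: pd.DataFrame     # family, a, b, n, t, p, p_fdr, cohens_d
    transform: str
    weights: str
    singular: bool
    fit: LmmFit | None = None


def _paired_contrasts(subject_values: pd.DataFrame, value_col: str,
                      family_col: str, level_col: str) -> pd.DataFrame:
    """All pairwise paired t-tests of ``level_col`` within each family.

    ``subject_values`` holds one value per (subject, family, level).
    Cohen's d is the paired form: mean of subject differences over their SD.
    BH-FDR is applied within each family.
    """
    rows = []
    for fam, sub in subject_values.groupby(family_col, sort=False):
        wide = sub.pivot_table(index="subject", columns=level_col,
                               values=value_col, aggfunc="mean")
        for a, b in combinations(wide.columns, 2):
            d = (wide[a] - wide[b]).dropna()
            n = len(d)
            if n < 2 or np.allclose(d.std(ddof=1), 0):
                continue
            t, p = stats.ttest_1samp(d, 0.0)
            rows.append({"family": fam, "a": a, "b": b, "n": n,
                         "t": float(t), "p": float(p),
                         "cohens_d": float(d.mean() / d.std(ddof=1))})
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["family", "a", "b", "n", "t", "p",
                                     "p_fdr", "cohens_d"])
    out["p_fdr"] = np.nan
    for fam in out["family"].unique():
        m = out["family"] == fam
        out.loc[m, "p_fdr"] = fdr_bh(out.loc[m, "p"].to_numpy())
    return out


def _rate_model_frame(cells: pd.DataFrame, include_prev: bool) -> pd.DataFrame:
    df = cells.copy()
    df["y"] = arcsine(df["rate"])
    df["pattern"] = df["pattern"].astype(int)
    df["snr"] = df["snr"].astype(str)
    if include_prev and "prev_detected" not in df.columns:
        raise ValueError("include_prev requires cells split by prev_detected "
                         "(detection_rates(..., by_prev=True))")
    return df


def fit_rate_model(cells: pd.DataFrame, include_prev: bool = False) -> ModelReport:
    """Mixed model for detection rates: pattern x SNR (+ previous detection).

    Arcsine-transformed subject-level rates are modeled with a subject
    random intercept, fixed effects for pattern, SNR and their interaction
    (plus the previous-detection status when requested), observations
    weighted by cell trial counts.  Terms are tested with Type-II Wald
    chi-square statistics: each main effect is tested in the model that
    omits interactions containing it, the interaction in the full model.
    Pairwise pattern contrasts within each SNR use paired t-tests on the
    subject-level transformed rates with BH-FDR correction within SNR.
    """
    df = _rate_model_frame(cells, include_prev)
    patterns = sorted(df["pattern"].unique())
    snrs = [s for s in SNR_ORDER if s in set(df["snr"])]
    factors: dict[str, list] = {"pattern": patterns, "snr": snrs}
    if include_prev:
        factors["prev_detected"] = [False, True]

    def fit_model(with_interaction: bool) -> LmmFit:
        inter = [("pattern", "snr")] if with_interaction else []
        x, names, term_cols = _design(df, factors, inter)
        fit = fit_weighted_lmm(df["y"].to_numpy(), x, df["subject"].to_numpy(),
                               df["n_trials"].to_numpy(), colnames=names)
        fit.term_cols = term_cols
        return fit

    full = fit_model(True)
    mains = fit_model(False)
    tests = []
    for term, fit in [("pattern", mains), ("snr", mains), ("pattern:snr", full)]:
        stat, dfree, p = _wald(fit, fit.term_cols[term])
        tests.append({"term": term, "chi2": stat, "df": dfree, "p": p})
    if include_prev:
        stat, dfree, p = _wald(full, full.term_cols["prev_detected"])
        tests.append({"term": "prev_detected", "chi2": stat, "df": dfree, "p": p})

    subj = (df.groupby(["subject", "snr", "pattern"], sort=False)
            .apply(lambda g: arcsine(g["n_detected"].sum() / g["n_trials"].sum()),
                   include_groups=False)
            .rename("y").reset_index())
    contrasts = _paired_contrasts(subj, "y", "snr", "pattern")
    return ModelReport(term_tests=pd.DataFrame(tests), contrasts=contrasts,
                       transform="arcsine", weights="n_trials",
                       singular=full.singular, fit=full)


def fit_rt_model(trials: pd.DataFrame, pattern_col: str = "pattern") -> ModelReport:
    """Mixed model for reaction times of detected stimuli.

    RTs are filtered to the closed window [0.4, 2.0] s, inverse-transformed
    (1/RT), aggregated to subject-level (pattern, SNR) cell means, and
    modeled like the detection rates (subject random intercept, trial-count
    weights, Type-II Wald tests).  Contrast families: patterns within SNR
    and SNR levels overall.
    """
    det = trials[(trials["detected"]) & (trials["snr"] != "catch")].copy()
    det = det[(det["rt_s"] >= RT_WINDOW[0]) & (det["rt_s"] <= RT_WINDOW[1])]
    if det.empty:
        raise ValueError("no detected trials survive the RT filter")
    det["inv_rt"] = 1.0 / det["rt_s"]
    cells = (det.groupby(["subject", pattern_col, "snr"], sort=False)
             .agg(y=("inv_rt", "mean"), n_trials=("inv_rt", "size"))
             .reset_index().rename(columns={pattern_col: "pattern"}))
    patterns = sorted(cells["pattern"].unique())
    snrs = [s for s in SNR_ORDER if s in set(cells["snr"])]
    factors = {"pattern": patterns, "snr": snrs}

    def fit_model(with_interaction: bool) -> LmmFit:
        inter = [("pattern", "snr")] if with_interaction else []
        x, names, term_cols = _design(cells, factors, inter)
        fit = fit_weighted_lmm(cells["y"].to_numpy(), x, cells["subject"].to_numpy(),
                               cells["n_trials"].to_numpy(), colnames=names)
        fit.term_cols = term_cols
        return fit

    full = fit_model(True)
    mains = fit_model(False)
    tests = [dict(zip(("term", "chi2", "df", "p"), (t, *_wald(f, f.term_cols[t]))))
             for t, f in [("pattern", mains), ("snr", mains), ("pattern:snr", full)]]
    within_snr = _paired_contrasts(cells.rename(columns={"snr": "family"}),
                                   "y", "family", "pattern")
    snr_cells = cells.assign(family="snr")
    snr_contrasts = _paired_contrasts(snr_cells, "y", "family", "snr")
    frames = [f for f in (within_snr, snr_contrasts) if not f.empty]
    contrasts = (pd.concat(frames, ignore_index=True) if frames
                 else within_snr)
    return ModelReport(term_tests=pd.DataFrame(tests), contrasts=contrasts,
                       transform="inverse_rt", weights="n_trials",
                       singular=full.singular, fit=full)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank paths
# ---------------------------------------------------------------------------

def signed_rank(diffs: np.ndarray, alternative: str = "two-sided"
                ) -> tuple[float, float, int]:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; the statistic is V, the sum of ranks of
    the positive differences.  The exact null distribution is used for
    n <= 25 without ties in |differences|, otherwise the normal
    approximation with continuity correction.  Returns (V, p, n_nonzero).
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return np.nan, np.nan, 0
    ranks = stats.rankdata(np.abs(d))
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    kwargs = {"correction": True} if method == "approx" else {}
    res = stats.wilcoxon(d, alternative=alternative, method=method, **kwargs)
    v = float(np.sum(ranks[d > 0]))
    return v, float(res.pvalue), n


def compare_to_baseline(cells: pd.DataFrame, baseline: float = 0.58,
                        snr: str = THRESHOLD_SNR) -> pd.DataFrame:
    """Per-pattern one-sided Wilcoxon of threshold detection rates vs. a scalar.

    One rate per subject per pattern (cells pooled over any extra splits);
    the alternative is that the pattern's rates exceed the baseline.
    Patterns with fewer than 3 nonzero differences are flagged unreliable.
    """
    at = cells[cells["snr"].astype(str) == snr]
    subj = (at.groupby(["subject", "pattern"], sort=False)
            .apply(lambda g: g["n_detected"].sum() / g["n_trials"].sum(),
                   include_groups=False)
            .rename("rate").reset_index())
    rows = []
    for pattern, sub in subj.groupby("pattern", sort=True):
        d = sub["rate"].to_numpy() - baseline
        v, p, n = signed_rank(d, alternative="greater")
        rows.append({"pattern": pattern, "n_nonzero": n, "V": v, "p": p,
                     "unreliable": n < 3})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pattern occupancy around threshold stimuli
# ---------------------------------------------------------------------------

def _trial_offset_labels(trials: pd.DataFrame,
                         state_seq: dict[tuple[str, int], StateSequence],
                         offsets: np.ndarray) -> pd.DataFrame:
    """Pattern label at each volume offset around each threshold-trial onset.

    Trials whose full offset window is not covered by the labeled run are
    dropped with a log entry.
    """
    at = trials[trials["snr"].astype(str) == THRESHOLD_SNR]
    rows = []
    n_dropped = 0
    for rec in at.itertuples():
        seq = state_seq[(rec.subject, rec.block)]
        v0 = int(np.floor(rec.onset_s / seq.tr))
        vols = v0 + offsets
        if vols.min() < 0 or vols.max() >= seq.n_volumes:
            n_dropped += 1
            continue
        for off, v in zip(offsets, vols):
            rows.append({"subject": rec.subject, "block": rec.block,
                         "trial": rec.trial, "detected": bool(rec.detected),
                         "offset": int(off), "label": int(seq.labels[v])})
    if n_dropped:
        logger.info("dropped %d threshold trial(s) with incomplete offset windows",
                    n_dropped)
    return pd.DataFrame(rows)


def poststim_occupancy(trials: pd.DataFrame,
                       state_seq: dict[tuple[str, int], StateSequence],
                       k: int, window: int = 9
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Post-stimulus pattern occupancy, detected vs. undetected threshold trials.

    For each threshold (SNR -9) trial, the fraction of the ``window``
    volumes at offsets +1..+window bearing each pattern; averaged within
    subject per condition; each pattern compared across subjects with a
    paired two-sided Wilcoxon signed-rank test (subjects lacking either
    condition are excluded from that pattern's test).

    Returns (occupancy, tests): occupancy has one row per (subject,
    condition, pattern) with the mean occupancy probability; tests one row
    per pattern with V, p and the subject count.
    """
    offsets = np.arange(1, window + 1)
    long = _trial_offset_labels(trials, state_seq, offsets)
    if long.empty:
        raise ValueError("no threshold trials with complete post-stimulus windows")
    occ_rows = []
    per_trial = (long.groupby(["subject", "detected", "block", "trial", "label"])
                 .size().rename("count").reset_index())
    per_trial["prob"] = per_trial["count"] / window
    for (subject, detected), sub in per_trial.groupby(["subject", "detected"]):
        n_trials = sub.groupby(["block", "trial"]).ngroups
        for pattern in range(1, k + 1):
            tot = sub.loc[sub["label"] == pattern, "prob"].sum()
            occ_rows.append({"subject": subject,
                             "condition": "detected" if detected else "undetected",
                             "pattern": pattern, "prob": tot / n_trials,
                             "n_trials": n_trials})
    occupancy = pd.DataFrame(occ_rows)
    tests = []
    wide = occupancy.pivot_table(index=["subject", "pattern"], columns="condition",
                                 values="prob")
    for col in ("detected", "undetected"):
        if col not in wide.columns:
            wide[col] = np.nan
    for pattern in range(1, k + 1):
        sub = wide.xs(pattern, level="pattern").dropna()
        if len(sub) < len(wide.index.get_level_values("subject").unique()):
            logger.info("pattern %d: %d subject(s) lack a condition; excluded",
                        pattern,
                        len(wide.index.get_level_values("subject").unique()) - len(sub))
        d = (sub["detected"] - sub["undetected"]).to_numpy()
        v, p, n = signed_rank(d, alternative="two-sided")
        tests.append({"pattern": pattern, "n_subjects": len(sub), "V": v, "p": p})
    return occupancy, pd.DataFrame(tests)


def time_resolved_occupancy(trials: pd.DataFrame,
                            state_seq: dict[tuple[str, int], StateSequence],
                            k: int, offsets=range(-3, 10)
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pattern occurrence probability on a volume-offset grid around onset.

    At each offset (default -3..+9 volumes, 13 time points at TR = 1 s) and
    for each pattern, the per-subject occurrence probability across
    detected and undetected threshold trials, compared with a paired
    two-sided Wilcoxon; BH-FDR applied within each pattern's offset family.

    Returns (profile, tests): profile has one row per (subject, condition,
    offset, pattern); tests one per (pattern, offset) with V, p, p_fdr.
    """
    offsets = np.asarray(list(offsets), dtype=int)
    long = _trial_offset_labels(trials, state_seq, offsets)
    if long.empty:
        raise ValueError("no threshold trials with complete offset windows")
    prof_rows = []
    for (subject, detected, off), sub in long.groupby(["subject", "detected", "offset"]):
        n = len(sub)
        for pattern in range(1, k + 1):
            prof_rows.append({"subject": subject,
                              "condition": "detected" if detected else "undetected",
                              "offset": off, "pattern": pattern,
                              "prob": float(np.mean(sub["label"] == pattern)),
                              "n_trials": n})
    profile = pd.DataFrame(prof_rows)
    tests = []
    wide = profile.pivot_table(index=["subject", "pattern", "offset"],
                               columns="condition", values="prob")
    for col in ("detected", "undetected"):
        if col not in wide.columns:
            wide[col] = np.nan
    for pattern in range(1, k + 1):
        for off in offsets:
            try:
                sub = wide.xs((pattern, off), level=("pattern", "offset")).dropna()
            except KeyError:
                sub = pd.DataFrame()
            if sub.empty:
                tests.append({"pattern": pattern, "offset": int(off),
                              "n_subjects": 0, "V": np.nan, "p": np.nan})
                continue
            d = (sub["detected"] - sub["undetected"]).to_numpy()
            v, p, n = signed_rank(d, alternative="two-sided")
            tests.append({"pattern": pattern, "offset": int(off),
                          "n_subjects": len(sub), "V": v, "p": p})
    tests = pd.DataFrame(tests)
    tests["p_fdr"] = np.nan
    for pattern in range(1, k + 1):
        m = (tests["pattern"] == pattern) & tests["p"].notna()
        if m.any():
            tests.loc[m, "p_fdr"] = fdr_bh(tests.loc[m, "p"].to_numpy())
    return profile, tests


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------

def block_pattern_occupancy(state_seq: dict[tuple[str, int], StateSequence],
                            k: int) -> pd.DataFrame:
    """Fraction of each block's volumes assigned to each pattern."""
    rows = []
    for (subject, block), seq in state_seq.items():
        for pattern in range(1, k + 1):
            rows.append({"subject": subject, "block": block, "pattern": pattern,
                         "occupancy": float(np.mean(seq.labels == pattern))})
    return pd.DataFrame(rows)


def ratings_correlation(block_occupancy: pd.DataFrame, ratings: pd.DataFrame,
                        rating_cols=("tiredness", "success", "focus")
                        ) -> pd.DataFrame:
    """Spearman correlation of block pattern occupancy with subjective ratings.

    Subject-blocks are pooled; BH-FDR is applied across the whole
    pattern x rating family.  A constant rating or occupancy vector has an
    undefined correlation, reported as NaN and excluded from the FDR step.
    """
    merged = block_occupancy.merge(ratings, on=["subject", "block"])
    if merged.groupby(["subject", "block"]).ngroups < 10:
        raise ValueError("need at least 10 subject-blocks")
    rows = []
    for pattern, sub in merged.groupby("pattern", sort=True):
        for col in rating_cols:
            occ, r = sub["occupancy"].to_numpy(), sub[col].to_numpy()
            if np.all(occ == occ[0]) or np.all(r == r[0]):
                rows.append({"pattern": pattern, "rating": col,
                             "rho": np.nan, "p": np.nan, "n": len(sub)})
                continue
            rho, p = stats.spearmanr(occ, r)
            rows.append({"pattern": pattern, "rating": col,
                         "rho": float(rho), "p": float(p), "n": len(sub)})
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    m = out["p"].notna()
    if m.any():
        out.loc[m, "p_fdr"] = fdr_bh(out.loc[m, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[1]
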
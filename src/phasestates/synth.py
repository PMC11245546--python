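"""Synthetic data generator for the phase-coherence brain-state pipeline.

Emulates the statistical structure of a multi-subject fMRI auditory-detection
study: 42-ROI BOLD-like time series whose inter-areal phase relations switch
among a small set of recurrent coherence templates under a Markov chain; a
6-block task schedule (10 stimuli per SNR in {-7, -9, -11} dB plus 3 catch
trials per block, inter-stimulus interval 14 +/- 1 s); a logistic observer
whose detection of the threshold stimulus (SNR -9) is boosted when a
designated favorable coherence state is active at stimulus onset and after a
detected previous trial (hysteresis); a one-up-one-down staircase that
calibrates the stimulus volume to 50% detection at SNR -9; circular-shift
surrogate time series; and block-level subjective ratings tied to the
occupancy of a designated "tired" state.

The generative trick that makes template recovery possible downstream: all
ROIs share one narrowband carrier oscillation, and each latent state
assigns every ROI a fixed phase offset psi_i, so ROI i's noiseless signal
is essentially cos(phi(t) + psi_i(s_t)): the instantaneous-phase coherence
of a pair is then cos(psi_i - psi_j), the planted template entry.  State
switches are implemented as band-limited blends of the per-state unit
phasors (see :func:`make_bold`), which keeps the signal free of
negative-frequency content so that the downstream analytic-signal phase is
exact rather than corrupted by switching transients.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .phase import RoiTimeSeries, pair_index, vector_from_matrix

__all__ = [
    "GeneratorConfig",
    "LatentStateSequence",
    "default_state_offsets",
    "templates_from_offsets",
    "fit_phase_offsets",
    "make_latent_states",
    "make_bold",
    "make_schedule",
    "simulate_observer",
    "simulate_staircase",
    "circular_shift_surrogate",
    "make_ratings",
    "simulate_coupled_block",
    "simulate_dataset",
    "SimulatedDataset",
    "child_rng",
]

SNR_LEVELS = (-7, -9, -11)
CATCH = "catch"

# mean reaction time (s) of the lognormal RT model per SNR; lower SNR = slower
_RT_MEAN = {-7: 1.02, -9: 1.10, -11: 1.20}
_RT_SIGMA = 0.25


def child_rng(master_seed: int, tag: str) -> np.random.Generator:
    """Per-purpose child generator derived from one master seed.

    A stable CRC32 of the tag keeps every derived entropy word below 2**31,
    and distinct tags give independent streams.
    """
    word = zlib.crc32(tag.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) % (2**31), word]))


# ---------------------------------------------------------------------------
# configuration and planted templates
# ---------------------------------------------------------------------------

def default_state_offsets(n_rois: int = 42) -> np.ndarray:
    """Per-state ROI phase offsets defining the five default templates.

    Offsets are chosen so the implied coherence templates
    cos(psi_i - psi_j) are mutually distinct and strictly ordered by mean
    absolute coherence, which pins down the canonical pattern numbering:

    1. two anticorrelated blocks (antiphase halves) -- the strongly
       connected, long-range positive/negative profile designated the
       "favorable" (conscious-state-like) pattern;
    2. a graded globally positive profile (phase ramp over 1.4 rad);
    3. three equal communities at mutual 120 degrees;
    4. three interleaved communities in quadrature -- weak off-diagonal
       structure, designated the "tired" pattern;
    5. two interleaved communities in quadrature.
    """
    p = n_rois
    idx = np.arange(p)
    offsets = np.zeros((5, p))
    offsets[0] = np.where(idx < p // 2, 0.0, np.pi)
    offsets[1] = 1.4 * idx / max(p - 1, 1)
    offsets[2] = (idx * 3 // p) * (2 * np.pi / 3)
    offsets[3] = (idx % 3) * (np.pi / 2)
    offsets[4] = (idx % 2) * (np.pi / 2)
    return offsets


def templates_from_offsets(offsets: np.ndarray) -> np.ndarray:
    """K x P x P coherence templates implied by per-state phase offsets."""
    d = offsets[:, :, None] - offsets[:, None, :]
    return np.cos(d)


@dataclass
class GeneratorConfig:
    """Study-level constants and generative parameters.

    Defaults mirror the study design: 25 subjects, 42 ROIs, TR = 1 s,
    600 resting-state volumes, 5 coherence states, 6 task blocks with
    10 stimuli per SNR level in {-7, -9, -11} dB plus 3 catch trials each,
    stimulus volume calibrated to 50% detection at SNR -9.
    """

    n_subjects: int = 25
    n_rois: int = 42
    tr: float = 1.0
    rest_volumes: int = 600
    n_states: int = 5
    state_templates: np.ndarray | None = None   # K x P x P; default derived
    state_offsets: np.ndarray | None = None     # K x P; set when defaults used
    transition_matrix: np.ndarray | None = None  # K x K row-stochastic
    dwell_scale: float = 25.0                   # mean state dwell time, s
    carrier_band: tuple[float, float] = (0.16, 0.26)  # Hz
    noise_sd: float = 0.15                      # additive noise / signal RMS
    # psychometric observer
    alpha: float = 0.0       # threshold location, dB (snr + volume scale)
    beta: float = 1.0        # logistic slope, 1/dB
    lapse: float = 0.02      # upper-asymptote lapse rate
    guess: float = 0.002     # catch-trial false-alarm rate
    delta: float = 0.12      # favorable-state detection boost at SNR -9
    gamma: float = 0.055     # hysteresis boost after a detected trial
    favorable_state: int = 1
    tired_state: int | None = None   # defaults to pattern 4 (or K if K < 4)
    post_detection_bias: float = 0.15  # transition-mass shift toward the
    bias_window: int = 9               # favorable state for this many volumes
    # task schedule
    n_blocks: int = 6
    trials_per_snr: int = 10
    catch_per_block: int = 3
    isi_mean: float = 14.0
    isi_jitter: float = 1.0
    # staircase
    staircase_start_db: float = 13.0
    staircase_step_db: float = 1.0
    # ratings
    rating_noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.state_templates is None:
            if self.state_offsets is None:
                self.state_offsets = default_state_offsets(self.n_rois)[: self.n_states]
                if self.n_states > 5:
                    raise ValueError("default templates define at most 5 states")
            self.state_templates = templates_from_offsets(np.asarray(self.state_offsets))
        self.state_templates = np.asarray(self.state_templates, dtype=float)
        if self.state_templates.shape != (self.n_states, self.n_rois, self.n_rois):
            raise ValueError("state_templates must be K x P x P")
        for k, t in enumerate(self.state_templates):
            if not np.allclose(t, t.T, atol=1e-10):
                raise ValueError(f"template {k + 1} is not symmetric")
            if not np.allclose(np.diag(t), 1.0, atol=1e-10):
                raise ValueError(f"template {k + 1} diagonal is not 1")
            if np.any(np.abs(t) > 1 + 1e-12):
                raise ValueError(f"template {k + 1} has entries outside [-1, 1]")
        if self.transition_matrix is None:
            self.transition_matrix = self._default_transition_matrix()
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        _validate_stochastic(self.transition_matrix, self.n_states)
        if not (0 <= self.guess <= 0.05 and 0 <= self.lapse <= 0.05):
            raise ValueError("guess and lapse must lie in [0, 0.05]")
        if not (0 <= self.delta <= 0.5 and 0 <= self.gamma <= 0.5):
            raise ValueError("delta and gamma must lie in [0, 0.5]")
        if not (1 <= self.favorable_state <= self.n_states):
            raise ValueError("favorable_state out of range")
        if self.tired_state is None:
            self.tired_state = min(4, self.n_states)
        if not (1 <= self.tired_state <= self.n_states):
            raise ValueError("tired_state out of range")

    def _default_transition_matrix(self) -> np.ndarray:
        # geometric dwell with mean dwell_scale / tr volumes
        k = self.n_states
        p_leave = min(1.0, self.tr / self.dwell_scale)
        m = np.full((k, k), p_leave / max(k - 1, 1))
        np.fill_diagonal(m, 1.0 - p_leave)
        return m

    def stationary_distribution(self) -> np.ndarray:
        """Left Perron eigenvector of the transition matrix, normalized."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("state_templates", "state_offsets", "transition_matrix"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        d = json.loads(Path(path).read_text())
        for key in ("state_templates", "state_offsets", "transition_matrix"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        if "carrier_band" in d:
            d["carrier_band"] = tuple(d["carrier_band"])
        return cls(**d)


def _validate_stochastic(m: np.ndarray, k: int) -> None:
    if m.shape != (k, k):
        raise ValueError(f"transition matrix must be {k} x {k}")
    if np.any(m < 0):
        raise ValueError("transition matrix has negative entries")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition matrix rows must sum to 1")


@dataclass
class LatentStateSequence:
    """Ground-truth per-volume state labels (1-based), with volume times."""

    states: np.ndarray   # int, values in 1..K
    tr: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)

    @property
    def n_volumes(self) -> int:
        return self.states.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr

    def state_at(self, onset: float) -> int:
        """State of the volume whose interval [k*tr, (k+1)*tr) contains onset."""
        k = int(np.floor(onset / self.tr))
        if not (0 <= k < self.n_volumes):
            raise ValueError(f"onset {onset} s outside the run (0..{self.n_volumes * self.tr} s)")
        return int(self.states[k])


# ---------------------------------------------------------------------------
# phase-offset realization of arbitrary templates
# ---------------------------------------------------------------------------

def fit_phase_offsets(template: np.ndarray, tol: float = 0.2) -> tuple[np.ndarray, float]:
    """Fit per-ROI phase offsets so cos(psi_i - psi_j) approximates a template.

    Embedding onto the unit circle: initialize from the top two eigenvectors
    of the template (the circular analogue of classical MDS), then refine by
    minimizing the squared deviation with L-BFGS.  Returns the offsets and
    the maximum absolute deviation between the realized coherence matrix and
    the template's off-diagonal entries.

    Raises
    ------
    ValueError
        If the best achievable approximation error exceeds ``tol`` (the
        template is not realizable as a phase-offset pattern to the
        requested accuracy).
    """
    t = np.asarray(template, dtype=float)
    p = t.shape[0]
    vals, vecs = np.linalg.eigh(t)
    order = np.argsort(vals)[::-1]
    v1 = vecs[:, order[0]] * np.sqrt(max(vals[order[0]], 0.0))
    v2 = vecs[:, order[1]] * np.sqrt(max(vals[order[1]], 0.0))
    psi0 = np.arctan2(v2, v1)

    mask = ~np.eye(p, dtype=bool)

    def cost(psi: np.ndarray) -> float:
        c = np.cos(psi[:, None] - psi[None, :])
        return float(np.sum((c - t)[mask] ** 2))

    def grad(psi: np.ndarray) -> np.ndarray:
        d = psi[:, None] - psi[None, :]
        r = (np.cos(d) - t) * mask
        g = -2.0 * np.sum(r * np.sin(d), axis=1) * 2.0  # symmetric pairs
        return g

    res = minimize(cost, psi0, jac=grad, method="L-BFGS-B")
    psi = res.x
    realized = np.cos(psi[:, None] - psi[None, :])
    err = float(np.max(np.abs((realized - t)[mask])))
    if err > tol:
        raise ValueError(
            f"template not realizable as phase offsets: max deviation {err:.3f} > tol {tol}")
    return psi, err


def _offsets_for(config: GeneratorConfig) -> np.ndarray:
    """Per-state phase offsets, fitting them from templates if not stored."""
    if config.state_offsets is not None:
        return np.asarray(config.state_offsets)
    fitted = [fit_phase_offsets(t)[0] for t in config.state_templates]
    return np.asarray(fitted)


# ---------------------------------------------------------------------------
# latent dynamics and BOLD synthesis
# ---------------------------------------------------------------------------

def make_latent_states(config: GeneratorConfig, n_volumes: int,
                       seed: int | np.random.Generator,
                       start_state: int | None = None) -> LatentStateSequence:
    """Sample a Markov chain of latent coherence states.

    The initial state is drawn from the chain's stationary distribution
    unless ``start_state`` (1-based) is given.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    m = config.transition_matrix
    _validate_stochastic(m, config.n_states)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = config.n_states
    states = np.empty(n_volumes, dtype=int)
    if start_state is None:
        pi = np.cumsum(config.stationary_distribution())
        states[0] = int(np.searchsorted(pi, rng.random())) + 1
    else:
        states[0] = start_state
    cum = np.cumsum(m, axis=1)
    u = rng.random(n_volumes)
    s = states[0] - 1
    for t in range(1, n_volumes):
        s = min(int(np.searchsorted(cum[s], u[t])), k - 1)
        states[t] = s + 1
    return LatentStateSequence(states=states, tr=config.tr)


# ratio of the carrier low-cut bin to the Gaussian bandwidth of the
# state-indicator envelope; larger values blur transitions more but leak less
_ENVELOPE_REL_BW = 2.2


def _state_weights(states: np.ndarray, k: int, cutoff_bin: int) -> np.ndarray:
    """Band-limited soft state indicators (T x K, rows summing to ~1).

    One-hot indicators are circularly smoothed with a Gaussian spectral
    gain of width (cutoff_bin - 1) / _ENVELOPE_REL_BW and truncated at the
    carrier's lowest bin, so the modulated signal has no negative-frequency
    content and the downstream analytic-signal phase is exact.  The
    time-domain cost is a blend window of a few volumes around each state
    switch.
    """
    t = states.size
    onehot = np.zeros((t, k))
    onehot[np.arange(t), states - 1] = 1.0
    return _bandlimit(onehot, cutoff_bin)


def _bandlimit(channels: np.ndarray, cutoff_bin: int) -> np.ndarray:
    """Circular Gaussian smoothing with a hard spectral cutoff below the
    carrier band."""
    t = channels.shape[0]
    bins = np.abs(np.fft.fftfreq(t)) * t
    sigma_f = max(cutoff_bin - 1, 1) / _ENVELOPE_REL_BW
    gain = np.exp(-0.5 * (bins / sigma_f) ** 2)
    gain[bins >= cutoff_bin - 0.5] = 0.0
    return np.real(np.fft.ifft(np.fft.fft(channels, axis=0) * gain[:, None], axis=0))


# random phase wander of the FM carrier: standard deviation (rad) and
# bandwidth (Hz); strong slow wander decorrelates circularly shifted copies
_CARRIER_WANDER_SD = 3.0
_CARRIER_WANDER_HZ = 0.012


def _fm_carrier(t: int, band: tuple[float, float], duration: float,
                rng: np.random.Generator) -> np.ndarray:
    """Constant-modulus frequency-modulated analytic carrier.

    exp(i theta(t)) with theta = a center tone at the middle of ``band``
    plus a band-limited Gaussian phase wander of sd _CARRIER_WANDER_SD.
    The constant modulus keeps the phase equally well defined at every
    volume (no amplitude fades), while the wander spreads the spectrum over
    the band so that circularly shifting different ROIs decorrelates their
    signals — a single-tone carrier would survive shifting as a mere phase
    rotation, defeating the surrogate control.
    """
    m_c = max(int(round((band[0] + band[1]) / 2 * duration)), 3)
    kw = max(int(round(_CARRIER_WANDER_HZ * duration)), 2)
    spec = np.zeros(t, complex)
    spec[1:kw + 1] = rng.normal(size=kw) + 1j * rng.normal(size=kw)
    wander = np.real(np.fft.ifft(spec))
    sd = wander.std()
    if sd > 0:
        wander *= _CARRIER_WANDER_SD / sd
    theta = 2 * np.pi * m_c * np.arange(t) / t + wander
    return np.exp(1j * theta)


def make_bold(latent: LatentStateSequence, config: GeneratorConfig,
              seed: int | np.random.Generator, subject_id: str = "sub-01",
              run_label: str = "rest") -> RoiTimeSeries:
    """Synthesize a T x P ROI signal matrix that carries the planted states.

    A shared constant-modulus FM carrier c(t) wandering inside
    ``carrier_band`` is modulated, per ROI, by a blend of per-state unit
    phasors exp(i psi_i(s)): ROI i's noiseless signal is
    Re[phasor_i(t) c(t)], scaled to unit RMS.  Deep inside a dwell the
    phasor is exactly exp(i psi_i(s_t)), so the pairwise instantaneous-
    phase coherence equals the active template entry cos(psi_i - psi_j)
    regardless of the carrier's own (shared) phase; around each state
    switch the phasors cross-fade over a band-limited window of a few
    volumes.  Because the blend envelope has no spectral content at or
    above the carrier band's lower edge, the noiseless signal carries
    essentially no negative-frequency energy and the Hilbert phase
    extracted downstream is accurate away from the blend windows.
    Gaussian noise of sd ``noise_sd`` (relative to the unit-RMS signal) is
    added per sample.

    The carrier band must sit above the state-switching rate: a slower
    carrier cannot express coherence reconfigurations every few tens of
    seconds.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offsets = _offsets_for(config)
    t = latent.n_volumes
    duration = t * config.tr
    k_lo = max(int(np.ceil(config.carrier_band[0] * duration)), 3)
    carrier = _fm_carrier(t, config.carrier_band, duration, rng)
    weights = _state_weights(latent.states, config.n_states, k_lo)
    phasor = weights @ np.exp(1j * offsets)          # T x P complex envelope
    data = np.sqrt(2.0) * np.real(phasor * carrier[:, None])
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
    return RoiTimeSeries(data=data, tr=config.tr, subject_id=subject_id,
                         run_label=run_label)


# ---------------------------------------------------------------------------
# task schedule and observer
# ---------------------------------------------------------------------------

def make_schedule(config: GeneratorConfig, seed: int | np.random.Generator) -> pd.DataFrame:
    """Randomized 6-block trial schedule.

    Each block holds ``trials_per_snr`` stimuli at each SNR level plus
    ``catch_per_block`` catch trials (33 trials per block, 198 total with
    the defaults), in randomized order, with successive onsets separated by
    a uniform draw from isi_mean +/- isi_jitter (14 +/- 1 s).  Onsets are
    seconds from the start of the trial's block.

    Returns a DataFrame with columns block, trial, onset_s, snr; catch
    trials carry the string sentinel "catch" in the snr column.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = config.isi_mean - config.isi_jitter, config.isi_mean + config.isi_jitter
    rows = []
    labels = ([str(s) for s in SNR_LEVELS for _ in range(config.trials_per_snr)]
              + [CATCH] * config.catch_per_block)
    for block in range(1, config.n_blocks + 1):
        order = rng.permutation(len(labels))
        isis = rng.uniform(lo, hi, size=len(labels))
        onsets = np.cumsum(isis)
        for i, (j, onset) in enumerate(zip(order, onsets), start=1):
            rows.append({"block": block, "trial": i, "onset_s": float(onset),
                         "snr": labels[j]})
    return pd.DataFrame(rows)


def _detect_prob(snr_db: float, volume_db: float, config: GeneratorConfig,
                 favorable: bool, prev_detected: bool | None) -> float:
    """Single-trial detection probability of the logistic observer."""
    p = (1.0 - config.lapse) * expit(config.beta * (snr_db + volume_db - config.alpha))
    if favorable and snr_db == -9:
        p += config.delta
    if prev_detected:
        p += config.gamma
    return float(np.clip(p, 0.0, 1.0))


def _draw_rt(rng: np.random.Generator, snr) -> float:
    mean = _RT_MEAN.get(snr, 1.10)
    mu = np.log(mean) - _RT_SIGMA**2 / 2
    return float(min(rng.lognormal(mu, _RT_SIGMA), 12.99))


def simulate_observer(schedule: pd.DataFrame,
                      latent: LatentStateSequence | dict[int, LatentStateSequence],
                      config: GeneratorConfig, volume_db: float,
                      seed: int | np.random.Generator,
                      subject_id: str = "sub-01") -> pd.DataFrame:
    """Simulate trial-by-trial detection behavior on a fixed latent sequence.

    Detection probability: ``guess`` for catch trials, otherwise a
    lapse-limited logistic in (snr + volume_db - alpha), plus ``delta`` when
    the favorable state is active at the onset volume and the stimulus is at
    threshold (SNR -9), plus ``gamma`` after a detected previous trial,
    clipped to [0, 1].  Reaction times for detected trials are lognormal
    with an SNR-dependent mean (slower at lower SNR).  The first trial of
    each block has no previous-detection covariate (stored as NaN).

    Returns a trial table with columns subject, block, trial, onset_s, snr,
    detected, rt_s, prev_detected, pattern_true.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lat_by_block = (latent if isinstance(latent, dict)
                    else {b: latent for b in schedule["block"].unique()})
    rows = []
    for block, sched_b in schedule.groupby("block", sort=True):
        lat = lat_by_block[block]
        prev: bool | None = None
        for rec in sched_b.sort_values("trial").itertuples():
            try:
                state = lat.state_at(rec.onset_s)
            except ValueError as exc:
                raise ValueError(f"block {block} trial {rec.trial}: {exc}") from exc
            if rec.snr == CATCH:
                p = config.guess
            else:
                p = _detect_prob(int(rec.snr), volume_db, config,
                                 favorable=(state == config.favorable_state),
                                 prev_detected=prev)
            detected = bool(rng.random() < p)
            rt = _draw_rt(rng, int(rec.snr) if rec.snr != CATCH else None) if detected else np.nan
            rows.append({"subject": subject_id, "block": block, "trial": rec.trial,
                         "onset_s": rec.onset_s, "snr": rec.snr, "detected": detected,
                         "rt_s": rt, "prev_detected": prev, "pattern_true": state})
            if rec.snr != CATCH:
                prev = detected
    return pd.DataFrame(rows)


def simulate_staircase(config: GeneratorConfig, n_trials: int,
                       seed: int | np.random.Generator) -> float:
    """One-up-one-down volume calibration at the threshold SNR (-9 dB).

    A detected trial lowers the stimulus volume by one step, an undetected
    trial raises it; the procedure converges around the 50% point of the
    observer's psychometric function.  Returns the mean volume over the
    reversal points after discarding the first 20% of reversals.
    """
    if n_trials < 50:
        raise ValueError("staircase needs n_trials >= 50")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    level = config.staircase_start_db
    step = config.staircase_step_db
    if step == 0:
        return level
    levels_at_reversal = []
    prev_dir = 0
    for _ in range(n_trials):
        p = (1.0 - config.lapse) * expit(config.beta * (-9 + level - config.alpha))
        detected = rng.random() < p
        direction = -1 if detected else +1
        if prev_dir != 0 and direction != prev_dir:
            levels_at_reversal.append(level)
        prev_dir = direction
        level += direction * step
    if not levels_at_reversal:
        raise ValueError("no reversal observed; increase n_trials")
    keep = levels_at_reversal[int(np.ceil(0.2 * len(levels_at_reversal))):]
    if not keep:
        keep = levels_at_reversal
    return float(np.mean(keep))


# ---------------------------------------------------------------------------
# surrogates and ratings
# ---------------------------------------------------------------------------

def circular_shift_surrogate(ts: RoiTimeSeries, seed: int | np.random.Generator,
                             offsets: np.ndarray | None = None) -> RoiTimeSeries:
    """Null data preserving each ROI's internal temporal structure.

    Every ROI column is independently rotated by a uniform random circular
    offset in 1..T-1 (wrap-around), which destroys inter-ROI alignment while
    leaving each column's value multiset and circular autocorrelation
    untouched.  ``offsets`` overrides the random draw (test hook; zeros give
    back the input).
    """
    t, p = ts.data.shape
    if t < 2:
        raise ValueError("need at least 2 volumes")
    if offsets is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        offsets = rng.integers(1, t, size=p)
    offsets = np.asarray(offsets, dtype=int) % t
    rows = (np.arange(t)[:, None] - offsets[None, :]) % t
    data = ts.data[rows, np.arange(p)[None, :]]
    return RoiTimeSeries(data=data, tr=ts.tr, subject_id=ts.subject_id,
                         run_label="surrogate", roi_names=list(ts.roi_names))


def make_ratings(occupancy: pd.DataFrame, config: GeneratorConfig,
                 seed: int | np.random.Generator) -> pd.DataFrame:
    """Block-level subjective ratings (1..7) tied to tired-state occupancy.

    ``occupancy`` needs columns subject, block, tired_occupancy (fraction of
    the block's volumes spent in the tired state, in [0, 1]).  Tiredness is
    a noisy monotone map of that occupancy discretized to 1..7; success and
    focus are weakly anti-associated with it, with more noise.
    """
    if np.any((occupancy["tired_occupancy"] < 0) | (occupancy["tired_occupancy"] > 1)):
        raise ValueError("tired_occupancy must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    occ = occupancy["tired_occupancy"].to_numpy()
    n = len(occ)
    sd = config.rating_noise_sd

    def discretize(raw: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(raw), 1, 7).astype(int)

    tired = discretize(1 + 6 * occ + rng.normal(0, sd, n))
    success = discretize(6 - 3 * occ + rng.normal(0, 1.5 * sd, n))
    focus = discretize(6 - 3 * occ + rng.normal(0, 1.5 * sd, n))
    out = occupancy[["subject", "block"]].copy()
    out["tiredness"] = tired
    out["success"] = success
    out["focus"] = focus
    return out


# ---------------------------------------------------------------------------
# coupled task simulation and the full dataset
# ---------------------------------------------------------------------------

def simulate_coupled_block(config: GeneratorConfig, block_schedule: pd.DataFrame,
                           volume_db: float, seed: int | np.random.Generator,
                           subject_id: str = "sub-01"
                           ) -> tuple[LatentStateSequence, pd.DataFrame]:
    """Jointly simulate one block's latent states and trial outcomes.

    Unlike :func:`simulate_observer` (fixed latent sequence), detection here
    feeds back into the dynamics: for ``bias_window`` volumes after a
    detected stimulus, a fraction ``post_detection_bias`` of each
    transition row's mass is moved onto the favorable state, so detected
    trials are followed by elevated favorable-state occupancy.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sched = block_schedule.sort_values("trial")
    block = int(sched["block"].iloc[0])
    n_volumes = int(np.ceil(sched["onset_s"].max())) + config.bias_window + 7
    m = config.transition_matrix
    k = config.n_states
    fav = config.favorable_state - 1
    b = config.post_detection_bias
    m_biased = (1 - b) * m.copy()
    m_biased[:, fav] += b

    cum = np.cumsum(m, axis=1)
    cum_biased = np.cumsum(m_biased, axis=1)
    onsets = sched["onset_s"].to_numpy(float)
    trial_nums = sched["trial"].to_numpy(int)
    snrs = sched["snr"].tolist()
    onset_vol = np.floor(onsets / config.tr).astype(int)
    trial_at_vol = {v: i for i, v in enumerate(onset_vol)}

    states = np.empty(n_volumes, dtype=int)
    pi = np.cumsum(config.stationary_distribution())
    states[0] = min(int(np.searchsorted(pi, rng.random())), k - 1) + 1
    rows: list[dict] = [{} for _ in range(len(sched))]
    prev: bool | None = None
    bias_until = -1

    def run_trial(i: int, vol: int) -> None:
        nonlocal prev, bias_until
        snr = snrs[i]
        state = int(states[vol])
        if snr == CATCH:
            p = config.guess
        else:
            p = _detect_prob(int(snr), volume_db, config,
                             favorable=(state == config.favorable_state),
                             prev_detected=prev)
        detected = bool(rng.random() < p)
        rt = _draw_rt(rng, int(snr) if snr != CATCH else None) if detected else np.nan
        rows[i] = {"subject": subject_id, "block": block, "trial": int(trial_nums[i]),
                   "onset_s": float(onsets[i]), "snr": snr, "detected": detected,
                   "rt_s": rt, "prev_detected": prev, "pattern_true": state}
        if detected and snr != CATCH:
            bias_until = vol + config.bias_window
        if snr != CATCH:
            prev = detected

    if 0 in trial_at_vol:
        run_trial(trial_at_vol[0], 0)
    u = rng.random(n_volumes)
    for t in range(1, n_volumes):
        row = cum_biased[states[t - 1] - 1] if t <= bias_until else cum[states[t - 1] - 1]
        states[t] = min(int(np.searchsorted(row, u[t])), k - 1) + 1
        if t in trial_at_vol:
            run_trial(trial_at_vol[t], t)
    latent = LatentStateSequence(states=states, tr=config.tr)
    return latent, pd.DataFrame(rows)


@dataclass
class SimulatedDataset:
    """Everything one simulated study session produces, for all subjects."""

    config: GeneratorConfig
    rest: dict[str, RoiTimeSeries]                      # subject -> run
    rest_latent: dict[str, LatentStateSequence]
    task: dict[tuple[str, int], RoiTimeSeries]          # (subject, block) -> run
    task_latent: dict[tuple[str, int], LatentStateSequence]
    trials: pd.DataFrame
    ratings: pd.DataFrame
    volume_db: dict[str, float]                         # per-subject staircase result

    @property
    def subjects(self) -> list[str]:
        return sorted(self.rest)


def simulate_dataset(config: GeneratorConfig, seed: int | None = None,
                     include_bold: bool = True) -> SimulatedDataset:
    """Simulate the whole study: rest runs, staircases, task blocks, ratings.

    Per subject: a resting-state run of ``rest_volumes`` volumes; a
    one-up-one-down staircase (300 trials) fixing the stimulus volume; six
    task blocks simulated with detection-coupled dynamics; and post-block
    ratings driven by the tired state's occupancy.  All randomness fans out
    from one master seed through tagged child generators.  ``include_bold``
    False skips ROI-signal synthesis (behavior-only studies run much faster).
    """
    master = config.rng_seed if seed is None else seed
    rest: dict[str, RoiTimeSeries] = {}
    rest_latent: dict[str, LatentStateSequence] = {}
    task: dict[tuple[str, int], RoiTimeSeries] = {}
    task_latent: dict[tuple[str, int], LatentStateSequence] = {}
    all_trials = []
    occ_rows = []
    volume_db: dict[str, float] = {}
    for s in range(1, config.n_subjects + 1):
        sid = f"sub-{s:02d}"
        lat = make_latent_states(config, config.rest_volumes,
                                 child_rng(master, f"{sid}/rest/latent"))
        rest_latent[sid] = lat
        if include_bold:
            rest[sid] = make_bold(lat, config, child_rng(master, f"{sid}/rest/bold"),
                                  subject_id=sid, run_label="rest")
        else:
            rest[sid] = None  # type: ignore[assignment]
        volume_db[sid] = simulate_staircase(config, 300,
                                            child_rng(master, f"{sid}/staircase"))
        schedule = make_schedule(config, child_rng(master, f"{sid}/schedule"))
        for block, sched_b in schedule.groupby("block", sort=True):
            lat_b, trials_b = simulate_coupled_block(
                config, sched_b, volume_db[sid],
                child_rng(master, f"{sid}/task/{block}"), subject_id=sid)
            task_latent[(sid, int(block))] = lat_b
            if include_bold:
                task[(sid, int(block))] = make_bold(
                    lat_b, config, child_rng(master, f"{sid}/task/{block}/bold"),
                    subject_id=sid, run_label="task")
            all_trials.append(trials_b)
            occ_rows.append({"subject": sid, "block": int(block),
                             "tired_occupancy": float(np.mean(
                                 lat_b.states == config.tired_state))})
    occupancy = pd.DataFrame(occ_rows)
    ratings = make_ratings(occupancy, config, child_rng(master, "ratings"))
    return SimulatedDataset(config=config, rest=rest, rest_latent=rest_latent,
                            task=task, task_latent=task_latent,
                            trials=pd.concat(all_trials, ignore_index=True),
                            ratings=ratings, volume_db=volume_db)
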
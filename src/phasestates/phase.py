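"""Per-volume phase-coherence connectivity.

Converts ROI-by-time BOLD-like signals into a series of instantaneous
phases (analytic signal of each demeaned ROI column) and then into
per-volume connectivity vectors: for each unordered ROI pair (i, j) the
cosine of the instantaneous phase difference, cos(theta_i - theta_j),
bounded in [-1, 1].  With P ROIs each volume lives in a
D = P(P-1)/2-dimensional coherence space (861 dimensions for P = 42).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import hilbert

__all__ = [
    "RoiTimeSeries",
    "PhaseSeries",
    "CoherenceSeries",
    "instantaneous_phase",
    "coherence_series",
    "pair_index",
    "matrix_from_vector",
    "vector_from_matrix",
    "read_roi_tsv",
    "write_roi_tsv",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RoiTimeSeries:
    """One run's T x P ROI signal matrix.

    Parameters
    ----------
    data : ndarray, shape (T, P)
        Real-valued signals, arbitrary units. Must be finite, T >= 3, P >= 2.
    tr : float
        Repetition time (volume sampling interval) in seconds.
    subject_id : str
        Subject label.
    run_label : str
        One of "rest", "task", "surrogate" (free-form accepted).
    roi_names : list of str, optional
        P labels; defaults to roi_001..roi_P.
    """

    data: np.ndarray
    tr: float
    subject_id: str = "sub-01"
    run_label: str = "rest"
    roi_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (T, P) array")
        t, p = self.data.shape
        if t < 3 or p < 2:
            raise ValueError(f"need T >= 3 and P >= 2, got T={t}, P={p}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in ROI time series")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not self.roi_names:
            self.roi_names = [f"roi_{i + 1:03d}" for i in range(p)]
        elif len(self.roi_names) != p:
            raise ValueError("roi_names length does not match column count")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Acquisition start time of each volume, in seconds."""
        return np.arange(self.n_volumes) * self.tr


@dataclass
class PhaseSeries:
    """T x P instantaneous phases in [-pi, pi], metadata carried through."""

    phases: np.ndarray
    tr: float
    subject_id: str = "sub-01"
    run_label: str = "rest"

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if np.any(self.phases < -np.pi) or np.any(self.phases > np.pi):
            raise ValueError("phases outside [-pi, pi]")


@dataclass
class CoherenceSeries:
    """T x D per-volume coherence vectors, D = P(P-1)/2.

    ``pairs`` fixes the vectorization order: row-major upper triangle,
    (i, j) with i < j, so centroid files are portable across runs.
    """

    vectors: np.ndarray
    pairs: list[tuple[int, int]]
    tr: float
    subject_id: str = "sub-01"
    run_label: str = "rest"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        d = self.vectors.shape[1]
        if len(self.pairs) != d:
            raise ValueError("pair index length does not match vector dimension")

    @property
    def n_volumes(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_rois(self) -> int:
        # D = P(P-1)/2  =>  P = (1 + sqrt(1 + 8D)) / 2
        d = self.vectors.shape[1]
        p = int(round((1 + np.sqrt(1 + 8 * d)) / 2))
        return p


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def instantaneous_phase(ts: RoiTimeSeries, bandpass: tuple[float, float] | None = None,
                        trim: int = 0) -> PhaseSeries:
    """Instantaneous phase of each ROI via the analytic signal.

    Each column is demeaned, Hilbert-transformed into its complex analytic
    representation, and the four-quadrant angle taken, which wraps into
    [-pi, pi] by construction.

    Parameters
    ----------
    bandpass : (low_hz, high_hz), optional
        Off by default (the coherence analysis is run on the unfiltered
        series).  When given, a zero-phase 4th-order Butterworth band-pass
        is applied after demeaning.
    trim : int, optional
        Drop this many volumes from each end of the run after the phase is
        computed, discarding the Hilbert edge transients at the cost of
        shortening the series.  Off (0) by default, preserving the run's
        volume count.

    Raises
    ------
    ValueError
        If a column has zero variance (phase undefined), naming the ROI.
    """
    x = ts.data - ts.data.mean(axis=0, keepdims=True)
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.roi_names[i] for i in dead)
        raise ValueError(f"constant signal, instantaneous phase undefined for ROI(s): {names}")
    if bandpass is not None:
        from scipy.signal import butter, filtfilt
        nyquist = 0.5 / ts.tr
        b, a = butter(4, [bandpass[0] / nyquist, bandpass[1] / nyquist], btype="band")
        x = filtfilt(b, a, x, axis=0)
    analytic = hilbert(x, axis=0)
    phases = np.angle(analytic)
    if trim > 0:
        if 2 * trim >= phases.shape[0]:
            raise ValueError("trim removes the whole run")
        phases = phases[trim:-trim]
    return PhaseSeries(phases=phases, tr=ts.tr,
                       subject_id=ts.subject_id, run_label=ts.run_label)


def pair_index(p: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle pair ordering (i, j), i < j, 0-based."""
    return [(i, j) for i in range(p) for j in range(i + 1, p)]


def coherence_series(ph: PhaseSeries) -> CoherenceSeries:
    """Per-volume pairwise phase coherence: cos(theta_i - theta_j).

    Computed for all P(P-1)/2 unordered ROI pairs at every volume; entries
    lie in [-1, 1] and are invariant to adding a common phase constant to
    all ROIs at a time point.
    """
    t, p = ph.phases.shape
    iu, ju = np.triu_indices(p, k=1)
    vec = np.cos(ph.phases[:, iu] - ph.phases[:, ju])
    return CoherenceSeries(vectors=vec, pairs=list(zip(iu.tolist(), ju.tolist())),
                           tr=ph.tr, subject_id=ph.subject_id, run_label=ph.run_label)


def matrix_from_vector(v: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    """Rebuild the symmetric unit-diagonal P x P coherence matrix from a vector."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size != len(pairs):
        raise ValueError(f"vector length {v.size} does not match pair index length {len(pairs)}")
    p = max(j for _, j in pairs) + 1
    m = np.eye(p)
    for val, (i, j) in zip(v, pairs):
        m[i, j] = val
        m[j, i] = val
    return m


def vector_from_matrix(m: np.ndarray, pairs: list[tuple[int, int]] | None = None) -> np.ndarray:
    """Inverse of :func:`matrix_from_vector`; round-trips bit-exactly."""
    m = np.asarray(m, dtype=float)
    p = m.shape[0]
    if pairs is None:
        pairs = pair_index(p)
    return np.array([m[i, j] for i, j in pairs])


# ---------------------------------------------------------------------------
# text I/O (TSV with a time column; the format synth writes)
# ---------------------------------------------------------------------------

def write_roi_tsv(ts: RoiTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.data, columns=ts.roi_names)
    df.insert(0, "time_s", ts.times)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_roi_tsv(path: str | Path, subject_id: str = "sub-01",
                 run_label: str = "rest") -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: expected a time_s column")
    times = df.pop("time_s").to_numpy()
    tr = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    return RoiTimeSeries(data=df.to_numpy(), tr=tr, subject_id=subject_id,
                         run_label=run_label, roi_names=list(df.columns))
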
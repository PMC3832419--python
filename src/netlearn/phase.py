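"""Instantaneous phases and windowed mean-phase-coherence matrices.

The interdependence measure is the *mean phase coherence* (MPC)

.. math::

    R_{jk} = \\Bigl| \\frac{1}{T} \\sum_{t=0}^{T-1}
             e^{\\,i[\\phi_j(t) - \\phi_k(t)]} \\Bigr| \\in [0, 1],

the modulus of the time-averaged unit phasor of the instantaneous phase
difference between channels *j* and *k*.  R = 1 means perfect phase locking;
for independent phases R fluctuates around the Rayleigh level
:math:`\\sqrt{\\pi/(4T)}`.

Instantaneous phases come from the analytic signal (Hilbert transform) of the
mean-subtracted channel.  The phase is computed once over the whole task
segment and only then split into windows, so Hilbert edge artifacts occur at
the two segment ends rather than at every window join.  No band-pass filter
is applied beyond the recorded bandwidth: the analytic phase tracks each
channel's predominant rhythm adaptively rather than a fixed band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .exceptions import DegenerateInputError, ParameterError, ShapeError
from .io import Recording

__all__ = [
    "SyncMatrix",
    "segment_windows",
    "instantaneous_phase",
    "mean_phase_coherence",
    "sync_matrices",
    "rayleigh_level",
    "save_sync_matrices",
    "load_sync_matrices",
]

#: interval length used throughout the analysis (seconds)
DEFAULT_WINDOW_S = 16.1

MIN_PHASE_SAMPLES = 16


@dataclass
class SyncMatrix:
    """Symmetric matrix of mean-phase-coherence values for one time window.

    Off-diagonal entries lie in [0, 1]; the diagonal is set to 1 by
    convention (a channel is trivially locked to itself) and is never used by
    the network construction.
    """

    values: np.ndarray
    window_index: int
    n_samples: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ShapeError(f"sync matrix must be square, got {v.shape}")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def segment_windows(n_samples: int, fs: float, window_s: float = DEFAULT_WINDOW_S
                    ) -> list[range]:
    """Partition ``n_samples`` into consecutive non-overlapping windows.

    Each window holds ``floor(window_s * fs)`` samples, starting at index 0;
    the trailing remainder is discarded.  A 3-minute task at 254.31 Hz with
    16.1-s windows gives 11 windows; a 5-minute baseline gives 18.
    """
    if window_s <= 0:
        raise ParameterError(f"window_s must be positive, got {window_s}")
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    if n_samples < 0:
        raise ParameterError(f"n_samples must be non-negative, got {n_samples}")
    width = int(np.floor(window_s * fs))
    if width == 0:
        raise ParameterError(f"window of {window_s} s holds no samples at fs={fs}")
    n_windows = n_samples // width
    return [range(w * width, (w + 1) * width) for w in range(n_windows)]


def instantaneous_phase(signal: np.ndarray) -> np.ndarray:
    """Phase of the analytic signal, in (-pi, pi], after mean subtraction.

    The mean is removed first: a DC offset adds a constant to the analytic
    signal and corrupts the phase of every sample.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ShapeError("instantaneous_phase expects a 1-D signal")
    if x.size < MIN_PHASE_SAMPLES:
        raise DegenerateInputError(
            f"signal of {x.size} samples; need at least {MIN_PHASE_SAMPLES}")
    x = x - x.mean()
    if not np.any(x):
        raise DegenerateInputError("all-zero signal has no defined phase")
    return np.angle(hilbert(x))


def mean_phase_coherence(phi_a: np.ndarray, phi_b: np.ndarray) -> float:
    """Mean phase coherence of two phase series (radians), a scalar in [0, 1]."""
    phi_a = np.asarray(phi_a, dtype=float)
    phi_b = np.asarray(phi_b, dtype=float)
    if phi_a.shape != phi_b.shape or phi_a.ndim != 1:
        raise ShapeError(
            f"phase series must be 1-D and equal length, got {phi_a.shape} vs {phi_b.shape}")
    if phi_a.size < 2:
        raise DegenerateInputError("need at least 2 samples for a temporal average")
    phasor = np.exp(1j * (phi_a - phi_b))
    return float(np.abs(phasor.mean()))


def rayleigh_level(t: int) -> float:
    """Expected MPC of two independent uniform phase series of length ``t``.

    The resultant of ``t`` i.i.d. unit phasors has, for large ``t``, a Rayleigh
    distributed modulus with mean ``sqrt(pi * t) / 2``; dividing by ``t`` gives
    ``sqrt(pi / (4 t))``.  Useful as the noise floor of an R estimate.
    """
    if t < 1:
        raise ParameterError("t must be >= 1")
    return float(np.sqrt(np.pi / (4.0 * t)))


def sync_matrices(segment: Recording, window_s: float = DEFAULT_WINDOW_S
                  ) -> list[SyncMatrix]:
    """Per-window MPC matrices for all channel pairs of a task segment.

    Phases are extracted once over the full segment; each window's matrix is
    ``R = |Z_w Z_w^H| / T_w`` where ``Z_w`` holds the unit phasors
    ``exp(i phi)`` of that window — algebraically identical to applying
    :func:`mean_phase_coherence` to every pair, but one matrix product.
    Returns an empty list when the segment is shorter than one window.
    """
    windows = segment_windows(segment.n_samples, segment.fs, window_s)
    if not windows:
        return []
    x = segment.data - segment.data.mean(axis=1, keepdims=True)
    if x.shape[1] < MIN_PHASE_SAMPLES:
        raise DegenerateInputError(
            f"segment of {x.shape[1]} samples; need at least {MIN_PHASE_SAMPLES}")
    dead = ~np.any(x, axis=1)
    if dead.any():
        raise DegenerateInputError(
            f"all-zero channel(s) {np.flatnonzero(dead).tolist()} have no defined phase")
    # batched analytic signal; its unit phasor is exp(i * instantaneous phase)
    analytic = hilbert(x, axis=-1)
    z_all = analytic / np.abs(analytic)
    out = []
    for w, rng in enumerate(windows):
        z = z_all[:, rng.start:rng.stop]
        r = np.abs(z @ z.conj().T) / len(rng)
        r = 0.5 * (r + r.T)          # enforce exact symmetry against fp noise
        np.fill_diagonal(r, 1.0)
        np.clip(r, 0.0, 1.0, out=r)
        out.append(SyncMatrix(values=r, window_index=w, n_samples=len(rng)))
    return out


def save_sync_matrices(mats: list[SyncMatrix], directory, subject: str,
                       task: str) -> list:
    """Write one CSV per window, named ``{subject}_{task}_{window:03d}.csv``.

    The file body is the full N x N matrix; the sample count is kept in a
    ``# n_samples=`` comment line so a round trip is lossless.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in mats:
        path = directory / f"{subject}_{task}_{m.window_index:03d}.csv"
        header = f"n_samples={m.n_samples}"
        np.savetxt(path, m.values, delimiter=",", fmt="%.17g", header=header)
        paths.append(path)
    return paths


def load_sync_matrices(directory, subject: str, task: str) -> list[SyncMatrix]:
    """Read back matrices written by :func:`save_sync_matrices`, in window order."""
    from pathlib import Path

    directory = Path(directory)
    out = []
    for path in sorted(directory.glob(f"{subject}_{task}_*.csv")):
        window = int(path.stem.rsplit("_", 1)[1])
        n_samples = 0
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#") and "n_samples=" in first:
                n_samples = int(first.split("n_samples=")[1])
        values = np.loadtxt(path, delimiter=",")
        out.append(SyncMatrix(values=values, window_index=window,
                              n_samples=n_samples))
    return out
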
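"""Synthetic study cohorts with task-modulated phase coupling.

The generator emulates the structure the analysis chain is built to detect,
with the ground truth living in *phase space* (the pipeline measures phase
synchronization, so amplitude mixing would test the wrong thing):

* channels are noisy oscillators grouped into frequency communities; each
  community carries one predominant rhythm drawn from 4-20 Hz, and phase
  coupling is implemented as shared phase-wander: a channel's phase is
  ``2*pi*f*t`` plus a weighted sum of a community wander process, a
  sub-cluster wander process and a private wander process (all
  Ornstein-Uhlenbeck), with weights summing to a fixed total phase variance.
  The fraction of shared wander variance is the coupling strength; the mean
  phase coherence of a pair increases monotonically with it.
* each community is split into two *sub-clusters*.  During the intentional
  learning task (L2) the sub-cluster wander gains weight
  ``effect_delta * max(0, 1 + ability_z)`` for a subject with latent ability
  ``ability_z``, so edges of the thresholded network reallocate toward
  triangle-rich sub-cliques *within* communities while the (repaired)
  inter-community bridges stay put: the clustering coefficient rises with
  ability, the average shortest path length barely moves.  Incidental
  learning (L1) applies no modulation by default.
* free-recall scores are linear in the same latent ability plus noise, with
  group offsets (controls above patients) sized so the four group recall
  means land on the study's observed scale (about 9.1/11.5 words for
  controls, 5.6/7.7 for patients, ceiling 15).

Per-subject randomness is derived from the master seed and the subject index
only, so a subject's data do not depend on how many other subjects are
generated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import json

import numpy as np
from scipy.signal import lfilter

from .exceptions import ParameterError
from .io import (
    Recording,
    SubjectRecord,
    TaskSchedule,
    write_behavior,
    write_recording,
    write_schedule,
)

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "SubjectBundle",
    "generate_subject",
    "generate_cohort",
    "coupled_pair",
    "write_cohort",
    "make_fixture_spec",
]

#: study cohort composition: 20 controls, 13 epilepsy patients
DEFAULT_GROUP_SIZES = (20, 13)

#: latent-ability group offsets (controls, patients); with the recall model
#: below they reproduce the observed group recall means
GROUP_ABILITY_OFFSETS = {"control": 0.6, "patient": -0.9}

#: recall model: intercept + slope * ability_z (+ noise), per retrieval task
RECALL_MODEL = {"intentional": (10.0, 2.5), "incidental": (7.7, 2.33)}

RECALL_CEILING = 15


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults reproduce the study conditions: 33 subjects (20 controls + 13
    patients), 29 scalp channels at 254.31 Hz, a 5-minute baseline and two
    3-minute learning tasks.  ``effect_delta`` is the intentional-learning
    coupling increase for an average-ability subject; its default is
    calibrated so the ground-truth correlation between ability and the
    clustering-coefficient deviation during L2 is about 0.6.
    """

    n_subjects: int = 33
    n_channels: int = 29
    fs: float = 254.31
    duration_B: float = 300.0
    duration_L1: float = 180.0
    duration_L2: float = 180.0
    gap_s: float = 5.0                 # rest gap between tasks
    n_communities: int = 2
    base_coupling: float = 0.30        # shared-wander fraction within a community
    effect_delta: float = 0.10         # L2 sub-cluster coupling gain at ability 0
    l1_effect_delta: float = 0.0       # incidental learning leaves networks alone
    ability_sd: float = 0.8            # latent-ability spread within a group
    noise_sd: float = 1.8              # recall-score noise, in words
    seed: int = 0
    # oscillator nuisance parameters
    phase_wander_sd: float = 1.5       # stationary phase-wander sd, radians
    wander_tau_s: float = 0.35         # OU correlation time, seconds
    measurement_noise: float = 0.4     # additive white noise relative to amplitude 1
    min_freq_sep_hz: float = 2.0       # spacing between community rhythms

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if self.n_channels < 4:
            raise ParameterError("need at least 4 channels for community structure")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if not 0 <= self.base_coupling < 1:
            raise ParameterError("base_coupling must be in [0, 1)")
        if self.effect_delta < 0 or self.l1_effect_delta < 0:
            raise ParameterError("effect deltas must be non-negative")
        if self.n_communities < 1 or self.n_communities > self.n_channels // 2:
            raise ParameterError("n_communities incompatible with n_channels")
        for name in ("duration_B", "duration_L1", "duration_L2"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.ability_sd < 0 or self.noise_sd < 0:
            raise ParameterError("ability_sd and noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Generative ground truth of one subject."""

    ability_z: float
    group: str
    community: np.ndarray          # community index per channel
    subcluster: np.ndarray         # sub-cluster index per channel (global ids)
    frequencies_hz: np.ndarray     # predominant rhythm per community
    coupling: dict                 # task -> (N, N) pairwise shared-wander fraction
    l2_boost: float                # realized sub-cluster gain during L2


@dataclass
class SubjectBundle:
    recording: Recording
    schedule: TaskSchedule
    behavior: SubjectRecord
    truth: GroundTruth


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _ou(rng: np.random.Generator, shape: tuple[int, int], rho: float) -> np.ndarray:
    """Rows of a stationary unit-variance AR(1)/OU process."""
    eps = rng.standard_normal(shape)
    y0 = rng.standard_normal(shape[0])
    s = np.sqrt(1.0 - rho * rho)
    zi = (rho * y0)[:, None]
    out, _ = lfilter([s], [1.0, -rho], eps, axis=1, zi=zi)
    return out


def _community_layout(n_channels: int, n_communities: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Near-equal contiguous communities, each split into two sub-clusters."""
    sizes = [n_channels // n_communities + (1 if i < n_channels % n_communities else 0)
             for i in range(n_communities)]
    community = np.repeat(np.arange(n_communities), sizes)
    sub = np.empty(n_channels, dtype=int)
    start = 0
    for c, size in enumerate(sizes):
        half = size // 2
        sub[start:start + half] = 2 * c
        sub[start + half:start + size] = 2 * c + 1
        start += size
    return community, sub


def _community_frequencies(rng: np.random.Generator, n_communities: int,
                           min_sep: float) -> np.ndarray:
    """Predominant rhythms in 4-20 Hz with pairwise separation >= min_sep."""
    for _ in range(1000):
        f = rng.uniform(4.0, 20.0, size=n_communities)
        if n_communities == 1 or np.diff(np.sort(f)).min() >= min_sep:
            return f
    raise ParameterError(
        f"cannot place {n_communities} rhythms in 4-20 Hz with {min_sep} Hz spacing")


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(subject_index,)))


def _schedule(spec: CohortSpec) -> TaskSchedule:
    entries = []
    t = 0.0
    for label, dur in (("B", spec.duration_B), ("REST1", spec.gap_s),
                       ("L1", spec.duration_L1), ("REST2", spec.gap_s),
                       ("L2", spec.duration_L2)):
        entries.append((label, t, dur))
        t += dur
    return TaskSchedule(entries)


def _coupling_matrix(spec: CohortSpec, community: np.ndarray, sub: np.ndarray,
                     g_sub: float) -> np.ndarray:
    same_comm = community[:, None] == community[None, :]
    same_sub = sub[:, None] == sub[None, :]
    k = np.where(same_comm, spec.base_coupling + g_sub * same_sub, 0.0)
    np.fill_diagonal(k, 1.0)
    return k


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_subject(spec: CohortSpec, subject_index: int) -> SubjectBundle:
    """Generate one subject: recording, schedule, behavior and ground truth."""
    rng = _subject_rng(spec.seed, subject_index)
    n_control = int(round(spec.n_subjects * DEFAULT_GROUP_SIZES[0]
                          / sum(DEFAULT_GROUP_SIZES)))
    group = "control" if subject_index < n_control else "patient"
    z = GROUP_ABILITY_OFFSETS[group] + spec.ability_sd * rng.standard_normal()

    community, sub = _community_layout(spec.n_channels, spec.n_communities)
    freqs = _community_frequencies(rng, spec.n_communities, spec.min_freq_sep_hz)
    sched = _schedule(spec)

    # sub-cluster coupling gain per task; headroom keeps total variance fractions <= 1
    headroom = 0.95 - spec.base_coupling
    boost_l2 = float(np.clip(spec.effect_delta * max(0.0, 1.0 + z), 0.0, headroom))
    boost_l1 = float(np.clip(spec.l1_effect_delta * max(0.0, 1.0 + z), 0.0, headroom))
    g_sub_by_task = {"B": 0.0, "REST1": 0.0, "L1": boost_l1,
                     "REST2": 0.0, "L2": boost_l2}

    total_s = sched.entries[-1][1] + sched.entries[-1][2]
    n_total = int(round(total_s * spec.fs))
    rho = float(np.exp(-1.0 / (spec.wander_tau_s * spec.fs)))

    u = _ou(rng, (spec.n_communities, n_total), rho)       # community wander
    w = _ou(rng, (2 * spec.n_communities, n_total), rho)   # sub-cluster wander
    v = _ou(rng, (spec.n_channels, n_total), rho)          # private wander

    g_sub_t = np.zeros(n_total)
    for label, onset, dur in sched.entries:
        a, b = int(round(onset * spec.fs)), int(round((onset + dur) * spec.fs))
        g_sub_t[a:min(b, n_total)] = g_sub_by_task[label]
    g_comm = spec.base_coupling
    sigma = spec.phase_wander_sd
    w_comm = sigma * np.sqrt(g_comm)
    w_sub_t = sigma * np.sqrt(g_sub_t)
    w_priv_t = sigma * np.sqrt(1.0 - g_comm - g_sub_t)

    t = np.arange(n_total) / spec.fs
    amp = rng.uniform(0.7, 1.3, size=spec.n_channels)
    phi = (2.0 * np.pi * freqs[community][:, None] * t[None, :]
           + w_comm * u[community]
           + w_sub_t[None, :] * w[sub]
           + w_priv_t[None, :] * v)
    data = amp[:, None] * np.cos(phi)
    data += spec.measurement_noise * rng.standard_normal(data.shape)
    data *= 40.0  # microvolt scale typical of scalp EEG

    labels = [f"CH{i + 1:02d}" for i in range(spec.n_channels)]
    rec = Recording(data=data, fs=spec.fs, channel_labels=labels, reference="RM")

    b0_int, b1_int = RECALL_MODEL["intentional"]
    b0_inc, b1_inc = RECALL_MODEL["incidental"]
    r_int = int(np.clip(np.rint(b0_int + b1_int * z + spec.noise_sd
                                * rng.standard_normal()), 0, RECALL_CEILING))
    r_inc = int(np.clip(np.rint(b0_inc + b1_inc * z + spec.noise_sd
                                * rng.standard_normal()), 0, RECALL_CEILING))
    behavior = SubjectRecord(
        subject_id=f"S{subject_index + 1:03d}", group=group,
        recall_incidental=r_inc, recall_intentional=r_int)

    truth = GroundTruth(
        ability_z=float(z), group=group, community=community, subcluster=sub,
        frequencies_hz=freqs,
        coupling={task: _coupling_matrix(spec, community, sub, g)
                  for task, g in (("B", 0.0), ("L1", boost_l1), ("L2", boost_l2))},
        l2_boost=boost_l2,
    )
    return SubjectBundle(recording=rec, schedule=sched, behavior=behavior,
                         truth=truth)


def generate_cohort(spec: CohortSpec) -> list[SubjectBundle]:
    """Generate all subjects of a cohort (independent per-subject seeds)."""
    if spec.n_subjects < 2:
        raise ParameterError("a cohort needs at least 2 subjects")
    return [generate_subject(spec, i) for i in range(spec.n_subjects)]


def coupled_pair(coupling: float, duration_s: float, fs: float,
                 freq_hz: float = 10.0, seed: int = 0,
                 phase_wander_sd: float = 1.5, wander_tau_s: float = 0.35,
                 measurement_noise: float = 0.4) -> Recording:
    """Two oscillator channels sharing a ``coupling`` fraction of phase wander.

    Convenience generator for calibration and property tests: the mean phase
    coherence of the pair increases monotonically with ``coupling`` (0 =
    independent wander, 1 = identical phases up to measurement noise).
    """
    if not 0.0 <= coupling <= 1.0:
        raise ParameterError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    rho = float(np.exp(-1.0 / (wander_tau_s * fs)))
    shared = _ou(rng, (1, n), rho)[0]
    priv = _ou(rng, (2, n), rho)
    t = np.arange(n) / fs
    sigma = phase_wander_sd
    data = np.empty((2, n))
    for i in range(2):
        phi = (2.0 * np.pi * freq_hz * t + sigma * np.sqrt(coupling) * shared
               + sigma * np.sqrt(1.0 - coupling) * priv[i])
        data[i] = np.cos(phi)
    data += measurement_noise * rng.standard_normal(data.shape)
    return Recording(data=data * 40.0, fs=fs, channel_labels=["A", "B"],
                     reference="")


# ---------------------------------------------------------------------------
# on-disk cohorts
# ---------------------------------------------------------------------------

def write_cohort(bundles: Sequence[SubjectBundle], outdir: str | Path,
                 fmt: str = "csv") -> Path:
    """Write a cohort in the layout the pipeline reads.

    ``<outdir>/<subject>.{csv,edf}`` (+ JSON sidecar for csv),
    ``<outdir>/<subject>_schedule.csv``, ``<outdir>/behavior.csv`` and
    ``<outdir>/ground_truth.json`` (generator bookkeeping, not a pipeline
    input).
    """
    if fmt not in ("csv", "edf"):
        raise ParameterError(f"unknown recording format {fmt!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_doc = {}
    for b in bundles:
        sid = b.behavior.subject_id
        write_recording(b.recording, outdir / f"{sid}.{fmt}")
        write_schedule(b.schedule, outdir / f"{sid}_schedule.csv")
        truth_doc[sid] = {
            "ability_z": b.truth.ability_z,
            "group": b.truth.group,
            "l2_boost": b.truth.l2_boost,
            "community": b.truth.community.tolist(),
            "subcluster": b.truth.subcluster.tolist(),
            "frequencies_hz": b.truth.frequencies_hz.tolist(),
        }
    write_behavior([b.behavior for b in bundles], outdir / "behavior.csv")
    (outdir / "ground_truth.json").write_text(json.dumps(truth_doc, indent=1))
    return outdir


def make_fixture_spec(seed: int = 0) -> CohortSpec:
    """Miniature cohort for the test suite: 3 subjects, short tasks."""
    return replace(
        CohortSpec(seed=seed), n_subjects=3, n_channels=12, fs=127.155,
        duration_B=60.0, duration_L1=30.0, duration_L2=30.0, gap_s=2.0,
    )
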
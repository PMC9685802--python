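"""Synthetic multi-subject, multi-session, multi-modality BOLD cohort.

The generator plants recurrent phase-locking states: a hidden Markov chain
switches between K phase-offset patterns, each pattern putting one reference
network in phase (offset 0) and the rest of cortex in anti-phase (offset pi).
Every region oscillates at a common carrier frequency inside the resting-state
band; the state only shifts regional phases. This is the minimal process for
which the downstream state metrics have closed-form ground truth: occurrence
follows the chain's stationary distribution, lifetimes are geometric, and the
switching matrix is the transition matrix itself.

Test-retest structure is injected on the transition-matrix logits: each
subject perturbs the population matrix by N(0, sigma_between^2) and each
session adds N(0, sigma_within^2), so any smooth per-session statistic of the
dynamics has intraclass correlation close to
``sigma_between^2 / (sigma_between^2 + sigma_within^2)``.

Motion traces (smooth drift plus occasional mm-scale spikes) and
noise-compartment signals are generated alongside, and a motion-coupled
artifact can be mixed into the BOLD signal so that denoising has something
real to remove.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import MotionTrace, RoiTimeseries
from .qc import framewise_displacement

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "make_reference_networks",
    "make_state_patterns",
    "draw_dynamics",
    "stationary_distribution",
    "simulate_session",
    "simulate_motion",
    "simulate_compartments",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "ideal_state_eigenvectors",
]

#: Acquisition defaults: (name, TR seconds, volumes per 8-minute run) for the
#: single-band sequence and the three multiband variants.
DEFAULT_MODALITIES: tuple[tuple[str, float, int], ...] = (
    ("SB-ASSET2", 2.0, 240),
    ("MB4-ARC1", 0.75, 644),
    ("MB4-ARC2", 0.75, 645),
    ("MB6-ARC1", 0.55, 873),
)

PASSBAND = (0.008, 0.09)  # Hz, resting-state window of interest


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort."""

    n_subjects: int = 24
    n_sessions: int = 3
    modalities: tuple[tuple[str, float, int], ...] = DEFAULT_MODALITIES
    n_roi: int = 105
    n_networks: int = 7
    k_true: int = 5
    carrier_freq: float = 0.04  # Hz, inside the pass-band
    stay_prob: float = 0.95  # population per-volume self-transition
    transition_window_s: float = 6.0  # amplitude-crossfade width at state switches
    sigma_between: float = 0.5  # SD of subject-level logit perturbations
    sigma_within: float = 0.5  # SD of session-level logit perturbations
    phase_jitter_sd: float = 0.2  # radians
    obs_noise_sd: float = 0.2  # signal units (carrier amplitude is 1)
    motion_spike_rate: float = 0.01  # per volume
    motion_drift_amplitude: float = 0.05  # mm
    artifact_gain: float = 0.0  # signal units per mm of FD; > 0 couples motion into BOLD
    n_compartments: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sessions", "n_roi", "n_networks", "k_true"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = PASSBAND
        if not lo < self.carrier_freq < hi:
            raise ValueError(f"carrier_freq must lie strictly inside {PASSBAND} Hz")
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise ValueError("sigma_between and sigma_within must be >= 0")
        if not 0 < self.stay_prob < 1:
            raise ValueError("stay_prob must be in (0, 1)")
        for name, tr, t in self.modalities:
            if tr <= 0 or t < 2:
                raise ValueError(f"modality {name!r}: TR must be > 0 and T >= 2")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline has to recover."""

    state_patterns: np.ndarray  # (k_true, n_roi) phase offsets, radians
    reference_networks: np.ndarray  # (n_roi, n_networks) weights
    subject_base_dynamics: np.ndarray  # (n_subjects, K, K)
    session_dynamics: np.ndarray  # (n_subjects, n_sessions, K, K)
    target_icc: float
    state_sequences: dict = field(default_factory=dict)  # key -> true labels (1-based)


@dataclass
class SyntheticCohort:
    config: CohortConfig
    timeseries: dict  # (subject, session, modality) -> RoiTimeseries
    motion: dict  # same keys -> MotionTrace
    noise_compartments: dict  # same keys -> (M, T) arrays
    ground_truth: GroundTruth

    def keys(self):
        return self.timeseries.keys()

    def runs(self, modality: str | None = None):
        """Iterate (key, RoiTimeseries), optionally restricted to one modality."""
        for key, ts in self.timeseries.items():
            if modality is None or key[2] == modality:
                yield key, ts


def make_reference_networks(
    n_roi: int, n_networks: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Partition ``n_roi`` regions into disjoint network blocks with positive weights.

    Mirrors reference functional networks expressed as length-N weight vectors:
    each region contributes to exactly one network. Block sizes are drawn at
    random but every network keeps at least 3 regions.
    """
    if n_networks < 2:
        raise ValueError("need at least 2 networks for correlation-based matching")
    if n_networks > n_roi:
        raise ValueError("n_networks cannot exceed n_roi")
    if n_roi < 3 * n_networks:
        raise ValueError("need at least 3 ROIs per network")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    # near-equal blocks: balanced communities keep planted states equally separated
    sizes = np.full(n_networks, n_roi // n_networks, dtype=int)
    sizes[: n_roi % n_networks] += 1
    weights = np.zeros((n_roi, n_networks))
    start = 0
    for j, size in enumerate(sizes):
        block = slice(start, start + size)
        weights[block, j] = rng.uniform(0.5, 1.5, size=size)
        start += size
    return weights


def make_state_patterns(reference_networks: np.ndarray, k_true: int) -> np.ndarray:
    """Phase-offset pattern per planted state.

    State ``j`` puts the regions of network ``j`` in phase (offset 0) and all
    other regions in anti-phase (offset pi), so the ideal phase-locking matrix
    of state ``j`` is +1 within the network community and -1 across.
    """
    reference_networks = np.asarray(reference_networks, dtype=float)
    n_roi, n_networks = reference_networks.shape
    if k_true > n_networks:
        raise ValueError("k_true cannot exceed the number of reference networks")
    patterns = np.full((k_true, n_roi), np.pi)
    for j in range(k_true):
        patterns[j, reference_networks[:, j] > 0] = 0.0
    return patterns


def ideal_state_eigenvectors(state_patterns: np.ndarray) -> np.ndarray:
    """Leading eigenvector of each state's noise-free phase-locking matrix.

    With offsets in {0, pi} the ideal matrix is the rank-1 outer product of the
    sign vector ``s_i = cos(offset_i)``; its unit leading eigenvector is
    ``s / sqrt(N)``, sign-normalized so that at most half the entries are
    strictly positive.
    """
    s = np.cos(np.asarray(state_patterns, dtype=float))
    s = np.where(s >= 0, 1.0, -1.0)
    vecs = s / np.sqrt(s.shape[1])
    out = np.empty_like(vecs)
    for i, v in enumerate(vecs):
        if (v > 0).sum() > v.size / 2:
            v = -v
        out[i] = v
    return out


def _population_transition_matrix(k: int, stay_prob: float) -> np.ndarray:
    p = np.full((k, k), (1.0 - stay_prob) / (k - 1)) if k > 1 else np.ones((1, 1))
    if k > 1:
        np.fill_diagonal(p, stay_prob)
    return p


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def draw_dynamics(
    config: CohortConfig, seed: int | np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Draw per-subject and per-session transition matrices.

    The population matrix's row logits are perturbed by subject-level
    N(0, sigma_between^2) noise and then session-level N(0, sigma_within^2)
    noise; rows are renormalized through a softmax, so every draw is a proper
    stochastic matrix. The implied variance-ratio target
    ``sigma_between^2 / (sigma_between^2 + sigma_within^2)`` is returned as the
    cohort's target intraclass correlation (NaN when both SDs are zero).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    k = config.k_true
    base_logits = np.log(_population_transition_matrix(k, config.stay_prob))
    n_s, n_v = config.n_subjects, config.n_sessions
    subj_logits = base_logits + config.sigma_between * rng.standard_normal((n_s, k, k))
    sess_logits = subj_logits[:, None] + config.sigma_within * rng.standard_normal(
        (n_s, n_v, k, k)
    )
    subject_base = _softmax_rows(subj_logits)
    session = _softmax_rows(sess_logits)
    denom = config.sigma_between**2 + config.sigma_within**2
    target_icc = config.sigma_between**2 / denom if denom > 0 else float("nan")
    return subject_base, session, target_icc


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of an ergodic Markov chain (left Perron vector)."""
    p = np.asarray(transition_matrix, dtype=float)
    w, v = np.linalg.eig(p.T)
    i = int(np.argmax(w.real))
    pi = np.abs(v[:, i].real)
    return pi / pi.sum()


def simulate_session(
    state_patterns: np.ndarray,
    transition_matrix: np.ndarray,
    tr: float,
    n_volumes: int,
    carrier_freq: float = 0.04,
    phase_jitter_sd: float = 0.0,
    obs_noise_sd: float = 0.0,
    transition_window_s: float = 6.0,
    seed: int | np.random.Generator | None = None,
    initial_state: int | None = None,
    **labels,
) -> tuple[RoiTimeseries, np.ndarray]:
    """Simulate one run: Markov state sequence driving regional phase offsets.

    Region ``i`` oscillates as ``A(t) * cos(2*pi*f*t*TR + theta_i(t) + jitter)
    + noise`` where the complex baseband ``A * exp(i*theta)`` follows the
    current state's phase offset and is crossfaded through a short amplitude
    envelope (``transition_window_s`` seconds, a moving average of the
    baseband) whenever the state switches. The crossfade makes the
    instantaneous phase step sharply at the switch instead of sweeping for a
    full carrier period — the envelope dips toward zero exactly where the
    phase is undefined, matching the amplitude-times-cosine signal model.
    Within a state the envelope is 1 and the signal is a pure cosine.
    Returns the run and the true 1-based state sequence.
    """
    patterns = np.asarray(state_patterns, dtype=float)
    p = np.asarray(transition_matrix, dtype=float)
    k = patterns.shape[0]
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    if p.shape != (k, k):
        raise ValueError("transition matrix shape must match the number of states")
    if np.max(np.abs(p.sum(axis=1) - 1.0)) > 1e-8:
        raise ValueError("transition-matrix rows must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    states = np.empty(n_volumes, dtype=int)
    if initial_state is None:
        states[0] = rng.choice(k, p=stationary_distribution(p))
    else:
        states[0] = initial_state - 1
    # draw the chain by inverse-CDF on per-row cumulative probabilities
    cdf = np.cumsum(p, axis=1)
    u = rng.random(n_volumes - 1)
    for t in range(1, n_volumes):
        states[t] = np.searchsorted(cdf[states[t - 1]], u[t - 1])

    offsets = patterns[states].T  # (n_roi, n_volumes)
    baseband = np.exp(1j * offsets)
    window = max(1, int(round(transition_window_s / tr)))
    if window > 1 and np.any(np.diff(states) != 0):
        kernel = np.ones(window) / window
        baseband = np.stack(
            [
                np.convolve(row.real, kernel, mode="same")
                + 1j * np.convolve(row.imag, kernel, mode="same")
                for row in baseband
            ]
        )
    t_axis = np.arange(n_volumes) * tr
    theta = 2 * np.pi * carrier_freq * t_axis[None, :] + np.angle(baseband)
    if phase_jitter_sd > 0:
        theta = theta + phase_jitter_sd * rng.standard_normal(theta.shape)
    x = np.abs(baseband) * np.cos(theta)
    if obs_noise_sd > 0:
        x = x + obs_noise_sd * rng.standard_normal(x.shape)
    return RoiTimeseries(x, tr=tr, **labels), states + 1


def simulate_motion(
    n_volumes: int,
    motion_spike_rate: float = 0.01,
    seed: int | np.random.Generator | None = None,
    drift_amplitude: float = 0.05,
) -> MotionTrace:
    """Smooth low-amplitude drift plus occasional 1-3 mm single-volume spikes."""
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n_volumes)
    params = np.zeros((n_volumes, 6))
    for j in range(6):
        amp = drift_amplitude if j < 3 else drift_amplitude / 100.0  # radians are small
        f1, f2 = rng.uniform(0.3, 1.5, size=2) / n_volumes
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        params[:, j] = amp * (np.sin(2 * np.pi * f1 * t + ph1) + 0.5 * np.sin(2 * np.pi * f2 * t + ph2))
    if motion_spike_rate > 0:
        spikes = rng.random(n_volumes) < motion_spike_rate
        spikes[0] = False
        for idx in np.flatnonzero(spikes):
            axis = rng.integers(0, 3)
            params[idx, axis] += rng.uniform(1.0, 3.0) * rng.choice([-1.0, 1.0])
    return MotionTrace(params)


def simulate_compartments(
    n_compartments: int,
    artifact: np.ndarray,
    tr: float,
    seed: int | np.random.Generator | None = None,
    noise_sd: float = 0.3,
) -> np.ndarray:
    """Noise-compartment signals carrying the shared artifact plus slow drift.

    Stands in for white-matter/CSF signals: each compartment loads on the
    motion-coupled artifact time course with a positive weight, adds a slow
    drift, and independent white noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(artifact.size) * tr
    drift_f = rng.uniform(0.005, 0.02)
    drift = np.sin(2 * np.pi * drift_f * t + rng.uniform(0, 2 * np.pi))
    loads_a = rng.uniform(0.5, 1.5, size=n_compartments)
    loads_d = rng.uniform(-0.5, 0.5, size=n_compartments)
    out = (
        loads_a[:, None] * artifact[None, :]
        + loads_d[:, None] * drift[None, :]
        + noise_sd * rng.standard_normal((n_compartments, artifact.size))
    )
    return out


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate the full cohort deterministically from ``config.seed``."""
    config = config or CohortConfig()
    root = np.random.SeedSequence(config.seed)
    ss_struct, ss_dyn, ss_runs = root.spawn(3)
    rng_struct = np.random.default_rng(ss_struct)

    networks = make_reference_networks(config.n_roi, config.n_networks, rng_struct)
    patterns = make_state_patterns(networks, config.k_true)
    subject_base, session_dyn, target_icc = draw_dynamics(
        config, np.random.default_rng(ss_dyn)
    )

    n_runs = config.n_subjects * config.n_sessions * len(config.modalities)
    run_seeds = ss_runs.spawn(n_runs)
    timeseries: dict = {}
    motion: dict = {}
    compartments: dict = {}
    sequences: dict = {}
    i = 0
    for s in range(config.n_subjects):
        sub = f"sub-{s + 1:02d}"
        for v in range(config.n_sessions):
            ses = f"ses-{v + 1:02d}"
            for name, tr, t_vol in config.modalities:
                rng = np.random.default_rng(run_seeds[i])
                i += 1
                ts, seq = simulate_session(
                    patterns,
                    session_dyn[s, v],
                    tr,
                    t_vol,
                    carrier_freq=config.carrier_freq,
                    phase_jitter_sd=config.phase_jitter_sd,
                    obs_noise_sd=config.obs_noise_sd,
                    transition_window_s=config.transition_window_s,
                    seed=rng,
                    subject=sub,
                    session=ses,
                    modality=name,
                )
                mot = simulate_motion(
                    t_vol,
                    config.motion_spike_rate,
                    seed=rng,
                    drift_amplitude=config.motion_drift_amplitude,
                )
                fd = framewise_displacement(mot)
                artifact = config.artifact_gain * fd
                if config.artifact_gain > 0:
                    loads = rng.uniform(0.3, 1.0, size=config.n_roi)
                    ts.data += loads[:, None] * artifact[None, :]
                comp = simulate_compartments(
                    config.n_compartments, artifact, tr, seed=rng
                )
                key = (sub, ses, name)
                timeseries[key] = ts
                motion[key] = mot
                compartments[key] = comp
                sequences[key] = seq

    truth = GroundTruth(
        state_patterns=patterns,
        reference_networks=networks,
        subject_base_dynamics=subject_base,
        session_dynamics=session_dyn,
        target_icc=target_icc,
        state_sequences=sequences,
    )
    return SyntheticCohort(config, timeseries, motion, compartments, truth)


# ---------------------------------------------------------------------------
# on-disk layout: <dir>/sub-XX/ses-YY/<modality>_bold.tsv etc., one TSV per
# matrix, plus manifest.json, networks.tsv and ground-truth tables.

_FLOAT_FMT = "%.17g"


def _write_tsv(path: Path, array: np.ndarray, index_prefix: str = "roi") -> None:
    df = pd.DataFrame(
        array,
        index=[f"{index_prefix}{i}" for i in range(array.shape[0])],
        columns=[str(j) for j in range(array.shape[1])],
    )
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _read_tsv(path: Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> Path:
    """Write the cohort to ``directory``; returns the manifest path.

    A written cohort round-trips bit-identically (values are serialized with
    17 significant digits).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: list[dict] = []
    for (sub, ses, mod), ts in cohort.timeseries.items():
        run_dir = directory / sub / ses
        run_dir.mkdir(parents=True, exist_ok=True)
        _write_tsv(run_dir / f"{mod}_bold.tsv", ts.data)
        _write_tsv(run_dir / f"{mod}_motion.tsv", cohort.motion[(sub, ses, mod)].params, "vol")
        _write_tsv(
            run_dir / f"{mod}_compartments.tsv",
            cohort.noise_compartments[(sub, ses, mod)],
            "comp",
        )
        files.append({"subject": sub, "session": ses, "modality": mod, "tr": ts.tr})
    _write_tsv(directory / "networks.tsv", cohort.ground_truth.reference_networks)

    truth = cohort.ground_truth
    truth_blob = {
        "state_patterns": truth.state_patterns.tolist(),
        "subject_base_dynamics": truth.subject_base_dynamics.tolist(),
        "session_dynamics": truth.session_dynamics.tolist(),
        "target_icc": None if np.isnan(truth.target_icc) else truth.target_icc,
        "state_sequences": {
            "|".join(k): np.asarray(v).tolist() for k, v in truth.state_sequences.items()
        },
    }
    (directory / "ground_truth.json").write_text(json.dumps(truth_blob))

    manifest = {
        "config": dataclasses.asdict(cohort.config),
        "seed": cohort.config.seed,
        "files": files,
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cfg_dict = dict(manifest["config"])
    cfg_dict["modalities"] = tuple(tuple(m) for m in cfg_dict["modalities"])
    config = CohortConfig(**cfg_dict)
    timeseries: dict = {}
    motion: dict = {}
    compartments: dict = {}
    for rec in manifest["files"]:
        sub, ses, mod = rec["subject"], rec["session"], rec["modality"]
        run_dir = directory / sub / ses
        timeseries[(sub, ses, mod)] = RoiTimeseries(
            _read_tsv(run_dir / f"{mod}_bold.tsv"),
            tr=rec["tr"],
            subject=sub,
            session=ses,
            modality=mod,
        )
        motion[(sub, ses, mod)] = MotionTrace(_read_tsv(run_dir / f"{mod}_motion.tsv"))
        compartments[(sub, ses, mod)] = _read_tsv(run_dir / f"{mod}_compartments.tsv")
    networks = _read_tsv(directory / "networks.tsv")
    blob = json.loads((directory / "ground_truth.json").read_text())
    truth = GroundTruth(
        state_patterns=np.asarray(blob["state_patterns"]),
        reference_networks=networks,
        subject_base_dynamics=np.asarray(blob["subject_base_dynamics"]),
        session_dynamics=np.asarray(blob["session_dynamics"]),
        target_icc=float("nan") if blob["target_icc"] is None else blob["target_icc"],
        state_sequences={
            tuple(k.split("|")): np.asarray(v, dtype=int)
            for k, v in blob["state_sequences"].items()
        },
    )
    return SyntheticCohort(config, timeseries, motion, compartments, truth)
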
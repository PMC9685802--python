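"""Leading Eigenvector Dynamics Analysis (LEiDA).

At each volume the instantaneous phases of all regions (Hilbert analytic
signal of the demeaned series) define a phase-locking matrix
``dPL(b, a, t) = cos(theta(b, t) - theta(a, t))``. Its leading eigenvector
``V1(t)`` — the unit eigenvector of the largest-magnitude eigenvalue,
sign-normalized so that most entries are non-positive — summarizes the
dominant phase-coupling pattern in N numbers instead of N(N-1)/2. Eigenvectors
pooled across subjects and sessions of one acquisition modality are clustered
with k-means over a range of candidate k; the Dunn index (minimum
between-cluster distance over maximum within-cluster diameter, Euclidean)
selects the number of recurrent states. Per run, three metrics are extracted
for each state: occurrence probability, mean lifetime, and the switching
probability matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert
from sklearn.cluster import KMeans

from .containers import RoiTimeseries

__all__ = [
    "PhaseSeries",
    "LeadingEigSeries",
    "StateSolution",
    "StateMetrics",
    "hilbert_phase",
    "phase_locking",
    "leading_eigenvector",
    "eigenvector_series",
    "pool_eigenvectors",
    "cluster_states",
    "dunn_index",
    "select_k",
    "state_metrics",
    "detect_states",
]


@dataclass
class PhaseSeries:
    """Instantaneous phase and amplitude per region, ``x = A cos(theta)``."""

    theta: np.ndarray  # (n_roi, T), radians in (-pi, pi]
    amplitude: np.ndarray  # (n_roi, T), >= 0
    tr: float


@dataclass
class LeadingEigSeries:
    """Sign-normalized leading eigenvectors, one row per kept volume."""

    vectors: np.ndarray  # (n_kept, n_roi), unit rows
    index: pd.DataFrame  # columns: subject, session, modality, volume

    @property
    def n_roi(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass
class StateSolution:
    """k-means solution for one candidate k over pooled eigenvectors."""

    k: int
    centroids: np.ndarray  # (k, n_roi)
    labels: np.ndarray  # 1-based state per pooled row
    index: pd.DataFrame
    inertia: float
    dunn: float = float("nan")
    seed: int | None = None

    def run_labels(self, subject: str, session: str) -> np.ndarray:
        mask = (self.index["subject"] == subject) & (self.index["session"] == session)
        return self.labels[mask.to_numpy()]


@dataclass
class StateMetrics:
    """Per-run state statistics; unvisited states carry NaN lifetimes/rows."""

    occurrence: np.ndarray  # (K,), sums to 1
    lifetime_tp: np.ndarray  # (K,), mean run length in volumes, NaN if unvisited
    lifetime_s: np.ndarray  # (K,), lifetime_tp * TR
    switching: np.ndarray  # (K, K), rows of visited sources sum to 1


def hilbert_phase(x: RoiTimeseries | np.ndarray, tr: float | None = None) -> PhaseSeries:
    """Demean each region and take the analytic-signal phase and amplitude."""
    if isinstance(x, RoiTimeseries):
        data, tr = x.data, x.tr
    else:
        data = np.asarray(x, dtype=float)
        if tr is None:
            raise ValueError("tr is required when passing a bare array")
    if data.shape[1] < 8:
        raise ValueError("need at least 8 volumes for a meaningful analytic signal")
    if not np.all(np.isfinite(data)):
        raise ValueError("timeseries contains non-finite values")
    demeaned = data - data.mean(axis=1, keepdims=True)
    dead = np.flatnonzero(np.all(demeaned == 0, axis=1))
    if dead.size:
        raise ValueError(f"ROI {dead[0]} is constant; phase undefined")
    analytic = hilbert(demeaned, axis=1)
    return PhaseSeries(theta=np.angle(analytic), amplitude=np.abs(analytic), tr=tr)


def phase_locking(theta_t: np.ndarray) -> np.ndarray:
    """Phase-locking matrix at one volume: ``cos(theta_b - theta_a)``.

    Symmetric with unit diagonal; +1 is full synchrony, -1 anti-phase.
    """
    theta_t = np.asarray(theta_t, dtype=float)
    if not np.all(np.isfinite(theta_t)):
        raise ValueError("phases must be finite")
    return np.cos(theta_t[:, None] - theta_t[None, :])


def _apply_sign_convention(v: np.ndarray) -> np.ndarray:
    n_pos = int(np.sum(v > 0))
    n = v.size
    if n_pos * 2 > n:
        return -v
    if n_pos * 2 == n:
        nz = np.flatnonzero(v)
        if nz.size and v[nz[0]] > 0:
            return -v
    return v


def leading_eigenvector(dpl: np.ndarray, return_eigenvalue: bool = False):
    """Unit eigenvector of the largest-magnitude eigenvalue of a symmetric matrix.

    Sign convention: if more than half the entries are strictly positive the
    vector is negated, so the minority (in-phase) community carries the
    positive sign. An exact half split is resolved by making the first nonzero
    entry negative.
    """
    dpl = np.asarray(dpl, dtype=float)
    if dpl.ndim != 2 or dpl.shape[0] != dpl.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(dpl, dpl.T, atol=1e-10):
        raise ValueError("expected a symmetric matrix")
    w, v = np.linalg.eigh(dpl)
    i = int(np.argmax(np.abs(w)))
    vec = _apply_sign_convention(v[:, i])
    return (vec, float(w[i])) if return_eigenvalue else vec


def eigenvector_series(
    x: RoiTimeseries, trim_edges: bool = True
) -> LeadingEigSeries:
    """Per-volume leading eigenvectors for one run.

    The first and last volume are discarded by default because the analytic
    signal is distorted at the run boundaries.
    """
    phases = hilbert_phase(x)
    t = phases.theta.shape[1]
    keep = np.arange(1, t - 1) if trim_edges else np.arange(t)
    vecs = np.empty((keep.size, x.n_roi))
    for row, ti in enumerate(keep):
        vecs[row] = leading_eigenvector(phase_locking(phases.theta[:, ti]))
    index = pd.DataFrame(
        {
            "subject": x.subject,
            "session": x.session,
            "modality": x.modality,
            "volume": keep,
        }
    )
    return LeadingEigSeries(vectors=vecs, index=index)


def pool_eigenvectors(
    runs: list[LeadingEigSeries], allow_mixed_modalities: bool = False
) -> LeadingEigSeries:
    """Row-stack eigenvector series across runs, preserving provenance.

    Pooling is per modality; mixing modalities is rejected unless explicitly
    allowed.
    """
    if not runs:
        raise ValueError("no runs to pool")
    n = runs[0].n_roi
    if any(r.n_roi != n for r in runs):
        raise ValueError("all runs must have the same number of ROIs")
    index = pd.concat([r.index for r in runs], ignore_index=True)
    if not allow_mixed_modalities and index["modality"].nunique() > 1:
        raise ValueError("refusing to pool across modalities (set allow_mixed_modalities=True)")
    return LeadingEigSeries(vectors=np.vstack([r.vectors for r in runs]), index=index)


def cluster_states(
    eigs: LeadingEigSeries,
    k_range=range(5, 11),
    replicates: int = 1000,
    seed: int | None = None,
) -> dict[int, StateSolution]:
    """k-means over candidate k, best of ``replicates`` initializations each.

    Euclidean distance on the unit eigenvectors; k-means++ initialization with
    replicate seeds derived from ``seed``, so results are deterministic.
    The Dunn index of each solution is computed and stored.
    """
    x = eigs.vectors
    ks = list(k_range)
    if x.shape[0] < max(ks):
        raise ValueError("fewer pooled eigenvectors than the largest candidate k")
    rng = np.random.default_rng(seed)
    solutions: dict[int, StateSolution] = {}
    for k in ks:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        km = KMeans(
            n_clusters=k, n_init=replicates, init="k-means++", random_state=sub_seed
        ).fit(x)
        labels = km.labels_.astype(int) + 1
        sol = StateSolution(
            k=k,
            centroids=km.cluster_centers_,
            labels=labels,
            index=eigs.index,
            inertia=float(km.inertia_),
            seed=sub_seed,
        )
        sol.dunn = dunn_index(x, labels)
        solutions[k] = sol
    return solutions


def _chunked_sq_dists(a: np.ndarray, b: np.ndarray, chunk: int = 2048):
    """Yield squared-Euclidean distance blocks of ``a`` rows against all of ``b``."""
    b_sq = np.einsum("ij,ij->i", b, b)
    for start in range(0, a.shape[0], chunk):
        blk = a[start : start + chunk]
        d2 = np.einsum("ij,ij->i", blk, blk)[:, None] + b_sq[None, :] - 2.0 * blk @ b.T
        np.maximum(d2, 0.0, out=d2)
        yield start, d2


def _max_pairwise(a: np.ndarray) -> float:
    best = 0.0
    for start, d2 in _chunked_sq_dists(a, a):
        best = max(best, float(d2.max()))
    return np.sqrt(best)


def _min_cross(a: np.ndarray, b: np.ndarray) -> float:
    best = np.inf
    for _, d2 in _chunked_sq_dists(a, b):
        best = min(best, float(d2.min()))
    return np.sqrt(best)


def dunn_index(x: np.ndarray, labels: np.ndarray) -> float:
    """Minimum between-cluster distance over maximum within-cluster diameter.

    Distances are Euclidean; the numerator is the single-linkage minimum over
    all cross-cluster point pairs and the denominator the largest cluster
    diameter. Returns ``inf`` if every cluster is a singleton (all diameters
    zero).
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("Dunn index needs at least 2 clusters")
    groups = [x[labels == c] for c in uniq]
    max_diam = max(_max_pairwise(g) for g in groups)
    min_inter = min(
        _min_cross(groups[i], groups[j])
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    )
    if max_diam == 0.0:
        return float("inf")
    return min_inter / max_diam


def select_k(solutions: dict[int, StateSolution]) -> StateSolution:
    """Solution with the highest Dunn index; ties resolved to the smallest k."""
    if not solutions:
        raise ValueError("no candidate solutions")
    best = None
    for k in sorted(solutions):
        sol = solutions[k]
        if best is None or sol.dunn > best.dunn:
            best = sol
    return best


def state_metrics(labels: np.ndarray, n_states: int, tr: float) -> StateMetrics:
    """Occurrence, lifetime, and switching probabilities for one run's labels.

    ``occurrence[c]`` is the fraction of volumes in state ``c``;
    ``lifetime_tp[c]`` the mean length of maximal consecutive runs of ``c``
    (runs touching a boundary included), NaN if the state never occurs;
    ``switching[a, b]`` the number of a->b transitions divided by the number
    of volumes in ``a`` that have a successor.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if labels.min() < 1 or labels.max() > n_states:
        raise ValueError("labels must lie in 1..n_states")
    t = labels.size
    occurrence = np.array([(labels == c).sum() / t for c in range(1, n_states + 1)])

    lifetime_tp = np.full(n_states, np.nan)
    boundaries = np.flatnonzero(np.diff(labels) != 0)
    run_ends = np.concatenate([boundaries, [t - 1]])
    run_starts = np.concatenate([[0], boundaries + 1])
    run_states = labels[run_starts]
    run_lengths = run_ends - run_starts + 1
    for c in range(1, n_states + 1):
        mask = run_states == c
        if mask.any():
            lifetime_tp[c - 1] = run_lengths[mask].mean()

    switching = np.full((n_states, n_states), np.nan)
    src = labels[:-1]
    dst = labels[1:]
    for a in range(1, n_states + 1):
        n_src = (src == a).sum()
        if n_src > 0:
            switching[a - 1] = [
                ((src == a) & (dst == b)).sum() / n_src for b in range(1, n_states + 1)
            ]
    return StateMetrics(
        occurrence=occurrence,
        lifetime_tp=lifetime_tp,
        lifetime_s=lifetime_tp * tr,
        switching=switching,
    )


def detect_states(
    runs: list[RoiTimeseries],
    k_range=range(5, 11),
    replicates: int = 1000,
    seed: int | None = None,
    trim_edges: bool = True,
) -> tuple[StateSolution, dict[int, StateSolution], dict]:
    """End-to-end per-modality analysis.

    Computes leading-eigenvector series for each run, pools them, clusters
    over ``k_range``, selects k by the Dunn index, and extracts per-run state
    metrics. Returns ``(chosen, all_solutions, metrics)`` with ``metrics``
    keyed by ``(subject, session)``.
    """
    series = [eigenvector_series(r, trim_edges=trim_edges) for r in runs]
    pooled = pool_eigenvectors(series)
    solutions = cluster_states(pooled, k_range=k_range, replicates=replicates, seed=seed)
    chosen = select_k(solutions)
    metrics = {}
    tr = runs[0].tr
    for r in runs:
        labels = chosen.run_labels(r.subject, r.session)
        metrics[(r.subject, r.session)] = state_metrics(labels, chosen.k, tr)
    return chosen, solutions, metrics
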
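"""Match detected states across modalities and against reference networks.

States found independently per acquisition modality come out in arbitrary
order, so they are aligned by Pearson correlation of their centroid vectors —
against each other across modalities and against reference functional-network
weight vectors. Significance uses the per-solution Bonferroni-style threshold
``p < alpha / k`` with ``k`` the number of states of the solution being
tested. Only networks significantly matched in every modality are carried
into the reliability analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .leida import StateSolution

__all__ = [
    "MatchResult",
    "correlate_centroids",
    "correlate_with_reference",
    "select_common_networks",
]


@dataclass
class MatchResult:
    r_matrix: np.ndarray  # (K_A, K_B) or (K, n_networks)
    p_matrix: np.ndarray
    significant: np.ndarray  # boolean, p < alpha / k
    assignment: dict  # row index -> column index, injective
    alpha: float
    k: int  # Bonferroni divisor (states of the tested solution)


def _corr_and_p(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-by-row Pearson correlations and two-sided t-test p-values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.shape[1]
    if b.shape[1] != n:
        raise ValueError("vectors must have the same length")
    if np.any(a.std(axis=1) == 0) or np.any(b.std(axis=1) == 0):
        raise ValueError("zero-variance vector; correlation undefined")
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    r = np.clip(az @ bz.T / n, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return r, p


def _greedy_assignment(r: np.ndarray, significant: np.ndarray) -> dict:
    """One-to-one pairing by descending r among significant pairs.

    Ties are broken toward the lower row then column index.
    """
    pairs = [
        (r[i, j], i, j)
        for i in range(r.shape[0])
        for j in range(r.shape[1])
        if significant[i, j]
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_rows: set[int] = set()
    used_cols: set[int] = set()
    assignment: dict = {}
    for _, i, j in pairs:
        if i not in used_rows and j not in used_cols:
            assignment[i] = j
            used_rows.add(i)
            used_cols.add(j)
    return assignment


def correlate_centroids(
    solution_a: StateSolution, solution_b: StateSolution, alpha: float = 0.01
) -> MatchResult:
    """Pairwise centroid correlations between two state solutions.

    Significance threshold is ``alpha / k_A`` (the solution being tested);
    the assignment is a greedy one-to-one pairing by descending r among
    significant pairs.
    """
    r, p = _corr_and_p(solution_a.centroids, solution_b.centroids)
    significant = p < alpha / solution_a.k
    return MatchResult(r, p, significant, _greedy_assignment(r, significant), alpha, solution_a.k)


def correlate_with_reference(
    solution: StateSolution, networks: np.ndarray, alpha: float = 0.01
) -> MatchResult:
    """Correlate each state centroid with each reference-network weight vector."""
    networks = np.asarray(networks, dtype=float)
    if networks.ndim != 2 or networks.shape[1] < 2:
        raise ValueError("need an (n_roi, n_networks) matrix with >= 2 networks")
    r, p = _corr_and_p(solution.centroids, networks.T)
    significant = p < alpha / solution.k
    return MatchResult(r, p, significant, _greedy_assignment(r, significant), alpha, solution.k)


def select_common_networks(
    match_results: dict[str, MatchResult],
) -> tuple[list[int], dict[str, dict[int, int]]]:
    """Networks significantly matched by at least one state in every modality.

    Returns the sorted common network ids and, per modality, the
    state -> network mapping (1-based states, 0-based network columns)
    restricted to those networks.
    """
    if len(match_results) < 2:
        raise ValueError("need match results for at least 2 modalities")
    per_modality: dict[str, dict[int, int]] = {}
    matched_sets = []
    for modality, result in match_results.items():
        mapping = {state: net for state, net in result.assignment.items()}
        per_modality[modality] = mapping
        matched_sets.append(set(mapping.values()))
    common = set.intersection(*matched_sets)
    if not common:
        warnings.warn("no network is significantly matched in every modality")
        return [], {m: {} for m in match_results}
    restricted = {
        modality: {state + 1: net for state, net in mapping.items() if net in common}
        for modality, mapping in per_modality.items()
    }
    return sorted(common), restricted
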
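"""Quality control: framewise displacement, DVARS, nuisance regression, filtering.

Framewise displacement follows the bounding-box convention: a 140 x 180 x 115
mm box around the brain with six control points at the face centers; FD at
volume t is the maximum displacement of any control point between the rigid
transforms of volumes t-1 and t. DVARS is the root-mean-square of the temporal
derivative across regions, optionally in percent signal change. Denoising is a
per-region least-squares regression on an intercept, supplied confound time
courses (component-based noise estimates), and one unit-impulse regressor per
flagged outlier volume; band-pass filtering is a zero-phase second-order
Butterworth over 0.008-0.09 Hz.
"""

from __future__ import annotations

import numpy as np
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .containers import MotionTrace, RoiTimeseries

__all__ = [
    "framewise_displacement",
    "dvars",
    "compcor_components",
    "flag_outliers",
    "denoise",
    "bandpass",
    "fd_dvars_association",
    "compare_paired",
    "fdr_adjust",
    "qc_run",
]

DEFAULT_BOX_MM = (140.0, 180.0, 115.0)
FD_THRESHOLD_MM = 0.9
GLOBAL_Z_THRESHOLD = 5.0


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, RoiTimeseries) else np.asarray(x, dtype=float)


def _control_points(box_mm) -> np.ndarray:
    """Six control points at the face centers of the box centered at the origin."""
    hx, hy, hz = (b / 2.0 for b in box_mm)
    return np.array(
        [
            [hx, 0, 0], [-hx, 0, 0],
            [0, hy, 0], [0, -hy, 0],
            [0, 0, hz], [0, 0, -hz],
        ]
    )


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotations applied about the box center in order x, then y, then z."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    rx_m = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry_m = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz_m = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz_m @ ry_m @ rx_m


def framewise_displacement(
    motion: MotionTrace | np.ndarray, box_mm=DEFAULT_BOX_MM
) -> np.ndarray:
    """Maximum control-point displacement between consecutive volumes (mm).

    ``fd[0] = 0`` so the series aligns with the volumes.
    """
    params = motion.params if isinstance(motion, MotionTrace) else np.asarray(motion, float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion parameters must have shape (n_volumes, 6)")
    if not np.all(np.isfinite(params)):
        raise ValueError("motion parameters contain non-finite values")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    pts = _control_points(box_mm)
    mapped = np.empty((params.shape[0], 6, 3))
    for t, (tx, ty, tz, rx, ry, rz) in enumerate(params):
        mapped[t] = pts @ _rotation_matrix(rx, ry, rz).T + np.array([tx, ty, tz])
    disp = np.linalg.norm(np.diff(mapped, axis=0), axis=2).max(axis=1)
    return np.concatenate([[0.0], disp])


def dvars(x, as_percent: bool = True) -> np.ndarray:
    """Root-mean-square over regions of the volume-to-volume signal change.

    With ``as_percent`` each region's series is first scaled to percent of its
    temporal mean, making the measure invariant to global signal scale.
    ``dvars[0] = 0``.
    """
    data = _as_array(x)
    if data.shape[1] < 2:
        raise ValueError("need at least 2 volumes")
    if as_percent:
        means = data.mean(axis=1)
        bad = np.flatnonzero(np.abs(means) < 1e-12)
        if bad.size:
            raise ValueError(f"ROI {bad[0]} has zero temporal mean; percent scaling undefined")
        data = 100.0 * data / means[:, None]
    d = np.diff(data, axis=1)
    out = np.sqrt(np.mean(d**2, axis=0))
    return np.concatenate([[0.0], out])


def compcor_components(noise_signals: np.ndarray, n_components: int = 4) -> np.ndarray:
    """Five-row confound matrix from noise-compartment signals.

    Row 1 is the average compartment signal; rows 2-5 are the first
    ``n_components`` principal-component time courses of the compartment
    signals within the subspace orthogonal to that average. Rows 2-5 are
    orthogonal to row 1.
    """
    c = np.asarray(noise_signals, dtype=float)
    if c.ndim != 2:
        raise ValueError("noise signals must be 2-D (n_compartments, n_volumes)")
    m, t = c.shape
    if m < n_components + 1 or t <= n_components + 1:
        raise ValueError("need more compartments and volumes than components")
    mean_signal = c.mean(axis=0)
    centered = c - c.mean(axis=1, keepdims=True)
    g = mean_signal - mean_signal.mean()
    g_norm = np.linalg.norm(g)
    if g_norm > 0:
        g_hat = g / g_norm
        centered = centered - np.outer(centered @ g_hat, g_hat)
    # principal-component time courses of the projected compartment signals
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = max(m, t) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    if np.sum(s > max(tol, 1e-12 * (s[0] if s.size and s[0] > 0 else 1.0))) < n_components:
        raise ValueError("noise signals are rank deficient; cannot extract components")
    comps = vt[:n_components] * s[:n_components, None]
    return np.vstack([mean_signal, comps])


def flag_outliers(
    fd: np.ndarray,
    global_signal: np.ndarray,
    fd_threshold: float = FD_THRESHOLD_MM,
    z_threshold: float = GLOBAL_Z_THRESHOLD,
) -> np.ndarray:
    """Flag volumes with FD above threshold or |z| of the global signal above threshold."""
    fd = np.asarray(fd, dtype=float)
    g = np.asarray(global_signal, dtype=float)
    if fd.shape != g.shape:
        raise ValueError("fd and global_signal lengths must agree")
    sd = g.std()
    z = np.zeros_like(g) if sd == 0 else (g - g.mean()) / sd
    return (fd > fd_threshold) | (np.abs(z) > z_threshold)


def denoise(
    x,
    confounds: np.ndarray | None = None,
    flags: np.ndarray | None = None,
) -> np.ndarray:
    """Per-region least-squares residual after regressing out nuisance terms.

    Design matrix: intercept, confound rows, and one unit-impulse column per
    flagged volume (so flagged volumes are absorbed exactly).
    """
    data = _as_array(x)
    t = data.shape[1]
    cols = [np.ones(t)]
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.shape[1] != t:
            raise ValueError("confound length must match the run")
        cols.extend(confounds)
    if flags is not None:
        flags = np.asarray(flags, dtype=bool)
        if flags.shape[0] != t:
            raise ValueError("flags length must match the run")
        for idx in np.flatnonzero(flags):
            e = np.zeros(t)
            e[idx] = 1.0
            cols.append(e)
    design = np.column_stack(cols)
    if design.shape[1] > t:
        raise ValueError("design matrix has more columns than volumes")
    beta, *_ = np.linalg.lstsq(design, data.T, rcond=None)
    return data - (design @ beta).T


def bandpass(x, tr: float, low: float = 0.008, high: float = 0.09) -> np.ndarray:
    """Zero-phase second-order Butterworth band-pass over the resting-state window."""
    data = _as_array(x)
    nyquist = 0.5 / tr
    if high >= nyquist:
        raise ValueError(f"high cutoff {high} Hz is at or above Nyquist {nyquist} Hz")
    sos = signal.butter(2, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
    return signal.sosfiltfilt(sos, data, axis=1)


def fd_dvars_association(fd: np.ndarray, dvars_series: np.ndarray) -> tuple[float, float]:
    """Pearson r between FD and DVARS (volumes t >= 1) and the regression R^2."""
    fd = np.asarray(fd, dtype=float)[1:]
    dv = np.asarray(dvars_series, dtype=float)[1:]
    if fd.shape != dv.shape:
        raise ValueError("fd and dvars lengths must agree")
    if fd.std() == 0 or dv.std() == 0:
        raise ValueError("association undefined for zero-variance input")
    r = stats.pearsonr(fd, dv).statistic
    return float(r), float(r * r)


def compare_paired(before: np.ndarray, after: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank test of paired per-subject values.

    Zero differences are handled by the Pratt method; the exact null is used
    when feasible (small n, no zeros/ties), otherwise the normal approximation.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.size < 5:
        raise ValueError("need paired vectors of equal length >= 5")
    if np.allclose(before, after):
        return 0.0, 1.0
    res = stats.wilcoxon(before, after, zero_method="pratt", method="auto")
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    return multipletests(p, method="fdr_bh")[1]


def qc_run(
    ts: RoiTimeseries,
    motion: MotionTrace,
    compartments: np.ndarray,
    fd_threshold: float = FD_THRESHOLD_MM,
    z_threshold: float = GLOBAL_Z_THRESHOLD,
    as_percent: bool = True,
    apply_bandpass: bool = True,
) -> dict:
    """Full QC pass for one run: flags, denoising, filtering, FD-DVARS stats.

    Confound regression precedes band-pass filtering. Returns a dict with the
    FD series, DVARS before and after denoising, outlier flags, the cleaned
    run, and the FD-DVARS correlation before/after.
    """
    fd = framewise_displacement(motion)
    dv_before = dvars(ts.data, as_percent=as_percent)
    global_signal = ts.data.mean(axis=0)
    flags = flag_outliers(fd, global_signal, fd_threshold, z_threshold)
    confounds = compcor_components(compartments)
    resid = denoise(ts.data, confounds=confounds, flags=flags)
    cleaned = bandpass(resid, ts.tr) if apply_bandpass else resid
    # residuals are zero-mean; DVARS after denoising on raw (not percent) scale
    dv_after = dvars(resid + ts.data.mean(axis=1, keepdims=True), as_percent=as_percent)
    r_before, r2_before = fd_dvars_association(fd, dv_before)
    r_after, r2_after = fd_dvars_association(fd, dv_after)
    cleaned_ts = RoiTimeseries(
        cleaned, tr=ts.tr, subject=ts.subject, session=ts.session, modality=ts.modality
    )
    return {
        "fd": fd,
        "dvars_before": dv_before,
        "dvars_after": dv_after,
        "flags": flags,
        "cleaned": cleaned_ts,
        "r_before": r_before,
        "r_after": r_after,
        "r2_before": r2_before,
        "r2_after": r2_after,
    }
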
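"""Test-retest reliability: intraclass correlation, CIs, comparisons, FDR.

The ICC is computed from a two-way ANOVA decomposition of the
subjects-by-sessions matrix ``x`` (n subjects, s sessions):

    SS_total = var(x(:)) * (n*s - 1)
    MSR      = var(row means) * s          (between-subject mean square)
    MSC      = var(column means) * n       (between-session mean square)
    MSE      = (SS_total - MSR*(n-1) - MSC*(s-1)) / ((n-1)*(s-1))

with sample (n-1 denominator) variances, which makes the decomposition
identity exact. The reported score is

    ICC = (MSR - MSE) / (MSR + MSE)

on a -100..100 scale. Note this differs from the classical consistency form
ICC(C,1) = (MSR - MSE) / (MSR + (s-1)*MSE); the classical variant is available
via ``variant="consistency"`` and is the one whose population value equals the
variance ratio sigma_b^2 / (sigma_b^2 + sigma_w^2). Confidence intervals come
from the exact F distribution of MSR/MSE under the two-way model, transformed
through the chosen ICC map. Two tables are compared by referring
``(MSR_A/MSE_A) * (1 - rho_B) / (1 + (s-1)*rho_B)`` — with ``rho_B`` the
consistency ICC of the other table — to F(n-1, (n-1)(s-1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qc import fdr_adjust

__all__ = [
    "MeasureTable",
    "IccResult",
    "IccComparison",
    "icc",
    "icc_ci",
    "categorize",
    "compare_icc",
    "fdr_family",
    "build_measure_table",
    "reliability_report",
]

CATEGORY_BANDS = (
    (20.0, "poor"),
    (40.0, "fair"),
    (60.0, "moderate"),
    (80.0, "substantial"),
    (float("inf"), "almost perfect"),
)


@dataclass
class MeasureTable:
    """n-subjects x s-sessions matrix of one metric for one state/modality."""

    x: np.ndarray
    metric: str = ""
    state: str = ""
    modality: str = ""
    n_dropped: int = 0  # subjects removed because of missing cells

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2 or self.x.shape[0] < 2 or self.x.shape[1] < 2:
            raise ValueError("need at least 2 subjects and 2 sessions")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("measure table contains missing values after policy")


@dataclass
class IccResult:
    icc_scaled: float
    ci_low: float
    ci_high: float
    category: str
    ss_total: float
    msr: float
    msc: float
    mse: float


@dataclass
class IccComparison:
    f_stat: float
    df1: int
    df2: int
    p: float
    contrast: tuple[str, str]
    p_fdr: float = float("nan")
    metric: str = ""
    state: str = ""


def _anova_components(x: np.ndarray) -> tuple[float, float, float, float, int, int]:
    x = np.asarray(x, dtype=float)
    n, s = x.shape
    ss_total = float(np.var(x, ddof=1) * (n * s - 1))
    msr = float(np.var(x.mean(axis=1), ddof=1) * s)
    msc = float(np.var(x.mean(axis=0), ddof=1) * n)
    mse = (ss_total - msr * (n - 1) - msc * (s - 1)) / ((n - 1) * (s - 1))
    return ss_total, msr, msc, mse, n, s


def _icc_from_msq(msr: float, mse: float, s: int, variant: str) -> float:
    if variant == "reported":
        denom = msr + mse
    elif variant == "consistency":
        denom = msr + (s - 1) * mse
    else:
        raise ValueError("variant must be 'reported' or 'consistency'")
    if denom == 0:
        raise ValueError("ICC undefined: MSR + MSE is zero")
    return (msr - mse) / denom


def icc(x, variant: str = "reported") -> IccResult:
    """ICC of a subjects-by-sessions table on the -100..100 scale.

    ``variant="reported"`` uses (MSR-MSE)/(MSR+MSE); ``"consistency"`` the
    classical ICC(C,1). The categorization bands are applied to the scaled
    score, and the 95% CI is attached.
    """
    table = x if isinstance(x, MeasureTable) else MeasureTable(x)
    ss_total, msr, msc, mse, n, s = _anova_components(table.x)
    value = _icc_from_msq(msr, mse, s, variant)
    scaled = float(np.clip(value * 100.0, -100.0, 100.0))
    lo, hi = icc_ci(table.x, variant=variant)
    return IccResult(
        icc_scaled=scaled,
        ci_low=lo,
        ci_high=hi,
        category=categorize(scaled),
        ss_total=ss_total,
        msr=msr,
        msc=msc,
        mse=mse,
    )


def _icc_from_f(f: float, s: int, variant: str) -> float:
    """Map the MSR/MSE ratio to the ICC scale (monotone)."""
    if np.isinf(f):
        return 1.0
    if variant == "reported":
        return (f - 1.0) / (f + 1.0)
    return (f - 1.0) / (f + s - 1.0)


def icc_ci(x, level: float = 0.95, variant: str = "reported") -> tuple[float, float]:
    """F-based confidence interval for the ICC, on the -100..100 scale.

    Under the two-way model MSR/MSE is a scaled F(n-1, (n-1)(s-1)) variable;
    the exact interval for that ratio is transformed through the (monotone)
    ICC map of the chosen variant.
    """
    table = x if isinstance(x, MeasureTable) else MeasureTable(x)
    _, msr, _, mse, n, s = _anova_components(table.x)
    df1, df2 = n - 1, (n - 1) * (s - 1)
    alpha = 1.0 - level
    if mse == 0:
        if msr == 0:
            raise ValueError("ICC CI undefined: MSR and MSE both zero")
        return 100.0, 100.0  # F ratio is infinite; both bounds collapse at the top
    f0 = msr / mse
    f_low = f0 / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_high = f0 * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = 100.0 * _icc_from_f(f_low, s, variant)
    hi = 100.0 * _icc_from_f(f_high, s, variant)
    return float(np.clip(lo, -100, 100)), float(np.clip(hi, -100, 100))


def categorize(icc_scaled: float) -> str:
    """Five descriptive bands on the -100..100 scale.

    Boundaries resolved at integers: poor <= 20, fair (20, 40], moderate
    (40, 60], substantial (60, 80], almost perfect > 80.
    """
    if not -100.0 <= icc_scaled <= 100.0:
        raise ValueError("scaled ICC must lie in [-100, 100]")
    for upper, name in CATEGORY_BANDS:
        if icc_scaled <= upper:
            return name
    raise AssertionError("unreachable")


def compare_icc(x_a, x_b, contrast: tuple[str, str] = ("A", "B")) -> IccComparison:
    """F-test of the null that table A's ICC equals table B's.

    The statistic refers ``(MSR_A/MSE_A) * (1 - rho_B) / (1 + (s-1)*rho_B)``
    — with rho_B the consistency ICC estimated from table B — to the
    F(n-1, (n-1)(s-1)) distribution; the two-sided p doubles the smaller tail.
    """
    a = (x_a if isinstance(x_a, MeasureTable) else MeasureTable(x_a)).x
    b = (x_b if isinstance(x_b, MeasureTable) else MeasureTable(x_b)).x
    if a.shape != b.shape:
        raise ValueError("tables must have the same shape")
    _, msr_a, _, mse_a, n, s = _anova_components(a)
    _, msr_b, _, mse_b, _, _ = _anova_components(b)
    if mse_a == 0 or msr_b + (s - 1) * mse_b == 0:
        raise ValueError("degenerate mean squares; comparison undefined")
    rho_b = _icc_from_msq(msr_b, mse_b, s, "consistency")
    f = (msr_a / mse_a) * (1.0 - rho_b) / (1.0 + (s - 1) * rho_b)
    df1, df2 = n - 1, (n - 1) * (s - 1)
    sf = stats.f.sf(f, df1, df2)
    p = float(min(1.0, 2.0 * min(sf, 1.0 - sf)))
    return IccComparison(f_stat=float(f), df1=df1, df2=df2, p=p, contrast=contrast)


def fdr_family(comparisons: list[IccComparison]) -> list[IccComparison]:
    """Benjamini-Hochberg adjustment over one family of ICC comparisons."""
    if not comparisons:
        raise ValueError("empty comparison family")
    adjusted = fdr_adjust([c.p for c in comparisons])
    for c, q in zip(comparisons, adjusted):
        c.p_fdr = float(q)
    return comparisons


def build_measure_table(
    metrics_by_run: dict,
    extractor,
    metric: str = "",
    state: str = "",
    modality: str = "",
) -> MeasureTable:
    """Assemble an n x s table of one scalar metric across subjects and sessions.

    ``metrics_by_run`` maps ``(subject, session)`` to per-run state metrics and
    ``extractor`` pulls the scalar of interest. Subjects with any missing cell
    (e.g. a state never visited in one session) are dropped pairwise and
    counted in ``n_dropped``.
    """
    subjects = sorted({k[0] for k in metrics_by_run})
    sessions = sorted({k[1] for k in metrics_by_run})
    x = np.full((len(subjects), len(sessions)), np.nan)
    for i, sub in enumerate(subjects):
        for j, ses in enumerate(sessions):
            m = metrics_by_run.get((sub, ses))
            if m is not None:
                x[i, j] = extractor(m)
    complete = np.all(np.isfinite(x), axis=1)
    n_dropped = int((~complete).sum())
    x = x[complete]
    if x.shape[0] < 2:
        raise ValueError("fewer than 2 subjects with complete data")
    return MeasureTable(x, metric=metric, state=state, modality=modality, n_dropped=n_dropped)


def reliability_report(
    metrics_by_modality: dict[str, dict],
    state_to_network: dict[str, dict[int, int]],
    network_names: dict[int, str] | None = None,
    variant: str = "reported",
) -> dict[str, pd.DataFrame]:
    """Full reliability layer across modalities.

    Parameters
    ----------
    metrics_by_modality
        modality -> {(subject, session) -> StateMetrics}.
    state_to_network
        modality -> {state (1-based) -> network id}, from the matching stage;
        only matched states are analysed, labelled by their network.
    network_names
        Optional pretty names per network id.

    Returns
    -------
    dict with ``icc`` (occurrence/lifetime per network x modality),
    ``switching_icc`` (per off-diagonal from->to cell), and ``contrasts``
    (pairwise modality F-tests with FDR per metric family).
    """
    names = network_names or {}
    modalities = sorted(metrics_by_modality)
    common_networks = sorted(
        set.intersection(*(set(m.values()) for m in state_to_network.values()))
    ) if state_to_network else []
    net_to_state = {
        mod: {net: st for st, net in state_to_network[mod].items()} for mod in modalities
    }

    icc_rows = []
    tables: dict[tuple[str, str, str], MeasureTable] = {}  # (metric, label, modality)
    scalar_metrics = {
        "occurrence": lambda m, c: m.occurrence[c - 1],
        "lifetime": lambda m, c: m.lifetime_tp[c - 1],
    }
    for net in common_networks:
        label = names.get(net, f"network-{net}")
        for metric, pull in scalar_metrics.items():
            for mod in modalities:
                state = net_to_state[mod][net]
                try:
                    table = build_measure_table(
                        metrics_by_modality[mod],
                        lambda m, _c=state, _p=pull: _p(m, _c),
                        metric=metric,
                        state=label,
                        modality=mod,
                    )
                except ValueError:  # too few subjects with complete data
                    continue
                try:
                    res = icc(table, variant=variant)
                except ValueError:  # degenerate (constant) table
                    continue
                tables[(metric, label, mod)] = table
                icc_rows.append(
                    {
                        "modality": mod,
                        "network": label,
                        "metric": metric,
                        "icc": res.icc_scaled,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "category": res.category,
                        "n_dropped": table.n_dropped,
                    }
                )

    # switching reliability per off-diagonal from->to cell of matched states
    switch_rows = []
    for net_a in common_networks:
        for net_b in common_networks:
            if net_a == net_b:
                continue
            label = f"{names.get(net_a, f'network-{net_a}')}->{names.get(net_b, f'network-{net_b}')}"
            for mod in modalities:
                sa, sb = net_to_state[mod][net_a], net_to_state[mod][net_b]
                try:
                    table = build_measure_table(
                        metrics_by_modality[mod],
                        lambda m, _a=sa, _b=sb: m.switching[_a - 1, _b - 1],
                        metric="switching",
                        state=label,
                        modality=mod,
                    )
                except ValueError:
                    continue
                try:
                    res = icc(table, variant=variant)
                except ValueError:
                    continue
                tables[("switching", label, mod)] = table
                switch_rows.append(
                    {
                        "modality": mod,
                        "cell": label,
                        "icc": res.icc_scaled,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "category": res.category,
                        "n_dropped": table.n_dropped,
                    }
                )

    # pairwise modality contrasts, FDR within each metric family
    # (family = all analysed states x all modality contrasts for that metric)
    contrast_rows = []
    for metric in ("occurrence", "lifetime", "switching"):
        family: list[IccComparison] = []
        meta: list[tuple[str, str, str]] = []
        labels = sorted({lab for (m, lab, _mod) in tables if m == metric})
        for label in labels:
            for i, mod_a in enumerate(modalities):
                for mod_b in modalities[i + 1 :]:
                    ta = tables.get((metric, label, mod_a))
                    tb = tables.get((metric, label, mod_b))
                    if ta is None or tb is None or ta.x.shape != tb.x.shape:
                        continue
                    try:
                        comp = compare_icc(ta, tb, contrast=(mod_a, mod_b))
                    except ValueError:
                        continue
                    comp.metric, comp.state = metric, label
                    family.append(comp)
                    meta.append((label, mod_a, mod_b))
        if family:
            fdr_family(family)
            for comp, (label, mod_a, mod_b) in zip(family, meta):
                contrast_rows.append(
                    {
                        "metric": metric,
                        "state": label,
                        "modality_a": mod_a,
                        "modality_b": mod_b,
                        "f": comp.f_stat,
                        "df1": comp.df1,
                        "df2": comp.df2,
                        "p": comp.p,
                        "p_fdr": comp.p_fdr,
                    }
                )

    return {
        "icc": pd.DataFrame(icc_rows),
        "switching_icc": pd.DataFrame(switch_rows),
        "contrasts": pd.DataFrame(contrast_rows),
    }
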
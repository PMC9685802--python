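"""One-shot orchestration: simulate -> QC -> state detection -> match -> reliability.

``run_pipeline`` executes the stages in order on a synthetic cohort, derives
every stage seed deterministically from the master seed, and returns a
manifest with per-stage wall clock, warnings, and (when an output directory is
given) content hashes of everything written, so a rerun with the same config
is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import leida, matching, qc, reliability
from .cohort import CohortConfig, SyntheticCohort, generate_cohort

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "render_report"]


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    run_qc: bool = True
    k_min: int = 5
    k_max: int = 10
    replicates: int = 50
    alpha: float = 0.01
    fd_threshold: float = qc.FD_THRESHOLD_MM
    z_threshold: float = qc.GLOBAL_Z_THRESHOLD
    trim_edges: bool = True
    icc_variant: str = "reported"
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        blob = json.loads(text)
        cblob = blob.pop("cohort")
        cblob["modalities"] = tuple(tuple(m) for m in cblob["modalities"])
        return cls(cohort=CohortConfig(**cblob), **blob)


@dataclass
class RunManifest:
    config: dict
    stage_seconds: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    output_hashes: dict = field(default_factory=dict)
    completed_stages: list = field(default_factory=list)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    cohort: SyntheticCohort | None = None,
) -> tuple[RunManifest, dict]:
    """Run all stages; returns ``(manifest, results)``.

    ``results`` holds the cohort, per-modality QC summaries, state solutions,
    match results, and the reliability tables. A pre-built cohort can be
    supplied to skip simulation.
    """
    config = config or RunConfig()
    manifest = RunManifest(config=json.loads(config.to_json()))
    results: dict = {}
    rng = np.random.default_rng(config.seed)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            out = fn()
            manifest.stage_seconds[name] = round(time.perf_counter() - t0, 3)
            manifest.completed_stages.append(name)
            return out

        return wrap

    if cohort is None:
        cohort = stage("simulate")(lambda: generate_cohort(config.cohort))
    results["cohort"] = cohort
    modalities = [m[0] for m in cohort.config.modalities]

    # --- QC / denoising ----------------------------------------------------
    def do_qc():
        cleaned: dict = {}
        group_rows = []
        for key, ts in cohort.timeseries.items():
            if config.run_qc:
                out = qc.qc_run(
                    ts,
                    cohort.motion[key],
                    cohort.noise_compartments[key],
                    fd_threshold=config.fd_threshold,
                    z_threshold=config.z_threshold,
                )
                cleaned[key] = out["cleaned"]
                group_rows.append(
                    {
                        "subject": key[0],
                        "session": key[1],
                        "modality": key[2],
                        "r_before": out["r_before"],
                        "r_after": out["r_after"],
                        "r2_before": out["r2_before"],
                        "r2_after": out["r2_after"],
                        "n_flagged": int(out["flags"].sum()),
                    }
                )
            else:
                data = qc.bandpass(ts.data, ts.tr)
                cleaned[key] = dataclasses.replace(ts, data=data)
        qc_table = pd.DataFrame(group_rows)
        group_stats = {}
        if config.run_qc:
            for mod in modalities:
                sub = qc_table[qc_table["modality"] == mod]
                per_subject = sub.groupby("subject")[["r_before", "r_after"]].mean()
                stat, p = qc.compare_paired(
                    per_subject["r_before"].to_numpy(), per_subject["r_after"].to_numpy()
                )
                group_stats[mod] = {"wilcoxon_stat": stat, "p": p}
            adj = qc.fdr_adjust([group_stats[m]["p"] for m in modalities])
            for m, q in zip(modalities, adj):
                group_stats[m]["p_fdr"] = float(q)
        else:
            manifest.warnings.append("qc stage skipped; band-pass only")
        return cleaned, qc_table, group_stats

    cleaned, qc_table, qc_group = stage("qc")(do_qc)
    results["qc_table"] = qc_table
    results["qc_group"] = qc_group

    # --- LEiDA per modality ------------------------------------------------
    def do_leida():
        chosen: dict = {}
        metrics: dict = {}
        for mod in modalities:
            runs = [ts for key, ts in cleaned.items() if key[2] == mod]
            seed = int(rng.integers(0, 2**31 - 1))
            sol, _, mod_metrics = leida.detect_states(
                runs,
                k_range=range(config.k_min, config.k_max + 1),
                replicates=config.replicates,
                seed=seed,
                trim_edges=config.trim_edges,
            )
            chosen[mod] = sol
            metrics[mod] = mod_metrics
        return chosen, metrics

    solutions, metrics = stage("leida")(do_leida)
    results["solutions"] = solutions
    results["metrics"] = metrics

    # --- matching ----------------------------------------------------------
    def do_match():
        networks = cohort.ground_truth.reference_networks
        ref_matches = {
            mod: matching.correlate_with_reference(sol, networks, alpha=config.alpha)
            for mod, sol in solutions.items()
        }
        cross = {}
        for i, mod_a in enumerate(modalities):
            for mod_b in modalities[i + 1 :]:
                cross[(mod_a, mod_b)] = matching.correlate_centroids(
                    solutions[mod_a], solutions[mod_b], alpha=config.alpha
                )
        if len(modalities) >= 2:
            common, mapping = matching.select_common_networks(ref_matches)
        else:
            m = ref_matches[modalities[0]]
            mapping = {modalities[0]: {st + 1: net for st, net in m.assignment.items()}}
            common = sorted(mapping[modalities[0]].values())
        return ref_matches, cross, common, mapping

    ref_matches, cross_matches, common, mapping = stage("match")(do_match)
    results["reference_matches"] = ref_matches
    results["cross_matches"] = cross_matches
    results["common_networks"] = common
    results["state_to_network"] = mapping

    # --- reliability -------------------------------------------------------
    def do_reliability():
        if not common:
            manifest.warnings.append("no common networks; reliability stage skipped")
            return {}
        return reliability.reliability_report(
            metrics, mapping, variant=config.icc_variant
        )

    report = stage("reliability")(do_reliability)
    results["reliability"] = report

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "run_config.json").write_text(config.to_json())
        qc_table.to_csv(out_dir / "qc_table.tsv", sep="\t", index=False)
        for mod, sol in solutions.items():
            pd.DataFrame(sol.centroids).to_csv(
                out_dir / f"centroids_{mod}.tsv", sep="\t", float_format="%.10g"
            )
        for name, df in report.items():
            df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
        (out_dir / "report.txt").write_text(render_report(results))
        for path in sorted(out_dir.iterdir()):
            if path.is_file():
                manifest.output_hashes[path.name] = _hash_file(path)
        (out_dir / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(manifest), indent=1, default=str)
        )
    return manifest, results


def render_report(results: dict) -> str:
    """Plain-text summary: chosen k, ICC tables with categories, contrasts."""
    lines = ["LEiDA test-retest reliability report", "=" * 40]
    solutions = results.get("solutions", {})
    for mod, sol in solutions.items():
        lines.append(f"{mod}: chosen k = {sol.k} (Dunn = {sol.dunn:.4f})")
    common = results.get("common_networks", [])
    lines.append("")
    if not common:
        lines.append("No network was significantly matched in every modality; "
                     "reliability analysis not performed.")
    report = results.get("reliability") or {}
    icc_df = report.get("icc")
    if icc_df is not None and len(icc_df):
        lines.append("ICC (scaled -100..100), occurrence and lifetime:")
        for _, row in icc_df.iterrows():
            lines.append(
                f"  {row['modality']:>10s}  {row['network']:>14s}  {row['metric']:>10s}  "
                f"{row['icc']:6.1f} (CI {row['ci_low']:.0f} to {row['ci_high']:.0f})  {row['category']}"
            )
    contrasts = report.get("contrasts")
    if contrasts is not None and len(contrasts):
        lines.append("")
        lines.append("Modality contrasts (F-tests on ICC equality):")
        for _, row in contrasts.iterrows():
            sig = "*" if row["p_fdr"] < 0.05 else ("(*)" if row["p"] < 0.05 else "n.s.")
            lines.append(
                f"  {row['metric']:>10s} {row['state']:>14s} {row['modality_a']} vs "
                f"{row['modality_b']}: F({row['df1']},{row['df2']}) = {row['f']:.2f}, "
                f"p = {row['p']:.4f}, pFDR = {row['p_fdr']:.4f} {sig}"
            )
    return "\n".join(lines) + "\n"
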
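"""One-shot pipeline: simulate -> QC -> LEiDA -> match -> reliability.

Runs the full orchestration on a reduced two-modality cohort and prints the
generated report: chosen k per modality, ICC tables with category bands, and
the modality-contrast F-tests.
"""

from leidakit import CohortConfig, RunConfig, render_report, run_pipeline

config = RunConfig(
    cohort=CohortConfig(
        n_subjects=8,
        n_sessions=3,
        modalities=(("SB-ASSET2", 2.0, 240), ("MB4-ARC1", 0.75, 644)),
        n_roi=42,
        n_networks=6,
        k_true=4,
        artifact_gain=1.0,
        seed=11,
    ),
    k_min=3,
    k_max=6,
    replicates=10,
    seed=11,
)

manifest, results = run_pipeline(config)
print("stage wall-clock (s):", manifest.stage_seconds)
print()
print(render_report(results))
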
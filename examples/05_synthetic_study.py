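"""The full synthetic study: both methods on a severity-spanning cohort.

Generates seeded phantoms from no MR to severe MR, quantifies each with
direct jet tracking and the indirect volumetric method, grades both, and
runs the agreement battery between the methods.
"""

from pathlib import Path

from jetflow.pipeline import RunConfig, run_pipeline

config = RunConfig.from_dict(
    {
        "seed": 1,
        "phantom": {"venc": 150.0, "noise_sd": 5.0},
        "batch": {"target_volumes": [0.0, 8.0, 16.0, 26.0, 40.0, 65.0]},
    },
    out_dir=Path("scratch/example_study"),
)
summary = run_pipeline(config)

print(f"{'subject':>10} {'truth':>6} {'tracked':>8} {'indirect':>9} grades")
for rec in summary["phantoms"]:
    print(f"{rec['subject']:>10} {rec['true_volume_ml']:>6.0f} "
          f"{rec['tracked_volume_ml']:>8.1f} {rec['indirect_volume_ml']:>9.1f} "
          f"{rec['tracked_grade']}/{rec['indirect_grade']}")

agg = summary["agreement_tracked_vs_indirect"]
print(f"\ntracked vs indirect: ICC {agg['icc']:.3f} ({agg['icc_label']}), "
      f"bias {agg['bias']:.2f} mL, LOA [{agg['loa_low']:.2f}, {agg['loa_high']:.2f}] mL")
print(f"severity kappa {agg['kappa']:.2f} ({agg['kappa_label']})")
# On this noise-level phantom cohort both methods recover the truth, so
# the agreement statistics sit near their ideal values; on clinical data
# the same battery quantifies how far the two methods drift apart.
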
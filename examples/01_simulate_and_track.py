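"""Simulate a digital MR jet phantom and quantify it by direct jet tracking.

Builds the default phantom — an eccentric 16 mL mid-to-late-systolic jet
in 5 cm/s velocity noise — then runs detection, per-frame peak-velocity
MPR plane placement and through-plane flow integration.
"""

from jetflow import (
    PhantomConfig,
    classify_mr_severity,
    generate_jet_phantom,
    track_mitral_regurgitation,
)

config = PhantomConfig(seed=1)
field, truth = generate_jet_phantom(config)
print(f"phantom: true MR volume {truth.true_volume:g} mL, "
      f"jet active in frames {truth.active_frames[0]}-{truth.active_frames[-1]}")

result = track_mitral_regurgitation(field, truth.atrial_roi_mask)

print(f"\n{'frame':>5} {'time (ms)':>9} {'peak (cm/s)':>11} {'flow (mL/s)':>11}")
for f in result.jets[0].frames:
    print(f"{f.frame_index:>5} {f.time_ms:>9.0f} {f.peak_speed:>11.1f} {f.flow_rate:>11.1f}")

grade = classify_mr_severity(result.total_mr_volume)
print(f"\ntracked MR volume: {result.total_mr_volume:.1f} mL ({grade} MR)")
print(f"truth: {truth.true_volume:g} mL -> relative error "
      f"{100 * (result.total_mr_volume / truth.true_volume - 1):+.1f}%")
# The per-frame flow rates trace the half-sine regurgitant flow program;
# their spline integral over the jet period is the regurgitant volume.
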
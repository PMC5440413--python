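"""Run the two study workflows end to end on phantom bones.

Workflow 1 pools all baseline (pre-immunization) surfaces into per-
(surface, radius) lognormal calibrations.  Workflow 2 scores every bone
(volume + roughness at the requested radii) and compares the arthritic and
control groups with the ratio/bootstrap machinery.
"""

from osteorough.phantoms import PhantomSpec, Perturbation, make_tube_phantom
from osteorough.pipeline import StackEntry, StudyConfig, calibrate_baseline, run_study

BONE = dict(shape=(72, 64, 64), outer_radius=20.0, inner_radius=13.0,
            z_margin=2, capped=True, cap_style="dome", cap_thickness=8)


def bone(seed, amp=0.5):
    perturb = {"outer": Perturbation(amp, 2.0), "inner": Perturbation(amp, 2.0)}
    return make_tube_phantom(PhantomSpec(seed=seed, perturb=perturb, **BONE))[0]


entries = (
    [StackEntry(id=f"base{i}", stack=bone(100 + i), role="baseline", group="CO")
     for i in range(3)]
    + [StackEntry(id=f"co{i}", stack=bone(200 + i), role="study", group="CO")
       for i in range(3)]
    + [StackEntry(id=f"ar{i}", stack=bone(300 + i, amp=2.0), role="study", group="AR")
       for i in range(3)]
)
cfg = StudyConfig(stacks=entries, stacks_are_vois=True, radii=(3,),
                  surfaces=("cs",), seed=42, n_boot=5000)

calibrations = calibrate_baseline(cfg)
for (kind, r), cal in calibrations.items():
    print(f"calibration {kind} r={r}: T = {cal.T:.1f} deg "
          f"from {len(cal.source_meshes)} baseline meshes")

out = run_study(cfg, calibrations, group_pair=("AR", "CO"))
r_rows = out["metrics"].query("metric == 'R'")
print(r_rows[["voi_id", "group", "value"]].to_string(index=False))
print(out["comparisons"][["metric", "mu_ratio", "sigma_ratio", "ci_low",
                          "ci_high", "significant"]].to_string(index=False))
# The AR group's roughness ratio sits well above 1 with disjoint group CIs:
# the phantom "arthritis" is detected by the automated pipeline.
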
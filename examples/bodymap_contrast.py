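"""Body-map learning: fluid-immersed versus flat-plane development.

A spinal-oscillator-driven fetus moves spontaneously either inside a
fluid-filled uterus or lying on a flat plane; a spiking cortex passively
learns the evoked receptor stream with STDP; each body part is then probed
and the segregation of the cortical response maps compared.  Small problem
size (600 neurons, 20 s of movement, 40 s of learning, 4 paired seeds) so
the script finishes in a couple of minutes.
"""

from somadev.experiments import bodymap_contrast

report = bodymap_contrast(
    seeds=(0, 1, 2, 3),
    cortex_config={"n_neurons": 600, "sim_duration": 20.0,
                   "train_duration": 40.0})

s = report.summary
print(f"segregation intrauterine : {s['mean_segregation_intra']:.3f}")
print(f"segregation extrauterine : {s['mean_segregation_extra']:.3f}")
print(f"paired one-sided p       : {s['p_one_sided']:.4f}")
print(f"tactile correlations     : within-part fluid/plane "
      f"{s['within_corr_fluid']:.2f}/{s['within_corr_plane']:.2f}, "
      f"between-part {s['between_corr_fluid']:.2f}/{s['between_corr_plane']:.2f}")
for name, ok in report.verdicts.items():
    print(f"[{'PASS' if ok else 'FAIL'}] {name}")
# Fluid drag makes each moving limb's skin input coherent (high within-part
# correlation) while parts stay independent; on the plane the ground couples
# everything.  The cortex trained in the fluid therefore acquires the more
# segregated body map.
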
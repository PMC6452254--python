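"""Closed-loop spinal learning: jerky movements and hand-face contacts.

Hebbian tactile-to-motor connections adapt online while the fetus moves in
the uterus.  The script prints the windowed jerk-event and hand-face
contact-event rates over the run for one human-like and one uniform taxel
distribution, together with the detected onset times.
"""

from somadev.experiments.development import development_run

for dist in ("humanlike", "uniform"):
    r = development_run(dist, gain_multiplier=1.0, seed=0)
    print(f"--- {dist} taxel distribution")
    print("  jerk rate /min  :", [round(x) for x in r["jerk_rate"][:-1]])
    print("  contact rate/min:", [round(x) for x in r["contact_rate"]])
    print(f"  onsets: jerk={r['onset_jerk']}  contact={r['onset_contact']}")
    print(f"  increases vs baseline: jerk={r['jerk_increase']:+.0f}/min, "
          f"contact={r['contact_increase']:+.0f}/min")
# In runs where the positive tactile-motor feedback expresses, the jerk rate
# climbs mid-run and decisive hand-face touches follow; the effect is
# stronger with the human-like (face/hand/foot-dense) skin.  See the model
# notes for why the effect is not robust across all seeds at this scale.
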
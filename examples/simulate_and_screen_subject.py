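"""Simulate one venous-entrapment subject and screen both limbs.

Builds a synthetic multichannel PPG recording for a patient whose
forearm veins stay trapped during arm elevation (emptying plateau 55%
of the full-emptying reference) while arterial inflow is preserved,
then runs the arterial and venous screening exactly as the clinical
pipeline does.
"""

from venoppg import (NoiseParams, SubjectParams, analyze_recording,
                     generate_recording)

params = SubjectParams(
    group_label="venous",
    baseline_hr=81.5,
    phase_hr_effects={"Su": 6.9, "Pra": 7.2, "End": 6.3},  # bpm over rest
    transition_peak=4.1,           # transient HR surge at each movement
    venous_emptying_max_left=55.0,  # % of full emptying -> entrapment
    venous_emptying_max_right=55.0,
    hr_noise_sd=1.5,
)
recording, truth = generate_recording(params, NoiseParams(), seed=7)
row = analyze_recording(recording)

print(f"subject {row['subject_id']}  ->  {row['group_label']}")
print(f"  remaining arterial pulsatility: "
      f"L {row['remaining_left']:.1f}%  R {row['remaining_right']:.1f}%  "
      "(arterial compression if < 25%)")
print(f"  maximum venous emptying:        "
      f"L {row['emptying_left']:.1f}%  R {row['emptying_right']:.1f}%  "
      "(entrapment if < 70%, normal if > 87%)")
print(f"  median normalized HR (bpm):  Su {row['median_delta_su']:+.1f}  "
      f"Pra {row['median_delta_pra']:+.1f}  End {row['median_delta_end']:+.1f}")
print()
print("Both limbs empty below 70%, so the patient is classified into the")
print("venous group; the sustained ~7 bpm HR rise during elevation is the")
print("chronotropic response attributed to reduced venous return.")
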
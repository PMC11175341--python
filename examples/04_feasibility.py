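"""Feasibility verdicts: can an eNose monitor beer-maturation volatiles?

Compares per-compound LOD/LOQ estimates against the bundled reference bands
(human odor thresholds and in-beer concentrations) and prints the verdicts.
The LOD values used here are illustrative estimates for a 62-sensor MOS
array; replace them with your own pipeline output.
"""

import enoselod as el

estimates = {
    "diacetyl": (0.02, 0.05),
    "isobutanol": (210.0, 320.0),
    "2-phenylethanol": (50.0, 160.0),
    "ethyl acetate": (1200.0, 3500.0),
    "acetaldehyde": (2400.0, 6500.0),
}

print(f"verdict rule: {el.SUITABILITY_RULE}\n")
verdicts = el.feasibility_report(estimates)
for v in verdicts:
    print(v.narrative)

frame = el.verdicts_to_frame(verdicts)
suitable = frame.index[frame["suitable"]].tolist()
print(f"\nsuitable for end-of-process monitoring: {suitable or 'none'}")
print("Only a compound whose LOD undercuts both the human odor threshold and "
      "the concentrations the process actually produces can be monitored online.")
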
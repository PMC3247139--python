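"""Parameter sensitivity of the cAMP signal and transient stimulation.

Scans multiply one parameter at a time by factors between 0.1 and 10
and report the change of the plateau; transient (prostacyclin-like)
stimuli decay exponentially and let the signal return to basal.
"""

import numpy as np

from plateletsig import (
    BasalConstants,
    H3,
    StimulusProtocol,
    feedback_sweep,
    perturbation_scan,
    transient_response,
)
from plateletsig.synth import true_drug_parameters

constants = BasalConstants()
drugs = true_drug_parameters()
protocol = StimulusProtocol.single("Iloprost", 1.0)  # low-dose stimulation

scan = perturbation_scan(constants, drugs, H3, protocol,
                         ["k11", "kf1", "kf2", "k3", "ki:Cilostamide"],
                         factors=[0.5, 2.0])
plateau = scan[scan.feature == "plateau"]
effect = plateau.groupby("parameter")["ratio"].apply(
    lambda r: float(np.abs(r - 1.0).max())).sort_values(ascending=False)
print("plateau sensitivity at 1 nM Iloprost (max |ratio-1| over 0.5x/2x):")
for name, value in effect.items():
    print(f"  {name:16s} {value:.3f}")
print("-> the basal cAMP formation rate dominates at low-dose stimulation\n")

sweep = feedback_sweep(drugs.kf1 * np.logspace(-1, 1, 9),
                       drugs.kf2 * np.logspace(-1, 1, 9),
                       constants, drugs, protocol)
for name in ("kf1", "kf2"):
    lo, hi = sweep[name]["span"]
    print(f"tenfold {name} sweep: plateau spans {lo:.2f} - {hi:.2f} uM")

print("\ntransient Iloprost stimulation (half-life 5 min):")
table = transient_response("Iloprost", [1.0, 5.0, 10.0, 100.0],
                           constants, drugs, half_life=5.0)
print(table.round(2).to_string(index=False))
print("Peaks grow with dose; after ~10 half-lives the signal is back")
print("within 5% of the resting level - transient endothelial prostacyclin")
print("release inhibits platelets only while the stimulus lasts.")
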
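"""Predict cAMP plateau surfaces for drug combinations.

An AC stimulator (Iloprost) combined with a PDE3 inhibitor
(Cilostamide) acts over-additively; the synergy constant k = 1.443
scales the stimulated cyclase influx whenever both drug classes are
present.  Combining a PDE3 inhibitor with an AC inhibitor instead is
antagonistic: the elevated plateau is pulled back down.
"""

from plateletsig import combination_surface
from plateletsig.synth import true_drug_parameters, with_influx_for

drugs = with_influx_for(true_drug_parameters(), "Iloprost", [2.0, 5.0, 20.0])

iloprost = [0.0, 2.0, 5.0, 20.0]     # nM
cilostamide = [0.0, 10.0, 50.0]      # uM

synergistic = combination_surface("Iloprost", iloprost, "Cilostamide",
                                  cilostamide, drugs=drugs, k_syn=1.443)
additive = combination_surface("Iloprost", iloprost, "Cilostamide",
                               cilostamide, drugs=drugs, k_syn=1.0)

print(f"basal cAMP: {synergistic.basal:.2f} uM\n")
print("cAMP plateaus (uM), synergistic model (k = 1.443):")
print("  Ilo\\Cil " + "".join(f"{c:>9.0f}" for c in cilostamide))
for dose, row in zip(iloprost, synergistic.plateaus):
    print(f"  {dose:6.0f}  " + "".join(f"{v:9.2f}" for v in row))

gain = synergistic.plateaus[1:, 1:] / additive.plateaus[1:, 1:]
print(f"\nover-additive gain vs purely mechanistic combination: "
      f"{gain.min():.2f}-{gain.max():.2f} fold on interior cells")

antagonist = combination_surface("Milrinone", [1.0, 10.0, 100.0],
                                 "AC-inhibitor", [0.0, 5.0, 20.0, 100.0],
                                 drugs=drugs)
print("\ncAMP plateaus (uM), Milrinone x AC-inhibitor (antagonism, k = 1):")
print("  Mil\\ACi " + "".join(f"{c:>9.0f}" for c in [0, 5, 20, 100]))
for dose, row in zip([1.0, 10.0, 100.0], antagonist.plateaus):
    print(f"  {dose:6.0f}  " + "".join(f"{v:9.2f}" for v in row))
print("\nEach row decreases along the AC-inhibitor axis: suppressing basal")
print("cAMP synthesis successively removes the inhibitor-driven elevation.")
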
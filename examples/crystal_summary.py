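"""Crystal microscopy: the compensated polarized-light decision table.

Classifies coded microscopy observations and summarises crystal
prevalence over a cohort, excluding cholesterol from crystal-arthritis
positivity.
"""

from oadx import CrystalObservation, Specimen, classify_crystal, crystal_prevalence

observations = {
    "needle, high birefringence, yellow/blue":
        CrystalObservation("needle", "high", "yellow", "blue"),
    "rhombic, weak birefringence, blue/yellow":
        CrystalObservation("rhombic_square", "weak", "blue", "yellow"),
    "plate-like body":
        CrystalObservation("plate_other", "none", "none", "none"),
    "needle with CPPD optics (contradictory)":
        CrystalObservation("needle", "weak", "blue", "yellow"),
}
for desc, obs in observations.items():
    call = classify_crystal(obs)
    print(f"{desc:<45} -> {call.crystal.value} ({call.disorder.value})")

msu = observations["needle, high birefringence, yellow/blue"]
chol = observations["plate-like body"]
cohort = (
    [Specimen(id=f"G{i}", comp=0.0, il8=0.0, crystals=[msu]) for i in range(4)]
    + [Specimen(id=f"C{i}", comp=0.0, il8=0.0, crystals=[chol]) for i in range(2)]
    + [Specimen(id=f"N{i}", comp=0.0, il8=0.0, crystals=[]) for i in range(4)]
)
prev = crystal_prevalence(cohort)
print(
    f"\ncrystal-positive: {prev.positive}/{prev.n_examined} "
    f"({prev.percent_positive}%) — cholesterol-only specimens do not count"
    " toward crystal-arthritis positivity."
)
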
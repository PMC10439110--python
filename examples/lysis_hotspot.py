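"""How far does a lysed cell's ion plume support further infection?

A lysed bacterium (1 µm sphere) releases its cytoplasmic ions, which dilute
evenly into a sphere of radius r: C(r) = C_cyto * (r0/r)^3.  The crossing
distance is where the concentration falls to the phage's requirement.
"""

from phagegeo import LysisModel, gen_environment_profiles, lysis_crossing_distance

cytoplasm = next(p for p in gen_environment_profiles() if p.category == "cytoplasm")
model = LysisModel(cytoplasm=cytoplasm, r0=1.0)

requirements = {"Na+": 100.0, "Ca2+": 2.38, "Mg2+": 5.08}  # literature mM
print(f"{'ion':5} {'cytoplasm mM':>13} {'required mM':>12} {'crossing r (um)':>16}")
for ion, thr in requirements.items():
    d = lysis_crossing_distance(model, ion, thr)
    print(f"{ion:5} {cytoplasm.concentrations[ion]:13.1f} {thr:12.2f} {d:16.3f}")

# Na+ stays above its ~100 mM requirement only out to ~1.29 µm — barely one
# cell radius past the lysed cell.  Cytoplasmic Ca2+ and Mg2+ start below
# their requirements, so the plume never enables those ions (crossing = r0).
# Phage blooms in biofilms must therefore run on very local, cell-to-cell
# ion plumes.
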
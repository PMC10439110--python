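"""Express ion thresholds as ionic strength.

Monovalent and divalent cations that enable phage infection can be put on a
common scale by converting each salt's EC50 to the ionic strength it
contributes (I = 1/2 * sum c_i z_i^2).  A CaCl2 threshold of c mM carries
three times the ionic strength of a NaCl threshold at the same molarity.
"""

from phagegeo import FourPLFit, chloride_salt, ec50_to_ionic_strength, salt_to_profile

thresholds = {  # literature consensus requirements, mM of the cation
    "Na+": (chloride_salt("Na+", 1), 100.0),
    "Mg2+": (chloride_salt("Mg2+", 2), 5.08),
    "Ca2+": (chloride_salt("Ca2+", 2), 2.38),
}
background = salt_to_profile(chloride_salt("Na+", 1), 30.0)  # assay medium ~30 mM Na+

print(f"{'ion':5} {'EC50 mM':>8} {'I(EC50) mM':>11} {'I + background mM':>18}")
for ion, (salt, ec50) in thresholds.items():
    fit = FourPLFit(ion=ion, phage="T4", top=1, bottom=0, hill=2,
                    half_max=ec50, rss=0, converged=True)
    i_salt = ec50_to_ionic_strength(fit, salt)
    i_total = ec50_to_ionic_strength(fit, salt, background=background)
    print(f"{ion:5} {ec50:8.2f} {i_salt:11.2f} {i_total:18.2f}")

# Even after the ionic-strength correction the monovalent requirement stays
# an order of magnitude above the divalent ones: the ion identity matters,
# not just the total charge concentration.
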
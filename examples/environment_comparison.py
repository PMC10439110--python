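"""Which environments reach the ion thresholds phages need?

Compares the bundled environment profiles (freshwaters, bacterial
cytoplasm, human gut, seawater) against literature ion requirements,
ion by ion: permissive when the ambient concentration meets the threshold,
limiting otherwise (with the fold deficit).
"""

from phagegeo import gen_environment_profiles, summarize_environments

thresholds = {
    ("T4", "Na+"): 100.0,
    ("T4", "Ca2+"): 2.38,
    ("T4", "Mg2+"): 5.08,
}
profiles = gen_environment_profiles()
verdicts, by_env, by_cat = summarize_environments(profiles, thresholds)

print(verdicts[["environment", "ion", "conc_mM", "threshold_mM",
                "status", "fold_deficit"]].to_string(index=False))
print()
print(by_cat.to_string(index=False))

# Freshwaters are limiting for every ion (global-mean Ca2+ is ~24-fold
# short of its requirement), while the cytoplasm, gut and seawater all
# exceed the Na+ requirement: lytic infection is geochemically favored in
# guts, marine systems and next to lysed cells, not in dilute freshwater.
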
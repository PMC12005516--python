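"""Which mechanism drives the DALY improvement?

Switches each benefit channel on alone (with common random numbers against
the no-therapy baseline) and prints its percent share of the total
improvement.  Side effects can contribute negatively.
"""

import insulinshift as ins

params = ins.load_params()
overall = ins.load_country_profiles(include_overall=True)["OVERALL"]
pop = ins.generate_population(overall, n=4000, seed=21)

for tname in ("glp1ra_inj", "sglt2i"):
    dec = ins.decompose_contributions(pop, tname, overall, params, seed=21)
    print(f"\n{tname}: share of total DALY improvement")
    for _, row in dec.sort_values("percent", ascending=False).iterrows():
        print(f"  {row['channel']:<13} {row['percent']:6.1f}%")

print(
    "\nWeight-related morbidity is the largest channel for GLP-1RA (its weight"
    "\nloss is about twice the SGLT2i's); kidney protection matters more for"
    "\nSGLT2i (hazard ratio 0.63 vs 0.79).  Shares sum to 100% by construction."
)
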
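"""End-to-end identification of a zinc site mismodeled as water.

Generates a synthetic structure containing a Cys4 tetrahedral zinc site
deliberately modeled as a water (plus four ordinary waters), runs the
full screening/decision pipeline with the default candidate set
(Mg, Ca, Zn, Cl), and prints the per-site report.
"""

from dataclasses import replace

from ionid import RunConfig, run_pipeline
from ionid.fixtures import CANONICAL_SPECS, make_site_fixture

spec = replace(CANONICAL_SPECS["ZN"], extra_waters=4)
bundle = make_site_fixture(spec, seed=7)

config = RunConfig(wavelength=1.0)  # 12.4 keV: strong Zn anomalous signal
result = run_pipeline(bundle.model, bundle.features, config)

print(result.summary_table())
print()
assigned = [d for d in result.decisions if d.status == "assign"]
d = assigned[0]
zn = next(c for c in d.alternatives if c.element == "ZN")
print(f"assigned element : {d.element}")
print(f"bond-valence sum : {zn.bvs:.3f} (window {zn.bvs_window[0]:.2f}-{zn.bvs_window[1]:.2f})")
print(f"VECSUM           : {zn.vecsum:.3f} (<= 0.25 required)")
print(f"f'' consistency  : {zn.fpp_consistent}")
print()
print("The water with a low B factor, strong difference peak and Zn-sized")
print("anomalous signal in a Cys4 tetrahedron is converted to Zn; the four")
print("unremarkable waters are left alone.")
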
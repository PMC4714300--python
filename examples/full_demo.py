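"""Full pipeline on synthetic surveillance: truth-vs-estimate recovery.

Simulate three diseases over a 12-region metapopulation whose regional
birth rates follow a fertility covariate, run every analysis stage, and
check that the estimated FOI (1 / adjusted mean age) tracks the generator's
realized FOI region by region.
"""

from kdepi import run_demo

report = run_demo(
    seed=42,
    n_regions=12,
    population=1.5e5,
    record_years=8,
    diseases={
        "kd_like": {"r0": 30.0, "infectious_years": 0.05},
        "hfmd_like": {"r0": 12.0, "infectious_years": 0.02},
    },
)

print(report["truth_vs_estimate"]["table"].head(6).to_string(index=False))
print(f"\nFOI recovery correlation: {report['truth_vs_estimate']['correlation']:.3f}")
print("screening retained:", report["screening"].retained)
for disease, entry in report["regression"].items():
    rho = entry["spatial"].rho if "spatial" in entry else float("nan")
    print(f"{disease}: selected {entry['selected']}, spatial rho = {rho:.3f}")
print("=> the pipeline recovers regional FOI differences and attributes "
      "them to the fertility covariate, with no residual spatial signal "
      "(the generator has none).")
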
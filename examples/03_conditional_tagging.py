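"""Epistasis or tagging?  The conditional LRT distinguishes the two.

Runs the full pipeline twice — once on a cohort with a genuine SNP x SNP
interaction and once on a cohort where the apparent interaction merely tags
a rare causal variant — and prints the conditional analysis that tells them
apart: conditioning on the rare variant collapses the tagging signal but
leaves a genuine interaction intact.
"""

import episcan as ep

for scenario in ("interaction", "tagging"):
    cfg = ep.PipelineConfig(
        scenario=scenario, n_studies=10, n_cases=1500, n_controls=1500,
        stage1_threshold=1e-5, seed=2,
    )
    result = ep.run_pipeline(cfg, write=False)
    print(f"=== scenario: {scenario} ===")
    print(f"classification: {result.classification}")
    if result.criteria is not None:
        print("conditional LRTs for the interaction term "
              "(dependent if p >= 7.8e-6):")
        for r in result.criteria.conditional:
            if not r.skipped:
                mark = "<- explains the signal" if r.dependent else ""
                print(f"  condition on {r.conditioning_snp:9s} "
                      f"LRT p = {r.p:.3g} {mark}")
    print()
print("A genuine interaction survives every conditioning SNP; the tagging\n"
      "signal collapses exactly when the rare variant enters the model.")
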
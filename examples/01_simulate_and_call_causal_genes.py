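"""Simulate a two-ancestry study and run the full causal-call cascade.

Builds a small synthetic study — five genes whose expression truly affects a
binary outcome (odds ratio 1.5 per SD of expression) and five null genes —
then runs instrument selection, IVW, the sensitivity suite, colocalization
and the four-criterion causal call in each ancestry.
"""

import math

import qtlmr

config = qtlmr.StudyConfig(
    ancestries=[
        qtlmr.AncestryConfig("EUR", n_ref=1500, n_exp=5000, n_case=2000, n_ctrl=2000),
        qtlmr.AncestryConfig("AFR", n_ref=1500, n_exp=3000, n_case=1500, n_ctrl=1500),
    ],
    genes=[
        qtlmr.GeneConfig(f"G{i}", theta=math.log(1.5) if i < 5 else 0.0,
                         n_causal=3, h2_expr=0.2, m_variants=40)
        for i in range(10)
    ],
)
bundle = qtlmr.simulate_study(config, seed=11)

for ancestry in ("EUR", "AFR"):
    analyses = qtlmr.analyze_cohort(bundle, ancestry, "blood")
    table = qtlmr.decisions_frame(analyses)
    print(f"\n=== {ancestry} blood eQTL MR ===")
    print(table[["trait_id", "n_iv", "or", "q", "crit_coloc", "causal"]]
          .round(4).to_string(index=False))

print(
    "\nEach row is one gene: `or` is the IVW odds ratio per SD of genetically"
    "\npredicted expression, `q` the within-cohort FDR-adjusted p-value, and"
    "\n`causal` the conjunction of the FDR, sensitivity-concordance,"
    "\nheterogeneity/pleiotropy and colocalization (PPH4 > 0.8) criteria."
    "\nGenes G0-G4 carry a true effect (OR 1.5); G5-G9 are null."
)
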
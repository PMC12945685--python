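"""Cross-ancestry meta-analysis, replication ladder and enrichment reporting.

Runs discovery and replication cohorts of the same high-power study, pools
the two ancestries with a random-effects model, tabulates the five-criterion
replication ladder and tests whether causal calls are enriched in a curated
gene set.
"""

import math

import pandas as pd

import qtlmr

config = qtlmr.StudyConfig(
    ancestries=[
        qtlmr.AncestryConfig("EUR", n_ref=1500, n_exp=5000, n_case=2500, n_ctrl=2500),
        qtlmr.AncestryConfig("EAS", n_ref=1500, n_exp=3000, n_case=1500, n_ctrl=1500),
    ],
    genes=[qtlmr.GeneConfig(f"G{i}", theta=math.log(1.6) if i < 6 else 0.0,
                            n_causal=3, h2_expr=0.25, m_variants=30)
           for i in range(18)],
)
discovery = qtlmr.simulate_study(config, seed=21, architecture_seed=99)
replication = qtlmr.simulate_study(config, seed=22, architecture_seed=99)

disc = {a: qtlmr.analyze_cohort(discovery, a, "blood") for a in ("EUR", "EAS")}
rep_eur = qtlmr.analyze_cohort(replication, "EUR", "blood")

# cross-ancestry random-effects meta-analysis (genes tested in both)
print("=== multi-ancestry meta-analysis ===")
for gene in sorted(set(disc["EUR"]) & set(disc["EAS"])):
    meta = qtlmr.meta_analyze([disc["EUR"][gene].mr, disc["EAS"][gene].mr])
    print(f"  {gene}: pooled OR {math.exp(meta.estimate):.3f} "
          f"(se {meta.se:.3f}), Cochran Q p = {meta.Q_p:.3f}")

# replication ladder in EUR
disc_df = qtlmr.decisions_frame(disc["EUR"])
ladder = qtlmr.replication_ladder(disc_df, {g: t.mr for g, t in rep_eur.items()})
print("\n=== replication ladder (EUR discovery -> EUR replication) ===")
print(ladder.round(3).to_string(index=False))

# enrichment of causal calls in a curated set containing the true genes
causal = set(disc_df.loc[disc_df["causal"], "trait_id"])
tested = set(disc_df["trait_id"])
curated = qtlmr.GeneSet("curated", frozenset({"G0", "G1", "G2", "G3", "G10"}))
enr = qtlmr.fisher_enrichment(causal, tested, curated)
print(f"\nenrichment in curated set: fold = {enr.fold:.2f}, "
      f"Fisher p = {enr.p:.4g}")
print(
    "\nThe ladder's replication rate rises as discovery criteria tighten;"
    "\nthe Fisher test checks whether causal calls concentrate in the"
    "\ncurated gene set (here seeded with four truly causal genes)."
)
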
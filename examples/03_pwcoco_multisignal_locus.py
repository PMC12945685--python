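"""Pairwise conditional colocalization at a multi-signal locus.

Builds a locus where each trait has two causal variants and the traits share
exactly one of them. Marginal colocalization is dominated by the distinct
primary signals (high PPH3); conditioning each trait on its primary reveals
the shared secondary signal (high PPH4).
"""

import numpy as np

import qtlmr
from qtlmr.coloc import PwcocoConfig, abf_coloc, pwcoco
from qtlmr.simulate import simulate_locus_zscores

panel = qtlmr.simulate_reference_panel(qtlmr.PanelConfig(
    m_variants=60, n_ref=4000, ld_rho=0.4, seed=3, maf_range=(0.15, 0.5)))

lam1 = np.zeros(panel.m)
lam2 = np.zeros(panel.m)
lam1[30] = lam2[30] = 8.0   # shared causal variant
lam1[5] = 14.0              # eQTL-specific primary
lam2[55] = 14.0             # GWAS-specific primary

eqtl = simulate_locus_zscores(panel, lam1, 20_000, seed=10, trait_id="gene")
gwas = simulate_locus_zscores(panel, lam2, 20_000, seed=20, trait_id="outcome")

marginal = abf_coloc(eqtl, gwas)
print("marginal PPH0..4:", np.round(marginal.pph, 3), f"PPH4 = {marginal.pph4:.3f}")

result = pwcoco(eqtl, gwas, panel,
                cfg=PwcocoConfig(p_threshold_1=1e-4, p_threshold_2=1e-4))
print(f"pwcoco: pairs tested = {result.pairs_tested}, "
      f"max PPH4 = {result.max_pph4:.3f}")
print("conditioning leads:", result.conditioned_on)
print(
    "\nThe marginal run sees two different primary signals and favours"
    "\ndistinct causal variants (PPH3); after conditioning each side on its"
    "\nprimary, the shared secondary signal colocalizes (max PPH4 > 0.8)."
)
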
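"""Screen compounds for association between signature score and drug response.

Simulates a 60-line cell panel where one compound's viability log-fold
change decreases with the signature (slope -0.8): higher-signature lines
are more sensitive.  The screen computes per-compound Spearman correlations
of score vs LFC with BH correction; negative rho at q <= 0.05 flags a
sensitizing association.
"""

from budsig import evaluate, scoring
from budsig.simulate import generate_drug_panel

expr, lfc = generate_drug_panel(
    n_lines=60, n_compounds=20, effect_map={"CPD007": -0.8}, seed=5, noise_sd=0.2
)
from budsig.containers import SignatureDef

signature = SignatureDef(name="sig", genes=list(expr.genes))
scores = scoring.score_signature(expr, signature)

screen = evaluate.drug_screen(scores, lfc)
print(screen.head(5)[["rho", "p", "q", "sensitizing"]])
hit = screen.loc["CPD007"]
print(f"\nplanted compound CPD007: rho = {hit['rho']:.2f}, q = {hit['q']:.1e} -> "
      f"{'flagged' if hit['sensitizing'] else 'missed'} as sensitizing")
print(f"compounds flagged at FDR 5%: {int(screen['sensitizing'].sum())} of {len(screen)} "
      "(a negative rho means viability drops as the signature rises)")
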
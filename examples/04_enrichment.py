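"""Gene-set enrichment with the fold-change-of-percentages score.

Builds a random GMT catalog with one set deliberately enriched for a
28-gene query, then scores every set: FC = (n/K)/(k/N), the rate at which
the query hits the set over the set's share of the universe, with a
one-sided Fisher exact p and BH correction across the catalog.
"""

from budsig.enrichment import enrich, read_gmt, write_gmt
from budsig.simulate import generate_geneset_catalog

universe = [f"g{i}" for i in range(4000)]
query = universe[:28]
catalog = generate_geneset_catalog(
    universe, n_sets=19, planted_set=query, seed=3, set_size=200, planted_overlap=10
)
write_gmt(catalog, "demo_catalog.gmt")
catalog = read_gmt("demo_catalog.gmt")  # GMT round-trip

table = enrich(query, catalog, universe_override=universe)
top = table.iloc[0]
print(table.head(3)[["k", "K", "n", "N", "fc", "p", "q"]])
print(f"\ntop set: {table.index[0]} with FC = {top['fc']:.2f} "
      f"(overlap {int(top['n'])}/{int(top['K'])} vs background {int(top['k'])}/{int(top['N'])}; "
      f"arithmetic check: (10/28)/(200/4000) = {(10 / 28) / (200 / 4000):.2f}), q = {top['q']:.2e}")
print("an FC of 1 would mean the query hits the set at the background rate")
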
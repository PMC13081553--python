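"""Gene-set enrichment: fold change of percentages plus Fisher exact test.

For a query gene list (e.g. a DEG set) and a catalog gene set, the
enrichment fold change compares the fraction of the query that lands in the
set with the fraction of the universe the set occupies::

    FC = (n / K) / (k / N)

where ``n`` is the overlap, ``K`` the query size, ``k`` the set size and
``N`` the universe size.  FC = 1 means the query hits the set at the
background rate.  Significance is a one-sided Fisher exact test on the
corresponding 2x2 table, BH-adjusted across the catalog.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class GeneSetCatalog(dict):
    """Mapping of set name -> gene list; the universe is the union of all sets."""

    @property
    def universe(self) -> set[str]:
        u: set[str] = set()
        for genes in self.values():
            u.update(genes)
        return u


def read_gmt(path: str | Path) -> GeneSetCatalog:
    """Parse a tab-separated GMT file (name, description, genes...)."""
    catalog = GeneSetCatalog()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >= 1 gene")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        if not genes:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
        if name in catalog:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} listed twice")
        # de-duplicate, preserving order and case
        catalog[name] = list(dict.fromkeys(genes))
    return catalog


def write_gmt(catalog: GeneSetCatalog, path: str | Path, description: str = "na") -> None:
    lines = ["\t".join([name, description, *genes]) for name, genes in catalog.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def enrichment_fc(n: int, K: int, k: int, N: int, printed_form: bool = False) -> float:
    """Fold change of percentages: (n/K)/(k/N) (overlap rate over background rate).

    ``printed_form=True`` swaps n and k, giving a score that *decreases* with
    overlap; it is kept only for comparison and is not used by :func:`enrich`.
    """
    if K <= 0 or k <= 0 or N <= 0:
        raise ValueError("K, k, N must be positive")
    if printed_form:
        return (k / K) / (n / N) if n else float("inf")
    return (n / K) / (k / N)


def enrich(
    query_genes,
    catalog: GeneSetCatalog,
    universe_override=None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Score every catalog set against a query gene list.

    The universe defaults to the catalog union (optionally overridden with,
    e.g., the measured genes); query genes outside the universe are dropped.
    Returns a DataFrame (one row per set) with k, K, n, N, fc, one-sided
    Fisher p and BH q, sorted by p.
    """
    universe = set(universe_override) if universe_override is not None else catalog.universe
    N = len(universe)
    query = set(query_genes) & universe
    if not query:
        raise ValueError("query empty after intersecting with the universe")
    K = len(query)
    rows = []
    for name, genes in catalog.items():
        in_set = set(genes) & universe
        k = len(in_set)
        n = len(query & in_set)
        # 2x2: membership in set x membership in query, over the universe
        table = [[n, K - n], [k - n, N - K - (k - n)]]
        p = stats.fisher_exact(table, alternative="greater")[1]
        rows.append((name, k, K, n, N, enrichment_fc(n, K, k, N), float(p)))
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "fc", "p"]).set_index("set")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["q"] <= fdr
    return out.sort_values("p")


__all__ = ["GeneSetCatalog", "read_gmt", "write_gmt", "enrichment_fc", "enrich"]
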
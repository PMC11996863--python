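"""Over-representation analysis of site groups against gene sets.

Sites are collapsed to their parent genes (multiple sites on one protein
count once), and each gene set is tested for enrichment of the query genes
by the hypergeometric upper tail against a background universe — by
default all genes in the analyzed site table.  Benjamini-Hochberg
adjustment runs across sets.
"""

from __future__ import annotations

import re

import pandas as pd
from scipy import stats

from .diffstats import bh_fdr
from .io import GeneSetCollection

_SITE_ID = re.compile(r"^(?P<gene>.+)_(?P<residue>[STY])(?P<position>\d+)$")


def map_sites_to_genes(site_ids) -> list[str]:
    """Parent genes of the given ``GENE_S123``-style site ids, deduplicated
    in order of first occurrence."""
    genes: list[str] = []
    seen = set()
    for sid in site_ids:
        m = _SITE_ID.match(str(sid))
        if not m:
            raise ValueError(f"malformed site_id {sid!r}")
        gene = m.group("gene")
        if gene not in seen:
            seen.add(gene)
            genes.append(gene)
    return genes


def ora_test(
    query_genes,
    gene_sets: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene list in every set.

    For a universe of ``N`` genes containing ``K`` set members, a query of
    ``n`` genes overlapping the set in ``k``, ``p = P(X >= k)`` with
    ``X ~ Hypergeom(N, K, n)``.  Sets are intersected with the universe;
    the query must be a subset of the universe.  Returns one row per set
    with counts, p and BH FDR, sorted by p.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    query = list(dict.fromkeys(query_genes))
    outside = [g for g in query if g not in uni]
    if outside:
        raise ValueError(f"query genes outside the universe: {outside[:5]}")
    N, n = len(uni), len(query)
    qset = set(query)
    rows = []
    for name in gene_sets:
        members = [g for g in gene_sets[name] if g in uni]
        K = len(members)
        k = len(qset.intersection(members))
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {"set": name, "overlap": k, "query_size": n, "set_size": K,
             "universe_size": N, "p": p}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
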
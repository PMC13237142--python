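"""Over-representation analysis of binder lists against gene sets.

One-sided hypergeometric over-representation (equivalent to a one-sided
Fisher exact test) with Benjamini-Hochberg adjustment across sets. The
background universe must always be supplied explicitly -- typically all
quantified proteins -- because the p-value is meaningless without it.
Also provides iBAQ-rank annotation, used to check that high-affinity hits
are not simply the most abundant proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def hypergeom_overrep(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    N: universe size, K: gene-set size, n: query size, k: observed overlap.
    Computed through the survival function (log-space internally), so it is
    stable for large tables; k = 0 gives exactly 1.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if min(N, K, n, k) < 0 or K > N or n > N or k > min(K, n):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def run_ora(
    query: Iterable[str],
    gene_sets: Mapping[str, Tuple[str, Sequence[str]]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Test each gene set for over-representation in the query.

    Query ids outside the universe are dropped with a warning; duplicates
    are removed (set semantics). Gene-set members outside the universe do
    not count toward the set size. Results are BH-adjusted across all
    tested sets and sorted by adjusted then raw p.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe must not be empty")
    query_set = set(query)
    if not query_set:
        raise ValueError("query must not be empty")
    if not gene_sets:
        raise ValueError("gene-set collection must not be empty")
    stray = query_set - universe_set
    if stray:
        warnings.warn(f"dropped {len(stray)} query ids not in the universe")
        query_set &= universe_set
    if not query_set:
        raise ValueError("no query ids remain inside the universe")

    N, n = len(universe_set), len(query_set)
    rows = []
    for name, (_, members) in gene_sets.items():
        mem = set(members) & universe_set
        overlap = sorted(mem & query_set)
        rows.append(
            {
                "set_name": name,
                "universe_size": N,
                "set_size": len(mem),
                "query_size": n,
                "overlap": len(overlap),
                "p_value": hypergeom_overrep(N, len(mem), n, len(overlap)),
                "overlap_ids": ";".join(overlap),
            }
        )
    res = pd.DataFrame(rows)
    res["adj_p"] = multipletests(res["p_value"], method="fdr_bh")[1]
    res = res.sort_values(["adj_p", "p_value", "set_name"], kind="mergesort")
    return res.reset_index(drop=True)[
        ["set_name", "universe_size", "set_size", "query_size", "overlap",
         "p_value", "adj_p", "overlap_ids"]
    ]


def ibaq_rank_annotation(
    ibaq: pd.Series,
    highlight: Iterable[str],
    top_m: Optional[int] = None,
) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Rank proteins by iBAQ abundance and annotate a highlighted subset.

    Proteins are ranked descending by iBAQ (rank 1 = most abundant) and
    annotated with -log10(iBAQ). Returns the ranked table restricted to
    the highlighted ids (optionally the top_m by affinity order given) and
    a summary with the abundance span (orders of magnitude) of the
    highlighted set; highlighted ids absent from the abundance table are
    listed as unranked.
    """
    ibaq = ibaq.dropna()
    if (ibaq <= 0).any():
        raise ValueError("iBAQ values must be positive to be ranked")
    highlight = list(dict.fromkeys(highlight))
    if top_m is not None:
        highlight = highlight[:top_m]
    ranked = ibaq.sort_values(ascending=False)
    rank = pd.Series(np.arange(1, len(ranked) + 1), index=ranked.index)
    present = [h for h in highlight if h in ibaq.index]
    unranked = [h for h in highlight if h not in ibaq.index]
    table = pd.DataFrame(
        {
            "protein_id": present,
            "ibaq": [ibaq[h] for h in present],
            "rank": [int(rank[h]) for h in present],
            "neg_log10_ibaq": [-np.log10(ibaq[h]) for h in present],
        }
    )
    span = (
        float(np.log10(table["ibaq"].max() / table["ibaq"].min()))
        if len(table) >= 2
        else 0.0
    )
    summary = {
        "n_highlighted": len(present),
        "n_unranked": len(unranked),
        "unranked_ids": unranked,
        "rank_min": int(table["rank"].min()) if len(table) else None,
        "rank_max": int(table["rank"].max()) if len(table) else None,
        "abundance_span_orders": span,
    }
    return table, summary
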
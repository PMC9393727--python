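"""Term over-representation analysis with a directional z-score.

Enrichment of an annotation term in a feature set of size n drawn from
a background of size N, where the term annotates K background features
and k of the set, is scored with the one-sided hypergeometric upper
tail P(X >= k) (equivalently Fisher's exact test, greater).  P-values
are BH-adjusted across terms and flagged significant at adjusted
<= 0.05.  The background is the set of features measured in the
relevant omics layer, not the genome.

Each term also gets a directional z-score: the difference between the
numbers of up- and down-regulated set members annotated to it, divided
by the total number of its differential members — a value in [-1, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .rna import bh_adjust


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    X counts annotated features in a size-``n`` draw without replacement
    from ``N`` features of which ``K`` are annotated.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need K <= N and n <= N; got K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(feature_set, background, annotation: pd.DataFrame,
           direction: pd.Series | dict | None = None,
           alpha: float = 0.05) -> pd.DataFrame:
    """Test every annotated term for over-representation in a set.

    ``annotation`` holds (term, feature) rows; features outside the
    background are ignored.  ``direction`` optionally labels set members
    "up"/"down" for the z-score.  Returns one row per term with at
    least one set hit: ``k, K, n, N, p, adjusted, z_score, significant``,
    ordered by term ID.
    """
    fset = set(feature_set)
    bg = set(background)
    if not fset <= bg:
        extra = sorted(fset - bg)
        raise ValueError(f"feature set is not a subset of the background "
                         f"(e.g. {extra[:5]}); enrichment would be inflated")
    if direction is None:
        direction = {}
    elif isinstance(direction, pd.Series):
        direction = direction.to_dict()

    ann = annotation[["term", "feature"]].drop_duplicates()
    ann = ann[ann["feature"].isin(bg)]
    n, N = len(fset), len(bg)
    rows = []
    for term, members in ann.groupby("term")["feature"]:
        members = set(members)
        hits = members & fset
        k, K = len(hits), len(members)
        if k == 0:
            continue
        n_up = sum(1 for f in hits if direction.get(f) == "up")
        n_down = sum(1 for f in hits if direction.get(f) == "down")
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "p": hypergeometric_test(k, K, n, N),
                     "z_score": (n_up - n_down) / k})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p", "z_score"])
    out = out.sort_values("term").set_index("term")
    out["adjusted"] = bh_adjust(out["p"]) if len(out) else np.array([])
    out["significant"] = out["adjusted"] <= alpha
    return out[["k", "K", "n", "N", "p", "adjusted", "z_score", "significant"]]


def top_terms(results: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """The N most enriched terms.

    Ordered by ascending adjusted value, ties broken by ascending raw p
    and then lexical term ID, so the selection is deterministic.
    """
    # stable sort over a lexically ordered index implements the tie rule
    ranked = results.sort_index().sort_values(["adjusted", "p"], kind="mergesort")
    return ranked.head(n)
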
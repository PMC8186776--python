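"""Robust Rank Aggregation (RRA) of per-criterion gene rankings.

Each gene's positions in L ranked lists over a universe of m genes are
normalized to (0, 1].  Under the null that a gene's ranks are uniform, the
k-th smallest normalized rank r_(k) follows a Beta(k, L-k+1) distribution;
the rho score is the minimum over k of P(Beta(k, L-k+1) <= r_(k)), and a
Bonferroni-style correction multiplies by L (capped at 1).  Genes are
ordered by ascending rho: consistently top-ranked genes get small scores.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def normalize_ranks(
    lists: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
    universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Normalized rank matrix: genes x lists, r = position / m in (0, 1].

    Genes absent from a list take the worst rank 1.  The universe defaults
    to the union of all lists.
    """
    if not isinstance(lists, Mapping):
        lists = {f"list{i+1}": l for i, l in enumerate(lists)}
    for name, lst in lists.items():
        if len(set(lst)) != len(lst):
            raise ValueError(f"duplicate gene in ranking {name!r}")
    if universe is None:
        universe = sorted(set().union(*map(set, lists.values())))
    else:
        universe = list(universe)
    m = len(universe)
    if m == 0:
        raise ValueError("empty gene universe")
    mat = pd.DataFrame(1.0, index=pd.Index(universe, name="gene_id"), columns=list(lists))
    for name, lst in lists.items():
        for pos, gene in enumerate(lst, start=1):
            if gene in mat.index:
                mat.loc[gene, name] = pos / m
    return mat


def rra_rho(r: Sequence[float]) -> tuple[float, float]:
    """(rho, corrected) for one sorted normalized rank vector of length L.

    rho = min_k P(Beta(k, L-k+1) <= r_(k)); corrected = min(1, L * rho).
    """
    r = np.asarray(r, dtype=float)
    if r.size == 0:
        raise ValueError("empty rank vector")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("normalized ranks must lie in (0, 1]")
    r = np.sort(r)
    L = r.size
    k = np.arange(1, L + 1)
    rho = float(np.min(stats.beta.cdf(r, k, L - k + 1)))
    return rho, min(1.0, L * rho)


def aggregate(
    lists: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
    universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Aggregate rankings; rows sorted by ascending rho (ties on gene id).

    Returns a DataFrame indexed by gene id with one normalized-rank column
    per input list plus ``rho``, ``corrected`` and 1-based ``final_rank``.
    """
    mat = normalize_ranks(lists, universe)
    scores = mat.apply(lambda row: rra_rho(row.to_numpy()), axis=1, result_type="expand")
    mat["rho"] = scores[0]
    mat["corrected"] = scores[1]
    order = sorted(mat.index, key=lambda g: (mat.loc[g, "rho"], g))
    mat = mat.loc[order]
    mat["final_rank"] = np.arange(1, len(mat) + 1)
    return mat
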
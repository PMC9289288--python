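"""Gene-set enrichment: Fisher overrepresentation and preranked running-sum
enrichment with a gene-permutation null.

The preranked score is the weighted Kolmogorov-Smirnov-style running sum
(weight = |stat|, exponent 1) over genes ranked by a statistic (the Wald z
of a contrast); the null permutes gene labels, or enumerates every subset
of the universe when that is cheaper than sampling, making small cases
exact. NES divides the observed score by the mean |null score| of the same
sign. The permutation floor 1/(n_perm+1) bounds attainable p-values.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


def read_gmt(path: str) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str, source: str = "gravirebound") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, source, *sorted(sets[name])]) + "\n")


def mechanical_axis_set() -> dict[str, set[str]]:
    """The packaged 55-gene cytoskeletal-nuclear mechanical axis set."""
    from importlib import resources

    path = resources.files("gravirebound.data").joinpath("mechanical_axis.gmt")
    with resources.as_file(path) as p:
        return read_gmt(str(p))


def ora_fisher(
    query: set[str],
    universe: set[str],
    sets: dict[str, set[str]],
    alpha: float = 0.05,
    warn=None,
) -> pd.DataFrame:
    """Two-sided Fisher overrepresentation of each set in the query.

    Sets are intersected with the detected universe first; sets left empty
    are dropped (with a warning hook). The p-value depends only on the four
    margins (overlap, set size, query size, universe size).
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & set(universe)
    rows = []
    for name in sorted(sets):
        members = set(sets[name]) & set(universe)
        if not members:
            if warn is not None:
                warn(f"set {name} disjoint from universe; dropped")
            continue
        k = len(query & members)
        table = [
            [k, len(members) - k],
            [len(query) - k, len(universe) - len(members) - (len(query) - k)],
        ]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": len(members),
                "query_size": len(query),
                "universe_size": len(universe),
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame()
    if len(out):
        out["fdr"] = bh_adjust(out["p"])
        out["sig"] = out["fdr"] < alpha
    return out


def _running_es(weights: np.ndarray, hit_mask: np.ndarray) -> float:
    """Signed enrichment score: running-sum deviation with |stat| weights
    for hits and a uniform decrement for misses; the extreme of largest
    magnitude (first occurrence) is returned. Always in [-1, 1]."""
    w_hit = weights * hit_mask
    denom_hit = w_hit.sum()
    n_miss = int((~hit_mask).sum())
    if denom_hit == 0 or n_miss == 0:
        return 0.0
    inc = np.where(hit_mask, w_hit / denom_hit, -1.0 / n_miss)
    run = np.cumsum(inc)
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def preranked_enrichment(
    stat: pd.Series,
    sets: dict[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    max_size: int = 400,
    min_size: int = 2,
) -> pd.DataFrame:
    """Preranked enrichment of each set over the stat-ranked gene list.

    Genes are ranked by decreasing statistic, ties broken by gene id. Sets
    larger than ``max_size`` genes (after intersection with the universe)
    are excluded before testing. The null permutes which genes carry the set
    label: when the number of distinct subsets C(N, K) is at most ``n_perm``
    all subsets are enumerated and the p-value is exact; otherwise
    ``n_perm`` random subsets are drawn (seeded) and p carries the +1
    correction. p is the (two-sided) fraction of null |ES| at least as large
    as the observed |ES|; NES is ES over the mean |null ES| of the same sign.
    """
    if stat.index.has_duplicates:
        raise ValueError("duplicate gene ids in ranking")
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives a coarse permutation floor", stacklevel=2)
    order = sorted(stat.index, key=lambda g: (-stat[g], g))
    ranked_stat = stat.loc[order].to_numpy(dtype=float)
    weights = np.abs(ranked_stat)
    pos = {g: i for i, g in enumerate(order)}
    N = len(order)
    rng = np.random.default_rng(seed)

    rows = []
    for name in sorted(sets):
        members = set(sets[name]) & set(pos)
        K = len(members)
        if K > N - 1:
            raise ValueError(f"set {name} as large as the universe")
        if K < min_size or K > max_size:
            continue
        hit = np.zeros(N, dtype=bool)
        hit[[pos[g] for g in members]] = True
        es = _running_es(weights, hit)

        exhaustive = comb(N, K) <= n_perm
        null_es = []
        if exhaustive:
            for subset in combinations(range(N), K):
                mask = np.zeros(N, dtype=bool)
                mask[list(subset)] = True
                null_es.append(_running_es(weights, mask))
            null_es = np.array(null_es)
            p = float(np.mean(np.abs(null_es) >= abs(es) - 1e-12))
        else:
            for _ in range(n_perm):
                idx = rng.choice(N, size=K, replace=False)
                mask = np.zeros(N, dtype=bool)
                mask[idx] = True
                null_es.append(_running_es(weights, mask))
            null_es = np.array(null_es)
            p = (1.0 + float(np.sum(np.abs(null_es) >= abs(es) - 1e-12))) / (
                n_perm + 1.0
            )
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        nes = es / np.mean(np.abs(same_sign)) if len(same_sign) else np.nan
        rows.append(
            {
                "set": name,
                "size": K,
                "es": es,
                "nes": nes,
                "p": p,
                "exhaustive": exhaustive,
            }
        )
    out = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame()
    if len(out):
        out["fdr"] = bh_adjust(out["p"])
    return out
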
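"""Temporal rebound analysis.

Per-contrast regulation calls (up / down / ns / unobserved), transition
tables between adjacent contrasts, the refined 15-min categories (inner and
outer "grey" states: still below/above control, either constant or already
recovering), the fold-change anticorrelation statistic between adjacent
contrasts, and the multi-dataset coherence flow across exposure times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CALLS = ("up", "ns", "down")


def call_regulation(res: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Map a contrast result to calls: up (fdr < alpha, lfc > 0), down
    (fdr < alpha, lfc < 0), otherwise ns; genes without an fdr are
    unobserved. lfc exactly 0 with fdr < alpha breaks the tie to ns."""
    fdr = res["fdr"].to_numpy()
    lfc = res["lfc"].to_numpy()
    call = np.where(np.isnan(fdr), "unobserved", "ns").astype(object)
    sig = ~np.isnan(fdr) & (fdr < alpha)
    call[sig & (lfc > 0)] = "up"
    call[sig & (lfc < 0)] = "down"
    return pd.Series(call, index=res.index, name="call")


@dataclass
class TransitionTable:
    counts: pd.DataFrame  # CALLS x CALLS, rows = call at A, cols = call at B
    gene_lists: dict[tuple[str, str], list[str]]
    n_genes: int


def transition_table(calls_a: pd.Series, calls_b: pd.Series) -> TransitionTable:
    """3x3 transition counts over genes observable in both contrasts.

    The cells partition the common observable gene universe; gene ids are
    preserved per cell for export.
    """
    shared = calls_a.index.intersection(calls_b.index)
    a = calls_a.loc[shared]
    b = calls_b.loc[shared]
    keep = (a != "unobserved") & (b != "unobserved")
    a, b = a[keep], b[keep]
    if len(a) == 0:
        raise ValueError("no gene observable in both contrasts")
    counts = pd.DataFrame(0, index=list(CALLS), columns=list(CALLS))
    gene_lists: dict[tuple[str, str], list[str]] = {}
    for ca in CALLS:
        for cb in CALLS:
            ids = list(a.index[(a == ca) & (b == cb)])
            counts.at[ca, cb] = len(ids)
            gene_lists[(ca, cb)] = ids
    return TransitionTable(counts, gene_lists, int(len(a)))


def refine_grey_categories(
    calls3: pd.Series, calls15v3: pd.Series, calls15vc: pd.Series
) -> pd.Series:
    """Refined trajectory category per gene from the three contrasts.

    For a gene down at 3 min: still down vs control at 15 min while flat
    between 3 and 15 -> ``down_inner_grey``; still down vs control while
    rising -> ``down_outer_grey``; back to ns vs control -> ``down_recovered``;
    above control -> ``down_overshoot``; still falling -> ``down_continued``.
    Mirror categories for genes up at 3 min (an up gene that ends below
    control is ``up_overshoot``, the inverted overshoot). Genes ns at 3 min
    are labelled by their late behaviour (late_up / late_down / none).
    """
    shared = calls3.index.intersection(calls15v3.index).intersection(calls15vc.index)
    out = pd.Series("unobserved", index=shared, dtype=object, name="category")
    c3 = calls3.loc[shared]
    cm = calls15v3.loc[shared]
    cc = calls15vc.loc[shared]
    ok = (c3 != "unobserved") & (cm != "unobserved") & (cc != "unobserved")

    for start, fall_back in (("down", "up"), ("up", "down")):
        m = ok & (c3 == start)
        same_side = cc == start  # still lower (down) / higher (up) than control
        out[m & same_side & (cm == "ns")] = f"{start}_inner_grey"
        out[m & same_side & (cm == fall_back)] = f"{start}_outer_grey"
        out[m & same_side & (cm == start)] = f"{start}_continued"
        out[m & (cc == "ns")] = f"{start}_recovered"
        out[m & (cc == fall_back)] = f"{start}_overshoot"
    m = ok & (c3 == "ns")
    out[m] = "none"
    out[m & (cc == "up")] = "late_up"
    out[m & (cc == "down")] = "late_down"
    return out


@dataclass
class CoherenceSummary:
    rho: float
    p: float
    n: int
    flagged_constant: bool = False


def rebound_correlation(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    universe: str = "observable",
    alpha: float = 0.05,
) -> CoherenceSummary:
    """Spearman correlation of fold changes between two adjacent contrasts.

    The default universe is every gene observable in both contrasts;
    ``universe="deg"`` restricts to genes called differentially expressed in
    at least one of the two (sensitivity mode). Strong anticorrelation is the
    rebound signature. Constant inputs yield an undefined, flagged rho.
    """
    shared = res_a.index.intersection(res_b.index)
    a, b = res_a.loc[shared], res_b.loc[shared]
    keep = a["observable"] & b["observable"] & np.isfinite(a["lfc"]) & np.isfinite(b["lfc"])
    if universe == "deg":
        keep &= (a["fdr"] < alpha) | (b["fdr"] < alpha)
    elif universe != "observable":
        raise ValueError("universe must be 'observable' or 'deg'")
    x = a.loc[keep, "lfc"].to_numpy()
    y = b.loc[keep, "lfc"].to_numpy()
    if len(x) < 3:
        raise ValueError("need >= 3 shared genes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CoherenceSummary(np.nan, np.nan, len(x), flagged_constant=True)
    rho, p = stats.spearmanr(x, y)
    return CoherenceSummary(float(rho), float(p), int(len(x)))


def cross_dataset_coherence(
    call_tables: list[pd.Series],
    names: list[str] | None = None,
    min_de_datasets: int = 3,
) -> dict:
    """Sankey-style flow over datasets ordered by exposure time.

    Restricts to genes observable in every dataset, counts per-step 3x3
    flows, and reports per-step directional coherence: the probability that
    a gene non-ns at step k keeps the same direction at step k+1. Also
    returns the subset of genes differentially expressed (non-ns) in at
    least ``min_de_datasets`` datasets.
    """
    if len(call_tables) < 2:
        raise ValueError("need >= 2 datasets")
    names = names or [f"t{i}" for i in range(len(call_tables))]
    shared = call_tables[0].index
    for t in call_tables[1:]:
        shared = shared.intersection(t.index)
    tables = [t.loc[shared] for t in call_tables]
    keep = np.logical_and.reduce([(t != "unobserved").to_numpy() for t in tables])
    shared = shared[keep]
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes detected in all datasets")
    tables = [t.loc[shared] for t in tables]

    steps = []
    coherence = []
    for k in range(len(tables) - 1):
        tt = transition_table(tables[k], tables[k + 1])
        steps.append({"from": names[k], "to": names[k + 1], "counts": tt.counts})
        non_ns = tables[k].isin(["up", "down"])
        n_non_ns = int(non_ns.sum())
        same = int((tables[k][non_ns] == tables[k + 1][non_ns]).sum())
        coherence.append(same / n_non_ns if n_non_ns else np.nan)

    de_counts = sum((t.isin(["up", "down"])).astype(int) for t in tables)
    robust = list(shared[de_counts >= min_de_datasets])
    return {
        "genes": list(shared),
        "steps": steps,
        "coherence": coherence,
        "robust_genes": robust,
    }


def sankey_export(tt: TransitionTable, include_genes: bool = False) -> dict:
    """Plain JSON-able {nodes, links} view of a transition table."""
    nodes = [f"A_{c}" for c in CALLS] + [f"B_{c}" for c in CALLS]
    links = []
    for (ca, cb), ids in tt.gene_lists.items():
        link = {"source": f"A_{ca}", "target": f"B_{cb}", "count": len(ids)}
        if include_genes:
            link["gene_ids"] = ids
        links.append(link)
    return {"nodes": nodes, "links": links}
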
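"""Observed-vs-expected distribution of regulated genes over chromosomes and
cytobands.

Expectation model: differential expression is uniformly likely across
detected genes, so a region's expected DEG count is its detected-gene count
times the global DEG fraction, and its expected upregulated count is its DEG
count times the global up fraction among up+down. Deviations are tested per
region with two-sided Fisher tests (one family for DEG enrichment, one for
up/down skew), BH-adjusted within each family, and summarised by Spearman
correlations between the expected and actual vectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


def region_tallies(calls: pd.Series, region_of: pd.Series) -> pd.DataFrame:
    """Tally detected / DEG / up / down genes per region.

    ``calls`` holds up/down/ns/unobserved per gene; ``region_of`` maps gene
    to chromosome or cytoband. Unobserved genes are not detected; regions
    with no detected gene are dropped (they carry no testable signal).
    """
    df = pd.DataFrame({"call": calls, "region": region_of.reindex(calls.index)})
    df = df[df["region"].notna() & (df["call"] != "unobserved")]
    tally = df.groupby("region", sort=True).agg(
        n_detected=("call", "size"),
        n_up=("call", lambda c: int((c == "up").sum())),
        n_down=("call", lambda c: int((c == "down").sum())),
    )
    tally["n_deg"] = tally["n_up"] + tally["n_down"]
    return tally[tally["n_detected"] > 0]


def expected_counts(tally: pd.DataFrame) -> pd.DataFrame:
    """Add expected_deg and expected_up columns under the uniform model.

    Expectations are conserved exactly: summed over regions they equal the
    global DEG and up totals.
    """
    total_detected = int(tally["n_detected"].sum())
    if total_detected == 0:
        raise ValueError("no detected genes")
    total_deg = int(tally["n_deg"].sum())
    total_up = int(tally["n_up"].sum())
    total_down = int(tally["n_down"].sum())
    out = tally.copy()
    out["expected_deg"] = out["n_detected"] * total_deg / total_detected
    up_frac = total_up / (total_up + total_down) if (total_up + total_down) else 0.0
    out["expected_up"] = out["n_deg"] * up_frac
    return out


def fisher_region_tests(tally: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-region two-sided Fisher tests with BH adjustment per family.

    Family (a): DEG enrichment, 2x2 of [deg / non-deg x region / rest].
    Family (b): up/down skew, 2x2 of [up / down x region / rest].
    Degenerate margins give p = 1. Significant regions (fdr < alpha) are
    flagged with the direction of deviation from expectation.
    """
    out = expected_counts(tally)
    total_detected = int(out["n_detected"].sum())
    total_deg = int(out["n_deg"].sum())
    total_up = int(out["n_up"].sum())
    total_down = int(out["n_down"].sum())

    p_total, p_updown = [], []
    for _, row in out.iterrows():
        a = int(row["n_deg"])
        b = int(row["n_detected"]) - a
        c = total_deg - a
        d = (total_detected - int(row["n_detected"])) - c
        p_total.append(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        u, dn = int(row["n_up"]), int(row["n_down"])
        p_updown.append(
            stats.fisher_exact(
                [[u, dn], [total_up - u, total_down - dn]], alternative="two-sided"
            )[1]
        )
    out["fisher_p_total"] = p_total
    out["fisher_p_updown"] = p_updown
    out["fdr_total"] = bh_adjust(out["fisher_p_total"])
    out["fdr_updown"] = bh_adjust(out["fisher_p_updown"])
    out["deviation_deg"] = out["n_deg"] - out["expected_deg"]
    out["deviation_up"] = out["n_up"] - out["expected_up"]
    out["sig_total"] = out["fdr_total"] < alpha
    out["sig_updown"] = out["fdr_updown"] < alpha
    out["direction_total"] = np.where(out["deviation_deg"] >= 0, "above", "below")
    out["direction_updown"] = np.where(out["deviation_up"] >= 0, "above", "below")
    return out


def expected_actual_correlation(tally: pd.DataFrame) -> dict[str, float]:
    """Spearman rho between expected and actual vectors over regions,
    separately for total DEG counts and for up counts. Constant vectors are
    flagged with NaN."""
    out = expected_counts(tally)
    if len(out) < 3:
        raise ValueError("need >= 3 regions")

    def _rho(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return float("nan")
        return float(stats.spearmanr(x, y)[0])

    return {
        "rho_total": _rho(out["expected_deg"].to_numpy(), out["n_deg"].to_numpy()),
        "rho_updown": _rho(out["expected_up"].to_numpy(), out["n_up"].to_numpy()),
    }


def du_exon_distribution(
    du_calls: pd.Series, chrom_of: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Observed-vs-expected distribution of differentially used exons.

    ``du_calls`` maps bin id to "increased"/"decreased" usage; ``chrom_of``
    maps bin id to chromosome. The expected increased-usage count per region
    is its DU-exon count times the global increased:decreased ratio; regions
    with zero DU exons are skipped. Fisher tests + BH as for genes.
    """
    df = pd.DataFrame({"call": du_calls, "region": chrom_of.reindex(du_calls.index)})
    df = df[df["region"].notna() & df["call"].isin(["increased", "decreased"])]
    tally = df.groupby("region", sort=True).agg(
        n_du=("call", "size"),
        n_increased=("call", lambda c: int((c == "increased").sum())),
        n_decreased=("call", lambda c: int((c == "decreased").sum())),
    )
    tally = tally[tally["n_du"] > 0]
    g_inc = int(tally["n_increased"].sum())
    g_dec = int(tally["n_decreased"].sum())
    ratio = g_inc / (g_inc + g_dec) if (g_inc + g_dec) else 0.0
    tally["expected_increased"] = tally["n_du"] * ratio

    pvals = []
    for _, row in tally.iterrows():
        inc, dec = int(row["n_increased"]), int(row["n_decreased"])
        pvals.append(
            stats.fisher_exact(
                [[inc, dec], [g_inc - inc, g_dec - dec]], alternative="two-sided"
            )[1]
        )
    tally["fisher_p"] = pvals
    tally["fdr"] = bh_adjust(tally["fisher_p"])
    tally["sig"] = tally["fdr"] < alpha
    tally["direction"] = np.where(
        tally["n_increased"] >= tally["expected_increased"], "above", "below"
    )
    return tally
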
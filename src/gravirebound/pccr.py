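"""Protein coding counts ratio (PCCR).

Per gene and condition, PCCR is the fraction of transcript counts carried by
protein-coding isoforms: coding / (coding + noncoding), where the noncoding
pool is retained-intron + ORF-lacking + NMD isoforms. lncRNA counts sit in
neither pool by default (the strict formula); an option folds them into the
noncoding pool for the broader reading. A gene whose ratio moves by more
than one percent point between Ctrl and 3 min of hypergravity has increased
or decreased PCCR, otherwise constant; the classes are then tested for
association with differential expression per layer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

NONCODING_BIOTYPES = ("retained_intron", "orf_lacking", "nmd")
PCCR_CLASSES = ("increased", "decreased", "constant")


def compute_pccr(
    tx_counts: pd.DataFrame,
    condition_of: pd.Series | None = None,
    baseline: str = "Ctrl",
    treatment: str = "hypg3",
    threshold: float = 0.01,
    include_lncrna: bool = False,
) -> pd.DataFrame:
    """Per-gene PCCR per condition plus the shift class.

    ``tx_counts`` must carry ``gene_id`` and ``biotype`` columns and one
    count column per sample (summed per condition via ``condition_of``) or
    directly per condition. ``delta`` is pccr(treatment) - pccr(baseline);
    |delta| > ``threshold`` (strictly) separates increased/decreased from
    constant. Genes with a zero coding+noncoding total in either condition
    are ``undefined`` and excluded downstream.
    """
    meta = tx_counts[["gene_id", "biotype"]]
    counts = tx_counts.drop(columns=["gene_id", "biotype"])
    if condition_of is not None:
        counts = counts.T.groupby(condition_of.reindex(counts.columns)).sum().T
    conditions = list(counts.columns)
    for cond in (baseline, treatment):
        if cond not in conditions:
            raise ValueError(f"condition {cond!r} missing from counts")

    noncoding = set(NONCODING_BIOTYPES) | ({"lncRNA"} if include_lncrna else set())
    is_coding = meta["biotype"].eq("protein_coding")
    is_noncoding = meta["biotype"].isin(sorted(noncoding))

    coding = counts[is_coding].groupby(meta.loc[is_coding, "gene_id"]).sum()
    noncod = counts[is_noncoding].groupby(meta.loc[is_noncoding, "gene_id"]).sum()
    genes = sorted(set(meta["gene_id"]))
    coding = coding.reindex(genes, fill_value=0.0)
    noncod = noncod.reindex(genes, fill_value=0.0)

    denom = coding + noncod
    with np.errstate(divide="ignore", invalid="ignore"):
        pccr = (coding / denom).where(denom > 0)

    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for cond in conditions:
        out[f"pccr_{cond}"] = pccr[cond]
        out[f"coding_{cond}"] = coding[cond]
        out[f"noncoding_{cond}"] = noncod[cond]
    out["delta"] = out[f"pccr_{treatment}"] - out[f"pccr_{baseline}"]
    # strict inequality with a rounding guard so a delta of exactly one
    # percent point stays constant regardless of float representation
    eps = 1e-12
    cls = np.where(
        out["delta"].isna(),
        "undefined",
        np.where(
            out["delta"] > threshold + eps,
            "increased",
            np.where(out["delta"] < -(threshold + eps), "decreased", "constant"),
        ),
    )
    out["pccr_class"] = cls
    return out


def pccr_deg_overlap(
    pccr: pd.DataFrame,
    calls_by_layer: dict[str, pd.Series],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Association of PCCR classes with differential expression per layer.

    For each class and layer: DEG counts and fraction, up/down split, a
    two-sided Fisher test of the class's up/down split against all other
    genes of that layer, the expected split from the layer-wide DEG
    background, BH across tests, and significance stars (fdr < 0.05 "*",
    < 0.01 "**"). Classes with no DEGs in a layer are reported untested.
    """
    rows = []
    for layer, calls in calls_by_layer.items():
        shared = pccr.index.intersection(calls.index)
        cls = pccr.loc[shared, "pccr_class"]
        c = calls.loc[shared]
        deg = c.isin(["up", "down"])
        down_frac_all = float((c[deg] == "down").mean()) if deg.any() else np.nan
        for klass in PCCR_CLASSES:
            members = cls == klass
            n_genes = int(members.sum())
            n_up = int(((c == "up") & members).sum())
            n_down = int(((c == "down") & members).sum())
            n_deg = n_up + n_down
            rest_up = int((c == "up").sum()) - n_up
            rest_down = int((c == "down").sum()) - n_down
            p = (
                stats.fisher_exact(
                    [[n_up, n_down], [rest_up, rest_down]], alternative="two-sided"
                )[1]
                if n_deg > 0
                else np.nan
            )
            rows.append(
                {
                    "layer": layer,
                    "pccr_class": klass,
                    "n_genes": n_genes,
                    "n_deg": n_deg,
                    "deg_fraction": n_deg / n_genes if n_genes else np.nan,
                    "n_up": n_up,
                    "n_down": n_down,
                    "expected_down": n_deg * down_frac_all,
                    "fisher_p": p,
                }
            )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["fisher_p"])
    out["stars"] = np.where(
        out["fdr"] < 0.01, "**", np.where(out["fdr"] < alpha, "*", "")
    )
    out["skew"] = np.where(
        out["n_down"] > out["expected_down"], "down", "up"
    )
    return out.set_index(["layer", "pccr_class"])
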
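"""Transcript-biotype structure of differential exon usage.

Tabulates DU-affected transcripts by Ensembl biotype and usage direction,
and tests whether differentially expressed genes hosting DU transcripts of
one biotype are skewed toward up- or downregulation relative to DEGs hosting
DU transcripts of the other biotypes (two-sided Fisher, BH across biotypes,
groups under 20 DEGs excluded before adjustment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import BIOTYPES, GenomeAnnotation
from .diffexpr import bh_adjust


def biotype_tally(du_transcripts: pd.DataFrame, ann: GenomeAnnotation) -> pd.DataFrame:
    """Counts (and within-direction fractions) of DU transcripts per biotype.

    ``du_transcripts`` is the deduplicated transcript/direction table from
    the exon-usage stage. Transcripts with unrecognised biotypes fall in the
    ``other`` bucket.
    """
    rows = []
    for _, row in du_transcripts.iterrows():
        t = ann.transcripts.get(row["transcript_id"])
        bt = t.biotype if t is not None and t.biotype in BIOTYPES else "other"
        rows.append((bt, row["direction"]))
    if not rows:
        return pd.DataFrame(columns=["increased", "decreased"])
    df = pd.DataFrame(rows, columns=["biotype", "direction"])
    tally = df.pivot_table(
        index="biotype", columns="direction", aggfunc="size", fill_value=0
    )
    for col in ("increased", "decreased"):
        if col not in tally:
            tally[col] = 0
    tally = tally[["increased", "decreased"]]
    frac = tally / tally.sum(axis=0).replace(0, np.nan)
    return tally.join(frac.add_prefix("fraction_"))


def biotype_deg_association(
    du_transcripts: pd.DataFrame,
    gene_calls: pd.Series,
    ann: GenomeAnnotation,
    min_degs: int = 20,
    alpha: float = 0.05,
    background: str = "pair",
) -> pd.DataFrame:
    """Up/down skew of DEGs hosting DU transcripts of each biotype.

    For each biotype, the test group is the DEGs (genes called up or down,
    typically on the spliced layer) that host at least one DU transcript of
    that biotype; the background is DEGs hosting DU transcripts of the other
    biotypes. With ``background="pair"`` a gene hosting DU transcripts of two
    biotypes contributes to both margins (gene-biotype pairs);
    ``background="gene"`` excludes the test genes from the background.
    Groups with fewer than ``min_degs`` DEGs are excluded before BH.
    ``expected_down`` is the group size times the global downregulated
    fraction among all DEGs of the contrast.
    """
    if background not in ("pair", "gene"):
        raise ValueError("background must be 'pair' or 'gene'")
    deg_calls = gene_calls[gene_calls.isin(["up", "down"])]
    total_down_frac = (
        float((deg_calls == "down").mean()) if len(deg_calls) else np.nan
    )

    genes_by_biotype: dict[str, set[str]] = {}
    for _, row in du_transcripts.iterrows():
        t = ann.transcripts.get(row["transcript_id"])
        if t is None:
            continue
        bt = t.biotype if t.biotype in BIOTYPES else "other"
        gid = t.gene_id
        if gid in deg_calls.index:
            genes_by_biotype.setdefault(bt, set()).add(gid)

    columns = [
        "n_deg", "n_up", "n_down", "expected_down", "included", "fisher_p"
    ]
    if not genes_by_biotype:
        return pd.DataFrame(columns=columns, index=pd.Index([], name="biotype"))

    rows = []
    for bt in sorted(genes_by_biotype):
        group = genes_by_biotype[bt]
        n_up = int((deg_calls.loc[sorted(group)] == "up").sum())
        n_down = len(group) - n_up
        if background == "pair":
            other_up = other_down = 0
            for bt2, genes2 in genes_by_biotype.items():
                if bt2 == bt:
                    continue
                other_up += int((deg_calls.loc[sorted(genes2)] == "up").sum())
                other_down += len(genes2) - int(
                    (deg_calls.loc[sorted(genes2)] == "up").sum()
                )
        else:
            others = set().union(
                *(g for b, g in genes_by_biotype.items() if b != bt), set()
            ) - group
            other_up = int((deg_calls.loc[sorted(others)] == "up").sum())
            other_down = len(others) - other_up
        included = len(group) >= min_degs
        p = (
            stats.fisher_exact(
                [[n_up, n_down], [other_up, other_down]], alternative="two-sided"
            )[1]
            if included
            else np.nan
        )
        rows.append(
            {
                "biotype": bt,
                "n_deg": len(group),
                "n_up": n_up,
                "n_down": n_down,
                "expected_down": len(group) * total_down_frac,
                "included": included,
                "fisher_p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("biotype")
    if len(out):
        out["fdr"] = bh_adjust(out["fisher_p"])
        out["sig"] = out["fdr"] < alpha
    return out
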
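"""Differential exon usage on flattened counting bins.

Overlapping exons of a gene's isoforms are split at every boundary into
disjoint bins, each recording the set of parent transcripts. The usage of a
bin is its share of the gene's counts; the test contrasts the (log) ratio of
bin counts to the gene-remainder counts between conditions, so gene-level
expression changes cancel by construction and only isoform-composition
shifts register. Significant bins map to their parent transcripts (each
transcript once per usage direction) for the biotype analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation
from .diffexpr import bh_adjust, estimate_dispersion


@dataclass(frozen=True)
class ExonBin:
    bin_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    transcript_ids: frozenset[str]

    @property
    def length(self) -> int:
        return self.end - self.start


def flatten_exons(ann: GenomeAnnotation) -> pd.DataFrame:
    """DEXSeq-style disjoint counting bins per gene.

    Exon boundaries of all isoforms split the gene's exonic territory into
    bins; each bin lists every transcript containing it. Returns a frame
    with one row per bin (bin_id = gene:index, ordered along the genome).
    """
    rows = []
    for gid, gene in ann.genes.items():
        edges = set()
        txs = ann.gene_transcripts(gid)
        for t in txs:
            for s, e in t.exons:
                edges.add(s)
                edges.add(e)
        edges = sorted(edges)
        idx = 0
        for s, e in zip(edges, edges[1:]):
            parents = frozenset(
                t.transcript_id
                for t in txs
                if any(es <= s and e <= ee for es, ee in t.exons)
            )
            if not parents:  # intronic segment between exon boundaries
                continue
            rows.append(
                ExonBin(f"{gid}:E{idx:03d}", gid, gene.chrom, s, e, parents)
            )
            idx += 1
    return pd.DataFrame(
        {
            "bin_id": [b.bin_id for b in rows],
            "gene_id": [b.gene_id for b in rows],
            "chrom": [b.chrom for b in rows],
            "start": [b.start for b in rows],
            "end": [b.end for b in rows],
            "length": [b.length for b in rows],
            "transcript_ids": [b.transcript_ids for b in rows],
        }
    ).set_index("bin_id")


def count_bins(
    sam_paths: dict[str, str],
    ann: GenomeAnnotation,
    bins: pd.DataFrame,
) -> pd.DataFrame:
    """Count read pairs into exon bins; a pair counts toward every bin one of
    its aligned blocks overlaps (deterministic whole-pair counting, junction
    reads hit every bin they touch)."""
    from .splice import GeneIndex, _iter_pairs, _mate_blocks_gaps, assign_gene

    index = GeneIndex(ann)
    by_gene = {gid: sub for gid, sub in bins.groupby("gene_id", sort=False)}
    out = pd.DataFrame(0, index=bins.index, columns=pd.Index(sam_paths, name="sample"))
    for sample, path in sam_paths.items():
        for mates in _iter_pairs(path):
            gid = assign_gene(mates, index)
            if gid is None or gid not in by_gene:
                continue
            sub = by_gene[gid]
            blocks = []
            for m in mates:
                bl, _ = _mate_blocks_gaps(m)
                blocks.extend(bl)
            hit = set()
            for bs, be in blocks:
                sel = (sub["start"] < be) & (sub["end"] > bs)
                hit.update(sub.index[sel])
            for bin_id in hit:
                out.at[bin_id, sample] += 1
    return out


def deu_test(
    bin_counts: pd.DataFrame,
    bins: pd.DataFrame,
    sf: pd.Series,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential usage test per bin plus per-gene aggregation.

    For each bin, usage is contrasted via the log ratio of normalized bin
    counts to gene-remainder counts between the two conditions; the Wald
    statistic uses NB variances with trend-shrunk dispersions estimated
    separately for bin and remainder counts. ``usage_lfc`` > 0 means
    increased usage in ``group_a``. Genes with a single bin are skipped
    (usage undefined). Gene-level q: Sidak-aggregated minimum bin p
    (1 - (1-p_min)^k), BH across genes.
    """
    gene_of = bins["gene_id"].reindex(bin_counts.index)
    multi = gene_of.map(gene_of.value_counts()) > 1
    counts = bin_counts[multi]
    gene_of = gene_of[multi]

    gene_totals = counts.groupby(gene_of).transform("sum")
    remainder = gene_totals - counts

    disp_bin = estimate_dispersion(counts, sf, groups)
    disp_rem = estimate_dispersion(remainder, sf, groups)

    cols_a = list(groups.index[groups == group_a])
    cols_b = list(groups.index[groups == group_b])
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both groups need >= 2 replicates")

    sf_v = sf.reindex(counts.columns).to_numpy()
    x = np.ascontiguousarray(counts.to_numpy(dtype=float)) / sf_v[None, :]
    r = np.ascontiguousarray(remainder.to_numpy(dtype=float)) / sf_v[None, :]
    ia = [counts.columns.get_loc(c) for c in cols_a]
    ib = [counts.columns.get_loc(c) for c in cols_b]

    def _ratio_stats(idx):
        xm = x[:, idx].mean(axis=1)
        rm = r[:, idx].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_ratio = np.log(xm) - np.log(rm)
            var = (
                (1.0 / xm + disp_bin.to_numpy())
                + (1.0 / rm + disp_rem.to_numpy())
            ) / len(idx)
        return log_ratio, var, xm, rm

    la, va, xa, ra = _ratio_stats(ia)
    lb, vb, xb, rb = _ratio_stats(ib)
    defined = (xa > 0) & (xb > 0) & (ra > 0) & (rb > 0)
    with np.errstate(invalid="ignore"):
        z = (la - lb) / np.sqrt(va + vb)
    usage_lfc = (la - lb) / np.log(2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(defined, p, np.nan)
    usage_lfc = np.where(defined, usage_lfc, np.nan)

    res = pd.DataFrame(
        {
            "gene_id": gene_of.to_numpy(),
            "usage_lfc": usage_lfc,
            "stat": np.where(defined, z, np.nan),
            "p": p,
            "fdr": bh_adjust(p),
        },
        index=counts.index,
    )
    res["call"] = "ns"
    res.loc[res["p"].isna(), "call"] = "unobserved"
    res.loc[(res["fdr"] < alpha) & (res["usage_lfc"] > 0), "call"] = "increased"
    res.loc[(res["fdr"] < alpha) & (res["usage_lfc"] < 0), "call"] = "decreased"

    gene_rows = []
    for gid, sub in res.groupby("gene_id", sort=True):
        pv = sub["p"].dropna()
        if pv.empty:
            gene_rows.append((gid, np.nan, len(sub)))
            continue
        k = len(pv)
        p_gene = 1.0 - (1.0 - pv.min()) ** k
        gene_rows.append((gid, p_gene, k))
    gene_df = pd.DataFrame(gene_rows, columns=["gene_id", "p_gene", "n_bins"]).set_index(
        "gene_id"
    )
    gene_df["gene_q"] = bh_adjust(gene_df["p_gene"])
    gene_df["significant_deu"] = gene_df["gene_q"] < alpha
    return res, gene_df


def du_temporal_coherence(calls_a: pd.Series, calls_b: pd.Series):
    """Transition table of increased/ns/decreased usage calls between two
    contrasts, over bins with a defined FDR in both (same machinery as the
    gene-level rebound flows)."""
    from .dynamics import TransitionTable  # noqa: F401 - same return type

    from . import dynamics

    remap = {"increased": "up", "decreased": "down", "ns": "ns", "unobserved": "unobserved"}
    tt = dynamics.transition_table(calls_a.map(remap), calls_b.map(remap))
    back = {"up": "increased", "ns": "ns", "down": "decreased"}
    tt.counts.index = [back[c] for c in tt.counts.index]
    tt.counts.columns = [back[c] for c in tt.counts.columns]
    tt.gene_lists = {
        (back[a], back[b]): ids for (a, b), ids in tt.gene_lists.items()
    }
    return tt


def map_du_to_transcripts(
    deu_res: pd.DataFrame, bins: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Transcripts affected by significant differential usage, by direction.

    Every parent transcript of a significant bin is included; duplicates are
    collapsed to a single instance per usage direction (a transcript hit by
    bins of both signs appears once in each direction).
    """
    sig = deu_res[(deu_res["fdr"] < alpha) & deu_res["usage_lfc"].notna()]
    seen = set()
    rows = []
    for bin_id, row in sig.iterrows():
        direction = "increased" if row["usage_lfc"] > 0 else "decreased"
        for tid in sorted(bins.at[bin_id, "transcript_ids"]):
            key = (tid, direction)
            if key in seen:
                continue
            seen.add(key)
            rows.append((tid, direction, row["gene_id"]))
    return pd.DataFrame(rows, columns=["transcript_id", "direction", "gene_id"])
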
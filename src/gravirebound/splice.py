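"""Classify aligned bulk read pairs into spliced / unspliced / ambiguous
layers per gene.

A pair provides *spliced* evidence when a mate's alignment gap matches an
annotated intron exactly at both boundaries (and its blocks lie in that
transcript's exons); *unspliced* evidence when any aligned base overlaps a
position that is intronic in every isoform of the gene. Unspliced evidence
takes precedence at the pair level; reads in intron-less genes fall in the
spliced pool by definition; everything else is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation import (
    GenomeAnnotation,
    Transcript,
    constitutive_introns,
    gene_has_introns,
    intron_intervals,
)
from .layers import LayeredCounts


class ReadClass(str, Enum):
    SPLICED = "spliced"
    UNSPLICED = "unspliced"
    AMBIGUOUS = "ambiguous"
    UNASSIGNED = "unassigned"


@dataclass
class _GeneGeometry:
    transcripts: list[Transcript]
    exon_sets: list[set[tuple[int, int]]]
    intron_sets: list[set[tuple[int, int]]]
    const_introns: list[tuple[int, int]]
    has_introns: bool


class GeneIndex:
    """Interval index of gene spans plus cached per-gene geometry."""

    def __init__(self, ann: GenomeAnnotation):
        self.ann = ann
        self.trees: dict[str, IntervalTree] = {}
        for gid, gene in ann.genes.items():
            tree = self.trees.setdefault(gene.chrom, IntervalTree())
            tree.addi(gene.span[0], gene.span[1], gid)
        self._geom: dict[str, _GeneGeometry] = {}

    def geometry(self, gene_id: str) -> _GeneGeometry:
        geom = self._geom.get(gene_id)
        if geom is None:
            txs = self.ann.gene_transcripts(gene_id)
            geom = _GeneGeometry(
                transcripts=txs,
                exon_sets=[set(t.exons) for t in txs],
                intron_sets=[set(intron_intervals(t)) for t in txs],
                const_introns=constitutive_introns(self.ann, gene_id),
                has_introns=gene_has_introns(self.ann, gene_id),
            )
            self._geom[gene_id] = geom
        return geom


def _mate_blocks_gaps(read: pysam.AlignedSegment):
    """Aligned reference blocks and N-gap intervals of one mate."""
    blocks: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    pos = read.reference_start
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):  # M/=/X consume reference and are aligned
            if blocks and blocks[-1][1] == pos:
                blocks[-1] = (blocks[-1][0], pos + length)
            else:
                blocks.append((pos, pos + length))
            pos += length
        elif op == 3:  # N
            gaps.append((pos, pos + length))
            pos += length
        elif op == 2:  # D consumes reference but is not a splice gap
            pos += length
    return blocks, gaps


def assign_gene(mates: list[pysam.AlignedSegment], index: GeneIndex) -> str | None:
    """Gene whose span contains all aligned blocks of the pair.

    Multiple candidate genes, none, or an unknown chromosome yield
    ``None`` (unassigned). Unmapped mates are ignored (classification by the
    mapped mate only).
    """
    chroms = {m.reference_name for m in mates}
    if len(chroms) != 1:
        return None
    tree = index.trees.get(chroms.pop())
    if tree is None:
        return None
    all_blocks = []
    for m in mates:
        blocks, _ = _mate_blocks_gaps(m)
        all_blocks.extend(blocks)
    if not all_blocks:
        return None
    lo = min(s for s, _ in all_blocks)
    hi = max(e for _, e in all_blocks)
    candidates = sorted(
        iv.data for iv in tree.overlap(lo, hi) if iv.begin <= lo and hi <= iv.end
    )
    if len(candidates) != 1:
        return None
    return candidates[0]


def _overlaps(blocks, intervals) -> bool:
    for bs, be in blocks:
        for s, e in intervals:
            if bs < e and be > s:
                return True
    return False


def classify_pair(mates: list[pysam.AlignedSegment], geom: _GeneGeometry) -> ReadClass:
    """Apply the layer rules to a (possibly single-mate) read pair.

    Rule order: unspliced evidence from either mate wins; otherwise spliced
    evidence (exact-intron gap) from either mate; otherwise intron-less genes
    are spliced by definition; otherwise ambiguous. The result is invariant
    to transcript ordering and mate ordering.
    """
    spliced_evidence = False
    unspliced_evidence = False
    for m in mates:
        blocks, gaps = _mate_blocks_gaps(m)
        if not blocks:
            continue
        if _overlaps(blocks, geom.const_introns):
            unspliced_evidence = True
            continue
        if gaps:
            for exons, introns in zip(geom.exon_sets, geom.intron_sets):
                if not all(g in introns for g in gaps):
                    continue
                exon_ivs = sorted(exons)
                if all(
                    any(es <= bs and be <= ee for es, ee in exon_ivs)
                    for bs, be in blocks
                ):
                    spliced_evidence = True
                    break
    if unspliced_evidence:
        return ReadClass.UNSPLICED
    if spliced_evidence:
        return ReadClass.SPLICED
    if not geom.has_introns:
        return ReadClass.SPLICED
    return ReadClass.AMBIGUOUS


def _iter_pairs(path: str):
    """Yield primary read pairs (or orphans) grouped by query name.

    Secondary, supplementary, duplicate-flagged and unmapped records are
    dropped so each fragment votes once.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(path, check_sq=True) as fh:
        for read in fh:
            if (
                read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.is_unmapped
            ):
                continue
            if not read.is_paired:
                yield [read]
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
            else:
                yield [mate, read]
    yield from ([m] for m in pending.values())


def count_layers(
    sam_paths: dict[str, str] | list[str],
    ann: GenomeAnnotation,
) -> tuple[LayeredCounts, pd.DataFrame]:
    """Count read pairs per gene and layer; one alignment file per sample.

    ``sam_paths`` maps sample name to SAM/BAM path (a list uses file stems).
    Every assigned pair is counted exactly once in one layer of one gene,
    independent of record order in the file. Returns the layered counts and
    a per-sample summary (assigned / unassigned / per-layer tallies).
    """
    if not isinstance(sam_paths, dict):
        import os

        sam_paths = {
            os.path.splitext(os.path.basename(p))[0]: p for p in sam_paths
        }
    index = GeneIndex(ann)
    genes = pd.Index(list(ann.genes), name="gene_id")
    samples = pd.Index(list(sam_paths), name="sample")
    frames = {
        layer: pd.DataFrame(0, index=genes, columns=samples)
        for layer in ("spliced", "unspliced", "ambiguous")
    }
    summary_rows = []
    for sample, path in sam_paths.items():
        tallies = {"spliced": 0, "unspliced": 0, "ambiguous": 0, "unassigned": 0}
        for mates in _iter_pairs(path):
            gid = assign_gene(mates, index)
            if gid is None:
                tallies["unassigned"] += 1
                continue
            cls = classify_pair(mates, index.geometry(gid))
            frames[cls.value].at[gid, sample] += 1
            tallies[cls.value] += 1
        summary_rows.append({"sample": sample, **tallies})
    summary = pd.DataFrame(summary_rows).set_index("sample")
    return LayeredCounts(**frames), summary
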
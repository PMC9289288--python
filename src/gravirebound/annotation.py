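"""Gene models and cytobands.

Parses Ensembl-dialect GTF into an in-memory :class:`GenomeAnnotation` with
0-based half-open coordinates, exposes exon/intron geometry, transcript
biotypes, and strand-aware cytoband assignment. All downstream stages (read
classification, exon flattening, chromosome/cytoband tallies, biotype
analyses) consume this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils

#: Recognised transcript biotypes. Ensembl's "processed_transcript" is the
#: ORF-lacking category; "nonsense_mediated_decay" is NMD.
BIOTYPES = ("protein_coding", "retained_intron", "orf_lacking", "nmd", "lncRNA", "other")

ENSEMBL_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "retained_intron": "retained_intron",
    "processed_transcript": "orf_lacking",
    "orf_lacking": "orf_lacking",
    "nonsense_mediated_decay": "nmd",
    "nmd": "nmd",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
}


def map_biotype(raw: str | None) -> str:
    """Map an Ensembl biotype string onto the internal enum (default ``other``)."""
    if raw is None:
        return "other"
    return ENSEMBL_BIOTYPE_MAP.get(raw, "other")


class GTFParseError(ValueError):
    pass


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    biotype: str = "other"
    #: sorted, non-overlapping (start, end) 0-based half-open intervals
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    transcript_ids: list[str] = field(default_factory=list)
    cytoband: str | None = None

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (0-based position of the first transcribed base)."""
        return self.span[0] if self.strand != "-" else self.span[1] - 1


@dataclass
class Cytoband:
    chrom: str
    name: str
    start: int
    end: int


@dataclass
class GenomeAnnotation:
    genes: dict[str, Gene] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    cytobands: list[Cytoband] = field(default_factory=list)

    def gene_transcripts(self, gene_id: str) -> list[Transcript]:
        return [self.transcripts[t] for t in self.genes[gene_id].transcript_ids]

    def validate(self) -> None:
        for t in self.transcripts.values():
            if not t.exons:
                raise ValueError(f"transcript {t.transcript_id} has no exons")
            for (s0, e0), (s1, e1) in zip(t.exons, t.exons[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping/unsorted exons in {t.transcript_id}")
            if t.gene_id not in self.genes:
                raise ValueError(f"transcript {t.transcript_id} references unknown gene")
            if t.biotype not in BIOTYPES:
                raise ValueError(f"unknown biotype {t.biotype!r}")
        for g in self.genes.values():
            exon_union = union_exons(self, g.gene_id)
            if (exon_union[0][0], exon_union[-1][1]) != tuple(g.span):
                raise ValueError(f"gene {g.gene_id} span does not cover its exons")
            if g.chrom in self.chrom_lengths and g.span[1] > self.chrom_lengths[g.chrom]:
                raise ValueError(f"gene {g.gene_id} exceeds chromosome length")


def intron_intervals(t: Transcript) -> list[tuple[int, int]]:
    """Gaps between consecutive exons; zero-length gaps (abutting exons) dropped."""
    out = []
    for (_, e0), (s1, _) in zip(t.exons, t.exons[1:]):
        if s1 > e0:
            out.append((e0, s1))
    return out


def merge_intervals(intervals) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_intervals(a, b) -> list[tuple[int, int]]:
    out, i, j = [], 0, 0
    a, b = list(a), list(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def union_exons(ann: GenomeAnnotation, gene_id: str) -> list[tuple[int, int]]:
    """Merged union of exon intervals over all transcripts of the gene."""
    ivs: list[tuple[int, int]] = []
    for t in ann.gene_transcripts(gene_id):
        ivs.extend(t.exons)
    return merge_intervals(ivs)


def constitutive_introns(ann: GenomeAnnotation, gene_id: str) -> list[tuple[int, int]]:
    """Positions intronic in *every* transcript of the gene.

    A read overlapping these positions cannot come from any mature isoform,
    which is the evidence used to place it in the unspliced layer.
    """
    transcripts = ann.gene_transcripts(gene_id)
    result: list[tuple[int, int]] | None = None
    for t in transcripts:
        ivs = intron_intervals(t)
        result = ivs if result is None else intersect_intervals(result, ivs)
        if not result:
            return []
    return result or []


def gene_has_introns(ann: GenomeAnnotation, gene_id: str) -> bool:
    return any(len(t.exons) > 1 for t in ann.gene_transcripts(gene_id))


# ---------------------------------------------------------------------------
# GTF I/O (Ensembl dialect; 1-based closed on disk, 0-based half-open inside)
# ---------------------------------------------------------------------------

def read_gtf(path: str) -> GenomeAnnotation:
    """Read a GTF file into a :class:`GenomeAnnotation`.

    Only ``exon`` features are required; gene spans are derived from exon
    unions. Biotype is taken from ``transcript_biotype`` (or ``biotype``)
    attributes, defaulting to ``other``. Raises :class:`GTFParseError` with
    the offending line number on malformed input.
    """
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gene, chrom, strand, biotype)
    chrom_max: dict[str, int] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise GTFParseError(
                    f"malformed GTF line {lineno}: expected 9 tab-separated fields"
                )
            try:
                feat = gffutils.feature.feature_from_line(line, dialect=None)
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise GTFParseError(f"malformed GTF line {lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            if "transcript_id" not in attrs:
                raise GTFParseError(f"exon without transcript_id at line {lineno}")
            if "gene_id" not in attrs:
                raise GTFParseError(f"exon without gene_id at line {lineno}")
            tid = attrs["transcript_id"][0]
            gid = attrs["gene_id"][0]
            raw_bt = None
            for key in ("transcript_biotype", "biotype"):
                if key in attrs:
                    raw_bt = attrs[key][0]
                    break
            start = feat.start - 1  # GTF 1-based closed -> 0-based half-open
            end = feat.end
            if start < 0 or end <= start:
                raise GTFParseError(f"invalid coordinates at line {lineno}")
            tx_exons.setdefault(tid, []).append((start, end))
            tx_meta.setdefault(tid, (gid, feat.seqid, feat.strand, map_biotype(raw_bt)))
            chrom_max[feat.seqid] = max(chrom_max.get(feat.seqid, 0), end)

    ann = GenomeAnnotation(chrom_lengths=dict(sorted(chrom_max.items())))
    gene_info: dict[str, list[str]] = {}
    for tid in sorted(tx_exons):
        gid, chrom, strand, biotype = tx_meta[tid]
        exons = sorted(tx_exons[tid])
        ann.transcripts[tid] = Transcript(tid, gid, biotype, exons)
        gene_info.setdefault(gid, []).append(tid)

    for gid, tids in gene_info.items():
        chrom, strand = tx_meta[tids[0]][1], tx_meta[tids[0]][2]
        spans = [ann.transcripts[t].span for t in tids]
        gene_span = (min(s for s, _ in spans), max(e for _, e in spans))
        ann.genes[gid] = Gene(gid, chrom, strand, gene_span, sorted(tids))

    # deterministic ordering by (chrom, start, id)
    ann.genes = dict(
        sorted(ann.genes.items(), key=lambda kv: (kv[1].chrom, kv[1].span[0], kv[0]))
    )
    ann.transcripts = dict(
        sorted(
            ann.transcripts.items(),
            key=lambda kv: (
                ann.genes[kv[1].gene_id].chrom,
                kv[1].span[0],
                kv[0],
            ),
        )
    )
    ann.validate()
    return ann


_BIOTYPE_TO_ENSEMBL = {
    "protein_coding": "protein_coding",
    "retained_intron": "retained_intron",
    "orf_lacking": "processed_transcript",
    "nmd": "nonsense_mediated_decay",
    "lncRNA": "lncRNA",
    "other": "other",
}


def write_gtf(ann: GenomeAnnotation, path: str) -> None:
    """Write the annotation back to GTF (inverse of :func:`read_gtf`)."""
    with open(path, "w") as fh:
        for gid, gene in ann.genes.items():
            for tid in gene.transcript_ids:
                t = ann.transcripts[tid]
                bt = _BIOTYPE_TO_ENSEMBL[t.biotype]
                for s, e in t.exons:
                    attrs = (
                        f'gene_id "{gid}"; transcript_id "{tid}"; '
                        f'transcript_biotype "{bt}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                gene.chrom,
                                "gravirebound",
                                "exon",
                                str(s + 1),
                                str(e),
                                ".",
                                gene.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def read_cytobands(path: str) -> list[Cytoband]:
    """Read a 4-column TSV (chrom, start, end, name) of 0-based half-open bands."""
    bands = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"cytoband line {lineno}: expected 4 columns")
            chrom, start, end, name = parts[:4]
            bands.append(Cytoband(chrom, name, int(start), int(end)))
    return bands


def assign_cytobands(ann: GenomeAnnotation, warn=None) -> dict[str, str | None]:
    """Assign each gene to the band containing its strand-aware 5' end.

    Genes on chromosomes absent from the band table, or whose 5' end falls
    outside every band, map to ``None`` (unassigned). The assignment is also
    stored on each :class:`Gene`.
    """
    by_chrom: dict[str, list[Cytoband]] = {}
    for band in ann.cytobands:
        by_chrom.setdefault(band.chrom, []).append(band)
    for bands in by_chrom.values():
        bands.sort(key=lambda b: b.start)

    out: dict[str, str | None] = {}
    for gid, gene in ann.genes.items():
        assigned = None
        bands = by_chrom.get(gene.chrom)
        if bands is None:
            if warn is not None and ann.cytobands:
                warn(f"gene {gid}: chromosome {gene.chrom} absent from cytoband table")
        else:
            pos = gene.tss
            for band in bands:
                if band.start <= pos < band.end:
                    assigned = band.name
                    break
        gene.cytoband = assigned
        out[gid] = assigned
    return out
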
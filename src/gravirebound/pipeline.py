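"""End-to-end orchestration: counts -> per-layer differential expression ->
rebound dynamics -> genomic distribution -> differential exon usage ->
biotype association -> PCCR -> enrichment, from a single YAML config, with
a deterministic manifest and a one-command synthetic demo.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import (
    annotation,
    biotypes,
    distribution,
    diffexpr,
    dynamics,
    enrichment,
    exon_usage,
    pccr as pccr_mod,
    simulate,
)
from .layers import LayeredCounts


@dataclass
class PipelineConfig:
    gtf: str
    counts_dir: str
    samples_tsv: str
    out_dir: str
    contrasts: list[str] = field(
        default_factory=lambda: ["hypg3-Ctrl", "hypg15-hypg3", "hypg15-Ctrl"]
    )
    cytobands: str | None = None
    bin_counts: str | None = None
    tx_counts: str | None = None
    gmt: str | None = None
    layers: list[str] = field(default_factory=lambda: ["total", "spliced", "unspliced"])
    alpha: float = 0.05
    pccr_threshold: float = 0.01
    min_mean: float = 5.0
    min_degs: int = 20
    max_set_size: int = 400
    n_perm: int = 500
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def validate_config(config: PipelineConfig) -> list[str]:
    """Empty list iff the config is runnable."""
    problems = []
    for name in ("gtf", "samples_tsv"):
        path = getattr(config, name)
        if not path or not os.path.exists(path):
            problems.append(f"{name}: missing file {path!r}")
    if not config.counts_dir or not os.path.isdir(config.counts_dir):
        problems.append(f"counts_dir: missing directory {config.counts_dir!r}")
    for name in ("cytobands", "bin_counts", "tx_counts", "gmt"):
        path = getattr(config, name)
        if path and not os.path.exists(path):
            problems.append(f"{name}: missing file {path!r}")
    if os.path.exists(config.samples_tsv):
        cond = set(
            pd.read_csv(config.samples_tsv, sep="\t", index_col=0)["condition"]
        )
        for contrast in config.contrasts:
            parts = contrast.split("-")
            if len(parts) != 2 or not set(parts) <= cond:
                problems.append(f"contrast {contrast!r} references unknown condition")
    return problems


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: str, params: dict):
        self.out_dir = out_dir
        self.entries: dict[str, dict] = {}
        self.params_hash = hashlib.sha256(
            json.dumps(params, sort_keys=True, default=str).encode()
        ).hexdigest()

    def add(self, stage: str, path: str) -> None:
        rel = os.path.relpath(path, self.out_dir)
        self.entries[rel] = {"stage": stage, "sha256": _sha256(path)}

    def write(self) -> str:
        path = os.path.join(self.out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(
                {"params_hash": self.params_hash, "outputs": self.entries},
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        return path


def _write(df: pd.DataFrame, path: str, manifest: _Manifest, stage: str, **kw) -> None:
    os.makedirs(os.path.dirname(path), exist_ok=True)
    df.to_csv(path, sep="\t", **kw)
    manifest.add(stage, path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dictionary.

    Deterministic under a fixed config seed: rerunning into a fresh
    directory produces byte-identical tables.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest = _Manifest(out, asdict(config))

    stage = "annotation"
    try:
        ann = annotation.read_gtf(config.gtf)
        if config.cytobands:
            ann.cytobands = annotation.read_cytobands(config.cytobands)
        band_of = annotation.assign_cytobands(ann)

        stage = "counts"
        layered = LayeredCounts.from_tsv(config.counts_dir)
        cond_of = pd.read_csv(config.samples_tsv, sep="\t", index_col=0)["condition"]
        contrast_pairs = [tuple(c.split("-")) for c in config.contrasts]

        stage = "diffexpr"
        results = diffexpr.run_contrasts(
            layered,
            cond_of,
            contrast_pairs,
            layers=tuple(config.layers),
            min_mean=config.min_mean,
        )
        for (cname, layer), res in results.items():
            _write(
                res,
                os.path.join(out, "de", f"{cname}_{layer}.tsv"),
                manifest,
                "diffexpr",
                index_label="gene_id",
            )

        stage = "dynamics"
        calls = {
            key: dynamics.call_regulation(res, alpha=config.alpha)
            for key, res in results.items()
        }
        dyn_summary: dict = {}
        for layer in config.layers:
            c0, c1 = config.contrasts[0], config.contrasts[1]
            tt = dynamics.transition_table(calls[(c0, layer)], calls[(c1, layer)])
            _write(
                tt.counts,
                os.path.join(out, "dynamics", f"transitions_{layer}.tsv"),
                manifest,
                "dynamics",
                index_label="call_at_first",
            )
            summ = dynamics.rebound_correlation(results[(c0, layer)], results[(c1, layer)])
            dyn_summary[layer] = {"rho": summ.rho, "p": summ.p, "n": summ.n}
            sankey = dynamics.sankey_export(tt)
            spath = os.path.join(out, "dynamics", f"sankey_{layer}.json")
            with open(spath, "w") as fh:
                json.dump(sankey, fh, indent=2, sort_keys=True)
            manifest.add("dynamics", spath)
        if len(config.contrasts) >= 3:
            c0, c1, c2 = config.contrasts[:3]
            for layer in config.layers:
                refined = dynamics.refine_grey_categories(
                    calls[(c0, layer)], calls[(c1, layer)], calls[(c2, layer)]
                )
                _write(
                    refined.to_frame(),
                    os.path.join(out, "dynamics", f"refined_{layer}.tsv"),
                    manifest,
                    "dynamics",
                    index_label="gene_id",
                )
        dpath = os.path.join(out, "dynamics", "rebound_correlation.json")
        with open(dpath, "w") as fh:
            json.dump(dyn_summary, fh, indent=2, sort_keys=True)
        manifest.add("dynamics", dpath)

        stage = "distribution"
        chrom_of = pd.Series({g: ann.genes[g].chrom for g in ann.genes})
        band_series = pd.Series(
            {
                g: (f"{ann.genes[g].chrom}:{band_of[g]}" if band_of[g] else None)
                for g in ann.genes
            }
        )
        for cname in config.contrasts:
            for layer in config.layers:
                call = calls[(cname, layer)]
                for level, region_of in (("chrom", chrom_of), ("cytoband", band_series)):
                    tally = distribution.region_tallies(call, region_of)
                    if tally.empty:
                        continue
                    tested = distribution.fisher_region_tests(tally, alpha=config.alpha)
                    _write(
                        tested,
                        os.path.join(out, "distribution", f"{cname}_{layer}_{level}.tsv"),
                        manifest,
                        "distribution",
                        index_label="region",
                    )

        deu_calls: dict[str, pd.Series] = {}
        du_tx: pd.DataFrame | None = None
        if config.bin_counts:
            stage = "exon_usage"
            bins = exon_usage.flatten_exons(ann)
            bin_counts = pd.read_csv(config.bin_counts, sep="\t", index_col=0)
            sf = diffexpr.size_factors(layered.total)
            for a, b in contrast_pairs:
                res, gene_df = exon_usage.deu_test(
                    bin_counts, bins, sf, cond_of, a, b, alpha=config.alpha
                )
                cname = f"{a}-{b}"
                deu_calls[cname] = res["call"]
                _write(
                    res.drop(columns=["call"]).join(res["call"]),
                    os.path.join(out, "deu", f"{cname}_bins.tsv"),
                    manifest,
                    "exon_usage",
                    index_label="bin_id",
                )
                _write(
                    gene_df,
                    os.path.join(out, "deu", f"{cname}_genes.tsv"),
                    manifest,
                    "exon_usage",
                    index_label="gene_id",
                )
                if du_tx is None:
                    du_tx = exon_usage.map_du_to_transcripts(res, bins, alpha=config.alpha)
                    _write(
                        du_tx,
                        os.path.join(out, "deu", f"{cname}_du_transcripts.tsv"),
                        manifest,
                        "exon_usage",
                        index=False,
                    )
                    du_chrom = distribution.du_exon_distribution(
                        res["call"], bins["chrom"].reindex(res.index), alpha=config.alpha
                    )
                    if len(du_chrom):
                        _write(
                            du_chrom,
                            os.path.join(out, "deu", f"{cname}_chrom_distribution.tsv"),
                            manifest,
                            "exon_usage",
                            index_label="region",
                        )
            if len(config.contrasts) >= 2:
                tt = exon_usage.du_temporal_coherence(
                    deu_calls[config.contrasts[0]], deu_calls[config.contrasts[1]]
                )
                _write(
                    tt.counts,
                    os.path.join(out, "deu", "transitions.tsv"),
                    manifest,
                    "exon_usage",
                    index_label="call_at_first",
                )

            stage = "biotypes"
            if du_tx is not None and len(du_tx):
                tally = biotypes.biotype_tally(du_tx, ann)
                _write(
                    tally,
                    os.path.join(out, "biotypes", "du_biotype_tally.tsv"),
                    manifest,
                    "biotypes",
                    index_label="biotype",
                )
                spliced_calls = calls.get((config.contrasts[0], "spliced"))
                if spliced_calls is not None:
                    assoc = biotypes.biotype_deg_association(
                        du_tx,
                        spliced_calls,
                        ann,
                        min_degs=config.min_degs,
                        alpha=config.alpha,
                    )
                    _write(
                        assoc,
                        os.path.join(out, "biotypes", "deg_association.tsv"),
                        manifest,
                        "biotypes",
                        index_label="biotype",
                    )

        if config.tx_counts:
            stage = "pccr"
            tx = pd.read_csv(config.tx_counts, sep="\t", index_col=0)
            records = pccr_mod.compute_pccr(
                tx, condition_of=cond_of, threshold=config.pccr_threshold
            )
            _write(
                records,
                os.path.join(out, "pccr", "pccr.tsv"),
                manifest,
                "pccr",
                index_label="gene_id",
            )
            first = config.contrasts[0]
            overlap = pccr_mod.pccr_deg_overlap(
                records,
                {layer: calls[(first, layer)] for layer in config.layers},
                alpha=config.alpha,
            )
            _write(
                overlap,
                os.path.join(out, "pccr", "deg_overlap.tsv"),
                manifest,
                "pccr",
            )

        if config.gmt:
            stage = "enrichment"
            sets = enrichment.read_gmt(config.gmt)
            first = config.contrasts[0]
            layer = "spliced" if "spliced" in config.layers else config.layers[0]
            res = results[(first, layer)]
            universe = set(res.index[res["observable"]])
            query = set(
                calls[(first, layer)].index[calls[(first, layer)].isin(["up", "down"])]
            )
            ora = enrichment.ora_fisher(query, universe, sets, alpha=config.alpha)
            if len(ora):
                _write(
                    ora,
                    os.path.join(out, "enrichment", "ora.tsv"),
                    manifest,
                    "enrichment",
                    index_label="set",
                )
            ranked = res.loc[res["observable"], "stat"].dropna()
            pre = enrichment.preranked_enrichment(
                ranked,
                sets,
                n_perm=config.n_perm,
                seed=config.seed,
                max_size=config.max_set_size,
            )
            if len(pre):
                _write(
                    pre,
                    os.path.join(out, "enrichment", "preranked.tsv"),
                    manifest,
                    "enrichment",
                    index_label="set",
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.write()
    return {"params_hash": manifest.params_hash, "outputs": manifest.entries}


# ---------------------------------------------------------------------------
# Synthetic demo
# ---------------------------------------------------------------------------

def demo(out_dir: str, seed: int = 1, n_genes: int = 1200, n_sam_pairs: int = 2000) -> dict:
    """Generate the synthetic study into ``out_dir`` and run the pipeline.

    Writes the generated inputs (GTF, cytobands, layered counts, bin counts,
    transcript counts, gene sets, a labelled SAM fixture) under
    ``out_dir/inputs`` and the analysis under ``out_dir/results``. Byte
    identical on rerun with the same seed.
    """
    inputs = os.path.join(out_dir, "inputs")
    os.makedirs(inputs, exist_ok=True)

    ann = simulate.synthetic_annotation(n_genes, seed=seed)
    gtf = os.path.join(inputs, "genes.gtf")
    annotation.write_gtf(ann, gtf)
    cyto = os.path.join(inputs, "cytobands.tsv")
    with open(cyto, "w") as fh:
        for band in ann.cytobands:
            fh.write(f"{band.chrom}\t{band.start}\t{band.end}\t{band.name}\n")

    design = simulate.SimulationDesign()
    truth = simulate.simulate_ground_truth(ann, seed=seed + 1)
    truth.to_csv(os.path.join(inputs, "truth.tsv"), sep="\t")
    layered, cond_of = simulate.simulate_layered_counts(design, ann, truth, seed=seed + 2)
    counts_dir = os.path.join(inputs, "counts")
    layered.to_tsv(counts_dir)
    samples_tsv = os.path.join(inputs, "samples.tsv")
    cond_of.to_frame().to_csv(samples_tsv, sep="\t", index_label="sample")

    bins = exon_usage.flatten_exons(ann)
    bin_counts = simulate.simulate_bin_counts(design, bins.reset_index(), truth, seed=seed + 3)
    bin_counts_tsv = os.path.join(inputs, "bin_counts.tsv")
    bin_counts.to_csv(bin_counts_tsv, sep="\t", index_label="bin_id")

    tx = simulate.simulate_transcript_counts(design, ann, truth, seed=seed + 4)
    tx_tsv = os.path.join(inputs, "tx_counts.tsv")
    tx.to_csv(tx_tsv, sep="\t", index_label="transcript_id")

    rng_sets = __import__("numpy").random.default_rng(seed + 5)
    genes = list(ann.genes)
    sets = {
        f"random_set_{i}": set(rng_sets.choice(genes, size=40, replace=False))
        for i in range(5)
    }
    sets["responsive_up"] = set(truth.index[truth["class"] == "rebound_up_then_down"][:60])
    gmt = os.path.join(inputs, "sets.gmt")
    enrichment.write_gmt(sets, gmt, source="synthetic")

    sam = os.path.join(inputs, "fixture.sam")
    sam_truth = simulate.generate_sam_fixture(ann, n_sam_pairs, seed=seed + 6, path=sam)
    sam_truth.to_csv(os.path.join(inputs, "fixture_truth.tsv"), sep="\t")
    from .splice import count_layers

    fixture_counts, summary = count_layers({"fixture": sam}, ann)
    summary.to_csv(os.path.join(inputs, "fixture_count_summary.tsv"), sep="\t")

    config = PipelineConfig(
        gtf=gtf,
        counts_dir=counts_dir,
        samples_tsv=samples_tsv,
        out_dir=os.path.join(out_dir, "results"),
        cytobands=cyto,
        bin_counts=bin_counts_tsv,
        tx_counts=tx_tsv,
        gmt=gmt,
        seed=seed,
    )
    config.to_yaml(os.path.join(out_dir, "config.yaml"))
    return run_pipeline(config)
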
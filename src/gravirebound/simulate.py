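"""Ground-truth-labelled synthetic data with the statistical structure the
analysis assumes.

The generator emulates the study design: three conditions (Ctrl at 1xg,
3 min at 9xg, 15 min at 9xg) with four replicates each. Per-gene mRNA
kinetics follow the standard two-stage model

    du/dt = alpha - beta * u        (transcription, splicing)
    ds/dt = beta * u - gamma * s    (splicing, degradation)

with piecewise-constant rates: a step perturbation of alpha (transcription)
or gamma (degradation of the spliced species) at hypergravity onset, and an
optional reversion of the perturbed rate at ``rebound_time`` producing a
mechanistic rebound. Layered counts are drawn from a negative binomial
around the kinetic means, with the unspliced pool depleted by a polyA
capture factor. Transcript-level counts with biotype-resolved isoform
fractions feed the coding-counts-ratio analysis, and a SAM fixture with
per-read truth labels exercises the read classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .annotation import (
    Cytoband,
    Gene,
    GenomeAnnotation,
    Transcript,
    assign_cytobands,
    constitutive_introns,
    gene_has_introns,
    intron_intervals,
    union_exons,
)
from .layers import LayeredCounts

GENE_CLASSES = (
    "null",
    "transcriptional_up",
    "post_transcriptional_down",
    "rebound_up_then_down",
    "rebound_down_then_up",
)


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

@dataclass
class KineticParams:
    """Rates in molecules/min (alpha) and 1/min (beta, gamma).

    ``perturbed`` selects which rate steps at t=0 by factor ``fold``;
    ``rebound_time`` (minutes) optionally multiplies the perturbed rate back
    to ``rebound_fold`` times its base value (1.0 = full reversion).
    """

    alpha: float
    beta: float
    gamma: float
    perturbed: str | None = None  # None | "alpha" | "gamma"
    fold: float = 1.0
    rebound_time: float | None = None
    rebound_fold: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta <= 0 or self.gamma <= 0:
            raise ValueError("require alpha >= 0, beta > 0, gamma > 0")
        if self.fold <= 0 or self.rebound_fold <= 0:
            raise ValueError("rate folds must be > 0")
        if self.perturbed not in (None, "alpha", "gamma"):
            raise ValueError("perturbed must be None, 'alpha' or 'gamma'")


def _phi(x: float) -> float:
    """(1 - exp(-x)) / x, stable at x -> 0."""
    if abs(x) < 1e-6:
        return 1.0 - x / 2.0 + x * x / 6.0
    return -math.expm1(-x) / x


def _segment(alpha: float, beta: float, gamma: float,
             u0: float, s0: float, tau: float) -> tuple[float, float]:
    """Closed-form (u, s) after time tau with constant rates from (u0, s0).

    The beta == gamma degenerate case is the analytic limit of the general
    solution (computed via a stable phi-form, so near-degenerate rates do not
    suffer cancellation).
    """
    u_ss = alpha / beta
    du = u0 - u_ss
    u = u_ss + du * math.exp(-beta * tau)
    s_ss = alpha / gamma
    # s = s_ss + (s0 - s_ss) e^{-gamma tau} + beta*du * (e^{-beta tau} - e^{-gamma tau})/(gamma - beta)
    bridge = beta * du * tau * math.exp(-beta * tau) * _phi((gamma - beta) * tau)
    s = s_ss + (s0 - s_ss) * math.exp(-gamma * tau) + bridge
    return u, s


def solve_kinetics(p: KineticParams, t: float) -> tuple[float, float]:
    """Unspliced and spliced abundance at ``t`` minutes after onset.

    The pre-perturbation state is the steady state of the base rates
    (u = alpha/beta, s = alpha/gamma); t <= 0 returns it unchanged. The
    solution is continuous in t across segment boundaries.
    """
    u, s = p.alpha / p.beta, p.alpha / p.gamma
    if t <= 0:
        return u, s

    def seg_rates(which: str) -> tuple[float, float]:
        mult = p.fold if which == "step" else p.rebound_fold
        alpha = p.alpha * (mult if p.perturbed == "alpha" else 1.0)
        gamma = p.gamma * (mult if p.perturbed == "gamma" else 1.0)
        return alpha, gamma

    if p.perturbed is None:
        return u, s
    if p.rebound_time is None or t <= p.rebound_time:
        a, g = seg_rates("step")
        return _segment(a, p.beta, g, u, s, t)
    a, g = seg_rates("step")
    u, s = _segment(a, p.beta, g, u, s, p.rebound_time)
    a, g = seg_rates("rebound")
    return _segment(a, p.beta, g, u, s, t - p.rebound_time)


# ---------------------------------------------------------------------------
# Design and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationDesign:
    """Study design: condition -> minutes of hypergravity before fixation.

    Ctrl samples never experience the perturbation (t = 0, baseline steady
    state). Four replicates per condition mirror the experimental campaign.
    """

    times: dict[str, float] = field(
        default_factory=lambda: {"Ctrl": 0.0, "hypg3": 3.0, "hypg15": 15.0}
    )
    replicates: int = 4
    library_scale: float = 1.0
    depth_jitter_sd: float = 0.05
    polya_capture: float = 0.15
    ambiguous_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per condition")

    @property
    def conditions(self) -> list[str]:
        return list(self.times)

    @property
    def sample_names(self) -> list[str]:
        return [f"{c}_r{i + 1}" for c in self.conditions for i in range(self.replicates)]

    def condition_of(self) -> pd.Series:
        return pd.Series(
            {f"{c}_r{i + 1}": c for c in self.conditions for i in range(self.replicates)},
            name="condition",
        )


DEFAULT_CLASS_FRACTIONS = {
    "null": 0.75,
    "rebound_up_then_down": 0.125,
    "rebound_down_then_up": 0.125,
}


def simulate_ground_truth(
    ann: GenomeAnnotation,
    seed: int,
    class_fractions: dict[str, float] | None = None,
    alpha_fold: float = 3.0,
    gamma_fold: float = 2.0,
    rebound_time: float = 5.0,
    s_base_median: float = 200.0,
    s_base_sigma: float = 1.0,
    beta_median: float = 1.0,
    beta_sigma: float = 0.2,
    gamma_median: float = 0.5,
    gamma_sigma: float = 0.2,
    dispersion: float = 0.05,
    dispersion_sigma: float = 0.3,
    pccr_down_fraction: float = 0.15,
    pccr_up_fraction: float = 0.05,
    pccr_delta: float = 0.05,
    du_fraction: float = 0.1,
    couple_shifts: bool = True,
) -> pd.DataFrame:
    """Per-gene ground truth: kinetic class and parameters, NB dispersion,
    coding-fraction (PCCR) shift and differential-exon-usage seeding.

    Rate medians correspond to the fast-turnover transcript pool in which
    minute-scale dynamics are observable (splicing half-life ~0.7 min,
    spliced half-life ~1.4 min). With ``couple_shifts`` the PCCR-down and
    DU seeds are preferentially placed on genes whose spliced pool is down
    at 3 min, reproducing the association structure the analysis looks for.
    """
    fractions = dict(class_fractions or DEFAULT_CLASS_FRACTIONS)
    if any(c not in GENE_CLASSES for c in fractions):
        raise ValueError(f"unknown gene class in {sorted(fractions)}")
    if not math.isclose(sum(fractions.values()), 1.0, abs_tol=1e-9):
        raise ValueError("class fractions must sum to 1")

    rng = np.random.default_rng(seed)
    genes = list(ann.genes)
    n = len(genes)

    classes = np.concatenate(
        [np.repeat(c, int(round(f * n))) for c, f in fractions.items()]
    )
    if len(classes) < n:  # rounding remainder -> null
        classes = np.concatenate([classes, np.repeat("null", n - len(classes))])
    classes = classes[:n]
    rng.shuffle(classes)

    beta = beta_median * np.exp(rng.normal(0.0, beta_sigma, n))
    gamma = gamma_median * np.exp(rng.normal(0.0, gamma_sigma, n))
    s_base = s_base_median * np.exp(rng.normal(0.0, s_base_sigma, n))
    alpha = s_base * gamma
    disp = dispersion * np.exp(rng.normal(0.0, dispersion_sigma, n))

    perturbed = np.array([None] * n, dtype=object)
    fold = np.ones(n)
    rb_time = np.full(n, np.nan)
    for i, cls in enumerate(classes):
        if cls == "transcriptional_up":
            perturbed[i], fold[i] = "alpha", alpha_fold
        elif cls == "post_transcriptional_down":
            perturbed[i], fold[i] = "gamma", gamma_fold
        elif cls == "rebound_up_then_down":
            perturbed[i], fold[i], rb_time[i] = "alpha", alpha_fold, rebound_time
        elif cls == "rebound_down_then_up":
            perturbed[i], fold[i], rb_time[i] = "alpha", 1.0 / alpha_fold, rebound_time

    truth = pd.DataFrame(
        {
            "class": classes,
            "alpha": alpha,
            "beta": beta,
            "gamma": gamma,
            "perturbed": perturbed,
            "fold": fold,
            "rebound_time": rb_time,
            "dispersion": disp,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    truth["chrom"] = [ann.genes[g].chrom for g in genes]
    bands = assign_cytobands(ann)
    truth["cytoband"] = [bands[g] for g in genes]

    # biotype structure of each gene's isoforms
    has_noncoding = []
    noncoding_biotype = []
    for g in genes:
        bts = {t.biotype for t in ann.gene_transcripts(g)}
        nc = sorted(bts & {"retained_intron", "orf_lacking", "nmd"})
        has_noncoding.append(bool(nc))
        noncoding_biotype.append(nc[0] if nc else None)
    truth["has_noncoding_tx"] = has_noncoding
    truth["noncoding_biotype"] = noncoding_biotype

    spliced_down_3min = truth["class"].isin(
        ["post_transcriptional_down", "rebound_down_then_up"]
    ).to_numpy()

    def _pick(mask: np.ndarray, k: int, prefer: np.ndarray | None) -> np.ndarray:
        """Pick k gene indices from mask, preferring `prefer & mask` if coupled."""
        idx = np.flatnonzero(mask)
        if prefer is not None and couple_shifts:
            first = np.flatnonzero(mask & prefer)
            rest = np.setdiff1d(idx, first, assume_unique=False)
            rng.shuffle(first)
            rng.shuffle(rest)
            pool = np.concatenate([first, rest])
        else:
            pool = idx.copy()
            rng.shuffle(pool)
        return pool[:k]

    eligible = truth["has_noncoding_tx"].to_numpy()
    n_elig = int(eligible.sum())
    n_down = min(int(round(pccr_down_fraction * n)), n_elig)
    down_idx = _pick(eligible, n_down, spliced_down_3min)
    remaining = eligible.copy()
    remaining[down_idx] = False
    n_up = min(int(round(pccr_up_fraction * n)), int(remaining.sum()))
    up_idx = _pick(remaining, n_up, None)

    shift = np.array(["none"] * n, dtype=object)
    shift[down_idx] = "down"
    shift[up_idx] = "up"
    truth["pccr_shift"] = shift
    coding_ctrl = rng.uniform(0.75, 0.95, n)
    coding_ctrl[~eligible] = 1.0
    delta = np.where(shift == "down", -pccr_delta, np.where(shift == "up", pccr_delta, 0.0))
    truth["coding_fraction_ctrl"] = coding_ctrl
    truth["coding_fraction_hypg3"] = np.clip(coding_ctrl + delta, 0.0, 1.0)

    multibin = np.array(
        [len(union_exons(ann, g)) > 1 for g in genes]
    )
    n_du = min(int(round(du_fraction * n)), int(multibin.sum()))
    ri_host = truth["noncoding_biotype"].eq("retained_intron").to_numpy()
    du_idx = _pick(multibin, n_du, spliced_down_3min & ri_host)
    du = np.zeros(n, dtype=bool)
    du[du_idx] = True
    truth["du_gene"] = du
    truth["du_direction"] = np.where(
        du, np.where(rng.random(n) < 0.5, "increased", "decreased"), "none"
    )
    return truth


def _kinetics_of(row: pd.Series) -> KineticParams:
    rb = row["rebound_time"]
    return KineticParams(
        alpha=row["alpha"],
        beta=row["beta"],
        gamma=row["gamma"],
        perturbed=row["perturbed"],
        fold=row["fold"],
        rebound_time=None if pd.isna(rb) else float(rb),
    )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) with var = m + d m^2; Poisson when d is negligible."""
    mean = np.asarray(mean, dtype=float)
    disp = np.broadcast_to(np.asarray(disp, dtype=float), mean.shape)
    out = np.zeros(mean.shape, dtype=np.int64)
    poisson = disp < 1e-8
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    nb = ~poisson
    if nb.any():
        size = 1.0 / disp[nb]
        p = size / (size + mean[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def simulate_layered_counts(
    design: SimulationDesign,
    ann: GenomeAnnotation,
    truth: pd.DataFrame,
    seed: int,
) -> tuple[LayeredCounts, pd.Series]:
    """Draw layered NB counts for every gene and sample of the design.

    Per sample, mean spliced counts are s(t) times a depth factor; mean
    unspliced counts are u(t) times depth and the polyA capture factor
    (polyA-enriched libraries deplete intron-bearing precursors); the
    ambiguous layer is a fixed fraction of the spliced mean. Returns the
    counts and the sample -> condition map.
    """
    if design.library_scale <= 0:
        raise ValueError("library size must be positive")
    missing = truth.index.difference(pd.Index(ann.genes))
    if len(missing):
        raise ValueError(f"truth genes absent from annotation: {list(missing)[:3]} ...")

    rng = np.random.default_rng(seed)
    genes = truth.index
    cond_of = design.condition_of()
    samples = design.sample_names

    u = np.zeros((len(genes), len(design.conditions)))
    s = np.zeros_like(u)
    for gi, (_, row) in enumerate(truth.iterrows()):
        p = _kinetics_of(row)
        for ci, cond in enumerate(design.conditions):
            u[gi, ci], s[gi, ci] = solve_kinetics(p, design.times[cond])

    depth = design.library_scale * np.exp(
        rng.normal(0.0, design.depth_jitter_sd, len(samples))
    )
    cidx = np.array([design.conditions.index(cond_of[sm]) for sm in samples])
    mean_s = s[:, cidx] * depth[None, :]
    mean_u = u[:, cidx] * depth[None, :] * design.polya_capture
    mean_a = mean_s * design.ambiguous_fraction

    disp = truth["dispersion"].to_numpy()[:, None]
    frames = {
        name: pd.DataFrame(
            _nb_sample(rng, mean, disp), index=genes, columns=pd.Index(samples, name="sample")
        )
        for name, mean in (("spliced", mean_s), ("unspliced", mean_u), ("ambiguous", mean_a))
    }
    return LayeredCounts(**frames), cond_of.loc[samples]


def simulate_transcript_counts(
    design: SimulationDesign,
    ann: GenomeAnnotation,
    truth: pd.DataFrame,
    seed: int,
    total_median: float = 20000.0,
    total_sigma: float = 0.7,
    total_floor: float = 500.0,
) -> pd.DataFrame:
    """Transcript x sample counts with biotype-resolved isoform fractions.

    Each gene receives a per-condition total (log-normal, floored), split
    across isoforms at condition-specific coding/noncoding fractions from the
    ground truth and sampled per replicate with Poisson counting noise.
    Between-replicate biological isoform-usage variability is deliberately
    not modelled: the composition of one RNA pool is measured, so the
    1-percent-point shift threshold operates at its counting-noise floor.
    Genes with a PCCR shift move coding mass at hypg3 and recover at hypg15.
    """
    rng = np.random.default_rng(seed)
    rows = []
    samples = design.sample_names
    cond_of = design.condition_of()
    for gid in truth.index:
        txs = ann.gene_transcripts(gid)
        coding = [t for t in txs if t.biotype == "protein_coding"]
        noncoding = [t for t in txs if t.biotype in ("retained_intron", "orf_lacking", "nmd")]
        total = max(total_floor, np.exp(rng.normal(np.log(total_median), total_sigma)))
        frac = {
            "Ctrl": truth.at[gid, "coding_fraction_ctrl"],
            "hypg3": truth.at[gid, "coding_fraction_hypg3"],
        }
        per_tx_mean = {}
        for t in txs:
            per_tx_mean[t.transcript_id] = {}
            for cond in design.conditions:
                fc = frac.get(cond, frac["Ctrl"])  # hypg15 recovers to Ctrl composition
                if t.biotype == "protein_coding":
                    share = fc / len(coding)
                elif t in noncoding:
                    share = (1.0 - fc) / len(noncoding) if noncoding else 0.0
                else:
                    share = 0.0
                per_tx_mean[t.transcript_id][cond] = total / design.replicates * share
        for t in txs:
            counts = [
                rng.poisson(per_tx_mean[t.transcript_id][cond_of[sm]]) for sm in samples
            ]
            rows.append([t.transcript_id, gid, t.biotype, *counts])
    df = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "biotype", *samples])
    return df.set_index("transcript_id")


def simulate_bin_counts(
    design: SimulationDesign,
    bins: pd.DataFrame,
    truth: pd.DataFrame,
    seed: int,
    gene_depth_median: float = 2000.0,
    gene_depth_sigma: float = 0.7,
    usage_shift: float = 2.0,
    bin_dispersion: float = 0.02,
) -> pd.DataFrame:
    """Exon-bin x sample counts with seeded usage shifts.

    ``bins`` is the flattened-bin table (``bin_id``, ``gene_id``, ``length``).
    Baseline bin usage is proportional to bin length; for genes flagged
    ``du_gene`` in the truth, one bin's share is multiplied (or divided) by
    ``usage_shift`` in the hypergravity conditions and shares renormalised,
    so differential usage exists without any gene-level expression change.
    """
    rng = np.random.default_rng(seed)
    samples = design.sample_names
    cond_of = design.condition_of()
    out = np.zeros((len(bins), len(samples)), dtype=np.int64)
    bins = bins.reset_index(drop=True)
    truth_bins = []

    for gid, sub in bins.groupby("gene_id", sort=False):
        lengths = sub["length"].to_numpy(dtype=float)
        base = lengths / lengths.sum()
        depth = np.exp(rng.normal(np.log(gene_depth_median), gene_depth_sigma))
        is_du = gid in truth.index and bool(truth.at[gid, "du_gene"]) and len(sub) > 1
        shifted = base.copy()
        du_bin = None
        if is_du:
            j = rng.integers(len(sub))
            du_bin = sub.iloc[j]["bin_id"]
            factor = (
                usage_shift
                if truth.at[gid, "du_direction"] == "increased"
                else 1.0 / usage_shift
            )
            shifted[j] *= factor
            shifted = shifted / shifted.sum()
        for si, sm in enumerate(samples):
            frac = shifted if (is_du and cond_of[sm] != "Ctrl") else base
            mean = depth * frac
            out[sub.index, si] = _nb_sample(
                rng, mean, np.full(len(sub), bin_dispersion)
            )
        if du_bin is not None:
            truth_bins.append(du_bin)

    df = pd.DataFrame(out, index=pd.Index(bins["bin_id"], name="bin_id"), columns=samples)
    df.attrs["du_bins"] = truth_bins
    return df


# ---------------------------------------------------------------------------
# SAM fixture
# ---------------------------------------------------------------------------

def _pick_interval(rng, intervals, length):
    """Uniformly pick a start for a read of `length` inside one interval."""
    ok = [(s, e) for s, e in intervals if e - s >= length]
    if not ok:
        return None
    s, e = ok[rng.integers(len(ok))]
    return int(rng.integers(s, e - length + 1))


def generate_sam_fixture(
    ann: GenomeAnnotation,
    n_pairs: int,
    seed: int,
    path: str,
    read_len: int = 75,
    secondary_every: int = 50,
) -> pd.DataFrame:
    """Write a headered, unsorted SAM of paired-end reads with known splice
    status; returns the per-pair truth table (gene, label).

    Pair archetypes: (a) one mate spans an annotated intron with an exact
    N-gap (truth spliced); (b) a mate lies wholly inside an intron shared by
    all isoforms (truth unspliced); (c) both mates exonic, non-junction, in a
    multi-isoform gene (truth ambiguous) or in an intron-less gene (truth
    spliced, by definition). Every ``secondary_every``-th pair also emits a
    secondary copy of one mate, which a correct counter must ignore.
    """
    rng = np.random.default_rng(seed)
    genes = list(ann.genes)
    geom = {}
    for gid in genes:
        txs = ann.gene_transcripts(gid)
        geom[gid] = {
            "multi": [t for t in txs if len(t.exons) > 1],
            "const_introns": constitutive_introns(ann, gid),
            "exon_union": union_exons(ann, gid),
            "has_introns": gene_has_introns(ann, gid),
        }

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": chrom, "LN": int(length)}
                for chrom, length in ann.chrom_lengths.items()
            ],
        }
    )
    tid_of = {chrom: i for i, chrom in enumerate(ann.chrom_lengths)}

    def make_segment(name, chrom, pos, cigar, flag, mate_pos):
        seg = pysam.AlignedSegment(header)
        seg.query_name = name
        seg.flag = flag
        seg.reference_id = tid_of[chrom]
        seg.reference_start = pos
        seg.mapping_quality = 60
        seg.cigarstring = cigar
        seg.next_reference_id = tid_of[chrom]
        seg.next_reference_start = mate_pos
        seg.template_length = 0
        return seg

    records = []
    truth_rows = []
    kinds = ("junction", "intronic", "exonic")
    for i in range(n_pairs):
        gid = genes[rng.integers(len(genes))]
        g = geom[gid]
        kind = kinds[rng.integers(3)]
        if kind == "junction" and not g["multi"]:
            kind = "exonic"
        if kind == "intronic" and not any(
            e - s >= read_len for s, e in g["const_introns"]
        ):
            kind = "exonic"

        chrom = ann.genes[gid].chrom
        if kind == "junction":
            t = g["multi"][rng.integers(len(g["multi"]))]
            introns = intron_intervals(t)
            j = int(rng.integers(len(introns)))
            istart, iend = introns[j]
            left_exon, right_exon = t.exons[j], t.exons[j + 1]
            a_max = min(read_len - 10, left_exon[1] - left_exon[0])
            a = int(rng.integers(10, a_max + 1))
            b = read_len - a
            if b > right_exon[1] - right_exon[0]:
                b = right_exon[1] - right_exon[0]
                a = read_len - b
            pos1 = left_exon[1] - a
            cigar1 = f"{a}M{iend - istart}N{b}M"
            pos2 = _pick_interval(rng, t.exons, read_len)
            cigar2 = f"{read_len}M"
            label = "spliced"
        elif kind == "intronic":
            pos1 = _pick_interval(rng, g["const_introns"], read_len)
            cigar1 = f"{read_len}M"
            pos2 = _pick_interval(rng, g["const_introns"], read_len)
            if pos2 is None:
                pos2 = _pick_interval(rng, g["exon_union"], read_len)
            cigar2 = f"{read_len}M"
            label = "unspliced"
        else:
            pos1 = _pick_interval(rng, g["exon_union"], read_len)
            cigar1 = f"{read_len}M"
            pos2 = _pick_interval(rng, g["exon_union"], read_len)
            cigar2 = f"{read_len}M"
            label = "spliced" if not g["has_introns"] else "ambiguous"
        if pos1 is None or pos2 is None:
            continue

        name = f"pair{i:06d}"
        records.append(make_segment(name, chrom, pos1, cigar1, 0x63, pos2))  # 99
        records.append(make_segment(name, chrom, pos2, cigar2, 0x93, pos1))  # 147
        if secondary_every and i % secondary_every == 0:
            records.append(make_segment(name, chrom, pos1, cigar1, 0x63 | 0x100, pos2))
        truth_rows.append([name, gid, label])

    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for seg in records:
            out.write(seg)

    return pd.DataFrame(truth_rows, columns=["read_name", "gene_id", "label"]).set_index(
        "read_name"
    )


# ---------------------------------------------------------------------------
# Synthetic annotation
# ---------------------------------------------------------------------------

def synthetic_annotation(
    n_genes: int,
    seed: int = 0,
    n_chroms: int = 4,
    bands_per_chrom: int = 5,
    exon_len: int = 300,
    intron_len: int = 500,
    intergenic: int = 1000,
    single_exon_fraction: float = 0.1,
    second_isoform_fraction: float = 0.7,
) -> GenomeAnnotation:
    """Build a compact genome annotation for simulations and fixtures.

    Genes are laid end-to-end across ``n_chroms`` chromosomes carved into
    first-level cytobands. Most genes have three exons and two isoforms: a
    full-length protein-coding transcript and an exon-skipping second isoform
    carrying a noncoding biotype (retained_intron / orf_lacking / nmd /
    lncRNA), so every analysis layer (splice classification, exon bins,
    biotypes, PCCR) has structure to work with. A fraction of genes are
    single-exon, which the read classifier must place in the spliced pool.
    """
    rng = np.random.default_rng(seed)
    ann = GenomeAnnotation()
    noncoding_cycle = ("retained_intron", "orf_lacking", "nmd", "lncRNA")
    per_chrom = int(np.ceil(n_genes / n_chroms))
    gi = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = intergenic
        for _ in range(per_chrom):
            if gi >= n_genes:
                break
            gid = f"G{gi:05d}"
            strand = "+" if gi % 2 == 0 else "-"
            single = rng.random() < single_exon_fraction
            if single:
                exons = [(cursor, cursor + exon_len)]
                t1 = Transcript(f"{gid}.t1", gid, "protein_coding", exons)
                ann.transcripts[t1.transcript_id] = t1
                tids = [t1.transcript_id]
            else:
                exons = []
                pos = cursor
                for _ in range(3):
                    exons.append((pos, pos + exon_len))
                    pos += exon_len + intron_len
                t1 = Transcript(f"{gid}.t1", gid, "protein_coding", exons)
                ann.transcripts[t1.transcript_id] = t1
                tids = [t1.transcript_id]
                if rng.random() < second_isoform_fraction:
                    bt = noncoding_cycle[gi % len(noncoding_cycle)]
                    t2 = Transcript(f"{gid}.t2", gid, bt, [exons[0], exons[2]])
                    ann.transcripts[t2.transcript_id] = t2
                    tids.append(t2.transcript_id)
            span = (exons[0][0], exons[-1][1])
            ann.genes[gid] = Gene(gid, chrom, strand, span, tids)
            cursor = span[1] + intergenic
            gi += 1
        chrom_len = cursor + intergenic
        ann.chrom_lengths[chrom] = chrom_len
        band_w = int(np.ceil(chrom_len / bands_per_chrom))
        for bi in range(bands_per_chrom):
            ann.cytobands.append(
                Cytoband(
                    chrom,
                    f"p{bi + 1}",
                    bi * band_w,
                    min((bi + 1) * band_w, chrom_len),
                )
            )
    assign_cytobands(ann)
    ann.validate()
    return ann
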
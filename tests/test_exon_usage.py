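import numpy as np
import pandas as pd
import pytest

from gravirebound import exon_usage as X
from gravirebound.annotation import Gene, GenomeAnnotation, Transcript


@pytest.fixture
def nested_ann():
    """One gene, two transcripts with exons [0,10) and [0,20)."""
    ann = GenomeAnnotation()
    ann.transcripts = {
        "t1": Transcript("t1", "g", "protein_coding", [(0, 10)]),
        "t2": Transcript("t2", "g", "protein_coding", [(0, 20)]),
    }
    ann.genes = {"g": Gene("g", "chr1", "+", (0, 20), ["t1", "t2"])}
    ann.chrom_lengths = {"chr1": 100}
    return ann


def _usage_counts(rng, n_genes, bins_per_gene, depth, usage_a, usage_b, n=4, disp=0.02):
    """Bin counts for two conditions at explicit first-bin usage fractions."""
    rows, bin_ids, gene_ids = [], [], []
    size = 1.0 / disp
    for g in range(n_genes):
        fracs_a = np.full(bins_per_gene, (1 - usage_a[g]) / (bins_per_gene - 1))
        fracs_a[0] = usage_a[g]
        fracs_b = np.full(bins_per_gene, (1 - usage_b[g]) / (bins_per_gene - 1))
        fracs_b[0] = usage_b[g]
        for j in range(bins_per_gene):
            ma = depth * fracs_a[j]
            mb = depth * fracs_b[j]
            counts = np.concatenate(
                [
                    rng.negative_binomial(size, size / (size + ma), n),
                    rng.negative_binomial(size, size / (size + mb), n),
                ]
            )
            rows.append(counts)
            bin_ids.append(f"g{g}:E{j:03d}")
            gene_ids.append(f"g{g}")
    cols = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
    counts = pd.DataFrame(rows, index=pd.Index(bin_ids, name="bin_id"), columns=cols)
    bins = pd.DataFrame({"gene_id": gene_ids}, index=counts.index)
    groups = pd.Series({c: c[0] for c in cols})
    sf = pd.Series(1.0, index=counts.columns)
    return counts, bins, sf, groups


class TestFlattenExons:
    def test_nested_exons_split_at_boundary(self, nested_ann):
        bins = X.flatten_exons(nested_ann)
        assert list(zip(bins["start"], bins["end"])) == [(0, 10), (10, 20)]

    def test_bin_parentage(self, nested_ann):
        bins = X.flatten_exons(nested_ann)
        assert bins.iloc[0]["transcript_ids"] == frozenset({"t1", "t2"})
        assert bins.iloc[1]["transcript_ids"] == frozenset({"t2"})

    def test_single_transcript_gene_bins_equal_exons(self, tiny_ann):
        bins = X.flatten_exons(tiny_ann)
        b = bins[bins["gene_id"] == "C"]
        assert list(zip(b["start"], b["end"])) == [(100, 300), (700, 900)]

    def test_bins_disjoint_and_cover_exon_union(self, sim_ann):
        from gravirebound.annotation import union_exons

        bins = X.flatten_exons(sim_ann)
        for gid, sub in bins.groupby("gene_id"):
            ivs = sorted(zip(sub["start"], sub["end"]))
            for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
                assert s1 >= e0
            union = union_exons(sim_ann, gid)
            assert sum(e - s for s, e in ivs) == sum(e - s for s, e in union)


class TestDeuTest:
    def test_detects_seeded_usage_shift(self, rng):
        usage_a = np.array([0.8] + [0.5] * 19)
        usage_b = np.full(20, 0.5)
        counts, bins, sf, groups = _usage_counts(rng, 20, 3, 1000, usage_a, usage_b)
        res, gene_df = X.deu_test(counts, bins, sf, groups, "A", "B")
        assert res.at["g0:E000", "fdr"] < 0.05
        assert res.at["g0:E000", "usage_lfc"] > 0
        assert gene_df.at["g0", "significant_deu"]

    def test_null_calibration(self, rng):
        usage = np.full(60, 0.4)
        counts, bins, sf, groups = _usage_counts(rng, 60, 3, 800, usage, usage)
        res, _ = X.deu_test(counts, bins, sf, groups, "A", "B")
        frac = (res["p"].dropna() < 0.05).mean()
        assert 0.01 <= frac <= 0.1

    def test_swapping_groups_negates_usage_lfc(self, rng):
        usage_a = rng.uniform(0.3, 0.7, 10)
        usage_b = rng.uniform(0.3, 0.7, 10)
        counts, bins, sf, groups = _usage_counts(rng, 10, 3, 500, usage_a, usage_b)
        ab, _ = X.deu_test(counts, bins, sf, groups, "A", "B")
        ba, _ = X.deu_test(counts, bins, sf, groups, "B", "A")
        assert np.allclose(ab["usage_lfc"], -ba["usage_lfc"], equal_nan=True)
        assert np.array_equal(ab["p"].to_numpy(), ba["p"].to_numpy(), equal_nan=True)

    def test_usage_immune_to_expression_fold_change(self, rng):
        # doubling every count of condition A changes bin/remainder ratios not
        # at all, so the usage statistic is bitwise identical
        usage = np.full(10, 0.4)
        counts, bins, sf, groups = _usage_counts(rng, 10, 3, 500, usage, usage)
        res1, _ = X.deu_test(counts, bins, sf, groups, "A", "B")
        doubled = counts.copy()
        a_cols = [c for c in counts.columns if c.startswith("A")]
        doubled[a_cols] = doubled[a_cols] * 2
        res2, _ = X.deu_test(doubled, bins, sf, groups, "A", "B")
        assert np.allclose(
            res1["usage_lfc"].to_numpy(),
            res2["usage_lfc"].to_numpy(),
            atol=1e-12,
            equal_nan=True,
        )

    def test_single_bin_gene_skipped(self, rng):
        counts, bins, sf, groups = _usage_counts(rng, 2, 3, 500, [0.4, 0.4], [0.4, 0.4])
        solo = pd.DataFrame(
            [[50] * 8], index=pd.Index(["solo:E000"], name="bin_id"), columns=counts.columns
        )
        counts = pd.concat([counts, solo])
        bins = pd.concat([bins, pd.DataFrame({"gene_id": ["solo"]}, index=["solo:E000"])])
        res, _ = X.deu_test(counts, bins, sf, groups, "A", "B")
        assert "solo:E000" not in res.index


class TestMapDuToTranscripts:
    def _deu_res(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "usage_lfc", "fdr"], index=[f"b{i}" for i in range(len(rows))]
        )

    def _bins(self, parents):
        return pd.DataFrame(
            {"transcript_ids": [frozenset(p) for p in parents]},
            index=[f"b{i}" for i in range(len(parents))],
        )

    def test_all_parents_included(self):
        res = self._deu_res([("g", 1.0, 0.01)])
        bins = self._bins([{"t1", "t2", "t3"}])
        out = X.map_du_to_transcripts(res, bins)
        assert set(out["transcript_id"]) == {"t1", "t2", "t3"}

    def test_shared_parent_counted_once(self):
        res = self._deu_res([("g", 1.0, 0.01), ("g", 2.0, 0.01)])
        bins = self._bins([{"t1"}, {"t1", "t2"}])
        out = X.map_du_to_transcripts(res, bins)
        assert sorted(out["transcript_id"]) == ["t1", "t2"]

    def test_transcript_hit_in_both_directions_appears_twice(self):
        res = self._deu_res([("g", 1.0, 0.01), ("g", -1.0, 0.01)])
        bins = self._bins([{"t1"}, {"t1"}])
        out = X.map_du_to_transcripts(res, bins)
        assert len(out) == 2
        assert set(out["direction"]) == {"increased", "decreased"}

    def test_non_significant_bins_ignored(self):
        res = self._deu_res([("g", 1.0, 0.2)])
        bins = self._bins([{"t1"}])
        assert len(X.map_du_to_transcripts(res, bins)) == 0


class TestDuTemporalCoherence:
    def test_transition_labels_use_usage_vocabulary(self):
        a = pd.Series(["increased", "decreased", "ns"], index=list("abc"))
        b = pd.Series(["decreased", "decreased", "ns"], index=list("abc"))
        tt = X.du_temporal_coherence(a, b)
        assert tt.counts.at["increased", "decreased"] == 1
        assert tt.counts.at["decreased", "decreased"] == 1
        assert tt.counts.to_numpy().sum() == 3
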
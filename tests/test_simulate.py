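import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from gravirebound import simulate as S
from gravirebound.pccr import compute_pccr


class TestKinetics:
    def test_unperturbed_steady_state(self):
        p = S.KineticParams(alpha=10, beta=1, gamma=0.1)
        for t in (0.0, 1.0, 50.0):
            u, s = S.solve_kinetics(p, t)
            assert u == pytest.approx(10.0)
            assert s == pytest.approx(100.0)

    def test_alpha_step_reaches_new_steady_state(self):
        p = S.KineticParams(alpha=10, beta=1, gamma=0.1, perturbed="alpha", fold=2)
        u, s = S.solve_kinetics(p, 500.0)
        assert u == pytest.approx(20.0, rel=1e-6)
        assert s == pytest.approx(200.0, rel=1e-6)

    def test_alpha_step_unspliced_closed_form(self):
        # u(t) = 20 - 10 e^{-t} for alpha 10 -> 20 with beta = 1
        p = S.KineticParams(alpha=10, beta=1, gamma=0.1, perturbed="alpha", fold=2)
        u, _ = S.solve_kinetics(p, 3.0)
        assert u == pytest.approx(20 - 10 * math.exp(-3), rel=1e-9)

    @pytest.mark.parametrize("degenerate", [False, True])
    def test_matches_numeric_ode(self, rng, degenerate):
        for _ in range(8):
            beta = rng.uniform(0.2, 2.0)
            gamma = beta if degenerate else rng.uniform(0.1, 1.0)
            p = S.KineticParams(
                alpha=rng.uniform(1, 20),
                beta=beta,
                gamma=gamma,
                perturbed="alpha" if rng.random() < 0.5 else "gamma",
                fold=rng.uniform(0.3, 3.0),
                rebound_time=5.0,
            )
            t = rng.uniform(0.5, 15.0)

            def rhs(tt, y):
                mult = p.fold if tt < 5.0 else 1.0
                a = p.alpha * (mult if p.perturbed == "alpha" else 1.0)
                g = p.gamma * (mult if p.perturbed == "gamma" else 1.0)
                return [a - p.beta * y[0], p.beta * y[0] - g * y[1]]

            sol = solve_ivp(
                rhs,
                (0, t),
                [p.alpha / p.beta, p.alpha / p.gamma],
                rtol=1e-10,
                atol=1e-12,
                max_step=0.1,
            )
            u, s = S.solve_kinetics(p, t)
            assert u == pytest.approx(sol.y[0, -1], rel=1e-6)
            assert s == pytest.approx(sol.y[1, -1], rel=1e-6)

    def test_gamma_step_degrades_spliced_only(self):
        # the mechanism behind the spliced/unspliced asymmetry: faster
        # degradation lowers s while u is untouched
        p = S.KineticParams(alpha=10, beta=1, gamma=0.5, perturbed="gamma", fold=2)
        u0, s0 = S.solve_kinetics(p, 0.0)
        u3, s3 = S.solve_kinetics(p, 3.0)
        assert u3 == pytest.approx(u0)
        assert s3 < s0

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            S.KineticParams(alpha=1, beta=0, gamma=0.1)
        with pytest.raises(ValueError):
            S.KineticParams(alpha=1, beta=1, gamma=1, fold=0)


class TestLayeredSimulation:
    def test_identical_seeds_identical_matrices(self, sim_ann, design):
        truth = S.simulate_ground_truth(sim_ann, seed=3)
        a, _ = S.simulate_layered_counts(design, sim_ann, truth, seed=9)
        b, _ = S.simulate_layered_counts(design, sim_ann, truth, seed=9)
        assert a.spliced.equals(b.spliced)
        assert a.unspliced.equals(b.unspliced)
        assert a.ambiguous.equals(b.ambiguous)

    def test_zero_library_size_is_error(self, sim_ann):
        design = S.SimulationDesign(library_scale=0.0)
        truth = S.simulate_ground_truth(sim_ann, seed=3)
        with pytest.raises(ValueError, match="library"):
            S.simulate_layered_counts(design, sim_ann, truth, seed=1)

    def test_truth_gene_missing_from_annotation_is_error(self, sim_ann, design):
        truth = S.simulate_ground_truth(sim_ann, seed=3)
        truth = truth.rename(index={truth.index[0]: "NOT_A_GENE"})
        with pytest.raises(ValueError, match="absent"):
            S.simulate_layered_counts(design, sim_ann, truth, seed=1)

    def test_nb_sampler_poisson_limit(self, rng):
        m = np.full(20000, 37.0)
        x = S._nb_sample(rng, m, np.full_like(m, 1e-12))
        assert x.mean() == pytest.approx(37.0, rel=0.02)
        assert x.var() == pytest.approx(37.0, rel=0.05)

    def test_nb_sampler_overdispersion(self, rng):
        m = np.full(20000, 100.0)
        x = S._nb_sample(rng, m, np.full_like(m, 0.1))
        assert x.var() == pytest.approx(100 + 0.1 * 100**2, rel=0.1)

    def test_gamma_step_means_spliced_down_unspliced_flat(self, sim_ann, design):
        truth = S.simulate_ground_truth(
            sim_ann, seed=3, class_fractions={"post_transcriptional_down": 1.0}
        )
        lc, cond = S.simulate_layered_counts(design, sim_ann, truth, seed=10)
        ctrl = cond.index[cond == "Ctrl"]
        h3 = cond.index[cond == "hypg3"]
        ratio_s = lc.spliced[h3].to_numpy().mean() / lc.spliced[ctrl].to_numpy().mean()
        ratio_u = lc.unspliced[h3].to_numpy().mean() / lc.unspliced[ctrl].to_numpy().mean()
        assert ratio_s < 0.7
        assert ratio_u == pytest.approx(1.0, abs=0.1)


class TestTranscriptCounts:
    def test_fully_coding_gene_has_pccr_one(self, sim_ann, design):
        truth = S.simulate_ground_truth(sim_ann, seed=3)
        tx = S.simulate_transcript_counts(design, sim_ann, truth, seed=4)
        rec = compute_pccr(tx, condition_of=design.condition_of())
        solo = truth.index[~truth["has_noncoding_tx"]]
        vals = rec.loc[rec.index.intersection(solo), "pccr_Ctrl"].dropna()
        assert (vals == 1.0).all()

    def test_seeded_shift_recovered_as_decreased(self, sim_ann, design):
        truth = S.simulate_ground_truth(sim_ann, seed=3)
        tx = S.simulate_transcript_counts(design, sim_ann, truth, seed=4)
        rec = compute_pccr(tx, condition_of=design.condition_of())
        down = truth.index[truth["pccr_shift"] == "down"]
        classes = rec.loc[down, "pccr_class"]
        assert (classes == "decreased").mean() > 0.9

    def test_seeds_reproduce(self, sim_ann, design):
        truth = S.simulate_ground_truth(sim_ann, seed=3)
        a = S.simulate_transcript_counts(design, sim_ann, truth, seed=4)
        b = S.simulate_transcript_counts(design, sim_ann, truth, seed=4)
        assert a.equals(b)


class TestSamFixture:
    def test_truth_labels_by_construction(self, sim_ann, tmp_path):
        path = str(tmp_path / "f.sam")
        truth = S.generate_sam_fixture(sim_ann, 300, seed=5, path=path)
        assert set(truth["label"]) <= {"spliced", "unspliced", "ambiguous"}
        # junction reads exist and carry N gaps in their CIGARs
        cigars = [
            line.split("\t")[5]
            for line in open(path)
            if line and not line.startswith("@")
        ]
        assert any("N" in c for c in cigars)
        assert (truth["label"] == "unspliced").any()
        assert (truth["label"] == "ambiguous").any()

    def test_secondary_records_emitted(self, sim_ann, tmp_path):
        path = str(tmp_path / "f.sam")
        S.generate_sam_fixture(sim_ann, 120, seed=5, path=path, secondary_every=50)
        flags = [
            int(line.split("\t")[1])
            for line in open(path)
            if line and not line.startswith("@")
        ]
        assert any(f & 0x100 for f in flags)
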
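"""Trinucleotide categorization, close/isolated partitioning, HMM/MMM
estimation and decoding, checked against exhaustive enumeration and an
independent HMM library."""

import itertools

import numpy as np
import pandas as pd
import pytest

import siglmf.synthetic as syn
from siglmf import mutsig
from siglmf.mutsig import (HmmModel, MmmModel, categorize_mutation,
                           decode_isolated, fit_hmm, fit_mmm, forward_logprob,
                           partition_samples, select_genes,
                           sequence_probability, signature_activity,
                           split_close_isolated, viterbi, viterbi_score)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _random_hmm(t: int, rng, n_categories: int = 6) -> HmmModel:
    E = rng.dirichlet(np.ones(n_categories), size=t)
    E = np.hstack([E, np.zeros((t, 96 - n_categories))])
    E = E / E.sum(axis=1, keepdims=True)
    return HmmModel(rng.dirichlet(np.ones(t)), rng.dirichlet(np.ones(t), size=t), E)


def _events(positions, chrom="1", cats=None):
    n = len(positions)
    return pd.DataFrame({"sample": ["s"] * n, "chrom": [chrom] * n,
                         "pos": positions,
                         "category": cats if cats is not None else [0] * n})


class TestCategorize:
    def test_first_category_is_aca_c_to_a(self):
        assert categorize_mutation("C", "A", "A", "A") == 0

    def test_strand_symmetry(self):
        # G>T with flanks (5'=T, 3'=T) is the reverse complement of
        # C>A in an A_A context
        assert categorize_mutation("G", "T", "T", "T") == \
            categorize_mutation("C", "A", "A", "A")

    def test_strand_symmetry_exhaustive(self):
        for cat in range(96):
            ref, alt, five, three = mutsig.category_context(cat)
            assert categorize_mutation(ref, alt, five, three) == cat
            assert categorize_mutation(COMP[ref], COMP[alt],
                                       COMP[three], COMP[five]) == cat

    def test_bijective_on_pyrimidine_domain(self):
        cats = {categorize_mutation(r, a, f, t)
                for r in "CT" for a in "ACGT" if a != r
                for f in "ACGT" for t in "ACGT"}
        assert cats == set(range(96))

    @pytest.mark.parametrize("bad", [("N", "A", "A", "A"), ("C", "C", "A", "A")])
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(ValueError):
            categorize_mutation(*bad)


class TestSplit:
    def test_single_mutation_is_one_close_run(self):
        part = split_close_isolated(_events([500]))
        assert [(r.kind, len(r.categories)) for r in part.runs] == [("close", 1)]

    def test_worked_positions_example(self):
        part = split_close_isolated(_events([100, 1500, 10000, 10500, 50000]))
        assert [(r.kind, len(r.categories)) for r in part.runs] == \
            [("close", 2), ("isolated", 1), ("close", 1), ("isolated", 1)]

    def test_alternating_decomposition_shape(self):
        # 5 close, 3 isolated, 5 close, 3 isolated, 1 close
        pos, p = [], 1000
        for kind, ln in [("c", 5), ("i", 3), ("c", 5), ("i", 3), ("c", 1)]:
            for _ in range(ln):
                p += 100 if kind == "c" else 5000
                pos.append(p)
        part = split_close_isolated(_events(pos))
        kinds = [r.kind for r in part.runs]
        assert kinds == ["close", "isolated", "close", "isolated", "close"]
        assert sum(r.kind == "close" for r in part.runs) == 3
        assert sum(r.kind == "isolated" for r in part.runs) == 2

    def test_gap_of_exactly_2000_is_close(self):
        part = split_close_isolated(_events([1000, 3000, 5001]))
        assert [r.kind for r in part.runs] == ["close", "isolated"]
        assert len(part.runs[0].categories) == 2

    def test_chromosome_change_restarts_close(self):
        ev = pd.concat([_events([100, 300], chrom="1"),
                        _events([100], chrom="2")], ignore_index=True)
        part = split_close_isolated(ev)
        assert [r.kind for r in part.runs] == ["close", "close"]
        assert [r.chromosome for r in part.runs] == ["1", "2"]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            split_close_isolated(_events([500, 100]))

    def test_flatten_is_identity(self):
        rng = np.random.default_rng(4)
        pos = np.cumsum(rng.integers(1, 6000, size=50))
        cats = rng.integers(0, 96, size=50)
        part = split_close_isolated(_events(pos.tolist(), cats=cats.tolist()))
        fc, fp = part.flatten()
        assert np.array_equal(fc, cats)
        assert np.array_equal(fp, pos)


class TestForwardViterbi:
    def test_single_state_path_is_zero(self):
        model = HmmModel([1.0], [[1.0]], np.full((1, 96), 1 / 96))
        assert viterbi(model, [3, 5, 7]).tolist() == [0, 0, 0]

    def test_forward_matches_bruteforce_sum(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            t = int(rng.integers(1, 5))
            length = int(rng.integers(1, 9))
            model = _random_hmm(t, rng)
            obs = rng.integers(0, 6, size=length)
            total = 0.0
            for path in itertools.product(range(t), repeat=length):
                p = model.pi[path[0]] * model.E[path[0], obs[0]]
                for a, b, o in zip(path[:-1], path[1:], obs[1:]):
                    p *= model.A[a, b] * model.E[b, o]
                total += p
            assert forward_logprob(model, obs) == pytest.approx(np.log(total),
                                                                rel=1e-10)

    def test_viterbi_matches_bruteforce_max(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            t = int(rng.integers(1, 5))
            length = int(rng.integers(1, 9))
            model = _random_hmm(t, rng)
            obs = rng.integers(0, 6, size=length)
            best = max(itertools.product(range(t), repeat=length),
                       key=lambda path: viterbi_score(model, path, obs))
            decoded = viterbi(model, obs)
            assert viterbi_score(model, decoded, obs) == \
                viterbi_score(model, best, obs)

    def test_deterministic_emissions_read_off_symbols(self):
        E = np.zeros((3, 96))
        E[0, 0] = E[1, 1] = E[2, 2] = 1.0
        model = HmmModel(np.full(3, 1 / 3), np.full((3, 3), 1 / 3), E)
        assert viterbi(model, [2, 0, 1, 1]).tolist() == [2, 0, 1, 1]

    def test_impossible_sequence_raises(self):
        E = np.zeros((2, 96))
        E[:, 0] = 1.0
        model = HmmModel([0.5, 0.5], np.full((2, 2), 0.5), E)
        with pytest.raises(ValueError, match="position 1"):
            forward_logprob(model, [0, 5])


class TestFitHmm:
    def test_single_state_closed_form(self):
        runs = [[0, 1, 1], [2, 1]]
        model = fit_hmm(runs, t=1)
        assert model.A.tolist() == [[1.0]]
        assert model.pi.tolist() == [1.0]
        freq = np.bincount([0, 1, 1, 2, 1], minlength=96) / 5
        assert np.allclose(model.E[0], freq)

    def test_loglik_nondecreasing(self, planted_mutations, sig_truth3):
        maf, _ = planted_mutations
        parts = partition_samples(maf.loc[maf["sample"] == "S000"])
        runs = [r for p in parts.values() for r in p.close_runs()]
        model = fit_hmm(runs, t=2, n_restarts=2, max_iter=40, seed=1)
        diffs = np.diff(model.loglik_trajectory)
        assert (diffs >= -1e-8).all()

    def test_matches_hmmlearn_likelihood(self):
        # independent implementation check: same fixed parameters must give
        # the same sequence likelihood
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(12)
        model = _random_hmm(3, rng)
        obs = rng.integers(0, 6, size=12)
        ref = hmmlearn.CategoricalHMM(n_components=3)
        ref.startprob_ = model.pi
        ref.transmat_ = model.A
        ref.emissionprob_ = model.E
        ref.n_features = 96
        assert forward_logprob(model, obs) == pytest.approx(
            ref.score(obs.reshape(-1, 1)), rel=1e-10)
        assert viterbi(model, obs).tolist() == \
            ref.predict(obs.reshape(-1, 1)).tolist()


class TestFitMmm:
    def test_single_component_closed_form(self):
        model = fit_mmm([0, 0, 1, 3], t=1)
        assert model.g.tolist() == [1.0]
        T = np.bincount([0, 0, 1, 3], minlength=96) / 4
        assert np.allclose(model.E[0], T)

    def test_disjoint_support_recovers_exact_fractions(self):
        E = np.zeros((2, 96))
        E[0, :3] = 1 / 3
        E[1, 3:6] = 1 / 3
        draws = [0] * 30 + [4] * 70
        model = fit_mmm(draws, t=2, fixed_E=E, seed=0)
        assert model.g == pytest.approx([0.3, 0.7], abs=1e-6)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(3)
        model = fit_mmm(rng.integers(0, 96, size=400), t=3, seed=0)
        assert (np.diff(model.loglik_trajectory) >= -1e-8).all()


class TestDecodeAndActivity:
    def test_decode_isolated_direct_product(self):
        E = np.full((2, 96), 1 / 96)
        E[0, 5], E[1, 5] = 0.5, 0.1
        E = E / E.sum(axis=1, keepdims=True)
        model = MmmModel([0.3, 0.7], E)
        # scores ~ (0.3*0.5, 0.7*0.1) before normalization -> state 0
        assert decode_isolated(model, 5) == 0

    def test_degenerate_mixing_always_first_state(self):
        model = MmmModel([1.0, 0.0], np.full((2, 96), 1 / 96))
        for cat in (0, 40, 95):
            assert decode_isolated(model, cat) == 0

    def test_counts_sum_to_mutation_count(self, planted_mutations, sig_truth3):
        maf, _ = planted_mutations
        hmm = HmmModel(sig_truth3.pi, sig_truth3.A, sig_truth3.E)
        mmm = MmmModel(sig_truth3.g, sig_truth3.E)
        parts = partition_samples(maf[maf["sample"].isin(["S000", "S001"])])
        for part in parts.values():
            act = signature_activity(part, hmm, mmm)
            assert act.counts.sum() == part.n_mutations

    def test_activity_additive_over_concatenated_samples(self, sig_truth3):
        maf, _ = syn.gen_mutation_dataset(sig_truth3, 2, seed=5,
                                          mean_mutations=30.0)
        hmm = HmmModel(sig_truth3.pi, sig_truth3.A, sig_truth3.E)
        mmm = MmmModel(sig_truth3.g, sig_truth3.E)
        parts = partition_samples(maf)
        separate = sum(signature_activity(p, hmm, mmm).counts
                       for p in parts.values())
        merged = mutsig.MutationPartition(
            "merged", [r for s in sorted(parts) for r in parts[s].runs])
        assert np.array_equal(signature_activity(merged, hmm, mmm).counts,
                              separate)


class TestSequenceProbability:
    def test_empty_partition_has_probability_one(self, sig_truth3):
        hmm = HmmModel(sig_truth3.pi, sig_truth3.A, sig_truth3.E)
        mmm = MmmModel(sig_truth3.g, sig_truth3.E)
        assert sequence_probability(mutsig.MutationPartition("x", []),
                                    hmm, mmm) == 0.0

    def test_factorizes_into_run_terms(self, sig_truth3):
        rng = np.random.default_rng(6)
        hmm = HmmModel(sig_truth3.pi, sig_truth3.A, sig_truth3.E)
        mmm = MmmModel(sig_truth3.g, sig_truth3.E)
        for _ in range(10):
            runs = []
            expected = 0.0
            for k in range(int(rng.integers(1, 6))):
                cats = rng.integers(0, 96, size=int(rng.integers(1, 6)))
                if rng.random() < 0.5:
                    runs.append(mutsig.Run("close", cats, np.arange(len(cats))))
                    expected += forward_logprob(hmm, cats)
                else:
                    runs.append(mutsig.Run("isolated", cats, np.arange(len(cats))))
                    expected += sum(np.log(mmm.g @ mmm.E[:, c]) for c in cats)
            got = sequence_probability(mutsig.MutationPartition("x", runs),
                                       hmm, mmm)
            assert got == pytest.approx(expected, rel=1e-12)


class TestSelectGenes:
    def test_gene_equal_to_activity_is_selected(self):
        rng = np.random.default_rng(0)
        act = pd.DataFrame(rng.integers(0, 30, size=(20, 2)).astype(float),
                           index=[f"s{i}" for i in range(20)],
                           columns=["sig0", "sig1"])
        expr = pd.DataFrame({"gene_hit": act["sig0"],
                             "gene_flat": np.ones(20),
                             "gene_noise": rng.normal(size=20)},
                            index=act.index)
        selected, table = select_genes(expr, act)
        assert "gene_hit" in selected
        assert "gene_flat" not in selected  # constant -> excluded
        hit_rho = table.query("gene == 'gene_hit' and signature == 'sig0'")
        assert hit_rho["rho"].iloc[0] == pytest.approx(1.0)

    def test_signed_threshold_ignores_anticorrelated_by_default(self):
        rng = np.random.default_rng(1)
        act = pd.DataFrame(rng.integers(0, 50, size=(30, 1)).astype(float),
                           index=[f"s{i}" for i in range(30)], columns=["sig0"])
        expr = pd.DataFrame({"anti": -act["sig0"]}, index=act.index)
        selected_signed, _ = select_genes(expr, act, use_abs=False)
        selected_abs, _ = select_genes(expr, act, use_abs=True)
        assert selected_signed == []
        assert selected_abs == ["anti"]

    def test_too_few_samples_rejected(self):
        act = pd.DataFrame({"sig0": [1.0, 2.0]}, index=["a", "b"])
        expr = pd.DataFrame({"g": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            select_genes(expr, act)
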
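import itertools

import numpy as np
import pandas as pd
import pytest

import protattr as pa
from protattr.data import ProteinRecord
from protattr.stats import (
    amino_acid_mean_scores,
    crosstab_embedding_vs_prediction,
    distance_profile,
    exclusive_pass_analysis,
    kendall_tau,
    mann_whitney_u,
    random_separability_check,
    residue_scores,
    results_frame,
    round_half_away,
    run_property_tests,
    summarize_pass_counts,
)


def tau_b_pair_count(x, y):
    """Brute-force tau-b over all pairs, with tie corrections."""
    n = len(x)
    C = D = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            C += 1
        else:
            D += 1
    n0 = n * (n - 1) / 2
    return (C - D) / np.sqrt((n0 - tx) * (n0 - ty))


class TestResidueScores:
    def test_identity_matrix_scores(self):
        s = residue_scores(np.eye(4), "ACDE")
        assert np.allclose(s.target_scores, 0.25)
        assert np.allclose(s.source_scores, 0.25)

    def test_constant_matrix_scores(self):
        s = residue_scores(np.full((5, 5), 2.5), "ACDEF")
        assert np.all(s.target_scores == 2.5) and np.all(s.source_scores == 2.5)

    def test_matches_loop_oracle_bit_exactly(self):
        X = np.random.default_rng(0).normal(size=(6, 6))
        s = residue_scores(X, "ACDEFG")
        for i in range(6):
            assert s.target_scores[i] == X[i, :].mean()
            assert s.source_scores[i] == X[:, i].mean()

    def test_absolute_transform(self):
        X = -np.eye(3)
        s = residue_scores(X, "ACD", transform="absolute")
        assert np.allclose(s.target_scores, 1 / 3)


class TestAminoAcidMeanScores:
    def test_single_letter_signal(self):
        rec = ProteinRecord("P", "A", 4, "AACA")
        X = np.diag([1.0, 1.0, 0.0, 1.0])  # A residues score 0.25, C scores 0
        s = residue_scores(X, rec.sequence)
        vec = amino_acid_mean_scores([s], "target")
        assert vec[pa.AA_ALPHABET.index("A")] == pytest.approx(0.25)
        assert vec[pa.AA_ALPHABET.index("C")] == pytest.approx(0.0)
        assert np.isnan(vec[pa.AA_ALPHABET.index("W")])

    def test_pooling_across_proteins_matches_oracle(self):
        rng = np.random.default_rng(1)
        recs = [ProteinRecord("P1", "A", 5, "ACACA"), ProteinRecord("P2", "A", 4, "CAAC")]
        sets, pooled = [], {}
        for r in recs:
            X = rng.normal(size=(r.length, r.length))
            s = residue_scores(X, r.sequence)
            sets.append(s)
            for letter, v in zip(r.sequence, s.target_scores):
                pooled.setdefault(letter, []).append(v)
        vec = amino_acid_mean_scores(sets, "target")
        for letter, vals in pooled.items():
            assert vec[pa.AA_ALPHABET.index(letter)] == pytest.approx(np.mean(vals))

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            amino_acid_mean_scores([], "target")


class TestMannWhitney:
    def test_exact_small_sample_enumeration(self):
        # all C(4,2)=6 orderings: U=0 occurs once per tail -> p = 2/6
        U, p = mann_whitney_u([1, 2], [3, 4])
        assert U == 0.0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_samples_give_p_near_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKendall:
    def test_perfect_concordance_and_discordance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert kendall_tau(x, x)[0] == pytest.approx(1.0)
        assert kendall_tau(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_tau_matches_brute_force_pair_count_on_property_table(self, property_table):
        # hydrophobicity vs molecular mass: 190 pairs, ties handled
        x = property_table["hydrophobicity"].to_numpy(dtype=float)
        y = property_table["molecular_mass"].to_numpy(dtype=float)
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(tau_b_pair_count(x, y), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _mats_for(records, matrices, key=("toy", "saliency", "embedding")):
    return {key: list(zip(records, matrices))}


class TestRunPropertyTests:
    def test_grid_shape_per_cell(self, small_corpus, property_table):
        rng = np.random.default_rng(2)
        mats = _mats_for(small_corpus,
                         [rng.normal(size=(r.length, r.length)) for r in small_corpus])
        res = run_property_tests(mats, property_table)
        assert len(res) == 14  # (3 categorical + 4 numerical) x 2 roles
        assert all(r.evaluable for r in res)

    def test_acidic_basic_split_uses_only_those_residues(self, property_table):
        # all acidic residues score +1, all basic -1, everything else huge:
        # the test must still separate acidic from basic perfectly
        seq = "DEHKRAAAACCCWWW"
        rec = ProteinRecord("P", "A", len(seq), seq,
                            np.zeros(len(seq), dtype=np.int8))
        X = np.zeros((len(seq), len(seq)))
        scores = {"D": 1.0, "E": 1.1, "H": -1.0, "K": -1.1, "R": -1.2}
        for i, letter in enumerate(seq):
            X[i, :] = scores.get(letter, 100.0 + i)
        res = run_property_tests(_mats_for([rec], [X]), property_table)
        # constant source-score vectors leave tau undefined: flagged, not raised
        assert all(not r.evaluable for r in res
                   if r.kind == "numerical" and r.role == "source")
        ab = [r for r in res if r.property == "acidity_basicity" and r.role == "target"][0]
        # 2 acidic vs 3 basic, perfectly separated: the most extreme of the
        # 10 orderings -> exact two-sided p = 0.2
        assert ab.statistic == pytest.approx(6.0)  # U = n1*n2
        assert ab.p_value == pytest.approx(0.2, abs=1e-12)

    def test_missing_interaction_labels_marked_not_evaluable(self, property_table):
        rec = ProteinRecord("P", "A", 6, "ACDEFG")  # no labels
        X = np.random.default_rng(3).normal(size=(6, 6))
        res = run_property_tests(_mats_for([rec], [X]), property_table)
        inter = [r for r in res if r.property == "interactivity"]
        assert all(not r.evaluable for r in inter)
        assert all(not r.passed() for r in inter)

    def test_interactivity_null_calibration(self, property_table):
        # labels independent of scores: about 5% of tests reject at 0.05
        rng = np.random.default_rng(4)
        rejections = 0
        for rep in range(200):
            recs = pa.generate_synthetic_proteins(5, (20, 20), 0.3, seed=rep)
            mats = _mats_for(recs, [rng.normal(size=(20, 20)) for _ in recs])
            res = run_property_tests(mats, property_table)
            inter = [r for r in res if r.property == "interactivity" and r.role == "target"]
            rejections += inter[0].passed()
        assert 0.01 <= rejections / 200 <= 0.10


def _toy_results(p_values):
    """Build a minimal complete results frame from a pass-pattern dict."""
    rows = []
    for (model, method, mode, role, prop, kind), p in p_values.items():
        rows.append({"model": model, "xai_method": method, "mode": mode,
                     "role": role, "property": prop, "kind": kind,
                     "tau": np.nan, "p_value": p, "evaluable": True})
    return pd.DataFrame(rows)


class TestSummaries:
    def test_all_pvalues_one_gives_zero_counts(self, reported):
        frame = reported.combined().copy()
        frame["p_value"] = 1.0
        s = summarize_pass_counts(frame)
        assert s.grand_total == 0

    def test_alpha_one_counts_everything(self, reported):
        s = summarize_pass_counts(reported, alpha=1.0)
        assert s.categorical_total == 324
        assert s.numerical_total == 432

    def test_counts_equal_brute_force_filter(self, reported):
        frame = reported.combined()
        s = summarize_pass_counts(reported)
        for method in pa.XAI_METHODS:
            brute = int((frame[(frame["xai_method"] == method)]["p_value"] < 0.05).sum())
            assert int(s.by_method_model.loc[method, ("all", "total")]) == brute

    def test_duplicate_keys_rejected(self, reported):
        frame = reported.combined()
        dup = pd.concat([frame, frame.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError):
            summarize_pass_counts(dup)

    def test_crosstab_identical_modes_has_empty_off_diagonal(self):
        pvals = {}
        for model in ("M1",):
            for mode in ("embedding", "prediction"):
                for i, prop in enumerate(("aromaticity", "acidity_basicity")):
                    pvals[(model, "saliency", mode, "target", prop, "categorical")] = 0.01 * (i + 1)
        ct = crosstab_embedding_vs_prediction(_toy_results(pvals))
        assert ct.loc["pass|fail", ("all", "total")] == 0
        assert ct.loc["fail|pass", ("all", "total")] == 0

    def test_crosstab_missing_partner_rejected(self):
        pvals = {("M1", "saliency", "embedding", "target", "aromaticity", "categorical"): 0.01}
        with pytest.raises(ValueError):
            crosstab_embedding_vs_prediction(_toy_results(pvals))

    def test_exclusivity_zero_when_all_models_pass(self):
        pvals = {}
        for model in ("M1", "M2", "M3"):
            pvals[(model, "saliency", "embedding", "target", "aromaticity", "categorical")] = 0.01
        excl = exclusive_pass_analysis(_toy_results(pvals))
        assert excl["all"].exactly_one == 0
        assert excl["all"].pct_of_passed == 0

    def test_exclusivity_matches_set_algebra_oracle(self, reported):
        frame = reported.combined()
        excl = exclusive_pass_analysis(reported)
        sets = {}
        for _, r in frame.iterrows():
            key = (r["xai_method"], r["mode"], r["role"], r["property"])
            sets.setdefault(key, set())
            if r["p_value"] < 0.05:
                sets[key].add(r["model"])
        exactly1 = sum(1 for s in sets.values() if len(s) == 1)
        atleast1 = sum(1 for s in sets.values() if len(s) >= 1)
        assert excl["all"].exactly_one == exactly1
        assert excl["all"].at_least_one == atleast1

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(52.5) == 53
        assert round_half_away(17.4) == 17
        assert round_half_away(-2.5) == -3


class TestDistanceProfile:
    def test_diagonal_matrix_concentrates_at_distance_zero(self):
        prof = distance_profile([np.eye(8)], max_distance=5)
        assert prof.mean_score[0] == 1.0
        assert np.all(prof.mean_score[1:] == 0.0)

    def test_constant_matrix_is_flat(self):
        prof = distance_profile([np.full((9, 9), 3.0)], max_distance=5)
        assert np.allclose(prof.mean_score, 3.0)

    def test_unreachable_distances_flagged_not_errors(self):
        prof = distance_profile([np.ones((4, 4))], max_distance=10)
        assert np.isnan(prof.mean_score[5])
        assert prof.pair_counts[5] == 0


class TestSeparability:
    def test_random_vs_random_is_chance_level(self):
        rnd = [pa.generate_random_matrix(34, 34, 0, 1, seed=i) for i in range(30)]
        accs = [random_separability_check(rnd, seed=s) for s in range(5)]
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_linearly_separable_features_reach_perfect_accuracy(self):
        rng = np.random.default_rng(5)
        real = [rng.normal(loc=5.0, size=(30, 30)) for _ in range(25)]
        # mean-shifted matrices against zero-mean moment-matched noise are
        # trivially separable -- a sanity floor for the classifier stage
        shifted = [m - m.mean() + 8.0 * np.eye(30) for m in real]
        assert random_separability_check(shifted, seed=0) == 1.0

    def test_too_few_matrices_rejected(self):
        with pytest.raises(ValueError):
            random_separability_check([np.eye(30)] * 5, seed=0)
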
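"""Association scan, clumping, scoring and AUC against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from pgscohort.gwas_ct import (
    Candidate,
    CandidateGrid,
    DataError,
    ProtocolError,
    ScoreWeights,
    auc_with_ci,
    build_candidates,
    clump,
    compute_pgs,
    meta_analyze,
    run_gwas,
    tune_and_select,
    weights_from_candidate,
)


def brute_force_clump(assoc, p_threshold, window):
    """Literal restatement of the greedy definition, O(m^2)."""
    ok = assoc[(assoc["flag"] == "ok") & (assoc["p_value"] <= p_threshold)]
    ok = ok.sort_values(["p_value", "position", "snp_id"], kind="mergesort")
    accepted = []
    for _, row in ok.iterrows():
        if window == 0 or all(abs(row["position"] - q) > window
                              for _, q in accepted):
            accepted.append((row["snp_id"], row["position"]))
    return [s for s, _ in accepted]


def brute_force_auc(scores, labels):
    """All-pairs concordance with ties counted one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))


def random_assoc(rng, m=50):
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(m)],
            "position": np.sort(rng.choice(2_000_000, size=m, replace=False)),
            "beta_hat": rng.normal(size=m),
            "se": np.full(m, 1.0),
            "p_value": rng.uniform(size=m),
            "flag": "ok",
        }
    )


class TestRunGwas:
    def test_monomorphic_flagged(self):
        dos = np.column_stack([np.ones(40), np.repeat([0, 1, 2], [10, 20, 10])])
        y = np.repeat([1, 0], 20)
        out = run_gwas(dos.astype(int), y)
        assert out.loc[0, "flag"] == "monomorphic"
        assert out.loc[0, "p_value"] == 1.0
        assert out.loc[0, "beta_hat"] == 0.0

    def test_allelic_or_oracle_on_haploid_expansion(self):
        # 2x2 allele table: cases 30/170 effect alleles, controls 10/190;
        # allelic OR = (30*190)/(170*10) = 3.3529, beta = log OR at the MLE
        dos = np.concatenate([np.repeat([1, 0], [30, 170]),
                              np.repeat([1, 0], [10, 190])])[:, None]
        y = np.repeat([1, 0], [200, 200])
        out = run_gwas(dos, y)
        assert out.loc[0, "beta_hat"] == pytest.approx(np.log(3.352941), abs=1e-3)

    def test_matches_statsmodels_with_covariates(self):
        rng = np.random.default_rng(21)
        n = 800
        dos = rng.binomial(2, 0.3, size=(n, 3))
        cov = rng.normal(size=(n, 2))
        eta = -1.0 + 0.4 * dos[:, 0] + 0.3 * cov[:, 0]
        y = rng.uniform(size=n) < 1 / (1 + np.exp(-eta))
        out = run_gwas(dos, y.astype(int), covariates=cov)
        for j in range(3):
            X = sm.add_constant(np.column_stack([dos[:, j], cov]))
            ref = sm.Logit(y.astype(float), X).fit(disp=0)
            assert out.loc[j, "beta_hat"] == pytest.approx(ref.params[1], abs=1e-6)
            assert out.loc[j, "se"] == pytest.approx(ref.bse[1], rel=1e-4)

    def test_type_one_error_calibration_under_null(self):
        rng = np.random.default_rng(31)
        n, m = 2000, 2000
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, size=m), size=(n, m))
        y = rng.permutation(np.repeat([1, 0], [400, 1600]))
        out = run_gwas(dos, y)
        frac = (out.loc[out["flag"] == "ok", "p_value"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_non_binary_status_rejected(self):
        with pytest.raises(DataError):
            run_gwas(np.zeros((10, 1), dtype=int), np.arange(10))

    def test_meta_analysis_pools_precision(self):
        rng = np.random.default_rng(41)
        tables = []
        for seed in (1, 2):
            t = random_assoc(np.random.default_rng(seed), m=20)
            t["beta_hat"] = 0.5 + rng.normal(0, 0.05, size=20)
            t["se"] = 0.2
            tables.append(t)
        meta = meta_analyze(tables)
        assert np.allclose(meta["se"], 0.2 / np.sqrt(2))
        assert np.allclose(meta["beta_hat"],
                           (tables[0]["beta_hat"] + tables[1]["beta_hat"]) / 2)


class TestClump:
    def test_all_above_threshold_empty(self):
        assoc = random_assoc(np.random.default_rng(0))
        assoc["p_value"] = 0.5
        assert clump(assoc, 0.01, 100) == []

    def test_window_zero_keeps_all_below_threshold(self):
        assoc = random_assoc(np.random.default_rng(1))
        kept = clump(assoc, 0.3, 0)
        assert set(kept) == set(assoc.loc[assoc["p_value"] <= 0.3, "snp_id"])

    def test_worked_example(self):
        assoc = pd.DataFrame(
            {
                "snp_id": ["a", "b", "c", "d", "e"],
                "position": [100, 150, 300, 320, 900],
                "p_value": [0.001, 0.0001, 0.01, 0.002, 0.03],
                "beta_hat": 1.0,
                "se": 1.0,
                "flag": "ok",
            }
        )
        kept = clump(assoc, 0.05, 100)
        assert kept == brute_force_clump(assoc, 0.05, 100)
        positions = assoc.set_index("snp_id").loc[kept, "position"].tolist()
        assert positions == [150, 320, 900]

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_greedy_matches_brute_force(self, seed):
        assoc = random_assoc(np.random.default_rng(seed))
        for thr in (0.01, 0.2, 1.0):
            for w in (0, 10_000, 200_000):
                assert clump(assoc, thr, w) == brute_force_clump(assoc, thr, w)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_nested_thresholds_give_nested_sets(self, seed):
        assoc = random_assoc(np.random.default_rng(seed))
        for w in (0, 50_000):
            inner = set(clump(assoc, 0.05, w))
            outer = set(clump(assoc, 0.5, w))
            assert inner <= outer


class TestCandidates:
    def test_default_grid_has_nine_candidates(self):
        grid = build_candidates(random_assoc(np.random.default_rng(2)))
        assert len(grid.candidates) == 9

    def test_single_pair_equals_clump(self):
        assoc = random_assoc(np.random.default_rng(3))
        grid = build_candidates(assoc, [0.2], [30_000])
        assert grid.candidates[0].snp_ids == clump(assoc, 0.2, 30_000)


class TestComputePgs:
    def test_hand_arithmetic(self):
        w = ScoreWeights(table=pd.DataFrame(
            {"snp_id": ["a", "b", "c"], "effect_allele": "A",
             "effect_weight": [0.1, -0.2, 0.3], "allele_freq": 0.5}))
        dos = np.array([[0, 1, 2]])
        out = compute_pgs(dos, ["a", "b", "c"], w)
        assert out.loc[0, "pgs_raw"] == pytest.approx(0.4)

    def test_zero_weights_zero_scores(self):
        w = ScoreWeights(table=pd.DataFrame(
            {"snp_id": ["a"], "effect_allele": "A", "effect_weight": [0.0],
             "allele_freq": 0.5}))
        out = compute_pgs(np.array([[2], [0]]), ["a"], w)
        assert (out["pgs_raw"] == 0).all()

    def test_self_standardization(self):
        rng = np.random.default_rng(4)
        w = ScoreWeights(table=pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(10)], "effect_allele": "A",
             "effect_weight": rng.normal(size=10), "allele_freq": 0.3}))
        dos = rng.binomial(2, 0.3, size=(500, 10))
        out = compute_pgs(dos, [f"s{i}" for i in range(10)], w)
        assert out["pgs_std"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["pgs_std"].std() == pytest.approx(1.0, rel=1e-2)

    def test_missing_snp_imputed_at_2f(self):
        w = ScoreWeights(table=pd.DataFrame(
            {"snp_id": ["a", "b"], "effect_allele": "A",
             "effect_weight": [1.0, 1.0], "allele_freq": [0.5, 0.25]}),
            ref_mean=0.0, ref_sd=1.0)
        out = compute_pgs(np.array([[2]]), ["a"], w, max_missing_frac=0.6)
        assert out.loc[0, "pgs_raw"] == pytest.approx(2.0 + 2 * 0.25)

    def test_too_many_missing_rejected(self):
        w = ScoreWeights(table=pd.DataFrame(
            {"snp_id": ["a", "b", "c"], "effect_allele": "A",
             "effect_weight": 1.0, "allele_freq": 0.5}))
        with pytest.raises(DataError):
            compute_pgs(np.array([[2]]), ["a"], w, max_missing_frac=0.2)

    def test_duplicate_weight_ids_rejected(self):
        with pytest.raises(DataError):
            ScoreWeights(table=pd.DataFrame(
                {"snp_id": ["a", "a"], "effect_allele": "A",
                 "effect_weight": [1.0, 2.0]}))


class TestTuneAndSelect:
    def _grid_with(self, assoc, sets):
        return CandidateGrid(assoc=assoc, candidates=[
            Candidate(p, 0, snp_ids) for p, snp_ids in sets])

    def test_overlap_is_protocol_error(self):
        assoc = random_assoc(np.random.default_rng(5))
        grid = self._grid_with(assoc, [(0.1, ["rs0"])])
        with pytest.raises(ProtocolError):
            tune_and_select(grid, np.zeros((4, 50), dtype=int),
                            list(assoc["snp_id"]), np.array([1, 0, 1, 0]),
                            tuning_ids=np.array(["x", "y"]),
                            gwas_ids=np.array(["y", "z"]))

    def test_argmax_and_reference_standardization(self):
        rng = np.random.default_rng(6)
        assoc = random_assoc(rng)
        n = 400
        dos = rng.binomial(2, 0.4, size=(n, 50))
        # outcome driven by rs0: the candidate containing rs0 must win
        y = (dos[:, 0] + rng.normal(0, 0.8, size=n) > 0.9).astype(int)
        assoc.loc[0, "beta_hat"] = 1.0
        grid = self._grid_with(assoc, [(0.1, ["rs0"]), (0.2, ["rs7"])])
        w = tune_and_select(grid, dos, list(assoc["snp_id"]), y)
        assert list(w.table["snp_id"]) == ["rs0"]
        assert w.ref_sd > 0
        scored = compute_pgs(dos, list(assoc["snp_id"]), w)
        assert scored["pgs_std"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_tie_breaks_toward_fewer_snps(self):
        assoc = random_assoc(np.random.default_rng(7))
        assoc.loc[[0, 1], "beta_hat"] = [1.0, 0.0]
        rng = np.random.default_rng(8)
        dos = rng.binomial(2, 0.4, size=(200, 50))
        y = (dos[:, 0] > 1).astype(int)
        # identical scores -> identical AUC; smaller set must win
        grid = self._grid_with(assoc, [(0.2, ["rs0", "rs1"]), (0.1, ["rs0"])])
        w = tune_and_select(grid, dos, list(assoc["snp_id"]), y)
        assert list(w.table["snp_id"]) == ["rs0"]


class TestEndToEndScore:
    def test_selected_score_brackets_between_chance_and_oracle(self):
        """With real heritability the tuned C+T score beats chance but stays
        below the true-score oracle on held-out data; selection never does
        worse than the worst candidate's tuning AUC."""
        from pgscohort.synthetic_cohort import SimConfig, generate_cohort

        cfg = SimConfig(n=43_000, m_snps=2000, n_causal=200, h2_snp=0.3,
                        c2_shared=0.0, seed=201)
        cohort, genos, model, truth = generate_cohort(cfg)
        rng = np.random.default_rng(201)
        part = rng.permutation(len(cohort))
        gw, tu, te = part[:20_000], part[20_000:28_000], part[28_000:]
        meta = model.meta_frame()
        status = cohort["t2d_status"].to_numpy()
        assoc = run_gwas(genos.offspring[gw], status[gw], snp_meta=meta)
        assoc = assoc.merge(meta[["snp_id", "allele_freq"]], on="snp_id")
        grid = build_candidates(assoc)
        w = tune_and_select(grid, genos.offspring[tu], list(meta["snp_id"]),
                            status[tu])
        s = compute_pgs(genos.offspring[te], list(meta["snp_id"]), w)
        auc_sel, _, _ = auc_with_ci(s["pgs_std"].to_numpy(), status[te],
                                    n_boot=0)
        auc_orc, _, _ = auc_with_ci(truth.table["score_true"].to_numpy()[te],
                                    status[te], n_boot=0)
        assert 0.5 < auc_sel < auc_orc
        worst = min(c.auc for c in grid.candidates if c.auc is not None)
        assert w.meta["tuning_auc"] >= worst


class TestAuc:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
        ([1, 3, 2, 4], [0, 0, 1, 1], 0.75),
        ([1, 1, 1, 1], [0, 0, 1, 1], 0.5),
    ])
    def test_worked_examples(self, scores, labels, expected):
        auc, _, _ = auc_with_ci(scores, labels, n_boot=0)
        assert auc == pytest.approx(expected)

    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        y = np.zeros(n, dtype=int)
        y[: max(1, n // 3)] = 1
        rng.shuffle(y)
        s = rng.choice([0.0, 0.5, 1.0, 2.0, 3.5], size=n)
        auc, _, _ = auc_with_ci(s, y, n_boot=0)
        assert auc == pytest.approx(brute_force_auc(s, y), abs=1e-12)

    def test_ci_brackets_point_and_single_class_rejected(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=300)
        y = (s + rng.normal(0, 1.5, size=300) > 0).astype(int)
        auc, lo, hi = auc_with_ci(s, y, n_boot=300, seed=2)
        assert lo <= auc <= hi
        with pytest.raises(DataError):
            auc_with_ci(s, np.ones(300), n_boot=10)
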
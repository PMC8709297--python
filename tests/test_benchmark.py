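"""Tests for the benchmarking protocol: controls, K-S tests, proximity,
diversity, box statistics, t-SNE, and the full orchestrator."""

import numpy as np
import pytest
from scipy import stats

from sigdesign.benchmark import (
    BenchmarkConfig,
    box_stats,
    ks_two_sample,
    make_random_control,
    make_same_indication_control,
    make_top_control,
    proximity,
    proximity_stats,
    run_benchmark,
    structural_diversity,
    subset_proximity_compare,
    tsne_embed,
)
from sigdesign.signatures import InteractionSignature, SignatureMatrix, signature_rmsd
from sigdesign.synthdata import IndicationMap


def toy_matrix(n=20, p=8, seed=0):
    rng = np.random.default_rng(seed)
    return SignatureMatrix(
        compound_ids=[f"c{i:03d}" for i in range(n)],
        values=rng.uniform(0, 1, (n, p)),
        protein_ids=[f"p{j}" for j in range(p)],
    )


class TestRandomControl:
    def test_full_corpus_sample_is_permutation(self, mini_pipeline):
        sc = mini_pipeline.scenario
        ctl = make_random_control(sc.corpus, len(sc.corpus), 1, sc.signatures)
        assert {r.compound_id for r in ctl.compounds} == {
            r.compound_id for r in sc.corpus
        }

    def test_seeded_determinism(self, mini_pipeline):
        sc = mini_pipeline.scenario
        a = make_random_control(sc.corpus, 30, 5, sc.signatures)
        b = make_random_control(sc.corpus, 30, 5, sc.signatures)
        assert [r.compound_id for r in a.compounds] == [
            r.compound_id for r in b.compounds
        ]

    def test_disjoint_seeds_differ(self, mini_pipeline):
        sc = mini_pipeline.scenario
        a = make_random_control(sc.corpus, 30, 5, sc.signatures)
        b = make_random_control(sc.corpus, 30, 6, sc.signatures)
        assert [r.compound_id for r in a.compounds] != [
            r.compound_id for r in b.compounds
        ]

    def test_oversized_request_rejected(self, mini_pipeline):
        sc = mini_pipeline.scenario
        with pytest.raises(ValueError):
            make_random_control(sc.corpus, len(sc.corpus) + 1, 0, sc.signatures)


class TestTopControl:
    def test_excludes_objective_itself(self):
        lib = toy_matrix()
        by_id = {cid: None for cid in lib.compound_ids}
        obj = InteractionSignature("c003", lib.values[3].copy())
        ctl = make_top_control(obj, lib, 5, {c: c for c in lib.compound_ids})
        assert "c003" not in [c for c in ctl.signatures.compound_ids]
        assert len(ctl) == 5

    def test_library_of_only_the_objective_gives_empty(self):
        lib = toy_matrix(n=1)
        obj = InteractionSignature("c000", lib.values[0].copy())
        ctl = make_top_control(obj, lib, 5, {"c000": None})
        assert len(ctl) == 0

    def test_matches_brute_force_sort(self):
        lib = toy_matrix(n=50, seed=2)
        obj = InteractionSignature("q", np.random.default_rng(3).uniform(0, 1, 8))
        ctl = make_top_control(obj, lib, 10, {c: c for c in lib.compound_ids})
        brute = sorted(
            (signature_rmsd(obj, InteractionSignature(c, v)), c)
            for c, v in zip(lib.compound_ids, lib.values)
        )[:10]
        assert ctl.signatures.compound_ids == [c for _, c in brute]

    def test_known_rmsd_fixture(self):
        # constructed RMSDs 0.1 / 0.2 / 0.3: n=1 must pick the 0.1 compound
        base = np.zeros(4)
        lib = SignatureMatrix(
            compound_ids=["far", "near", "mid"],
            values=np.array([[0.3] * 4, [0.1] * 4, [0.2] * 4]),
            protein_ids=[f"p{j}" for j in range(4)],
        )
        obj = InteractionSignature("q", base)
        ctl = make_top_control(obj, lib, 1, {c: c for c in lib.compound_ids})
        assert ctl.signatures.compound_ids == ["near"]


class TestSameIndicationControl:
    def test_symmetric_membership(self, mini_pipeline):
        sc = mini_pipeline.scenario
        imap = sc.indications
        a, b = None, None
        for ind in {i for _, i in imap.pairs}:
            members = imap.members(ind)
            if len(members) >= 2:
                a, b = members[0], members[1]
                break
        assert a is not None
        ctl_a = make_same_indication_control(a, imap, sc.corpus, sc.signatures)
        ctl_b = make_same_indication_control(b, imap, sc.corpus, sc.signatures)
        assert b in [r.compound_id for r in ctl_a.compounds]
        assert a in [r.compound_id for r in ctl_b.compounds]

    def test_sole_member_yields_empty_control(self):
        imap = IndicationMap(pairs=[("lonely", "indX")])
        sigs = toy_matrix(n=2)
        sigs.compound_ids = ["lonely", "other"]
        corpus = []
        ctl = make_same_indication_control("lonely", imap, corpus, sigs)
        assert len(ctl) == 0

    def test_unknown_objective_rejected(self, mini_pipeline):
        sc = mini_pipeline.scenario
        with pytest.raises(ValueError, match="no indication"):
            make_same_indication_control(
                "nonexistent", sc.indications, sc.corpus, sc.signatures
            )

    def test_matches_set_intersection_oracle(self, mini_pipeline):
        sc = mini_pipeline.scenario
        oid = sc.corpus[0].compound_id
        ctl = make_same_indication_control(
            oid, sc.indications, sc.corpus, sc.signatures
        )
        inds = set(sc.indications.indications_of(oid))
        expected = {
            r.compound_id
            for r in sc.corpus
            if r.compound_id != oid
            and inds & set(sc.indications.indications_of(r.compound_id))
        }
        assert {r.compound_id for r in ctl.compounds} == expected


class TestKsTwoSample:
    def test_identical_samples_statistic_zero(self):
        a = [0.1, 0.5, 0.9, 0.3]
        stat, p = ks_two_sample(a, list(a))
        assert stat == 0.0

    def test_fully_separated_statistic_one(self):
        stat, _ = ks_two_sample([1.0, 2.0, 3.0], [10.0, 11.0])
        assert stat == 1.0

    def test_ecdf_enumeration_example(self):
        # ECDF sup-difference of {1,2} vs {1.5,2.5} is 0.5
        stat, _ = ks_two_sample([1.0, 2.0], [1.5, 2.5])
        assert stat == pytest.approx(0.5)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_matches_scipy_exact_flag(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=12), rng.normal(0.5, size=15)
        stat, p = ks_two_sample(a, b, exact=True)
        ref = stats.ks_2samp(a, b, method="exact")
        assert (stat, p) == (ref.statistic, ref.pvalue)

    def test_null_calibration(self):
        # same-population resampling: rejection rate at alpha=0.05 should
        # sit near 0.05 over 200 replicates
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(200):
            pop = rng.uniform(0, 1, 200)
            a, b = pop[:100], pop[100:]
            _, p = ks_two_sample(a, b)
            rejections += p <= 0.05
        assert 0.02 <= rejections / 200 <= 0.10


class TestProximity:
    def test_equal_rmsd_gives_zero(self):
        assert proximity(0.2, 0.2) == 0.0

    def test_perfect_redesign_gives_one(self):
        assert proximity(0.2, 0.0) == 1.0

    def test_direct_substitution(self):
        assert proximity(0.2, 0.15) == pytest.approx(0.25)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            proximity(0.0, 0.1)

    def test_self_proximity_of_naive_control_near_zero(self):
        # control compared against its own mean has mean proximity ~ 0
        rng = np.random.default_rng(7)
        means = []
        for _ in range(100):
            sample = rng.uniform(0.05, 0.3, 100)
            ps = proximity_stats(sample, sample)
            means.append(ps.mean_proximity)
        assert abs(np.mean(means)) < 0.05

    def test_subset_compare_translation(self):
        a = [0.1, 0.2, 0.3, 0.4]
        b = [x + 0.1 for x in a]
        res = subset_proximity_compare(a, b)
        assert res["mean_b"] - res["mean_a"] == pytest.approx(0.1)
        same = subset_proximity_compare(a, list(a))
        assert same["ks_statistic"] == 0.0


class TestBoxStats:
    def test_matches_order_statistics_oracle(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=500)
        v[:5] += 20  # force outliers
        b = box_stats(v)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        assert b["q1"] == pytest.approx(q1)
        assert b["median"] == pytest.approx(med)
        assert b["q3"] == pytest.approx(q3)
        iqr = q3 - q1
        inl = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
        assert b["whisker_low"] == pytest.approx(inl.min())
        assert b["whisker_high"] == pytest.approx(inl.max())
        assert sorted(b["outliers"]) == pytest.approx(
            sorted(v[(v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)])
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            box_stats([])


class TestStructuralDiversity:
    def test_summary_matches_recomputation(self, mini_pipeline):
        from sigdesign.designer import DesignRequest, design_for_objective

        p = mini_pipeline
        ds = design_for_objective(
            DesignRequest(objective=p.scenario.objectives[0], n_designs=15, seed=3),
            p.reducer, p.model, p.scenario.proteome,
        )
        div = structural_diversity(ds)
        assert div["mean_tanimoto"] == pytest.approx(float(np.mean(ds.tanimotos)))
        assert div["max_tanimoto"] == pytest.approx(float(np.max(ds.tanimotos)))


class TestTsne:
    def test_shape_and_determinism(self):
        m = toy_matrix(n=30, seed=4)
        e1 = tsne_embed(m, seed=3)
        e2 = tsne_embed(m, seed=3)
        assert e1.shape == (30, 3)  # compound_id, x, y
        assert np.allclose(e1[["x", "y"]].values, e2[["x", "y"]].values)

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            tsne_embed(toy_matrix(n=3))
        with pytest.raises(ValueError):
            tsne_embed(toy_matrix(n=10), perplexity=10)

    def test_duplicate_signatures_land_close(self):
        # two identical rows should embed closer to each other than to a
        # far-away third point, across most seeds
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 1, 12)
        values = rng.uniform(0, 1, (12, 12))
        values[0] = base
        values[1] = base
        values[2] = 1.0 - base
        m = SignatureMatrix(
            compound_ids=[f"c{i}" for i in range(12)],
            values=values,
            protein_ids=[f"p{j}" for j in range(12)],
        )
        hits = 0
        for seed in range(10):
            emb = tsne_embed(m, seed=seed)
            xy = emb[["x", "y"]].values
            d01 = np.linalg.norm(xy[0] - xy[1])
            d02 = np.linalg.norm(xy[0] - xy[2])
            hits += d01 < d02
        assert hits >= 9


class TestRunBenchmark:
    def test_structure_and_determinism(self, mini_pipeline):
        p = mini_pipeline
        cfg = BenchmarkConfig(n_designs=15, n_random=20, n_top=10, seed=21)
        objectives = p.scenario.objectives[:2]
        res = run_benchmark(
            objectives, p.scenario.corpus, p.scenario.proteome,
            p.reducer, p.model, p.scenario.signatures,
            p.scenario.indications, cfg,
        )
        assert len(res.per_objective) == 2
        for r in res.per_objective.values():
            assert set(r.rmsd_distributions) == {
                "design", "random", "top100", "same_indication",
            }
            assert len(r.ks) == 3
            for stat, pval in r.ks.values():
                assert 0 <= stat <= 1 and 0 <= pval <= 1
        res2 = run_benchmark(
            objectives, p.scenario.corpus, p.scenario.proteome,
            p.reducer, p.model, p.scenario.signatures,
            p.scenario.indications, cfg,
        )
        for oid in res.per_objective:
            assert (
                res.per_objective[oid].rmsd_distributions
                == res2.per_objective[oid].rmsd_distributions
            )

    def test_report_json(self, mini_pipeline, tmp_path):
        import json

        p = mini_pipeline
        cfg = BenchmarkConfig(n_designs=10, n_random=15, n_top=8, seed=4)
        res = run_benchmark(
            p.scenario.objectives[:1], p.scenario.corpus, p.scenario.proteome,
            p.reducer, p.model, p.scenario.signatures,
            p.scenario.indications, cfg,
        )
        res.to_json(tmp_path / "report.json")
        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload["summary"]["n_objectives"] == 1
        assert "median_wins_vs_random" in payload["summary"]
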
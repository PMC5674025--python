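"""Ranking metrics, the weighted KS enrichment score and the permutation null."""

import numpy as np
import pandas as pd
import pytest

import herbnet as hn
from herbnet.errors import DomainError
from herbnet.expression import ExpressionMatrix
from herbnet.gsea import SD_FLOOR_FRACTION


def reference_es(genes, scores, members, weight_p):
    """Literal quadratic-time transcription of the weighted KS walk."""
    n = len(genes)
    hits = [g in members for g in genes]
    n_hit = sum(hits)
    denom = sum(abs(scores[i]) ** weight_p for i in range(n) if hits[i])
    best, running = 0.0, 0.0
    for i in range(n):
        if hits[i]:
            running += (abs(scores[i]) ** weight_p) / denom if denom else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def _mat(values, n_per_group, genes=None):
    n = values.shape[0]
    genes = genes or [f"G{i:04d}" for i in range(n)]
    cols = [f"a_{i}" for i in range(n_per_group)] + [f"b_{i}" for i in range(n_per_group)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=cols),
        groups=pd.Series(["a"] * n_per_group + ["b"] * n_per_group, index=cols),
    )


class TestRankGenes:
    def test_metrics_match_direct_formulas(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(8, 1, size=(5, 8))
        mat = _mat(vals, 4)
        x1, x2 = vals[:, :4], vals[:, 4:]
        m1, m2 = x1.mean(1), x2.mean(1)
        s1, s2 = x1.std(1, ddof=1), x2.std(1, ddof=1)
        s1 = np.maximum(s1, SD_FLOOR_FRACTION * np.abs(m1))
        s2 = np.maximum(s2, SD_FLOOR_FRACTION * np.abs(m2))
        expect = {
            "signal_to_noise": (m1 - m2) / (s1 + s2),
            "t_stat": (m1 - m2) / np.sqrt(s1**2 / 4 + s2**2 / 4),
            "log_fc": m1 - m2,
        }
        for metric, ref in expect.items():
            ranked = hn.rank_genes(mat, metric)
            got = dict(zip(ranked.genes, ranked.scores))
            for i, g in enumerate(f"G{i:04d}" for i in range(5)):
                assert got[g] == pytest.approx(ref[i], abs=1e-12)

    def test_upshifted_gene_ranks_top_with_positive_metric(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(8, 1, size=(50, 10))
        vals[13, :5] += 5.0  # up in group 1
        ranked = hn.rank_genes(_mat(vals, 5))
        assert ranked.genes[0] == "G0013"
        assert ranked.scores[0] > 0

    def test_ties_broken_by_symbol(self):
        vals = np.tile([[1.0, 1.0, 2.0, 2.0]], (3, 1))
        ranked = hn.rank_genes(_mat(vals, 2, genes=["B", "C", "A"]), "log_fc")
        assert ranked.genes == ("A", "B", "C")

    def test_single_sample_group_rejected(self):
        # the matrix container itself enforces >= 2 samples per group
        vals = np.ones((4, 4))
        cols = ["a_0", "b_0", "b_1", "b_2"]
        with pytest.raises(hn.ValidationError):
            ExpressionMatrix(
                values=pd.DataFrame(vals, index=list("WXYZ"), columns=cols),
                groups=pd.Series(["a", "b", "b", "b"], index=cols),
            )


class TestEnrichmentScore:
    def test_two_gene_trivial_case(self):
        ranked = hn.RankedList(genes=("A", "B"), scores=np.array([2.0, 1.0]))
        es, running = hn.enrichment_score(ranked, {"A"}, weight_p=0.0)
        assert es == 1.0
        assert running[0] == pytest.approx(1.0)

    def test_matches_quadratic_reference(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            scores = np.sort(rng.normal(size=50))[::-1]
            genes = tuple(f"G{i:03d}" for i in range(50))
            ranked = hn.RankedList(genes=genes, scores=scores)
            members = {genes[i] for i in rng.choice(50, size=rng.integers(1, 49), replace=False)}
            wp = float(rng.choice([0.0, 1.0, 1.5, 2.0]))
            es, _ = hn.enrichment_score(ranked, members, weight_p=wp)
            assert es == pytest.approx(reference_es(genes, scores, members, wp), abs=1e-12)

    def test_unweighted_walk_ends_at_zero(self):
        rng = np.random.default_rng(6)
        scores = np.sort(rng.normal(size=40))[::-1]
        genes = tuple(f"G{i}" for i in range(40))
        ranked = hn.RankedList(genes=genes, scores=scores)
        _, running = hn.enrichment_score(ranked, set(list(genes)[::3]), weight_p=0.0)
        assert running[-1] == pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        scores = np.sort(rng.normal(size=30))[::-1]
        genes = tuple(f"G{i}" for i in range(30))
        members = set(list(genes)[5:12])
        es1, _ = hn.enrichment_score(hn.RankedList(genes, scores), members)
        es2, _ = hn.enrichment_score(hn.RankedList(genes, scores * 7.5), members)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_random_sets_have_mean_es_near_zero(self):
        rng = np.random.default_rng(8)
        scores = np.sort(rng.normal(size=60))[::-1]
        genes = tuple(f"G{i}" for i in range(60))
        ranked = hn.RankedList(genes, scores)
        draws = np.array(
            [
                hn.enrichment_score(
                    ranked, {genes[i] for i in rng.choice(60, 10, replace=False)}, weight_p=0.0
                )[0]
                for _ in range(1000)
            ]
        )
        assert abs(draws.mean()) <= 3 * draws.std() / np.sqrt(len(draws))

    def test_degenerate_member_sets_rejected(self):
        ranked = hn.RankedList(genes=("A", "B"), scores=np.array([1.0, 0.5]))
        with pytest.raises(DomainError):
            hn.enrichment_score(ranked, {"Z"})
        with pytest.raises(DomainError):
            hn.enrichment_score(ranked, {"A", "B"})


@pytest.fixture(scope="module")
def planted():
    mat, _ = hn.gen_expression(n_genes=300, n_per_group=8, n_de=0, seed=21)
    # plant one coordinately up-regulated set (group 2)
    members = [f"G{i:06d}" for i in range(1, 21)]
    vals = mat.values.copy()
    vals.loc[members, [c for c in vals.columns if c.startswith("tumor")]] += 3.0
    mat = ExpressionMatrix(values=vals, groups=mat.groups, group_order=mat.group_order)
    sets, _ = hn.gen_gene_sets(
        list(mat.genes), n_terms=12, term_size_range=(10, 30),
        planted_term_members=members, seed=21, exclude_from_random=members,
    )
    return mat, sets


class TestGseaRun:
    def test_planted_set_is_top_and_significant(self, planted):
        mat, sets = planted
        res = hn.gsea_run(mat, sets, n_perm=200, seed=3)
        assert res.table.iloc[0]["term_id"] == "SET_PLANTED"
        assert res.table.iloc[0]["p_nominal"] < 0.05
        assert res.table.iloc[0]["es"] < 0  # up in group 2 => negative walk

    def test_same_seed_is_bitwise_reproducible(self, planted):
        mat, sets = planted
        a = hn.gsea_run(mat, sets, n_perm=100, seed=9).table
        b = hn.gsea_run(mat, sets, n_perm=100, seed=9).table
        pd.testing.assert_frame_equal(a, b)

    def test_null_nominal_p_calibration(self):
        mat, _ = hn.gen_expression(n_genes=400, n_per_group=6, n_de=0, seed=31)
        sets, _ = hn.gen_gene_sets(list(mat.genes), n_terms=40, term_size_range=(10, 30), seed=31)
        res = hn.gsea_run(mat, sets, n_perm=200, seed=4)
        frac = (res.table["p_nominal"] < 0.05).mean()
        sd = np.sqrt(0.05 * 0.95 / len(res.table))
        assert abs(frac - 0.05) <= 3 * sd + 1e-9

    def test_tiny_cohort_runs_exhaustive_null(self):
        mat, _ = hn.gen_expression(n_genes=50, n_per_group=3, n_de=0, seed=41)
        sets, _ = hn.gen_gene_sets(list(mat.genes), n_terms=4, term_size_range=(5, 10), seed=41)
        res = hn.gsea_run(mat, sets, n_perm=100, seed=5)
        assert res.exhaustive and res.n_perm == 20  # C(6,3) distinct labelings

    def test_nominal_p_has_pseudocount_floor(self, planted):
        mat, sets = planted
        res = hn.gsea_run(mat, sets, n_perm=100, seed=6)
        assert (res.table["p_nominal"] >= 1.0 / 101 - 1e-12).all()
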
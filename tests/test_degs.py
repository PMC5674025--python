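"""Disease-gene filtering, DEG calling and the three-set intersection."""

import numpy as np
import pandas as pd
import pytest

import herbnet as hn
from herbnet.expression import ExpressionMatrix


def _matrix(values, n_per_group):
    n_genes = values.shape[0]
    cols = [f"a_{i}" for i in range(n_per_group)] + [f"b_{i}" for i in range(n_per_group)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=[f"G{i:04d}" for i in range(n_genes)], columns=cols),
        groups=pd.Series(["a"] * n_per_group + ["b"] * n_per_group, index=cols),
    )


class TestDiseaseGenes:
    def test_strict_boundary_excludes_exact_threshold(self):
        recs = [("TP53", 5.0), ("EGFR", 5.01), ("BRCA1", 4.0)]
        assert hn.filter_disease_genes(recs) == {"EGFR"}
        assert hn.filter_disease_genes(recs, strict=False) == {"EGFR", "TP53"}

    def test_empty_input(self):
        assert hn.filter_disease_genes([]) == frozenset()

    def test_monotone_in_score_min(self):
        rng = np.random.default_rng(0)
        recs = [(f"G{i}", float(s)) for i, s in enumerate(rng.uniform(0, 20, 100))]
        sizes = [len(hn.filter_disease_genes(recs, score_min=t)) for t in (0, 5, 10, 15)]
        assert sizes == sorted(sizes, reverse=True)

    def test_load_collapses_duplicates_to_max(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("gene\tscore\ntp53\t3\nTP53\t9\nEGFR\t1\n")
        df = hn.load_disease_genes(p)
        assert len(df) == 2
        assert df.set_index("gene").loc["TP53", "relevance_score"] == 9.0


class TestCallDegs:
    def test_null_type_one_error_near_alpha(self):
        mat, _ = hn.gen_expression(n_genes=1000, n_per_group=10, n_de=0, seed=5)
        res = hn.call_degs(mat, alpha=0.05)
        frac = len(res.significant) / 1000
        sd = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) <= 3 * sd

    def test_single_planted_gene_has_smallest_p(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(8, 1, size=(200, 20))
        vals[7, 10:] += 5.0  # +5 within-group SDs in group 2
        mat = _matrix(vals, 10)
        res = hn.call_degs(mat)
        assert res.table.iloc[0]["gene"] == "G0007"
        assert "G0007" in res.significant
        assert res.table.iloc[0]["log2fc"] == pytest.approx(
            vals[7, 10:].mean() - vals[7, :10].mean()
        )

    @pytest.mark.parametrize("method", ["welch_t", "moderated_t"])
    def test_planted_effects_recovered(self, method):
        mat, truth = hn.gen_expression(
            n_genes=500, n_per_group=10, n_de=25, effect_sd_units=5.0, seed=2
        )
        res = hn.call_degs(mat, method=method)
        assert truth.de_genes <= res.significant

    def test_constant_gene_flagged_degenerate(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(8, 1, size=(10, 8))
        vals[4] = 8.0
        res = hn.call_degs(_matrix(vals, 4))
        row = res.table.set_index("gene").loc["G0004"]
        assert row["degenerate"] and row["p"] == 1.0
        assert "G0004" not in res.significant

    def test_adjusted_p_bounds(self):
        mat, _ = hn.gen_expression(n_genes=200, n_per_group=5, n_de=20, seed=4)
        t = hn.call_degs(mat).table
        assert ((t["p_adj"] >= t["p"] - 1e-15) & (t["p_adj"] <= 1.0)).all()

    def test_use_adjusted_thresholds_bh_column(self):
        mat, _ = hn.gen_expression(n_genes=300, n_per_group=8, n_de=30, effect_sd_units=4, seed=6)
        raw = hn.call_degs(mat, use_adjusted=False)
        adj = hn.call_degs(mat, use_adjusted=True)
        assert adj.significant <= raw.significant

    def test_probe_collapse_keeps_min_p(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(8, 1, size=(4, 10))
        vals[0, 5:] += 4.0
        mat = _matrix(vals, 5)
        res = hn.call_degs(mat, probe_map={"G0000": "X", "G0001": "X", "G0002": "Y", "G0003": "Y"})
        assert set(res.table["gene"]) == {"X", "Y"}
        x_p = res.table.set_index("gene").loc["X", "p"]
        assert x_p == hn.call_degs(mat).table.set_index("gene").loc["G0000", "p"]

    def test_moderated_t_matches_limma_reference(self, tmp_path):
        """Cross-check the empirical-Bayes moderated t against Bioconductor limma."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(12)
        vals = rng.normal(8, 1, size=(60, 12))
        vals[:5, 6:] += 2.0
        mat = _matrix(vals, 6)
        res = hn.call_degs(mat, method="moderated_t")
        mpath = tmp_path / "m.tsv"
        pd.DataFrame(vals).to_csv(mpath, sep="\t", index=False, header=False)
        script = tmp_path / "limma.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.table("{mpath}", sep="\\t"))\n'
            'design <- cbind(1, rep(c(0, 1), each = 6))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'cat(fit$t[, 2], sep = "\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=120
        )
        if out.returncode != 0:
            pytest.skip(f"limma unavailable: {out.stderr[-200:]}")
        ref_t = np.array([float(v) for v in out.stdout.split()])
        ours = res.table.set_index("gene").loc[[f"G{i:04d}" for i in range(60)], "t"].to_numpy()
        assert np.allclose(ours, ref_t, rtol=1e-6, atol=1e-8)


class TestIntersectThree:
    def test_small_example_regions(self):
        v = hn.intersect_three({"X", "Y"}, {"Y", "Z"}, {"Y"})
        assert v.triple == {"Y"}
        assert v.region_sizes() == {"A": 1, "B": 1, "C": 0, "AB": 0, "AC": 0, "BC": 0, "ABC": 1}

    def test_disjoint_sets_have_empty_triple(self):
        v = hn.intersect_three({"A1"}, {"B1"}, {"C1"})
        assert v.triple == frozenset()

    def test_regions_match_brute_force_membership_scan(self):
        rng = np.random.default_rng(17)
        pool = [f"G{i}" for i in range(60)]
        for _ in range(100):
            A, B, C = (
                {pool[i] for i in rng.choice(60, size=rng.integers(0, 30), replace=False)}
                for _ in range(3)
            )
            v = hn.intersect_three(A, B, C)
            for g in set(A) | set(B) | set(C):
                key = "".join(k for k, s in (("A", A), ("B", B), ("C", C)) if g in s)
                assert g in v.regions[key]
            # regions are disjoint and cover the union
            assert v.union_size() == len(A | B | C)

    def test_inclusion_exclusion(self):
        rng = np.random.default_rng(18)
        pool = [f"G{i}" for i in range(40)]
        A, B, C = ({pool[i] for i in rng.choice(40, size=15, replace=False)} for _ in range(3))
        v = hn.intersect_three(A, B, C)
        sizes = v.region_sizes()
        assert sum(sizes.values()) == len(A | B | C)
        assert len(v.triple) <= min(len(A), len(B), len(C))

    def test_symbols_normalized_across_sources(self):
        v = hn.intersect_three({"tp53"}, {" TP53 "}, {"Tp53"})
        assert v.triple == {"TP53"}
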
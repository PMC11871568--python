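"""Gene filtering, dual-contrast partition, dependence ranking, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

import kinomeflow as kf


def _table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"])


class TestFilterGenes:
    def _counts(self, fpm_rows):
        # library size 1e6 makes counts equal FPM directly
        df = pd.DataFrame(fpm_rows, columns=[f"s{i}" for i in range(len(fpm_rows[0]))])
        df.index = [f"g{i}" for i in range(len(fpm_rows))]
        return df

    def test_threshold_and_fraction_boundaries(self):
        counts = self._counts([[6, 6, 6, 6], [6, 6, 6, 4], [4, 4, 6, 6], [5, 5, 5, 4]])
        lib = pd.Series(1e6, index=counts.columns)
        kept = kf.filter_genes(counts, library_sizes=lib)
        # all pass; 3/4 = 0.75 inclusive passes; 2/4 fails; FPM exactly 5 counts as expressed
        assert kept == ["g0", "g1", "g3"]

    def test_zero_library_size_raises(self):
        counts = self._counts([[6, 6]])
        lib = pd.Series([1e6, 0.0], index=counts.columns)
        with pytest.raises(ValueError, match="library sizes"):
            kf.filter_genes(counts, library_sizes=lib)

    def test_negative_counts_raise(self):
        counts = self._counts([[6, -1]])
        with pytest.raises(ValueError, match="negative"):
            kf.filter_genes(counts)


class TestPartitionGenes:
    def test_shared_up(self):
        part = kf.partition_genes(
            _table([("g", 1.0, 0.01)]), _table([("g", 2.0, 0.01)])
        )
        assert set(part.shared_up) == {"g"}

    def test_opposite(self):
        part = kf.partition_genes(
            _table([("g", 1.0, 0.01)]), _table([("g", -1.0, 0.01)])
        )
        assert set(part.opposite) == {"g"}

    def test_padj_cutoff_is_strict(self):
        part = kf.partition_genes(
            _table([("g", 1.0, 0.05)]), _table([("g", 1.0, 0.01)])
        )
        assert set(part.unique_to_b) == {"g"}  # padj exactly .05 is not significant

    def test_flat_gene_reported_separately(self):
        part = kf.partition_genes(
            _table([("g", 0.0, 0.01)]), _table([("g", 1.0, 0.01)])
        )
        assert set(part.shared_flat) == {"g"}
        assert part.shared_total == 1

    def test_partition_cells_disjoint_and_complete(self):
        a, b, _ = kf.simulate_contrast_tables(
            300, n_shared_up=20, n_shared_down=15, n_opposite=5, n_unique_each=10,
            null_sd=0.3, seed=4,
        )
        part = kf.partition_genes(a, b)
        cells = [part.shared_up, part.shared_down, part.opposite,
                 part.unique_to_a, part.unique_to_b, part.shared_flat]
        union = set().union(*cells)
        assert sum(len(c) for c in cells) == len(union)
        sig_any = set(a.loc[a["padj"] < 0.05, "gene_id"]) | set(b.loc[b["padj"] < 0.05, "gene_id"])
        assert union == sig_any
        assert part.shared_total == len(part.shared_up) + len(part.shared_down) + len(part.opposite)

    def test_noiseless_roundtrip_equals_truth(self):
        a, b, truth = kf.simulate_contrast_tables(
            500, n_shared_up=30, n_shared_down=25, n_opposite=4, n_unique_each=12,
            null_sd=0.0, seed=5,
        )
        part = kf.partition_genes(a, b)
        lab = truth.set_index("gene_id")["label"]
        assert set(part.shared_up) == set(lab.index[lab == "shared_up"])
        assert set(part.shared_down) == set(lab.index[lab == "shared_down"])
        assert set(part.opposite) == set(lab.index[lab == "opposite"])
        assert set(part.unique_to_a) == set(lab.index[lab == "unique_a"])
        assert set(part.unique_to_b) == set(lab.index[lab == "unique_b"])


class TestDependenceScores:
    def test_single_gene_arithmetic(self):
        with pytest.warns(UserWarning, match="truncating"):
            r = kf.dependence_scores(_table([("g", 1.0, 0.5)]), _table([("g", 3.0, 0.5)]), top_n=1)
        assert r.scores["g"] == pytest.approx(2.0)

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i:03d}" for i in range(500)]
        a = _table([(g, x, 0.5) for g, x in zip(genes, rng.normal(size=500))])
        b = _table([(g, x, 0.5) for g, x in zip(genes, rng.normal(size=500))])
        r = kf.dependence_scores(a, b, top_n=100)
        scores = (b.set_index("gene_id")["log2fc"] - a.set_index("gene_id")["log2fc"])
        order = scores.sort_values(ascending=False).index.tolist()
        assert r.top == order[:100]
        assert r.bottom == order[::-1][:100]

    def test_tie_break_is_lexicographic_and_deterministic(self):
        a = _table([(g, 0.0, 0.5) for g in ("gb", "ga", "gc", "gd")])
        b = _table([(g, 1.0, 0.5) for g in ("gb", "ga", "gc", "gd")])
        r = kf.dependence_scores(a, b, top_n=2)
        assert r.top == ["ga", "gb"]
        assert r.bottom == ["ga", "gb"]

    def test_oversized_top_n_warns_and_truncates(self):
        a = _table([(f"g{i}", float(i), 0.5) for i in range(6)])
        b = _table([(f"g{i}", 0.0, 0.5) for i in range(6)])
        with pytest.warns(UserWarning, match="truncating"):
            r = kf.dependence_scores(a, b, top_n=5)
        assert len(r.top) == 3 and not set(r.top) & set(r.bottom)

    def test_contrast_swap_negates_scores_and_swaps_lists(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i:03d}" for i in range(50)]
        a = _table([(g, x, 0.5) for g, x in zip(genes, rng.normal(size=50))])
        b = _table([(g, x, 0.5) for g, x in zip(genes, rng.normal(size=50))])
        fwd = kf.dependence_scores(a, b, top_n=10)
        rev = kf.dependence_scores(b, a, top_n=10)
        np.testing.assert_allclose(rev.scores, -fwd.scores, rtol=1e-12)
        assert rev.top == fwd.bottom and rev.bottom == fwd.top


class TestEnrich:
    def test_disjoint_pathway(self):
        uni = [f"g{i}" for i in range(20)]
        res = kf.enrich(uni[:5], {"pw": uni[10:15]}, uni)
        row = res.iloc[0]
        assert row["n_overlap"] == 0 and row["p_value"] == pytest.approx(1.0)

    def test_perfect_overlap_closed_form(self):
        uni = [f"g{i}" for i in range(20)]
        res = kf.enrich(uni[:5], {"pw": uni[:5]}, uni)
        assert res.iloc[0]["p_value"] == pytest.approx(1 / comb(20, 5, exact=True))

    def test_bh_monotone_in_raw_p(self):
        rng = np.random.default_rng(8)
        uni = [f"g{i}" for i in range(100)]
        sets = {f"pw{j}": list(rng.choice(uni, 20, replace=False)) for j in range(12)}
        res = kf.enrich(list(rng.choice(uni, 15, replace=False)), sets, uni)
        srt = res.sort_values("p_value")
        assert (np.diff(srt["padj"].to_numpy()) >= -1e-12).all()

    def test_equal_p_equal_padj_ranked_by_overlap(self):
        uni = [f"g{i}" for i in range(20)]
        # two identical pathways: identical p, identical padj, identical aes
        res = kf.enrich(uni[:5], {"pw1": uni[:10], "pw2": uni[:10]}, uni)
        assert res["p_value"].nunique() == 1 and res["padj"].nunique() == 1
        assert res["pathway_id"].tolist() == ["pw1", "pw2"]  # name tie-break

    def test_query_outside_universe_raises(self):
        with pytest.raises(ValueError, match="subset"):
            kf.enrich(["x"], {"pw": ["a"]}, ["a", "b"])

    def test_gmt_roundtrip(self, tmp_path):
        sets = {"pwA": ["g1", "g2"], "pwB": ["g2", "g3", "g4"]}
        path = tmp_path / "sets.gmt"
        kf.write_gmt(sets, path)
        assert kf.read_gmt(path) == sets
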
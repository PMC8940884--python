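import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio import TreeNode

from rhizoassembly import (
    CountTable,
    alpha_diversity,
    bray_curtis,
    group_tests,
    pcoa,
    rarefy,
    unweighted_unifrac,
    weighted_unifrac,
)
from rhizoassembly.diversity import DistanceMatrix


def _table(rows, taxa=None, samples=None):
    rows = np.atleast_2d(rows)
    taxa = taxa or [f"t{j}" for j in range(rows.shape[1])]
    samples = samples or [f"S{i}" for i in range(rows.shape[0])]
    return CountTable(samples, taxa, rows)


def _star_tree(taxa):
    return TreeNode.read(io.StringIO("(" + ",".join(f"{t}:1" for t in taxa) + ");"))


class TestAlpha:
    def test_richness_counts_present_taxa(self):
        rec = alpha_diversity(_table([[5, 0, 2, 1]]))[0]
        assert rec.observed_richness == 3

    def test_shannon_uniform_two_taxa(self):
        rec = alpha_diversity(_table([[10, 10]]))[0]
        assert rec.shannon == pytest.approx(np.log(2), abs=1e-12)

    def test_shannon_hand_value(self):
        # independent evaluation: p = (1/6, 1/3, 1/2)
        p = np.array([1 / 6, 1 / 3, 1 / 2])
        expected = float(-(p * np.log(p)).sum())
        rec = alpha_diversity(_table([[1, 2, 3]]))[0]
        assert rec.shannon == pytest.approx(expected, abs=1e-12)
        assert rec.shannon == pytest.approx(1.0114, abs=1e-4)

    def test_empty_sample(self):
        rec = alpha_diversity(_table([[0, 0]]))[0]
        assert rec.observed_richness == 0 and rec.shannon == 0.0


class TestRarefy:
    def test_identity_at_full_depth(self, tiny_table):
        depth = int(tiny_table.counts[0].sum())
        out = rarefy(tiny_table.select_samples(["S1"]), depth, seed=0)
        assert np.array_equal(out.counts, tiny_table.counts[:1])

    def test_rows_sum_to_depth_and_drops_shallow(self, small_study):
        table, _, _ = small_study
        out = rarefy(table, 800, seed=1)
        assert (out.counts.sum(axis=1) == 800).all()
        kept_ok = {
            s for s, tot in zip(table.sample_ids, table.counts.sum(axis=1))
            if tot >= 800
        }
        assert set(out.sample_ids) == kept_ok

    def test_expected_counts_hypergeometric(self):
        row = np.array([500, 300, 150, 50])
        table = _table([row])
        depth = 100
        draws = np.array(
            [rarefy(table, depth, seed=s).counts[0] for s in range(200)]
        )
        expected = depth * row / row.sum()
        assert np.all(np.abs(draws.mean(axis=0) - expected) / expected < 0.05)

    def test_richness_never_increases(self, tiny_table):
        out = rarefy(tiny_table, 3, seed=0)
        for sid in out.sample_ids:
            i, j = out.sample_ids.index(sid), tiny_table.sample_ids.index(sid)
            assert (out.counts[i] > 0).sum() <= (tiny_table.counts[j] > 0).sum()

    def test_invalid_depth(self, tiny_table):
        with pytest.raises(ValueError):
            rarefy(tiny_table, 0)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        dm = bray_curtis(_table([[3, 1, 0], [3, 1, 0], [0, 0, 7]]))
        assert dm.data[0, 1] == pytest.approx(0.0)
        assert dm.data[0, 2] == pytest.approx(1.0)

    def test_hand_value(self):
        dm = bray_curtis(_table([[6, 4], [2, 8]]))
        assert dm.data[0, 1] == pytest.approx(0.4, abs=1e-12)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="S1"):
            bray_curtis(_table([[1, 1], [0, 0]], samples=["S0", "S1"]))


class TestUniFrac:
    def test_unweighted_star_tree(self):
        tree = _star_tree(["t0", "t1", "t2"])
        dm = unweighted_unifrac(_table([[1, 1, 0], [0, 1, 1]]), tree)
        assert dm.data[0, 1] == pytest.approx(2 / 3)

    def test_unweighted_disjoint_clades(self):
        tree = TreeNode.read(io.StringIO("((t0:1,t1:1):1,(t2:1,t3:1):1);"))
        dm = unweighted_unifrac(_table([[1, 1, 0, 0], [0, 0, 1, 1]]), tree)
        assert dm.data[0, 1] == pytest.approx(1.0)

    def test_weighted_hand_values(self):
        tree = _star_tree(["t0", "t1"])
        dm = weighted_unifrac(_table([[10, 0], [5, 5]]), tree)
        assert dm.data[0, 1] == pytest.approx(0.5)
        dm2 = weighted_unifrac(_table([[10, 0], [0, 7]]), tree)
        assert dm2.data[0, 1] == pytest.approx(1.0)

    def test_identical_composition_zero(self):
        tree = _star_tree(["t0", "t1"])
        dm = weighted_unifrac(_table([[10, 30], [1, 3]]), tree)
        assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_missing_taxon_named(self):
        tree = _star_tree(["t0", "t1"])
        with pytest.raises(KeyError, match="t2"):
            unweighted_unifrac(_table([[1, 1, 1], [1, 0, 1]]), tree)

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_star_tree_jaccard_identity(self, data):
        """On a unit-branch star tree, unweighted UniFrac = 1 - Jaccard."""
        t = data.draw(st.integers(3, 8))
        a = data.draw(st.lists(st.booleans(), min_size=t, max_size=t))
        b = data.draw(st.lists(st.booleans(), min_size=t, max_size=t))
        if not (any(a) and any(b)):
            return
        tree = _star_tree([f"t{j}" for j in range(t)])
        table = _table(np.array([a, b], dtype=int))
        dm = unweighted_unifrac(table, tree)
        inter = sum(x and y for x, y in zip(a, b))
        union = sum(x or y for x, y in zip(a, b))
        assert dm.data[0, 1] == pytest.approx(1 - inter / union, abs=1e-12)


class TestPCoA:
    def test_collinear_reconstruction(self):
        pts = np.array([0.0, 3.0, 5.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        assert (res.eigenvalues > 1e-9).sum() == 1
        coords = res.coordinates[:, 0]
        recon = np.abs(coords[:, None] - coords[None, :])
        assert np.allclose(recon, d, atol=1e-9)

    def test_duplicated_sample_identical_coordinates(self):
        x = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        res = pcoa(DistanceMatrix(["a", "b", "b2"], x))
        assert np.allclose(res.coordinates[1], res.coordinates[2], atol=1e-9)

    def test_axis_scaling_convention(self, small_study):
        table, _, _ = small_study
        dm = bray_curtis(table.select_samples(table.sample_ids[:10]))
        res = pcoa(dm)
        assert np.sum(res.coordinates[:, 0] ** 2) == pytest.approx(
            res.eigenvalues[0], rel=1e-9
        )

    def test_euclidean_embeddable_no_negative_eigenvalues(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(8)], d))
        assert res.eigenvalues.min() > -1e-8

    def test_matches_skbio(self):
        import skbio

        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ours = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], d))
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        ref_e = np.sort(np.asarray(ref.eigvals))[::-1][:2]
        assert np.allclose(np.sort(ours.eigenvalues)[::-1][:2], ref_e, atol=1e-8)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(["a"], np.zeros((1, 1))))


class TestGroupTests:
    def _records(self, values):
        from rhizoassembly.diversity import AlphaDiversityRecord

        return [
            AlphaDiversityRecord(f"S{i}", int(v), float(v))
            for i, v in enumerate(values)
        ]

    def _metadata(self, groups):
        import pandas as pd
        from rhizoassembly.io_formats import SampleMetadata

        df = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(len(groups))],
                "plant": ["wheat"] * len(groups),
                "sample_type": groups,
                "replicate": list(range(1, len(groups) + 1)),
            }
        ).set_index("sample_id")
        return SampleMetadata(df)

    def test_separated_groups_exact_p(self):
        """(1,2,3) vs (10,11,12): exact two-sided rank-sum p = 2/C(6,3) = 0.1."""
        md = self._metadata(["soil"] * 3 + ["rhizosphere"] * 3)
        out = group_tests(self._records([1, 2, 3, 10, 11, 12]), md)
        assert out["pairwise"]["p"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_bh_adjustment_matches_hand_step_up(self):
        """Adjusted pairwise p-values equal a hand-applied BH step-up rule."""
        md = self._metadata(["soil"] * 3 + ["rhizosphere"] * 3 + ["rhizoplane"] * 3)
        out = group_tests(self._records([1, 5, 3, 4, 2, 6, 7, 8, 9]), md)
        p = out["pairwise"]["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty_like(p)
        expected[order] = np.minimum(stepped, 1.0)
        assert np.allclose(out["pairwise"]["p_adj"].to_numpy(), expected)

    def test_three_groups_reports_all_pairs(self):
        md = self._metadata(["soil"] * 3 + ["rhizosphere"] * 3 + ["rhizoplane"] * 3)
        out = group_tests(self._records([1, 2, 3, 4, 5, 6, 7, 8, 9]), md)
        assert len(out["pairwise"]) == 3
        assert out["kruskal_p"] < 0.1

    def test_single_group_rejected(self):
        md = self._metadata(["soil"] * 3)
        with pytest.raises(ValueError):
            group_tests(self._records([1, 2, 3]), md)
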
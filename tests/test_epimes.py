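"""Gene z-scoring, signature refinement, EPI-MES scoring and helpers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import cityblock

from calshape import (
    ExpressionSimSpec,
    cluster_correlation_matrix,
    ddct_quantitation,
    load_gene_lists,
    marker_correlations,
    refine_signature,
    score_and_stratify,
    simulate_expression,
    zscore_genes,
)
from calshape.epimes import QUINTILE_LABELS


@pytest.fixture(scope="module")
def sim_z():
    spec = ExpressionSimSpec(n_tumors=200, noise_sd=0.5, extra_genes=20, seed=11)
    matrix, latent = simulate_expression(spec)
    z = zscore_genes(matrix)
    return z, matrix, latent


class TestZscore:
    def test_hand_computed_example(self):
        z = zscore_genes(pd.DataFrame({"g": [1.0, 2.0, 3.0], "h": [1.0, 1.0, 2.0]}))
        np.testing.assert_allclose(z["g"], [-1.0, 0.0, 1.0])
        assert z["g"].iloc[2] - z["g"].iloc[0] == pytest.approx(2.0)
        # n-1 denominator: sd of {1,2,3} is 1, so z = {-1, 0, 1}

    def test_columns_standardised(self):
        rng = np.random.default_rng(0)
        z = zscore_genes(pd.DataFrame(rng.normal(5, 2, (40, 6)),
                                      columns=list("abcdef")))
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0)

    def test_constant_gene_dropped_with_warning(self):
        df = pd.DataFrame({"flat": [2.0, 2.0, 2.0], "ok": [1.0, 2.0, 4.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_genes(df)
        assert list(z.columns) == ["ok"]

    def test_missing_values_dropped_not_zeroed(self):
        df = pd.DataFrame({"na": [1.0, np.nan, 3.0], "ok": [1.0, 2.0, 4.0]})
        with pytest.warns(UserWarning, match="missing"):
            z = zscore_genes(df)
        assert list(z.columns) == ["ok"]


class TestRefineSignature:
    def test_perfectly_coexpressed_list_fully_retained(self):
        rng = np.random.default_rng(1)
        axis = rng.normal(size=50)
        z = zscore_genes(pd.DataFrame({f"g{i}": 2 + i * axis if i else 2 + axis
                                       for i in range(1, 5)}))
        assert refine_signature(z, [f"g{i}" for i in range(1, 5)]) == tuple(
            f"g{i}" for i in range(1, 5))

    def test_anticorrelated_member_dropped(self):
        rng = np.random.default_rng(2)
        axis = rng.normal(size=80)
        cols = {f"g{i}": axis + rng.normal(0, 0.1, 80) for i in range(4)}
        cols["bad"] = -axis + rng.normal(0, 0.1, 80)
        z = zscore_genes(pd.DataFrame(cols))
        kept = refine_signature(z, list(cols))
        assert "bad" not in kept and len(kept) == 4

    def test_matches_brute_force_thresholding(self, sim_z):
        z, _, _ = sim_z
        lists = load_gene_lists()
        kept = refine_signature(z, lists.epithelial)
        ref = z[list(lists.epithelial)].mean(axis=1)
        brute = tuple(g for g in lists.epithelial
                      if np.corrcoef(z[g], ref)[0, 1] > 0.5)
        assert kept == brute

    def test_order_invariance(self, sim_z):
        z, _, _ = sim_z
        lists = load_gene_lists()
        fwd = refine_signature(z, lists.mesenchymal)
        rev = refine_signature(z, lists.mesenchymal[::-1])
        assert set(fwd) == set(rev)

    def test_absent_genes_rejected(self, sim_z):
        z, _, _ = sim_z
        with pytest.raises(ValueError):
            refine_signature(z, ["NOT_A_GENE"])


class TestScoreAndStratify:
    def test_ten_increasing_scores_split_two_per_quintile(self):
        z = pd.DataFrame({"e": np.arange(10.0), "m": -np.arange(10.0)})
        z = zscore_genes(z)
        res = score_and_stratify(z, ["e"], ["m"])
        assert list(res.table["quintile"]) == [
            "H-MES", "H-MES", "L-MES", "L-MES", "Ambig", "Ambig",
            "L-EPI", "L-EPI", "H-EPI", "H-EPI"]

    def test_quintiles_balanced_and_monotone(self, sim_z):
        z, _, _ = sim_z
        lists = load_gene_lists()
        res = score_and_stratify(z, refine_signature(z, lists.epithelial),
                                 refine_signature(z, lists.mesenchymal))
        sizes = res.table["quintile"].value_counts()
        assert sizes.max() - sizes.min() <= 1
        by_label = res.table.groupby("quintile", observed=True)["score"]
        maxima = by_label.max().reindex(list(QUINTILE_LABELS))
        minima = by_label.min().reindex(list(QUINTILE_LABELS))
        assert np.all(maxima.to_numpy()[:-1] <= minima.to_numpy()[1:])

    def test_score_tracks_latent_axis(self, sim_z):
        z, _, latent = sim_z
        lists = load_gene_lists()
        res = score_and_stratify(z, refine_signature(z, lists.epithelial),
                                 refine_signature(z, lists.mesenchymal))
        rho = stats.spearmanr(res.table["score"], latent).statistic
        assert rho > 0.9

    def test_invariant_to_per_gene_affine_rescaling(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(8, 1, (30, 6)),
                            columns=["e1", "e2", "e3", "m1", "m2", "m3"])
        scaled = expr * np.array([2.0, 0.5, 7.0, 1.0, 3.0, 0.1]) + np.arange(6)
        r1 = score_and_stratify(zscore_genes(expr), ["e1", "e2", "e3"], ["m1", "m2", "m3"])
        r2 = score_and_stratify(zscore_genes(scaled), ["e1", "e2", "e3"], ["m1", "m2", "m3"])
        np.testing.assert_allclose(r1.table["score"], r2.table["score"], atol=1e-12)

    def test_too_few_tumors_rejected(self):
        z = pd.DataFrame({"e": [1.0, 2.0, 3.0], "m": [3.0, 2.0, 1.0]})
        with pytest.raises(ValueError, match="5 tumors"):
            score_and_stratify(zscore_genes(z), ["e"], ["m"])


class TestMarkerCorrelations:
    def test_target_against_itself(self, sim_z):
        _, matrix, _ = sim_z
        strata = pd.Series("all", index=matrix.index)
        out = marker_correlations(matrix, "VIM", ["VIM"], strata)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] < 1e-10

    def test_null_pairs_rarely_exceed_point_two(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 500
        for _ in range(reps):
            x, y = rng.normal(size=(2, 100))
            r, _ = stats.pearsonr(x, y)
            hits += abs(r) < 0.2
        assert hits / reps > 0.9  # ~95% expected under independence

    def test_correlation_decays_with_noise(self):
        rng = np.random.default_rng(6)
        target = rng.normal(size=300)
        rs = []
        for sd in (0.1, 1.0, 5.0):
            expr = pd.DataFrame({"t": target, "m": target + rng.normal(0, sd, 300)})
            strata = pd.Series("s", index=expr.index)
            rs.append(marker_correlations(expr, "t", ["m"], strata)["r"].iloc[0])
        assert rs[0] > rs[1] > rs[2]

    def test_small_stratum_marked_not_computable(self, sim_z):
        _, matrix, _ = sim_z
        strata = pd.Series("big", index=matrix.index)
        strata.iloc[:2] = "tiny"
        out = marker_correlations(matrix, "VIM", ["CDH1"], strata)
        tiny = out[out["stratum"] == "tiny"].iloc[0]
        assert not tiny["computable"] and np.isnan(tiny["r"])


class TestClusterCorrelationMatrix:
    def test_two_perfect_blocks_recovered(self):
        rng = np.random.default_rng(7)
        axis1, axis2 = rng.normal(size=(2, 60))
        cols = {f"a{i}": axis1 + rng.normal(0, 0.05, 60) for i in range(4)}
        cols |= {f"b{i}": axis2 + rng.normal(0, 0.05, 60) for i in range(4)}
        corr = pd.DataFrame(cols).corr()
        _, groups = cluster_correlation_matrix(corr, k=2)
        a = {groups[f"a{i}"] for i in range(4)}
        b = {groups[f"b{i}"] for i in range(4)}
        assert len(a) == 1 and len(b) == 1 and a != b

    def test_k_equal_to_gene_count_gives_singletons(self):
        rng = np.random.default_rng(8)
        corr = pd.DataFrame(rng.normal(size=(50, 5))).corr()
        _, groups = cluster_correlation_matrix(corr, k=5)
        assert groups.nunique() == 5

    def test_matches_brute_force_average_linkage(self):
        rng = np.random.default_rng(9)
        corr = pd.DataFrame(rng.normal(size=(80, 20))).corr()
        corr.index = corr.columns = [f"g{i}" for i in range(20)]
        _, groups = cluster_correlation_matrix(corr, k=4)
        brute = brute_force_average_linkage(corr.to_numpy(), 4)
        # same partition up to group relabelling
        ours = pd.Series(groups.to_numpy())
        theirs = pd.Series(brute)
        assert (ours.groupby(theirs).nunique() == 1).all()
        assert (theirs.groupby(ours).nunique() == 1).all()

    def test_oversized_k_rejected(self):
        corr = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            cluster_correlation_matrix(corr, k=4)


def brute_force_average_linkage(rows, k):
    """Agglomerative average linkage over Manhattan distances, step by step."""
    n = len(rows)
    clusters = {i: [i] for i in range(n)}
    dist = {(i, j): cityblock(rows[i], rows[j]) for i in range(n) for j in range(i + 1, n)}

    def avg(ci, cj):
        return float(np.mean([dist[tuple(sorted((a, b)))]
                              for a in clusters[ci] for b in clusters[cj]]))

    while len(clusters) > k:
        keys = sorted(clusters)
        best = min(((avg(a, b), a, b) for i, a in enumerate(keys) for b in keys[i + 1:]),
                   key=lambda x: x[0])
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(n, dtype=int)
    for g, members in enumerate(clusters.values()):
        labels[members] = g
    return labels


class TestDdct:
    @pytest.mark.parametrize("ddct,fold,percent", [(0.0, 1.0, 100.0),
                                                   (1.0, 0.5, 50.0),
                                                   (-2.0, 4.0, 400.0)])
    def test_comparative_ct_values(self, ddct, fold, percent):
        out = ddct_quantitation(ddct)
        assert out["fold_change"] == pytest.approx(fold)
        assert out["percent_remaining"] == pytest.approx(percent)
        assert out["relative_mrna"] == -ddct

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ddct_quantitation(np.nan)
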
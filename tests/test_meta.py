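"""Cross-layer integration: Venn partition, meta sets, profiles, clustering, PCA."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from arteryscope import (correlation_cluster, fc_profiles, meta_up_down,
                         pca_scores, profile_similarity, venn_partition,
                         venn_table)


def brute_force_regions(deg_sets):
    """Per-gene membership enumeration (independent of the set algebra)."""
    layers = list(deg_sets)
    regions = {}
    for r in range(1, len(layers) + 1):
        for combo in combinations(layers, r):
            regions[frozenset(combo)] = 0
    for gene in set().union(*deg_sets.values()):
        member = frozenset(l for l in layers if gene in deg_sets[l])
        regions[member] += 1
    return regions


def test_venn_disjoint_sets():
    sets = {"intima": {"a", "b"}, "media": {"c", "d", "e"},
            "adventitia": {"f", "g", "h", "i"}}
    regions = venn_partition(sets)
    assert regions[frozenset({"intima"})] == 2
    assert regions[frozenset({"media"})] == 3
    assert regions[frozenset({"adventitia"})] == 4
    assert all(v == 0 for k, v in regions.items() if len(k) > 1)
    assert sum(regions.values()) == 9


def test_venn_identical_sets():
    s = {f"g{i}" for i in range(7)}
    regions = venn_partition({"intima": set(s), "media": set(s), "adventitia": set(s)})
    assert regions[frozenset({"intima", "media", "adventitia"})] == 7
    assert sum(regions.values()) == 7


def test_venn_matches_brute_force_on_random_triples(rng):
    universe = [f"g{i}" for i in range(50)]
    for _ in range(50):
        sets = {
            layer: set(rng.choice(universe, size=rng.integers(0, 30), replace=False))
            for layer in ("intima", "media", "adventitia")
        }
        if not any(sets.values()):
            continue
        regions = venn_partition(sets)
        assert regions == brute_force_regions(sets)
        assert sum(regions.values()) == len(set().union(*sets.values()))


def test_venn_needs_two_layers():
    with pytest.raises(ValueError):
        venn_partition({"intima": {"a"}})


def test_venn_table_lists_members():
    t = venn_table({"intima": {"a", "b"}, "media": {"b"}})
    row = t[t["region"] == "intima&media"].iloc[0]
    assert row["count"] == 1 and row["genes"] == "b"


def _de_table(up=(), down=()):
    genes = sorted(set(up) | set(down))
    return pd.DataFrame(
        {"beta": [2.0 if g in up else -2.0 for g in genes],
         "p_adj": [1e-4] * len(genes),
         "deg": ["up" if g in up else "down" for g in genes],
         "model_used": ["ols_fallback"] * len(genes)},
        index=genes,
    )


def test_meta_up_down_rules():
    res = {
        "intima": _de_table(up=("a", "b"), down=("x",)),
        "media": _de_table(up=("b", "c"), down=("a",)),  # 'a' conflicts
    }
    up, down, conflict = meta_up_down(res)
    assert up == {"b", "c"}
    assert down == {"x"}
    assert conflict == {"a"}
    # partition property: disjoint, union = all layer DEGs
    assert not (up & down or up & conflict or down & conflict)
    assert up | down | conflict == {"a", "b", "c", "x"}


def test_profile_similarity_seed_scale_and_negation():
    profiles = pd.DataFrame(
        {"intima": [1.0, 2.0, -1.0, 0.5], "media": [2.0, 4.0, -2.0, 0.1],
         "adventitia": [3.0, 6.0, -3.0, 0.9], "PVAT": [4.0, 8.0, -4.0, 0.2]},
        index=["SEED", "SCALED", "NEGATED", "OTHER"],
    )
    out = profile_similarity(profiles, "SEED", min_r=0.95)
    assert list(out["gene"][:2]) == ["SCALED", "SEED"] or list(out["gene"][:2]) == ["SEED", "SCALED"]
    assert out.loc[out["gene"] == "SEED", "r"].iloc[0] == pytest.approx(1.0)
    assert out.loc[out["gene"] == "SCALED", "r"].iloc[0] == pytest.approx(1.0)
    assert "NEGATED" not in set(out["gene"])  # r = -1 excluded at min_r=0.95


def test_profile_similarity_scaling_invariance():
    rng = np.random.default_rng(3)
    profiles = pd.DataFrame(rng.normal(size=(20, 4)),
                            index=[f"g{i}" for i in range(20)],
                            columns=list("WXYZ"))
    out1 = profile_similarity(profiles, "g0", min_r=-1.1)
    out2 = profile_similarity(profiles * 3.7, "g0", min_r=-1.1)
    pd.testing.assert_frame_equal(out1, out2)


def test_profile_similarity_missing_seed_errors():
    profiles = pd.DataFrame({"intima": [1.0], "media": [1.0]}, index=["g"])
    with pytest.raises(KeyError):
        profile_similarity(profiles, "absent")


def test_profile_similarity_requires_enough_shared_layers():
    profiles = pd.DataFrame(
        {"intima": [1.0, 1.0], "media": [2.0, 2.0],
         "adventitia": [3.0, np.nan], "PVAT": [4.0, np.nan]},
        index=["SEED", "SPARSE"],
    )
    out = profile_similarity(profiles, "SEED", min_r=-1.1)
    assert "SPARSE" not in set(out["gene"])  # only 2 shared layers


def test_correlation_cluster_merges_identical_rois_first(rng):
    base = rng.gamma(2.0, 20.0, size=60)
    expr = pd.DataFrame(
        {"R1": base, "R2": base, "R3": rng.gamma(2.0, 20.0, size=60)})
    corr, linkage, order = correlation_cluster(expr)
    assert corr.loc["R1", "R2"] == pytest.approx(1.0)
    first_pair = set(linkage[0, :2].astype(int))
    assert first_pair == {0, 1}  # R1, R2 merge first
    assert np.allclose(corr.values, corr.values.T)
    assert np.allclose(np.diag(corr.values), 1.0)


def test_correlation_cluster_recovers_block_structure(rng):
    n_genes = 80
    group_effect = np.zeros(n_genes)
    group_effect[:40] = 3.0
    cols = {}
    labels = {}
    for i in range(6):
        in_group = i < 3
        mu = 5.0 + (group_effect if in_group else -group_effect)
        cols[f"R{i}"] = 2.0 ** (mu + rng.normal(0, 0.1, n_genes))
        labels[f"R{i}"] = int(in_group)
    expr = pd.DataFrame(cols)
    corr, linkage, order = correlation_cluster(expr)
    parts = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    sorted_rois = sorted(expr.columns)
    got = {roi: p for roi, p in zip(sorted_rois, parts)}
    groups = {0: set(), 1: set()}
    for roi, lab in labels.items():
        groups[lab].add(got[roi])
    assert len(groups[0]) == 1 and len(groups[1]) == 1 and groups[0] != groups[1]


def test_correlation_cluster_constant_roi_flagged_zero(rng):
    expr = pd.DataFrame(
        {"R1": rng.gamma(2, 10, 30), "R2": rng.gamma(2, 10, 30),
         "CONST": np.ones(30)})
    corr, _, _ = correlation_cluster(expr, log_transform=False)
    assert (corr.loc["CONST"].drop("CONST") == 0).all()
    assert corr.loc["CONST", "CONST"] == 1.0


def test_correlation_cluster_needs_three_rois():
    with pytest.raises(ValueError):
        correlation_cluster(pd.DataFrame({"A": [1.0, 2], "B": [2.0, 1]}))


def test_pca_rank_one_explains_everything():
    v = np.arange(1.0, 11.0)
    expr = pd.DataFrame({"A": v, "B": 2 * v, "C": 3 * v})
    _, explained = pca_scores(expr, log_transform=False)
    assert explained[0] == pytest.approx(1.0, abs=1e-9)


def test_pca_explained_variance_ordering_and_sign_determinism(rng):
    expr = pd.DataFrame(rng.gamma(2, 10, size=(50, 6)),
                        columns=[f"R{i}" for i in range(6)])
    scores1, explained = pca_scores(expr)
    scores2, _ = pca_scores(expr)
    pd.testing.assert_frame_equal(scores1, scores2)
    assert explained[0] >= explained[1] >= 0
    assert explained.sum() <= 1.0 + 1e-12


def test_pca_scores_preserve_pairwise_distances(rng):
    expr = pd.DataFrame(rng.gamma(2, 10, size=(40, 5)),
                        columns=[f"R{i}" for i in range(5)])
    scores, _ = pca_scores(expr, log_transform=False, n_components=5)
    x = expr.to_numpy().T
    x = x - x.mean(axis=0, keepdims=True)
    d_orig = squareform(pdist(x))
    d_pca = squareform(pdist(scores.to_numpy()))
    assert np.allclose(d_orig, d_pca, atol=1e-8)


def test_pca_needs_three_rois():
    with pytest.raises(ValueError):
        pca_scores(pd.DataFrame({"A": [1.0, 2], "B": [2.0, 1]}))


def test_fc_profiles_masks_untestable():
    t = _de_table(up=("a",))
    t.loc["a", "model_used"] = "untestable"
    profiles = fc_profiles({"intima": t})
    assert np.isnan(profiles.loc["a", "intima"])
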
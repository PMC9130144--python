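import numpy as np
import pytest

from rerepop import (
    HaplotypeAlignment,
    IslandModelParams,
    amova,
    collapse_haplotypes,
    haplotype_diversity,
    haplotype_sharing,
    nucleotide_diversity,
    pairwise_fst,
    simulate_island_model,
)
from rerepop.differentiation import genotype_distance_matrix, haplotype_distance_matrix
from conftest import make_dataset


# ---------------------------------------------------------------------------
# Pairwise F_ST
# ---------------------------------------------------------------------------

def test_theta_one_for_fixed_differences():
    rows = [[[1, 1], [5, 5]]] * 5 + [[[2, 2], [6, 6]]] * 5
    ds = make_dataset(rows, ["A"] * 5 + ["B"] * 5)
    res = pairwise_fst(ds, n_perm=49, seed=0)
    assert res.theta.loc["A", "B"] == pytest.approx(1.0)
    assert res.p.loc["A", "B"] < 0.05


def test_theta_symmetric_zero_diagonal(island_ds):
    ds, _ = island_ds
    res = pairwise_fst(ds, n_perm=19, seed=0)
    t = res.theta.to_numpy()
    np.testing.assert_allclose(t, t.T)
    np.testing.assert_allclose(np.diag(t), 0.0)


def test_theta_invariant_to_group_label_order(island_ds):
    ds, _ = island_ds
    res = pairwise_fst(ds, n_perm=0 + 9, seed=1)
    rev = pairwise_fst(
        ds, {p: [p] for p in reversed(ds.population_names)}, n_perm=9, seed=1
    )
    for a in ds.population_names:
        for b in ds.population_names:
            if a != b:
                assert res.theta.loc[a, b] == pytest.approx(rev.theta.loc[a, b])


def test_null_split_theta_near_zero_and_not_significant():
    rng = np.random.default_rng(0)
    inside = 0
    for seed in range(20):
        p = IslandModelParams(D=1, N=40, m=0.0, L=6, mu=1e-3, G=40,
                              missing_rate=0.0, seed=seed)
        ds, _ = simulate_island_model(p)
        labels = ["X"] * 20 + ["Y"] * 20
        rng.shuffle(labels)
        ds2 = make_dataset(ds.genotypes.tolist(), labels)
        res = pairwise_fst(ds2, n_perm=99, seed=seed)
        if res.p.loc["X", "Y"] > 0.05:
            inside += 1
    assert inside >= 18  # >= 90% of random splits non-significant


def test_singleton_group_reported_na():
    ds = make_dataset([[[1, 2]], [[1, 1]], [[2, 2]]], ["A", "B", "B"])
    res = pairwise_fst(ds, n_perm=9, seed=0)
    assert np.isnan(res.theta.loc["A", "B"])


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def brute_force_amova(d2, labels, group_of):
    """Independent recomputation: naive pair loops for SS, direct formulas."""
    pops = {}
    for i, l in enumerate(labels):
        pops.setdefault(l, []).append(i)
    pop_names = list(pops)
    groups = {}
    for p in pop_names:
        groups.setdefault(group_of[p], []).append(p)
    N, P, G = len(labels), len(pop_names), len(groups)

    def ss(idx):
        tot = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                tot += d2[idx[a], idx[b]]
        return tot / len(idx)

    ss_total = ss(list(range(N)))
    ss_wp = sum(ss(pops[p]) for p in pop_names)
    ss_wg = sum(ss([i for p in g for i in pops[p]]) for g in groups.values())
    ss_ap, ss_ag = ss_wg - ss_wp, ss_total - ss_wg
    gsz = {gn: sum(len(pops[p]) for p in g) for gn, g in groups.items()}
    sum_n2_over_g = sum(
        sum(len(pops[p]) ** 2 for p in g) / gsz[gn] for gn, g in groups.items()
    )
    sum_n2 = sum(len(pops[p]) ** 2 for p in pop_names)
    n1 = (N - sum_n2_over_g) / (P - G)
    n2 = (sum_n2_over_g - sum_n2 / N) / (G - 1)
    n3 = (N - sum(s**2 for s in gsz.values()) / N) / (G - 1)
    sc = ss_wp / (N - P)
    sb = (ss_ap / (P - G) - sc) / n1
    sa = (ss_ag / (G - 1) - sc - n2 * sb) / n3
    return {"among_groups": sa, "among_pops_within_groups": sb, "within_pops": sc}


def test_amova_matches_brute_force_on_toy_genotypes():
    rng = np.random.default_rng(3)
    g = np.sort(rng.integers(1, 5, size=(12, 3, 2)), axis=2)
    labels = ["p1"] * 3 + ["p2"] * 3 + ["p3"] * 3 + ["p4"] * 3
    ds = make_dataset(g.tolist(), labels)
    group_of = {"p1": "g1", "p2": "g1", "p3": "g2", "p4": "g2"}
    res = amova(ds, group_of, n_perm=20, seed=0, level="individual")
    oracle = brute_force_amova(genotype_distance_matrix(ds), labels, group_of)
    for k in oracle:
        assert res.sigma2[k] == pytest.approx(oracle[k], abs=1e-9)


def test_amova_matches_brute_force_on_haplotypes():
    rng = np.random.default_rng(5)
    seqs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(16)]
    strata = ["a"] * 4 + ["b"] * 4 + ["c"] * 4 + ["d"] * 4
    aln = HaplotypeAlignment([f"s{i}" for i in range(16)], seqs, strata)
    group_of = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
    res = amova(aln, group_of, n_perm=10, seed=0)
    oracle = brute_force_amova(haplotype_distance_matrix(aln), strata, group_of)
    for k in oracle:
        assert res.sigma2[k] == pytest.approx(oracle[k], abs=1e-9)
    assert sum(res.percent.values()) == pytest.approx(100.0)


def test_amova_all_identical_flagged():
    ds = make_dataset([[[1, 1]]] * 6, ["a"] * 3 + ["b"] * 3)
    with pytest.raises(ValueError, match="identical"):
        amova(ds, {"a": "g1", "b": "g2"}, n_perm=5, seed=0)


def test_amova_phi_st_tracks_theta_on_island_fixtures():
    """Gene-level Phi_ST and multilocus Weir-Cockerham theta agree closely
    on island-model data (mean difference within +/-0.05 over seeds)."""
    diffs = []
    for seed in range(20):
        p = IslandModelParams(D=4, N=15, m=0.01, L=6, mu=1e-3, G=60,
                              missing_rate=0.0, seed=seed)
        ds, _ = simulate_island_model(p)
        group_of = {f"deme{i+1}": "all" if i < 2 else "all2" for i in range(4)}
        res = amova(ds, group_of, n_perm=0 + 5, seed=seed)
        from rerepop.wc import multilocus_theta
        from rerepop.diversity import resolve_grouping

        theta = multilocus_theta(ds.genotypes, list(resolve_grouping(ds, None).values()))
        diffs.append(res.phi["phi_st"] - theta)
    assert abs(float(np.mean(diffs))) < 0.05


def test_increasing_migration_decreases_theta():
    means = []
    for m in (0.002, 0.02, 0.2):
        vals = []
        for seed in range(4):
            p = IslandModelParams(D=4, N=20, m=m, L=6, mu=1e-3, G=80,
                                  missing_rate=0.0, seed=seed)
            ds, _ = simulate_island_model(p)
            from rerepop.wc import multilocus_theta
            from rerepop.diversity import resolve_grouping

            vals.append(multilocus_theta(ds.genotypes, list(resolve_grouping(ds, None).values())))
        means.append(float(np.mean(vals)))
    assert means[0] > means[1] > means[2]


# ---------------------------------------------------------------------------
# mtDNA diversity
# ---------------------------------------------------------------------------

def test_haplotype_diversity_hand_cases():
    res = haplotype_diversity(np.array([3, 2, 1]))
    assert res["Hd"] == pytest.approx(1.2 * (1 - 14 / 36))
    assert res["Hd"] == pytest.approx(0.7333, abs=1e-4)
    assert haplotype_diversity(np.array([5]))["Hd"] == 0.0
    assert haplotype_diversity(np.array([1] * 7))["Hd"] == pytest.approx(1.0)
    assert haplotype_diversity(np.array([4]))["var"] == pytest.approx(0.0)
    with pytest.raises(ValueError):
        haplotype_diversity(np.array([1]))


def test_nucleotide_diversity_hand_cases():
    aln = HaplotypeAlignment(["a", "b"], ["AAAAAAAAAA", "AAAAAAAAAT"], ["w", "w"])
    assert nucleotide_diversity(aln) == pytest.approx(0.1)
    same = HaplotypeAlignment(["a", "b", "c"], ["ACGT"] * 3, ["w"] * 3)
    assert nucleotide_diversity(same) == 0.0


def test_nucleotide_diversity_pairwise_deletion_and_order_invariance():
    aln = HaplotypeAlignment(["a", "b", "c"], ["AANA", "AATA", "CCTA"], ["w"] * 3)
    pi = nucleotide_diversity(aln)
    perm = nucleotide_diversity(aln.subset([2, 0, 1]))
    assert pi == pytest.approx(perm)
    # a-b: 3 comparable sites, 0 diffs; a-c: 3 sites 2 diff; b-c: 4 sites 2 diff
    assert pi == pytest.approx((0 + 2 / 3 + 2 / 4) / 3)


def test_haplotype_sharing_classification(small_alignment):
    table = collapse_haplotypes(small_alignment)
    df = haplotype_sharing(table, ("wild", "captive"))
    assert (df[["wild", "captive"]].sum() == [4, 2]).all()
    statuses = set(df["status"])
    assert "shared" in statuses and "private_wild" in statuses
    disjoint = HaplotypeAlignment(["a", "b"], ["AAAA", "TTTT"], ["wild", "captive"])
    df2 = haplotype_sharing(collapse_haplotypes(disjoint), ("wild", "captive"))
    assert (df2["status"] != "shared").all()
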
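import numpy as np
import pytest

from rerepop import (
    IslandModelParams,
    allelic_richness,
    average_alleles_per_locus,
    by_fdr,
    expected_heterozygosity,
    fis,
    global_hwe,
    ld_all_pairs,
    ld_test,
    migrants_over_horizon,
    null_allele_estimate,
    observed_heterozygosity,
    private_allele_nm,
    simulate_island_model,
)
from conftest import make_dataset


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

def test_observed_heterozygosity_extremes():
    homs = make_dataset([[[1, 1], [2, 2]], [[3, 3], [2, 2]]], ["A", "A"])
    assert observed_heterozygosity(homs)["mean"].iloc[0] == 0.0
    hets = make_dataset([[[1, 2], [3, 4]], [[1, 3], [3, 5]]], ["A", "A"])
    assert observed_heterozygosity(hets)["mean"].iloc[0] == 1.0


def test_expected_heterozygosity_hand_case():
    # n=2, both A/B: 1 - 0.5 = 0.5, x 2n/(2n-1) = 4/3 -> 2/3
    ds = make_dataset([[[1, 2]], [[1, 2]]], ["A", "A"])
    assert expected_heterozygosity(ds)["mean"].iloc[0] == pytest.approx(2 / 3)
    mono = make_dataset([[[1, 1]], [[1, 1]]], ["A", "A"])
    assert expected_heterozygosity(mono)["mean"].iloc[0] == 0.0


def test_heterozygosity_invariant_to_allele_relabelling():
    ds = make_dataset([[[1, 2]], [[2, 3]], [[1, 1]]], ["A"] * 3)
    relab = make_dataset([[[101, 202]], [[202, 303]], [[101, 101]]], ["A"] * 3)
    for fn in (observed_heterozygosity, expected_heterozygosity):
        assert fn(ds)["mean"].iloc[0] == fn(relab)["mean"].iloc[0]


# ---------------------------------------------------------------------------
# Allelic richness
# ---------------------------------------------------------------------------

def test_allelic_richness_hand_case():
    # allele counts (6,2) among 2n=8 genes, g=2 -> 40/28
    ds = make_dataset(
        [[[1, 1]], [[1, 1]], [[1, 2]], [[1, 2]]], ["A"] * 4
    )
    ar = allelic_richness(ds, g=2)
    assert ar["L1"].iloc[0] == pytest.approx(40 / 28)


def test_allelic_richness_full_depth_equals_allele_count():
    ds = make_dataset([[[1, 2]], [[3, 3]], [[1, 4]]], ["A"] * 3)
    ar = allelic_richness(ds, g=6)
    assert ar["L1"].iloc[0] == pytest.approx(4.0)


def test_allelic_richness_monotone_in_g(island_ds):
    ds, _ = island_ds
    vals = [allelic_richness(ds, g=g)["mean"].mean() for g in (2, 4, 8, 12)]
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


def test_allelic_richness_g_too_large():
    ds = make_dataset([[[1, 2]]], ["A"])
    with pytest.raises(ValueError, match="exceeds"):
        allelic_richness(ds, g=4)


# ---------------------------------------------------------------------------
# Allele counts
# ---------------------------------------------------------------------------

def test_average_alleles_per_locus():
    ds = make_dataset(
        [[[1, 2], [5, 5]], [[3, 3], [5, 5]]], ["A", "A"]
    )
    an = average_alleles_per_locus(ds)
    assert an["anapl"].iloc[0] == pytest.approx(2.0)  # (3 + 1) / 2
    assert an["total_alleles"].iloc[0] == 4


def test_pooling_never_loses_alleles(island_ds):
    ds, _ = island_ds
    per_pop = average_alleles_per_locus(ds)["total_alleles"]
    pooled = average_alleles_per_locus(ds, {"all": ds.population_names})
    assert pooled["total_alleles"].iloc[0] >= per_pop.max()


# ---------------------------------------------------------------------------
# F_IS
# ---------------------------------------------------------------------------

def test_fis_complete_heterozygote_excess_is_minus_one():
    ds = make_dataset([[[1, 2]]] * 8, ["A"] * 8)
    res = fis(ds, n_perm=99, seed=0)
    assert res[0].f == pytest.approx(-1.0)


def test_fis_hwe_proportions_near_zero():
    # exact HWE proportions p=q=0.5: 1/4 AA, 1/2 AB, 1/4 BB
    rows = [[[1, 1]]] * 25 + [[[1, 2]]] * 50 + [[[2, 2]]] * 25
    ds = make_dataset(rows, ["A"] * 100)
    res = fis(ds, n_perm=49, seed=0)
    assert abs(res[0].f) < 0.02


def test_fis_single_individual_is_na():
    ds = make_dataset([[[1, 2]]], ["A"])
    res = fis(ds, n_perm=9, seed=0)
    assert np.isnan(res[0].f) and np.isnan(res[0].p_value)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def test_ld_duplicated_locus_maximal_dependence():
    rng = np.random.default_rng(0)
    g = rng.integers(1, 4, size=(30, 2))
    rows = [[list(r), list(r)] for r in np.sort(g, axis=1)]
    ds = make_dataset(rows, ["A"] * 30)
    p = ld_test(ds, "A", ("L1", "L2"), n_perm=199, seed=1)
    assert p == pytest.approx(1 / 200)


def test_ld_monomorphic_locus_undefined():
    ds = make_dataset([[[1, 1], [2, 3]], [[1, 1], [2, 2]]], ["A", "A"])
    assert np.isnan(ld_test(ds, "A", ("L1", "L2"), n_perm=9, seed=0))


def test_ld_all_pairs_shape(island_ds):
    ds, _ = island_ds
    df = ld_all_pairs(ds, "deme1", n_perm=19, seed=0)
    assert len(df) == ds.n_loci * (ds.n_loci - 1) // 2


# ---------------------------------------------------------------------------
# Null alleles
# ---------------------------------------------------------------------------

def test_null_allele_estimators():
    # Ho == He -> both estimators 0 (n>=15 but r<0.08 -> disregard)
    rows = [[[1, 1]]] * 4 + [[[1, 2]]] * 8 + [[[2, 2]]] * 4
    ds = make_dataset(rows, ["A"] * 16)
    est = null_allele_estimate(ds, "A", "L1")
    assert est["r_chakraborty"] == pytest.approx((est["He"] - est["Ho"]) / (est["He"] + est["Ho"]))
    assert est["r_brookfield"] == pytest.approx((est["He"] - est["Ho"]) / (1 + est["He"]))
    assert est["disregard"]  # tiny r


def test_null_allele_hand_values():
    # He=0.8, Ho=0.6 -> r_C = 0.2/1.4, r_B = 0.2/1.8 (checked via direct formula)
    he, ho = 0.8, 0.6
    assert (he - ho) / (he + ho) == pytest.approx(0.142857, abs=1e-6)
    assert (he - ho) / (1 + he) == pytest.approx(0.111111, abs=1e-6)


def test_null_allele_small_sample_disregarded():
    rows = [[[1, 1]]] * 8 + [[[1, 2]]] * 2
    ds = make_dataset(rows, ["A"] * 10)
    est = null_allele_estimate(ds, "A", "L1")
    assert est["n"] < 15 and est["disregard"]


# ---------------------------------------------------------------------------
# Private alleles / Nm
# ---------------------------------------------------------------------------

def test_no_private_alleles_flagged():
    rows = [[[1, 2]], [[1, 2]], [[1, 2]], [[1, 2]]]
    ds = make_dataset(rows, ["A", "A", "B", "B"])
    est = private_allele_nm(ds)
    assert not est.defined and np.isnan(est.nm_corrected)


def test_private_allele_regression_hand_check():
    """pbar(1)=0.065 at reference size 10 maps to ~1.79 migrants/generation
    under the log-linear calibration ln p(1) = -0.505 ln(Nm) - 2.44."""
    nm = np.exp((np.log(0.065) + 2.44) / -0.505)
    assert nm == pytest.approx(1.79, abs=0.02)


def test_private_allele_nm_monotone_in_migration():
    settings = [0.002, 0.02, 0.1]
    estimates = []
    for m in settings:
        vals = []
        for seed in range(4):
            p = IslandModelParams(
                D=4, N=25, m=m, L=6, mu=1e-3, G=80, missing_rate=0.0, seed=seed
            )
            ds, _ = simulate_island_model(p)
            est = private_allele_nm(ds)
            if est.defined:
                vals.append(est.nm_corrected)
        estimates.append(float(np.mean(vals)))
    assert estimates[0] < estimates[1] < estimates[2]


def test_migrants_over_horizon():
    res = migrants_over_horizon(1.79, 40, 200)
    assert res["exact"] == pytest.approx(8.95)
    assert res["rounded"] == 9
    assert migrants_over_horizon(0, 25, 100)["exact"] == 0
    assert migrants_over_horizon(2, 25, 100)["exact"] == pytest.approx(8.0)
    with pytest.raises(ValueError):
        migrants_over_horizon(1.0, 0, 100)
    with pytest.raises(ValueError):
        migrants_over_horizon(1.0, 25, -1)


# ---------------------------------------------------------------------------
# FDR / Fisher
# ---------------------------------------------------------------------------

def test_by_fdr_hand_case():
    adj = by_fdr(np.array([0.01, 0.02, 0.04]))
    np.testing.assert_allclose(adj, [0.055, 0.055, 0.0733333], atol=1e-6)


def test_by_fdr_identity_for_single_p():
    assert by_fdr(np.array([0.3]))[0] == pytest.approx(0.3)


def test_by_fdr_properties():
    rng = np.random.default_rng(1)
    p = rng.random(20)
    adj = by_fdr(p)
    assert (adj >= p - 1e-12).all() and (adj <= 1 + 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()
    with pytest.raises(ValueError):
        by_fdr(np.array([1.2]))


def test_by_fdr_no_more_discoveries_than_bh():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(2)
    for _ in range(20):
        p = rng.random(15) ** 2
        by = by_fdr(p) < 0.05
        bh = multipletests(p, method="fdr_bh")[1] < 0.05
        assert by.sum() <= bh.sum()


def test_global_hwe_fisher():
    res = global_hwe(np.array([0.05]))
    assert res["chi2"] == pytest.approx(5.991, abs=0.01)
    assert res["df"] == 2 and res["p"] == pytest.approx(0.05)
    res2 = global_hwe(np.array([0.1, 0.2]))
    assert res2["chi2"] == pytest.approx(7.824, abs=0.01)
    assert res2["df"] == 4
    res3 = global_hwe(np.array([0.5, 0.0]))
    assert np.isinf(res3["chi2"]) and res3["p"] == 0.0
    with pytest.raises(ValueError):
        global_hwe(np.array([]))


def test_captive_colony_shows_more_ld_than_source_deme():
    """Non-random mating from few founders leaves more locus pairs in
    linkage disequilibrium in the captive colony than in its source deme."""
    from rerepop import (
        CaptiveFounderParams,
        GenotypeDataset,
        sample_captive_founders,
        simulate_mtdna,
    )

    wins, n_seeds = 0, 10
    for seed in range(n_seeds):
        p = IslandModelParams(D=3, N=30, m=0.002, L=8, mu=5e-4, G=80,
                              missing_rate=0.0, seed=seed)
        ds, _ = simulate_island_model(p)
        aln = simulate_mtdna(p, seq_len=60, mt_mu=1e-3)
        cp = CaptiveFounderParams(
            founder_count=9, source_demes=["deme1", "deme2", "deme3"],
            offspring_count=60, n_females=3, skew=0.5, seed=seed + 50,
        )
        cap, _ = sample_captive_founders(ds, aln, cp)
        both = GenotypeDataset(
            ds.individuals + cap.individuals, ds.populations + cap.populations,
            ds.loci, np.concatenate([ds.genotypes, cap.genotypes]),
        )
        n_cap = (ld_all_pairs(both, "captive", n_perm=99, seed=seed)["p"] <= 0.05).sum()
        n_src = (ld_all_pairs(both, "deme1", n_perm=99, seed=seed)["p"] <= 0.05).sum()
        wins += int(n_cap > n_src)
    assert wins >= 0.8 * n_seeds
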
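"""Per-group diversity statistics, disequilibrium tests, null-allele
screening, the private-allele migrant estimate, and FDR control.

All statistics accept a *grouping*: ``None`` (group by population label), a
mapping of group name to a list of population labels (e.g. genetic clusters
or wild/captive strata), or an explicit per-individual label sequence.
Heterozygosities use Nei's unbiased estimator with the 2n/(2n-1) factor;
allelic richness uses hypergeometric rarefaction to a standard gene-sample
size g; F_IS is the Weir-Cockerham within-group f with significance from
permuting alleles among individuals within the group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import MISSING, GenotypeDataset
from .wc import component_sums, locus_allele_stats, multilocus_f

__all__ = [
    "resolve_grouping",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "allelic_richness",
    "average_alleles_per_locus",
    "FisResult",
    "fis",
    "ld_test",
    "ld_all_pairs",
    "null_allele_estimate",
    "NmEstimate",
    "private_allele_nm",
    "migrants_over_horizon",
    "by_fdr",
    "global_hwe",
]

Grouping = None | dict | list | tuple


def resolve_grouping(ds: GenotypeDataset, grouping: Grouping) -> dict[str, np.ndarray]:
    """Turn a grouping spec into an ordered ``{name: index array}`` mapping."""
    if grouping is None:
        return {p: ds.indices_of(p) for p in ds.population_names}
    if isinstance(grouping, dict):
        out = {}
        for name, pops in grouping.items():
            idx = ds.indices_of(pops)
            if len(idx) == 0:
                raise ValueError(f"group {name!r} matches no individuals")
            out[name] = idx
        return out
    labels = list(grouping)
    if len(labels) != ds.n_individuals:
        raise ValueError("per-individual grouping must have one label per individual")
    out: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        out.setdefault(str(lab), []).append(i)
    return {k: np.array(v, dtype=int) for k, v in out.items()}


def _locus_alleles(ds: GenotypeDataset, idx: np.ndarray, locus: int) -> np.ndarray:
    g = ds.genotypes[idx, locus, :]
    return g[(g != MISSING).all(axis=1)]


# ---------------------------------------------------------------------------
# Heterozygosity / richness / allele counts
# ---------------------------------------------------------------------------

def observed_heterozygosity(ds: GenotypeDataset, grouping: Grouping = None) -> pd.DataFrame:
    """Per-locus and mean observed heterozygosity (Ho) per group.

    Ho at a locus is the fraction of heterozygous genotypes among non-missing
    genotypes; loci with no data in a group are excluded from the mean.
    """
    rows = []
    for name, idx in resolve_grouping(ds, grouping).items():
        row: dict = {"group": name, "n": len(idx)}
        vals = []
        for l, locus in enumerate(ds.loci):
            g = _locus_alleles(ds, idx, l)
            if len(g) == 0:
                row[locus] = np.nan
                continue
            ho = float((g[:, 0] != g[:, 1]).mean())
            row[locus] = ho
            vals.append(ho)
        row["mean"] = float(np.mean(vals)) if vals else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def expected_heterozygosity(ds: GenotypeDataset, grouping: Grouping = None) -> pd.DataFrame:
    """Nei's unbiased expected heterozygosity He = (2n/(2n-1)) (1 - sum p^2)."""
    rows = []
    for name, idx in resolve_grouping(ds, grouping).items():
        row: dict = {"group": name, "n": len(idx)}
        vals = []
        for l, locus in enumerate(ds.loci):
            g = _locus_alleles(ds, idx, l)
            n = len(g)
            if n == 0 or 2 * n - 1 == 0:
                row[locus] = np.nan
                continue
            _, counts = np.unique(g.ravel(), return_counts=True)
            p = counts / (2 * n)
            he = (2 * n) / (2 * n - 1) * (1 - float((p**2).sum()))
            row[locus] = he
            vals.append(he)
        row["mean"] = float(np.mean(vals)) if vals else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def _rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected allele count in a random sample of g genes (El Mousadik-Petit)."""
    two_n = int(counts.sum())
    total = math.comb(two_n, g)
    return float(sum(1 - math.comb(two_n - int(c), g) / total for c in counts))


def allelic_richness(
    ds: GenotypeDataset, grouping: Grouping = None, g: int | None = None
) -> pd.DataFrame:
    """Rarefied allelic richness A_R(g) per group and locus.

    ``g`` defaults to twice the smallest genotyped sample over all groups and
    loci (so every table cell is defined); it must be an even number >= 2 and
    cannot exceed any group's gene count at any locus.
    """
    groups = resolve_grouping(ds, grouping)
    min_genes = min(
        2 * len(_locus_alleles(ds, idx, l))
        for idx in groups.values()
        for l in range(ds.n_loci)
    )
    if g is None:
        g = min_genes
    if g < 2 or g % 2:
        raise ValueError("rarefaction size g must be an even integer >= 2")
    rows = []
    for name, idx in groups.items():
        row: dict = {"group": name, "n": len(idx)}
        vals = []
        for l, locus in enumerate(ds.loci):
            garr = _locus_alleles(ds, idx, l)
            if 2 * len(garr) < g:
                raise ValueError(
                    f"g={g} exceeds gene count {2 * len(garr)} in group "
                    f"{name!r} at locus {locus!r}"
                )
            _, counts = np.unique(garr.ravel(), return_counts=True)
            ar = _rarefied_richness(counts, g)
            row[locus] = ar
            vals.append(ar)
        row["mean"] = float(np.mean(vals)) if vals else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def average_alleles_per_locus(ds: GenotypeDataset, grouping: Grouping = None) -> pd.DataFrame:
    """A_n (mean distinct alleles per locus) and total distinct alleles per group."""
    rows = []
    for name, idx in resolve_grouping(ds, grouping).items():
        counts = []
        for l in range(ds.n_loci):
            g = _locus_alleles(ds, idx, l)
            counts.append(len(np.unique(g.ravel())) if len(g) else 0)
        nonzero = [c for c in counts if c > 0]
        rows.append(
            {
                "group": name,
                "n": len(idx),
                "anapl": float(np.mean(nonzero)) if nonzero else np.nan,
                "total_alleles": int(sum(counts)),
            }
        )
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# F_IS
# ---------------------------------------------------------------------------

@dataclass
class FisResult:
    group: str
    n: int
    f: float
    per_locus: dict[str, float]
    p_value: float
    p_adjusted: float = np.nan


def _permuted_f(genotypes: np.ndarray, idx: np.ndarray, rng: np.random.Generator) -> float:
    """f after shuffling alleles among individuals within the group, per locus."""
    tb = tc = 0.0
    for l in range(genotypes.shape[1]):
        g = genotypes[idx, l, :]
        g = g[(g != MISSING).all(axis=1)]
        if len(g) < 2:
            continue
        flat = rng.permutation(g.ravel()).reshape(-1, 2)
        stats = locus_allele_stats(flat, [np.arange(len(flat))])
        if stats is None:
            continue
        _, b, c = component_sums(*stats)
        if not np.isnan(b):
            tb, tc = tb + b, tc + c
    return np.nan if tb + tc == 0 else 1 - tc / (tb + tc)


def fis(
    ds: GenotypeDataset,
    grouping: Grouping = None,
    n_perm: int = 10000,
    seed: int = 0,
) -> list[FisResult]:
    """Weir-Cockerham f per group with within-group allele-permutation p.

    The two-sided p-value is the fraction of permutations with |f| at least
    the observed |f| (+1 correction); p-values are BY-adjusted across groups.
    Groups where f is undefined (e.g. n=1) get NA.
    """
    rng = np.random.default_rng(seed)
    results = []
    for name, idx in resolve_grouping(ds, grouping).items():
        f_obs, per_locus = multilocus_f(ds.genotypes, idx)
        if np.isnan(f_obs) or len(idx) < 2:
            results.append(
                FisResult(name, len(idx), np.nan, dict(zip(ds.loci, per_locus)), np.nan)
            )
            continue
        exceed = 0
        for _ in range(n_perm):
            f_p = _permuted_f(ds.genotypes, idx, rng)
            if not np.isnan(f_p) and abs(f_p) >= abs(f_obs) - 1e-12:
                exceed += 1
        p = (exceed + 1) / (n_perm + 1)
        results.append(FisResult(name, len(idx), f_obs, dict(zip(ds.loci, per_locus)), p))
    defined = [r for r in results if not np.isnan(r.p_value)]
    if defined:
        adj = by_fdr(np.array([r.p_value for r in defined]))
        for r, a in zip(defined, adj):
            r.p_adjusted = float(a)
    return results


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def _g_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Log-likelihood-ratio G for a contingency table of two code vectors."""
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    obs = np.zeros((nx, ny))
    np.add.at(obs, (xi, yi), 1)
    n = obs.sum()
    exp = obs.sum(axis=1, keepdims=True) * obs.sum(axis=0, keepdims=True) / n
    mask = obs > 0
    return float(2 * (obs[mask] * np.log(obs[mask] / exp[mask])).sum())


def ld_test(
    ds: GenotypeDataset,
    group: str | np.ndarray,
    locus_pair: tuple[str, str],
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Genotypic linkage-disequilibrium permutation test for one locus pair.

    Builds the two-locus genotype contingency table within the group, takes
    the G statistic, and permutes one locus's genotypes across individuals;
    p = (#{G_perm >= G_obs} + 1) / (n_perm + 1).  Returns nan when either
    locus is monomorphic (or has < 2 joint genotypes) in the group.
    """
    idx = ds.indices_of(group) if isinstance(group, str) else np.asarray(group)
    l1, l2 = (ds.loci.index(l) for l in locus_pair)
    g1 = ds.genotypes[idx, l1, :]
    g2 = ds.genotypes[idx, l2, :]
    ok = (g1 != MISSING).all(axis=1) & (g2 != MISSING).all(axis=1)
    g1, g2 = g1[ok], g2[ok]
    if len(g1) < 2:
        return np.nan
    x = g1[:, 0] * 10000 + g1[:, 1]
    y = g2[:, 0] * 10000 + g2[:, 1]
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return np.nan
    rng = np.random.default_rng(seed)
    g_obs = _g_statistic(x, y)
    exceed = 0
    for _ in range(n_perm):
        if _g_statistic(x, rng.permutation(y)) >= g_obs - 1e-12:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


def ld_all_pairs(
    ds: GenotypeDataset,
    group: str | np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """LD test for every locus pair in a group, with BY-FDR adjustment."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(ds.n_loci):
        for j in range(i + 1, ds.n_loci):
            p = ld_test(
                ds, group, (ds.loci[i], ds.loci[j]), n_perm,
                seed=int(rng.integers(2**31)),
            )
            rows.append({"locus1": ds.loci[i], "locus2": ds.loci[j], "p": p})
    df = pd.DataFrame(rows)
    defined = df["p"].notna()
    df["p_adjusted"] = np.nan
    if defined.any():
        df.loc[defined, "p_adjusted"] = by_fdr(df.loc[defined, "p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Null alleles
# ---------------------------------------------------------------------------

def null_allele_estimate(ds: GenotypeDataset, group: str, locus: str) -> dict:
    """Closed-form null-allele frequency estimates with the disregard rule.

    r_C = (He-Ho)/(He+Ho) (Chakraborty) and r_B = (He-Ho)/(1+He)
    (Brookfield-1).  The estimate is flagged ``disregard`` when the group has
    fewer than 15 genotyped individuals or the larger estimate is below 8%.
    """
    idx = ds.indices_of(group)
    l = ds.loci.index(locus)
    g = _locus_alleles(ds, idx, l)
    n = len(g)
    ho = float((g[:, 0] != g[:, 1]).mean()) if n else np.nan
    if n:
        _, counts = np.unique(g.ravel(), return_counts=True)
        p = counts / (2 * n)
        he = (2 * n) / (2 * n - 1) * (1 - float((p**2).sum())) if 2 * n > 1 else np.nan
    else:
        he = np.nan
    r_c = np.nan if not n or (he + ho) == 0 else (he - ho) / (he + ho)
    r_b = np.nan if not n else (he - ho) / (1 + he)
    r_max = np.nanmax([r_c, r_b]) if n else np.nan
    disregard = bool(n < 15 or (not np.isnan(r_max) and r_max < 0.08))
    return {
        "group": group, "locus": locus, "n": n, "Ho": ho, "He": he,
        "r_chakraborty": r_c, "r_brookfield": r_b, "disregard": disregard,
    }


# ---------------------------------------------------------------------------
# Private-allele migrant estimate
# ---------------------------------------------------------------------------

# ln(pbar(1)) = a * ln(Nm) + b regressions at the reference sample sizes
# (Slatkin 1985 / Barton & Slatkin 1986 calibration, as used by Genepop).
_BS_COEFF = {10: (-0.505, -2.44), 25: (-0.576, -2.655), 50: (-0.612, -2.585)}


@dataclass
class NmEstimate:
    grouping_name: str
    p1_mean: float
    mean_sample_size: float
    nm_corrected: float
    nm_by_reference: dict[int, float] = field(default_factory=dict)
    private_counts: dict[str, int] = field(default_factory=dict)
    defined: bool = True


def private_allele_nm(
    ds: GenotypeDataset, grouping: Grouping = None, grouping_name: str = "groups"
) -> NmEstimate:
    """Number of migrants per generation from the private-allele method.

    A private allele occurs in exactly one group.  The mean frequency of
    private alleles in their home groups, pbar(1), is mapped to Nm via the
    Barton-Slatkin log-linear calibrations at reference sample sizes
    10/25/50; the size-corrected estimate interpolates linearly between the
    bracketing reference sizes at the observed mean sample size (nearest
    segment extrapolation outside [10, 50]).
    """
    groups = resolve_grouping(ds, grouping)
    if len(groups) < 2:
        raise ValueError("private-allele Nm needs >= 2 groups")
    p1: list[float] = []
    private_counts = {name: 0 for name in groups}
    sample_sizes = []
    for l in range(ds.n_loci):
        per_group = {}
        for name, idx in groups.items():
            g = _locus_alleles(ds, idx, l)
            sample_sizes.append(len(g))
            if len(g):
                alleles, counts = np.unique(g.ravel(), return_counts=True)
                per_group[name] = (alleles, counts, 2 * len(g))
        presence: dict[int, list[str]] = {}
        for name, (alleles, _, _) in per_group.items():
            for a in alleles:
                presence.setdefault(int(a), []).append(name)
        for a, names in presence.items():
            if len(names) == 1:
                home = names[0]
                alleles, counts, genes = per_group[home]
                freq = counts[np.where(alleles == a)[0][0]] / genes
                p1.append(float(freq))
                private_counts[home] += 1
    nbar = float(np.mean(sample_sizes))
    if not p1:
        return NmEstimate(grouping_name, np.nan, nbar, np.nan, {}, private_counts, False)
    p1_mean = float(np.mean(p1))
    by_ref = {
        size: float(np.exp((np.log(p1_mean) - b) / a))
        for size, (a, b) in _BS_COEFF.items()
    }
    refs = sorted(by_ref)
    if nbar <= refs[1]:
        lo, hi = refs[0], refs[1]
    else:
        lo, hi = refs[1], refs[2]
    slope = (by_ref[hi] - by_ref[lo]) / (hi - lo)
    nm = by_ref[lo] + slope * (nbar - lo)
    nm = max(nm, 0.0)
    return NmEstimate(grouping_name, p1_mean, nbar, float(nm), by_ref, private_counts)


def migrants_over_horizon(nm: float, gen_time: float, horizon: float) -> dict:
    """Expected migrant count over a time horizon: nm * horizon / gen_time."""
    if gen_time <= 0:
        raise ValueError("gen_time must be > 0")
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    exact = nm * horizon / gen_time
    return {"exact": exact, "rounded": int(round(exact))}


# ---------------------------------------------------------------------------
# FDR and Fisher combination
# ---------------------------------------------------------------------------

def by_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli step-up FDR adjustment (any-dependence valid)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_by")[1]


def global_hwe(p_values: np.ndarray) -> dict:
    """Fisher's combination chi2 = -2 sum(ln p), df = 2k, upper-tail p.

    A zero p-value (from a permutation/enumeration proxy) propagates as
    chi2 = infinity and combined p = 0.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no finite p-values to combine")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    df = 2 * p.size
    if (p == 0).any():
        return {"chi2": np.inf, "df": df, "p": 0.0}
    chi2 = float(-2 * np.log(p).sum())
    return {"chi2": chi2, "df": df, "p": float(sps.chi2.sf(chi2, df))}
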
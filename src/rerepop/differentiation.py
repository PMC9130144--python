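"""Pairwise F_ST with permutation significance, hierarchical AMOVA, and
mtDNA diversity summaries.

F_ST is the multilocus Weir-Cockerham theta; pair significance comes from
shuffling individuals between the two groups.  AMOVA partitions squared
inter-individual distances (site differences for haplotypes, allele
mismatches for genotypes) into among-group, among-population-within-group
and within-population components with Phi statistics and the standard
component-specific permutation schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset, HaplotypeAlignment, HaplotypeTable
from .diversity import Grouping, by_fdr, resolve_grouping
from .wc import multilocus_theta

__all__ = [
    "FstMatrix",
    "pairwise_fst",
    "AmovaResult",
    "amova",
    "genotype_distance_matrix",
    "haplotype_distance_matrix",
    "haplotype_diversity",
    "nucleotide_diversity",
    "haplotype_sharing",
]


# ---------------------------------------------------------------------------
# Pairwise F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstMatrix:
    groups: list[str]
    theta: pd.DataFrame
    p: pd.DataFrame
    p_adjusted: pd.DataFrame


def pairwise_fst(
    ds: GenotypeDataset,
    grouping: Grouping = None,
    n_perm: int = 10000,
    seed: int = 0,
) -> FstMatrix:
    """Pairwise multilocus Weir-Cockerham theta with permutation p-values.

    For each group pair, individuals are shuffled between the two groups
    ``n_perm`` times; p = (#{theta_perm >= theta_obs} + 1) / (n_perm + 1),
    then BY-FDR adjusted across all pairs.  Pairs involving a group with
    fewer than two individuals are reported NA.
    """
    groups = resolve_grouping(ds, grouping)
    names = list(groups)
    theta = pd.DataFrame(0.0, index=names, columns=names)
    pmat = pd.DataFrame(np.nan, index=names, columns=names)
    rng = np.random.default_rng(seed)
    raw: list[tuple[str, str, float]] = []
    for i, gi in enumerate(names):
        for j in range(i + 1, len(names)):
            gj = names[j]
            ia, ib = groups[gi], groups[gj]
            if len(ia) < 2 or len(ib) < 2:
                theta.loc[gi, gj] = theta.loc[gj, gi] = np.nan
                continue
            t_obs = multilocus_theta(ds.genotypes, [ia, ib])
            theta.loc[gi, gj] = theta.loc[gj, gi] = t_obs
            if np.isnan(t_obs):
                continue
            combined = np.concatenate([ia, ib])
            na = len(ia)
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(combined)
                t = multilocus_theta(ds.genotypes, [perm[:na], perm[na:]])
                if not np.isnan(t) and t >= t_obs - 1e-12:
                    exceed += 1
            raw.append((gi, gj, (exceed + 1) / (n_perm + 1)))
    for gi, gj, p in raw:
        pmat.loc[gi, gj] = pmat.loc[gj, gi] = p
    padj = pmat.copy()
    if raw:
        adj = by_fdr(np.array([p for _, _, p in raw]))
        for (gi, gj, _), a in zip(raw, adj):
            padj.loc[gi, gj] = padj.loc[gj, gi] = a
    return FstMatrix(names, theta, pmat, padj)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def genotype_distance_matrix(ds: GenotypeDataset) -> np.ndarray:
    """Allele-identity mismatch distance, summed over loci.

    Per locus each pair of diploid genotypes contributes 2 minus the number
    of alleles shared (counting multiplicity); missing-locus comparisons are
    skipped for that pair.
    """
    n = ds.n_individuals
    d = np.zeros((n, n))
    for l in range(ds.n_loci):
        g = ds.genotypes[:, l, :]
        ok = (g != MISSING).all(axis=1)
        a1, a2 = g[:, 0], g[:, 1]
        # shared alleles with multiplicity: best of the two pairings
        s_direct = (a1[:, None] == a1[None, :]).astype(np.int8) + (
            a2[:, None] == a2[None, :]
        )
        s_cross = (a1[:, None] == a2[None, :]).astype(np.int8) + (
            a2[:, None] == a1[None, :]
        )
        contrib = 2 - np.maximum(s_direct, s_cross)
        contrib[~ok, :] = 0
        contrib[:, ~ok] = 0
        d += contrib
    np.fill_diagonal(d, 0.0)
    return d


def haplotype_distance_matrix(aln: HaplotypeAlignment) -> np.ndarray:
    """Pairwise number of differing sites (N/gap sites excluded pairwise)."""
    x = aln.as_int_matrix()
    valid = x >= 0
    n = aln.n
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        diff = (x[i] != x) & both
        d[i] = diff.sum(axis=1)
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    levels: list[str]
    ss: dict[str, float]
    df: dict[str, int]
    sigma2: dict[str, float]
    percent: dict[str, float]
    percent_truncated: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ss": self.ss, "df": self.df, "sigma2": self.sigma2,
                "percent": self.percent, "percent_trunc": self.percent_truncated,
            }
        )


def _ss_within(d2: np.ndarray, idx: np.ndarray) -> float:
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2 * len(idx)))


def _amova_components(
    d2: np.ndarray, pops: list[np.ndarray], groups: list[list[int]]
) -> tuple[dict, dict, dict, dict]:
    """Variance components from squared distances for a two-level hierarchy.

    ``pops`` is a list of index arrays (one per population); ``groups`` lists
    population indices per group.
    """
    N = sum(len(p) for p in pops)
    P, G = len(pops), len(groups)
    all_idx = np.concatenate(pops)
    ss_total = _ss_within(d2, all_idx)
    ss_wp = sum(_ss_within(d2, p) for p in pops)
    ss_wg = sum(
        _ss_within(d2, np.concatenate([pops[pi] for pi in g])) for g in groups
    )
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    group_sizes = [sum(len(pops[pi]) for pi in g) for g in groups]
    sum_n2_over_g = sum(
        sum(len(pops[pi]) ** 2 for pi in g) / gs for g, gs in zip(groups, group_sizes)
    )
    sum_n2_all = sum(len(p) ** 2 for p in pops)
    n1 = (N - sum_n2_over_g) / df_ap if df_ap > 0 else np.nan
    n2 = (sum_n2_over_g - sum_n2_all / N) / df_ag if df_ag > 0 else np.nan
    n3 = (N - sum(gs**2 for gs in group_sizes) / N) / df_ag if df_ag > 0 else np.nan
    ms_wp = ss_wp / df_wp if df_wp > 0 else np.nan
    ms_ap = ss_ap / df_ap if df_ap > 0 else np.nan
    ms_ag = ss_ag / df_ag if df_ag > 0 else np.nan
    sig_c = ms_wp
    sig_b = (ms_ap - sig_c) / n1 if df_ap > 0 else np.nan
    sig_a = (ms_ag - sig_c - n2 * sig_b) / n3 if df_ag > 0 else np.nan
    ss = {"among_groups": ss_ag, "among_pops_within_groups": ss_ap, "within_pops": ss_wp}
    df = {"among_groups": df_ag, "among_pops_within_groups": df_ap, "within_pops": df_wp}
    sig = {"among_groups": sig_a, "among_pops_within_groups": sig_b, "within_pops": sig_c}
    tot = sig_a + sig_b + sig_c
    phi = {
        "phi_ct": sig_a / tot if tot else np.nan,
        "phi_sc": sig_b / (sig_b + sig_c) if (sig_b + sig_c) else np.nan,
        "phi_st": (sig_a + sig_b) / tot if tot else np.nan,
    }
    return ss, df, sig, phi


def _gene_level_components(
    genotypes: np.ndarray, pops: list[np.ndarray], groups: list[list[int]]
) -> tuple[dict, dict, dict]:
    """Locus-by-locus AMOVA on allele copies, components summed over loci.

    Treating the 2n gene copies as units with 0/1 allele-mismatch distance
    makes Phi_ST the direct F_ST analogue (the convention reference software
    applies to unphased multi-locus genotype data); sums of squares per set
    reduce to (n - sum c_a^2 / n) / 2 from the allele counts.
    """
    acc_ss = {"among_groups": 0.0, "among_pops_within_groups": 0.0, "within_pops": 0.0}
    acc_df = {"among_groups": 0, "among_pops_within_groups": 0, "within_pops": 0}
    acc_sig = {"among_groups": 0.0, "among_pops_within_groups": 0.0, "within_pops": 0.0}
    for l in range(genotypes.shape[1]):
        counts = []
        for idx in pops:
            g = genotypes[idx, l, :]
            g = g[(g != MISSING).all(axis=1)]
            counts.append(g.ravel())
        ngenes = np.array([len(c) for c in counts], dtype=float)
        if (ngenes < 1).any() or ngenes.sum() < 2:
            continue  # a locus absent from some population is skipped

        def ss(sets: list[np.ndarray]) -> float:
            arr = np.concatenate(sets)
            n = len(arr)
            _, c = np.unique(arr, return_counts=True)
            return float((n - (c**2).sum() / n) / 2)

        N, P, G = ngenes.sum(), len(pops), len(groups)
        ss_total = ss(counts)
        ss_wp = sum(ss([c]) for c in counts)
        ss_wg = sum(ss([counts[pi] for pi in g]) for g in groups)
        ss_ap, ss_ag = ss_wg - ss_wp, ss_total - ss_wg
        df_ag, df_ap, df_wp = G - 1, P - G, int(N) - P
        gsz = [sum(ngenes[pi] for pi in g) for g in groups]
        sum_n2_over_g = sum(
            sum(ngenes[pi] ** 2 for pi in g) / s for g, s in zip(groups, gsz)
        )
        sum_n2 = float((ngenes**2).sum())
        n1 = (N - sum_n2_over_g) / df_ap if df_ap > 0 else np.nan
        n2 = (sum_n2_over_g - sum_n2 / N) / df_ag
        n3 = (N - sum(s**2 for s in gsz) / N) / df_ag
        sc = ss_wp / df_wp
        sb = (ss_ap / df_ap - sc) / n1 if df_ap > 0 else 0.0
        sa = (ss_ag / df_ag - sc - n2 * sb) / n3
        for key, s, d, v in (
            ("among_groups", ss_ag, df_ag, sa),
            ("among_pops_within_groups", ss_ap, df_ap, sb),
            ("within_pops", ss_wp, df_wp, sc),
        ):
            acc_ss[key] += s
            acc_df[key] += d
            acc_sig[key] += v
    return acc_ss, acc_df, acc_sig


def _phi_from_sigma(sig: dict) -> dict:
    sig_a = sig["among_groups"]
    sig_b = sig["among_pops_within_groups"]
    sig_c = sig["within_pops"]
    tot = sig_a + sig_b + sig_c
    return {
        "phi_ct": sig_a / tot if tot else np.nan,
        "phi_sc": sig_b / (sig_b + sig_c) if (sig_b + sig_c) else np.nan,
        "phi_st": (sig_a + sig_b) / tot if tot else np.nan,
    }


def amova(
    data: GenotypeDataset | HaplotypeAlignment,
    group_of: dict[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    distance_matrix: np.ndarray | None = None,
    level: str = "gene",
) -> AmovaResult:
    """Two-level AMOVA (among groups / among populations within groups /
    within populations).

    ``group_of`` maps each population (or stratum) label to its group label.
    For genotype data ``level="gene"`` (default) decomposes variance over
    allele copies locus by locus, making Phi_ST the direct F_ST analogue;
    ``level="individual"`` partitions squared inter-individual
    allele-mismatch distances instead.  Haplotype data always use the
    pairwise site-difference distance.  Permutation p-values follow the
    component-specific schemes: individuals among populations within groups
    (Phi_SC), whole populations among groups (Phi_CT), and individuals among
    populations without regard to groups (Phi_ST).
    """
    gene_level = isinstance(data, GenotypeDataset) and level == "gene" and distance_matrix is None
    if isinstance(data, GenotypeDataset):
        labels = data.populations
        d2 = None
        if not gene_level:
            d2 = genotype_distance_matrix(data) if distance_matrix is None else distance_matrix
    else:
        labels = data.strata
        d2 = haplotype_distance_matrix(data) if distance_matrix is None else distance_matrix
    pop_names: list[str] = []
    for lab in labels:
        if lab not in pop_names:
            pop_names.append(lab)
    missing = [p for p in pop_names if p not in group_of]
    if missing:
        raise ValueError(f"populations without a group assignment: {missing}")
    pops = [np.array([i for i, l in enumerate(labels) if l == p]) for p in pop_names]
    group_names: list[str] = []
    for p in pop_names:
        if group_of[p] not in group_names:
            group_names.append(group_of[p])
    if len(group_names) < 2:
        raise ValueError("AMOVA needs >= 2 groups")
    groups = [
        [pi for pi, p in enumerate(pop_names) if group_of[p] == gname]
        for gname in group_names
    ]
    singleton = [group_names[gi] for gi, g in enumerate(groups)
                 if sum(len(pops[pi]) for pi in g) < 2]
    if singleton:
        raise ValueError(f"groups with a single individual: {singleton}")

    if gene_level:
        def components(pop_idx, grp):
            ss_, df_, sig_ = _gene_level_components(data.genotypes, pop_idx, grp)
            return ss_, df_, sig_, _phi_from_sigma(sig_)
        if sum(_gene_level_components(data.genotypes, pops, groups)[0].values()) == 0:
            raise ValueError("all individuals identical: AMOVA undefined (all SS = 0)")
    else:
        if d2.sum() == 0:
            raise ValueError("all individuals identical: AMOVA undefined (all SS = 0)")

        def components(pop_idx, grp):
            return _amova_components(d2, pop_idx, grp)

    ss, df, sig, phi = components(pops, groups)
    tot = sum(sig.values())
    percent = {k: 100 * v / tot for k, v in sig.items()}
    sig_t = {k: max(v, 0.0) for k, v in sig.items()}
    tot_t = sum(sig_t.values())
    percent_t = {k: (100 * v / tot_t if tot_t else np.nan) for k, v in sig_t.items()}

    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}
    pop_sizes = [len(p) for p in pops]
    all_idx = np.concatenate(pops)

    def split(perm: np.ndarray) -> list[np.ndarray]:
        out, pos = [], 0
        for s in pop_sizes:
            out.append(perm[pos : pos + s])
            pos += s
        return out

    # Phi_ST: individuals among populations, ignoring groups
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(all_idx)
        ph = components(split(perm), groups)[3]
        if ph["phi_st"] >= phi["phi_st"] - 1e-12:
            exceed += 1
    p_values["phi_st"] = (exceed + 1) / (n_perm + 1)

    # Phi_SC: individuals among populations within their group
    exceed = 0
    for _ in range(n_perm):
        new_pops: list[np.ndarray | None] = [None] * len(pops)
        for g in groups:
            gidx = np.concatenate([pops[pi] for pi in g])
            perm = rng.permutation(gidx)
            pos = 0
            for pi in g:
                new_pops[pi] = perm[pos : pos + len(pops[pi])]
                pos += len(pops[pi])
        ph = components(new_pops, groups)[3]  # type: ignore[arg-type]
        if not np.isnan(ph["phi_sc"]) and ph["phi_sc"] >= phi["phi_sc"] - 1e-12:
            exceed += 1
    p_values["phi_sc"] = (exceed + 1) / (n_perm + 1) if not np.isnan(phi["phi_sc"]) else np.nan

    # Phi_CT: whole populations among groups (keep group sizes in populations)
    exceed = 0
    sizes_per_group = [len(g) for g in groups]
    for _ in range(n_perm):
        perm = rng.permutation(len(pops))
        new_groups, pos = [], 0
        for s in sizes_per_group:
            new_groups.append(list(perm[pos : pos + s]))
            pos += s
        ph = components(pops, new_groups)[3]
        if not np.isnan(ph["phi_ct"]) and ph["phi_ct"] >= phi["phi_ct"] - 1e-12:
            exceed += 1
    p_values["phi_ct"] = (exceed + 1) / (n_perm + 1) if not np.isnan(phi["phi_ct"]) else np.nan

    return AmovaResult(
        ["among_groups", "among_pops_within_groups", "within_pops"],
        ss, df, sig, percent, percent_t, phi, p_values,
    )


# ---------------------------------------------------------------------------
# mtDNA diversity
# ---------------------------------------------------------------------------

def haplotype_diversity(counts: np.ndarray | HaplotypeTable, stratum: str | None = None) -> dict:
    """Nei's haplotype diversity with sampling variance.

    Hd = n/(n-1) (1 - sum x_i^2); Var is Nei's (1987) estimator
    2/(n(n-1)) { 2(n-2) [sum x^3 - (sum x^2)^2] + sum x^2 - (sum x^2)^2 }.
    """
    if isinstance(counts, HaplotypeTable):
        arr = counts.counts_for(stratum) if stratum else counts.counts.sum(axis=1).to_numpy()
    else:
        arr = np.asarray(counts, dtype=float)
    arr = arr[arr > 0]
    n = arr.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    x = arr / n
    s2 = float((x**2).sum())
    s3 = float((x**3).sum())
    hd = n / (n - 1) * (1 - s2)
    var = 2 / (n * (n - 1)) * (2 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return {"n": int(n), "k": len(arr), "Hd": float(hd), "var": float(var),
            "sd": float(np.sqrt(max(var, 0.0)))}


def nucleotide_diversity(aln: HaplotypeAlignment, stratum: str | None = None) -> float:
    """Mean per-site difference over unordered sequence pairs (pi).

    Sites with N/gap in either member of a pair are excluded for that pair;
    pairs with no comparable site are dropped.
    """
    idx = np.arange(aln.n) if stratum is None else aln.stratum_indices(stratum)
    if len(idx) < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    x = aln.as_int_matrix()[idx]
    valid = x >= 0
    vals = []
    for i in range(len(idx)):
        both = valid[i] & valid[i + 1 :]
        sites = both.sum(axis=1)
        diffs = ((x[i] != x[i + 1 :]) & both).sum(axis=1)
        ok = sites > 0
        vals.extend((diffs[ok] / sites[ok]).tolist())
    if not vals:
        raise ValueError("no comparable pairs")
    return float(np.mean(vals))


def haplotype_sharing(table: HaplotypeTable, strata: tuple[str, str]) -> pd.DataFrame:
    """Shared/private classification of haplotypes between two strata."""
    a, b = strata
    for s in strata:
        if s not in table.counts.columns:
            raise ValueError(f"stratum {s!r} not present")
    df = table.counts[[a, b]].copy()
    df["status"] = np.select(
        [(df[a] > 0) & (df[b] > 0), df[a] > 0, df[b] > 0],
        ["shared", f"private_{a}", f"private_{b}"],
        default="absent",
    )
    return df
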
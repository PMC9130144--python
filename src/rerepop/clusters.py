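"""Cluster-number estimation from replicate membership matrices.

Implements the second-difference log-likelihood statistic (Delta K), the
location-based MedMeaK/MaxMeaK/MedMedK/MaxMedK estimators that are robust to
uneven sampling, and the anti-bias subsampling protocol applied to genotype
data before Bayesian clustering (drop any-missing individuals, cap large
populations at a fixed size).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ClusterRunSet, GenotypeDataset

__all__ = ["subsample_for_structure", "evanno", "mmmm_estimators"]


def subsample_for_structure(
    ds: GenotypeDataset,
    cap: int = 30,
    drop_missing: bool = True,
    seed: int = 0,
) -> GenotypeDataset:
    """Remove any-missing individuals, then cap each population at ``cap``.

    Populations with at least ``cap`` complete individuals are reduced to
    exactly ``cap`` by uniform sampling without replacement; smaller ones are
    left untouched.  Order of retained individuals is preserved.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    keep = (
        np.where(~ds.missing_mask().any(axis=1))[0]
        if drop_missing
        else np.arange(ds.n_individuals)
    )
    chosen: list[int] = []
    for pop in ds.population_names:
        idx = [i for i in keep if ds.populations[i] == pop]
        if len(idx) >= cap:
            idx = sorted(rng.choice(idx, size=cap, replace=False).tolist())
        chosen.extend(idx)
    return ds.subset(sorted(chosen))


def evanno(runs: ClusterRunSet) -> pd.DataFrame:
    """Mean L(K), sd and Delta K per K.

    Delta K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)),
    defined only at interior K with >= 2 replicates at every K involved.
    A zero sd at an interior K yields an infinite Delta K.
    """
    ks = runs.k_values
    if len(ks) < 3:
        raise ValueError("Delta K needs >= 3 consecutive K values")
    means, sds, counts = {}, {}, {}
    for k in ks:
        ls = [r.log_likelihood for r in runs.runs_at(k)]
        if len(ls) < 2:
            raise ValueError(f"K={k}: >= 2 replicates required for sd(L)")
        means[k] = float(np.mean(ls))
        sds[k] = float(np.std(ls, ddof=1))
        counts[k] = len(ls)
    rows = []
    for k in ks:
        dk = np.nan
        if k - 1 in means and k + 1 in means:
            num = abs(means[k + 1] - 2 * means[k] + means[k - 1])
            dk = np.inf if sds[k] == 0 else num / sds[k]
        rows.append(
            {"K": k, "replicates": counts[k], "mean_L": means[k], "sd_L": sds[k],
             "delta_K": dk}
        )
    df = pd.DataFrame(rows).set_index("K")
    interior = df["delta_K"].dropna()
    df.attrs["best_K_delta"] = int(interior.idxmax()) if len(interior) else None
    df.attrs["best_K_meanL"] = int(df["mean_L"].idxmax())
    return df


def _represented_clusters(q: np.ndarray, loc_idx: list[np.ndarray], threshold: float,
                          use_median: bool) -> int:
    """Clusters for which some location's mean/median membership >= threshold."""
    stat = np.median if use_median else np.mean
    per_loc = np.array([stat(q[idx], axis=0) for idx in loc_idx])  # (locs, K)
    return int((per_loc.max(axis=0) >= threshold).sum())


def mmmm_estimators(
    runs: ClusterRunSet, threshold: float = 0.8
) -> pd.DataFrame:
    """MedMeaK / MaxMeaK / MedMedK / MaxMedK per analysed K.

    Per replicate run, a cluster counts as represented when at least one
    sampling location's mean (resp. median) membership in it reaches the
    threshold; the four estimators are the median/max across replicates of
    the mean- and median-based counts.  Medians over an even number of
    replicates are reported as-is with a rounded companion.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    loc_names: list[str] = []
    for l in runs.locations:
        if l not in loc_names:
            loc_names.append(l)
    loc_idx = [
        np.array([i for i, l in enumerate(runs.locations) if l == name])
        for name in loc_names
    ]
    rows = []
    for k in runs.k_values:
        mea, med = [], []
        for run in runs.runs_at(k):
            mea.append(_represented_clusters(run.membership, loc_idx, threshold, False))
            med.append(_represented_clusters(run.membership, loc_idx, threshold, True))
        rows.append(
            {
                "K": k,
                "replicates": len(mea),
                "MedMeaK": float(np.median(mea)),
                "MaxMeaK": int(np.max(mea)),
                "MedMedK": float(np.median(med)),
                "MaxMedK": int(np.max(med)),
                "MedMeaK_rounded": int(round(np.median(mea))),
                "MedMedK_rounded": int(round(np.median(med))),
                "threshold": threshold,
            }
        )
    return pd.DataFrame(rows).set_index("K")
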
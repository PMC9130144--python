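"""Weir & Cockerham variance components for multi-allelic co-dominant loci.

For each locus and allele the classical components are computed from per-group
allele frequencies ``p``, heterozygote-carrier frequencies ``h`` and sample
sizes ``n``:

    a  — among groups
    b  — among individuals within groups
    c  — within individuals (heterozygosity)

Multilocus estimators are ratios of sums over alleles and loci:
theta = sum(a) / sum(a+b+c), and the within-group inbreeding coefficient
f = 1 - sum(c) / sum(b+c).  With a single group the ``a`` and the
among-group terms vanish and only ``f`` is defined.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .io import MISSING

__all__ = ["locus_allele_stats", "component_sums", "multilocus_theta", "multilocus_f"]


def locus_allele_stats(
    geno_locus: np.ndarray, groups: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Per-group allele frequencies and heterozygote-carrier frequencies.

    ``geno_locus`` is the ``(n, 2)`` allele-pair array for one locus;
    ``groups`` a sequence of index arrays.  Returns ``(n_i, p, h)`` with
    ``p`` and ``h`` of shape ``(r, A)``, or None if no group has data.
    """
    per_group = []
    allele_set: set[int] = set()
    for idx in groups:
        g = geno_locus[idx]
        g = g[(g != MISSING).all(axis=1)]
        per_group.append(g)
        allele_set.update(np.unique(g).tolist())
    allele_set.discard(MISSING)
    if not allele_set:
        return None
    alleles = np.array(sorted(allele_set))
    A, r = len(alleles), len(groups)
    n = np.array([len(g) for g in per_group], dtype=float)
    p = np.zeros((r, A))
    h = np.zeros((r, A))
    for i, g in enumerate(per_group):
        if len(g) == 0:
            continue
        flat = np.searchsorted(alleles, g.ravel())
        p[i] = np.bincount(flat, minlength=A) / (2 * len(g))
        het = g[:, 0] != g[:, 1]
        if het.any():
            carriers = np.bincount(
                np.searchsorted(alleles, g[het].ravel()), minlength=A
            )
            h[i] = carriers / len(g)
    return n, p, h


def component_sums(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[float, float, float]:
    """Summed (over alleles) a, b, c components for one locus.

    Groups with no data are dropped; at least one group with n >= 2 and,
    for the among-group component, at least two non-empty groups are
    required — otherwise the undefined components are returned as nan.
    """
    keep = n > 0
    n, p, h = n[keep], p[keep], h[keep]
    r = len(n)
    if r == 0 or n.sum() < 2:
        return (np.nan, np.nan, np.nan)
    nbar = n.mean()
    pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
    hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
    c = hbar / 2
    if nbar <= 1:
        return (np.nan, np.nan, float(c.sum()))
    if r >= 2:
        nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
        s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        return (float(a.sum()), float(b.sum()), float(c.sum()))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (2 * nbar - 1) / (4 * nbar) * hbar)
    return (0.0, float(b.sum()), float(c.sum()))


def _sum_components(
    genotypes: np.ndarray, groups: Sequence[np.ndarray]
) -> tuple[float, float, float]:
    ta = tb = tc = 0.0
    for l in range(genotypes.shape[1]):
        stats = locus_allele_stats(genotypes[:, l, :], groups)
        if stats is None:
            continue
        a, b, c = component_sums(*stats)
        if np.isnan(a) or np.isnan(b) or np.isnan(c):
            continue
        ta, tb, tc = ta + a, tb + b, tc + c
    return ta, tb, tc


def multilocus_theta(genotypes: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """Multilocus Weir–Cockerham theta (F_ST) over >= 2 groups."""
    a, b, c = _sum_components(genotypes, groups)
    denom = a + b + c
    return np.nan if denom == 0 or np.isnan(denom) else a / denom


def multilocus_f(genotypes: np.ndarray, idx: np.ndarray) -> tuple[float, np.ndarray]:
    """Multilocus and per-locus Weir–Cockerham f (F_IS) within one group."""
    tb = tc = 0.0
    per_locus = np.full(genotypes.shape[1], np.nan)
    for l in range(genotypes.shape[1]):
        stats = locus_allele_stats(genotypes[:, l, :], [idx])
        if stats is None:
            continue
        _, b, c = component_sums(*stats)
        if np.isnan(b):
            continue
        if b + c > 0:
            per_locus[l] = 1 - c / (b + c)
        tb, tc = tb + b, tc + c
    f = np.nan if tb + tc == 0 else 1 - tc / (tb + tc)
    return f, per_locus
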
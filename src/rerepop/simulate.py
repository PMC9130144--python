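"""Forward-time synthetic data: island-model microsatellites, maternally
inherited haplotype sequences, and a captive colony founded from few wild
individuals.

The generator exists so the whole analysis chain can be exercised on data
whose truth is known.  It emulates a freshwater-turtle metapopulation:
several demes exchanging migrants under an island model, multi-allelic
stepwise-mutating microsatellite loci, a maternally inherited mtDNA locus
with finite-sites mutation, uniformly random missing genotypes, and a
captive colony bred from a handful of founders taken from a few source
demes, with Dirichlet-distributed reproductive skew among breeders.

Everything is driven by an explicit seed; the same parameters and seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import MISSING, GenotypeDataset, HaplotypeAlignment

__all__ = [
    "IslandModelParams",
    "CaptiveFounderParams",
    "simulate_island_model",
    "simulate_mtdna",
    "sample_captive_founders",
]

_BASES = "ACGT"


@dataclass
class IslandModelParams:
    """Parameters of the wild-metapopulation simulator.

    ``D`` demes of diploid size ``N`` (scalar or one size per deme) exchange
    migrants at per-generation probability ``m`` (an offspring's parents come
    from a uniformly chosen *other* deme with probability ``m``).  ``L``
    microsatellite loci mutate stepwise (+/-1 repeat) at rate ``mu`` per
    transmitted allele, reflecting at allele state 1.  ``missing_rate`` of
    sampled genotypes are masked uniformly at random.  The realised migrant
    number is recorded as ``Nm = N * m`` (per-deme immigrant count), the
    convention under which the island-model expectation FST ~ 1/(1+4Nm)
    applies.
    """

    D: int = 6
    N: int | Sequence[int] = 30
    m: float = 0.01
    L: int = 8
    mu: float = 5e-4
    G: int = 100
    missing_rate: float = 0.02
    seed: int = 0
    init_allele_low: int = 10
    init_allele_high: int = 30

    def deme_sizes(self) -> np.ndarray:
        sizes = (
            np.full(self.D, self.N, dtype=int)
            if np.isscalar(self.N)
            else np.asarray(self.N, dtype=int)
        )
        if sizes.shape != (self.D,):
            raise ValueError(f"need {self.D} deme sizes, got {sizes.shape}")
        return sizes

    def validate(self) -> None:
        if self.D < 1:
            raise ValueError("D must be >= 1")
        if self.D == 1 and self.m > 0:
            raise ValueError("single-deme model cannot have migration (m > 0)")
        if not (0.0 <= self.m <= 1.0):
            raise ValueError("m must be in [0, 1]")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must be in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if (self.deme_sizes() < 1).any():
            raise ValueError("deme sizes must be >= 1")


@dataclass
class CaptiveFounderParams:
    """Captive-colony founding scenario.

    ``founder_count`` wild individuals (of which ``n_females`` breed as
    females) are drawn without replacement from ``source_demes``; every
    offspring picks its mother and father from Dirichlet(``skew``)-weighted
    breeders, so small ``skew`` concentrates reproduction in few animals
    while large ``skew`` approaches uniform parental success.
    """

    founder_count: int = 9
    source_demes: Sequence[str] = field(default_factory=lambda: ["deme1", "deme2", "deme3"])
    offspring_count: int = 88
    skew: float = 1.0
    n_females: int = 3
    generations: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.founder_count < 2:
            raise ValueError("founder_count must be >= 2")
        if self.offspring_count < 1:
            raise ValueError("offspring_count must be >= 1")
        if self.skew <= 0:
            raise ValueError("skew must be > 0")
        if not (1 <= self.n_females < self.founder_count):
            raise ValueError("n_females must be in [1, founder_count)")
        if len(self.source_demes) < 1 or len(self.source_demes) > 3:
            raise ValueError("1-3 source demes required")


def _parent_demes(rng: np.random.Generator, deme: int, D: int, n: int, m: float) -> np.ndarray:
    """Source deme per offspring: own with prob 1-m, uniform other with m."""
    src = np.full(n, deme, dtype=int)
    if D > 1 and m > 0:
        mig = rng.random(n) < m
        k = int(mig.sum())
        if k:
            others = rng.integers(0, D - 1, size=k)
            others[others >= deme] += 1
            src[mig] = others
    return src


def simulate_island_model(
    p: IslandModelParams,
) -> tuple[GenotypeDataset, dict]:
    """Simulate the island model forward in time and sample the last generation.

    Returns the dataset (populations ``deme1..demeD``) and a truth record
    with the realised parameters, including ``Nm = mean(N) * m``.
    """
    p.validate()
    rng = np.random.default_rng(p.seed)
    sizes = p.deme_sizes()
    # state[d] : (N_d, L, 2) allele arrays
    state = [
        rng.integers(p.init_allele_low, p.init_allele_high + 1, size=(n, p.L, 2))
        for n in sizes
    ]
    for _ in range(p.G):
        new_state = []
        for d, n in enumerate(sizes):
            src = _parent_demes(rng, d, p.D, n, p.m)
            geno = np.empty((n, p.L, 2), dtype=np.int64)
            for s in np.unique(src):
                rows = np.where(src == s)[0]
                pool = state[s]
                parents = rng.integers(0, len(pool), size=(len(rows), 2))
                # one random allele per parent per locus
                picks = rng.integers(0, 2, size=(len(rows), p.L, 2))
                geno[rows, :, 0] = pool[parents[:, 0]][
                    np.arange(len(rows))[:, None], np.arange(p.L)[None, :], picks[:, :, 0]
                ]
                geno[rows, :, 1] = pool[parents[:, 1]][
                    np.arange(len(rows))[:, None], np.arange(p.L)[None, :], picks[:, :, 1]
                ]
            if p.mu > 0:
                hit = rng.random(geno.shape) < p.mu
                step = rng.choice([-1, 1], size=geno.shape)
                geno = np.where(hit, geno + step, geno)
                geno[geno < 1] = 2  # reflect at a floor of 1
            new_state.append(geno)
        state = new_state

    individuals, populations = [], []
    geno = np.concatenate(state, axis=0)
    for d, n in enumerate(sizes):
        individuals.extend(f"d{d + 1}_i{i + 1}" for i in range(n))
        populations.extend([f"deme{d + 1}"] * n)
    if p.missing_rate > 0:
        mask = rng.random((geno.shape[0], p.L)) < p.missing_rate
        geno[mask] = MISSING
    ds = GenotypeDataset(individuals, populations, [f"L{j + 1}" for j in range(p.L)], geno)
    truth = {
        "D": p.D,
        "N_mean": float(sizes.mean()),
        "m": p.m,
        "Nm": float(sizes.mean()) * p.m,
        "mu": p.mu,
        "G": p.G,
        "seed": p.seed,
    }
    return ds, truth


def simulate_mtdna(
    p: IslandModelParams,
    seq_len: int = 342,
    mt_mu: float = 1e-4,
    m_f: float | None = None,
) -> HaplotypeAlignment:
    """Simulate one maternally inherited sequence per individual.

    Each deme starts from its own random ancestral sequence; every
    generation each individual copies a uniformly chosen mother from its
    source deme (female migration at rate ``m_f``, defaulting to ``p.m``)
    and mutates each site with probability ``mt_mu`` to a different base.
    Individual IDs match :func:`simulate_island_model` run with the same
    params, so the two can be paired.
    """
    p.validate()
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    if m_f is None:
        m_f = p.m
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 915]))
    sizes = p.deme_sizes()
    state = [
        np.tile(rng.integers(0, 4, size=seq_len, dtype=np.int8), (n, 1)) for n in sizes
    ]
    for _ in range(p.G):
        new_state = []
        for d, n in enumerate(sizes):
            src = _parent_demes(rng, d, p.D, n, m_f)
            seqs = np.empty((n, seq_len), dtype=np.int8)
            for s in np.unique(src):
                rows = np.where(src == s)[0]
                mothers = rng.integers(0, len(state[s]), size=len(rows))
                seqs[rows] = state[s][mothers]
            if mt_mu > 0:
                hit = rng.random(seqs.shape) < mt_mu
                if hit.any():
                    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.int8)
                    seqs[hit] = (seqs[hit] + shift) % 4
            new_state.append(seqs)
        state = new_state
    ids, strata, seqs = [], [], []
    for d, n in enumerate(sizes):
        ids.extend(f"d{d + 1}_i{i + 1}" for i in range(n))
        strata.extend([f"deme{d + 1}"] * n)
        for row in state[d]:
            seqs.append("".join(_BASES[b] for b in row))
    return HaplotypeAlignment(ids, seqs, strata, "mtdna_sim")


def sample_captive_founders(
    ds: GenotypeDataset,
    aln: HaplotypeAlignment,
    p: CaptiveFounderParams,
    captive_label: str = "captive",
) -> tuple[GenotypeDataset, HaplotypeAlignment]:
    """Found a captive colony and breed offspring from it.

    Founders are drawn without replacement from the source demes of ``ds``
    (their mtDNA haplotypes looked up by ID in ``aln``).  Offspring
    genotypes are Mendelian draws from a Dirichlet-weighted mother and
    father; offspring mtDNA copies the mother's haplotype.  With
    ``generations > 1`` the offspring themselves breed (females keep their
    maternal line).
    """
    p.validate()
    rng = np.random.default_rng(p.seed)
    pool = ds.indices_of(list(p.source_demes))
    if len(pool) == 0:
        raise ValueError(f"source demes {list(p.source_demes)} not present in dataset")
    if p.founder_count > len(pool):
        raise ValueError(
            f"founder_count={p.founder_count} exceeds {len(pool)} available individuals"
        )
    founders = rng.choice(pool, size=p.founder_count, replace=False)
    hap_by_id = dict(zip(aln.ids, aln.sequences))
    for i in founders:
        if ds.individuals[i] not in hap_by_id:
            raise ValueError(f"founder {ds.individuals[i]} has no haplotype in alignment")

    females = founders[: p.n_females]
    males = founders[p.n_females :]
    mother_geno = ds.genotypes[females]  # (F, L, 2)
    father_geno = ds.genotypes[males]
    mother_hap = [hap_by_id[ds.individuals[i]] for i in females]

    L = ds.n_loci
    for _ in range(p.generations):
        wf = rng.dirichlet(np.full(len(mother_geno), p.skew))
        wm = rng.dirichlet(np.full(len(father_geno), p.skew))
        C = p.offspring_count
        mi = rng.choice(len(mother_geno), size=C, p=wf)
        fi = rng.choice(len(father_geno), size=C, p=wm)
        picks_m = rng.integers(0, 2, size=(C, L))
        picks_f = rng.integers(0, 2, size=(C, L))
        geno = np.empty((C, L, 2), dtype=np.int64)
        geno[:, :, 0] = mother_geno[mi][np.arange(C)[:, None], np.arange(L)[None, :], picks_m]
        geno[:, :, 1] = father_geno[fi][np.arange(C)[:, None], np.arange(L)[None, :], picks_f]
        haps = [mother_hap[i] for i in mi]
        # missing genotypes in a parent propagate as missing in the child
        half = (geno == MISSING).any(axis=2)
        geno[half] = MISSING
        if p.generations > 1:
            # next generation breeds among the offspring, split by sex at random
            sex = rng.random(C) < 0.5
            if sex.all() or not sex.any():
                sex[0], sex[-1] = True, False
            mother_geno, father_geno = geno[sex], geno[~sex]
            mother_hap = [h for h, s in zip(haps, sex) if s]

    ids = [f"cap_i{i + 1}" for i in range(p.offspring_count)]
    cap_ds = GenotypeDataset(ids, [captive_label] * len(ids), list(ds.loci), geno)
    cap_aln = HaplotypeAlignment(ids, haps, [captive_label] * len(ids), aln.marker_name)
    return cap_ds, cap_aln
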
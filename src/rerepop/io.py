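"""Data model and readers/writers for genotypes, sequences and cluster runs.

The in-memory containers are deliberately small dataclasses around numpy
arrays and plain lists:

* :class:`GenotypeDataset` — diploid multi-locus microsatellite genotypes
  with one population label per individual.  Allele codes are positive
  integers (fragment lengths / repeat counts); 0 marks a missing genotype.
* :class:`HaplotypeAlignment` — an aligned set of equal-length mtDNA
  sequences, one per individual, with a stratum label each.
* :class:`HaplotypeTable` — distinct haplotypes with counts per stratum.
* :class:`ClusterRunSet` — replicate cluster-membership (Q) matrices with
  per-run log-likelihoods across a range of K.

File formats: GenePop text for genotypes, FASTA for alignments (via
Bio.SeqIO), CSV for strata maps and membership matrices.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

MISSING = 0

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "HaplotypeAlignment",
    "HaplotypeTable",
    "ClusterRun",
    "ClusterRunSet",
    "GenePopError",
    "read_genepop",
    "write_genepop",
    "read_fasta_alignment",
    "collapse_haplotypes",
    "read_membership_runs",
    "write_membership_run",
]


class GenePopError(ValueError):
    """Raised when a GenePop file cannot be parsed or written."""


@dataclass
class GenotypeDataset:
    """Diploid multi-locus genotypes with population labels.

    ``genotypes`` has shape ``(n_individuals, n_loci, 2)``; each genotype is
    an unordered allele pair stored sorted so that ``a/b`` and ``b/a``
    compare equal.  ``0`` in both slots marks a missing genotype.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        if self.genotypes.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if len(self.populations) != len(self.individuals):
            raise ValueError("one population label required per individual")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicated individual IDs")
        if (self.genotypes < 0).any():
            raise ValueError("allele codes must be positive (0 = missing)")
        # normalise pair order; a half-missing genotype is treated as missing
        half = (self.genotypes == MISSING).any(axis=2) & (
            self.genotypes != MISSING
        ).any(axis=2)
        if half.any():
            self.genotypes[half] = MISSING
        self.genotypes = np.sort(self.genotypes, axis=2)

    # -- basic structure ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_names(self) -> list[str]:
        """Unique population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` mask, True where the genotype is missing."""
        return (self.genotypes == MISSING).all(axis=2)

    def indices_of(self, population: str | Sequence[str]) -> np.ndarray:
        names = {population} if isinstance(population, str) else set(population)
        return np.array(
            [i for i, p in enumerate(self.populations) if p in names], dtype=int
        )

    def subset(self, indices: Iterable[int]) -> "GenotypeDataset":
        idx = np.asarray(list(indices), dtype=int)
        return GenotypeDataset(
            [self.individuals[i] for i in idx],
            [self.populations[i] for i in idx],
            list(self.loci),
            self.genotypes[idx].copy(),
        )

    def relabel(self, mapping: dict[str, str]) -> "GenotypeDataset":
        """Return a copy with population labels mapped through ``mapping``."""
        return GenotypeDataset(
            list(self.individuals),
            [mapping.get(p, p) for p in self.populations],
            list(self.loci),
            self.genotypes.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class HaplotypeAlignment:
    """Aligned equal-length sequences with one stratum label each."""

    ids: list[str]
    sequences: list[str]
    strata: list[str]
    marker_name: str = "mtdna"

    _ALPHABET = set("ACGTN-")

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.sequences) == len(self.strata)):
            raise ValueError("ids, sequences and strata must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicated sequence IDs")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths {sorted(lengths)}: alignment required")
        for s in self.sequences:
            bad = set(s) - self._ALPHABET
            if bad:
                raise ValueError(f"invalid characters in sequence: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def subset(self, indices: Iterable[int]) -> "HaplotypeAlignment":
        idx = list(indices)
        return HaplotypeAlignment(
            [self.ids[i] for i in idx],
            [self.sequences[i] for i in idx],
            [self.strata[i] for i in idx],
            self.marker_name,
        )

    def stratum_indices(self, stratum: str | Sequence[str]) -> np.ndarray:
        names = {stratum} if isinstance(stratum, str) else set(stratum)
        return np.array([i for i, s in enumerate(self.strata) if s in names], dtype=int)

    def as_int_matrix(self) -> np.ndarray:
        """Encode as integers A,C,G,T -> 0..3, N/- -> -1 (shape n x L)."""
        lut = np.full(128, -1, dtype=np.int8)
        for i, b in enumerate("ACGT"):
            lut[ord(b)] = i
        arr = np.frombuffer("".join(self.sequences).encode(), dtype=np.uint8)
        return lut[arr].reshape(self.n, self.length)


@dataclass
class HaplotypeTable:
    """Distinct haplotype sequences with counts per stratum."""

    haplotypes: list[str]
    counts: pd.DataFrame  # index = haplotype label, columns = strata
    excluded: list[str] = field(default_factory=list)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def total_n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def counts_for(self, stratum: str) -> np.ndarray:
        return self.counts[stratum].to_numpy()


@dataclass
class ClusterRun:
    K: int
    replicate: int
    log_likelihood: float
    membership: np.ndarray  # (n_individuals, K), rows sum to 1


@dataclass
class ClusterRunSet:
    """Replicate membership matrices and log-likelihoods across K values."""

    individuals: list[str]
    locations: list[str]
    runs: list[ClusterRun]

    ROW_SUM_TOL = 1e-4

    def __post_init__(self) -> None:
        if len(self.locations) != len(self.individuals):
            raise ValueError("one location per individual required")
        n = len(self.individuals)
        for run in self.runs:
            q = np.asarray(run.membership, dtype=float)
            if q.shape != (n, run.K):
                raise ValueError(
                    f"run K={run.K} rep={run.replicate}: membership shape "
                    f"{q.shape} != ({n}, {run.K})"
                )
            dev = np.abs(q.sum(axis=1) - 1.0)
            if (dev > self.ROW_SUM_TOL).any():
                i = int(dev.argmax())
                raise ValueError(
                    f"run K={run.K} rep={run.replicate}: membership row "
                    f"{i} sums to {q[i].sum():.6f}, not 1"
                )
            run.membership = q / q.sum(axis=1, keepdims=True)

    @property
    def k_values(self) -> list[int]:
        return sorted({r.K for r in self.runs})

    def runs_at(self, K: int) -> list[ClusterRun]:
        return [r for r in self.runs if r.K == K]


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path: str | Path) -> GenotypeDataset:
    """Parse a GenePop file into a :class:`GenotypeDataset`.

    Both 2- and 3-digit allele codings are accepted (auto-detected from the
    width of the genotype fields); ``00``/``000`` encodes a missing allele.
    Population labels are ``pop1``, ``pop2``, ... in file order.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenePopError("file too short to be GenePop")
    # title line is free text; locus names follow until the first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        for name in lines[i].split(","):
            name = name.strip()
            if name:
                loci.append(name)
        i += 1
    if i == len(lines):
        raise GenePopError("no POP separator found")
    if not loci:
        raise GenePopError("no locus names before first POP")

    individuals: list[str] = []
    populations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    digit_width: int | None = None
    pop_index = 0
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if not line.strip():
            continue
        if _POP_RE.match(line):
            pop_index += 1
            continue
        if "," not in line:
            raise GenePopError(f"line {lineno + 1}: missing comma after individual ID")
        ind_id, _, geno_part = line.partition(",")
        ind_id = ind_id.strip()
        if not ind_id:
            raise GenePopError(f"line {lineno + 1}: empty individual ID")
        if ind_id in individuals:
            raise GenePopError(f"line {lineno + 1}: duplicated individual ID {ind_id!r}")
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise GenePopError(
                f"line {lineno + 1}: {len(fields)} genotype fields for "
                f"{len(loci)} loci"
            )
        row: list[tuple[int, int]] = []
        for f in fields:
            if not f.isdigit() or len(f) % 2 or len(f) not in (4, 6):
                raise GenePopError(
                    f"line {lineno + 1}: unknown allele-code width in field {f!r}"
                )
            w = len(f) // 2
            if digit_width is None:
                digit_width = w
            elif w != digit_width:
                raise GenePopError(
                    f"line {lineno + 1}: mixed allele-code widths ({w} vs {digit_width})"
                )
            a, b = int(f[:w]), int(f[w:])
            if a == 0 or b == 0:
                a = b = MISSING
            row.append((a, b))
        individuals.append(ind_id)
        populations.append(f"pop{pop_index}")
        rows.append(row)
    if not rows:
        raise GenePopError("no individuals found")
    geno = np.array(rows, dtype=np.int64)
    return GenotypeDataset(individuals, populations, loci, geno)


def write_genepop(
    ds: GenotypeDataset, path: str | Path, title: str = "rerepop export"
) -> Path:
    """Write a dataset as a GenePop file that :func:`read_genepop` round-trips.

    Digit width is 2 when every allele code is <= 99, else 3; codes over 999
    are rejected.
    """
    max_allele = int(ds.genotypes.max()) if ds.n_individuals else 0
    width = 2 if max_allele <= 99 else 3
    if max_allele > 10**width - 1:
        raise GenePopError(f"allele code {max_allele} exceeds 3-digit GenePop coding")
    pops = ds.population_names
    for p in pops:
        if len(ds.indices_of(p)) == 0:  # pragma: no cover - unreachable by construction
            raise GenePopError(f"population {p!r} has no individuals")
    if not pops:
        raise GenePopError("GenePop requires at least one individual per POP")
    out: list[str] = [title]
    out.extend(ds.loci)
    for p in pops:
        out.append("POP")
        for i in ds.indices_of(p):
            fields = [
                f"{a:0{width}d}{b:0{width}d}" for a, b in ds.genotypes[i]
            ]
            out.append(f"{ds.individuals[i]} , " + " ".join(fields))
    path = Path(path)
    path.write_text("\n".join(out) + "\n")
    return path


# ---------------------------------------------------------------------------
# FASTA / haplotypes
# ---------------------------------------------------------------------------

def read_fasta_alignment(
    path: str | Path,
    strata: pd.DataFrame | dict[str, str],
    marker_name: str = "mtdna",
) -> HaplotypeAlignment:
    """Read an aligned FASTA plus an id->stratum map.

    ``strata`` is either a mapping or a DataFrame with ``id`` and ``stratum``
    columns.  Sequences are uppercased; a header absent from the map or
    ragged sequence lengths raise ``ValueError``.
    """
    if isinstance(strata, pd.DataFrame):
        strata = dict(zip(strata["id"].astype(str), strata["stratum"].astype(str)))
    ids, seqs, labels = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id not in strata:
            raise ValueError(f"FASTA header {rec.id!r} absent from strata map")
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
        labels.append(strata[rec.id])
    if not ids:
        raise ValueError(f"no sequences in {path}")
    return HaplotypeAlignment(ids, seqs, labels, marker_name)


def collapse_haplotypes(aln: HaplotypeAlignment) -> HaplotypeTable:
    """Collapse an alignment into distinct haplotypes with per-stratum counts.

    A haplotype is a distinct fully-resolved sequence.  A sequence containing
    ``N`` or ``-`` is merged into an otherwise-identical resolved haplotype
    only when it matches exactly one of them at its resolved sites; otherwise
    it is excluded with a logged warning (ambiguity cannot be resolved
    deterministically).
    """
    if aln.n == 0:
        raise ValueError("empty alignment")
    strata_order: list[str] = []
    for s in aln.strata:
        if s not in strata_order:
            strata_order.append(s)

    resolved: dict[str, list[int]] = {}
    ambiguous: list[int] = []
    for i, seq in enumerate(aln.sequences):
        if "N" in seq or "-" in seq:
            ambiguous.append(i)
        else:
            resolved.setdefault(seq, []).append(i)
    haps = list(resolved)
    assignment: dict[int, int] = {}
    for h, members in enumerate(resolved.values()):
        for i in members:
            assignment[i] = h
    excluded: list[str] = []
    for i in ambiguous:
        seq = aln.sequences[i]
        sites = [k for k, c in enumerate(seq) if c not in "N-"]
        matches = [
            h for h, hap in enumerate(haps) if all(hap[k] == seq[k] for k in sites)
        ]
        if len(matches) == 1:
            assignment[i] = matches[0]
        else:
            excluded.append(aln.ids[i])
            logger.warning(
                "excluding ambiguous sequence %s (matches %d resolved haplotypes)",
                aln.ids[i],
                len(matches),
            )
    counts = pd.DataFrame(
        0, index=[f"H{h + 1}" for h in range(len(haps))], columns=strata_order
    )
    for i, h in assignment.items():
        counts.loc[f"H{h + 1}", aln.strata[i]] += 1
    return HaplotypeTable(haps, counts, excluded)


# ---------------------------------------------------------------------------
# Cluster membership runs
# ---------------------------------------------------------------------------

def write_membership_run(
    path: str | Path,
    K: int,
    replicate: int,
    log_likelihood: float,
    individuals: Sequence[str],
    locations: Sequence[str],
    membership: np.ndarray,
) -> Path:
    """Write one run as a CSV with ``#key=value`` metadata header lines."""
    path = Path(path)
    q = np.asarray(membership, dtype=float)
    df = pd.DataFrame(q, columns=[f"q{k + 1}" for k in range(K)])
    df.insert(0, "location", list(locations))
    df.insert(0, "id", list(individuals))
    with path.open("w") as fh:
        fh.write(f"#K={K}\n#replicate={replicate}\n#logL={log_likelihood!r}\n")
        df.to_csv(fh, index=False)
    return path


def read_membership_runs(paths: Iterable[str | Path]) -> ClusterRunSet:
    """Read run CSVs (as written by :func:`write_membership_run`).

    All runs must share the same individual set; membership rows deviating
    from sum 1 by more than 1e-4 are rejected.
    """
    runs: list[ClusterRun] = []
    individuals: list[str] | None = None
    locations: list[str] | None = None
    paths = sorted(Path(p) for p in paths)
    if not paths:
        raise ValueError("no run files given")
    for p in paths:
        meta: dict[str, str] = {}
        with p.open() as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key] = val
                    pos = fh.tell()
                else:
                    break
            fh.seek(pos)
            df = pd.read_csv(fh)
        for key in ("K", "replicate", "logL"):
            if key not in meta:
                raise ValueError(f"{p}: missing metadata record #{key}=")
        K = int(meta["K"])
        qcols = [f"q{k + 1}" for k in range(K)]
        if list(df.columns[:2]) != ["id", "location"] or list(df.columns[2:]) != qcols:
            raise ValueError(f"{p}: expected columns id, location, {', '.join(qcols)}")
        ids = df["id"].astype(str).tolist()
        locs = df["location"].astype(str).tolist()
        if individuals is None:
            individuals, locations = ids, locs
        elif ids != individuals:
            raise ValueError(f"{p}: individual set differs from previous runs")
        runs.append(
            ClusterRun(K, int(meta["replicate"]), float(meta["logL"]), df[qcols].to_numpy())
        )
    assert individuals is not None and locations is not None
    return ClusterRunSet(individuals, locations, runs)
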
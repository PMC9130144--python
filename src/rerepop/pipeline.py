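"""End-to-end analysis pipeline: simulate-or-load, filter, diversity and
differentiation statistics, K selection, captive representativeness, report.

Stages communicate through files (GenePop / FASTA / CSV) inside the output
directory so each stage is independently re-runnable and auditable.  Every
table carries the config hash and seed in a sidecar run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    GenotypeDataset,
    HaplotypeAlignment,
    collapse_haplotypes,
    read_fasta_alignment,
    read_genepop,
    write_genepop,
)
from .simulate import (
    CaptiveFounderParams,
    IslandModelParams,
    sample_captive_founders,
    simulate_island_model,
    simulate_mtdna,
)
from .diversity import (
    average_alleles_per_locus,
    expected_heterozygosity,
    fis,
    ld_all_pairs,
    observed_heterozygosity,
    private_allele_nm,
)
from .differentiation import (
    amova,
    haplotype_diversity,
    nucleotide_diversity,
    pairwise_fst,
)
from .hwe import hwe_table
from .represent import bootstrap_distribution, representativeness_report

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Exactly one of ``genepop_path`` (+ optional ``fasta_path``/``strata_csv``)
    or ``simulate`` must be given.  ``wild_populations``/``captive_population``
    name the strata used for the representativeness stage.
    """

    out_dir: str = "rerepop_out"
    seed: int = 0
    genepop_path: str | None = None
    fasta_path: str | None = None
    strata_csv: str | None = None
    simulate: dict | None = None
    n_perm_fst: int = 1000
    n_perm_ld: int = 200
    n_perm_fis: int = 200
    n_perm_amova: int = 200
    bootstrap_S: int = 100
    captive_population: str = "captive"
    rarefaction_g: int | None = None
    stages: list[str] = field(
        default_factory=lambda: [
            "sumstats", "hwe", "ld", "nm", "fst", "amova", "mtdiv", "represent",
        ]
    )

    def validate(self) -> None:
        has_input = self.genepop_path is not None
        has_sim = self.simulate is not None
        if has_input == has_sim:
            raise ValueError("exactly one of genepop_path or simulate must be set")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_inputs(cfg: PipelineConfig, out: Path):
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        cap_cfg = sim.pop("captive", None)
        mt_cfg = sim.pop("mtdna", {})
        p = IslandModelParams(**sim, seed=cfg.seed)
        ds, truth = simulate_island_model(p)
        aln = simulate_mtdna(p, **mt_cfg)
        if cap_cfg is not None:
            cp = CaptiveFounderParams(**cap_cfg, seed=cfg.seed + 1)
            cap_ds, cap_aln = sample_captive_founders(ds, aln, cp, cfg.captive_population)
            ds = GenotypeDataset(
                ds.individuals + cap_ds.individuals,
                ds.populations + cap_ds.populations,
                ds.loci,
                np.concatenate([ds.genotypes, cap_ds.genotypes]),
            )
            aln = HaplotypeAlignment(
                aln.ids + cap_aln.ids,
                aln.sequences + cap_aln.sequences,
                aln.strata + cap_aln.strata,
                aln.marker_name,
            )
        write_genepop(ds, out / "genotypes.gen")
        with (out / "mtdna.fasta").open("w") as fh:
            for i, s in zip(aln.ids, aln.sequences):
                fh.write(f">{i}\n{s}\n")
        pd.DataFrame({"id": aln.ids, "stratum": aln.strata}).to_csv(
            out / "strata.csv", index=False
        )
        pd.DataFrame([truth]).to_csv(out / "truth.csv", index=False)
        # population labels are lost in GenePop round-trip; keep the originals
        return ds, aln
    ds = read_genepop(cfg.genepop_path)
    aln = None
    if cfg.fasta_path:
        if not cfg.strata_csv:
            raise ValueError("fasta_path requires strata_csv")
        aln = read_fasta_alignment(cfg.fasta_path, pd.read_csv(cfg.strata_csv))
    return ds, aln


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all configured stages; returns the output directory.

    Deterministic for a fixed config and seed.  A failing stage is logged
    and skipped without corrupting the outputs of other stages.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"rerepop {__version__}", f"config_hash={cfg.hash()}", f"seed={cfg.seed}",
    ]
    rng = np.random.default_rng(cfg.seed)
    ds, aln = _load_inputs(cfg, out)
    wild_pops = [p for p in ds.population_names if p != cfg.captive_population]
    has_captive = cfg.captive_population in ds.population_names

    def stage(name: str, fn) -> None:
        if name not in cfg.stages:
            return
        t0 = time.perf_counter()
        try:
            fn()
            log_lines.append(f"stage={name} ok wall={time.perf_counter() - t0:.2f}s")
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            log_lines.append(f"stage={name} FAILED: {exc}")
            logger.exception("stage %s failed", name)

    def do_sumstats() -> None:
        ho = observed_heterozygosity(ds)
        he = expected_heterozygosity(ds)
        an = average_alleles_per_locus(ds)
        fres = fis(ds, n_perm=cfg.n_perm_fis, seed=int(rng.integers(2**31)))
        summary = pd.DataFrame(
            {
                "n": ho["n"], "Ho": ho["mean"], "He": he["mean"],
                "ANAPL": an["anapl"], "total_alleles": an["total_alleles"],
                "Fis": [r.f for r in fres], "Fis_p": [r.p_value for r in fres],
                "Fis_p_adj": [r.p_adjusted for r in fres],
            }
        )
        summary.to_csv(out / "sumstats.csv")

    def do_hwe() -> None:
        hwe_table(ds, seed=int(rng.integers(2**31))).to_csv(out / "hwe.csv", index=False)

    def do_ld() -> None:
        frames = []
        for pop in ds.population_names:
            if len(ds.indices_of(pop)) < 4:
                continue
            df = ld_all_pairs(ds, pop, n_perm=cfg.n_perm_ld, seed=int(rng.integers(2**31)))
            df.insert(0, "group", pop)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(out / "ld.csv", index=False)

    def do_nm() -> None:
        est = private_allele_nm(ds, grouping_name="populations")
        pd.DataFrame(
            [
                {
                    "grouping": est.grouping_name, "p1_mean": est.p1_mean,
                    "mean_sample_size": est.mean_sample_size,
                    "nm_corrected": est.nm_corrected, "defined": est.defined,
                    **{f"nm_ref{k}": v for k, v in est.nm_by_reference.items()},
                }
            ]
        ).to_csv(out / "nm.csv", index=False)

    def do_fst() -> None:
        res = pairwise_fst(ds, n_perm=cfg.n_perm_fst, seed=int(rng.integers(2**31)))
        res.theta.to_csv(out / "fst_theta.csv")
        res.p_adjusted.to_csv(out / "fst_p_adjusted.csv")

    def do_amova() -> None:
        # demes as populations nested in wild/captive groups
        group_of = {
            p: ("captive" if p == cfg.captive_population else "wild")
            for p in ds.population_names
        }
        if len(set(group_of.values())) < 2:
            group_of = {p: p for p in ds.population_names}  # flat: each pop its own group
        res = amova(ds, group_of, n_perm=cfg.n_perm_amova, seed=int(rng.integers(2**31)))
        tbl = res.table()
        tbl["phi"] = pd.Series(
            {
                "among_groups": res.phi["phi_ct"],
                "among_pops_within_groups": res.phi["phi_sc"],
                "within_pops": res.phi["phi_st"],
            }
        )
        tbl["p"] = pd.Series(
            {
                "among_groups": res.p_values.get("phi_ct", np.nan),
                "among_pops_within_groups": res.p_values.get("phi_sc", np.nan),
                "within_pops": res.p_values.get("phi_st", np.nan),
            }
        )
        tbl.to_csv(out / "amova.csv")

    def do_mtdiv() -> None:
        if aln is None:
            raise ValueError("no mtDNA alignment available")
        table = collapse_haplotypes(aln)
        rows = []
        for stratum in table.counts.columns:
            counts = table.counts_for(stratum)
            if counts.sum() < 2:
                continue
            hd = haplotype_diversity(counts)
            rows.append(
                {
                    "stratum": stratum, **hd,
                    "pi": nucleotide_diversity(aln, stratum),
                }
            )
        pd.DataFrame(rows).to_csv(out / "mtdiv.csv", index=False)

    def do_represent() -> None:
        if not has_captive:
            raise ValueError(f"no {cfg.captive_population!r} population present")
        wild_idx = ds.indices_of(wild_pops)
        cap_idx = ds.indices_of(cfg.captive_population)
        wild_ds, cap_ds = ds.subset(wild_idx), ds.subset(cap_idx)
        dists = []
        m = cap_ds.n_individuals
        from .represent import GENOTYPE_STATS, SEQUENCE_STATS

        for stat, fn in GENOTYPE_STATS.items():
            dists.append(
                bootstrap_distribution(
                    wild_ds, m, stat, fn(cap_ds), S=cfg.bootstrap_S,
                    seed=int(rng.integers(2**31)),
                )
            )
        if aln is not None:
            w_aln = aln.subset(aln.stratum_indices(wild_pops))
            c_aln = aln.subset(aln.stratum_indices(cfg.captive_population))
            if c_aln.n >= 2:
                for stat, fn in SEQUENCE_STATS.items():
                    dists.append(
                        bootstrap_distribution(
                            w_aln, c_aln.n, stat, fn(c_aln), S=cfg.bootstrap_S,
                            seed=int(rng.integers(2**31)),
                        )
                    )
        df, summary = representativeness_report(dists)
        df.to_csv(out / "representativeness.csv", index=False)
        log_lines.append(f"representativeness: {summary}")
        pd.DataFrame(
            {d.statistic: d.values for d in dists}
        ).to_csv(out / "bootstrap_replicates.csv", index=False)

    stage("sumstats", do_sumstats)
    stage("hwe", do_hwe)
    stage("ld", do_ld)
    stage("nm", do_nm)
    stage("fst", do_fst)
    stage("amova", do_amova)
    stage("mtdiv", do_mtdiv)
    stage("represent", do_represent)

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
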
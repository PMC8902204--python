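"""Configuration, seeding and the end-to-end scenario grid driver.

A run simulates, per replicate, one base population lineage (historical
population -> divergent pure lines -> reciprocal F1 -> reciprocal F2), then
for every heritability rescales the same raw QTL effects and draws
phenotypes, and for every reference-population size samples an RP from F2
generations 5-6, runs the mixed-model scan and scores QTL detection. Sharing
the lineage across heritabilities reduces Monte-Carlo variance in grid
comparisons.

Seeding: the master seed is split into named substreams per replicate and
stage (map, hp, trait, lines, f1, f2, artifacts, pheno, rp), so changing one
stage's settings does not perturb the draws of any other stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .assoc import MixedModelGWAS
from .detection import (DetectionReport, manhattan_table,
                        match_significant_to_qtl, summarize_grid)
from .forward_sim import (BreedingPhase, HistoricalPhase, Population,
                          advance_generation, censor_pedigree,
                          cross_populations, sample_reference_population,
                          select_founders, simulate_historical)
from .genome import (GenomeMap, MutationModel, build_genome_map,
                     default_chrom_lengths)
from .quantgen import (GenotypingArtifacts, apply_genotyping_artifacts,
                       compute_tbv, filter_segregating_loci,
                       sample_qtl_effects, scale_to_h2, simulate_phenotypes)

__all__ = [
    "SimConfig", "ConfigError", "PROFILES", "load_config", "save_config",
    "substream", "simulate_lineage", "Lineage", "run_scenario_grid",
    "export_dataset",
]

log = logging.getLogger("f2qtl")


class ConfigError(ValueError):
    pass


def substream(master_seed: int, *tags) -> np.random.Generator:
    """Independent, named random substream of a master seed."""
    key = [int(master_seed) & 0x7FFFFFFF]
    key += [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(key))


@dataclass
class SimConfig:
    """Resolved run configuration (defaults = the "paper" profile, i.e. the
    full Table-1-scale design)."""

    profile: str = "paper"
    seed: int = 1
    replicates: int = 1
    out_dir: str | None = None

    # genome
    n_chromosomes: int = 18
    total_length_cM: float = 2729.4
    n_markers: int = 33802
    n_qtl: int = 35
    marker_mutation_rate: float = 2.5e-4
    qtl_mutation_rate: float = 2.5e-5
    marker_maf: float = 0.1
    qtl_maf: float = 0.01

    # historical population
    hp_phase1_generations: int = 1000
    hp_phase1_size: int = 10000
    hp_phase2_generations: int = 1050
    hp_phase2_end_size: int = 8000

    # bred phases
    line_males: int = 60
    line_females: int = 600
    line_generations: int = 20
    f1_males: int = 30
    f1_females: int = 300
    f1_generations: int = 5
    f2_males: int = 15
    f2_females: int = 150
    f2_generations: int = 6
    offspring_per_dam: int = 10
    replacement_ratio: float = 1.0
    missing_parent_rate: float = 0.05

    # trait + artifacts
    h2_levels: tuple = (0.1, 0.3, 0.5)
    vp: float = 1.0
    gamma_shape: float = 0.4
    missing_rate: float = 0.05
    error_rate: float = 0.005

    # analysis
    rp_sizes: tuple = (100, 500, 1000)
    rp_generations: tuple = (5, 6)
    alpha: float = 0.05
    window_cM: float = 2.5
    scan_maf: float = 0.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        def check(cond, key):
            if not cond:
                raise ConfigError(f"invalid value for '{key}': {getattr(self, key)!r}")
        check(self.n_chromosomes >= 1, "n_chromosomes")
        check(self.total_length_cM > 0, "total_length_cM")
        check(self.n_markers >= self.n_chromosomes, "n_markers")
        check(self.n_qtl >= 1, "n_qtl")
        for k in ("marker_mutation_rate", "qtl_mutation_rate"):
            check(0 <= getattr(self, k) <= 1e-2, k)
        for k in ("marker_maf", "qtl_maf"):
            check(0 <= getattr(self, k) <= 0.5, k)
        for k in ("hp_phase1_generations", "hp_phase1_size", "hp_phase2_generations",
                  "hp_phase2_end_size", "line_males", "line_females", "line_generations",
                  "f1_males", "f1_females", "f1_generations", "f2_males", "f2_females",
                  "f2_generations", "offspring_per_dam", "replicates"):
            check(int(getattr(self, k)) >= 0, k)
        for k in ("missing_rate", "error_rate", "missing_parent_rate",
                  "replacement_ratio"):
            check(0 <= getattr(self, k) <= 1, k)
        for h2 in self.h2_levels:
            check(0 < h2 < 1, "h2_levels")
        check(self.vp > 0, "vp")
        check(self.gamma_shape > 0, "gamma_shape")
        check(0 < self.alpha < 1, "alpha")
        check(self.window_cM > 0, "window_cM")
        for n in self.rp_sizes:
            check(int(n) > 0, "rp_sizes")

    # -- derived pieces ------------------------------------------------------
    def mutation_model(self) -> MutationModel:
        return MutationModel(self.marker_mutation_rate, self.qtl_mutation_rate)

    def historical_phases(self) -> list[HistoricalPhase]:
        return [HistoricalPhase(self.hp_phase1_generations, self.hp_phase1_size),
                HistoricalPhase(self.hp_phase2_generations, self.hp_phase2_end_size,
                                ramp=True)]

    def artifacts(self) -> GenotypingArtifacts:
        return GenotypingArtifacts(self.missing_rate, self.error_rate)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["h2_levels"] = list(self.h2_levels)
        d["rp_sizes"] = list(self.rp_sizes)
        d["rp_generations"] = list(self.rp_generations)
        return d


def _profile_overrides(name: str) -> dict:
    if name == "paper":
        return {}
    if name == "desk":
        # documented scale-down of the historical phase; the F2/RP design of
        # the full-scale run is preserved exactly
        return dict(
            n_markers=10000,
            hp_phase1_generations=150, hp_phase1_size=1000,
            hp_phase2_generations=100, hp_phase2_end_size=800,
            line_males=12, line_females=120, line_generations=10,
            f1_males=10, f1_females=100, f1_generations=3,
        )
    if name == "mini":
        # test-scale profile: small enough for replicated grids on one CPU,
        # with the F2/RP structure still identical to the full design
        return dict(
            n_markers=5000,
            hp_phase1_generations=50, hp_phase1_size=500,
            hp_phase2_generations=30, hp_phase2_end_size=400,
            line_males=8, line_females=80, line_generations=8,
            f1_males=10, f1_females=100, f1_generations=3,
        )
    raise ConfigError(f"invalid value for 'profile': {name!r}")


PROFILES = ("paper", "desk", "mini")


def make_config(profile: str = "paper", **overrides) -> SimConfig:
    base = _profile_overrides(profile)
    base["profile"] = profile
    base.update(overrides)
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(base) - fields
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    return SimConfig(**base)


def load_config(path) -> SimConfig:
    """Load a YAML config: a flat mapping of SimConfig keys (all optional)
    plus ``profile``; unknown keys are rejected by name."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(p.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    for k in ("h2_levels", "rp_sizes", "rp_generations"):
        if k in raw:
            raw[k] = tuple(raw[k])
    profile = raw.pop("profile", "paper")
    return make_config(profile, **raw)


def save_config(cfg: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


# -- lineage simulation ------------------------------------------------------

@dataclass
class Lineage:
    """Everything one replicate's base simulation produces."""

    genome_full: GenomeMap          # all loci, pre-filter panel
    genome: GenomeMap               # panel restricted to segregating loci
    trait_raw: object               # unscaled TraitArchitecture
    hp_final: Population
    line1: Population
    line2: Population
    f1a: Population
    f1b: Population
    f2_founders: Population         # union of the two selected F2 parent sets
    f2_gen1: Population             # pooled first F2 generation (h2 scaling cohort)
    f2_cohorts: dict                # {("a"|"b", generation): Population}
    filter_report: object


def _breed_line(founders: Population, phase: BreedingPhase, genome, mut, trait,
                rng, label: str) -> Population:
    pop = founders
    for g in range(phase.n_generations):
        cohort = advance_generation(pop, phase, genome, mut, trait, rng,
                                    generation=g + 1, label=label)
        if g + 1 < phase.n_generations:
            pop = select_founders(cohort, phase.n_males, phase.n_females,
                                  phase.selection, rng)
        else:
            pop = cohort
    return pop


def simulate_lineage(cfg: SimConfig, replicate: int = 0) -> Lineage:
    """Simulate one full base-population lineage for a replicate."""
    seed = cfg.seed
    mut = cfg.mutation_model()

    rng_map = substream(seed, "map", replicate)
    lengths = (default_chrom_lengths(cfg.total_length_cM)
               if cfg.n_chromosomes == 18 else None)
    genome_full = build_genome_map(cfg.n_chromosomes, lengths,
                                   cfg.n_markers, cfg.n_qtl, rng_map)
    log.info("replicate %d: genome %d markers / %d QTLs", replicate,
             genome_full.n_markers, genome_full.n_qtl)

    rng_hp = substream(seed, "hp", replicate)
    hp = simulate_historical(genome_full, mut, cfg.historical_phases(), rng_hp)

    genome, report = filter_segregating_loci(hp, genome_full,
                                             cfg.marker_maf, cfg.qtl_maf)
    log.info("replicate %d: panel %d/%d markers, %d/%d QTLs after MAF filter",
             replicate, report.n_markers_after, report.n_markers_before,
             report.n_qtl_after, report.n_qtl_before)

    rng_trait = substream(seed, "trait", replicate)
    trait_raw = sample_qtl_effects(genome.n_qtl,
                                   genome_full.n_alleles[genome.qtl_idx],
                                   cfg.gamma_shape, rng_trait)
    hp.tbv = compute_tbv(hp, trait_raw, genome)

    # divergent pure lines (sire line: high TBV; dam line: low TBV)
    rng_lines = substream(seed, "lines", replicate)
    line_phase_hi = BreedingPhase(cfg.line_males, cfg.line_females,
                                  cfg.line_generations, "high_tbv",
                                  "positive_assortative", cfg.offspring_per_dam)
    line_phase_lo = dataclasses.replace(line_phase_hi, selection="low_tbv")
    l1 = select_founders(hp, cfg.line_males, cfg.line_females, "high_tbv")
    l1 = dataclasses.replace(l1, label="L1")
    l1 = _breed_line(l1, line_phase_hi, genome, mut, trait_raw, rng_lines, "L1")
    l2 = select_founders(hp, cfg.line_males, cfg.line_females, "low_tbv")
    l2 = dataclasses.replace(l2, label="L2")
    l2 = _breed_line(l2, line_phase_lo, genome, mut, trait_raw, rng_lines, "L2")

    # reciprocal F1 crosses, then random selection + assortative mating
    rng_f1 = substream(seed, "f1", replicate)
    f1_phase = BreedingPhase(cfg.f1_males, cfg.f1_females, cfg.f1_generations,
                             "random", "positive_assortative", cfg.offspring_per_dam)
    f1a = cross_populations(l1, l2, cfg.f1_males, cfg.f1_females, f1_phase,
                            genome, mut, trait_raw, rng_f1, "F1a",
                            selection_a="high_tbv", selection_b="low_tbv")
    f1b = cross_populations(l2, l1, cfg.f1_males, cfg.f1_females, f1_phase,
                            genome, mut, trait_raw, rng_f1, "F1b",
                            selection_a="low_tbv", selection_b="high_tbv")
    for g in range(1, cfg.f1_generations):
        sel_a = select_founders(f1a, cfg.f1_males, cfg.f1_females, "random", rng_f1)
        f1a = advance_generation(sel_a, f1_phase, genome, mut, trait_raw,
                                 rng_f1, generation=g + 1, label="F1a")
        sel_b = select_founders(f1b, cfg.f1_males, cfg.f1_females, "random", rng_f1)
        f1b = advance_generation(sel_b, f1_phase, genome, mut, trait_raw,
                                 rng_f1, generation=g + 1, label="F1b")

    # reciprocal F2 crosses: random founders, random mating
    rng_f2 = substream(seed, "f2", replicate)
    f2_phase = BreedingPhase(cfg.f2_males, cfg.f2_females, cfg.f2_generations,
                             "random", "random", cfg.offspring_per_dam)
    founders_a = Population.concat(
        [select_founders(f1a, cfg.f2_males, 0, "random", rng_f2),
         select_founders(f1b, 0, cfg.f2_females, "random", rng_f2)], label="F2a")
    founders_b = Population.concat(
        [select_founders(f1b, cfg.f2_males, 0, "random", rng_f2),
         select_founders(f1a, 0, cfg.f2_females, "random", rng_f2)], label="F2b")
    f2_founders = Population.concat([founders_a, founders_b], label="F2founders")

    cohorts = {}
    gen1 = []
    for tag, founders in (("a", founders_a), ("b", founders_b)):
        pop = advance_generation(founders, f2_phase, genome, mut, trait_raw,
                                 rng_f2, generation=1, label=f"F2{tag}")
        gen1.append(pop)
        if 1 in cfg.rp_generations:
            cohorts[(tag, 1)] = pop
        for g in range(2, cfg.f2_generations + 1):
            sel = select_founders(pop, cfg.f2_males, cfg.f2_females, "random", rng_f2)
            pop = advance_generation(sel, f2_phase, genome, mut, trait_raw,
                                     rng_f2, generation=g, label=f"F2{tag}")
            if g in cfg.rp_generations:
                cohorts[(tag, g)] = pop
    f2_gen1 = Population.concat(gen1, label="F2gen1")

    return Lineage(genome_full, genome, trait_raw, hp, l1, l2, f1a, f1b,
                   f2_founders, f2_gen1, cohorts, report)


# -- grid driver -------------------------------------------------------------

def _qtl_segregating_mask(pop: Population, genome: GenomeMap) -> np.ndarray:
    al = pop.qtl_alleles(genome)
    return np.array([len(np.unique(al[:, :, j])) > 1 for j in range(al.shape[2])])


def run_scenario_grid(cfg: SimConfig):
    """Run the full RP-size x heritability grid.

    Returns ``(grid_table, reports)``; per-scenario association tables,
    Manhattan tables and reports are written under ``cfg.out_dir`` when set.
    A stage failure aborts that scenario only.
    """
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        save_config(cfg, out / "resolved_config.yaml")
    reports: list[DetectionReport] = []
    scan_meta: list[dict] = []

    for rep in range(cfg.replicates):
        lineage = simulate_lineage(cfg, rep)
        genome = lineage.genome
        pool = Population.concat(list(lineage.f2_cohorts.values()), label="F2pool")

        # genotyping artifacts, one draw per replicate (h2-independent)
        rng_art = substream(cfg.seed, "artifacts", rep)
        observed = apply_genotyping_artifacts(pool.marker_genotypes(genome),
                                              cfg.artifacts(), rng_art)

        # phenotypes per heritability on the shared lineage
        tbv_raw = compute_tbv(pool, lineage.trait_raw, genome)
        pheno = {}
        for h2 in cfg.h2_levels:
            trait = scale_to_h2(lineage.trait_raw, lineage.f2_gen1, h2,
                                cfg.vp, genome)
            scale = np.sqrt(h2 * cfg.vp /
                            np.var(compute_tbv(lineage.f2_gen1,
                                               lineage.trait_raw, genome)))
            rng_ph = substream(cfg.seed, "pheno", rep, h2)
            tbv = tbv_raw * scale
            pheno[h2] = (tbv, tbv + rng_ph.normal(0.0, np.sqrt(trait.ve), pool.n))

        midx = genome.marker_idx
        for n_rp in cfg.rp_sizes:
            rng_rp = substream(cfg.seed, "rp", rep, n_rp)
            try:
                idx = np.sort(rng_rp.choice(pool.n, size=int(n_rp), replace=False))
                rp = pool.subset(idx, label=f"RP{n_rp}")
                ctx = MixedModelGWAS(
                    observed[idx], rp.generation, rp.sex,
                    marker_id=lineage.genome_full.ids[midx],
                    chrom=lineage.genome_full.chrom[midx],
                    pos_cM=lineage.genome_full.pos[midx],
                    maf=cfg.scan_maf)
                seg = _qtl_segregating_mask(rp, genome)
            except Exception:
                log.exception("replicate %d RP %d: setup failed", rep, n_rp)
                continue
            for h2 in cfg.h2_levels:
                scen = dict(rp_size=int(n_rp), h2=float(h2), replicate=rep,
                            seed=cfg.seed)
                try:
                    tbv, y = pheno[h2]
                    res = ctx.scan(y[idx], alpha=cfg.alpha)
                    rpt = match_significant_to_qtl(res, genome, cfg.window_cM,
                                                   qtl_segregating=seg,
                                                   scenario=scen)
                    reports.append(rpt)
                    scan_meta.append(dict(scen, h2_hat=res.vc.h2,
                                          sigma_a2=res.vc.sigma_a2,
                                          sigma_e2=res.vc.sigma_e2,
                                          n_tests=res.n_tests,
                                          threshold_p=res.threshold_p))
                    log.info("rep %d RP %d h2 %.1f: %d detected, %d false, "
                             "h2_hat %.3f", rep, n_rp, h2, rpt.n_detected,
                             rpt.n_false_signals, res.vc.h2)
                    if out:
                        d = out / f"rep{rep}_rp{n_rp}_h2{h2:g}"
                        d.mkdir(exist_ok=True)
                        res.to_frame().to_csv(d / "assoc.tsv", sep="\t", index=False)
                        manhattan_table(res, genome).to_csv(
                            d / "manhattan.tsv", sep="\t", index=False)
                        (d / "report.json").write_text(json.dumps(
                            rpt.to_row(), indent=2))
                except Exception:
                    log.exception("replicate %d RP %d h2 %s: scenario failed",
                                  rep, n_rp, h2)

    grid = summarize_grid(reports) if reports else pd.DataFrame()
    if len(grid) and scan_meta:
        meta = (pd.DataFrame(scan_meta).groupby(["rp_size", "h2"])["h2_hat"]
                .median().reset_index(name="median_h2_hat"))
        grid = grid.merge(meta, on=["rp_size", "h2"], how="left")
    if out and len(grid):
        grid.to_csv(out / "grid.tsv", sep="\t", index=False)
        pd.DataFrame(scan_meta).to_csv(out / "scans.tsv", sep="\t", index=False)
    return grid, reports


def export_dataset(pop: Population, genome: GenomeMap, out_dir,
                   observed: np.ndarray | None = None, trait=None,
                   missing_parent_rate: float = 0.0, rng=None,
                   prefix: str = "dataset") -> dict:
    """Write PED/MAP, VCF, phenotype TSV, pedigree CSV (parent ids censored
    at *missing_parent_rate*) and, when a trait is given, the architecture TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped_pop = pop
    if missing_parent_rate > 0:
        if rng is None:
            raise ConfigError("missing_parent_rate > 0 requires an rng")
        ped_pop = censor_pedigree(pop, missing_parent_rate, rng)
    paths = {
        "ped": str(out / f"{prefix}.ped"),
        "map": str(out / f"{prefix}.map"),
        "vcf": str(out / f"{prefix}.vcf"),
        "phenotypes": str(out / f"{prefix}.pheno.tsv"),
        "pedigree": str(out / f"{prefix}.pedigree.csv"),
    }
    fio.write_ped_map(str(out / prefix), pop, genome, observed)
    fio.write_vcf(paths["vcf"], pop, genome, observed)
    fio.write_phenotypes(paths["phenotypes"], pop)
    fio.write_pedigree(paths["pedigree"], ped_pop)
    if trait is not None:
        paths["trait"] = str(out / f"{prefix}.trait.tsv")
        fio.write_trait_architecture(paths["trait"], trait, genome)
    return paths
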
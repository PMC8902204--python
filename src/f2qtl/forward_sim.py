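"""Population phases of the breeding design.

The design mirrors a classical F2 intercross breeding program: a large
random-mating historical population establishes drift/bottleneck LD and a
standing allele-frequency spectrum; two pure lines are then selected from it
divergently on true breeding value (TBV) with positive assortative mating;
reciprocal line crosses give F1a/F1b, reciprocal F1 crosses give F2a/F2b; and
reference populations for association analysis are drawn from late F2
generations.

All randomness flows through explicit ``numpy.random.Generator`` objects, so
one master seed reproduces every cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .genome import GenomeMap, MutationModel, make_gametes

__all__ = [
    "Population",
    "HistoricalPhase",
    "BreedingPhase",
    "founder_population",
    "simulate_historical",
    "select_founders",
    "advance_generation",
    "cross_populations",
    "sample_reference_population",
    "censor_pedigree",
]

MALE, FEMALE = 1, 2
UNKNOWN_PARENT = "0"


class BreedingError(ValueError):
    """Impossible mating/selection request."""


@dataclass
class Population:
    """One generation cohort: haplotypes, pedigree, labels, TBV, phenotype."""

    ids: np.ndarray                 # (n,) object
    sire: np.ndarray                # (n,) object, UNKNOWN_PARENT for founders
    dam: np.ndarray
    sex: np.ndarray                 # (n,) int8, 1 = male, 2 = female
    generation: np.ndarray          # (n,) int32 (within-population generation)
    haplotypes: np.ndarray          # (n, 2, L) int8
    label: str = "HP"
    tbv: np.ndarray | None = None
    phenotype: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)

    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)

    def subset(self, idx: np.ndarray, label: str | None = None) -> "Population":
        return Population(
            self.ids[idx], self.sire[idx], self.dam[idx], self.sex[idx],
            self.generation[idx], self.haplotypes[idx],
            label if label is not None else self.label,
            None if self.tbv is None else self.tbv[idx],
            None if self.phenotype is None else self.phenotype[idx],
        )

    @staticmethod
    def concat(pops: Sequence["Population"], label: str | None = None) -> "Population":
        def cat(attr):
            vals = [getattr(p, attr) for p in pops]
            return None if any(v is None for v in vals) else np.concatenate(vals)
        return Population(
            np.concatenate([p.ids for p in pops]),
            np.concatenate([p.sire for p in pops]),
            np.concatenate([p.dam for p in pops]),
            np.concatenate([p.sex for p in pops]),
            np.concatenate([p.generation for p in pops]),
            np.concatenate([p.haplotypes for p in pops]),
            label if label is not None else pops[0].label,
            cat("tbv"), cat("phenotype"),
        )

    def marker_genotypes(self, genome: GenomeMap) -> np.ndarray:
        """(n, M) int8 counts of allele 1 at the panel markers."""
        h = self.haplotypes[:, :, genome.marker_idx]
        return (h[:, 0, :] + h[:, 1, :]).astype(np.int8)

    def qtl_alleles(self, genome: GenomeMap) -> np.ndarray:
        """(n, 2, Q) int8 allele codes at the active QTLs."""
        return self.haplotypes[:, :, genome.qtl_idx]


@dataclass(frozen=True)
class HistoricalPhase:
    """A stretch of random-mating generations; cohort size moves linearly
    from the previous phase's end size to *size* when *ramp* is set."""

    n_generations: int
    size: int
    ramp: bool = False

    def __post_init__(self):
        if self.n_generations < 0 or self.size <= 0:
            raise BreedingError("historical phase sizes/generations must be positive")


@dataclass(frozen=True)
class BreedingPhase:
    """Selection + mating scheme of a bred population (pure line, F1 or F2)."""

    n_males: int
    n_females: int
    n_generations: int
    selection: str = "random"          # random | high_tbv | low_tbv
    mating: str = "random"             # random | positive_assortative
    offspring_per_dam: int = 10
    replacement_ratio: float = 1.0

    def __post_init__(self):
        if self.n_males <= 0 or self.n_females <= 0 or self.n_generations < 0:
            raise BreedingError("breeding phase sizes must be positive")
        if self.selection not in ("random", "high_tbv", "low_tbv"):
            raise BreedingError(f"unknown selection rule {self.selection!r}")
        if self.mating not in ("random", "positive_assortative"):
            raise BreedingError(f"unknown mating rule {self.mating!r}")
        if not 0.0 <= self.replacement_ratio <= 1.0:
            raise BreedingError("replacement_ratio must be in [0, 1]")


def _make_ids(label: str, gen: int, n: int) -> np.ndarray:
    return np.array([f"{label}.G{gen}.{i}" for i in range(n)], dtype=object)


def founder_population(genome: GenomeMap, n: int, rng, label: str = "HP") -> Population:
    """Unrelated founders: marker alleles Bernoulli(1/2), QTL alleles uniform
    over each locus's allele set."""
    u = rng.random((n, 2, genome.n_loci))
    haps = (u * genome.n_alleles[None, None, :]).astype(np.int8)
    unknown = np.full(n, UNKNOWN_PARENT, dtype=object)
    sex = rng.integers(MALE, FEMALE + 1, size=n).astype(np.int8)
    return Population(_make_ids(label, 0, n), unknown.copy(), unknown.copy(), sex,
                      np.zeros(n, np.int32), haps, label)


def _random_union_generation(pop: Population, n_out: int, gen: int,
                             genome, mut, rng) -> Population:
    males, females = pop.males(), pop.females()
    if len(males) == 0 or len(females) == 0:
        raise BreedingError("historical cohort lost one sex entirely")
    sire_i = males[rng.integers(0, len(males), n_out)]
    dam_i = females[rng.integers(0, len(females), n_out)]
    pat = make_gametes(pop.haplotypes, sire_i, genome, mut, rng)
    mat = make_gametes(pop.haplotypes, dam_i, genome, mut, rng)
    haps = np.stack([pat, mat], axis=1)
    sex = rng.integers(MALE, FEMALE + 1, size=n_out).astype(np.int8)
    return Population(_make_ids(pop.label, gen, n_out), pop.ids[sire_i], pop.ids[dam_i],
                      sex, np.full(n_out, gen, np.int32), haps, pop.label)


def historical_size_schedule(phases: Sequence[HistoricalPhase]) -> np.ndarray:
    """Cohort size per generation; ramp phases interpolate linearly."""
    sizes: list[int] = []
    prev = phases[0].size
    for ph in phases:
        if ph.ramp:
            steps = np.linspace(prev, ph.size, ph.n_generations + 1)[1:]
            sizes.extend(int(round(s)) for s in steps)
        else:
            sizes.extend([ph.size] * ph.n_generations)
        prev = ph.size
    return np.array(sizes, dtype=int)


def simulate_historical(genome: GenomeMap, mut: MutationModel,
                        phases: Sequence[HistoricalPhase], rng,
                        label: str = "HP") -> Population:
    """Random-mating historical population; returns the final cohort.

    Founders start at allele frequency 1/2 (markers) / uniform (QTLs); each
    generation is a random union of gametes from randomly paired parents with
    offspring sex i.i.d. fair. A shrinking phase models the bottleneck that
    generates LD.
    """
    sizes = historical_size_schedule(phases)
    pop = founder_population(genome, phases[0].size, rng, label)
    for g, n_out in enumerate(sizes, start=1):
        pop = _random_union_generation(pop, int(n_out), g, genome, mut, rng)
    return pop


def _ranked(pop: Population, idx: np.ndarray, descending: bool) -> np.ndarray:
    """Indices sorted by TBV (ties broken by id for determinism)."""
    if pop.tbv is None:
        raise BreedingError("TBV required for TBV-based selection/mating")
    key = -pop.tbv[idx] if descending else pop.tbv[idx]
    order = np.lexsort((pop.ids[idx], key))
    return idx[order]


def select_founders(pop: Population, n_males: int, n_females: int,
                    rule: str = "random", rng=None) -> Population:
    """Select breeding individuals per sex: top TBV (``high_tbv``), bottom
    (``low_tbv``), or uniformly at random."""
    chosen = []
    for n_want, idx in ((n_males, pop.males()), (n_females, pop.females())):
        if n_want == 0:
            continue
        if len(idx) < n_want:
            raise BreedingError(
                f"need {n_want} candidates of one sex, only {len(idx)} available")
        if rule == "random":
            if rng is None:
                raise BreedingError("random selection requires an rng")
            chosen.append(rng.choice(idx, size=n_want, replace=False))
        elif rule == "high_tbv":
            chosen.append(_ranked(pop, idx, descending=True)[:n_want])
        elif rule == "low_tbv":
            chosen.append(_ranked(pop, idx, descending=False)[:n_want])
        else:
            raise BreedingError(f"unknown selection rule {rule!r}")
    return pop.subset(np.concatenate(chosen))


def _pair_dams_to_sires(pop: Population, mating: str, rng) -> tuple[np.ndarray, np.ndarray]:
    """Return (sire_index_per_dam, dam_indices).

    Positive assortative mating rank-matches sires and dams by TBV, each sire
    serving a contiguous block of similarly ranked dams; random mating
    shuffles the dam order first and pairs arbitrary-order sires.
    """
    sires, dams = pop.males(), pop.females()
    if len(sires) == 0 or len(dams) == 0:
        raise BreedingError("need at least one sire and one dam")
    if mating == "positive_assortative":
        sires = _ranked(pop, sires, descending=True)
        dams = _ranked(pop, dams, descending=True)
    else:
        dams = rng.permutation(dams)
    n_s, n_d = len(sires), len(dams)
    base, extra = divmod(n_d, n_s)
    block_sizes = np.full(n_s, base)
    block_sizes[:extra] += 1
    sire_of_dam = np.repeat(sires, block_sizes)
    return sire_of_dam, dams


def advance_generation(parents: Population, phase: BreedingPhase,
                       genome: GenomeMap, mut: MutationModel,
                       trait, rng, generation: int | None = None,
                       label: str | None = None) -> Population:
    """Breed one generation from an already-selected parent cohort.

    Every dam produces ``offspring_per_dam`` offspring by union of one
    paternal and one maternal gamete; offspring sex is an i.i.d. fair coin.
    With replacement ratio 1 the parents are never reused (the caller selects
    the next parents from the returned cohort). TBV is filled in when a trait
    architecture is supplied.
    """
    from .quantgen import compute_tbv

    sire_of_dam, dams = _pair_dams_to_sires(parents, phase.mating, rng)
    opd = phase.offspring_per_dam
    sire_i = np.repeat(sire_of_dam, opd)
    dam_i = np.repeat(dams, opd)
    n_out = len(dam_i)
    pat = make_gametes(parents.haplotypes, sire_i, genome, mut, rng)
    mat = make_gametes(parents.haplotypes, dam_i, genome, mut, rng)
    haps = np.stack([pat, mat], axis=1)
    gen = int(parents.generation.max()) + 1 if generation is None else generation
    lab = parents.label if label is None else label
    sex = rng.integers(MALE, FEMALE + 1, size=n_out).astype(np.int8)
    pop = Population(_make_ids(lab, gen, n_out), parents.ids[sire_i], parents.ids[dam_i],
                     sex, np.full(n_out, gen, np.int32), haps, lab)
    if trait is not None:
        pop.tbv = compute_tbv(pop, trait, genome)
    return pop


def cross_populations(pop_a: Population, pop_b: Population,
                      n_males_from_a: int, n_females_from_b: int,
                      phase: BreedingPhase, genome: GenomeMap, mut: MutationModel,
                      trait, rng, label: str,
                      selection_a: str | None = None,
                      selection_b: str | None = None) -> Population:
    """First cohort of a cross: males of *pop_a* x females of *pop_b*.

    Founder selection rules default to the phase's rule and may be overridden
    per source population (e.g. high-TBV males from the sire line).
    """
    rule_a = phase.selection if selection_a is None else selection_a
    rule_b = phase.selection if selection_b is None else selection_b
    males = select_founders(pop_a, n_males_from_a, 0, rule_a, rng)
    females = select_founders(pop_b, 0, n_females_from_b, rule_b, rng)
    founders = Population.concat([males, females], label=label)
    return advance_generation(founders, phase, genome, mut, trait, rng,
                              generation=1, label=label)


def sample_reference_population(cohorts: Sequence[Population], n: int, rng,
                                label: str = "RP") -> Population:
    """Uniform sample without replacement from the union of cohorts,
    preserving generation and sex labels (the contemporary-group factors)."""
    pool = Population.concat(list(cohorts), label=label)
    if n > pool.n:
        raise BreedingError(f"requested RP of {n} from {pool.n} available")
    idx = rng.choice(pool.n, size=n, replace=False)
    return pool.subset(np.sort(idx), label=label)


def censor_pedigree(pop: Population, missing_parent_rate: float, rng) -> Population:
    """Copy with each recorded sire/dam id independently replaced by unknown
    with the given probability (pedigree-export artifact only)."""
    if not 0.0 <= missing_parent_rate <= 1.0:
        raise BreedingError("missing_parent_rate must be in [0, 1]")
    out = replace(pop, sire=pop.sire.copy(), dam=pop.dam.copy())
    for arr in (out.sire, out.dam):
        known = arr != UNKNOWN_PARENT
        hit = known & (rng.random(pop.n) < missing_parent_rate)
        arr[hit] = UNKNOWN_PARENT
    return out
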
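"""Trait architecture, phenotypes and genotyping artifacts.

The trait is purely additive: each QTL allele carries one effect, an
individual's true breeding value (TBV) is the sum of its two allele effects
over all QTLs, and markers are neutral. Raw allele-effect magnitudes are
gamma-distributed (shape 0.4, scale 1) with random signs and per-locus
centering, then rescaled by a single constant so the TBV variance in a chosen
scaling cohort equals h2 * Vp; phenotypes add i.i.d. Gaussian residuals with
variance Ve = (1 - h2) * Vp.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .forward_sim import Population
from .genome import GenomeMap

__all__ = [
    "TraitArchitecture",
    "GenotypingArtifacts",
    "sample_qtl_effects",
    "scale_to_h2",
    "compute_tbv",
    "simulate_phenotypes",
    "apply_genotyping_artifacts",
    "filter_segregating_loci",
    "MISSING",
]

MISSING = np.int8(-1)   # missing-genotype code in observed marker matrices

MAX_QTL_ALLELES = 4


class ArchitectureError(ValueError):
    pass


@dataclass
class TraitArchitecture:
    """Additive allele effects for the active QTLs of a genome map.

    ``allele_effects[q, a]`` is the effect (trait units) of allele *a* at the
    q-th active QTL; entries beyond a locus's allele count are NaN. ``h2``,
    ``vp`` and ``ve`` are set once the raw effects have been scaled.
    """

    allele_counts: np.ndarray          # (Q,) int8, 2-4
    allele_effects: np.ndarray         # (Q, 4) float
    gamma_shape: float = 0.4
    h2: float | None = None
    vp: float | None = None

    def __post_init__(self):
        if np.any((self.allele_counts < 2) | (self.allele_counts > MAX_QTL_ALLELES)):
            raise ArchitectureError("QTL allele counts must be in {2, 3, 4}")

    @property
    def n_qtl(self) -> int:
        return len(self.allele_counts)

    @property
    def ve(self) -> float | None:
        if self.h2 is None:
            return None
        return (1.0 - self.h2) * self.vp


@dataclass(frozen=True)
class GenotypingArtifacts:
    """Per-genotype missingness and mis-call probabilities for markers."""

    missing_rate: float = 0.05
    error_rate: float = 0.005

    def __post_init__(self):
        for name in ("missing_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ArchitectureError(f"{name} must be in [0, 1], got {v}")


def sample_qtl_effects(n_qtl: int, allele_counts: np.ndarray, shape: float,
                       rng) -> TraitArchitecture:
    """Draw raw (unscaled) allele effects.

    Magnitudes are Gamma(shape, scale 1), signs independent fair coins, and
    effects are centered to mean zero within each locus so an allele set
    carries no built-in trend. Effect *differences* between alleles — which
    is all that matters for variance — keep the heavy-tailed gamma character:
    a few QTLs dominate the genetic variance.
    """
    if shape <= 0:
        raise ArchitectureError("gamma shape must be > 0")
    allele_counts = np.asarray(allele_counts, dtype=np.int8)
    eff = np.full((n_qtl, MAX_QTL_ALLELES), np.nan)
    for q in range(n_qtl):
        k = int(allele_counts[q])
        mag = rng.gamma(shape, 1.0, size=k)
        sgn = rng.integers(0, 2, size=k) * 2 - 1
        e = mag * sgn
        eff[q, :k] = e - e.mean()
    return TraitArchitecture(allele_counts, eff, gamma_shape=shape)


def compute_tbv(pop: Population, trait: TraitArchitecture,
                genome: GenomeMap) -> np.ndarray:
    """TBV = sum over active QTLs of the two carried allele effects."""
    alleles = pop.qtl_alleles(genome)              # (n, 2, Q)
    Q = trait.n_qtl
    if alleles.shape[2] != Q:
        raise ArchitectureError(
            f"genome has {alleles.shape[2]} active QTLs, trait has {Q}")
    if np.any(alleles >= trait.allele_counts[None, None, :]):
        raise ArchitectureError("QTL allele code outside the effect table")
    e = trait.allele_effects[np.arange(Q)[None, None, :], alleles]
    return e.sum(axis=(1, 2))


def scale_to_h2(raw: TraitArchitecture, cohort: Population, h2: float, vp: float,
                genome: GenomeMap) -> TraitArchitecture:
    """Rescale all allele effects by one constant so var(TBV) in *cohort*
    equals ``h2 * vp`` (population variance, ddof 0)."""
    if not 0.0 < h2 < 1.0:
        raise ArchitectureError("h2 must be in (0, 1)")
    tbv = compute_tbv(cohort, raw, genome)
    v = float(np.var(tbv))
    if v <= 0.0:
        raise ArchitectureError("no genetic variance in the scaling cohort")
    c = np.sqrt(h2 * vp / v)
    return replace(raw, allele_effects=raw.allele_effects * c, h2=h2, vp=vp)


def simulate_phenotypes(pop: Population, trait: TraitArchitecture, rng,
                        genome: GenomeMap) -> np.ndarray:
    """y_i = TBV_i + e_i with e ~ N(0, Ve); no fixed effects are added here
    (contemporary groups enter only the analysis model)."""
    if trait.h2 is None:
        raise ArchitectureError("trait must be scaled (h2 set) before phenotyping")
    tbv = pop.tbv if pop.tbv is not None else compute_tbv(pop, trait, genome)
    return tbv + rng.normal(0.0, np.sqrt(trait.ve), size=pop.n)


def apply_genotyping_artifacts(marker_matrix: np.ndarray,
                               art: GenotypingArtifacts, rng) -> np.ndarray:
    """Observed marker matrix: missing entries coded -1, mis-calls applied.

    Each genotype is independently set missing with ``missing_rate``; else
    mis-called with ``error_rate`` (heterozygote -> random homozygote,
    homozygote -> heterozygote). The input (true) matrix is left untouched.
    """
    obs = np.asarray(marker_matrix, dtype=np.int8).copy()
    u = rng.random(obs.shape, dtype=np.float32)
    miss = u < art.missing_rate
    # disjoint interval => P(error | not missing) = error_rate, independent entries
    err = (~miss) & (u < art.missing_rate + art.error_rate * (1.0 - art.missing_rate))
    ei, ej = np.nonzero(err)
    if len(ei):
        g = obs[ei, ej]
        new = np.where(g == 1,
                       rng.integers(0, 2, size=len(ei)).astype(np.int8) * 2,
                       np.int8(1))
        obs[ei, ej] = new
    obs[miss] = MISSING
    return obs


@dataclass
class LocusFilterReport:
    n_markers_before: int
    n_markers_after: int
    n_qtl_before: int
    n_qtl_after: int
    marker_keep: np.ndarray
    qtl_keep: np.ndarray
    marker_maf: np.ndarray
    qtl_maf: np.ndarray


def _multiallelic_maf(alleles_2d: np.ndarray, k: int) -> float:
    """Frequency of the rarest *segregating* allele (0 if monomorphic)."""
    counts = np.bincount(alleles_2d.ravel(), minlength=k)
    seg = counts[counts > 0]
    if len(seg) < 2:
        return 0.0
    return float(seg.min() / counts.sum())


def filter_segregating_loci(pop: Population, genome: GenomeMap,
                            marker_maf: float = 0.1, qtl_maf: float = 0.01
                            ) -> tuple[GenomeMap, LocusFilterReport]:
    """Restrict the analysis panel to loci with MAF >= threshold in *pop*.

    Markers use the biallelic minor-allele frequency; multi-allelic QTLs use
    the frequency of the rarest segregating allele. A locus is retained iff
    its MAF is >= the threshold. Typically applied to the final historical
    cohort, where the panel is selected.
    """
    for t in (marker_maf, qtl_maf):
        if not 0.0 <= t <= 0.5:
            raise ArchitectureError("MAF thresholds must be in [0, 0.5]")
    geno = pop.marker_genotypes(genome)
    p = geno.mean(axis=0) / 2.0
    m_maf = np.minimum(p, 1.0 - p)
    marker_keep = m_maf >= marker_maf

    q_al = pop.qtl_alleles(genome)
    ks = genome.n_alleles[genome.qtl_idx]
    q_maf = np.array([_multiallelic_maf(q_al[:, :, j], int(ks[j]))
                      for j in range(q_al.shape[2])])
    qtl_keep = q_maf >= qtl_maf
    if not qtl_keep.any():
        raise ArchitectureError(
            "no QTL segregates above the MAF threshold; re-draw QTL positions")

    report = LocusFilterReport(
        n_markers_before=genome.n_markers,
        n_markers_after=int(marker_keep.sum()),
        n_qtl_before=genome.n_qtl,
        n_qtl_after=int(qtl_keep.sum()),
        marker_keep=marker_keep, qtl_keep=qtl_keep,
        marker_maf=m_maf, qtl_maf=q_maf,
    )
    return genome.restrict(marker_keep, qtl_keep), report
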
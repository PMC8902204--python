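"""Genome map and gametogenesis primitives.

The simulated genome is a set of autosomes described purely in genetic-map
coordinates (centimorgans, 0-based, half-open ``[0, L)`` per chromosome).
Biallelic markers are evenly spaced within each chromosome and allocated to
chromosomes proportionally to map length; QTLs (2-4 alleles each) are placed
uniformly at random with expected counts proportional to length.

Meiosis follows the standard no-interference model: crossover counts are
Poisson with mean equal to the map length in Morgans and crossover positions
are i.i.d. uniform, so two-locus recombination fractions obey Haldane's map
function r = (1 - exp(-2d/100 cM)) / 2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._meiosis import gametes_kernel

__all__ = [
    "DEFAULT_TOTAL_LENGTH_CM",
    "default_chrom_lengths",
    "GenomeMap",
    "MutationModel",
    "build_genome_map",
    "sample_crossovers",
    "make_gamete",
    "make_gametes",
    "write_map_table",
    "read_map_table",
]

DEFAULT_TOTAL_LENGTH_CM = 2729.4

# Relative map lengths for 18 autosomes, patterned after the strongly
# size-skewed chicken linkage map (one micro-chromosome-like short element
# included); rescaled so the defaults sum to DEFAULT_TOTAL_LENGTH_CM exactly.
_CHROM_WEIGHTS = np.array(
    [554, 412, 311, 244, 197, 133, 127, 121, 112, 102,
     92, 91, 82, 72, 62, 60, 57, 6],
    dtype=float,
)


def default_chrom_lengths(total_cM: float = DEFAULT_TOTAL_LENGTH_CM) -> np.ndarray:
    """18 chromosome lengths (cM) with size-skewed proportions summing to *total_cM*."""
    return _CHROM_WEIGHTS * (total_cM / _CHROM_WEIGHTS.sum())


class ConfigurationError(ValueError):
    """Invalid genome/simulation configuration."""


@dataclass(frozen=True)
class MutationModel:
    """Recurrent-mutation rates per locus per gamete.

    Markers flip to the opposite allele; QTLs move to a uniformly chosen
    different allele of their fixed allele set (the allele count never grows).
    """

    marker_rate: float = 2.5e-4
    qtl_rate: float = 2.5e-5

    def __post_init__(self) -> None:
        for name in ("marker_rate", "qtl_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1e-2):
                raise ConfigurationError(f"{name} must be in [0, 1e-2], got {v}")


NO_MUTATION = MutationModel(0.0, 0.0)


@dataclass
class GenomeMap:
    """Ordered loci (markers + QTLs interleaved by position) on a multi-chromosome map.

    ``marker_idx`` / ``qtl_idx`` are global locus indices of the *analysis*
    panel; :meth:`restrict` narrows them (e.g. after MAF filtering) without
    changing the underlying loci, so haplotype matrices stay aligned.
    """

    chrom_lengths: np.ndarray          # (C,) cM
    chrom: np.ndarray                  # (L,) int16, 0-based chromosome of each locus
    pos: np.ndarray                    # (L,) float64, cM from chromosome start
    is_qtl: np.ndarray                 # (L,) bool
    n_alleles: np.ndarray              # (L,) int8 (2 for markers, 2-4 for QTLs)
    ids: np.ndarray                    # (L,) object, locus identifiers
    marker_idx: np.ndarray = field(default=None)  # global indices of panel markers
    qtl_idx: np.ndarray = field(default=None)     # global indices of active QTLs

    def __post_init__(self) -> None:
        if self.marker_idx is None:
            self.marker_idx = np.flatnonzero(~self.is_qtl)
        if self.qtl_idx is None:
            self.qtl_idx = np.flatnonzero(self.is_qtl)
        # per-chromosome locus slices, used by the meiosis kernel
        self.chrom_start = np.searchsorted(self.chrom, np.arange(self.n_chromosomes))
        self.chrom_end = np.searchsorted(self.chrom, np.arange(self.n_chromosomes), side="right")

    # -- basic shape ---------------------------------------------------------
    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths)

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    @property
    def n_markers(self) -> int:
        return len(self.marker_idx)

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_idx)

    @property
    def total_length_cM(self) -> float:
        return float(self.chrom_lengths.sum())

    @property
    def cum_offsets_cM(self) -> np.ndarray:
        """Cumulative cM offset of each chromosome start (for genome-wide coordinates)."""
        return np.concatenate([[0.0], np.cumsum(self.chrom_lengths)[:-1]])

    def marker_positions(self) -> list[np.ndarray]:
        """Panel marker positions (cM) per chromosome."""
        return [self.pos[self.marker_idx[self.chrom[self.marker_idx] == c]]
                for c in range(self.n_chromosomes)]

    def qtl_positions(self) -> list[np.ndarray]:
        return [self.pos[self.qtl_idx[self.chrom[self.qtl_idx] == c]]
                for c in range(self.n_chromosomes)]

    def locus_index(self, chrom: int, pos: float, tol: float = 1e-9) -> int:
        """Global ordinal of the locus at (chrom, pos)."""
        lo, hi = self.chrom_start[chrom], self.chrom_end[chrom]
        j = lo + int(np.searchsorted(self.pos[lo:hi], pos - tol))
        if j < hi and abs(self.pos[j] - pos) <= tol:
            return j
        raise KeyError(f"no locus at chromosome {chrom}, {pos} cM")

    def restrict(self, marker_keep: np.ndarray, qtl_keep: np.ndarray) -> "GenomeMap":
        """New map view with marker/QTL panels restricted by boolean masks.

        Masks are over the *current* ``marker_idx`` / ``qtl_idx``; loci and
        haplotype alignment are unchanged.
        """
        return dataclasses.replace(
            self,
            marker_idx=self.marker_idx[np.asarray(marker_keep, bool)],
            qtl_idx=self.qtl_idx[np.asarray(qtl_keep, bool)],
        )


def build_genome_map(
    n_chrom: int = 18,
    chrom_lengths=None,
    n_markers: int = 33802,
    n_qtl: int = 35,
    rng=None,
    qtl_allele_range: tuple[int, int] = (2, 4),
    min_separation_cM: float = 1e-6,
) -> GenomeMap:
    """Build a genome map with evenly spaced markers and random QTL positions.

    Markers are allocated to chromosomes by largest-remainder rounding of the
    length-proportional quota and placed at ``(j + 1/2) * L / n`` within each
    chromosome, so adjacent spacing is exactly ``L / n``. Each QTL is assigned
    a chromosome with probability proportional to its length, a uniform
    position, and a uniform allele count in ``qtl_allele_range``; positions
    within *min_separation_cM* of a marker or another QTL are re-drawn.
    """
    rng = np.random.default_rng(rng)
    if chrom_lengths is None:
        chrom_lengths = default_chrom_lengths() if n_chrom == 18 else None
    if chrom_lengths is None:
        raise ConfigurationError("chrom_lengths required when n_chrom != 18")
    chrom_lengths = np.asarray(chrom_lengths, dtype=float)
    if len(chrom_lengths) != n_chrom:
        raise ConfigurationError(
            f"chrom_lengths has {len(chrom_lengths)} entries, expected {n_chrom}")
    if np.any(chrom_lengths <= 0):
        raise ConfigurationError("all chromosome lengths must be > 0")
    if n_markers < n_chrom:
        raise ConfigurationError("n_markers must be >= n_chrom")
    if n_qtl < 1:
        raise ConfigurationError("n_qtl must be >= 1")

    total = chrom_lengths.sum()
    # largest-remainder allocation of markers proportional to map length
    quota = n_markers * chrom_lengths / total
    counts = np.floor(quota).astype(int)
    rem = n_markers - counts.sum()
    if rem > 0:
        frac = quota - np.floor(quota)
        counts[np.argsort(-frac, kind="stable")[:rem]] += 1
    if np.any(counts == 0):
        raise ConfigurationError("a chromosome received zero markers; increase n_markers")

    # QTL chromosomes with expected counts proportional to length
    qtl_chrom = rng.choice(n_chrom, size=n_qtl, p=chrom_lengths / total)

    chroms, poss, isq, nall = [], [], [], []
    for c in range(n_chrom):
        L, nc = chrom_lengths[c], counts[c]
        mpos = (np.arange(nc) + 0.5) * (L / nc)
        nq = int(np.sum(qtl_chrom == c))
        qpos = np.empty(nq)
        for k in range(nq):
            while True:
                p = rng.uniform(0.0, L)
                if np.min(np.abs(mpos - p)) > min_separation_cM and (
                        k == 0 or np.min(np.abs(qpos[:k] - p)) > min_separation_cM):
                    qpos[k] = p
                    break
        pos_c = np.concatenate([mpos, qpos])
        isq_c = np.concatenate([np.zeros(nc, bool), np.ones(nq, bool)])
        order = np.argsort(pos_c, kind="stable")
        chroms.append(np.full(nc + nq, c, dtype=np.int16))
        poss.append(pos_c[order])
        isq.append(isq_c[order])
        na = np.full(nc + nq, 2, dtype=np.int8)
        na[isq_c[order]] = rng.integers(qtl_allele_range[0], qtl_allele_range[1] + 1,
                                        size=nq, dtype=np.int8)
        nall.append(na)

    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    is_qtl = np.concatenate(isq)
    n_alleles = np.concatenate(nall)
    ids = np.empty(len(pos), dtype=object)
    ids[~is_qtl] = [f"M{i + 1:06d}" for i in range(int((~is_qtl).sum()))]
    ids[is_qtl] = [f"Q{i + 1:02d}" for i in range(int(is_qtl.sum()))]
    return GenomeMap(chrom_lengths, chrom, pos, is_qtl, n_alleles, ids)


def sample_crossovers(chrom_length_cM: float, rng) -> np.ndarray:
    """Sorted crossover positions on one chromosome (Poisson count, uniform positions)."""
    if chrom_length_cM <= 0:
        raise ConfigurationError("chromosome length must be > 0")
    k = rng.poisson(chrom_length_cM / 100.0)
    return np.sort(rng.uniform(0.0, chrom_length_cM, size=k))


def _draw_crossovers(n_gametes: int, chrom_lengths: np.ndarray, rng):
    """Poisson crossover counts and flat uniform positions for a batch of gametes."""
    C = len(chrom_lengths)
    counts = rng.poisson(chrom_lengths / 100.0, size=(n_gametes, C))
    flat = counts.ravel()
    total = int(flat.sum())
    lens = np.repeat(np.tile(chrom_lengths, n_gametes), flat)
    xo_pos = rng.random(total) * lens
    xo_off = np.concatenate([[0], np.cumsum(flat)]).astype(np.int64)
    return xo_pos, xo_off


def make_gametes(
    parent_haps: np.ndarray,
    parent_index: np.ndarray,
    genome: GenomeMap,
    mut: MutationModel,
    rng,
) -> np.ndarray:
    """Generate one gamete per entry of *parent_index*.

    ``parent_haps`` is the ``(n_parents, 2, n_loci)`` int8 haplotype pool;
    gamete *g* is a recombinant of individual ``parent_index[g]``'s two
    haplotypes (independent per-chromosome start haplotype, crossovers from
    the no-interference Poisson process), followed by recurrent mutation at
    rate ``mut.marker_rate`` per marker locus and ``mut.qtl_rate`` per QTL
    locus.
    """
    parent_haps = np.ascontiguousarray(parent_haps, dtype=np.int8)
    parent_index = np.asarray(parent_index, dtype=np.int64)
    if parent_haps.shape[2] != genome.n_loci:
        raise ValueError(
            f"haplotypes cover {parent_haps.shape[2]} loci, genome has {genome.n_loci}")
    G = len(parent_index)
    C = genome.n_chromosomes
    start_bits = rng.integers(0, 2, size=(G, C), dtype=np.uint8)
    xo_pos, xo_off = _draw_crossovers(G, genome.chrom_lengths, rng)
    out = np.empty((G, genome.n_loci), dtype=np.int8)
    gametes_kernel(parent_haps, parent_index, start_bits, xo_pos, xo_off,
                   genome.chrom_start.astype(np.int64),
                   genome.chrom_end.astype(np.int64),
                   genome.pos, out)
    _apply_recurrent_mutation(out, genome, mut, rng)
    return out


def _apply_recurrent_mutation(gametes: np.ndarray, genome: GenomeMap,
                              mut: MutationModel, rng) -> None:
    """In-place recurrent mutation on a (G, L) gamete batch (sparse sampling)."""
    G = gametes.shape[0]
    all_markers = np.flatnonzero(~genome.is_qtl)
    all_qtl = np.flatnonzero(genome.is_qtl)
    if mut.marker_rate > 0 and len(all_markers):
        n = rng.binomial(G * len(all_markers), mut.marker_rate)
        if n:
            flat = rng.integers(0, G * len(all_markers), size=n)
            g, l = flat // len(all_markers), all_markers[flat % len(all_markers)]
            gametes[g, l] = 1 - gametes[g, l]
    if mut.qtl_rate > 0 and len(all_qtl):
        n = rng.binomial(G * len(all_qtl), mut.qtl_rate)
        if n:
            flat = rng.integers(0, G * len(all_qtl), size=n)
            g, l = flat // len(all_qtl), all_qtl[flat % len(all_qtl)]
            k = genome.n_alleles[l].astype(np.int64)
            shift = (rng.random(n) * (k - 1)).astype(np.int64) + 1
            gametes[g, l] = ((gametes[g, l] + shift) % k).astype(np.int8)


def make_gamete(parent_hap_pair: np.ndarray, genome: GenomeMap,
                mut: MutationModel, rng) -> np.ndarray:
    """Single gamete from one parent's ``(2, n_loci)`` haplotype pair."""
    pair = np.asarray(parent_hap_pair, dtype=np.int8)
    if pair.shape != (2, genome.n_loci):
        raise ValueError(f"expected haplotype pair of shape (2, {genome.n_loci})")
    return make_gametes(pair[None, :, :], np.zeros(1, dtype=np.int64),
                        genome, mut, rng)[0]


# -- plain-text map table ----------------------------------------------------

def write_map_table(genome: GenomeMap, path) -> None:
    """Write the map as TSV: chrom, id, pos_cM, class, n_alleles (panel loci only)."""
    keep = np.zeros(genome.n_loci, bool)
    keep[genome.marker_idx] = True
    keep[genome.qtl_idx] = True
    with open(path, "w") as fh:
        fh.write("chrom\tid\tpos_cM\tclass\tn_alleles\n")
        for j in np.flatnonzero(keep):
            cls = "qtl" if genome.is_qtl[j] else "marker"
            fh.write(f"{genome.chrom[j] + 1}\t{genome.ids[j]}\t"
                     f"{genome.pos[j]:.10g}\t{cls}\t{genome.n_alleles[j]}\n")


def read_map_table(path, chrom_lengths=None) -> GenomeMap:
    """Re-load a map table written by :func:`write_map_table`.

    Chromosome lengths are not stored in the table; pass them explicitly or
    they default to the maximum observed position per chromosome.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    df = df.sort_values(["chrom", "pos_cM"], kind="stable").reset_index(drop=True)
    chrom = (df["chrom"].to_numpy() - 1).astype(np.int16)
    n_chrom = int(chrom.max()) + 1
    if chrom_lengths is None:
        chrom_lengths = np.array([df.loc[chrom == c, "pos_cM"].max() for c in range(n_chrom)])
    return GenomeMap(
        np.asarray(chrom_lengths, float),
        chrom,
        df["pos_cM"].to_numpy(float),
        (df["class"] == "qtl").to_numpy(),
        df["n_alleles"].to_numpy(np.int8),
        df["id"].to_numpy(object),
    )
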
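"""Numba kernel for batched gamete formation."""

import numba
import numpy as np


@numba.njit(cache=True, nogil=True)
def gametes_kernel(haps, parent_index, start_bits, xo_pos, xo_off,
                   chrom_start, chrom_end, positions, out):  # pragma: no cover
    """Copy recombinant haplotypes for a batch of gametes.

    haps: (P, 2, L) int8 parental haplotype pool
    parent_index: (G,) parent of each gamete
    start_bits: (G, C) which haplotype each chromosome starts on
    xo_pos/xo_off: flat crossover positions with per-(gamete, chromosome)
        offsets, gamete-major; each segment is sorted in place
    chrom_start/chrom_end: locus index range of each chromosome
    positions: (L,) locus positions in cM from chromosome start
    out: (G, L) int8 gametes (written)
    """
    G = parent_index.shape[0]
    C = chrom_start.shape[0]
    for g in range(G):
        p = parent_index[g]
        for c in range(C):
            lo = xo_off[g * C + c]
            hi = xo_off[g * C + c + 1]
            # insertion sort of this gamete-chromosome's crossovers
            for i in range(lo + 1, hi):
                key = xo_pos[i]
                j = i - 1
                while j >= lo and xo_pos[j] > key:
                    xo_pos[j + 1] = xo_pos[j]
                    j -= 1
                xo_pos[j + 1] = key
            src = start_bits[g, c]
            ptr = lo
            for l in range(chrom_start[c], chrom_end[c]):
                pos = positions[l]
                while ptr < hi and xo_pos[ptr] <= pos:
                    src = 1 - src
                    ptr += 1
                out[g, l] = haps[p, src, l]
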
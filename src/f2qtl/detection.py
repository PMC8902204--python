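"""Matching significant markers to true QTLs and summarizing detection power.

A QTL counts as detected when at least one genome-wide-significant marker
lies on its chromosome within a +/- window (default 2.5 cM). Each significant
marker is assigned to its nearest in-window QTL (ties toward the lower-index
QTL); significant markers with no in-window QTL are false signals. Power is
the detected fraction of QTLs segregating in the analyzed cohort — fixed
QTLs are undetectable in principle and excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import AssocResult
from .genome import GenomeMap

__all__ = [
    "DetectionReport",
    "match_significant_to_qtl",
    "summarize_grid",
    "manhattan_table",
    "plot_manhattan",
]

DEFAULT_WINDOW_CM = 2.5


@dataclass
class DetectionReport:
    """Detection outcome of one scan against the true QTL positions."""

    scenario: dict                      # e.g. {"rp_size":..., "h2":..., "replicate":...}
    detected_qtl: np.ndarray            # indices into the QTL list
    n_detected: int
    n_false_signals: int
    n_qtl_segregating: int
    power: float
    window_cM: float
    qtl_detected_flags: np.ndarray      # (Q,) bool
    nearest_sig_distance_cM: np.ndarray  # (Q,) float, inf when none on chromosome

    def to_row(self) -> dict:
        row = dict(self.scenario)
        row.update(n_detected=self.n_detected, n_false_signals=self.n_false_signals,
                   n_qtl_segregating=self.n_qtl_segregating, power=self.power,
                   window_cM=self.window_cM)
        return row


def match_significant_to_qtl(assoc: AssocResult, genome: GenomeMap,
                             window_cM: float = DEFAULT_WINDOW_CM,
                             qtl_segregating: np.ndarray | None = None,
                             scenario: dict | None = None) -> DetectionReport:
    """Build a :class:`DetectionReport` from a scan and the true QTL map.

    *qtl_segregating* is a boolean mask over the genome's active QTLs; only
    segregating QTLs can be detected or counted in the power denominator
    (default: all active QTLs).
    """
    if window_cM <= 0:
        raise ValueError("window_cM must be > 0")
    q_chrom = genome.chrom[genome.qtl_idx]
    q_pos = genome.pos[genome.qtl_idx]
    Q = len(q_pos)
    seg = (np.ones(Q, bool) if qtl_segregating is None
           else np.asarray(qtl_segregating, bool))

    sig = assoc.significant
    s_chrom = assoc.chrom[sig]
    s_pos = assoc.pos_cM[sig]

    detected = np.zeros(Q, bool)
    nearest = np.full(Q, np.inf)
    n_false = 0
    for c, p in zip(s_chrom, s_pos):
        cand = np.flatnonzero(seg & (q_chrom == c))
        if len(cand) == 0:
            n_false += 1
            continue
        dist = np.abs(q_pos[cand] - p)
        j = cand[np.argmin(dist)]          # argmin ties -> lower index
        if dist.min() <= window_cM:
            detected[j] = True
        else:
            n_false += 1
        for q in cand:
            nearest[q] = min(nearest[q], abs(q_pos[q] - p))

    n_seg = int(seg.sum())
    n_det = int(detected.sum())
    return DetectionReport(
        scenario=scenario or {},
        detected_qtl=np.flatnonzero(detected),
        n_detected=n_det,
        n_false_signals=n_false,
        n_qtl_segregating=n_seg,
        power=n_det / n_seg if n_seg else 0.0,
        window_cM=window_cM,
        qtl_detected_flags=detected,
        nearest_sig_distance_cM=nearest,
    )


def summarize_grid(reports) -> pd.DataFrame:
    """Per (RP size, h2) cell: replicate count, mean/median detections, mean
    power and false signals; ordered by RP size then h2."""
    df = pd.DataFrame([r.to_row() for r in reports])
    out = (df.groupby(["rp_size", "h2"])
             .agg(n_replicates=("n_detected", "size"),
                  mean_detected=("n_detected", "mean"),
                  median_detected=("n_detected", "median"),
                  mean_power=("power", "mean"),
                  mean_false_signals=("n_false_signals", "mean"),
                  mean_qtl_segregating=("n_qtl_segregating", "mean"))
             .reset_index()
             .sort_values(["rp_size", "h2"], kind="stable")
             .reset_index(drop=True))
    return out


def manhattan_table(assoc: AssocResult, genome: GenomeMap) -> pd.DataFrame:
    """Plot-ready table: markers with cumulative genome coordinates plus
    tagged QTL overlay rows and the threshold line value."""
    offsets = genome.cum_offsets_cM
    thr = -np.log10(assoc.threshold_p)
    m = pd.DataFrame({
        "kind": "marker",
        "chrom": assoc.chrom + 1,
        "pos_cM": assoc.pos_cM,
        "cum_pos_cM": offsets[assoc.chrom] + assoc.pos_cM,
        "neglog10p": assoc.neglog10p,
        "parity": assoc.chrom % 2,
        "threshold": thr,
        "id": assoc.marker_id,
    })
    q_chrom = genome.chrom[genome.qtl_idx]
    q_pos = genome.pos[genome.qtl_idx]
    q = pd.DataFrame({
        "kind": "qtl",
        "chrom": q_chrom + 1,
        "pos_cM": q_pos,
        "cum_pos_cM": offsets[q_chrom] + q_pos,
        "neglog10p": np.nan,
        "parity": q_chrom % 2,
        "threshold": thr,
        "id": genome.ids[genome.qtl_idx],
    })
    return pd.concat([m, q], ignore_index=True)


def plot_manhattan(table: pd.DataFrame, path, title: str = "") -> None:
    """Render a Manhattan plot (threshold line, QTL triangles) to *path*."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mk = table[table["kind"] == "marker"]
    qt = table[table["kind"] == "qtl"]
    fig, ax = plt.subplots(figsize=(10, 3.2))
    for parity, color in ((0, "#23527c"), (1, "#7aa6cc")):
        sub = mk[mk["parity"] == parity]
        ax.scatter(sub["cum_pos_cM"], sub["neglog10p"], s=4, c=color, linewidths=0)
    ax.axhline(float(mk["threshold"].iloc[0]), ls="--", c="grey", lw=1)
    ax.scatter(qt["cum_pos_cM"], np.zeros(len(qt)) - 0.3, marker="^", c="red", s=18)
    ax.set_xlabel("genome position (cM)")
    ax.set_ylabel(r"$-\log_{10} p$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
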
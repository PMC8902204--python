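"""Mixed-model genome scan (EMMAX approximation).

Model per marker k:

    y = mu + CG_i + b1 * SNP_k + A1 + e,
    A1 ~ N(0, G sigma_a^2),  e ~ N(0, I sigma_e^2),

where CG is the fixed contemporary-group effect (generation x sex), SNP_k is
the additive 0/1/2 genotype code, and G is VanRaden's method-1 genomic
relationship matrix. Variance components are estimated once by exact REML on
the null model (1-D profile likelihood in the ratio gamma = sigma_a^2 /
sigma_e^2, evaluated in the eigenbasis of G) and held fixed across markers;
each marker is then tested by generalized least squares with a two-sided Wald
chi-square on b1, which is exact under the Gaussian model given V.

The experiment-wise threshold is the Bonferroni bound alpha / M over the M
markers actually tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .quantgen import MISSING

__all__ = [
    "EncodedGenotypes",
    "VarianceComponents",
    "AssocResult",
    "encode_genotypes",
    "contemporary_group_design",
    "compute_grm",
    "reml_null_fit",
    "reml_loglik",
    "emmax_scan",
    "bonferroni_threshold",
    "MixedModelGWAS",
    "run_gwas",
]

_P_FLOOR = 1e-300


@dataclass
class EncodedGenotypes:
    """0/1/2 additive codes with missing entries mean-imputed to 2p."""

    matrix: np.ndarray        # (n, M) float64
    freqs: np.ndarray         # (M,) allele-1 frequency from non-missing calls
    kept: np.ndarray          # indices into the input columns that survived

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_markers(self) -> int:
        return self.matrix.shape[1]


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    h2: float
    log_gamma: float
    boundary: bool
    reml_loglik: float


@dataclass
class AssocResult:
    """Per-marker scan results plus the genome-wide threshold."""

    marker_id: np.ndarray
    chrom: np.ndarray             # 0-based
    pos_cM: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    stat: np.ndarray              # Wald chi-square (1 df)
    p: np.ndarray
    threshold_p: float
    alpha: float
    n_tests: int
    vc: VarianceComponents
    degenerate: np.ndarray = field(default=None)   # SNP collinear with fixed effects

    def __post_init__(self):
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.p), dtype=bool)

    @property
    def neglog10p(self) -> np.ndarray:
        return -np.log10(np.maximum(self.p, _P_FLOOR))

    @property
    def significant(self) -> np.ndarray:
        return self.p <= self.threshold_p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom + 1,
            "pos_cM": self.pos_cM,
            "marker_id": self.marker_id,
            "beta": self.beta,
            "se": self.se,
            "stat": self.stat,
            "p": self.p,
            "neglog10p": self.neglog10p,
            "significant": self.significant.astype(int),
        })


def encode_genotypes(observed: np.ndarray) -> EncodedGenotypes:
    """Encode an observed marker matrix (0/1/2, missing = -1).

    Missing entries become the column mean 2p computed from non-missing
    calls; entirely missing columns are dropped with a warning.
    """
    obs = np.asarray(observed)
    miss = obs == MISSING
    n_obs = (~miss).sum(axis=0)
    dead = n_obs == 0
    if dead.any():
        warnings.warn(f"dropping {int(dead.sum())} entirely missing marker column(s)")
    kept = np.flatnonzero(~dead)
    obs = obs[:, kept]
    miss = miss[:, kept]
    x = obs.astype(np.float64)
    x[miss] = 0.0
    p = x.sum(axis=0) / (2.0 * n_obs[kept])
    x = np.where(miss, 2.0 * p[None, :], x)
    return EncodedGenotypes(x, p, kept)


def compute_grm(enc: EncodedGenotypes, ridge: float = 1e-6) -> np.ndarray:
    """VanRaden method-1 GRM: G = W W' / (2 sum p(1-p)), W column-centered.

    A small ridge is added to the diagonal for numerical invertibility.
    """
    if enc.n < 2:
        raise ValueError("GRM needs at least two individuals")
    p = enc.freqs
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic; GRM denominator is zero")
    w = enc.matrix - 2.0 * p[None, :]
    g = (w @ w.T) / denom
    g[np.diag_indices_from(g)] += ridge
    return g


def contemporary_group_design(generation: np.ndarray, sex: np.ndarray,
                              min_size: int = 2) -> np.ndarray:
    """Fixed-effect design [intercept | CG dummies] for generation-by-sex groups.

    Groups smaller than *min_size* are merged into the nearest (adjacent in
    sorted group order) level; the first level is the reference.
    """
    gen = np.asarray(generation)
    sx = np.asarray(sex)
    keys = np.array([f"{g}|{s}" for g, s in zip(gen, sx)])
    levels, codes = np.unique(keys, return_inverse=True)
    counts = np.bincount(codes)
    remap = np.arange(len(levels))
    for lv in np.flatnonzero(counts < min_size):
        others = np.flatnonzero((counts >= min_size) & (np.arange(len(levels)) != lv))
        if len(others) == 0:
            continue
        remap[lv] = others[np.argmin(np.abs(others - lv))]
    codes = remap[codes]
    _, codes = np.unique(codes, return_inverse=True)
    k = codes.max() + 1
    X = np.ones((len(codes), k))
    for j in range(1, k):
        X[:, j] = (codes == j).astype(float)
    return X


# -- REML in the eigenbasis of G --------------------------------------------

def _eig(G: np.ndarray):
    d, U = np.linalg.eigh(G)
    return np.maximum(d, 0.0), U


def _profiled_reml(yr: np.ndarray, Xr: np.ndarray, d: np.ndarray, gamma: float):
    """Restricted log-likelihood profiled over sigma_e^2 at ratio gamma,
    with V = sigma_e^2 (gamma D + I) diagonal in the eigenbasis."""
    n, p = Xr.shape
    v = gamma * d + 1.0
    wX = Xr / v[:, None]
    XtVX = Xr.T @ wX
    beta = np.linalg.solve(XtVX, wX.T @ yr)
    r = yr - Xr @ beta
    rss = float(np.sum(r * r / v))
    s2 = rss / (n - p)
    _, ld_xvx = np.linalg.slogdet(XtVX)
    ll = -0.5 * ((n - p) * (np.log(2.0 * np.pi * s2) + 1.0)
                 + np.sum(np.log(v)) + ld_xvx)
    return ll, s2


def reml_loglik(y: np.ndarray, X: np.ndarray, G: np.ndarray, gamma: float) -> float:
    """Restricted log-likelihood of the null model at variance ratio
    gamma = sigma_a^2 / sigma_e^2 (profiled over sigma_e^2)."""
    d, U = _eig(G)
    return _profiled_reml(U.T @ y, U.T @ X, d, gamma)[0]


_LOG_GAMMA_LO, _LOG_GAMMA_HI = -6.0, 6.0


def _reml_from_eig(yr, Xr, d) -> VarianceComponents:
    grid = np.linspace(_LOG_GAMMA_LO, _LOG_GAMMA_HI, 49)
    lls = np.array([_profiled_reml(yr, Xr, d, 10.0 ** lg)[0] for lg in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda lg: -_profiled_reml(yr, Xr, d, 10.0 ** lg)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8})
    log_gamma = float(res.x)
    gamma = 10.0 ** log_gamma
    ll, s2 = _profiled_reml(yr, Xr, d, gamma)
    boundary = log_gamma <= _LOG_GAMMA_LO + 1e-3 or log_gamma >= _LOG_GAMMA_HI - 1e-3
    sigma_e2 = s2
    sigma_a2 = gamma * s2
    return VarianceComponents(sigma_a2, sigma_e2, sigma_a2 / (sigma_a2 + sigma_e2),
                              log_gamma, boundary, ll)


def reml_null_fit(y: np.ndarray, cg_design: np.ndarray, G: np.ndarray) -> VarianceComponents:
    """Exact REML of y = Xb + A1 + e with Var(A1) = G sigma_a^2.

    One eigendecomposition of G plus a 1-D bounded optimization of the
    profile restricted likelihood in log10(gamma); deterministic given inputs.
    Estimates at the gamma search bounds are flagged as boundary solutions.
    """
    y = np.asarray(y, float)
    X = np.asarray(cg_design, float)
    if y.shape[0] < X.shape[1] + 2:
        raise ValueError("too few individuals for the fixed-effect design")
    d, U = _eig(G)
    return _reml_from_eig(U.T @ y, U.T @ X, d)


def _scan_rotated(yr, Xr, Sr, d, vc: VarianceComponents, degenerate_tol=1e-10):
    """GLS Wald tests of each column of Sr given fixed variance components."""
    v = vc.sigma_a2 * d + vc.sigma_e2
    sv = np.sqrt(v)
    yw = yr / sv
    Xw = Xr / sv[:, None]
    Sw = Sr / sv[:, None]
    Q, _ = np.linalg.qr(Xw)
    ry = yw - Q @ (Q.T @ yw)
    Rs = Sw - Q @ (Q.T @ Sw)
    ss = np.einsum("ij,ij->j", Rs, Rs)
    scale = np.einsum("ij,ij->j", Sw, Sw) + 1.0
    degen = ss <= degenerate_tol * scale
    ss_safe = np.where(degen, 1.0, ss)
    beta = (Rs.T @ ry) / ss_safe
    se = 1.0 / np.sqrt(ss_safe)
    stat = (beta / se) ** 2
    p = chi2.sf(stat, df=1)
    beta[degen] = 0.0
    se[degen] = np.inf
    stat[degen] = 0.0
    p[degen] = 1.0
    return beta, se, stat, p, degen


def emmax_scan(y: np.ndarray, cg_design: np.ndarray, G: np.ndarray,
               enc: EncodedGenotypes, vc: VarianceComponents,
               alpha: float = 0.05,
               marker_id=None, chrom=None, pos_cM=None) -> AssocResult:
    """Per-marker GLS scan with variance components fixed at the null fit.

    V = sigma_a^2 G + sigma_e^2 I is decorrelated once through the eigenbasis
    of G; each marker is a two-sided Wald chi-square (1 df) on its allele
    substitution effect. Markers collinear with the fixed effects get p = 1
    and a degenerate flag.
    """
    d, U = _eig(G)
    yr = U.T @ np.asarray(y, float)
    Xr = U.T @ np.asarray(cg_design, float)
    Sr = U.T @ enc.matrix
    beta, se, stat, p, degen = _scan_rotated(yr, Xr, Sr, d, vc)
    M = enc.n_markers
    p_star, _ = bonferroni_threshold(M, alpha)
    ids = marker_id if marker_id is not None else np.array(
        [f"snp{j}" for j in range(M)], dtype=object)
    chrom = chrom if chrom is not None else np.zeros(M, int)
    pos = pos_cM if pos_cM is not None else np.arange(M, dtype=float)
    return AssocResult(np.asarray(ids), np.asarray(chrom), np.asarray(pos, float),
                       beta, se, stat, p, p_star, alpha, M, vc, degen)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> tuple[float, float]:
    """Experiment-wise Bonferroni bound: (p*, -log10 p*) with p* = alpha / M."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p_star = alpha / n_tests
    return p_star, -np.log10(p_star)


class MixedModelGWAS:
    """Scan context caching everything phenotype-independent.

    The GRM, its eigendecomposition and the rotated genotype matrix depend
    only on the genotypes and fixed-effect design, so one context serves many
    phenotype vectors (different heritabilities, null replicates) cheaply.
    """

    def __init__(self, observed_markers: np.ndarray, generation: np.ndarray,
                 sex: np.ndarray, marker_id=None, chrom=None, pos_cM=None,
                 maf: float = 0.0):
        enc = encode_genotypes(observed_markers)
        poly = (enc.freqs > 0.0) & (enc.freqs < 1.0)
        if maf > 0.0:
            poly &= np.minimum(enc.freqs, 1.0 - enc.freqs) >= maf
        keep = np.flatnonzero(poly)
        self.enc = EncodedGenotypes(enc.matrix[:, keep], enc.freqs[keep],
                                    enc.kept[keep])
        sel = self.enc.kept
        self.marker_id = (np.asarray(marker_id)[sel] if marker_id is not None
                          else np.array([f"snp{j}" for j in sel], dtype=object))
        self.chrom = np.asarray(chrom)[sel] if chrom is not None else np.zeros(len(sel), int)
        self.pos_cM = (np.asarray(pos_cM)[sel] if pos_cM is not None
                       else np.arange(len(sel), dtype=float))
        self.X = contemporary_group_design(generation, sex)
        self.G = compute_grm(self.enc)
        self._d, self._U = _eig(self.G)
        self._Xr = self._U.T @ self.X
        self._Sr = self._U.T @ self.enc.matrix

    def reml(self, y: np.ndarray) -> VarianceComponents:
        return _reml_from_eig(self._U.T @ np.asarray(y, float), self._Xr, self._d)

    def scan(self, y: np.ndarray, alpha: float = 0.05,
             vc: VarianceComponents | None = None) -> AssocResult:
        yr = self._U.T @ np.asarray(y, float)
        if vc is None:
            vc = _reml_from_eig(yr, self._Xr, self._d)
        beta, se, stat, p, degen = _scan_rotated(yr, self._Xr, self._Sr, self._d, vc)
        M = self.enc.n_markers
        p_star, _ = bonferroni_threshold(M, alpha)
        return AssocResult(self.marker_id, self.chrom, self.pos_cM, beta, se,
                           stat, p, p_star, alpha, M, vc, degen)


def run_gwas(observed_markers: np.ndarray, phenotype: np.ndarray,
             generation: np.ndarray, sex: np.ndarray,
             marker_id=None, chrom=None, pos_cM=None,
             alpha: float = 0.05, maf: float = 0.0) -> AssocResult:
    """Convenience one-shot scan: encode, GRM, REML null fit, EMMAX scan."""
    ctx = MixedModelGWAS(observed_markers, generation, sex,
                         marker_id=marker_id, chrom=chrom, pos_cM=pos_cM, maf=maf)
    return ctx.scan(phenotype, alpha=alpha)
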
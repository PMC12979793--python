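"""Ensemble mechanics and thermodynamics.

Free-energy surfaces over the two dominant principal components of the
nucleosome-coordinate covariance, F(PC1, PC2) = -k_BT ln P (k_BT = 1
reduced), with local-minimum basin counting and Boltzmann entropy
S = -sum P ln P. Chain mechanics through the discrete worm-like chain:
tangent-tangent correlations C(s) = <t_i . t_{i+s}> fit to
C(s) = exp(-s b_eff / l_p), by a per-conformation lag-wise estimator and
by a pooled global fit with variance-weighted trimming of noisy long
lags. Bending rigidity K_b = k_BT l_p with k_BT = 4.114 pN nm at 300 K.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import label as cc_label
from scipy.stats import spearmanr

from .chain import NLChain

log = logging.getLogger(__name__)

__all__ = [
    "FESurface",
    "RigidityEstimate",
    "ActivityScore",
    "kabsch_align",
    "pca_fes",
    "count_basins",
    "boltzmann_entropy",
    "effective_bond_length",
    "tangent_correlations",
    "lagwise_wlc",
    "global_wlc",
    "rg_windows",
    "tss_distance_profile",
    "composite_activity",
    "KBT_PN_NM",
]

#: physical thermal energy used for rigidity conversion (pN nm, 300 K)
KBT_PN_NM = 4.114
#: cap for effectively rigid chains (nm)
LP_CAP_NM = 1e6


@dataclass
class FESurface:
    """Free-energy surface over the first two principal components."""

    edges1: np.ndarray
    edges2: np.ndarray
    P: np.ndarray               # normalised probability, sums to 1
    F: np.ndarray               # -ln P, +inf on empty bins
    explained_variance: float   # PC1+PC2 share of total variance
    basins: int | None = None
    entropy: float | None = None


@dataclass
class RigidityEstimate:
    """Worm-like-chain persistence length / bending rigidity estimate."""

    method: str
    b_eff_nm: float
    lp_nm: float
    kb_pn_nm2: float
    ci_lp: tuple[float, float]
    ci_kb: tuple[float, float]
    n: int                       # conformations (lag-wise) or kept lags (global)
    kbt_pn_nm: float = KBT_PN_NM
    capped: bool = False

    def __post_init__(self) -> None:
        if not np.isclose(self.kb_pn_nm2, self.kbt_pn_nm * self.lp_nm):
            raise ValueError("K_b must equal k_BT x l_p")


@dataclass
class ActivityScore:
    """Omics-mechanics composite across loci."""

    z_table: pd.DataFrame
    composite: pd.Series
    spearman_vs_rigidity: float


# ---------------------------------------------------------------------------
# free-energy surfaces
# ---------------------------------------------------------------------------

def kabsch_align(frames: np.ndarray, n_iter: int = 5) -> np.ndarray:
    """Iterative rigid-body alignment of all frames to their running mean.

    Frames are centred, aligned to the first frame, then re-aligned to the
    ensemble mean until it stabilises (Kabsch superposition via SVD).
    """
    x = np.asarray(frames, dtype=float).copy()
    x -= x.mean(axis=1, keepdims=True)
    ref = x[0].copy()
    for _ in range(n_iter):
        for f in range(x.shape[0]):
            h = x[f].T @ ref
            u, _, vt = np.linalg.svd(h)
            d = np.sign(np.linalg.det(u @ vt))
            r = u @ np.diag([1.0, 1.0, d]) @ vt
            x[f] = x[f] @ r
        new_ref = x.mean(axis=0)
        if np.allclose(new_ref, ref, atol=1e-10):
            break
        ref = new_ref
    return x


def pca_fes(
    frames: np.ndarray,
    grid_bins: int = 150,
    align: bool = True,
    grid_sd: float = 3.0,
) -> FESurface:
    """Project an ensemble on its two dominant principal components and
    histogram into a free-energy surface F = -ln P.

    The covariance is taken over flattened Cartesian coordinates after
    optional rigid-body alignment (unaligned covariance is dominated by
    global rotation). Grid spans +/- ``grid_sd`` standard deviations of
    each PC. Warns below 100 conformations; raises if the ensemble has no
    variance.
    """
    frames = np.asarray(frames, dtype=float)
    n_frames = frames.shape[0]
    if n_frames < 100:
        warnings.warn("fewer than 100 conformations: FES will be sparse", stacklevel=2)
    if align:
        frames = kabsch_align(frames)
    flat = frames.reshape(n_frames, -1)
    flat = flat - flat.mean(axis=0)
    if not np.any(flat):
        raise ValueError("rank-deficient ensemble: all frames identical")
    # SVD-based PCA; eigenvalues of the covariance are s^2/(n-1)
    u, s, _ = np.linalg.svd(flat, full_matrices=False)
    var = s**2
    if var[1] == 0:
        raise ValueError("ensemble varies along a single direction only")
    scores = u[:, :2] * s[:2]
    explained = float(var[:2].sum() / var.sum())
    sd1, sd2 = scores.std(axis=0)
    edges1 = np.linspace(-grid_sd * sd1, grid_sd * sd1, grid_bins + 1)
    edges2 = np.linspace(-grid_sd * sd2, grid_sd * sd2, grid_bins + 1)
    h, _, _ = np.histogram2d(scores[:, 0], scores[:, 1], bins=[edges1, edges2])
    p = h / h.sum()
    f = np.full_like(p, np.inf)
    np.log(p, out=f, where=p > 0)
    f = np.where(p > 0, -f, np.inf)
    return FESurface(edges1, edges2, p, f, explained)


def count_basins(fes: FESurface) -> int:
    """Number of local free-energy minima on the occupied grid.

    A basin is an occupied bin whose F is not exceeded by any occupied
    8-neighbour; connected plateaus of equal F count once.
    """
    f = fes.F
    occ = np.isfinite(f)
    if not occ.any():
        raise ValueError("empty free-energy surface")
    cand = occ.copy()
    n1, n2 = f.shape
    padded = np.full((n1 + 2, n2 + 2), np.inf)
    padded[1:-1, 1:-1] = np.where(occ, f, np.inf)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            nb = padded[1 + di : 1 + di + n1, 1 + dj : 1 + dj + n2]
            cand &= ~(nb < padded[1:-1, 1:-1])
    structure = np.ones((3, 3), dtype=int)
    _, n_basins = cc_label(cand, structure=structure)
    return int(n_basins)


def boltzmann_entropy(fes: FESurface) -> float:
    """S = -sum P ln P over occupied bins, in units of k_B."""
    p = fes.P[fes.P > 0]
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("P must be normalised")
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# worm-like-chain rigidity
# ---------------------------------------------------------------------------

def effective_bond_length(frames: np.ndarray) -> float:
    """Geometric mean of adjacent bead distances over all frames (nm in,
    nm out). Accounts for mixed bead composition along the fibre."""
    frames = np.asarray(frames, dtype=float)
    if frames.shape[1] < 2:
        raise ValueError("need at least 2 beads")
    d = np.linalg.norm(np.diff(frames, axis=1), axis=2)
    if np.any(d <= 0):
        raise ValueError("zero-length bond encountered")
    return float(np.exp(np.mean(np.log(d))))


def tangent_correlations(frames: np.ndarray, max_lag: int) -> np.ndarray:
    """Per-conformation tangent autocorrelations.

    Returns C with shape (n_conformations, max_lag); C[c, s-1] is the mean
    over i of t_i . t_{i+s} in conformation c.
    """
    frames = np.asarray(frames, dtype=float)
    bonds = np.diff(frames, axis=1)
    t = bonds / np.linalg.norm(bonds, axis=2, keepdims=True)
    n_conf, n_t, _ = t.shape
    if max_lag >= n_t:
        raise ValueError("max_lag must be below the tangent count")
    c = np.empty((n_conf, max_lag))
    for s in range(1, max_lag + 1):
        c[:, s - 1] = np.einsum("cij,cij->c", t[:, :-s], t[:, s:]) / (n_t - s)
    return c


def _wls_origin_slope(s: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted least squares slope of y = m s through the origin."""
    return float(np.sum(w * s * y) / np.sum(w * s * s))


def _fit_lp_pooled(c_mat: np.ndarray, b_eff: float) -> float:
    """Persistence length from conformation-averaged tangent correlations.

    The per-lag mean C(s) over conformations is fit by a log-linear
    weighted least squares through the origin, weights proportional to the
    inverse variance of ln mean C(s) (delta method), so noisy near-zero
    lags cannot bias the slope. Non-positive lags are dropped. Returns
    +inf for non-decaying correlations, nan when no lag is usable.
    """
    cbar = c_mat.mean(axis=0)
    var = c_mat.var(axis=0, ddof=1) / max(c_mat.shape[0], 2)
    s = np.arange(1, cbar.size + 1, dtype=float)
    keep = (cbar > 0) & (var > 0)
    if not keep.any():
        # noiseless degenerate case: exact exponential, equal weights
        if np.all(cbar > 0):
            m = _wls_origin_slope(s, np.log(cbar), np.ones_like(s))
            return np.inf if m >= 0 else -b_eff / m
        return np.nan
    w = cbar[keep] ** 2 / var[keep]
    m = _wls_origin_slope(s[keep], np.log(cbar[keep]), w)
    if m >= 0:
        return np.inf
    return -b_eff / m


def _percentile_ci(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    lo = float(np.percentile(samples, 50 * (1 - level)))
    hi = float(np.percentile(samples, 100 - 50 * (1 - level)))
    return lo, hi


def lagwise_wlc(
    frames: np.ndarray,
    b_eff: float | None = None,
    max_lag: int = 5,
    n_boot: int = 1000,
    seed: int = 0,
) -> RigidityEstimate:
    """Lag-wise WLC estimator over short contour lags (s = 1..max_lag).

    C(s) is computed per conformation and averaged with equal weight per
    conformation; the averaged correlations are fit to
    exp(-s b_eff / l_p) by inverse-variance-weighted log-linear least
    squares. The 95% CI is a percentile bootstrap over conformations that
    repeats the whole procedure per resample. Non-decaying (rigid-rod)
    correlations are capped at 10^6 nm and flagged.
    """
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2")
    frames = np.asarray(frames, dtype=float)
    if b_eff is None:
        b_eff = effective_bond_length(frames)
    c = tangent_correlations(frames, max_lag)
    lp = _fit_lp_pooled(c, b_eff)
    if np.isnan(lp):
        raise ValueError("no usable lag for the WLC fit")
    capped = bool(np.isinf(lp))
    if capped:
        warnings.warn("non-decaying correlations: l_p capped", stacklevel=2)
        lp = LP_CAP_NM
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, c.shape[0], c.shape[0])
        bl = _fit_lp_pooled(c[idx], b_eff)
        if not np.isnan(bl):
            boots.append(min(bl, LP_CAP_NM))
    ci = _percentile_ci(np.array(boots)) if boots else (np.nan, np.nan)
    return RigidityEstimate(
        method="lagwise",
        b_eff_nm=float(b_eff),
        lp_nm=float(lp),
        kb_pn_nm2=KBT_PN_NM * float(lp),
        ci_lp=ci,
        ci_kb=(KBT_PN_NM * ci[0], KBT_PN_NM * ci[1]),
        n=int(c.shape[0]),
        capped=capped,
    )


def _global_fit(c_mat: np.ndarray, b_eff: float, trim_frac: float) -> tuple[float, int]:
    """Pooled weighted fit; returns (l_p, kept lag count)."""
    cbar = c_mat.mean(axis=0)
    var = c_mat.var(axis=0, ddof=1) / c_mat.shape[0]
    s = np.arange(1, cbar.size + 1, dtype=float)
    keep = (cbar > 0) & (var > 0)
    w = np.zeros_like(cbar)
    w[keep] = cbar[keep] ** 2 / var[keep]  # inverse variance of ln cbar
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable lags in the global fit")
    # trim lags whose weight falls below trim_frac of the maximum; if that
    # leaves fewer than 3, backfill with the earliest usable lags (short
    # lags carry the signal; long lags have quadratic leverage through the
    # origin and must never be force-included)
    trimmed = keep & (w >= trim_frac * w[keep].max())
    if trimmed.sum() < 3:
        for lag in np.nonzero(keep)[0]:
            trimmed[lag] = True
            if trimmed.sum() >= 3:
                break
    keep = trimmed
    if keep.sum() < 3:
        raise ValueError("fewer than 3 kept lags in the global fit")
    m = _wls_origin_slope(s[keep], np.log(cbar[keep]), w[keep])
    lp = np.inf if m >= 0 else -b_eff / m
    return lp, int(keep.sum())


def global_wlc(
    frames: np.ndarray,
    b_eff: float | None = None,
    max_lag: int = 50,
    n_boot: int = 1000,
    seed: int = 0,
    trim_frac: float = 0.05,
) -> RigidityEstimate:
    """Global ensemble-fit WLC estimator.

    Tangent correlations pooled over conformations are fit simultaneously
    across lags, weighted by the inverse variance of ln C(s), with lags
    whose weight falls below ``trim_frac`` of the maximum trimmed out
    (noisy long lags). The reported n is the kept lag count; the CI is a
    percentile bootstrap over conformations.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 conformations")
    if b_eff is None:
        b_eff = effective_bond_length(frames)
    max_lag = min(max_lag, frames.shape[1] - 2)
    c = tangent_correlations(frames, max_lag)
    lp, kept = _global_fit(c, b_eff, trim_frac)
    capped = bool(np.isinf(lp))
    if capped:
        warnings.warn("non-decaying pooled correlations: l_p capped", stacklevel=2)
        lp = LP_CAP_NM
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, c.shape[0], c.shape[0])
        try:
            bl, _ = _global_fit(c[idx], b_eff, trim_frac)
        except ValueError:
            continue
        boots.append(min(bl, LP_CAP_NM))
    ci = _percentile_ci(np.array(boots)) if boots else (np.nan, np.nan)
    return RigidityEstimate(
        method="global",
        b_eff_nm=float(b_eff),
        lp_nm=float(lp),
        kb_pn_nm2=KBT_PN_NM * float(lp),
        ci_lp=ci,
        ci_kb=(KBT_PN_NM * ci[0], KBT_PN_NM * ci[1]),
        n=kept,
        capped=capped,
    )


# ---------------------------------------------------------------------------
# window statistics and profiles
# ---------------------------------------------------------------------------

def rg_windows(
    frames_nm: np.ndarray,
    chain: NLChain,
    window_bp: int = 10_000,
    step_bp: int = 1_000,
) -> pd.DataFrame:
    """Sliding-window radius of gyration.

    For each window the R_g of beads whose genomic midpoint falls inside
    is computed per frame; the table holds window start, mean and SD (nm).
    """
    if window_bp > chain.region.length:
        raise ValueError("window exceeds region")
    frames = np.asarray(frames_nm, dtype=float)
    mid = chain.midpoints
    rows = []
    start = chain.region.start
    while start + window_bp <= chain.region.end:
        sel = (mid >= start) & (mid < start + window_bp)
        if not sel.any():
            raise ValueError(f"empty window at {start}")
        sub = frames[:, sel, :]
        cen = sub - sub.mean(axis=1, keepdims=True)
        rg = np.sqrt((cen**2).sum(axis=2).mean(axis=1))
        rows.append((start, float(rg.mean()), float(rg.std())))
        start += step_bp
    return pd.DataFrame(rows, columns=["window_start", "rg_mean_nm", "rg_sd_nm"])


def tss_distance_profile(
    frames_nm: np.ndarray,
    chain: NLChain,
    tss_bp: int,
    segment_bp: int = 200,
) -> pd.DataFrame:
    """Mean spatial distance of every 200-bp segment from the TSS segment.

    Segments are genomic bins of ``segment_bp``; each frame contributes the
    distance between segment centres of mass and the TSS-containing
    segment's centre of mass.
    """
    region = chain.region
    if not (region.start <= tss_bp < region.end):
        raise ValueError("TSS outside region")
    frames = np.asarray(frames_nm, dtype=float)
    mid = chain.midpoints
    n_seg = region.n_bins(segment_bp)
    seg = np.clip(((mid - region.start) // segment_bp).astype(int), 0, n_seg - 1)
    tss_seg = int((tss_bp - region.start) // segment_bp)
    coms = np.zeros((frames.shape[0], n_seg, 3))
    for b in range(n_seg):
        sel = seg == b
        if not sel.any():
            raise ValueError(f"empty segment {b}")
        coms[:, b] = frames[:, sel].mean(axis=1)
    d = np.linalg.norm(coms - coms[:, tss_seg : tss_seg + 1, :], axis=2)
    offsets = (np.arange(n_seg) - tss_seg) * segment_bp
    return pd.DataFrame(
        {
            "offset_bp": offsets,
            "mean_distance_nm": d.mean(axis=0),
            "sd_distance_nm": d.std(axis=0),
        }
    )


# ---------------------------------------------------------------------------
# omics-mechanics composite
# ---------------------------------------------------------------------------

REPRESSIVE_MARKS = ("h3k27me3",)


def composite_activity(
    omics: pd.DataFrame, rigidity: pd.Series
) -> ActivityScore:
    """Composite activity score and its Spearman trend versus rigidity.

    Each omics column is z-scored across loci (sample SD), signs aligned
    so positive means more active (repressive marks flipped); the
    composite is the per-locus mean of aligned z-scores. Requires >= 2
    loci; warns below 4 (Spearman is then fragile).
    """
    if omics.shape[0] < 2:
        raise ValueError("z-scores undefined for a single locus")
    if omics.shape[0] < 4:
        warnings.warn("fewer than 4 loci: Spearman trend is fragile", stacklevel=2)
    z = (omics - omics.mean()) / omics.std(ddof=1)
    for col in z.columns:
        if col.lower() in REPRESSIVE_MARKS:
            z[col] = -z[col]
    composite = z.mean(axis=1)
    rig = rigidity.loc[composite.index]
    rho = float(spearmanr(composite.to_numpy(), rig.to_numpy())[0])
    return ActivityScore(z_table=z, composite=composite, spearman_vs_rigidity=rho)
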
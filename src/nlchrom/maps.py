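"""Contact-map construction and validation analyses.

Simulated ensembles are coarse-grained to 200-bp or 5-kb contact maps
(two bins are in contact when their bead centre-of-mass distance falls
below a cutoff, by default 2.5 nucleosome diameters at 200 bp). Maps are
compared through P(s) scaling slopes, Pearson/Spearman correlation,
distance-corrected Pearson correlation (dcPCC), insulation-score boundary
detection, boundary Venn overlap, and chromatin-state contact enrichment
(effective Flory-Huggins chi).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import pearsonr, spearmanr

from .chain import NLChain, NUCLEOSOME_DIAMETER_NM, DOMAIN_RADIUS_NM
from .core import ContactMap, Trajectory

log = logging.getLogger(__name__)

__all__ = [
    "BoundarySet",
    "StateEnrichment",
    "contact_map_from_frames",
    "coarse_grain_ensemble",
    "coarse_grain_contacts",
    "ps_curve",
    "correlate_maps",
    "dc_pearson",
    "insulation_score",
    "insulation_boundaries",
    "boundary_overlap",
    "state_contact_enrichment",
]


@dataclass
class BoundarySet:
    """Insulation-minimum domain boundaries of one contact map."""

    boundaries: np.ndarray        # sorted bin indices
    score: np.ndarray             # insulation profile (NaN at excluded edges)
    window: int
    prominence: float

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be sorted and unique")

    def __len__(self) -> int:
        return len(self.boundaries)


@dataclass
class StateEnrichment:
    """Contact-frequency shares by chromatin-state pair class."""

    p_aa: float
    p_ab: float
    p_bb: float
    chi_eff: float


def contact_map_from_frames(frames: np.ndarray, cutoff: float) -> np.ndarray:
    """Contact frequency over frames: fraction of frames in which each
    position pair lies within ``cutoff``. frames: (F, N, 3)."""
    frames = np.asarray(frames, dtype=float)
    f, n, _ = frames.shape
    acc = np.zeros((n, n))
    for fr in frames:
        d = np.linalg.norm(fr[:, None, :] - fr[None, :, :], axis=-1)
        acc += d <= cutoff
    return acc / f


def coarse_grain_ensemble(
    traj: Trajectory, chain: NLChain, resolution: int
) -> tuple[np.ndarray, np.ndarray]:
    """Bin NL beads by genomic midpoint and return per-frame bin COMs.

    Returns (coms with shape (F, n_bins, 3) in the trajectory's units,
    bin index per bead). Empty bins are disallowed (the chain tiles the
    region, so every bin holds at least one bead at NL resolutions).
    """
    mid = chain.midpoints
    n_bins = chain.region.n_bins(resolution)
    bins = np.clip(
        np.floor((mid - chain.region.start) / resolution).astype(int), 0, n_bins - 1
    )
    counts = np.bincount(bins, minlength=n_bins)
    if np.any(counts == 0):
        raise ValueError("empty coarse-grained bin; resolution too fine for chain")
    coms = np.zeros((traj.n_frames, n_bins, 3))
    for c in range(3):
        w = traj.frames[..., c]
        for b in range(n_bins):
            coms[:, b, c] = w[:, bins == b].mean(axis=1)
    return coms, bins


def coarse_grain_contacts(
    traj: Trajectory,
    chain: NLChain,
    resolution: int = 200,
    cutoff_nm: float | None = None,
) -> ContactMap:
    """Ensemble-averaged contact map of an NL trajectory at a target
    resolution.

    Default cutoffs: 2.5 nucleosome diameters (25 nm) at fine (< 1 kb)
    resolutions; 1.5 domain envelope radii (135 nm) at coarse resolutions,
    where the contact partner is a whole 5-kb domain.
    """
    if traj.n_frames == 0:
        raise ValueError("empty ensemble")
    if cutoff_nm is None:
        cutoff_nm = (
            2.5 * NUCLEOSOME_DIAMETER_NM if resolution < 1000 else 1.5 * DOMAIN_RADIUS_NM
        )
    scale = chain.nm_per_sigma if traj.units == "reduced" else 1.0
    coms, _ = coarse_grain_ensemble(traj, chain, resolution)
    m = contact_map_from_frames(coms * scale, cutoff_nm)
    np.fill_diagonal(m, 1.0)
    return ContactMap(chain.region, resolution, m, balanced=False, source="simulated")


def ps_curve(
    cmap: ContactMap | np.ndarray,
    fit_ranges: list[tuple[int, int]] | None = None,
    n_geom_bins: int = 20,
):
    """Mean contact probability versus genomic separation with log-log slopes.

    Returns (s values, mean P(s), list of fitted slopes — one per fit
    range, or a single whole-range slope when none are given). s values
    are geometric-binned diagonal separations; zero / empty bins are
    dropped from fits.
    """
    m = cmap.matrix if isinstance(cmap, ContactMap) else np.asarray(cmap)
    n = m.shape[0]
    if n < 8:
        raise ValueError("map too small for P(s) analysis (N >= 8)")
    s_vals = np.arange(1, n)
    p_s = np.array([np.diagonal(m, offset=d).mean() for d in s_vals])
    if not np.any(p_s > 0):
        raise ValueError("all diagonals are zero")
    # geometric binning for reporting
    edges = np.unique(
        np.geomspace(1, n - 1, n_geom_bins + 1).round().astype(int)
    )
    sb, pb = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (s_vals >= lo) & (s_vals <= hi) & (p_s > 0)
        if sel.any():
            sb.append(np.exp(np.mean(np.log(s_vals[sel]))))
            pb.append(p_s[sel].mean())
    sb, pb = np.array(sb), np.array(pb)

    if fit_ranges is None:
        fit_ranges = [(1, n - 1)]
    slopes = []
    for lo, hi in fit_ranges:
        sel = (s_vals >= lo) & (s_vals <= hi) & (p_s > 0)
        if sel.sum() < 2:
            slopes.append(np.nan)
            continue
        slope = np.polyfit(np.log(s_vals[sel]), np.log(p_s[sel]), 1)[0]
        slopes.append(float(slope))
    return sb, pb, slopes


def _upper_triangle(m: np.ndarray, k: int = 1) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=k)
    return m[iu]


def correlate_maps(map_a, map_b) -> tuple[float, float]:
    """Pearson and Spearman correlation over the upper triangle.

    Bins masked with NaN in either map are excluded."""
    a = map_a.matrix if isinstance(map_a, ContactMap) else np.asarray(map_a)
    b = map_b.matrix if isinstance(map_b, ContactMap) else np.asarray(map_b)
    if a.shape != b.shape:
        raise ValueError("maps must have the same shape")
    x, y = _upper_triangle(a), _upper_triangle(b)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance map")
    return float(pearsonr(x, y)[0]), float(spearmanr(x, y)[0])


def dc_pearson(map_a, map_b, min_diag_entries: int = 3) -> float:
    """Distance-corrected Pearson correlation.

    Each genomic-separation diagonal's mean is subtracted from both maps,
    removing the shared distance-decay profile; Pearson is then computed
    over the retained off-diagonal entries. Diagonals with fewer than
    ``min_diag_entries`` entries are skipped.
    """
    a = (map_a.matrix if isinstance(map_a, ContactMap) else np.asarray(map_a)).copy()
    b = (map_b.matrix if isinstance(map_b, ContactMap) else np.asarray(map_b)).copy()
    if a.shape != b.shape:
        raise ValueError("maps must have the same shape")
    n = a.shape[0]
    xs, ys = [], []
    for d in range(1, n):
        da = np.diagonal(a, offset=d)
        db = np.diagonal(b, offset=d)
        if da.size < min_diag_entries:
            continue
        xs.append(da - da.mean())
        ys.append(db - db.mean())
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero residual variance")
    return float(pearsonr(x, y)[0])


def insulation_score(m: np.ndarray, window: int) -> np.ndarray:
    """Mean contact intensity in the window x window box straddling each
    bin; NaN within ``window`` bins of the map edges."""
    n = m.shape[0]
    score = np.full(n, np.nan)
    for i in range(window, n - window):
        score[i] = m[i - window : i, i + 1 : i + 1 + window].mean()
    return score


def insulation_boundaries(
    cmap, window: int = 10, prominence: float = 0.1
) -> BoundarySet:
    """Boundaries = local minima of the insulation score with relative
    prominence >= ``prominence`` (as a fraction of the score range)."""
    m = cmap.matrix if isinstance(cmap, ContactMap) else np.asarray(cmap)
    n = m.shape[0]
    if window < 2:
        raise ValueError("window must be >= 2 bins")
    if window >= n / 2:
        raise ValueError("window too large for map")
    score = insulation_score(m, window)
    valid = score[np.isfinite(score)]
    rng = float(valid.max() - valid.min())
    if rng == 0:
        return BoundarySet(np.array([], dtype=int), score, window, prominence)
    inner = score[window : n - window]
    peaks, _ = find_peaks(-inner, prominence=prominence * rng)
    return BoundarySet(peaks + window, score, window, prominence)


def boundary_overlap(set_a, set_b, tolerance_bins: int = 1):
    """Greedy nearest matching of two boundary sets within a tolerance.

    Returns (matched count, only_a, only_b, matched fraction relative to
    the smaller set; 1.0 when both sets are empty)."""
    a = list(set_a.boundaries if isinstance(set_a, BoundarySet) else set_a)
    b = list(set_b.boundaries if isinstance(set_b, BoundarySet) else set_b)
    matched = 0
    remaining = list(b)
    for x in a:
        if not remaining:
            break
        j = int(np.argmin([abs(x - y) for y in remaining]))
        if abs(x - remaining[j]) <= tolerance_bins:
            matched += 1
            remaining.pop(j)
    only_a = len(a) - matched
    only_b = len(b) - matched
    denom = min(len(a), len(b))
    frac = matched / denom if denom else 1.0
    return matched, only_a, only_b, float(frac)


def state_contact_enrichment(cmap, states: np.ndarray) -> StateEnrichment:
    """Contact-weight shares by state pair class, normalised by class
    abundance, and the effective Flory-Huggins chi.

    ``states`` is a binary per-bin label vector (1 = active, 0 = inactive).
    chi_eff = -1/2 ln(P_AB^2 / (P_AA P_BB)); positive chi means like-like
    contact preference. Invariant under swapping the two labels.
    """
    m = cmap.matrix if isinstance(cmap, ContactMap) else np.asarray(cmap)
    states = np.asarray(states).astype(bool)
    if states.size != m.shape[0]:
        raise ValueError("state labels must match bin count")
    if states.all() or not states.any():
        raise ValueError("both states must be present")
    iu, ju = np.triu_indices(m.shape[0], k=1)
    w = m[iu, ju]
    sa, sb = states[iu], states[ju]
    classes = {
        "aa": sa & sb,
        "ab": sa ^ sb,
        "bb": ~sa & ~sb,
    }
    # contact weight per class, normalised by the number of pairs in the class
    dens = {k: w[v].sum() / max(v.sum(), 1) for k, v in classes.items()}
    total = sum(dens.values())
    p_aa, p_ab, p_bb = dens["aa"] / total, dens["ab"] / total, dens["bb"] / total
    if p_ab <= 0 or p_aa <= 0 or p_bb <= 0:
        raise ValueError("degenerate pair-class contact frequencies")
    chi = -0.5 * float(np.log(p_ab**2 / (p_aa * p_bb)))
    return StateEnrichment(float(p_aa), float(p_ab), float(p_bb), chi)
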
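"""Synthetic input generators.

Everything the pipeline consumes can be generated here: balanced contact
maps with TAD-like block structure and power-law distance decay,
nucleosome arrays with tunable repeat length / fuzziness / NDRs, worm-like
chain ensembles of known persistence length (an analytic oracle for the
rigidity estimators), and 3D point clouds with planted blob clusters.

All generators are pure functions of (spec, seed).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .core import (
    ContactMap,
    GenomicRegion,
    NucleosomeAnnotation,
    Trajectory,
    NUCLEOSOME_CORE_BP,
)
from .preprocess import sinkhorn_balance

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticMapSpec",
    "NucleosomeArraySpec",
    "gen_hic",
    "gen_nucleosomes",
    "gen_wlc",
    "gen_blob_cloud",
]


@dataclass
class SyntheticMapSpec:
    """Recipe for a balanced synthetic contact map.

    ``P_ij ∝ |i-j|^-alpha``, multiplied by ``block_enrichment`` when i and j
    fall in the same block, with multiplicative lognormal noise of the given
    coefficient of variation, then Sinkhorn-balanced to unit row sums.
    """

    n_bins: int
    block_boundaries: tuple[int, ...] = ()
    block_enrichment: float = 4.0
    alpha: float = 1.0
    noise_cv: float = 0.0
    seed: int = 0
    region: GenomicRegion | None = None
    resolution: int = 5000

    def __post_init__(self) -> None:
        if self.n_bins < 4:
            raise ValueError("n_bins must be >= 4")
        bb = tuple(self.block_boundaries)
        if any(b2 <= b1 for b1, b2 in zip(bb, bb[1:])) or any(
            not (1 <= b <= self.n_bins - 1) for b in bb
        ):
            raise ValueError("block boundaries must be strictly increasing in [1, n_bins-1]")
        if self.alpha <= 0:
            raise ValueError("decay exponent alpha must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.region is None:
            self.region = GenomicRegion("chrS", 0, self.n_bins * self.resolution)


def _block_ids(n_bins: int, boundaries: tuple[int, ...]) -> np.ndarray:
    ids = np.zeros(n_bins, dtype=int)
    for b in boundaries:
        ids[b:] += 1
    return ids


def gen_hic(spec: SyntheticMapSpec, balance: bool = True) -> ContactMap:
    """Generate a synthetic balanced contact map from a SyntheticMapSpec."""
    n = spec.n_bins
    rng = np.random.default_rng(spec.seed)
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    s = np.abs(i - j).astype(float)
    with np.errstate(divide="ignore"):
        m = np.where(s > 0, s ** (-spec.alpha), 0.0)
    blocks = _block_ids(n, spec.block_boundaries)
    same = blocks[:, None] == blocks[None, :]
    m = np.where(same & (s > 0), m * spec.block_enrichment, m)
    if spec.noise_cv > 0:
        s_ln = np.sqrt(np.log1p(spec.noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * s_ln**2, sigma=s_ln, size=(n, n))
        noise = np.triu(noise, 1)
        noise = noise + noise.T
        m = np.where(s > 0, m * noise, m)
    m = 0.5 * (m + m.T)
    # diagonal = row max, the strongest entry of each row
    np.fill_diagonal(m, m.max(axis=1))
    if balance:
        m, _ = sinkhorn_balance(m, tol=1e-10)
    return ContactMap(
        spec.region, spec.resolution, m, balanced=balance, source="simulated"
    )


@dataclass
class NucleosomeArraySpec:
    """Recipe for a synthetic nucleosome array.

    Dyads sit on a grid of the nucleosome repeat length (NRL) with Gaussian
    positional jitter ("fuzziness"); nucleosome-depleted regions (NDRs)
    exclude dyads entirely.
    """

    region: GenomicRegion
    nrl: int = 200
    jitter_sd: float = 0.0
    ndrs: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrl < NUCLEOSOME_CORE_BP + 10:
            raise ValueError(f"NRL must be >= {NUCLEOSOME_CORE_BP + 10} bp")
        if self.jitter_sd < 0:
            raise ValueError("jitter SD must be >= 0")
        covered = sum(
            max(0, min(e, self.region.end) - max(s, self.region.start))
            for s, e in self.ndrs
        )
        if covered >= self.region.length:
            raise ValueError("NDRs cover the whole region")


def _in_ndr(pos: int, ndrs) -> bool:
    return any(s <= pos < e for s, e in ndrs)


def gen_nucleosomes(spec: NucleosomeArraySpec) -> NucleosomeAnnotation:
    """Place dyads on the NRL grid with Gaussian jitter.

    Jittered dyads that would violate the 147-bp core spacing are
    redrawn (up to a retry cap, then snapped to the closest admissible
    position); dyads inside NDRs, or whose 142-bp bead would overhang the
    region, are dropped.
    """
    rng = np.random.default_rng(spec.seed)
    region = spec.region
    half = 71  # nucleosome bead half-span: cores must fit inside the region
    grid = np.arange(region.start + half, region.end - half + 1, spec.nrl)
    dyads: list[int] = []
    occ: list[float] = []
    for g in grid:
        if _in_ndr(int(g), spec.ndrs):
            continue
        placed = None
        for _ in range(100):
            d = int(round(g + rng.normal(0.0, spec.jitter_sd))) if spec.jitter_sd else int(g)
            if d - half < region.start or d + half > region.end:
                continue
            if _in_ndr(d, spec.ndrs):
                continue
            if dyads and d - dyads[-1] < NUCLEOSOME_CORE_BP:
                continue
            placed = d
            break
        if placed is None and spec.jitter_sd:
            # snap to the closest admissible position on the grid side
            d = max(int(g), (dyads[-1] + NUCLEOSOME_CORE_BP) if dyads else int(g))
            if (
                d + half <= region.end
                and d - half >= region.start
                and not _in_ndr(d, spec.ndrs)
            ):
                placed = d
        if placed is not None:
            dyads.append(placed)
            occ.append(float(rng.uniform(1.0, 2.0)))
    if not dyads:
        raise ValueError("no dyads could be placed")
    return NucleosomeAnnotation(region, np.array(dyads), np.array(occ))


def _kappa_for_mean_cos(target: float) -> float:
    """Concentration of p(cos t) ∝ exp(kappa cos t) with Langevin-function
    mean coth(k) - 1/k equal to ``target``."""
    if target <= 0:
        raise ValueError("mean cosine must be positive for a WLC step")
    langevin = lambda k: 1.0 / np.tanh(k) - 1.0 / k
    lo, hi = 1e-8, 1e8
    if langevin(hi) < target:  # effectively rigid
        return hi
    return brentq(lambda k: langevin(k) - target, lo, hi, xtol=1e-12, rtol=1e-12)


def gen_wlc(
    n_beads: int,
    bond_length: float,
    persistence_length: float,
    n_chains: int,
    seed: int = 0,
) -> Trajectory:
    """Sample discrete worm-like chains with exact tangent statistics.

    Each step rotates the previous tangent by a polar angle drawn from
    p(cos θ) ∝ exp(κ cos θ) with κ set so ⟨cos θ⟩ = exp(-b/ℓp), and a
    uniform azimuth. The Markov construction gives
    ⟨t_i · t_{i+s}⟩ = exp(-s b/ℓp) exactly in expectation — the analytic
    ground truth for persistence-length estimators. ``persistence_length``
    = inf gives straight rods. Coordinates are in the same length unit as
    ``bond_length`` (nm throughout the package).
    """
    if n_beads < 3:
        raise ValueError("n_beads must be >= 3")
    if bond_length <= 0 or persistence_length <= 0:
        raise ValueError("bond length and persistence length must be > 0")
    rng = np.random.default_rng(seed)
    n_steps = n_beads - 1
    coords = np.zeros((n_chains, n_beads, 3))
    if np.isinf(persistence_length):
        cos_t = np.ones((n_chains, n_steps - 1))
    else:
        target = float(np.exp(-bond_length / persistence_length))
        kappa = _kappa_for_mean_cos(target)
        u = rng.random((n_chains, n_steps - 1))
        # inverse CDF of exp(kappa x) on [-1, 1]
        cos_t = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
        cos_t = np.clip(cos_t, -1.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * np.pi, (n_chains, n_steps - 1))

    t = np.zeros((n_chains, 3))
    t[:, 2] = 1.0  # initial tangent along z
    coords[:, 1] = coords[:, 0] + bond_length * t
    for step in range(1, n_steps):
        c = cos_t[:, step - 1]
        s = np.sqrt(np.maximum(0.0, 1.0 - c**2))
        # orthonormal frame around current tangent
        ref = np.where(np.abs(t[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
        e1 = np.cross(t, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(t, e1)
        p = phi[:, step - 1]
        t = (
            c[:, None] * t
            + s[:, None] * (np.cos(p)[:, None] * e1 + np.sin(p)[:, None] * e2)
        )
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        coords[:, step + 1] = coords[:, step] + bond_length * t
    return Trajectory(frames=coords, chain_id="wlc", units="nm", seed=seed)


def gen_blob_cloud(
    k: int,
    points_per_blob: int,
    blob_sd: float,
    centroid_spacing: float,
    noise_points: int = 0,
    seed: int = 0,
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Plant k Gaussian clusters plus uniform noise; return (coords, labels).

    Labels are 0..k-1 for cluster members and -1 for noise. ``axis_ratios``
    scale the per-axis SDs for anisotropic (ellipsoidal) blobs. Centroids
    are laid out on a line with the requested spacing; spacing below
    4×blob_sd triggers a separability warning, not an error.
    """
    if centroid_spacing < 4.0 * blob_sd:
        warnings.warn(
            "centroid spacing < 4 x blob SD: clusters may not be separable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    sds = blob_sd * np.asarray(axis_ratios, dtype=float)
    pts = []
    labels = []
    for c in range(k):
        center = np.array([c * centroid_spacing, 0.0, 0.0])
        pts.append(center + rng.normal(0.0, 1.0, (points_per_blob, 3)) * sds)
        labels.append(np.full(points_per_blob, c))
    if noise_points:
        lo = -centroid_spacing if k > 1 else -10 * blob_sd
        hi = k * centroid_spacing if k > 1 else 10 * blob_sd
        pts.append(rng.uniform(lo, hi, (noise_points, 3)))
        labels.append(np.full(noise_points, -1))
    return np.vstack(pts), np.concatenate(labels).astype(int)
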
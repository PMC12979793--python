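"""Nucleosome-blob detection and morphometrics.

Blobs are dense clusters of nucleosome bead centres found by DBSCAN in
each conformation. Morphometrics cover convex-hull surface area (with a
lognormal fit across the ensemble), ellipsoid eccentricity from the
principal axes of the member-coordinate covariance, a compaction index
(local fixed-radius density over frame background density), inter-blob
centroid spacing and its radial distribution function, per-nucleosome
mean blob-size profiles, genomic packing density, and intra-blob contact
frequency maps.

All coordinates entering this module are in nm.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, cKDTree
from scipy.stats import lognorm
from sklearn.cluster import DBSCAN

from .chain import NLChain, NUCLEOSOME_DIAMETER_NM

log = logging.getLogger(__name__)

__all__ = [
    "Blob",
    "detect_blobs",
    "blob_morphometrics",
    "compaction_index",
    "blob_spatial_stats",
    "intra_blob_contact_map",
    "blob_size_profile",
    "packing_density",
    "fit_lognormal",
    "radius_of_gyration",
]

NM2_PER_UM2 = 1e6
NM3_PER_UM3 = 1e9


@dataclass
class Blob:
    """One DBSCAN cluster of nucleosomes in one conformation."""

    members: np.ndarray           # nucleosome indices (into the nucleosome list)
    centroid: np.ndarray          # nm
    frame: int = 0
    hull_area_um2: float | None = None
    bp_content: float | None = None
    semi_axes_nm: np.ndarray | None = None
    eccentricity: float | None = None
    degenerate: bool = False
    compaction: float | None = None
    core_fraction: float | None = None
    rg_nm: float | None = None
    rho_fixed: float | None = None

    @property
    def size(self) -> int:
        return int(self.members.size)


def radius_of_gyration(coords: np.ndarray) -> float:
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c**2).sum(axis=1).mean()))


def detect_blobs(
    coords: np.ndarray,
    eps: float = 2.0 * NUCLEOSOME_DIAMETER_NM,
    min_pts: int = 3,
    frame: int = 0,
) -> tuple[list[Blob], np.ndarray]:
    """DBSCAN over nucleosome centres (nm). Returns (blobs, labels).

    Defaults: eps = two nucleosome diameters (20 nm), min_pts = 3, chosen
    so a 3-4 nucleosome aggregate (~600-700 bp) is detectable. Labels
    follow scikit-learn conventions (-1 = noise); results are
    deterministic given the input order.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < min_pts:
        raise ValueError("fewer nucleosomes than min_pts")
    if eps <= 0 or min_pts < 3:
        raise ValueError("eps must be > 0 and min_pts >= 3")
    db = DBSCAN(eps=eps, min_samples=min_pts).fit(coords)
    labels = db.labels_
    core = np.zeros(coords.shape[0], dtype=bool)
    core[db.core_sample_indices_] = True
    blobs = []
    for lab in sorted(set(labels) - {-1}):
        idx = np.nonzero(labels == lab)[0]
        b = Blob(
            members=idx,
            centroid=coords[idx].mean(axis=0),
            frame=frame,
            core_fraction=float(core[idx].mean()),
            rg_nm=radius_of_gyration(coords[idx]),
        )
        blobs.append(b)
    return blobs, labels


def blob_morphometrics(blob: Blob, coords: np.ndarray, bp_per_nucleosome: float = 142.0) -> Blob:
    """Fill hull surface area (um^2), bp content, principal semi-axes (nm)
    and eccentricity for one blob.

    Semi-axes are sqrt of the member-coordinate covariance eigenvalues
    (x2 for full axes); eccentricity e = sqrt(1 - (b/a)^2) from the
    extreme axes. Collinear/coplanar blobs are flagged degenerate with
    hull area undefined.
    """
    pts = np.asarray(coords, dtype=float)[blob.members]
    blob.bp_content = float(blob.size * bp_per_nucleosome)
    cov = np.cov(pts.T) if pts.shape[0] > 1 else np.zeros((3, 3))
    eig = np.sort(np.clip(np.linalg.eigvalsh(cov), 0.0, None))[::-1]
    blob.semi_axes_nm = np.sqrt(eig)
    a, b = blob.semi_axes_nm[0], blob.semi_axes_nm[-1]
    if a <= 0:
        blob.eccentricity = 0.0
        blob.degenerate = True
    elif b <= 1e-12 * a:
        blob.eccentricity = 1.0
        blob.degenerate = True
    else:
        blob.eccentricity = float(np.sqrt(1.0 - (b / a) ** 2))
    if pts.shape[0] >= 4 and not blob.degenerate:
        try:
            hull = ConvexHull(pts)
            blob.hull_area_um2 = float(hull.area / NM2_PER_UM2)
        except Exception:  # coplanar members: no 3D hull
            log.info("blob of %d members has no 3D hull (coplanar)", blob.size)
            blob.degenerate = True
    return blob


def _local_density(
    coords: np.ndarray, centers: np.ndarray, r0: float, tree: cKDTree | None = None
) -> float:
    """Mean count density inside r0-spheres around ``centers``."""
    tree = tree or cKDTree(coords)
    counts = tree.query_ball_point(centers, r0, return_length=True)
    vol = 4.0 / 3.0 * np.pi * r0**3
    return float(np.mean(counts) / vol)


def compaction_index(
    coords: np.ndarray,
    blobs: list[Blob],
    core_fraction_min: float = 0.8,
    rg_range_nm: tuple[float, float] = (10.0, 40.0),
    top_quartile: bool = True,
) -> list[Blob]:
    """Compaction index CI = rho_fixed / rho_bg for the retained blobs.

    r0 = 2x the frame-wide median nucleosome nearest-neighbour distance;
    rho_fixed is the mean count density in r0-spheres around blob members,
    rho_bg the same statistic over all nucleosomes. Retains blobs with
    core-member fraction >= 0.8 and 10 <= R_g <= 40 nm; per frame the top
    quartile by rho_fixed is kept. Returns the retained blobs with
    ``compaction`` set.
    """
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords)
    nn = tree.query(coords, k=2)[0][:, 1]
    r0 = 2.0 * float(np.median(nn))
    rho_bg = _local_density(coords, coords, r0, tree)
    kept = []
    for b in blobs:
        if b.core_fraction is not None and b.core_fraction < core_fraction_min:
            continue
        rg = b.rg_nm if b.rg_nm is not None else radius_of_gyration(coords[b.members])
        if not (rg_range_nm[0] <= rg <= rg_range_nm[1]):
            continue
        b.rho_fixed = _local_density(coords, coords[b.members], r0, tree)
        b.compaction = float(b.rho_fixed / rho_bg)
        kept.append(b)
    if not kept:
        log.info("no blob passed the compaction filters")
        return []
    if top_quartile and len(kept) > 1:
        cut = np.quantile([b.rho_fixed for b in kept], 0.75)
        kept = [b for b in kept if b.rho_fixed >= cut]
    return kept


def _sample_in_hull(points: np.ndarray, n: int, rng) -> np.ndarray:
    """Uniform samples inside the convex hull of ``points`` (rejection)."""
    delau = Delaunay(points)
    lo, hi = points.min(axis=0), points.max(axis=0)
    out = []
    need = n
    while need > 0:
        cand = rng.uniform(lo, hi, (max(4 * need, 128), 3))
        inside = cand[delau.find_simplex(cand) >= 0]
        out.append(inside[:need])
        need -= len(inside[:need])
    return np.vstack(out)


def blob_spatial_stats(
    blobs_per_frame: list[list[Blob]],
    r_edges: np.ndarray | None = None,
    n_controls: int = 20,
    seed: int = 0,
):
    """Inter-blob centroid distances pooled over frames, their median, and
    the centroid RDF normalised by a Poisson process of equal intensity
    inside the pooled-centroid convex hull.

    Frames with a single blob are skipped for distances. Returns
    (distances, median, (r centers, g(r))).
    """
    dists = []
    centroids = []
    for blobs in blobs_per_frame:
        cs = np.array([b.centroid for b in blobs])
        if len(cs):
            centroids.append(cs)
        if len(cs) < 2:
            continue
        iu, ju = np.triu_indices(len(cs), k=1)
        dists.append(np.linalg.norm(cs[iu] - cs[ju], axis=1))
    if not dists:
        return np.array([]), np.nan, (np.array([]), np.array([]))
    dists = np.concatenate(dists)
    med = float(np.median(dists))
    allc = np.vstack(centroids)
    if r_edges is None:
        r_edges = np.linspace(0, np.quantile(dists, 0.99), 25)
    hist, _ = np.histogram(dists, bins=r_edges)
    rng = np.random.default_rng(seed)
    ctrl = np.zeros(len(r_edges) - 1)
    if allc.shape[0] >= 5:
        try:
            for _ in range(n_controls):
                sim = _sample_in_hull(allc, allc.shape[0], rng)
                iu, ju = np.triu_indices(sim.shape[0], k=1)
                d = np.linalg.norm(sim[iu] - sim[ju], axis=1)
                h, _ = np.histogram(d, bins=r_edges)
                ctrl += h
            ctrl /= n_controls
            # scale to the observed pair count
            npairs = hist.sum()
            ctrl = ctrl * (npairs / max(ctrl.sum(), 1e-12))
        except Exception:
            ctrl[:] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(ctrl > 0, hist / ctrl, np.nan)
    centers = 0.5 * (r_edges[:-1] + r_edges[1:])
    return dists, med, (centers, g)


def intra_blob_contact_map(
    blobs_per_frame: list[list[Blob]], n_nucleosomes: int
) -> np.ndarray:
    """Frequency over frames of each nucleosome pair sharing a blob."""
    acc = np.zeros((n_nucleosomes, n_nucleosomes))
    n_frames = len(blobs_per_frame)
    for blobs in blobs_per_frame:
        for b in blobs:
            m = b.members
            acc[np.ix_(m, m)] += 1
    acc /= max(n_frames, 1)
    np.fill_diagonal(acc, 0.0)
    return acc


def blob_size_profile(
    blobs_per_frame: list[list[Blob]], n_nucleosomes: int, bp_per_size: float = 142.0
):
    """Per-nucleosome mean (and SD) of its containing blob's member count.

    Noise nucleosomes count as singleton blobs of size 1, so the profile
    is defined everywhere. Returns (mean sizes, SDs, mean bp sizes).
    """
    n_frames = len(blobs_per_frame)
    sizes = np.ones((n_frames, n_nucleosomes))
    for f, blobs in enumerate(blobs_per_frame):
        for b in blobs:
            sizes[f, b.members] = b.size
    return sizes.mean(axis=0), sizes.std(axis=0), sizes.mean(axis=0) * bp_per_size


def packing_density(frames_nm: np.ndarray, region_bp: float) -> float:
    """Genomic packing density in bp per um^3: region bp divided by the
    convex-hull volume of all beads, averaged over frames."""
    frames_nm = np.asarray(frames_nm, dtype=float)
    dens = []
    for fr in frames_nm:
        hull = ConvexHull(fr)
        dens.append(region_bp / (hull.volume / NM3_PER_UM3))
    return float(np.mean(dens))


def fit_lognormal(areas: np.ndarray, min_samples: int = 10):
    """Maximum-likelihood lognormal fit of blob areas.

    Returns (mode of the density, ln-scale SD s, SD of the distribution in
    area units). The mode (exp(mu - s^2)) and the distribution SD are
    reported separately because for wide lognormals the SD exceeds the
    mode by far.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size < min_samples:
        raise ValueError(f"need >= {min_samples} samples for a lognormal fit")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    s, _, scale = lognorm.fit(areas, floc=0)
    mu = np.log(scale)
    mode = float(np.exp(mu - s**2))
    sd = float(np.sqrt((np.exp(s**2) - 1.0)) * np.exp(mu + s**2 / 2.0))
    return mode, float(s), sd
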
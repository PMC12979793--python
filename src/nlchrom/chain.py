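"""Nucleosome-linker (NL) copolymer construction.

A chain is built from consensus dyad positions: each nucleosome bead
represents exactly 142 bp of wrapped DNA centred on its dyad; each
inter-core gap of L bp becomes round(L/8) linker beads of equal bp
(each nominally ~8 bp of B-DNA). Bead genomic spans tile the region
edge-to-edge, so base pairs are conserved exactly.

Reduced units: 1 sigma = 2.5 nm (the linker bead diameter); nucleosome
beads are 4 sigma (10 nm) wide.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import GenomicRegion, NucleosomeAnnotation, NUCLEOSOME_BEAD_BP

log = logging.getLogger(__name__)

__all__ = [
    "NLChain",
    "ScaffoldPlacement",
    "build_nl_chain",
    "map_nl_to_cg",
    "initialize_from_scaffold",
    "NM_PER_SIGMA",
    "NUCLEOSOME_DIAMETER_NM",
    "LINKER_DIAMETER_NM",
    "DOMAIN_RADIUS_NM",
]

#: reduced length unit of the NL model (nm per sigma)
NM_PER_SIGMA = 2.5
#: physical nucleosome bead diameter (core particle scale), nm
NUCLEOSOME_DIAMETER_NM = 10.0
#: physical linker bead diameter (~8 bp of B-DNA), nm
LINKER_DIAMETER_NM = 2.5
#: radius of the sphere within which a 5-kb domain's beads are initialised, nm
DOMAIN_RADIUS_NM = 90.0
#: physical size of one coarse-grained (5-kb) bead diameter, nm
CG_NM_PER_SIGMA = 90.0

LINKER, NUCLEOSOME = 0, 1


@dataclass
class NLChain:
    """Annotated nucleosome-linker bead chain."""

    region: GenomicRegion
    types: np.ndarray        # (n,) int: 1 nucleosome, 0 linker
    span_start: np.ndarray   # (n,) float bp, tiling the region
    span_end: np.ndarray     # (n,) float bp
    nm_per_sigma: float = NM_PER_SIGMA
    cg_bin: np.ndarray | None = None
    cg_resolution: int | None = None

    def __post_init__(self) -> None:
        self.types = np.asarray(self.types, dtype=int)
        self.span_start = np.asarray(self.span_start, dtype=float)
        self.span_end = np.asarray(self.span_end, dtype=float)
        n = self.types.size
        if not (self.span_start.size == n and self.span_end.size == n):
            raise ValueError("span arrays must match bead count")
        if not np.allclose(self.span_end[:-1], self.span_start[1:]):
            raise ValueError("bead spans must tile the region without gaps/overlaps")
        if not (
            np.isclose(self.span_start[0], self.region.start)
            and np.isclose(self.span_end[-1], self.region.end)
        ):
            raise ValueError("bead spans must cover the region edge-to-edge")
        nuc = self.types == NUCLEOSOME
        if not np.allclose(self.span_end[nuc] - self.span_start[nuc], NUCLEOSOME_BEAD_BP):
            raise ValueError("every nucleosome bead must span exactly 142 bp")
        if self.cg_bin is not None:
            self.cg_bin = np.asarray(self.cg_bin, dtype=int)
            if np.any(np.diff(self.cg_bin) < 0):
                raise ValueError("cg_bin must be non-decreasing along the chain")

    @property
    def n_beads(self) -> int:
        return int(self.types.size)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.span_start + self.span_end)

    @property
    def bp_per_bead(self) -> np.ndarray:
        return self.span_end - self.span_start

    @property
    def nucleosome_indices(self) -> np.ndarray:
        return np.nonzero(self.types == NUCLEOSOME)[0]

    @property
    def diameters_sigma(self) -> np.ndarray:
        """Bead diameters in reduced units."""
        d = np.where(
            self.types == NUCLEOSOME,
            NUCLEOSOME_DIAMETER_NM / self.nm_per_sigma,
            LINKER_DIAMETER_NM / self.nm_per_sigma,
        )
        return d

    @property
    def n_domains(self) -> int:
        if self.cg_bin is None:
            raise ValueError("chain has no coarse-grained bin assignment")
        return int(self.cg_bin.max()) + 1

    def to_dict(self) -> dict:
        return {
            "region": {"chrom": self.region.chrom, "start": self.region.start,
                       "end": self.region.end},
            "types": self.types.tolist(),
            "span_start": self.span_start.tolist(),
            "span_end": self.span_end.tolist(),
            "nm_per_sigma": self.nm_per_sigma,
            "cg_bin": None if self.cg_bin is None else self.cg_bin.tolist(),
            "cg_resolution": self.cg_resolution,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NLChain":
        return cls(
            region=GenomicRegion(**d["region"]),
            types=np.array(d["types"]),
            span_start=np.array(d["span_start"]),
            span_end=np.array(d["span_end"]),
            nm_per_sigma=d.get("nm_per_sigma", NM_PER_SIGMA),
            cg_bin=None if d.get("cg_bin") is None else np.array(d["cg_bin"]),
            cg_resolution=d.get("cg_resolution"),
        )


@dataclass
class ScaffoldPlacement:
    """Coarse scaffold coordinates (nm) and the per-domain envelope."""

    coords_nm: np.ndarray  # (n_domains, 3)
    radius_nm: float = DOMAIN_RADIUS_NM
    seed: int = 0

    def __post_init__(self) -> None:
        self.coords_nm = np.asarray(self.coords_nm, dtype=float).reshape(-1, 3)
        if self.radius_nm <= 0:
            raise ValueError("domain radius must be > 0")


def _linker_run(gap_start: float, gap_end: float, terminal: bool) -> tuple[list, list]:
    """Split a gap into equal-bp linker bead spans.

    round(L/8) beads, at least 1 for L >= 4 bp. Interior gaps are always
    >= 5 bp because dyads are >= 147 bp apart; gaps of 1-3 bp can only
    occur at the region edges, where a single short terminal linker is
    emitted (there is no flanking linker to absorb them into).
    """
    L = gap_end - gap_start
    if L <= 0:
        return [], []
    n = int(round(L / 8.0))
    if n == 0:
        if L >= 4 or terminal:
            n = 1
        else:  # pragma: no cover - excluded by the 147-bp dyad spacing
            raise ValueError(f"interior gap of {L} bp cannot be tiled")
    bounds = np.linspace(gap_start, gap_end, n + 1)
    return list(bounds[:-1]), list(bounds[1:])


def build_nl_chain(annotation: NucleosomeAnnotation) -> NLChain:
    """Construct the NL copolymer from dyad positions.

    Dyads whose 142-bp bead would overhang the region are dropped with a
    warning (the bead span must stay exactly 142 bp and inside the region).
    """
    region = annotation.region
    half = NUCLEOSOME_BEAD_BP // 2  # 71
    dyads = annotation.dyads
    fits = (dyads - half >= region.start) & (dyads + half <= region.end)
    if not np.all(fits):
        log.warning(
            "dropping %d dyad(s) whose core overhangs the region edge",
            int((~fits).sum()),
        )
    dyads = dyads[fits]
    if dyads.size == 0:
        raise ValueError("no nucleosome fits inside the region")

    types: list[int] = []
    starts: list[float] = []
    ends: list[float] = []
    cursor = float(region.start)
    for k, d in enumerate(dyads):
        core_start, core_end = float(d - half), float(d + half)
        s, e = _linker_run(cursor, core_start, terminal=(k == 0))
        types += [LINKER] * len(s)
        starts += s
        ends += e
        types.append(NUCLEOSOME)
        starts.append(core_start)
        ends.append(core_end)
        cursor = core_end
    s, e = _linker_run(cursor, float(region.end), terminal=True)
    types += [LINKER] * len(s)
    starts += s
    ends += e
    return NLChain(region, np.array(types), np.array(starts), np.array(ends))


def map_nl_to_cg(chain: NLChain, cg_resolution: int = 5000) -> NLChain:
    """Assign each bead to the coarse-grained bin of its genomic midpoint."""
    mid = chain.midpoints
    bins = np.floor((mid - chain.region.start) / cg_resolution).astype(int)
    n_bins = chain.region.n_bins(cg_resolution)
    bins = np.clip(bins, 0, n_bins - 1)
    return NLChain(
        region=chain.region,
        types=chain.types,
        span_start=chain.span_start,
        span_end=chain.span_end,
        nm_per_sigma=chain.nm_per_sigma,
        cg_bin=bins,
        cg_resolution=cg_resolution,
    )


def initialize_from_scaffold(
    chain: NLChain,
    scaffold: ScaffoldPlacement,
    seed: int = 0,
    max_sweeps: int = 200,
) -> np.ndarray:
    """Place NL beads stochastically inside their domain spheres.

    Each bead is drawn uniformly inside the sphere of radius
    ``scaffold.radius_nm`` centred on its domain's scaffold coordinate;
    a short steepest-descent-style sweep then removes bond stretching
    beyond 2x the rest length and hard overlaps. Returns coordinates in
    reduced units (sigma). Deterministic given ``seed``.
    """
    if chain.cg_bin is None:
        raise ValueError("chain must be coarse-grain mapped first")
    n_dom = chain.n_domains
    if scaffold.coords_nm.shape[0] != n_dom:
        raise ValueError(
            f"scaffold has {scaffold.coords_nm.shape[0]} beads, chain has "
            f"{n_dom} domains"
        )
    rng = np.random.default_rng(seed)
    n = chain.n_beads
    # uniform in sphere: scaled radius ~ U^(1/3)
    u = rng.random(n) ** (1.0 / 3.0)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pos_nm = scaffold.coords_nm[chain.cg_bin] + scaffold.radius_nm * u[:, None] * v
    pos = pos_nm / chain.nm_per_sigma  # reduced units

    diam = chain.diameters_sigma
    rest = 0.5 * (diam[:-1] + diam[1:])  # bonded contact distance
    # bonds must end near the rest length, well inside the FENE divergence
    # at R0 = 1.5 x rest, and non-bonded pairs outside the steep WCA core;
    # otherwise the stored energy detonates the first dynamics steps
    contact = 0.5 * (diam[:, None] + diam[None, :])
    ok = max_sweeps == 0
    for sweep in range(max_sweeps):
        moved = False
        # forward pass: project each bead onto the rest-length sphere of
        # its predecessor (one pass leaves every bond at the rest length)
        bond_vec = pos[1:] - pos[:-1]
        bond_len = np.linalg.norm(bond_vec, axis=1)
        if np.any((bond_len > 1.05 * rest) | (bond_len < 0.95 * rest)):
            moved = True
            for b in range(len(rest)):
                delta = pos[b + 1] - pos[b]
                r = np.linalg.norm(delta)
                if r < 1e-9:
                    delta = rng.normal(size=3)
                    r = np.linalg.norm(delta)
                pos[b + 1] = pos[b] + delta * (rest[b] / r)
        # push overlapping non-bonded pairs out to the contact distance
        from scipy.spatial import cKDTree

        tree = cKDTree(pos)
        cand = tree.query_pairs(r=float(diam.max()), output_type="ndarray")
        if cand.size:
            aa, bb = cand[:, 0], cand[:, 1]
            sep = np.linalg.norm(pos[aa] - pos[bb], axis=1)
            close = (np.abs(aa - bb) >= 2) & (sep < 0.95 * contact[aa, bb])
            ii, jj = aa[close], bb[close]
        else:
            ii = jj = np.empty(0, dtype=int)
        for a, b in zip(ii, jj):
            delta = pos[b] - pos[a]
            r = np.linalg.norm(delta)
            if r < 1e-9:
                delta = rng.normal(size=3)
                r = np.linalg.norm(delta)
            shift = 0.5 * (contact[a, b] - r) * delta / r
            pos[a] -= shift
            pos[b] += shift
            moved = True
        if not moved:
            ok = True
            break
    if not ok:
        log.warning("scaffold relaxation hit the sweep cap (%d sweeps)", max_sweeps)
    return pos
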
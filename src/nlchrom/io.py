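"""Readers and writers for every external artifact.

Formats are deliberately plain text for desk-scale inspectability:

* dense contact TSV (N x N values),
* COO contact text ``i<TAB>j<TAB>value`` with 0-based bin indices,
* BED3+score / DANPOS-style tab tables for nucleosome dyads,
* extended-XYZ trajectories (bead type tag + x y z per line per frame).

Every reader validates against the core type invariants and is the exact
left inverse of the matching writer. Writers stamp tool version and, where
relevant, the seed, as ``#`` header comments.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ContactMap,
    GenomicRegion,
    NucleosomeAnnotation,
    Trajectory,
    NUCLEOSOME_CORE_BP,
)

__version__ = "0.1.0"
log = logging.getLogger(__name__)

__all__ = [
    "read_contact_map",
    "write_contact_map",
    "read_nucleosome_positions",
    "read_trajectory",
    "write_trajectory",
    "parse_region",
]


def parse_region(text: str) -> GenomicRegion:
    """Parse ``chrom:start-end`` (commas allowed in numbers)."""
    chrom, _, span = text.partition(":")
    lo, _, hi = span.partition("-")
    return GenomicRegion(chrom, int(lo.replace(",", "")), int(hi.replace(",", "")))


def _header_lines(extra: dict | None = None) -> list[str]:
    lines = [f"# nlchrom v{__version__}"]
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

def _sniff_contact_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            n_fields = len(line.rstrip("\n").split("\t"))
            return "coo" if n_fields == 3 else "dense"
    raise ValueError(f"{path}: empty contact file")


def read_contact_map(
    path,
    region: GenomicRegion,
    resolution: int,
    format_hint: str | None = None,
    balanced: bool = False,
    source: str = "experimental",
) -> ContactMap:
    """Read a dense-TSV or COO contact file into a validated ContactMap.

    Asymmetric dense inputs are symmetrised by averaging (logged); COO files
    holding only one triangle are mirrored. NaN entries are an error naming
    the offending cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint or _sniff_contact_format(path)
    n = region.n_bins(resolution)

    if fmt == "dense":
        m = np.loadtxt(path, ndmin=2)
        if m.shape[0] != m.shape[1]:
            raise ValueError(f"{path}: dense contact matrix not square {m.shape}")
        bad = np.argwhere(np.isnan(m))
        if bad.size:
            i, j = bad[0]
            raise ValueError(f"{path}: NaN contact value at cell ({i}, {j})")
        if not np.allclose(m, m.T, atol=ContactMap.SYMMETRY_TOL, rtol=0.0):
            log.warning("%s: asymmetric dense matrix symmetrised by averaging", path)
            m = 0.5 * (m + m.T)
    elif fmt == "coo":
        rec = np.loadtxt(path, ndmin=2, comments="#")
        if rec.shape[1] != 3:
            raise ValueError(f"{path}: COO rows must be 'i<TAB>j<TAB>value'")
        if np.any(np.isnan(rec)):
            r = int(np.argwhere(np.isnan(rec))[0][0])
            raise ValueError(f"{path}: NaN in COO record {r}")
        ii = rec[:, 0].astype(int)
        jj = rec[:, 1].astype(int)
        if ii.min(initial=0) < 0 or jj.min(initial=0) < 0:
            raise ValueError(f"{path}: negative bin index in COO file")
        m = np.zeros((n, n))
        m[ii, jj] = rec[:, 2]
        # mirror: entries present in only one triangle are completed
        lower = m.T.copy()
        both = (m != 0) & (lower != 0)
        m = np.where(m != 0, m, lower)
        if np.any(both) and not np.allclose(
            m[both], lower[both], atol=ContactMap.SYMMETRY_TOL
        ):
            log.warning("%s: conflicting symmetric COO entries averaged", path)
            m[both] = 0.5 * (m[both] + lower[both])
            m = 0.5 * (m + m.T)
    else:
        raise ValueError(f"unknown contact format {fmt!r}")

    return ContactMap(region, resolution, m, balanced=balanced, source=source)


def write_contact_map(cmap: ContactMap, path, format: str = "dense") -> None:
    """Write a ContactMap as dense TSV or COO triples (zeros dropped,
    upper triangle incl. diagonal). Round-trips to < 1e-12 entrywise."""
    path = Path(path)
    hdr = _header_lines(
        {
            "region": str(cmap.region),
            "resolution": cmap.resolution,
            "balanced": cmap.balanced,
            "source": cmap.source,
        }
    )
    if format == "dense":
        with open(path, "w") as fh:
            fh.write("\n".join(hdr) + "\n")
            np.savetxt(fh, cmap.matrix, delimiter="\t", fmt="%.17g")
    elif format == "coo":
        iu, ju = np.triu_indices(cmap.n_bins)
        vals = cmap.matrix[iu, ju]
        keep = vals != 0
        with open(path, "w") as fh:
            fh.write("\n".join(hdr) + "\n")
            for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
                fh.write(f"{i}\t{j}\t{v:.17g}\n")
    else:
        raise ValueError(f"unknown contact format {format!r}")


# ---------------------------------------------------------------------------
# nucleosome positions
# ---------------------------------------------------------------------------

def read_nucleosome_positions(
    path, region: GenomicRegion, one_based: bool = False
) -> NucleosomeAnnotation:
    """Read dyads from a BED-like or DANPOS-style tab table.

    Accepted layouts (tab-separated, ``#`` comments ignored):

    * ``chrom  dyad  occupancy``
    * ``chrom  start  end  [name]  occupancy`` — dyad = floor((start+end)/2)

    DANPOS emits 1-based coordinates; pass ``one_based=True`` to shift them
    onto the internal 0-based convention. Dyads are clipped to the region
    and 147-bp core overlaps are resolved by keeping the higher-occupancy
    dyad (logged).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: malformed nucleosome table")
    # tolerate a header row of column names
    if not str(df.iloc[0, 1]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"{path}: no data rows")

    chroms = df.iloc[:, 0].astype(str)
    if df.shape[1] == 2:
        dyads = df.iloc[:, 1].astype(np.int64).to_numpy()
        occ = np.ones(len(df))
    elif df.shape[1] == 3:
        dyads = df.iloc[:, 1].astype(np.int64).to_numpy()
        occ = df.iloc[:, 2].astype(float).to_numpy()
    else:
        start = df.iloc[:, 1].astype(np.int64).to_numpy()
        end = df.iloc[:, 2].astype(np.int64).to_numpy()
        dyads = (start + end) // 2
        occ = df.iloc[:, df.shape[1] - 1].astype(float).to_numpy()
    if one_based:
        dyads = dyads - 1

    keep = (chroms.to_numpy() == region.chrom) & (dyads >= region.start) & (
        dyads < region.end
    )
    dyads, occ = dyads[keep], occ[keep]
    if dyads.size == 0:
        raise ValueError(f"{path}: no dyads within {region}")

    order = np.argsort(dyads, kind="stable")
    dyads, occ = dyads[order], occ[order]

    # resolve 147-bp core overlaps by occupancy rank
    kept_d: list[int] = []
    kept_o: list[float] = []
    for d, o in zip(dyads, occ):
        if kept_d and d - kept_d[-1] < NUCLEOSOME_CORE_BP:
            if o > kept_o[-1]:
                log.info(
                    "dropping dyad %d (occ %.3g) overlapping %d (occ %.3g)",
                    kept_d[-1], kept_o[-1], d, o,
                )
                kept_d[-1], kept_o[-1] = int(d), float(o)
            else:
                log.info("dropping dyad %d (occ %.3g): overlaps kept dyad", d, o)
        else:
            kept_d.append(int(d))
            kept_o.append(float(o))
    return NucleosomeAnnotation(region, np.array(kept_d), np.array(kept_o))


def write_nucleosome_positions(ann: NucleosomeAnnotation, path) -> None:
    """Write dyads as a 3-column BED-like table (chrom, dyad, occupancy)."""
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines({"region": str(ann.region)})) + "\n")
        for d, o in zip(ann.dyads, ann.occupancy):
            fh.write(f"{ann.region.chrom}\t{d}\t{o:.17g}\n")


# ---------------------------------------------------------------------------
# trajectories (extended-XYZ text)
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Write an extended-XYZ text trajectory.

    Per frame: a bead-count line, a comment line, then one
    ``type x y z`` line per bead with 17 significant digits (lossless for
    float64 round-trips).
    """
    types = traj.bead_types
    if types is None:
        types = np.zeros(traj.n_beads, dtype=int)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_beads}\n")
            fh.write(
                f"frame={f} interval={traj.frame_interval} units={traj.units} "
                f"seed={traj.seed} chain={traj.chain_id} nlchrom={__version__}\n"
            )
            for t, (x, y, z) in zip(types, traj.frames[f]):
                fh.write(f"{int(t)} {x:.17g} {y:.17g} {z:.17g}\n")


def read_trajectory(path) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    frames: list[np.ndarray] = []
    types: np.ndarray | None = None
    interval, units, seed, chain_id = 1, "reduced", None, ""
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    n_beads = None
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos])
        if n_beads is None:
            n_beads = n
        elif n != n_beads:
            raise ValueError(
                f"{path}: frame {len(frames)} has {n} beads, expected {n_beads}"
            )
        comment = lines[pos + 1]
        for token in comment.split():
            key, _, val = token.partition("=")
            if key == "interval":
                interval = int(val)
            elif key == "units":
                units = val
            elif key == "seed" and val not in ("None", ""):
                seed = int(val)
            elif key == "chain":
                chain_id = val
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated frame {len(frames)}")
        tt = np.empty(n, dtype=int)
        xyz = np.empty((n, 3))
        for b, line in enumerate(block):
            parts = line.split()
            tt[b] = int(parts[0])
            xyz[b] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if types is None:
            types = tt
        frames.append(xyz)
        pos += 2 + n
    if not frames:
        raise ValueError(f"{path}: empty trajectory")
    return Trajectory(
        frames=np.stack(frames),
        chain_id=chain_id,
        frame_interval=interval,
        seed=seed,
        units=units,
        bead_types=types,
    )
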
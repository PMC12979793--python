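"""Core domain types shared across the package.

All genomic coordinates are 0-based, half-open (BED convention). Contact
maps are dense, symmetric, non-negative matrices tied to a genomic region
and a bin resolution. Trajectories hold ordered coordinate frames for a
fixed bead count.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicRegion",
    "ContactMap",
    "NucleosomeAnnotation",
    "Trajectory",
    "NUCLEOSOME_CORE_BP",
    "NUCLEOSOME_BEAD_BP",
    "LINKER_BEAD_BP",
]

#: Nucleosome core particle footprint used for overlap checks (bp).
NUCLEOSOME_CORE_BP = 147
#: DNA represented by one nucleosome bead in the NL model (bp).
NUCLEOSOME_BEAD_BP = 142
#: Nominal DNA content of one linker bead (bp).
LINKER_BEAD_BP = 8


@dataclass(frozen=True)
class GenomicRegion:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"region start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"region end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def n_bins(self, resolution: int) -> int:
        return math.ceil(self.length / resolution)

    def __str__(self) -> str:  # chr:start-end, human readable
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class ContactMap:
    """Symmetric contact-probability matrix over a binned genomic region."""

    region: GenomicRegion
    resolution: int
    matrix: np.ndarray
    balanced: bool = False
    source: str = "simulated"

    SYMMETRY_TOL = 1e-9

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"contact matrix must be square, got {m.shape}")
        expected = self.region.n_bins(self.resolution)
        if m.shape[0] != expected:
            raise ValueError(
                f"bin count {m.shape[0]} inconsistent with region {self.region} "
                f"at {self.resolution} bp ({expected} bins expected)"
            )
        if not np.all(np.isfinite(m)):
            i, j = np.argwhere(~np.isfinite(m))[0]
            raise ValueError(f"non-finite contact value at bin ({i}, {j})")
        if np.any(m < 0):
            i, j = np.argwhere(m < 0)[0]
            raise ValueError(f"negative contact value at bin ({i}, {j})")
        if not np.allclose(m, m.T, atol=self.SYMMETRY_TOL, rtol=0.0):
            raise ValueError("contact matrix not symmetric within 1e-9")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def copy_with(self, matrix: np.ndarray, **kw) -> "ContactMap":
        args = dict(
            region=self.region,
            resolution=self.resolution,
            matrix=matrix,
            balanced=self.balanced,
            source=self.source,
        )
        args.update(kw)
        return ContactMap(**args)


@dataclass
class NucleosomeAnnotation:
    """Consensus nucleosome dyad positions with occupancy scores.

    Dyads are absolute bp positions, strictly increasing, at least 147 bp
    apart (core non-overlap), each inside the region.
    """

    region: GenomicRegion
    dyads: np.ndarray
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.dyads = np.asarray(self.dyads, dtype=np.int64)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.dyads.ndim != 1 or self.dyads.shape != self.occupancy.shape:
            raise ValueError("dyads and occupancy must be matching 1-D arrays")
        if self.dyads.size == 0:
            raise ValueError("annotation contains no dyads")
        if np.any(np.diff(self.dyads) <= 0):
            raise ValueError("dyads must be strictly increasing")
        if np.any(np.diff(self.dyads) < NUCLEOSOME_CORE_BP):
            d = int(np.argmax(np.diff(self.dyads) < NUCLEOSOME_CORE_BP))
            raise ValueError(
                f"dyads {self.dyads[d]} and {self.dyads[d + 1]} closer than "
                f"{NUCLEOSOME_CORE_BP} bp"
            )
        if self.dyads[0] < self.region.start or self.dyads[-1] >= self.region.end:
            raise ValueError("dyad outside region")
        if np.any(self.occupancy < 0):
            raise ValueError("occupancy must be non-negative")

    @property
    def n_nucleosomes(self) -> int:
        return int(self.dyads.size)


@dataclass
class Trajectory:
    """Ordered coordinate frames for one bead chain.

    ``frames`` is an (n_frames, n_beads, 3) float array; ``units`` records
    whether coordinates are in reduced simulation units or nm.
    """

    frames: np.ndarray
    chain_id: str = ""
    frame_interval: int = 1
    seed: int | None = None
    units: str = "reduced"
    bead_types: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(
                f"frames must have shape (n_frames, n_beads, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] == 0:
            raise ValueError("trajectory has no frames")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]
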
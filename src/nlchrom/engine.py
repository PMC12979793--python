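"""Bead-spring Langevin dynamics and the two folding protocols.

The coarse (homopolymer) level folds one 5-kb bead chain against a
replicate restraint set: harmonic bonds, WCA excluded volume (restrained
pairs exempt), and flat-bottom harmonic contact restraints. The
nucleosome-linker (NL) level uses FENE bonds, linker bending, WCA plus a
short-range nucleosome-nucleosome attraction, and centre-of-mass (COM)
restraints that transfer the coarse contacts onto 5-kb domains.

Integration is BAOAB velocity-Verlet Langevin at dt = 0.005 tau, k_BT = 1.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .chain import NLChain, ScaffoldPlacement, initialize_from_scaffold, DOMAIN_RADIUS_NM
from .core import Trajectory
from .forcefield import ForceField, SimulationParams

log = logging.getLogger(__name__)

__all__ = [
    "System",
    "make_homopolymer_system",
    "make_nl_system",
    "energy_and_forces",
    "langevin_run",
    "fold_homopolymer",
    "fold_nl",
    "contact_satisfaction",
    "self_avoiding_walk",
]

ENERGY_TERMS = (
    "wca", "attraction", "bond", "fene", "bend", "restraint",
    "com_restraint", "com_wca",
)

_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_F = np.empty(0, dtype=np.float64)


@dataclass
class System:
    """Everything the kernels need, in flat arrays."""

    diam: np.ndarray                     # bead diameters, sigma
    is_nuc: np.ndarray                   # int8 flags
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_kind: np.ndarray                # 0 harmonic, 1 FENE
    bond_r0: np.ndarray
    bond_R0: np.ndarray
    bond_k: np.ndarray = field(default_factory=lambda: _EMPTY_F)
    ang_i: np.ndarray = field(default_factory=lambda: _EMPTY_I)
    ang_j: np.ndarray = field(default_factory=lambda: _EMPTY_I)
    ang_k: np.ndarray = field(default_factory=lambda: _EMPTY_I)
    rest_i: np.ndarray = field(default_factory=lambda: _EMPTY_I)
    rest_j: np.ndarray = field(default_factory=lambda: _EMPTY_I)
    rest_rc: np.ndarray = field(default_factory=lambda: _EMPTY_F)   # well radius
    rest_check: np.ndarray = field(default_factory=lambda: _EMPTY_F)  # contact radius
    dom_id: np.ndarray = field(default_factory=lambda: _EMPTY_I)
    n_dom: int = 0
    dom_count: np.ndarray = field(default_factory=lambda: _EMPTY_I)
    crest_a: np.ndarray = field(default_factory=lambda: _EMPTY_I)
    crest_b: np.ndarray = field(default_factory=lambda: _EMPTY_I)
    crest_rc: np.ndarray = field(default_factory=lambda: _EMPTY_F)   # well radius
    crest_check: np.ndarray = field(default_factory=lambda: _EMPTY_F)  # contact radius
    cwca_a: np.ndarray = field(default_factory=lambda: _EMPTY_I)
    cwca_b: np.ndarray = field(default_factory=lambda: _EMPTY_I)
    sigma_com: float = 1.0
    ff: ForceField = field(default_factory=ForceField)
    skip_nonbonded: np.ndarray = field(default_factory=lambda: _EMPTY_I)  # sorted i*n+j

    @property
    def n_beads(self) -> int:
        return int(self.diam.size)

    def _buffers(self, cap_per_bead: int = 96):
        cap = max(64, cap_per_bead * self.n_beads)
        return (
            np.empty(cap, dtype=np.int64),
            np.empty(cap, dtype=np.int64),
            np.empty(cap, dtype=np.float64),
            np.empty(cap, dtype=np.int64),
        )


_STATUS_MSG = {
    1: "FENE bond reached R0 (exploded dynamics)",
    2: "non-finite force encountered",
    3: "neighbour-list overflow",
}


def _raise_status(status: int, context: str) -> None:
    if status != 0:
        raise FloatingPointError(f"{context}: {_STATUS_MSG.get(status, status)}")


def energy_and_forces(pos: np.ndarray, system: System):
    """Total energy, per-bead forces, and a per-term energy breakdown."""
    pos = np.ascontiguousarray(pos, dtype=float)
    ff = system.ff
    pi, pj, ps, pk = system._buffers()
    n_pairs = K.build_pairs(
        pos, system.diam, system.is_nuc, ff.eps_nn, ff.rc_nn_factor, 0.0,
        system.skip_nonbonded, pi, pj, ps, pk,
    )
    if n_pairs < 0:
        raise FloatingPointError("neighbour-list overflow")
    forces = np.zeros_like(pos)
    energies = np.zeros(K.N_TERMS)
    status = K.compute_forces(
        pos, forces, energies,
        pi, pj, ps, pk, n_pairs, ff.epsilon, ff.eps_nn, ff.rc_nn_factor,
        system.bond_i, system.bond_j, system.bond_kind, system.bond_r0,
        system.bond_R0, system.bond_k,
        system.ang_i, system.ang_j, system.ang_k, ff.k_bend,
        system.rest_i, system.rest_j, system.rest_rc, ff.k_contact, ff.f_cap,
        system.dom_id, system.n_dom, system.dom_count,
        system.crest_a, system.crest_b, system.crest_rc, ff.k_com,
        system.cwca_a, system.cwca_b, system.sigma_com,
    )
    _raise_status(status, "energy_and_forces")
    breakdown = dict(zip(ENERGY_TERMS, energies))
    return float(energies.sum()), forces, breakdown


def langevin_run(
    pos: np.ndarray,
    system: System,
    params: SimulationParams,
    vel: np.ndarray | None = None,
    gamma: float | None = None,
    chunk: int = 2000,
    rebuild_every: int = 10,
    skin: float = 1.0,
) -> Trajectory:
    """Run BAOAB Langevin dynamics, saving a frame every save_interval.

    gamma = 0 disables the thermostat (NVE velocity Verlet). Deterministic
    given ``params.seed``. Raises on energy blow-up with a diagnostic.
    """
    pos = np.ascontiguousarray(pos, dtype=float).copy()
    ff = system.ff
    g = ff.gamma if gamma is None else gamma
    rng = np.random.default_rng(params.seed)
    if vel is None:
        vel = (
            rng.normal(0.0, np.sqrt(params.kT), pos.shape)
            if g > 0
            else np.zeros_like(pos)
        )
    else:
        vel = np.ascontiguousarray(vel, dtype=float).copy()
    pi, pj, ps, pk = system._buffers()
    forces = np.zeros_like(pos)
    energies = np.zeros(K.N_TERMS)
    frames = []
    done = 0
    while done < params.n_steps:
        n = min(chunk, params.save_interval, params.n_steps - done)
        noise = (
            rng.standard_normal((n,) + pos.shape)
            if g > 0
            else np.zeros((n,) + pos.shape)
        )
        status = K.run_chunk(
            pos, vel, noise, params.dt, g, params.kT,
            system.diam, system.is_nuc, skin, rebuild_every,
            system.skip_nonbonded, pi, pj, ps, pk,
            ff.epsilon, ff.eps_nn, ff.rc_nn_factor,
            system.bond_i, system.bond_j, system.bond_kind, system.bond_r0,
            system.bond_R0, system.bond_k,
            system.ang_i, system.ang_j, system.ang_k, ff.k_bend,
            system.rest_i, system.rest_j, system.rest_rc, ff.k_contact, ff.f_cap,
            system.dom_id, system.n_dom, system.dom_count,
            system.crest_a, system.crest_b, system.crest_rc, ff.k_com,
            system.cwca_a, system.cwca_b, system.sigma_com,
            forces, energies,
        )
        _raise_status(status, f"langevin_run at step {done}")
        done += n
        if done % params.save_interval == 0:
            frames.append(pos.copy())
    return Trajectory(
        frames=np.stack(frames),
        frame_interval=params.save_interval,
        seed=params.seed,
        units="reduced",
        bead_types=np.asarray(system.is_nuc, dtype=int),
    )


def contact_satisfaction(pos, pairs, cutoff) -> float:
    """Fraction of restrained pairs with pairwise distance <= cutoff.

    ``cutoff`` may be scalar or per-pair. Empty restraint lists are defined
    as fully satisfied (warned)."""
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if pairs.shape[0] == 0:
        warnings.warn("empty restraint list: satisfaction defined as 1.0", stacklevel=2)
        return 1.0
    d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
    return float(np.mean(d <= np.asarray(cutoff)))


def self_avoiding_walk(
    n_beads: int,
    seed: int = 0,
    bond_length: float = 1.0,
    diameter: float = 1.0,
    n_pivots: int | None = None,
) -> np.ndarray:
    """Equilibrated off-lattice self-avoiding walk via the pivot algorithm.

    Starts from a straight rod and applies random pivot rotations,
    accepting moves with no hard-core overlap (non-adjacent beads closer
    than ``diameter``). Gives Flory-like R_g scaling (nu ~ 0.59).
    """
    rng = np.random.default_rng(seed)
    pos = np.zeros((n_beads, 3))
    pos[:, 0] = np.arange(n_beads) * bond_length
    if n_pivots is None:
        n_pivots = 12 * n_beads
    d2min = diameter * diameter
    accepted = 0
    for _ in range(n_pivots):
        p = rng.integers(1, n_beads - 1)
        # random rotation matrix (QR of a Gaussian matrix)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        tail = (pos[p + 1 :] - pos[p]) @ q.T + pos[p]
        head = pos[: p + 1]
        # overlap check head vs moved tail (skip the bonded neighbour pair)
        diff = head[:, None, :] - tail[None, :, :]
        dd = (diff**2).sum(-1)
        dd[p, 0] = np.inf  # bonded pair p -- p+1
        if dd.min() > d2min * 0.999999:
            pos = np.vstack([head, tail])
            accepted += 1
    log.debug("pivot SAW: %d/%d moves accepted", accepted, n_pivots)
    return pos


def make_homopolymer_system(
    n_bins: int, restraints, ff: ForceField | None = None
) -> System:
    """Coarse 5-kb chain: harmonic bonds, WCA, flat-bottom restraints.

    Restrained pairs are exempt from WCA (the restraint well replaces it).
    The harmonic wall of each restraint sits ``well_margin`` inside the
    contact radius so thermal fluctuations keep satisfied pairs inside it.
    """
    ff = ff or ForceField()
    restraints = np.asarray(restraints, dtype=int).reshape(-1, 2)
    diam = np.ones(n_bins)
    bonds = np.arange(n_bins - 1, dtype=np.int64)
    skip = np.sort(
        np.array(
            [i * n_bins + j for i, j in np.sort(restraints, axis=1)], dtype=np.int64
        )
    )
    return System(
        diam=diam,
        is_nuc=np.zeros(n_bins, dtype=np.int64),
        bond_i=bonds,
        bond_j=bonds + 1,
        bond_kind=np.zeros(n_bins - 1, dtype=np.int64),
        bond_r0=np.ones(n_bins - 1),
        bond_R0=np.full(n_bins - 1, ff.fene_r0_factor),
        bond_k=np.full(n_bins - 1, ff.k_bond),
        rest_i=restraints[:, 0].astype(np.int64),
        rest_j=restraints[:, 1].astype(np.int64),
        rest_rc=np.full(restraints.shape[0], (1.0 - ff.well_margin) * ff.rc_factor),
        rest_check=np.full(restraints.shape[0], ff.rc_factor * 1.0),
        ff=ff,
        skip_nonbonded=skip,
    )


def fold_homopolymer(
    restraints,
    n_bins: int,
    ff: ForceField | None = None,
    params: SimulationParams | None = None,
    target_satisfaction: float = 0.95,
    max_steps: int = 200_000,
    check_interval: int = 4_000,
    fold_gamma: float = 2.0,
):
    """Fold one coarse replicate from a pivot-equilibrated SAW start.

    Runs restrained Langevin dynamics until the fraction of satisfied
    restraints reaches the target (or max_steps). Folding uses a higher
    friction than production so restraint-driven drift stays below the
    excluded-volume tunnelling speed. Returns
    (final positions, satisfaction, converged flag).
    """
    ff = ff or ForceField()
    params = params or SimulationParams(n_steps=check_interval, save_interval=check_interval)
    system = make_homopolymer_system(n_bins, restraints, ff)
    pos = self_avoiding_walk(n_bins, seed=params.seed)
    rc = system.rest_check if len(system.rest_check) else ff.rc_factor
    pairs = np.column_stack([system.rest_i, system.rest_j]) if len(system.rest_i) else np.empty((0, 2), int)
    sat = contact_satisfaction(pos, pairs, rc) if len(pairs) else 1.0
    steps_done = 0
    seed_stride = 0
    while sat < target_satisfaction and steps_done < max_steps:
        block = params.with_(
            n_steps=check_interval, save_interval=check_interval,
            seed=(params.seed + 1_000_003 * seed_stride) % (2**31),
        )
        traj = langevin_run(pos, system, block, gamma=fold_gamma)
        pos = traj.frames[-1]
        steps_done += check_interval
        seed_stride += 1
        sat = contact_satisfaction(pos, pairs, rc) if len(pairs) else 1.0
    converged = bool(sat >= target_satisfaction)
    if not converged:
        log.warning(
            "fold_homopolymer: satisfaction %.3f < %.2f after %d steps",
            sat, target_satisfaction, steps_done,
        )
    return pos, float(sat), bool(converged)


def make_nl_system(
    chain: NLChain,
    restraints_cg,
    ff: ForceField | None = None,
    com_radius_nm: float = DOMAIN_RADIUS_NM,
) -> System:
    """NL copolymer system: FENE bonds, linker bending, WCA + nucleosome
    attraction, and domain-COM restraints carrying the coarse contacts.

    Restrained domain pairs are exempt from the COM-level WCA (the
    flat-bottom well replaces it), mirroring the bead-level exemption.
    """
    ff = ff or ForceField()
    if chain.cg_bin is None:
        raise ValueError("chain must be coarse-grain mapped first")
    diam = chain.diameters_sigma
    n = chain.n_beads
    bonds = np.arange(n - 1, dtype=np.int64)
    r0 = 0.5 * (diam[:-1] + diam[1:])
    # bending on consecutive all-linker triplets
    lin = chain.types == 0
    trip = np.nonzero(lin[:-2] & lin[1:-1] & lin[2:])[0]
    restraints_cg = np.asarray(restraints_cg, dtype=int).reshape(-1, 2)
    n_dom = chain.n_domains
    dom_count = np.bincount(chain.cg_bin, minlength=n_dom).astype(np.int64)
    rc_com = com_radius_nm / chain.nm_per_sigma
    rest_set = {tuple(sorted(p)) for p in map(tuple, restraints_cg)}
    cw_a, cw_b = [], []
    for a in range(n_dom):
        for b in range(a + 1, n_dom):
            if abs(a - b) >= 2 and (a, b) not in rest_set:
                cw_a.append(a)
                cw_b.append(b)
    return System(
        diam=diam,
        is_nuc=chain.types.astype(np.int64),
        bond_i=bonds,
        bond_j=bonds + 1,
        bond_kind=np.ones(n - 1, dtype=np.int64),
        bond_r0=r0,
        bond_R0=ff.fene_r0_factor * r0,
        # dimensionless Kremer-Grest form: k scales with the pair size
        bond_k=ff.k_fene / r0**2,
        ang_i=trip.astype(np.int64),
        ang_j=(trip + 1).astype(np.int64),
        ang_k=(trip + 2).astype(np.int64),
        dom_id=chain.cg_bin.astype(np.int64),
        n_dom=n_dom,
        dom_count=dom_count,
        crest_a=restraints_cg[:, 0].astype(np.int64),
        crest_b=restraints_cg[:, 1].astype(np.int64),
        crest_rc=np.full(restraints_cg.shape[0], (1.0 - ff.well_margin) * rc_com),
        crest_check=np.full(restraints_cg.shape[0], rc_com),
        cwca_a=np.array(cw_a, dtype=np.int64),
        cwca_b=np.array(cw_b, dtype=np.int64),
        sigma_com=rc_com,
        ff=ff,
    )


def _domain_coms(pos: np.ndarray, dom_id: np.ndarray, n_dom: int) -> np.ndarray:
    out = np.zeros((n_dom, 3))
    counts = np.bincount(dom_id, minlength=n_dom)
    for c in range(3):
        out[:, c] = np.bincount(dom_id, weights=pos[:, c], minlength=n_dom) / counts
    return out


def fold_nl(
    chain: NLChain,
    scaffold: ScaffoldPlacement,
    restraints_cg,
    ff: ForceField | None = None,
    params: SimulationParams | None = None,
    target_satisfaction: float = 0.95,
    max_phase_a_steps: int = 100_000,
    check_interval: int = 4_000,
    fold_gamma: float = 2.0,
):
    """Two-phase NL folding: drive domain-COM restraints to satisfaction
    (phase A), then run production saving frames every save_interval
    (phase B). Returns (Trajectory, phase-A satisfaction, converged flag).
    """
    ff = ff or ForceField()
    params = params or SimulationParams()
    system = make_nl_system(chain, restraints_cg, ff)
    pos = initialize_from_scaffold(chain, scaffold, seed=params.seed)
    com_pairs = np.column_stack([system.crest_a, system.crest_b])

    def com_sat(p):
        if com_pairs.shape[0] == 0:
            return 1.0
        coms = _domain_coms(p, system.dom_id, system.n_dom)
        return contact_satisfaction(coms, com_pairs, system.crest_check)

    sat = com_sat(pos)
    steps = 0
    stride = 0
    while sat < target_satisfaction and steps < max_phase_a_steps:
        block = params.with_(
            n_steps=check_interval, save_interval=check_interval,
            seed=(params.seed + 7_919 * (stride + 1)) % (2**31),
        )
        pos = langevin_run(pos, system, block, gamma=fold_gamma).frames[-1]
        steps += check_interval
        stride += 1
        sat = com_sat(pos)
    converged = sat >= target_satisfaction
    if not converged:
        log.warning("fold_nl phase A: satisfaction %.3f after %d steps", sat, steps)

    traj = langevin_run(pos, system, params)
    traj.chain_id = str(chain.region)
    return traj, float(sat), bool(converged)
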
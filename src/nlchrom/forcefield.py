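"""Force-field and integrator parameter containers.

Reduced Lennard-Jones units throughout: energies in epsilon, lengths in
sigma (2.5 nm at NL resolution), k_BT = 1, time in tau. Defaults follow
Kremer-Grest bead-spring conventions: FENE bonds with k = 30 eps/sigma^2
and R0 = 1.5 sigma_pair, WCA excluded volume, harmonic bonds at the
coarse-grained level, a k_theta = 5 k_BT linker bending stiffness, and
flat-bottom harmonic contact restraints. A short-range non-specific
nucleosome-nucleosome attraction (truncated-shifted LJ) drives local
compaction at NL resolution.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["ForceField", "SimulationParams"]

WCA_CUT = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ForceField:
    epsilon: float = 1.0           # WCA energy scale
    k_bond: float = 200.0          # harmonic bond stiffness (CG chain), eps/sigma^2
    k_fene: float = 30.0           # FENE stiffness (NL chain), eps/sigma^2
    fene_r0_factor: float = 1.5    # FENE R0 = factor * bonded contact distance
    k_bend: float = 5.0            # linker-triplet bending, k_BT
    k_contact: float = 10.0        # contact-restraint well stiffness, eps/sigma^2
    rc_factor: float = 2.5         # contact radius = factor * pair contact distance
    well_margin: float = 0.2       # restraint well sits (1 - margin) * contact radius
    f_cap: float = 5.0             # linear force cap on restraints, eps/sigma
    k_com: float = 10.0            # domain COM restraint stiffness
    eps_nn: float = 0.5            # nucleosome-nucleosome attraction depth (0 = off)
    rc_nn_factor: float = 2.5      # attraction cutoff, in nucleosome contact distances
    gamma: float = 1.0             # Langevin friction, 1/tau

    def __post_init__(self) -> None:
        for name in (
            "epsilon", "k_bond", "k_fene", "k_bend", "k_contact", "k_com",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.fene_r0_factor <= 1.0:
            raise ValueError("FENE R0 must exceed the bond rest length")
        if self.eps_nn < 0:
            raise ValueError("eps_nn must be >= 0")

    def with_(self, **kw) -> "ForceField":
        return replace(self, **kw)


@dataclass(frozen=True)
class SimulationParams:
    """Langevin integrator settings (reduced units).

    Time is measured in the fundamental simulation time unit tau, so the
    integration step is dt = 0.005 tau = 0.005 code units. tau's value in
    physical units never enters the equations of motion.
    """

    tau: float = 1.0              # the reduced time unit (time is measured in tau)
    dt_factor: float = 0.005      # time step = dt_factor * tau
    kT: float = 1.0
    n_steps: int = 6_500_000      # production length (full-scale protocol)
    save_interval: int = 50_000   # frame stride -> 130 frames at defaults
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("time step must be > 0")
        if self.save_interval <= 0 or self.n_steps % self.save_interval != 0:
            raise ValueError("save_interval must divide n_steps")

    @property
    def dt(self) -> float:
        return self.dt_factor * self.tau

    @property
    def n_frames(self) -> int:
        return self.n_steps // self.save_interval

    def with_(self, **kw) -> "SimulationParams":
        return replace(self, **kw)
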
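"""End-to-end pipeline: preprocess -> coarse folding -> NL build ->
NL folding -> analyses, with a checksummed run manifest and per-stage
resumability.

The master seed fans out deterministically per stage and replicate, so
replicates can be recomputed in any order with identical results. A stage
is skipped when its outputs exist and the stage-relevant configuration is
unchanged (tracked by config hashes in the manifest).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from .chain import (
    NLChain,
    ScaffoldPlacement,
    build_nl_chain,
    map_nl_to_cg,
    CG_NM_PER_SIGMA,
    DOMAIN_RADIUS_NM,
)
from .core import GenomicRegion, Trajectory
from .engine import (
    fold_homopolymer,
    fold_nl,
    langevin_run,
    make_homopolymer_system,
)
from .forcefield import ForceField, SimulationParams
from .preprocess import balance_map, decompose, significant_contacts
from .synth import NucleosomeArraySpec, SyntheticMapSpec, gen_hic, gen_nucleosomes

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(master: int, stage: str, replicate: int = 0) -> int:
    """Deterministic per-stage / per-replicate seed below 2^31."""
    key = f"{master}:{stage}:{replicate}".encode()
    return zlib.crc32(key) % (2**31)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_root: str
    region: str = "chrS:0-20000"
    resolution: int = 5000
    # inputs: either file paths or synthetic generation blocks
    map_path: str | None = None
    nucleosome_path: str | None = None
    synthetic_map: dict | None = None
    synthetic_nucleosomes: dict | None = None
    replicates: int = 4
    seed: int = 0
    balanced_input: bool = True
    production_steps: int = 200_000
    save_interval: int = 20_000
    phase_a_max_steps: int = 60_000
    cg_fold_max_steps: int = 120_000
    forcefield: dict = field(default_factory=dict)
    analyses: tuple[str, ...] = ("maps", "blobs", "motifs", "mechanics")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analyses"] = list(self.analyses)
        return d

    def stage_hash(self, *fields: str) -> str:
        d = self.to_dict()
        payload = {k: d[k] for k in fields}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {"stages": {}, "artifacts": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def stage_done(self, name: str, h: str) -> bool:
        rec = self.data["stages"].get(name)
        if not rec or rec["hash"] != h:
            return False
        for p in rec["outputs"]:
            path = Path(p)
            if not path.exists():
                return False
            # silent artifact corruption invalidates the stage
            if self.data["artifacts"].get(p) != _sha256(path):
                log.warning("artifact %s changed on disk: stage %s rerun", p, name)
                return False
        return True

    def record(self, name: str, h: str, outputs: list[Path], wall: float) -> None:
        self.data["stages"][name] = {
            "hash": h,
            "outputs": [str(p) for p in outputs],
            "wall_s": round(wall, 2),
        }
        for p in outputs:
            self.data["artifacts"][str(p)] = _sha256(Path(p))
        self.save()

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _stage(manifest: _Manifest, name: str, h: str, outputs: list[Path], fn) -> bool:
    """Run one stage unless its outputs are current. Returns True if run."""
    if manifest.stage_done(name, h):
        log.info("stage %s: up to date, skipped", name)
        return False
    t0 = time.time()
    log.info("stage %s: running", name)
    fn()
    missing = [p for p in outputs if not p.exists()]
    if missing:
        raise RuntimeError(f"stage {name} did not produce {missing}")
    manifest.record(name, h, outputs, time.time() - t0)
    return True


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = Path(config.out_root)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    manifest = _Manifest(out / "manifest.json")
    region = fio.parse_region(config.region)
    ff = ForceField(**config.forcefield)
    M = config.replicates

    # ---- stage: inputs ----------------------------------------------------
    map_file = out / "inputs" / "contact_map.tsv"
    nuc_file = out / "inputs" / "nucleosomes.tsv"
    h_in = config.stage_hash(
        "region", "resolution", "map_path", "nucleosome_path",
        "synthetic_map", "synthetic_nucleosomes", "seed",
    )

    def do_inputs():
        (out / "inputs").mkdir(exist_ok=True)
        if config.map_path:
            cmap = fio.read_contact_map(
                config.map_path, region, config.resolution,
                balanced=config.balanced_input,
            )
        else:
            smap = dict(config.synthetic_map or {})
            smap.setdefault("n_bins", region.n_bins(config.resolution))
            smap.setdefault("seed", stage_seed(config.seed, "synthetic_map"))
            cmap = gen_hic(
                SyntheticMapSpec(
                    region=region, resolution=config.resolution, **smap
                )
            )
        if not config.balanced_input and config.map_path:
            cmap = balance_map(cmap)
        fio.write_contact_map(cmap, map_file)
        if config.nucleosome_path:
            ann = fio.read_nucleosome_positions(config.nucleosome_path, region)
        else:
            snuc = dict(config.synthetic_nucleosomes or {})
            snuc.setdefault("seed", stage_seed(config.seed, "synthetic_nucs"))
            ann = gen_nucleosomes(NucleosomeArraySpec(region=region, **snuc))
        fio.write_nucleosome_positions(ann, nuc_file)

    _stage(manifest, "inputs", h_in, [map_file, nuc_file], do_inputs)
    cmap = fio.read_contact_map(map_file, region, config.resolution, balanced=True)
    ann = fio.read_nucleosome_positions(nuc_file, region)

    # ---- stage: preprocess ------------------------------------------------
    rest_dir = out / "restraints"
    rest_files = [rest_dir / f"replicate_{k:03d}.tsv" for k in range(M)]
    h_pre = h_in + config.stage_hash("replicates", "seed")

    def do_preprocess():
        rest_dir.mkdir(exist_ok=True)
        sig = significant_contacts(cmap)
        if len(sig) == 0:
            # tiny/featureless maps: every diagonal is skipped or flat, so
            # replicates carry no restraints (backbone-only folding)
            log.warning("no significant contacts: replicates are unrestrained")
            replicates = [np.empty((0, 2), dtype=int)] * M
        else:
            ens = decompose(sig, M, seed=stage_seed(config.seed, "decompose"))
            replicates = ens.replicates
        for k, rep in enumerate(replicates):
            np.savetxt(rest_files[k], rep.reshape(-1, 2), fmt="%d", delimiter="\t")

    _stage(manifest, "preprocess", h_pre, rest_files, do_preprocess)

    def _load_pairs(f: Path) -> np.ndarray:
        if f.stat().st_size == 0:
            return np.empty((0, 2), dtype=int)
        return np.loadtxt(f, dtype=int, ndmin=2).reshape(-1, 2)

    replicate_restraints = [_load_pairs(f) for f in rest_files]

    # ---- stage: fold-cg ---------------------------------------------------
    cg_dir = out / "fold_cg"
    cg_files = [cg_dir / f"scaffold_{k:03d}.xyz" for k in range(M)]
    h_cg = h_pre + config.stage_hash("forcefield", "cg_fold_max_steps")

    def do_fold_cg():
        cg_dir.mkdir(exist_ok=True)
        n_bins = cmap.n_bins
        for k, rest in enumerate(replicate_restraints):
            seed = stage_seed(config.seed, "fold_cg", k)
            pos, sat, ok = fold_homopolymer(
                rest, n_bins, ff,
                params=SimulationParams(
                    n_steps=4000, save_interval=4000, seed=seed
                ),
                max_steps=config.cg_fold_max_steps,
            )
            if not ok:
                log.warning("replicate %d: CG satisfaction %.2f", k, sat)
            traj = Trajectory(
                frames=pos[None], chain_id=f"cg_{k}", seed=seed, units="reduced"
            )
            fio.write_trajectory(traj, cg_files[k])

    _stage(manifest, "fold_cg", h_cg, cg_files, do_fold_cg)

    # ---- stage: build-nl --------------------------------------------------
    chain_file = out / "chain.json"
    h_chain = h_in

    def do_build():
        chain = map_nl_to_cg(build_nl_chain(ann), config.resolution)
        chain_file.write_text(json.dumps(chain.to_dict()))

    _stage(manifest, "build_nl", h_chain, [chain_file], do_build)
    chain = NLChain.from_dict(json.loads(chain_file.read_text()))

    # ---- stage: fold-nl ---------------------------------------------------
    nl_dir = out / "fold_nl"
    nl_files = [nl_dir / f"traj_{k:03d}.xyz" for k in range(M)]
    h_nl = h_cg + config.stage_hash(
        "production_steps", "save_interval", "phase_a_max_steps"
    )

    def do_fold_nl():
        nl_dir.mkdir(exist_ok=True)
        for k, rest in enumerate(replicate_restraints):
            scaffold_traj = fio.read_trajectory(cg_files[k])
            scaffold = ScaffoldPlacement(
                coords_nm=scaffold_traj.frames[-1] * CG_NM_PER_SIGMA,
                radius_nm=DOMAIN_RADIUS_NM,
                seed=stage_seed(config.seed, "scaffold", k),
            )
            params = SimulationParams(
                n_steps=config.production_steps,
                save_interval=config.save_interval,
                seed=stage_seed(config.seed, "fold_nl", k),
            )
            traj, sat, ok = fold_nl(
                chain, scaffold, rest, ff, params,
                max_phase_a_steps=config.phase_a_max_steps,
            )
            if not ok:
                log.warning("replicate %d: COM satisfaction %.2f", k, sat)
            fio.write_trajectory(traj, nl_files[k])

    _stage(manifest, "fold_nl", h_nl, nl_files, do_fold_nl)

    # ---- stage: analyses --------------------------------------------------
    ana_dir = out / "analysis"
    ana_file = ana_dir / "summary.json"
    h_ana = h_nl + config.stage_hash("analyses")

    def do_analyses():
        ana_dir.mkdir(exist_ok=True)
        from .analysis_driver import analyse_ensemble

        trajs = [fio.read_trajectory(f) for f in nl_files]
        frames = np.concatenate([t.frames for t in trajs])
        ensemble = Trajectory(
            frames=frames, chain_id=str(chain.region), units="reduced",
            frame_interval=config.save_interval,
            bead_types=chain.types,
        )
        summary = analyse_ensemble(
            ensemble, chain, cmap,
            which=config.analyses,
            seed=stage_seed(config.seed, "analysis"),
            out_dir=ana_dir,
        )
        ana_file.write_text(json.dumps(summary, indent=2, sort_keys=True))

    _stage(manifest, "analyses", h_ana, [ana_file], do_analyses)
    return manifest.data
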
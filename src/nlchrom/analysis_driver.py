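"""Shared analysis driver: turn one NL ensemble into the full set of
map-, blob-, motif- and mechanics-level summaries.

Used by the pipeline's analysis stage and by the CLI `analyze`
subcommands; everything is computed from the trajectory, the chain
annotation, and the input contact map.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import blobs as B
from . import maps as M
from . import mechanics as X
from . import motifs as T
from .chain import NLChain
from .core import ContactMap, Trajectory

log = logging.getLogger(__name__)

__all__ = ["analyse_ensemble"]


def _nucleosome_frames_nm(ensemble: Trajectory, chain: NLChain) -> np.ndarray:
    scale = chain.nm_per_sigma if ensemble.units == "reduced" else 1.0
    return ensemble.frames[:, chain.nucleosome_indices, :] * scale


def analyse_ensemble(
    ensemble: Trajectory,
    chain: NLChain,
    input_map: ContactMap | None = None,
    which=("maps", "blobs", "motifs", "mechanics"),
    seed: int = 0,
    out_dir: Path | None = None,
) -> dict:
    """Run the requested analyses; returns a JSON-serialisable summary."""
    summary: dict = {
        "n_frames": ensemble.n_frames,
        "n_beads": ensemble.n_beads,
        "n_nucleosomes": int(chain.nucleosome_indices.size),
    }
    nuc_nm = _nucleosome_frames_nm(ensemble, chain)
    all_nm = ensemble.frames * (
        chain.nm_per_sigma if ensemble.units == "reduced" else 1.0
    )

    if "maps" in which:
        cg_map = M.coarse_grain_contacts(ensemble, chain, resolution=chain.cg_resolution or 5000)
        fine_map = M.coarse_grain_contacts(ensemble, chain, resolution=200)
        res = {"fine_resolution_bp": 200}
        if input_map is not None and input_map.n_bins == cg_map.n_bins:
            pear, spear = M.correlate_maps(cg_map, input_map)
            res["pearson_vs_input"] = pear
            res["spearman_vs_input"] = spear
            try:
                res["dcpcc_vs_input"] = M.dc_pearson(cg_map, input_map)
            except ValueError:
                res["dcpcc_vs_input"] = None
        if fine_map.n_bins >= 8:
            try:
                _, _, slopes = M.ps_curve(fine_map)
                res["ps_slope"] = slopes[0]
            except ValueError:
                res["ps_slope"] = None
        if fine_map.n_bins >= 2 * 10 + 2:
            bset = M.insulation_boundaries(fine_map, window=10, prominence=0.1)
            res["n_boundaries_200bp"] = int(len(bset))
        summary["maps"] = res
        if out_dir is not None:
            from . import io as fio

            fio.write_contact_map(cg_map, out_dir / "map_cg.tsv")
            fio.write_contact_map(fine_map, out_dir / "map_200bp.tsv")

    blobs_per_frame = None
    if "blobs" in which:
        blobs_per_frame = []
        areas, eccs, cis = [], [], []
        for f in range(nuc_nm.shape[0]):
            frame_blobs, _ = B.detect_blobs(nuc_nm[f], frame=f)
            for b in frame_blobs:
                B.blob_morphometrics(b, nuc_nm[f])
                if b.hull_area_um2 is not None:
                    areas.append(b.hull_area_um2)
                if b.eccentricity is not None and not b.degenerate:
                    eccs.append(b.eccentricity)
            kept = B.compaction_index(nuc_nm[f], frame_blobs)
            cis.extend(b.compaction for b in kept)
            blobs_per_frame.append(frame_blobs)
        n_nuc = nuc_nm.shape[1]
        mean_sizes, _, _ = B.blob_size_profile(blobs_per_frame, n_nuc)
        dists, med, _ = B.blob_spatial_stats(blobs_per_frame, seed=seed)
        res = {
            "n_blobs_total": int(sum(len(bs) for bs in blobs_per_frame)),
            "median_inter_blob_nm": None if np.isnan(med) else float(med),
            "mean_blob_size_nucleosomes": float(np.mean(mean_sizes)),
            "median_compaction_index": float(np.median(cis)) if cis else None,
            "mean_eccentricity": float(np.mean(eccs)) if eccs else None,
            "packing_density_bp_per_um3": B.packing_density(
                all_nm, chain.region.length
            ),
        }
        if len(areas) >= 10:
            mode, s, sd = B.fit_lognormal(np.array(areas))
            res["blob_area_mode_um2"] = mode
            res["blob_area_sd_um2"] = sd
        summary["blobs"] = res

    if "motifs" in which and nuc_nm.shape[1] >= 4:
        motifs = T.tetra_contact_maps(nuc_nm)
        k = min(10, np.unique(motifs.vectors, axis=0).shape[0])
        clustered = T.cluster_motifs(motifs, k=k, seed=seed)
        summary["motifs"] = {
            "k": int(k),
            "top3_prevalence": [float(p) for p in clustered.prevalence[:3]],
            "closed_motif_prevalence": float(
                clustered.prevalence[
                    np.argmin(
                        [
                            np.abs(m[np.triu_indices(4, 1)] - 1).sum()
                            for m in clustered.cluster_means
                        ]
                    )
                ]
            ),
        }

    if "mechanics" in which:
        coms200, _ = M.coarse_grain_ensemble(ensemble, chain, 200)
        scale = chain.nm_per_sigma if ensemble.units == "reduced" else 1.0
        frames200 = coms200 * scale
        b_eff = X.effective_bond_length(frames200)
        res = {"b_eff_nm": b_eff}
        try:
            lw = X.lagwise_wlc(frames200, b_eff, n_boot=300, seed=seed)
            gl = X.global_wlc(frames200, b_eff, n_boot=300, seed=seed + 1)
            res.update(
                lp_lagwise_nm=lw.lp_nm,
                kb_lagwise_pn_nm2=lw.kb_pn_nm2,
                kb_lagwise_ci=list(lw.ci_kb),
                lp_global_nm=gl.lp_nm,
                kb_global_pn_nm2=gl.kb_pn_nm2,
                kb_global_ci=list(gl.ci_kb),
                kept_lags_global=gl.n,
            )
        except ValueError as exc:
            log.warning("WLC estimation failed: %s", exc)
        if ensemble.n_frames >= 10:
            fes = X.pca_fes(nuc_nm, grid_bins=min(40, max(10, ensemble.n_frames // 4)))
            res["fes_explained_variance"] = fes.explained_variance
            res["fes_basins"] = X.count_basins(fes)
            res["entropy_kb"] = X.boltzmann_entropy(fes)
        if chain.region.length >= 10_000:
            rg = X.rg_windows(all_nm, chain)
            res["rg_mean_nm"] = float(rg["rg_mean_nm"].mean())
        summary["mechanics"] = res

    return summary
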
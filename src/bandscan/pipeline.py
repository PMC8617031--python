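"""Config-driven end-to-end band-region runs.

A run proceeds: load (or receive) the assembled complex -> apply lysine
point mutations -> scaffold-mode perturbation (elastic-network animation)
-> hinge-loop resampling on every mode frame -> streaming clash filtering
and catalytic-distance evaluation -> per-site verdicts and a written report.

Loop-stage conformations are evaluated in vectorised batches and discarded
on the fly; with the default settings (5 modes x 28 frames x 10,000 draws)
that is 1.4 million conformations per run, none of which is ever
materialised as a full structure.

Sampling tiers escalate per site: a lysine already reachable under scaffold
modes alone keeps its verdict when the loop stage or the two-mode combined
scan is added, so escalation can only discover new contacts, never lose one.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.spatial import cKDTree

from .accessibility import (AccessibilityResult, BandRegionReport,
                            ContactCriteria, LysineSite, SiteAggregator,
                            detect_clash)
from .enm import (ConformerEnsemble, ElasticNetwork, FrameInfo, animate_mode,
                  build_anm, combined_mode_scan, normal_modes)
from .loop import HingeKinematics, LoopDefinition
from .structure import AtomSet, Structure, mutate_to_lysine, read_structure, select

__all__ = ["RunConfig", "EnmConfig", "SamplerConfig", "LoopConfig",
           "SiteConfig", "CriteriaConfig", "AtomAddress", "run_pipeline",
           "escalate_sampling", "run_escalating_pipeline", "TIERS"]

logger = logging.getLogger(__name__)

TIERS = ("modes-only", "modes+loop", "two-mode-combined+loop")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EnmConfig(_Strict):
    cutoff: float = 15.0
    gamma: float = 1.0
    n_modes: int = 5
    n_frames: int = 28
    rmsd_max: float = 10.0
    secondary_frame_picks: list[int] = Field(default=[5, 10, 15, 20, 25])


class SamplerConfig(_Strict):
    n_draws: int = 10000
    chunk: int = 10000


class LoopConfig(_Strict):
    chain_id: str
    res_start: int
    res_end: int
    attached_selection: str | None = None

    def to_loop(self) -> LoopDefinition:
        return LoopDefinition(self.chain_id, self.res_start, self.res_end,
                              self.attached_selection)


class SiteConfig(_Strict):
    chain_id: str
    res_seq: int
    label: str | None = None
    mutate: bool = False  # build the lysine side chain first (point mutant)


class AtomAddress(_Strict):
    chain_id: str
    res_seq: int
    name: str


class CriteriaConfig(_Strict):
    contact_threshold: float = 8.0
    clash_cutoff: float = 2.5
    anchor_max: float = 50.0
    salt_bridge_max: float = 4.0
    hbond_max: float = 3.5
    surface_rel_sasa_min: float = 0.25

    def to_criteria(self) -> ContactCriteria:
        return ContactCriteria(**self.model_dump())


class RunConfig(_Strict):
    """Declarative description of one band-region run.

    Unknown keys are rejected up front, before any computation starts.
    """

    structure_path: str | None = None
    loop: LoopConfig
    sites: list[SiteConfig]
    cys_sg: AtomAddress
    poi_selection: str
    enm: EnmConfig = EnmConfig()
    sampler: SamplerConfig = SamplerConfig()
    criteria: CriteriaConfig = CriteriaConfig()
    tier: Literal["modes-only", "modes+loop", "two-mode-combined+loop"] = "modes+loop"
    seed: int = 0
    output_dir: str | None = None

    def config_hash(self) -> str:
        """Hash of the scientific parameters (where outputs go is excluded)."""
        payload = self.model_dump_json(exclude={"output_dir"})
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def escalate_sampling(config: RunConfig, level: str) -> RunConfig:
    """Derive a config at the requested sampling tier.

    Tiers, in strictly increasing breadth: scaffold modes only; modes plus
    hinge-loop resampling; two-mode combined scan plus hinge-loop
    resampling. Only the sampling tier differs from the input config.
    """
    if level not in TIERS:
        raise ValueError(f"unknown sampling tier {level!r}; choose from {TIERS}")
    return config.model_copy(update={"tier": level})


# ---------------------------------------------------------------------------
# Stage drivers
# ---------------------------------------------------------------------------

def _prepare(config: RunConfig, structure: Structure | None):
    if structure is None:
        if config.structure_path is None:
            raise ValueError("config names no structure and none was passed")
        structure = read_structure(config.structure_path)
    for site in config.sites:
        if site.mutate:
            structure = mutate_to_lysine(structure, site.chain_id, site.res_seq)
    sites = [LysineSite.from_structure(structure, sc.chain_id, sc.res_seq,
                                       label=sc.label, is_mutant=sc.mutate)
             for sc in config.sites]
    sg_idx = structure.find_atom(config.cys_sg.chain_id, config.cys_sg.res_seq,
                                 config.cys_sg.name)
    poi = select(structure, config.poi_selection)
    return structure, sites, sg_idx, poi


def _stage1_ensemble(structure: Structure, config: RunConfig) -> ConformerEnsemble:
    """Scaffold-mode conformers: n_modes x n_frames animations, or the
    two-mode combined scan (picks x n_frames)."""
    e = config.enm
    if config.tier == "two-mode-combined+loop":
        return combined_mode_scan(structure, e.secondary_frame_picks,
                                  n_frames=e.n_frames, rmsd_max=e.rmsd_max,
                                  cutoff=e.cutoff, gamma=e.gamma)
    net = ElasticNetwork.from_structure(structure, cutoff=e.cutoff, gamma=e.gamma)
    modes = normal_modes(build_anm(net), e.n_modes)
    ensemble = ConformerEnsemble(parent=structure)
    for rank in range(1, e.n_modes + 1):
        ensemble.extend(animate_mode(structure, net, rank, n_frames=e.n_frames,
                                     rmsd_max=e.rmsd_max, modes=modes))
    return ensemble


def _evaluate_mode_frames(structure, stage1, sites, sg_idx, poi, moving_idx,
                          criteria, agg):
    nz_idx = np.array([s.nz_index for s in sites], dtype=np.int64)
    for coord, info in zip(stage1.frames, stage1.provenance):
        frame = structure.with_coord(coord)
        clashed = detect_clash(frame, AtomSet(frame, moving_idx),
                               AtomSet(frame, poi.indices),
                               criteria.clash_cutoff) > 0
        distances = np.linalg.norm(coord[nz_idx] - coord[sg_idx], axis=1)
        agg.add_frame(distances, clashed, info.to_dict())


def _evaluate_loop_stage(structure, stage1, kin, sites, sg_idx, poi, criteria,
                         sampler: SamplerConfig, rng, agg):
    nz_idx = np.array([s.nz_index for s in sites], dtype=np.int64)
    base_pos = {g: l for l, g in enumerate(kin.base_indices)}
    if sg_idx not in base_pos:
        raise ValueError("catalytic atom is not part of the hinge's moving "
                         "set; check the attached-group selection")
    sg_local = base_pos[sg_idx]
    poi_static = np.setdiff1d(poi.indices, kin.moving_superset)
    for f_index, (coord, info) in enumerate(zip(stage1.frames, stage1.provenance)):
        tree = cKDTree(coord[poi_static])
        nz_coords = coord[nz_idx]
        base = coord[kin.base_indices]
        frame_info = info.to_dict()
        done = 0
        while done < sampler.n_draws:
            b = min(sampler.chunk, sampler.n_draws - done)
            angles = rng.uniform(-180.0, 180.0, size=(b, kin.n_torsions))
            batch = kin.apply_batch(angles, base)
            moving_pts = batch[:, kin.moving_local, :]
            d_env, _ = tree.query(moving_pts.reshape(-1, 3), k=1)
            clashed = d_env.reshape(b, -1).min(axis=1) < criteria.clash_cutoff
            sg_pos = batch[:, sg_local, :]
            dists = np.linalg.norm(sg_pos[:, None, :] - nz_coords[None, :, :],
                                   axis=-1)
            offset = done

            def provenance_fn(row, _f=frame_info, _o=offset):
                return {"stage1": _f, "draw_index": _o + row}

            agg.add_batch(dists, clashed, provenance_fn=provenance_fn)
            done += b
        logger.debug("loop stage: frame %d evaluated %d draws", f_index, done)


def run_pipeline(config: RunConfig,
                 structure: Structure | None = None) -> BandRegionReport:
    """Execute one tier of the band-region analysis and write its report.

    Returns the :class:`BandRegionReport`; when ``config.output_dir`` is set,
    ``report.tsv`` (one row per site) and ``report.json`` (full provenance)
    are written there, byte-identical across runs with the same seed.
    """
    structure, sites, sg_idx, poi = _prepare(config, structure)
    criteria = config.criteria.to_criteria()
    loop = config.loop.to_loop()
    kin = HingeKinematics(structure, loop)
    moving_idx = kin.moving_superset

    stage1 = _stage1_ensemble(structure, config)
    logger.info("stage 1 (%s): %d scaffold-mode conformers", config.tier,
                len(stage1))

    agg = SiteAggregator(sites, criteria)
    if config.tier == "modes-only":
        _evaluate_mode_frames(structure, stage1, sites, sg_idx, poi,
                              moving_idx, criteria, agg)
    else:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, TIERS.index(config.tier)]))
        _evaluate_loop_stage(structure, stage1, kin, sites, sg_idx, poi,
                             criteria, config.sampler, rng, agg)
    logger.info("evaluated %d conformations (%d clash-free)",
                agg.n_frames, agg.n_surviving)

    report = agg.finalise(structure, metadata={
        "tier": config.tier,
        "stage1_conformers": len(stage1),
        "loop_conformations_evaluated": (0 if config.tier == "modes-only"
                                         else agg.n_frames),
        "seed": config.seed,
        "config_hash": config.config_hash(),
    })
    if config.output_dir:
        _write_report(report, config.output_dir)
    return report


def run_escalating_pipeline(config: RunConfig,
                            structure: Structure | None = None,
                            tiers=TIERS) -> BandRegionReport:
    """Per-site tier escalation.

    Each tier is run in order; a site classified in-band (or chemically
    excluded) at any tier keeps that verdict, and only still-out-of-band
    sites are re-examined with broader sampling. Verdicts are therefore
    monotone: escalation never turns in-band into out-of-band.
    """
    merged: dict[str, AccessibilityResult] = {}
    tier_meta = []
    report = None
    for tier in tiers:
        report = run_pipeline(escalate_sampling(config, tier), structure)
        tier_meta.append({"tier": tier, **{k: report.metadata[k] for k in
                          ("stage1_conformers", "n_frames", "n_surviving")}})
        for result in report.results:
            label = result.site.label
            prior = merged.get(label)
            if prior is None or (prior.verdict == "out_of_band"
                                 and result.verdict != "out_of_band"):
                merged[label] = result
            elif prior.verdict == result.verdict:
                # keep the better (smaller) minimum distance for reporting
                if result.min_distance < prior.min_distance:
                    merged[label] = result
        if all(r.verdict != "out_of_band" for r in merged.values()):
            break
    final = BandRegionReport(
        results=[merged[sc.label or f"K{sc.res_seq}"] for sc in config.sites],
        metadata={"escalation": tier_meta, "seed": config.seed,
                  "config_hash": config.config_hash()})
    if config.output_dir:
        _write_report(final, config.output_dir)
    return final


def _write_report(report: BandRegionReport, output_dir: str) -> None:
    os.makedirs(output_dir, exist_ok=True)
    rows = report.to_rows()
    with open(os.path.join(output_dir, "report.tsv"), "w") as fh:
        fh.write("label\tmin_distance\tn_contact_frames\texclusion\tverdict\n")
        for row in rows:
            md = row["min_distance"]
            md_text = "inf" if not np.isfinite(md) else f"{md:.4f}"
            fh.write(f"{row['label']}\t{md_text}\t{row['n_contact_frames']}\t"
                     f"{row['exclusion']}\t{row['verdict']}\n")
    payload = {"metadata": report.metadata,
               "results": [{**row,
                            "best_frame": res.best_frame,
                            "partners": res.partners,
                            "warnings": res.warnings}
                           for row, res in zip(rows, report.results)]}
    with open(os.path.join(output_dir, "report.json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
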
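"""End-to-end planning runs: phantom -> lead field -> montage -> dose -> evaluation."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

import tesplan
from tesplan.cortex import make_sphere_mesh, nearest_patch, parcellate_surface
from tesplan.dosimetry import StimulationProtocol, dose_report
from tesplan.fdm import assemble_fdm_system, lead_field_from_reciprocity
from tesplan.phantom import DEFAULT_4SHELL, ShellSpec, build_shell_phantom, place_geodesic_electrodes
from tesplan.targeting import MontageEvaluator, SafetyLimits, build_sham_montage, plan_montage
from tesplan.io import save_electrode_positions, save_montage_json

log = logging.getLogger("tesplan")

__all__ = ["PlanConfig", "run_plan"]


@dataclass
class PlanConfig:
    """Configuration of a full planning run on a synthetic shell phantom."""

    spacing_mm: float = 4.0
    n_electrodes: int = 64
    cortex_radius_mm: float = 70.0
    cortex_subdivisions: int = 3
    patch_area_cm2: float = 1.0
    target_point_mm: tuple[float, float, float] | None = None  # default: top of cortex
    polarity: str = "cortical_surface_anodal"
    n_sources: int = 8
    n_sinks: int = 8
    requested_total_ma: float = 2.0
    max_channel_ua: float = 200.0
    max_total_ma: float = 2.0
    solver_tol: float = 1e-8
    seed: int = 0
    out_dir: str = "plan_out"

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def run_plan(config: PlanConfig) -> dict:
    """Run the whole planning chain and write a bundle to ``config.out_dir``.

    Returns a dictionary with the montage, sham montage, dose report and
    per-patch evaluation; deterministic for a fixed config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    limits = SafetyLimits(config.max_channel_ua, config.max_total_ma)

    log.info("stage phantom: 4-shell, spacing %.1f mm", config.spacing_mm)
    model = build_shell_phantom(DEFAULT_4SHELL, spacing_mm=config.spacing_mm)
    center = model._center_mm

    log.info("stage electrodes: %d geodesic positions", config.n_electrodes)
    electrodes = place_geodesic_electrodes(model, config.n_electrodes)
    save_electrode_positions(electrodes, out / "electrodes.csv")

    log.info("stage cortex: parcellating")
    mesh = make_sphere_mesh(
        radius_mm=config.cortex_radius_mm,
        subdivisions=config.cortex_subdivisions,
        center_mm=tuple(center),
    )
    parcellation = parcellate_surface(mesh, config.patch_area_cm2)

    log.info("stage leadfield: %d electrode solves", config.n_electrodes)
    system = assemble_fdm_system(model)
    lfm, solutions = lead_field_from_reciprocity(
        system, electrodes, parcellation, tol=config.solver_tol, return_solutions=True
    )

    target_point = (
        np.asarray(config.target_point_mm)
        if config.target_point_mm is not None
        else center + np.array([0.0, 0.0, config.cortex_radius_mm])
    )
    patch_id = nearest_patch(parcellation, target_point)

    log.info("stage plan: target patch %d, %s", patch_id, config.polarity)
    montage = plan_montage(
        lfm,
        patch_id,
        config.polarity,
        config.n_sources,
        config.n_sinks,
        config.requested_total_ma,
        limits,
    )
    sham = build_sham_montage(montage, electrodes)
    provenance = {
        "config_digest": config.digest(),
        "tesplan_version": tesplan.__version__,
        "target_patch": patch_id,
    }
    save_montage_json(montage, out / "montage.json", meta=provenance)
    save_montage_json(sham, out / "sham_montage.json", meta=provenance)

    log.info("stage evaluate")
    evaluator = MontageEvaluator(system, electrodes, parcellation, solutions=solutions)
    evaluation = evaluator.evaluate(montage)
    evaluation.to_csv(out / "evaluation.csv", index=False)

    protocol = StimulationProtocol(
        kind="tpcs",
        total_current_ma=montage.total_source_ua / 1000.0,
        session_s=1020.0,
        pulse_s=0.1,
        frequency_hz=0.5,
        electrode_area_cm2=float(config.n_sources),
        label="planned pulsed protocol",
    )
    dose = dose_report(protocol)
    (out / "dose.json").write_text(
        json.dumps(
            {
                "injection_time_s": dose.injection_time_s,
                "total_charge_mc": dose.total_charge_mc,
                "mean_current_density_ma_per_cm2": dose.mean_current_density_ma_per_cm2,
            },
            indent=2,
        )
    )
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return {
        "model": model,
        "electrodes": electrodes,
        "parcellation": parcellation,
        "lead_field": lfm,
        "target_patch": patch_id,
        "montage": montage,
        "sham": sham,
        "evaluation": evaluation,
        "dose": dose,
        "provenance": provenance,
    }
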
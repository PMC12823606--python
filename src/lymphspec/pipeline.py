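"""End-to-end pipeline: cubes -> masks -> ROI spectra -> deltas -> staging.

``run_measurement`` handles one side of one site (up to three repeat
cubes): segment each repeat, keep the best-framed one, average the
central-ROI tissue spectra and compute the indices. ``run_cohort``
drives a whole synthetic cohort (streaming patient by patient in cube
mode), builds the per-site delta table, fits the staging model on the
physician-flagged affected sites, and assembles the Spearman
correlation table of every metric against clinical stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical import percent_change, questionnaire_score
from .hypercube import Hypercube, Spectrum
from .indices import DEFAULT_SCALING, IndexScaling, side_indices
from .model import HsiStagingModel, HsiStagingResults
from .roi import (
    MissingMeasurementError,
    central_roi_mask,
    delta_metrics,
)
from .segmentation import body_mask, select_best_repeat
from .stats import TestResult, spearman
from .synthetic import CohortConfig, PatientSim, SyntheticCohort, iter_patients

logger = logging.getLogger("lymphspec")

__all__ = ["RunConfig", "CohortResults", "run_measurement", "run_cohort"]


@dataclass
class RunConfig:
    """Pipeline knobs: ROI size, index scaling, clustering and staging sign."""

    roi_diameter: int = 100
    scaling: IndexScaling = field(default_factory=lambda: DEFAULT_SCALING)
    k: int = 3
    linkage: str = "ward"
    staging_direction: int = 1  # +1: high imaging stage = large positive dLWR


def run_measurement(cubes: list[Hypercube], config: RunConfig | None = None) -> dict:
    """Process the repeats of one (patient, site, side) measurement.

    Returns a result row with the chosen repeat, segmentation
    provenance, the representative spectrum and its indices. Fewer than
    three repeats are tolerated with a warning; an empty body-ROI
    intersection raises :class:`MissingMeasurementError`.
    """
    config = config or RunConfig()
    if not cubes:
        raise ValueError("no repeat cubes given")
    if len(cubes) < 3:
        logger.warning("only %d of 3 repeats present", len(cubes))
    roi = central_roi_mask(cubes[0].spatial_shape, config.roi_diameter)
    masks = [body_mask(c, scaling=config.scaling, central_region=roi) for c in cubes]
    best = select_best_repeat(masks, roi)
    spectrum = _roi_spectrum(cubes[best], masks[best].mask, roi)
    idx = side_indices(spectrum, scaling=config.scaling)
    return {
        "repeat": best,
        "threshold": masks[best].threshold,
        "method": masks[best].method,
        "coverage_central": masks[best].coverage_central,
        "n_roi_pixels": int((masks[best].mask & roi).sum()),
        "spectrum": spectrum,
        "indices": idx,
    }


def _roi_spectrum(cube: Hypercube, body: np.ndarray, roi: np.ndarray) -> Spectrum:
    from .roi import representative_spectrum

    return representative_spectrum(cube, body, roi)


@dataclass
class CohortResults:
    """All cohort-level outputs of one pipeline run."""

    delta_table: pd.DataFrame
    staging: HsiStagingResults
    correlations: pd.DataFrame
    adjacent_tests: dict[str, TestResult]

    def summary(self) -> str:
        top = self.correlations.sort_values("spearman_r", key=abs, ascending=False)
        lines = [self.staging.summary(), "", "Spearman r vs clinical stage:"]
        for _, row in top.iterrows():
            lines.append(f"  {row['metric']:<28} r = {row['spearman_r']:+.3f} "
                         f"(n = {int(row['n'])})")
        return "\n".join(lines)


def _side_indices_of(patient: PatientSim, site_idx: int, side: str,
                     config: RunConfig):
    sim = patient.sites[site_idx]
    if sim.spectra is not None:
        return side_indices(sim.spectra[side], scaling=config.scaling)
    row = run_measurement(sim.cubes[side], config)
    return row["indices"]


def run_cohort(
    cohort: SyntheticCohort | CohortConfig,
    config: RunConfig | None = None,
) -> CohortResults:
    """Run the full analysis over a (synthetic) cohort.

    Accepts a materialized cohort or a :class:`CohortConfig` (the
    latter streams patients to bound memory in cube mode). The staging
    model and the dLWR stage comparisons use only measurements of sites
    flagged as affected, mirroring how affected-site analyses are
    restricted clinically; patient-level metrics use all patients.
    """
    if isinstance(cohort, CohortConfig):
        cohort_cfg = cohort
        patients_iter = iter_patients(cohort_cfg)
    else:
        cohort_cfg = cohort.config
        patients_iter = iter(cohort.patients)
    config = config or RunConfig()
    if cohort_cfg.render == "cubes":
        config = RunConfig(roi_diameter=cohort_cfg.roi_diameter,
                           scaling=config.scaling, k=config.k,
                           linkage=config.linkage,
                           staging_direction=config.staging_direction)

    rows = []
    clin_rows = []
    patient_rows = []
    for patient in patients_iter:
        for i, sim in enumerate(patient.sites):
            try:
                aff = _side_indices_of(patient, i, "affected", config)
                una = _side_indices_of(patient, i, "unaffected", config)
            except MissingMeasurementError as err:
                logger.warning("%s/%s: %s", patient.patient, sim.site, err)
                continue
            d = delta_metrics(aff, una)
            rows.append({
                "patient": patient.patient, "site": sim.site,
                "isl_stage": patient.stage, "site_affected": sim.affected_flag,
                "d_lwr": d.d_lwr, "d_twi": d.d_twi, "d_tli": d.d_tli,
            })
            c = patient.clinical
            clin_rows.append({
                "patient": patient.patient, "site": sim.site,
                "isl_stage": patient.stage, "site_affected": sim.affected_flag,
                "circumference_pct": percent_change(
                    c["circumference_affected"][i], c["circumference_unaffected"][i]),
                "cutis_pct": percent_change(
                    c["cutis_affected"][i], c["cutis_unaffected"][i]),
                "subcutis_pct": percent_change(
                    c["subcutis_affected"][i], c["subcutis_unaffected"][i]),
            })
        prow = {"patient": patient.patient, "isl_stage": patient.stage}
        for key, val in patient.clinical.items():
            if not isinstance(val, tuple):
                prow[key] = val
        for cat, items in patient.questionnaire.items():
            try:
                prow[f"questionnaire_{cat}"] = questionnaire_score(items)
            except ValueError:
                prow[f"questionnaire_{cat}"] = np.nan
        patient_rows.append(prow)

    delta = pd.DataFrame(rows)
    clin = pd.DataFrame(clin_rows)
    patients = pd.DataFrame(patient_rows)

    affected = delta[delta["site_affected"]]
    model = HsiStagingModel(
        affected["d_lwr"].to_numpy(),
        le_stage=affected["isl_stage"].to_numpy(),
        k=config.k, linkage=config.linkage, direction=config.staging_direction,
    )
    staging = model.fit()

    corr_rows = [{"metric": "hsi_stage",
                  "spearman_r": staging.spearman_r_, "n": staging.nobs}]
    for col in ("d_twi", "d_lwr", "d_tli"):
        corr_rows.append({
            "metric": col,
            "spearman_r": spearman(affected["isl_stage"], affected[col]),
            "n": len(affected),
        })
    clin_aff = clin[clin["site_affected"]]
    for col in ("circumference_pct", "cutis_pct", "subcutis_pct"):
        corr_rows.append({
            "metric": col,
            "spearman_r": spearman(clin_aff["isl_stage"], clin_aff[col]),
            "n": len(clin_aff),
        })
    for col in patients.columns:
        if col in ("patient", "isl_stage"):
            continue
        ok = patients[col].notna()
        corr_rows.append({
            "metric": col,
            "spearman_r": spearman(patients.loc[ok, "isl_stage"],
                                   patients.loc[ok, col]),
            "n": int(ok.sum()),
        })
    correlations = pd.DataFrame(corr_rows)

    return CohortResults(
        delta_table=delta,
        staging=staging,
        correlations=correlations,
        adjacent_tests=staging.adjacent_tests_,
    )
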
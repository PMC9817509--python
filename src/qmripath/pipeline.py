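"""End-to-end cohort analysis: volumes -> parameter maps -> VOI feature
table joined with pathology, ready for the association battery."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import dce as dce_mod
from . import dki as dki_mod
from .features import BinSpec, feature_table
from .phantom import AcquisitionConfig, PatientRecord
from .voi import extract_values

logger = logging.getLogger(__name__)

PARAM_ORDER = ("ktrans", "kep", "ve", "d", "k")


def analyze_cohort(records: list[PatientRecord], config: AcquisitionConfig,
                   dki_settings: dki_mod.FitSettings | None = None,
                   pk_settings: dce_mod.PKFitSettings | None = None,
                   conversion: dce_mod.ConversionSettings | None = None,
                   bins: BinSpec | None = None,
                   fit_dce: bool = True) -> pd.DataFrame:
    """Fit every lesion's maps and assemble the per-lesion cohort table.

    Lesions without a DWI (or DCE) volume keep their diffusion (or
    perfusion) feature cells missing, mirroring incomplete acquisitions.
    Returns one row per lesion: imaging features plus pathology columns.
    """
    dki_settings = dki_settings or dki_mod.FitSettings()
    pk_settings = pk_settings or dce_mod.PKFitSettings()
    conversion = conversion or dce_mod.ConversionSettings(mode="linear", calibration=0.5)
    aif = dce_mod.population_aif(config.dce_times_min,
                                 arrival_min=config.bolus_arrival_min)

    lesion_values: dict[str, dict] = {}
    for rec in records:
        mask = rec.truth.lesion_mask
        per_param: dict[str, np.ndarray | None] = {p: None for p in PARAM_ORDER}
        if rec.dwi is not None:
            fit = dki_mod.fit_dki_map(rec.dwi, mask, config.b_values, dki_settings)
            for p in ("d", "k"):
                per_param[p] = _safe_extract(fit[p], mask, rec.patient_id, p)
        if fit_dce and rec.dce is not None:
            pk = dce_mod.fit_tofts_map(rec.dce, mask, aif, pk_settings,
                                       conversion=conversion,
                                       baseline_count=config.dce_baseline_volumes)
            for p in ("ktrans", "kep", "ve"):
                per_param[p] = _safe_extract(pk[p], mask, rec.patient_id, p)
        lesion_values[rec.patient_id] = per_param

    feats = feature_table(lesion_values, bins)
    from .phantom import pathology_frame

    path = pathology_frame(records)
    return feats.join(path)


def _safe_extract(pmap, mask, patient_id, param):
    try:
        vals, n_excluded = extract_values(pmap, mask)
    except ValueError:
        logger.warning("%s: no valid %s voxels", patient_id, param)
        return None
    if n_excluded:
        logger.info("%s: excluded %d invalid %s voxels", patient_id, n_excluded, param)
    return vals
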
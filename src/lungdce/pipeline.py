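"""End-to-end quantification: series in, perfusion maps + AIF out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aif import AifCurve, detect_aif_voxels, extract_aif
from .deconv import PerfusionMaps, quantify_lung
from .errors import ValidationError
from .kinetics import ConcentrationSeries, detect_bolus_arrival, signal_to_concentration
from .series import DynamicSeries


@dataclass
class QuantResult:
    maps: PerfusionMaps
    aif: AifCurve
    aif_voxels: np.ndarray
    conc: ConcentrationSeries
    arrival_frame: int


def quantify_series(
    series: DynamicSeries,
    lung_mask: np.ndarray | None = None,
    trunk_mask: np.ndarray | None = None,
    mode: str = "linear",
    sat_beta: float | None = None,
    baseline_conc=0.0,
    truncation_frac: float = 0.15,
    arrival_k: float = 3.0,
    aif_top_quantile: float = 0.01,
) -> QuantResult:
    """Run arrival detection, conversion, AIF extraction and deconvolution.

    If ``trunk_mask`` is given it both seeds arrival detection and bypasses
    the AIF voxel search; otherwise the trunk is located automatically in
    the whole volume and the arrival re-estimated on the detected voxels.
    """
    lung = series.lung_mask if lung_mask is None else lung_mask
    if lung is None:
        raise ValidationError("a lung mask is required")
    trunk = series.trunk_mask if trunk_mask is None else trunk_mask

    if trunk is not None:
        arrival = detect_bolus_arrival(series, trunk, k=arrival_k)
        conc = signal_to_concentration(series, arrival, mode=mode,
                                       sat_beta=sat_beta,
                                       baseline_conc=baseline_conc, mask=lung)
        aif_voxels = np.asarray(trunk).astype(bool)
    else:
        whole = np.ones(series.data.shape[:3], dtype=bool)
        arrival = detect_bolus_arrival(series, whole, k=arrival_k)
        conc = signal_to_concentration(series, arrival, mode=mode,
                                       sat_beta=sat_beta,
                                       baseline_conc=baseline_conc, mask=lung)
        aif_voxels = detect_aif_voxels(conc, search_mask=None,
                                       top_quantile=aif_top_quantile)
        refined = detect_bolus_arrival(series, aif_voxels, k=arrival_k)
        if refined != arrival:
            arrival = refined
            conc = signal_to_concentration(series, arrival, mode=mode,
                                           sat_beta=sat_beta,
                                           baseline_conc=baseline_conc, mask=lung)

    aif_curve = extract_aif(conc, aif_voxels)
    maps = quantify_lung(conc, lung, aif_curve, truncation_frac=truncation_frac)
    return QuantResult(maps=maps, aif=aif_curve, aif_voxels=aif_voxels,
                       conc=conc, arrival_frame=arrival)
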
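"""Brain/CSF threshold splitting and voxel-count volumetry.

The intracranial space is split into parenchyma and CSF by a single global
intensity threshold (Otsu's criterion by default, on T2-like contrast where
CSF is hyperintense), and compartment volumes are obtained by counting
voxels -- no partial-volume weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .volume_model import (
    COMPARTMENT_ROLES,
    CompartmentVolumes,
    LabeledVolume,
    ParameterError,
)

__all__ = ["ThresholdResult", "split_brain_csf", "compute_volumes", "volume_ratio"]


@dataclass
class ThresholdResult:
    """Outcome of the brain/CSF split.

    ``csf_mask`` and ``brain_mask`` partition the intracranial mask exactly.
    """

    threshold: float
    csf_mask: np.ndarray
    brain_mask: np.ndarray


def split_brain_csf(
    intensity: np.ndarray,
    intracranial_mask: np.ndarray,
    threshold: float | None = None,
) -> ThresholdResult:
    """Split intracranial voxels into brain (< threshold) and CSF (>= threshold).

    When no threshold is given it is chosen by Otsu's bimodal-histogram
    criterion over the intracranial intensities. A degenerate (constant)
    histogram yields a midpoint threshold with a warning.
    """
    intensity = np.asarray(intensity, dtype=float)
    intracranial_mask = np.asarray(intracranial_mask, dtype=bool)
    if intensity.shape != intracranial_mask.shape:
        raise ParameterError("intensity and mask shapes differ")
    values = intensity[intracranial_mask]
    if values.size == 0:
        raise ParameterError("intracranial mask is empty")
    if threshold is None:
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:
            warnings.warn(
                "intensity histogram is degenerate; threshold set to midpoint",
                stacklevel=2,
            )
            threshold = lo
        else:
            threshold = float(threshold_otsu(values))
    csf = intracranial_mask & (intensity >= threshold)
    brain = intracranial_mask & ~csf
    return ThresholdResult(threshold=float(threshold), csf_mask=csf, brain_mask=brain)


def compute_volumes(vol: LabeledVolume) -> CompartmentVolumes:
    """Voxel-count volumetry: compartment volume = count x voxel volume, in mL.

    A required compartment with no voxels contributes 0 mL (with a warning
    raised by the container), never an error.
    """
    vv = vol.voxel_volume_mm3 / 1000.0  # mL per voxel
    codes = vol.schema.codes
    counts = np.bincount(vol.labels.ravel(), minlength=max(codes.values()) + 1)
    return CompartmentVolumes(
        **{role: float(counts[codes[role]] * vv) for role in COMPARTMENT_ROLES}
    )


def volume_ratio(volumes: CompartmentVolumes, role: str) -> float:
    """Compartment volume divided by total intracranial volume (fraction)."""
    return volumes.vr(role)
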
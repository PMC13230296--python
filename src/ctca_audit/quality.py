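"""Image-quality metrics for contrast-enhanced coronary CT.

Three per-case scores quantify how clearly the arteries stand out:

* **artery contrast enhancement** (HU) — mean attenuation inside the artery
  minus the mean over the immediately surrounding non-arterial tissue;
* **contrast-to-noise ratio** (dimensionless) — the same contrast divided by
  the noise standard deviation measured in that surrounding tissue;
* **edge sharpness** (HU/mm) — mean spacing-aware attenuation-gradient
  magnitude over the arterial boundary voxels.

"Surrounding non-arterial tissue" is realised as a peri-arterial ring: the
voxels reached by `width` face-connected dilation steps of the artery mask,
minus the artery itself (default width 3 voxels, which at CTCA resolution
stays within the immediate peri-arterial tissue).  Noise is the population
(ddof=0) SD over that same ring, so a single region definition drives both
CNR terms.  The gradient is central differences divided by 2·spacing per
axis with no smoothing; boundary voxels are artery voxels with at least one
face-connected background neighbour, excluding voxels on the volume border
where central differences are undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import CTVolume, Mask, check_aligned

#: face-connected (6-neighbour) structuring element used throughout
_STRUCT6 = ndimage.generate_binary_structure(3, 1)

DEFAULT_RING_WIDTH = 3


@dataclass
class QualityMetrics:
    cnr: float
    contrast_enhancement: float
    edge_sharpness: float
    ring_width_voxels: int = DEFAULT_RING_WIDTH


def peri_arterial_ring(mask: Mask, width: int = DEFAULT_RING_WIDTH) -> Mask:
    """Ring of voxels within `width` face-connected dilation steps of the
    artery, excluding the artery itself."""
    if width < 1:
        raise ValueError("ring width must be >= 1 voxel")
    fg = mask.foreground()
    if not fg.any():
        raise ValueError(f"{mask.id or 'mask'}: empty artery mask")
    if fg.all():
        raise ValueError(f"{mask.id or 'mask'}: artery mask fills the volume")
    dilated = ndimage.binary_dilation(fg, structure=_STRUCT6, iterations=width)
    ring = dilated & ~fg
    return Mask(ring.astype(np.uint8), mask.spacing, mask.affine, "binary", mask.id)


def artery_contrast_enhancement(volume: CTVolume, artery: Mask, width: int = DEFAULT_RING_WIDTH) -> float:
    """Mean HU inside the artery minus mean HU over the peri-arterial ring."""
    check_aligned(volume, artery)
    fg = artery.foreground()
    ring = peri_arterial_ring(artery, width).foreground()
    return float(volume.values[fg].mean(dtype=np.float64)
                 - volume.values[ring].mean(dtype=np.float64))


def contrast_to_noise_ratio(volume: CTVolume, artery: Mask, width: int = DEFAULT_RING_WIDTH) -> float:
    """(artery mean − ring mean) / ring population SD."""
    check_aligned(volume, artery)
    fg = artery.foreground()
    ring = peri_arterial_ring(artery, width).foreground()
    ring_vals = volume.values[ring].astype(np.float64)
    sd = float(ring_vals.std(ddof=0))
    if sd == 0.0:
        raise ValueError("no measurable noise: peri-arterial ring has zero standard deviation")
    return float((volume.values[fg].mean(dtype=np.float64) - ring_vals.mean()) / sd)


def _boundary_voxels(fg: np.ndarray) -> np.ndarray:
    """Artery voxels with >= 1 face-connected background neighbour, away
    from the volume border."""
    eroded = ndimage.binary_erosion(fg, structure=_STRUCT6, border_value=1)
    boundary = fg & ~eroded
    interior = np.zeros_like(boundary)
    interior[1:-1, 1:-1, 1:-1] = True
    return boundary & interior


def edge_sharpness(volume: CTVolume, artery: Mask) -> float:
    """Mean gradient magnitude of HU (central differences, HU/mm) over the
    arterial boundary voxels."""
    check_aligned(volume, artery)
    fg = artery.foreground()
    if not fg.any():
        raise ValueError("empty artery mask")
    boundary = _boundary_voxels(fg)
    if not boundary.any():
        raise ValueError("no eligible boundary voxels away from the volume border")
    gx, gy, gz = np.gradient(volume.values.astype(np.float64), *volume.spacing)
    mag = np.sqrt(gx**2 + gy**2 + gz**2)
    return float(mag[boundary].mean())


def quality_metrics(volume: CTVolume, artery: Mask, width: int = DEFAULT_RING_WIDTH) -> QualityMetrics:
    """All three quality scores for one volume/artery pair."""
    return QualityMetrics(
        cnr=contrast_to_noise_ratio(volume, artery, width),
        contrast_enhancement=artery_contrast_enhancement(volume, artery, width),
        edge_sharpness=edge_sharpness(volume, artery),
        ring_width_voxels=width,
    )
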
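"""Compartment masks: validation of external segmentations and a
geometry-prior fallback segmenter.

The quality map needs a partition of the slice into background, total
abdominal muscle (TAMA), visceral fat (VFA) and subcutaneous fat (SFA).
In clinical use this comes from an external segmenter and is only
*validated* here.  For synthetic slices — an elliptical body with a
subcutaneous fat layer, a muscle ring and a visceral cavity — the classical
fallback segmenter below recovers the compartments from HU thresholds and
ring geometry alone.  It is phantom-grade, not clinical-grade: real anatomy
(paraspinal clefts, fascia, bowel contents touching the muscle wall) will
defeat its geometric assumptions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from musclemap.errors import AlignmentError, SegmentationError, ValidationError
from musclemap.io import CTSlice, MaskImage
from musclemap.quality import round_half_away_from_zero

__all__ = [
    "CompartmentMask",
    "FallbackParams",
    "validate_compartments",
    "fallback_segment",
    "dice",
]

# 8-neighbor connectivity for components; hole filling keeps scipy's default
# 4-neighbor background connectivity.
_S8 = np.ones((3, 3), dtype=bool)

_CODES = {"background": 0, "tama": 1, "vfa": 2, "sfa": 3}


@dataclass
class CompartmentMask:
    """Mutually exclusive compartment labels over a slice.

    ``labels`` uses the dialect {0: background, 1: TAMA, 2: VFA, 3: SFA};
    a single code per pixel makes exclusivity structural.  ``provenance``
    records whether the mask came from an external segmenter, the fallback
    segmenter, or a phantom's ground truth.
    """

    labels: np.ndarray
    provenance: str = "external"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels).astype(np.uint8)
        if self.provenance not in ("external", "fallback", "truth"):
            raise ValidationError(f"unknown mask provenance {self.provenance!r}")

    def mask_of(self, name: str) -> np.ndarray:
        return self.labels == _CODES[name]

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.labels == code))
            for name, code in _CODES.items()
        }


def validate_compartments(mask: MaskImage, ct_slice: CTSlice) -> CompartmentMask:
    """Turn an externally supplied label image into a validated CompartmentMask.

    Plausibility checks stand in for the radiologist's visual review of the
    segmentation: they are heuristic, always reported (via ``warnings.warn``
    and the returned ``warnings`` list), never silently passed.  An empty
    muscle compartment is a hard error because the quality map is undefined
    without it.
    """
    if mask.labels.shape != ct_slice.pixels.shape:
        raise AlignmentError(
            f"mask shape {mask.labels.shape} != slice shape {ct_slice.pixels.shape}"
        )
    out = CompartmentMask(labels=mask.labels, provenance="external")
    tama = out.mask_of("tama")
    n_tama = int(tama.sum())
    if n_tama == 0:
        raise ValidationError("TAMA is empty: muscle quality map undefined")

    tama_hu = ct_slice.pixels[tama]
    frac_below = float(np.mean(tama_hu < -190))
    if frac_below > 0.5:
        out.warnings.append(
            "TAMA implausible: "
            f"{100 * frac_below:.0f}% of TAMA pixels below -190 HU "
            "(heuristic check; thresholds are not clinically validated)"
        )
    mean_hu = float(tama_hu.mean())
    if not -50.0 <= mean_hu <= 120.0:
        out.warnings.append(
            f"TAMA mean density {mean_hu:.1f} HU outside the plausible "
            "muscle range [-50, 120] HU (heuristic check)"
        )
    for msg in out.warnings:
        warnings.warn(msg, stacklevel=2)
    return out


@dataclass(frozen=True)
class FallbackParams:
    """Geometry priors for the fallback segmenter.

    ``rim_width_px`` is the width of the body-rim band used to separate
    subcutaneous from visceral fat; 3 px is the smallest band robust to
    one-pixel boundary noise on phantoms.
    """

    air_threshold_hu: float = -500.0
    rim_width_px: int = 3
    fat_lo_hu: float = -190.0
    fat_hi_hu: float = -30.0
    muscle_lo_hu: float = -29.0
    muscle_hi_hu: float = 150.0


def _largest_component(binary: np.ndarray) -> np.ndarray | None:
    lbl, n = ndi.label(binary, structure=_S8)
    if n == 0:
        return None
    sizes = ndi.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
    return lbl == (1 + int(np.argmax(sizes)))


def fallback_segment(ct_slice: CTSlice, params: FallbackParams | None = None) -> CompartmentMask:
    """Segment an axial slice into body compartments from ring geometry.

    Steps: (1) body = hole-filled largest connected component above the air
    threshold; (2) fat candidates = body pixels in the gross-fat HU range;
    (3) subcutaneous fat = fat components touching the body-rim band;
    (4) the muscle ring = muscle-range components on the outer edge of the
    remaining core, with enclosed non-cavity pockets (intramuscular fat)
    reclaimed into TAMA; (5) visceral fat = the remaining interior fat.
    """
    if params is None:
        params = FallbackParams()
    hu = round_half_away_from_zero(ct_slice.pixels)

    body = _largest_component(hu >= params.air_threshold_hu)
    if body is None:
        raise SegmentationError("no body found above the air threshold")
    body = ndi.binary_fill_holes(body)

    fat = body & (hu >= params.fat_lo_hu) & (hu <= params.fat_hi_hu)

    rim = body & ~ndi.binary_erosion(body, structure=_S8, iterations=params.rim_width_px)
    fat_lbl, n_fat = ndi.label(fat, structure=_S8)
    rim_codes = np.setdiff1d(np.unique(fat_lbl[rim]), [0])
    sfa = np.isin(fat_lbl, rim_codes)

    core = _largest_component(body & ~sfa)
    if core is None:
        raise SegmentationError("no tissue core inside the subcutaneous fat layer")
    core = ndi.binary_fill_holes(core)

    muscle_cand = core & (hu >= params.muscle_lo_hu) & (hu <= params.muscle_hi_hu)
    outer_edge = core & ~ndi.binary_erosion(core, structure=_S8)
    mus_lbl, n_mus = ndi.label(muscle_cand, structure=_S8)
    ring_codes = np.setdiff1d(np.unique(mus_lbl[outer_edge]), [0])
    if ring_codes.size == 0:
        raise SegmentationError("no muscle ring found on the core boundary")
    ring = np.isin(mus_lbl, ring_codes)

    # interior of the ring: the large component is the visceral cavity, any
    # small enclosed pockets are intramuscular fat and belong to TAMA
    enclosed = ndi.binary_fill_holes(ring)
    interior = enclosed & ~ring
    tama = ring.copy()
    cavity = _largest_component(interior)
    if cavity is not None:
        tama |= interior & ~cavity

    vfa = fat & ~sfa & ~tama

    labels = np.zeros(hu.shape, dtype=np.uint8)
    labels[sfa] = _CODES["sfa"]
    labels[vfa] = _CODES["vfa"]
    labels[tama] = _CODES["tama"]
    return CompartmentMask(labels=labels, provenance="fallback")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two binary masks.

    Two empty masks agree perfectly: defined as 1.0 (conventions differ, so
    this is stated explicitly).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise AlignmentError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
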
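"""Pixel-wise muscle quality classification and composition reporting.

Every pixel inside the total abdominal muscle area (TAMA) is classified by
its CT attenuation in Hounsfield units (HU) into one of three components:

* NAMA — normal-attenuation muscle, +30 to +150 HU: healthy muscle tissue;
* LAMA — low-attenuation muscle, -29 to +29 HU: muscle with intramyocellular
  lipid (density lowered, but no gross fat visible);
* IMAT — inter/intramuscular adipose tissue, -190 to -30 HU: gross fat
  within or between muscle groups.

Muscle pixels outside all three ranges fall into an explicit ``other``
class so the decomposition always partitions TAMA.  Derived indices:
skeletal muscle area SMA = NAMA + LAMA, myosteatosis area = LAMA + IMAT.

The three HU ranges have inclusive *integer* endpoints; fractional HU
values (non-integer rescale slopes, resampled data) are rounded
half-away-from-zero to the nearest integer before binning, which makes the
classes an exact partition of the interval [-190.5, +150.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from musclemap.errors import InputError, SchemaError, ValidationError

__all__ = [
    "ClassBin",
    "HUClassificationScheme",
    "MuscleQualityMap",
    "CompositionReport",
    "round_half_away_from_zero",
    "classify_hu",
    "build_quality_map",
    "compute_composition",
    "render_map",
    "sma_area",
    "myosteatosis_area",
    "tama_area",
]

#: label used for TAMA pixels matching no bin
OTHER_NAME = "other"


def round_half_away_from_zero(x):
    """Round to the nearest integer, halves away from zero.

    This is the rounding applied to HU values before binning (np.round's
    banker's rounding would send 29.5 to 30 but -29.5 to -30 *and* 28.5 to
    28, breaking the symmetry of the inclusive integer endpoints).
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class ClassBin:
    """One attenuation class: inclusive integer HU bounds and a display color."""

    name: str
    lo: int
    hi: int
    color: tuple[int, int, int]

    def __post_init__(self):
        if int(self.lo) != self.lo or int(self.hi) != self.hi:
            raise SchemaError(f"bin {self.name!r}: bounds must be integers")
        if self.lo > self.hi:
            raise SchemaError(f"bin {self.name!r}: lo {self.lo} > hi {self.hi}")


@dataclass(frozen=True)
class HUClassificationScheme:
    """Ordered, non-overlapping integer HU bins plus an implicit 'other' class.

    Class codes used in label arrays are 1-based in bin order; the 'other'
    class gets code ``len(bins) + 1``; code 0 means "not a muscle pixel".
    """

    bins: tuple[ClassBin, ...]
    other_color: tuple[int, int, int] = (128, 128, 128)

    def __post_init__(self):
        if not self.bins:
            raise SchemaError("scheme needs at least one bin")
        names = [b.name for b in self.bins]
        if len(set(names)) != len(names) or OTHER_NAME in names:
            raise SchemaError(f"bin names must be unique and not {OTHER_NAME!r}")
        ordered = sorted(self.bins, key=lambda b: b.lo)
        for a, b in zip(ordered, ordered[1:]):
            if b.lo <= a.hi:
                raise SchemaError(
                    f"bins {a.name!r} and {b.name!r} overlap on integers"
                )

    @classmethod
    def default(cls) -> "HUClassificationScheme":
        """The standard three-class myosteatosis scheme (contiguous over integers)."""
        return cls(
            bins=(
                ClassBin("nama", 30, 150, (220, 20, 60)),     # red
                ClassBin("lama", -29, 29, (255, 215, 0)),     # yellow
                ClassBin("imat", -190, -30, (50, 205, 50)),   # green
            )
        )

    @classmethod
    def from_yaml(cls, path) -> "HUClassificationScheme":
        """Load a scheme override from a YAML file.

        Schema: ``bins: [{name, lo, hi, color: [r,g,b]}, ...]`` with an
        optional ``other_color``.  Overlapping bins are rejected.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "bins" not in raw:
            raise SchemaError(f"scheme file {path}: missing 'bins'")
        bins = []
        for entry in raw["bins"]:
            try:
                bins.append(
                    ClassBin(
                        str(entry["name"]),
                        int(entry["lo"]),
                        int(entry["hi"]),
                        tuple(int(c) for c in entry.get("color", (200, 200, 200))),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise SchemaError(f"scheme file {path}: bad bin entry {entry!r}") from exc
        other = tuple(int(c) for c in raw.get("other_color", (128, 128, 128)))
        return cls(bins=tuple(bins), other_color=other)

    # -- code bookkeeping ------------------------------------------------
    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bins) + (OTHER_NAME,)

    @property
    def other_code(self) -> int:
        return len(self.bins) + 1

    def code_of(self, name: str) -> int:
        for i, b in enumerate(self.bins, start=1):
            if b.name == name:
                return i
        if name == OTHER_NAME:
            return self.other_code
        raise KeyError(name)

    def color_of(self, code: int) -> tuple[int, int, int]:
        if 1 <= code <= len(self.bins):
            return self.bins[code - 1].color
        if code == self.other_code:
            return self.other_color
        raise KeyError(code)

    def classify_array(self, hu: np.ndarray) -> np.ndarray:
        """Vectorized classification: HU array -> class-code array.

        Non-finite entries raise; rounding is half-away-from-zero.
        """
        hu = np.asarray(hu, dtype=float)
        if not np.all(np.isfinite(hu)):
            raise InputError("non-finite HU value in input")
        r = round_half_away_from_zero(hu)
        out = np.full(hu.shape, self.other_code, dtype=np.uint8)
        for i, b in enumerate(self.bins, start=1):
            out[(r >= b.lo) & (r <= b.hi)] = i
        return out


def classify_hu(hu: float, scheme: HUClassificationScheme | None = None) -> str:
    """Classify a single HU value; returns the class name (or 'other')."""
    if scheme is None:
        scheme = HUClassificationScheme.default()
    if not math.isfinite(hu):
        raise InputError(f"non-finite HU value: {hu!r}")
    code = int(scheme.classify_array(np.array([hu]))[0])
    return scheme.class_names[code - 1]


# ---------------------------------------------------------------------------
# quality map
# ---------------------------------------------------------------------------

@dataclass
class MuscleQualityMap:
    """Per-pixel class labels over the muscle compartment.

    ``labels`` has the slice shape; 0 outside TAMA, otherwise the scheme's
    class code.  Labels exist exactly for TAMA pixels.
    """

    labels: np.ndarray
    scheme: HUClassificationScheme

    def counts(self) -> dict[str, int]:
        """Pixel count per class name (TAMA pixels only)."""
        out = {}
        for name in self.scheme.class_names:
            out[name] = int(np.count_nonzero(self.labels == self.scheme.code_of(name)))
        return out

    def mask_of(self, *names: str) -> np.ndarray:
        codes = [self.scheme.code_of(n) for n in names]
        return np.isin(self.labels, codes)


def build_quality_map(ct_slice, compartments, scheme: HUClassificationScheme | None = None) -> MuscleQualityMap:
    """Classify every TAMA pixel of ``ct_slice`` under ``scheme``.

    ``compartments`` is a :class:`~musclemap.segmentation.CompartmentMask`
    aligned to the slice.  Raises :class:`ValidationError` if the muscle
    compartment is empty (the map is undefined).
    """
    if scheme is None:
        scheme = HUClassificationScheme.default()
    tama = compartments.mask_of("tama")
    if tama.shape != ct_slice.pixels.shape:
        raise ValidationError(
            f"compartment mask shape {tama.shape} != slice shape {ct_slice.pixels.shape}"
        )
    if not tama.any():
        raise ValidationError("muscle compartment (TAMA) is empty; quality map undefined")
    labels = np.zeros(ct_slice.pixels.shape, dtype=np.uint8)
    labels[tama] = scheme.classify_array(ct_slice.pixels[tama])
    return MuscleQualityMap(labels=labels, scheme=scheme)


# ---------------------------------------------------------------------------
# derived indices and composition report
# ---------------------------------------------------------------------------

def sma_area(nama: float, lama: float) -> float:
    """Skeletal muscle area: NAMA + LAMA (any consistent unit)."""
    return nama + lama


def myosteatosis_area(lama: float, imat: float) -> float:
    """Myosteatosis burden: LAMA + IMAT (any consistent unit)."""
    return lama + imat


def tama_area(nama: float, lama: float, imat: float, other: float = 0.0) -> float:
    """Total abdominal muscle area reconstructed from its components."""
    return nama + lama + imat + other


@dataclass
class CompositionReport:
    """Areas (cm²), mean densities (HU) and the TAMA HU histogram for one slice."""

    tama_cm2: float
    nama_cm2: float
    lama_cm2: float
    imat_cm2: float
    other_cm2: float
    sma_cm2: float
    myosteatosis_cm2: float
    vfa_cm2: float
    sfa_cm2: float
    mean_tama_density_hu: float | None
    mean_sma_density_hu: float | None
    pixel_area_cm2: float
    histogram_bin_width_hu: float
    histogram_edges_hu: list[float] = field(default_factory=list)
    histogram_counts: list[int] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    _NUMERIC_FIELDS = (
        "tama_cm2", "nama_cm2", "lama_cm2", "imat_cm2", "other_cm2",
        "sma_cm2", "myosteatosis_cm2", "vfa_cm2", "sfa_cm2",
        "mean_tama_density_hu", "mean_sma_density_hu",
        "pixel_area_cm2", "histogram_bin_width_hu",
    )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self._NUMERIC_FIELDS}
        d["histogram_edges_hu"] = list(self.histogram_edges_hu)
        d["histogram_counts"] = [int(c) for c in self.histogram_counts]
        d["provenance"] = dict(self.provenance)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CompositionReport":
        kwargs = {k: d[k] for k in cls._NUMERIC_FIELDS}
        return cls(
            **kwargs,
            histogram_edges_hu=list(d.get("histogram_edges_hu", [])),
            histogram_counts=[int(c) for c in d.get("histogram_counts", [])],
            provenance=dict(d.get("provenance", {})),
        )


def _histogram(values: np.ndarray, width: float) -> tuple[list[float], list[int]]:
    """Histogram with bins of ``width`` HU aligned so integer HU fall at bin
    centers when width == 1; covers the full data range (counts conserve n)."""
    if values.size == 0:
        return [], []
    lo = math.floor(values.min()) - 0.5
    n_bins = max(1, math.ceil((values.max() - lo) / width + 1e-9))
    edges = lo + width * np.arange(n_bins + 1)
    counts, edges = np.histogram(values, bins=edges)
    return [float(e) for e in edges], [int(c) for c in counts]


def compute_composition(
    qmap: MuscleQualityMap,
    ct_slice,
    compartments,
    histogram_bin_width: float = 1.0,
) -> CompositionReport:
    """Quantify a quality map: per-class areas, mean densities, HU histogram.

    Area(class) = pixel_count x row_spacing_mm x col_spacing_mm / 100 (cm²).
    Mean TAMA density averages *all* TAMA pixels (IMAT and other included);
    mean SMA density averages NAMA and LAMA pixels only and is reported as
    None (undefined) when SMA is empty.
    """
    if histogram_bin_width <= 0:
        raise InputError("histogram bin width must be positive")
    px_cm2 = ct_slice.row_spacing_mm * ct_slice.col_spacing_mm / 100.0
    counts = qmap.counts()
    area = {name: counts[name] * px_cm2 for name in counts}
    nama, lama, imat = area["nama"], area["lama"], area["imat"]
    other = area.get(OTHER_NAME, 0.0)

    tama_mask = compartments.mask_of("tama")
    tama_hu = ct_slice.pixels[tama_mask]
    sma_mask = qmap.mask_of("nama", "lama")
    sma_hu = ct_slice.pixels[sma_mask]

    edges, hist = _histogram(tama_hu, histogram_bin_width)
    comp_counts = compartments.counts()

    return CompositionReport(
        tama_cm2=tama_area(nama, lama, imat, other),
        nama_cm2=nama,
        lama_cm2=lama,
        imat_cm2=imat,
        other_cm2=other,
        sma_cm2=sma_area(nama, lama),
        myosteatosis_cm2=myosteatosis_area(lama, imat),
        vfa_cm2=comp_counts.get("vfa", 0) * px_cm2,
        sfa_cm2=comp_counts.get("sfa", 0) * px_cm2,
        mean_tama_density_hu=float(tama_hu.mean()) if tama_hu.size else None,
        mean_sma_density_hu=float(sma_hu.mean()) if sma_hu.size else None,
        pixel_area_cm2=px_cm2,
        histogram_bin_width_hu=float(histogram_bin_width),
        histogram_edges_hu=edges,
        histogram_counts=hist,
        provenance={
            "scheme": [
                {"name": b.name, "lo": b.lo, "hi": b.hi} for b in qmap.scheme.bins
            ],
            "compartment_provenance": getattr(compartments, "provenance", "unknown"),
            "contrast_phase": ct_slice.meta.get("contrast_phase", ""),
            "source": ct_slice.meta.get("source", ""),
        },
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_map(
    qmap: MuscleQualityMap,
    ct_slice,
    window_center: float = 40.0,
    window_width: float = 400.0,
    opacity: float = 0.6,
) -> np.ndarray:
    """Render the quality map as an RGB overlay on the windowed CT image.

    The base image uses a standard soft-tissue display window; each class is
    blended in its solid scheme color at the given opacity.  A pixel carries
    color iff it carries a class label, so the overlay support equals the
    muscle mask.  Returns a uint8 H x W x 3 array (PNG-writable); rendering
    is a pure function of its inputs.
    """
    if not 0.0 <= opacity <= 1.0:
        raise InputError("opacity must be in [0, 1]")
    lo = window_center - window_width / 2.0
    hi = window_center + window_width / 2.0
    gray = np.clip((ct_slice.pixels - lo) / (hi - lo), 0.0, 1.0) * 255.0
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    for name in qmap.scheme.class_names:
        code = qmap.scheme.code_of(name)
        sel = qmap.labels == code
        if not sel.any():
            continue
        color = np.array(qmap.scheme.color_of(code), dtype=float)
        rgb[sel] = (1.0 - opacity) * rgb[sel] + opacity * color
    return np.round(rgb).astype(np.uint8)
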
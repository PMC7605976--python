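"""Synthetic L3-slice phantoms and cohort simulation.

The phantom emulates the geometry the pipeline sees at the L3 vertebral
level: an elliptical body on an air background, a subcutaneous fat layer, a
closed muscle ring, a thin visceral-fat lining inside the ring (the
retroperitoneal/mesenteric fat that lines the abdominal wall) and a
visceral cavity holding fat blobs and organ-density background.  Muscle
pixels are assigned NAMA / LAMA / IMAT roles at requested fractions, LAMA
and IMAT as random compact clusters (fat infiltration appears as streaks,
not isolated pixels).  HU values are sampled from per-role truncated
normals so the noiseless ground truth is exact; boundary leakage between
classes appears only through the optional additive Gaussian noise.

The cohort simulator draws per-subject component areas from per-group
normals tied together by a shared adiposity factor, and derives mean
densities from the composition itself, reproducing the study-shaped
structure (two sexes, six age decades) without any patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from musclemap.errors import SchemaError
from musclemap.io import CTSlice
from musclemap.quality import HUClassificationScheme, myosteatosis_area, sma_area, tama_area
from musclemap.segmentation import CompartmentMask

__all__ = [
    "PhantomSpec",
    "PhantomResult",
    "generate_phantom",
    "CohortGroup",
    "CohortSpec",
    "generate_cohort",
    "reference_cohort_spec",
]

_S8 = np.ones((3, 3), dtype=bool)

#: per-role (mean HU, sd HU, truncation interval) — truncation keeps every
#: sampled value inside its class bin so noiseless ground truth is exact
DEFAULT_HU = {
    "air": (-1000.0, 5.0, (-1100.0, -900.0)),
    "sfa": (-100.0, 8.0, (-190.0, -30.0)),
    "vfa": (-90.0, 8.0, (-190.0, -30.0)),
    "nama": (55.0, 6.0, (30.0, 150.0)),
    "lama": (0.0, 8.0, (-29.0, 29.0)),
    "imat": (-85.0, 15.0, (-190.0, -30.0)),
    "cavity": (40.0, 15.0, (30.0, 150.0)),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one synthetic L3-like slice.

    Geometry is in millimetres; the defaults give a body of realistic
    abdominal girth with a muscle cross-section of roughly 95 cm².
    ``lama_fraction`` / ``imat_fraction`` are the fractions of muscle-ring
    pixels assigned to the two myosteatosis roles (defaults match a healthy
    young adult: ~12% LAMA, ~2% IMAT).  ``noise_sd_hu`` adds global Gaussian
    noise after ground truth is recorded.
    """

    n_rows: int = 256
    n_cols: int = 256
    row_spacing_mm: float = 1.5
    col_spacing_mm: float = 1.5
    body_semi_axis_x_mm: float = 160.0
    body_semi_axis_y_mm: float = 110.0
    sfa_thickness_mm: float = 18.0
    muscle_thickness_mm: float = 14.0
    vfa_lining_mm: float = 6.0
    visceral_fat_fraction: float = 0.35
    lama_fraction: float = 0.12
    imat_fraction: float = 0.02
    cluster_radius_px: int = 2
    hu_params: dict = field(default_factory=lambda: {k: v for k, v in DEFAULT_HU.items()})
    noise_sd_hu: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("lama_fraction", "imat_fraction", "visceral_fat_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SchemaError(f"{name} must be in [0, 1], got {v}")
        if self.lama_fraction + self.imat_fraction > 1.0:
            raise SchemaError("lama_fraction + imat_fraction must be <= 1")
        if self.noise_sd_hu < 0:
            raise SchemaError("noise_sd_hu must be >= 0")
        fov_x = self.n_cols * self.col_spacing_mm / 2.0
        fov_y = self.n_rows * self.row_spacing_mm / 2.0
        if self.body_semi_axis_x_mm >= fov_x or self.body_semi_axis_y_mm >= fov_y:
            raise SchemaError("body ellipse does not fit inside the image")
        inner = min(self.body_semi_axis_x_mm, self.body_semi_axis_y_mm) - (
            self.sfa_thickness_mm + self.muscle_thickness_mm + self.vfa_lining_mm
        )
        if inner <= 0:
            raise SchemaError("layer thicknesses exceed the body semi-axes")
        scheme = HUClassificationScheme.default()
        for role, bin_name in (("nama", "nama"), ("lama", "lama"), ("imat", "imat")):
            mean = self.hu_params[role][0]
            b = scheme.bins[scheme.code_of(bin_name) - 1]
            if not b.lo <= mean <= b.hi:
                raise SchemaError(
                    f"{role} HU mean {mean} outside its class bin [{b.lo}, {b.hi}]"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown phantom spec fields: {sorted(unknown)}")
        if "hu_params" in d:
            base = {k: v for k, v in DEFAULT_HU.items()}
            for role, entry in d["hu_params"].items():
                if role not in base:
                    raise SchemaError(f"unknown hu_params role {role!r}")
                mean, sd = float(entry[0]), float(entry[1])
                trunc = tuple(entry[2]) if len(entry) > 2 else base[role][2]
                base[role] = (mean, sd, trunc)
            d = {**d, "hu_params": base}
        spec = cls(**d)
        spec.validate()
        return spec


@dataclass
class PhantomResult:
    """A generated slice plus its exact ground truth.

    ``class_truth`` labels every muscle pixel with its generated role using
    the default scheme's codes (1 NAMA, 2 LAMA, 3 IMAT); ``true_areas_cm2``
    are pixel counts times pixel area, recorded before noise.
    """

    ct_slice: CTSlice
    compartments: CompartmentMask
    class_truth: np.ndarray
    true_areas_cm2: dict[str, float]


def _ellipse(xx: np.ndarray, yy: np.ndarray, ax: float, ay: float) -> np.ndarray:
    return (xx / ax) ** 2 + (yy / ay) ** 2 <= 1.0


def _sample_role(rng: np.random.Generator, role: str, hu_params: dict, n: int) -> np.ndarray:
    mean, sd, (lo, hi) = hu_params[role]
    if sd == 0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _place_clusters(
    rng: np.random.Generator,
    allowed: np.ndarray,
    taken: np.ndarray,
    target: int,
    radius: int,
) -> np.ndarray:
    """Grow random compact clusters inside ``allowed`` until exactly
    ``target`` pixels are marked; never overlaps ``taken``."""
    out = np.zeros_like(allowed)
    if target <= 0:
        return out
    r2 = radius * radius
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk = (dy * dy + dx * dx) <= r2
    offs = np.argwhere(disk) - radius
    # sort offsets by distance so partial clusters stay compact
    offs = offs[np.argsort((offs ** 2).sum(axis=1), kind="stable")]
    n_rows, n_cols = allowed.shape
    placed = 0
    while placed < target:
        eligible = np.argwhere(allowed & ~taken & ~out)
        if eligible.size == 0:
            break
        cy, cx = eligible[rng.integers(len(eligible))]
        for oy, ox in offs:
            y, x = cy + oy, cx + ox
            if 0 <= y < n_rows and 0 <= x < n_cols and allowed[y, x] and not taken[y, x] and not out[y, x]:
                out[y, x] = True
                placed += 1
                if placed == target:
                    break
    return out


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomResult:
    """Generate a synthetic L3-like slice with exact ground truth.

    Deterministic given ``spec.seed``: one seed sequence is split into
    independent streams for cluster geometry, per-role HU sampling and
    additive noise, so changing the noise level does not move the geometry.
    """
    if spec is None:
        spec = PhantomSpec()
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_geom, rng_hu, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    y = (np.arange(spec.n_rows) - (spec.n_rows - 1) / 2.0) * spec.row_spacing_mm
    x = (np.arange(spec.n_cols) - (spec.n_cols - 1) / 2.0) * spec.col_spacing_mm
    yy, xx = np.meshgrid(y, x, indexing="ij")

    ax, ay = spec.body_semi_axis_x_mm, spec.body_semi_axis_y_mm
    t1 = spec.sfa_thickness_mm
    t2 = t1 + spec.muscle_thickness_mm
    t3 = t2 + spec.vfa_lining_mm
    body = _ellipse(xx, yy, ax, ay)
    inner_sfa = _ellipse(xx, yy, ax - t1, ay - t1)
    inner_mus = _ellipse(xx, yy, ax - t2, ay - t2)
    inner_lin = _ellipse(xx, yy, ax - t3, ay - t3)

    sfa = body & ~inner_sfa
    ring = inner_sfa & ~inner_mus
    lining = inner_mus & ~inner_lin
    cavity = inner_lin

    # visceral fat: the lining plus random blobs filling the requested
    # fraction of the cavity
    n_cavity = int(cavity.sum())
    blob_target = int(round(spec.visceral_fat_fraction * n_cavity))
    blobs = _place_clusters(
        rng_geom, cavity, np.zeros_like(cavity), blob_target, radius=6
    )
    vfa = lining | blobs
    cavity_bg = cavity & ~vfa

    # muscle roles: LAMA / IMAT clusters strictly interior to the ring so
    # fat pockets never touch the ring boundary
    ring_interior = ndi.binary_erosion(ring, structure=_S8)
    n_ring = int(ring.sum())
    n_lama = int(round(spec.lama_fraction * n_ring))
    n_imat = int(round(spec.imat_fraction * n_ring))
    imat = _place_clusters(
        rng_geom, ring_interior, np.zeros_like(ring), n_imat, spec.cluster_radius_px
    )
    lama = _place_clusters(
        rng_geom, ring_interior, imat, n_lama, spec.cluster_radius_px
    )
    nama = ring & ~lama & ~imat

    hu = np.empty((spec.n_rows, spec.n_cols), dtype=float)
    hu[:] = np.nan
    regions = {
        "air": ~body,
        "sfa": sfa,
        "vfa": vfa,
        "nama": nama,
        "lama": lama,
        "imat": imat,
        "cavity": cavity_bg,
    }
    for role, region in regions.items():
        n = int(region.sum())
        if n:
            hu[region] = _sample_role(rng_hu, role, spec.hu_params, n)

    scheme = HUClassificationScheme.default()
    class_truth = np.zeros(hu.shape, dtype=np.uint8)
    class_truth[nama] = scheme.code_of("nama")
    class_truth[lama] = scheme.code_of("lama")
    class_truth[imat] = scheme.code_of("imat")

    labels = np.zeros(hu.shape, dtype=np.uint8)
    labels[ring] = 1
    labels[vfa] = 2
    labels[sfa] = 3
    compartments = CompartmentMask(labels=labels, provenance="truth")

    px_cm2 = spec.row_spacing_mm * spec.col_spacing_mm / 100.0
    true_areas = {
        "tama": n_ring * px_cm2,
        "nama": int(nama.sum()) * px_cm2,
        "lama": int(lama.sum()) * px_cm2,
        "imat": int(imat.sum()) * px_cm2,
        "vfa": int(vfa.sum()) * px_cm2,
        "sfa": int(sfa.sum()) * px_cm2,
    }

    if spec.noise_sd_hu > 0:
        hu = hu + rng_noise.normal(0.0, spec.noise_sd_hu, size=hu.shape)

    ct_slice = CTSlice(
        pixels=hu,
        row_spacing_mm=spec.row_spacing_mm,
        col_spacing_mm=spec.col_spacing_mm,
        meta={
            "hu_calibrated": True,
            "modality": "CT",
            "contrast_phase": "synthetic phantom",
            "source": f"phantom(seed={spec.seed})",
        },
    )
    return PhantomResult(
        ct_slice=ct_slice,
        compartments=compartments,
        class_truth=class_truth,
        true_areas_cm2=true_areas,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: area variables drawn per subject; everything else is derived
_AREA_VARS = ("nama", "lama", "imat", "vfa", "sfa")


@dataclass(frozen=True)
class CohortGroup:
    """One sex x age-band cell: sample size and generative means/sds (cm²)."""

    sex: str
    age_band: str
    n: int
    means: dict
    sds: dict

    def validate(self) -> None:
        if self.n < 2:
            raise SchemaError(f"group {self.sex}/{self.age_band}: n must be >= 2")
        for var in _AREA_VARS:
            if var not in self.means or var not in self.sds:
                raise SchemaError(
                    f"group {self.sex}/{self.age_band}: missing mean/sd for {var!r}"
                )
            if self.sds[var] < 0:
                raise SchemaError(
                    f"group {self.sex}/{self.age_band}: sd for {var!r} must be >= 0"
                )


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic study cohort.

    Per-variable marginals are gamma distributions moment-matched to the
    group mean and sd (areas are strictly positive and right-skewed, and the
    matching keeps the generative mean exact, which a normal clipped at zero
    would not).  Dependence comes from a Gaussian copula whose scores share
    a per-subject adiposity factor: ``adiposity_loadings`` give, per
    variable, the loading on that factor, inducing the positive fat–fat and
    negative fat–muscle correlations seen in body-composition data.  Mean
    densities are derived from the drawn composition using representative
    per-class HU values (``class_hu``) with small per-subject jitter plus
    measurement noise.
    """

    groups: tuple[CohortGroup, ...]
    adiposity_loadings: dict = field(
        default_factory=lambda: {
            "nama": -0.3, "lama": 0.6, "imat": 0.5, "vfa": 0.6, "sfa": 0.4,
        }
    )
    class_hu: dict = field(
        default_factory=lambda: {"nama": 55.0, "lama": 0.0, "imat": -85.0}
    )
    class_hu_jitter_sd: float = 2.0
    density_noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise SchemaError("cohort spec has no groups")
        for g in self.groups:
            g.validate()
        for var, load in self.adiposity_loadings.items():
            if not -1.0 <= load <= 1.0:
                raise SchemaError(f"adiposity loading for {var!r} must be in [-1, 1]")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate per-subject body-composition records.

    Returns one row per subject with drawn areas (cm²), derived indices
    (TAMA = NAMA+LAMA+IMAT, SMA = NAMA+LAMA, myosteatosis = LAMA+IMAT — the
    additive identities hold exactly by construction) and derived mean
    densities (HU).  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rows = []
    sid = 0
    for g in spec.groups:
        z = rng.normal(size=g.n)  # shared adiposity factor
        draws = {}
        for var in _AREA_VARS:
            load = float(spec.adiposity_loadings.get(var, 0.0))
            eps = rng.normal(size=g.n)
            score = load * z + np.sqrt(1.0 - load * load) * eps
            mean, sd = float(g.means[var]), float(g.sds[var])
            if sd == 0.0 or mean <= 0.0:
                draws[var] = np.full(g.n, max(mean, 0.0))
            else:
                # gamma marginal with exactly the requested mean and sd,
                # coupled through the Gaussian score (copula transform)
                shape = (mean / sd) ** 2
                scale = sd * sd / mean
                u = stats.norm.cdf(score)
                draws[var] = stats.gamma.ppf(u, shape, scale=scale)
        hu_n = spec.class_hu["nama"] + rng.normal(0, spec.class_hu_jitter_sd, g.n)
        hu_l = spec.class_hu["lama"] + rng.normal(0, spec.class_hu_jitter_sd, g.n)
        hu_i = spec.class_hu["imat"] + rng.normal(0, spec.class_hu_jitter_sd, g.n)
        for i in range(g.n):
            nama, lama, imat = draws["nama"][i], draws["lama"][i], draws["imat"][i]
            tama = tama_area(nama, lama, imat)
            sma = sma_area(nama, lama)
            dens_noise = rng.normal(0, spec.density_noise_sd, 2)
            mean_tama = (
                (nama * hu_n[i] + lama * hu_l[i] + imat * hu_i[i]) / tama
                + dens_noise[0]
                if tama > 0
                else np.nan
            )
            mean_sma = (
                (nama * hu_n[i] + lama * hu_l[i]) / sma + dens_noise[1]
                if sma > 0
                else np.nan
            )
            rows.append(
                {
                    "subject_id": f"S{sid:04d}",
                    "sex": g.sex,
                    "age_band": g.age_band,
                    "nama_cm2": nama,
                    "lama_cm2": lama,
                    "imat_cm2": imat,
                    "tama_cm2": tama,
                    "sma_cm2": sma,
                    "myosteatosis_cm2": myosteatosis_area(lama, imat),
                    "vfa_cm2": draws["vfa"][i],
                    "sfa_cm2": draws["sfa"][i],
                    "mean_tama_density_hu": mean_tama,
                    "mean_sma_density_hu": mean_sma,
                }
            )
            sid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study-shaped default cohort
# ---------------------------------------------------------------------------

_AGE_BANDS = ("20-29", "30-39", "40-49", "50-59", "60-69", "70-79")

# generative area means/sds (cm²) per sex and age decade for the muscle
# components of a healthy adult screening cohort; VFA/SFA values are
# synthetic but age-plausible
_MALE_N = (29, 17, 22, 15, 25, 27)
_MALE = {
    "nama": ((153.4, 150.4, 144.3, 133.5, 122.0, 105.9),
             (20.0, 26.1, 19.5, 19.1, 16.7, 17.5)),
    "lama": ((20.2, 30.9, 27.0, 30.5, 32.9, 37.8),
             (8.9, 11.7, 10.5, 6.7, 10.3, 14.4)),
    "imat": ((3.3, 6.6, 3.9, 4.4, 5.1, 5.9),
             (2.5, 5.1, 2.4, 1.7, 2.4, 3.6)),
    "vfa": ((70.0, 100.0, 115.0, 125.0, 130.0, 135.0),
            (35.0, 35.0, 35.0, 35.0, 35.0, 35.0)),
    "sfa": ((120.0, 130.0, 125.0, 120.0, 115.0, 110.0),
            (40.0, 40.0, 40.0, 40.0, 40.0, 40.0)),
}
_FEMALE_N = (11, 23, 18, 25, 15, 13)
_FEMALE = {
    "nama": ((91.9, 92.6, 84.3, 81.0, 73.1, 63.9),
             (9.5, 15.1, 11.2, 13.1, 14.2, 17.3)),
    "lama": ((15.1, 16.5, 22.1, 24.9, 30.0, 33.5),
             (5.7, 5.7, 8.4, 8.1, 8.8, 11.2)),
    "imat": ((2.6, 2.8, 4.8, 5.7, 5.7, 8.9),
             (1.4, 1.6, 3.1, 2.5, 3.3, 5.1)),
    "vfa": ((45.0, 60.0, 80.0, 95.0, 110.0, 120.0),
            (30.0, 30.0, 30.0, 30.0, 30.0, 30.0)),
    "sfa": ((150.0, 160.0, 165.0, 170.0, 165.0, 160.0),
            (45.0, 45.0, 45.0, 45.0, 45.0, 45.0)),
}


def reference_cohort_spec(
    sexes: tuple[str, ...] = ("male", "female"),
    n_per_group: int | None = None,
    seed: int = 0,
) -> CohortSpec:
    """The default study-shaped cohort: two sexes x six age decades.

    ``n_per_group`` overrides the per-cell sample sizes (e.g. a balanced 40
    per decade); by default cells use the unbalanced sizes typical of a
    retrospectively sampled screening cohort.
    """
    groups = []
    for sex in sexes:
        params = {"male": _MALE, "female": _FEMALE}[sex]
        ns = {"male": _MALE_N, "female": _FEMALE_N}[sex]
        for j, band in enumerate(_AGE_BANDS):
            groups.append(
                CohortGroup(
                    sex=sex,
                    age_band=band,
                    n=n_per_group if n_per_group is not None else ns[j],
                    means={var: params[var][0][j] for var in _AREA_VARS},
                    sds={var: params[var][1][j] for var in _AREA_VARS},
                )
            )
    return CohortSpec(groups=tuple(groups), seed=seed)


def cohort_spec_from_dict(d: dict, seed: int | None = None) -> CohortSpec:
    """Build a CohortSpec from a plain dict (parsed YAML/JSON spec file)."""
    if "groups" not in d:
        raise SchemaError("cohort spec file: missing 'groups'")
    groups = []
    for entry in d["groups"]:
        try:
            groups.append(
                CohortGroup(
                    sex=str(entry["sex"]),
                    age_band=str(entry["age_band"]),
                    n=int(entry["n"]),
                    means={k: float(v) for k, v in entry["means"].items()},
                    sds={k: float(v) for k, v in entry["sds"].items()},
                )
            )
        except KeyError as exc:
            raise SchemaError(f"cohort spec group entry missing field: {exc}") from exc
    kwargs = {}
    for key in ("adiposity_loadings", "class_hu", "class_hu_jitter_sd", "density_noise_sd", "seed"):
        if key in d:
            kwargs[key] = d[key]
    if seed is not None:
        kwargs["seed"] = seed
    spec = CohortSpec(groups=tuple(groups), **kwargs)
    spec.validate()
    return spec
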
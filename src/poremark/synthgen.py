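"""Synthetic negative-stain-style micrographs of membrane sheets bearing
ring-shaped pore complexes, with full ground truth.

The generator emulates the en-face appearance of large membrane pores in
*Gemmata obscuriglobus*: an electron-dense (dark) central plug, a thin
lighter inner ring, and a thicker dark outer ring carrying an n-fold
subunit modulation. Geometry defaults follow the published measurements
(outer ring 33.5 nm, inner ring 17.5 nm, plug 9.5 nm, 8-fold subunits at
0.69 nm/px), with two smaller pore classes (14.5/5 nm and 6 nm) available
as presets. Pores are scattered over a membrane sheet by a hard-core point
process at a stated areal density (87 or 200 per um^2 in the source data),
optionally tilt-foreshortened, blurred by a Gaussian PSF, and degraded by
additive Gaussian noise. SNR is defined as |contrast_outer| / noise_sigma.

Diameter convention: every diameter refers to the annulus ridge (intensity
peak) line, i.e. twice the ridge radius; the plug diameter is the full
width at half contrast of the central disk. The morphometry module uses the
identical convention so recovery is exact in the noiseless limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .imaging_io import Micrograph

#: Cryo-EM detector pixel size used throughout as the default, nm/px.
PIXEL_SIZE_NM = 0.69

#: Areal pore densities reported for the two preparations, pores per um^2.
LYSED_SHEET_DENSITY = 87.0
FRACTION3_DENSITY = 200.0

#: Interior (membrane) and exterior background intensity levels.
BACKGROUND_MEMBRANE = 0.5
BACKGROUND_EXTERIOR = 0.3

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class GeometryError(ValueError):
    """Pore or scene geometry violates an invariant."""


class PackingError(RuntimeError):
    """Hard-core sampling could not place the requested number of points."""


# ---------------------------------------------------------------------------
# Parametric pore model


@dataclass(frozen=True)
class PoreModel:
    """Parametric description of one pore complex seen en face.

    Diameters are ridge-line diameters in nm; contrasts are signed offsets
    from the local background (negative = electron-dense = darker); ring
    widths are FWHM in nm (for the plug, the width of its edge roll-off).
    ``basket_depth`` is carried as metadata only — the basket is a 3D
    feature and is never rendered in these en-face images.
    """

    d_plug: float = 9.5
    d_inner: float = 17.5
    d_outer: float = 33.5
    n_fold: int = 8
    subunit_amplitude: float = 0.5
    ring_width_plug: float = 2.0
    ring_width_inner: float = 3.0
    ring_width_outer: float = 5.0
    contrast_plug: float = -0.25
    contrast_inner: float = 0.15
    contrast_outer: float = -0.25
    basket_depth: float = 0.0
    tilt_deg: float = 0.0
    tilt_axis_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.d_plug < self.d_inner < self.d_outer):
            raise GeometryError(
                f"need 0 < d_plug < d_inner < d_outer, got "
                f"({self.d_plug}, {self.d_inner}, {self.d_outer})"
            )
        if self.n_fold < 1:
            raise GeometryError(f"n_fold must be >= 1, got {self.n_fold}")
        if not 0.0 <= self.subunit_amplitude <= 1.0:
            raise GeometryError(f"subunit_amplitude must be in [0,1], got {self.subunit_amplitude}")
        for name in ("ring_width_plug", "ring_width_inner", "ring_width_outer"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be > 0")
        if not 0.0 <= self.tilt_deg < 45.0:
            raise GeometryError(f"tilt_deg must be in [0, 45), got {self.tilt_deg}")
        if not 0.0 <= self.tilt_axis_deg < 180.0:
            raise GeometryError(f"tilt_axis_deg must be in [0, 180), got {self.tilt_axis_deg}")

    @property
    def r_outer(self) -> float:
        return self.d_outer / 2.0

    def with_tilt(self, tilt_deg: float, tilt_axis_deg: float = 0.0) -> "PoreModel":
        return replace(self, tilt_deg=tilt_deg, tilt_axis_deg=tilt_axis_deg)


def noise_sigma_for_snr(model: PoreModel, snr: float) -> float:
    """Noise sigma giving the stated SNR = |contrast_outer| / noise_sigma."""
    if snr <= 0:
        raise ValueError("snr must be > 0")
    return abs(model.contrast_outer) / snr


#: The large pore complex of the published geometry (basket depth from the
#: deduced 3D model is metadata only).
LARGE_PORE = PoreModel(basket_depth=25.0)

#: Intermediate pore class: 14.5 nm ring with a 5 nm dense centre. No inner
#: ring is described for this class; a zero-contrast placeholder keeps the
#: plug < inner < outer ordering and is flagged "missing" by morphometry.
MEDIUM_PORE = PoreModel(
    d_plug=5.0,
    d_inner=9.5,
    d_outer=14.5,
    n_fold=1,
    subunit_amplitude=0.0,
    ring_width_plug=1.4,
    ring_width_inner=2.0,
    ring_width_outer=2.8,
    contrast_inner=0.0,
)

#: Smallest pore class: ~6 nm pores with a dense centre, no resolved rings.
SMALL_PORE = PoreModel(
    d_plug=2.5,
    d_inner=4.0,
    d_outer=6.0,
    n_fold=1,
    subunit_amplitude=0.0,
    ring_width_plug=1.0,
    ring_width_inner=1.2,
    ring_width_outer=1.5,
    contrast_inner=0.0,
)


@dataclass(frozen=True)
class PoreClassMix:
    """Mixture of pore classes with mixing proportions summing to 1."""

    classes: tuple[tuple[PoreModel, float], ...]

    def __post_init__(self) -> None:
        props = [p for _, p in self.classes]
        if any(p < 0 for p in props):
            raise GeometryError("mixing proportions must be >= 0")
        if abs(sum(props) - 1.0) > 1e-9:
            raise GeometryError(f"mixing proportions must sum to 1, got {sum(props)}")

    @classmethod
    def single(cls, model: PoreModel) -> "PoreClassMix":
        return cls(((model, 1.0),))

    @property
    def max_d_outer(self) -> float:
        return max(m.d_outer for m, _ in self.classes)


# ---------------------------------------------------------------------------
# Analytic rendering


def _pore_field(model: PoreModel, dx: np.ndarray, dy: np.ndarray, phase_deg: float) -> np.ndarray:
    """Intensity offset of one pore evaluated at offsets (dx, dy) nm from
    its centre, before PSF and noise. Tilt foreshortening is applied as an
    affine compression of the image by cos(tilt) along the tilt axis."""
    if model.tilt_deg > 0.0:
        phi = math.radians(model.tilt_axis_deg)
        c, s = math.cos(phi), math.sin(phi)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        u = u / math.cos(math.radians(model.tilt_deg))
        dx, dy = u, v
    else:
        # still need (u, v) names consistent below
        pass
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    out = np.zeros_like(r)
    # central plug: erf-edged disk whose half-contrast radius is d_plug/2
    s_plug = model.ring_width_plug * _FWHM_TO_SIGMA
    out += model.contrast_plug * 0.5 * special.erfc((r - model.d_plug / 2.0) / (s_plug * math.sqrt(2.0)))
    # inner ring: Gaussian-profile annulus with ridge at d_inner/2
    s_in = model.ring_width_inner * _FWHM_TO_SIGMA
    out += model.contrast_inner * np.exp(-((r - model.d_inner / 2.0) ** 2) / (2.0 * s_in**2))
    # outer ring: Gaussian annulus with n-fold subunit modulation
    s_out = model.ring_width_outer * _FWHM_TO_SIGMA
    modulation = 1.0 + model.subunit_amplitude * np.cos(
        model.n_fold * (theta - math.radians(phase_deg))
    )
    out += (
        model.contrast_outer
        * modulation
        * np.exp(-((r - model.d_outer / 2.0) ** 2) / (2.0 * s_out**2))
    )
    return out


def render_pore_patch(
    model: PoreModel,
    pixel_size: float = PIXEL_SIZE_NM,
    patch_radius: float | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = 0,
    *,
    phase_deg: float = 0.0,
    center_offset_nm: tuple[float, float] = (0.0, 0.0),
    psf_sigma: float = 1.0,
    background: float = BACKGROUND_MEMBRANE,
) -> Micrograph:
    """Render one pore on a square odd-sided patch.

    The pore centre sits at the central pixel plus ``center_offset_nm``
    (x, y). ``patch_radius`` defaults to 1.5 x the outer radius and must be
    at least 0.75 x d_outer. Ground-truth parameters are echoed in the
    patch provenance.
    """
    if pixel_size <= 0:
        raise GeometryError(f"pixel_size must be > 0, got {pixel_size}")
    if patch_radius is None:
        # 1.1 x d_outer leaves a ring-free margin for baseline estimation
        patch_radius = 1.1 * model.d_outer
    if patch_radius < 0.75 * model.d_outer:
        raise GeometryError(
            f"patch_radius {patch_radius} nm too small for d_outer {model.d_outer} nm "
            f"(need >= {0.75 * model.d_outer} nm)"
        )
    half = math.ceil(patch_radius / pixel_size)
    idx = np.arange(-half, half + 1, dtype=np.float64) * pixel_size
    offx, offy = center_offset_nm
    dx = idx[None, :] - offx  # x = col
    dy = idx[:, None] - offy  # y = row
    img = background + _pore_field(model, dx, dy, phase_deg)
    if psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=psf_sigma / pixel_size, mode="nearest")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    prov = {
        "generator": "render_pore_patch",
        "model": {k: getattr(model, k) for k in model.__dataclass_fields__},
        "phase_deg": phase_deg,
        "center_offset_nm": (float(offx), float(offy)),
        "noise_sigma": noise_sigma,
        "psf_sigma": psf_sigma,
        "seed": seed,
    }
    return Micrograph(img, pixel_size, prov)


# ---------------------------------------------------------------------------
# Membrane sheet scenes


@dataclass
class SheetMask:
    """Binary membrane region on the scene pixel grid."""

    mask: np.ndarray  # bool, (rows, cols)
    pixel_size: float

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size**2 * 1e-6

    def contains(self, x_nm: float, y_nm: float) -> bool:
        row = int(round(y_nm / self.pixel_size))
        col = int(round(x_nm / self.pixel_size))
        if row < 0 or col < 0 or row >= self.mask.shape[0] or col >= self.mask.shape[1]:
            return False
        return bool(self.mask[row, col])

    def sample_points(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n uniform points (x_nm, y_nm) inside the mask, by rejection."""
        h, w = self.mask.shape
        pts = np.empty((n, 0 + 2))
        filled = 0
        while filled < n:
            batch = max(64, 2 * (n - filled))
            xs = rng.uniform(0, w * self.pixel_size, size=batch)
            ys = rng.uniform(0, h * self.pixel_size, size=batch)
            for x, y in zip(xs, ys):
                if self.contains(x, y):
                    pts[filled] = (x, y)
                    filled += 1
                    if filled == n:
                        break
        return pts


def rectangle_mask(width_nm: float, height_nm: float, pixel_size: float = PIXEL_SIZE_NM) -> SheetMask:
    """Full-frame rectangular membrane sheet."""
    shape = (math.ceil(height_nm / pixel_size), math.ceil(width_nm / pixel_size))
    return SheetMask(np.ones(shape, dtype=bool), pixel_size)


def ellipse_mask(
    width_nm: float,
    height_nm: float,
    pixel_size: float = PIXEL_SIZE_NM,
    *,
    fill_fraction: float = 0.92,
) -> SheetMask:
    """Elliptical ("canoe"-shaped) sheet inscribed in a frame with a margin."""
    shape = (math.ceil(height_nm / pixel_size), math.ceil(width_nm / pixel_size))
    rr = np.arange(shape[0])[:, None] - (shape[0] - 1) / 2.0
    cc = np.arange(shape[1])[None, :] - (shape[1] - 1) / 2.0
    a = fill_fraction * shape[1] / 2.0
    b = fill_fraction * shape[0] / 2.0
    return SheetMask((cc / a) ** 2 + (rr / b) ** 2 <= 1.0, pixel_size)


@dataclass
class SheetScene:
    """Everything needed to simulate one membrane-sheet micrograph."""

    mask: SheetMask
    density: float  # pores per um^2
    min_separation: float = 35.0  # nm, hard-core distance
    pore_mix: PoreClassMix = field(default_factory=lambda: PoreClassMix.single(LARGE_PORE))
    noise_sigma: float = 0.05
    psf_sigma: float = 1.0
    pixel_size: float = PIXEL_SIZE_NM
    seed: int = 0
    randomize_phase: bool = True

    def __post_init__(self) -> None:
        if self.density < 0:
            raise GeometryError(f"density must be >= 0, got {self.density}")
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be > 0")
        if self.min_separation < self.pore_mix.max_d_outer:
            raise GeometryError(
                f"min_separation {self.min_separation} nm < largest d_outer "
                f"{self.pore_mix.max_d_outer} nm in the mix"
            )
        packing = self.density * 1e-6 * math.pi * (self.min_separation / 2.0) ** 2
        if packing >= 0.55:
            raise GeometryError(
                f"requested packing fraction {packing:.2f} >= 0.55; hard-core "
                "rejection sampling is not feasible at this density/separation"
            )


@dataclass
class GroundTruth:
    """Per-pore and per-gold ground-truth tables.

    ``pores`` columns: pore_id, x_nm, y_nm, class, n_fold, tilt_deg (plus
    internal r_outer_nm and phase_deg). ``gold`` columns: gold_id, x_nm,
    y_nm, intended_associated, nearest_pore_id, distance_nm.
    """

    pores: pd.DataFrame
    gold: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gold_id", "x_nm", "y_nm", "intended_associated", "nearest_pore_id", "distance_nm"]
        )
    )

    PORE_COLUMNS = ["pore_id", "x_nm", "y_nm", "class", "n_fold", "tilt_deg"]
    GOLD_COLUMNS = ["gold_id", "x_nm", "y_nm", "intended_associated", "nearest_pore_id", "distance_nm"]

    def pores_csv(self, path) -> None:
        self.pores[self.PORE_COLUMNS].to_csv(path, index=False)

    def gold_csv(self, path) -> None:
        self.gold[self.GOLD_COLUMNS].to_csv(path, index=False)


def _hardcore_sample(
    mask: SheetMask, n_target: int, min_separation: float, rng: np.random.Generator
) -> np.ndarray:
    """Sequential hard-core rejection sampling of n_target points (x, y) nm."""
    accepted: list[tuple[float, float]] = []
    max_attempts = max(1000, 100 * n_target)
    attempts = 0
    h, w = mask.mask.shape
    min_sep2 = min_separation**2
    while len(accepted) < n_target and attempts < max_attempts:
        attempts += 1
        x = rng.uniform(0, w * mask.pixel_size)
        y = rng.uniform(0, h * mask.pixel_size)
        if not mask.contains(x, y):
            continue
        ok = True
        for ax, ay in accepted:
            if (ax - x) ** 2 + (ay - y) ** 2 < min_sep2:
                ok = False
                break
        if ok:
            accepted.append((x, y))
    if len(accepted) < n_target:
        raise PackingError(
            f"hard-core sampling placed {len(accepted)} of {n_target} requested pores "
            f"after {max_attempts} attempts (min_separation {min_separation} nm)"
        )
    return np.array(accepted).reshape(-1, 2)


def render_sheet(scene: SheetScene) -> tuple[Micrograph, GroundTruth]:
    """Simulate one membrane-sheet micrograph plus its ground truth.

    Pore centres come from sequential hard-core rejection sampling at the
    scene density; each pore is drawn from the class mix, rendered
    analytically at its (sub-pixel) centre, then the whole frame is PSF
    blurred and Gaussian noise is added. The membrane interior and the
    exterior have distinct background means so membrane masking is
    learnable from the image itself.
    """
    rng = np.random.default_rng(scene.seed)
    n_target = int(round(scene.density * scene.mask.area_um2))
    centers = (
        _hardcore_sample(scene.mask, n_target, scene.min_separation, rng)
        if n_target > 0
        else np.empty((0, 2))
    )

    models = [m for m, _ in scene.pore_mix.classes]
    props = np.array([p for _, p in scene.pore_mix.classes])
    class_idx = rng.choice(len(models), size=len(centers), p=props) if len(centers) else np.array([], int)
    phases = (
        rng.uniform(0.0, 360.0, size=len(centers))
        if scene.randomize_phase
        else np.zeros(len(centers))
    )

    h, w = scene.mask.mask.shape
    img = np.where(scene.mask.mask, BACKGROUND_MEMBRANE, BACKGROUND_EXTERIOR).astype(np.float64)
    ps = scene.pixel_size
    rows = []
    for i, ((x, y), ci, ph) in enumerate(zip(centers, class_idx, phases)):
        model = models[ci]
        # paint the analytic pore field into a local window
        reach = 0.8 * model.d_outer
        r0 = max(0, int((y - reach) / ps))
        r1 = min(h, int((y + reach) / ps) + 1)
        c0 = max(0, int((x - reach) / ps))
        c1 = min(w, int((x + reach) / ps) + 1)
        dy = np.arange(r0, r1, dtype=np.float64)[:, None] * ps - y
        dx = np.arange(c0, c1, dtype=np.float64)[None, :] * ps - x
        img[r0:r1, c0:c1] += _pore_field(model, dx, dy, ph)
        rows.append(
            {
                "pore_id": i,
                "x_nm": x,
                "y_nm": y,
                "class": ci,
                "n_fold": model.n_fold,
                "tilt_deg": model.tilt_deg,
                "r_outer_nm": model.r_outer,
                "phase_deg": ph,
            }
        )

    if scene.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=scene.psf_sigma / ps, mode="nearest")
    if scene.noise_sigma > 0:
        img = img + rng.normal(0.0, scene.noise_sigma, size=img.shape)

    truth = GroundTruth(
        pores=pd.DataFrame(rows, columns=list(GroundTruth.PORE_COLUMNS) + ["r_outer_nm", "phase_deg"])
    )
    prov = {
        "generator": "render_sheet",
        "density_per_um2": scene.density,
        "min_separation_nm": scene.min_separation,
        "noise_sigma": scene.noise_sigma,
        "psf_sigma": scene.psf_sigma,
        "seed": scene.seed,
        "n_pores": len(rows),
    }
    return Micrograph(img, ps, prov), truth


# ---------------------------------------------------------------------------
# Immunogold placement


def _edge_distances(x: float, y: float, pores: pd.DataFrame) -> np.ndarray:
    d = np.hypot(pores["x_nm"].to_numpy() - x, pores["y_nm"].to_numpy() - y)
    return np.maximum(0.0, d - pores["r_outer_nm"].to_numpy())


def place_gold(
    truth: GroundTruth,
    mask: SheetMask,
    frac_associated: float,
    threshold: float = 20.0,
    n_particles: int = 100,
    seed: int | None = 0,
) -> GroundTruth:
    """Populate the gold table with particles at controlled association.

    ``round(frac_associated * n_particles)`` particles land within
    ``threshold`` nm of some pore's outer-ring edge (edge distance uniform
    on [0, threshold]); the remainder are uniform in the mask at edge
    distance strictly greater than ``threshold`` from every pore.
    """
    if not 0.0 <= frac_associated <= 1.0:
        raise ValueError(f"frac_associated must be in [0,1], got {frac_associated}")
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    pores = truth.pores
    n_assoc = int(round(frac_associated * n_particles))
    if n_assoc > 0 and len(pores) == 0:
        raise ValueError("cannot place associated particles: ground truth has no pores")
    rng = np.random.default_rng(seed)

    rows = []
    for gid in range(n_assoc):
        for _ in range(10_000):
            pore = pores.iloc[rng.integers(len(pores))]
            ang = rng.uniform(0.0, 2.0 * math.pi)
            radial = pore["r_outer_nm"] + rng.uniform(0.0, threshold)
            x = pore["x_nm"] + radial * math.cos(ang)
            y = pore["y_nm"] + radial * math.sin(ang)
            dists = _edge_distances(x, y, pores)
            if mask.contains(x, y) and dists.min() <= threshold:
                break
        else:
            raise PackingError("could not place an associated gold particle")
        j = int(dists.argmin())
        rows.append(
            {
                "gold_id": gid,
                "x_nm": x,
                "y_nm": y,
                "intended_associated": True,
                "nearest_pore_id": int(pores.iloc[j]["pore_id"]),
                "distance_nm": float(dists[j]),
            }
        )
    for gid in range(n_assoc, n_particles):
        for _ in range(10_000):
            (x, y), = mask.sample_points(rng, 1)
            if len(pores) == 0:
                dists = np.array([np.inf])
            else:
                dists = _edge_distances(x, y, pores)
            if dists.min() > threshold:
                break
        else:
            raise PackingError(
                "mask too crowded with pores to place non-associated gold particles"
            )
        j = int(dists.argmin()) if len(pores) else -1
        rows.append(
            {
                "gold_id": gid,
                "x_nm": x,
                "y_nm": y,
                "intended_associated": False,
                "nearest_pore_id": int(pores.iloc[j]["pore_id"]) if j >= 0 else -1,
                "distance_nm": float(dists[j]) if j >= 0 else float("inf"),
            }
        )
    gold = pd.DataFrame(rows, columns=GroundTruth.GOLD_COLUMNS)
    return GroundTruth(pores=truth.pores, gold=gold)
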
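"""Synthetic head-CT-like phantom slices with dural-hemorrhage lesions.

Each slice is a bright elliptical skull ring around a textured brain
interior on a dark background, with a hyperdense peripheral lesion hugging
the inner skull table: a thin crescent (annular sector) for subdural
hemorrhage (SDH) and a biconvex lens (intersection of two discs) for
epidural hemorrhage (EDH) — the classic radiological shape convention.
Lesion size is matched to a target area fraction of the brain by a
monotone bisection on the shape's thickness parameter, so ground-truth
masks are pixel-accurate by construction.

Intensities roughly follow the relative attenuation ordering of head CT
(skull >> fresh blood > brain parenchyma > air) on a [0, 1] scale, with a
smooth random texture inside the brain and additive Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .records import DatasetManifest, LABELS, SampleRecord

# relative intensity levels, [0,1] scale (skull brightest, air darkest)
SKULL_LEVEL = 0.95
LESION_LEVEL = 0.70
BRAIN_LEVEL = 0.40
BACKGROUND_LEVEL = 0.05
TEXTURE_AMPLITUDE = 0.05


class DegenerateGeometryError(ValueError):
    """Requested lesion cannot fit inside the brain interior."""


@dataclass
class PhantomParams:
    """Geometry, intensity-noise and seeding knobs of the generator.

    ``skull_thickness`` in pixels (None derives ~5% of the image side);
    ``lesion_area_fraction`` is the lesion's share of the brain area;
    ``sdh_arc_span`` is the crescent's angular extent in degrees;
    ``edh_lens_eccentricity`` sets the lens thickness-to-radius ratio
    (smaller = flatter); ``noise_sigma`` is the additive Gaussian noise
    standard deviation on the [0,1] intensity scale.
    """

    image_size: int = 256
    skull_thickness: int | None = None
    lesion_area_fraction: float = 0.06
    sdh_arc_span: float = 110.0
    edh_lens_eccentricity: float = 0.5
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if not 0 <= self.lesion_area_fraction <= 0.2:
            raise ValueError("lesion_area_fraction must lie in [0, 0.2]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 < self.sdh_arc_span < 360:
            raise ValueError("sdh_arc_span must lie in (0, 360) degrees")
        if self.edh_lens_eccentricity <= 0:
            raise ValueError("edh_lens_eccentricity must be positive")

    @property
    def skull_px(self) -> int:
        if self.skull_thickness is not None:
            if self.skull_thickness < 1:
                raise ValueError("skull_thickness must be >= 1 pixel")
            return int(self.skull_thickness)
        return max(2, round(0.05 * self.image_size))


def _geometry(params: PhantomParams):
    n = params.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    dy, dx = yy - c, xx - c
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_out = 0.46 * n
    r_in = r_out - params.skull_px
    if r_in <= 3:
        raise DegenerateGeometryError("skull thickness leaves no brain interior")
    return r, theta, r_in, r_out


def _bisect_thickness(count_fn, target_px, upper):
    """Monotone bisection of a thickness parameter to hit a pixel-count target."""
    if count_fn(upper) < target_px:
        raise DegenerateGeometryError(
            "lesion of requested area cannot fit inside the brain interior")
    lo, hi = 0.0, upper
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if count_fn(mid) < target_px:
            lo = mid
        else:
            hi = mid
    return hi


def _sdh_mask(r, theta, r_in, theta0, span_deg, target_px):
    """Crescent: annular sector of the inner-skull margin around theta0."""
    half = math.radians(span_deg) / 2.0
    dtheta = np.abs(np.angle(np.exp(1j * (theta - theta0))))
    sector = dtheta <= half
    inner = r < r_in

    def mask_at(t):
        return sector & inner & (r >= r_in - t)

    t = _bisect_thickness(lambda t: int(mask_at(t).sum()), target_px, upper=r_in * 0.9)
    return mask_at(t)

def _edh_mask(r, theta, r_in, theta0, eccentricity, target_px):
    """Biconvex lens: intersection of the brain disc with an external disc.

    The external disc is centered beyond the inner skull table along
    theta0 and reaches depth ``h`` into the brain; its radius is h divided
    by the eccentricity, so smaller eccentricities give flatter lenses.
    The intersection of two discs is convex, giving the lentiform shape.
    """
    n = r.shape[0]
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    inner = r < r_in

    def mask_at(h):
        r2 = h / eccentricity
        cy = c + (r_in + r2 - h) * math.sin(theta0)
        cx = c + (r_in + r2 - h) * math.cos(theta0)
        return inner & (np.hypot(yy - cy, xx - cx) < r2)

    h = _bisect_thickness(lambda h: int(mask_at(h).sum()), target_px, upper=r_in * 0.95)
    return mask_at(h)


def generate_slice(class_label: str, params: PhantomParams | None = None) -> SampleRecord:
    """Generate one phantom slice with a pixel-accurate ground-truth mask.

    Identical (class_label, params) including the seed give bit-identical
    output.  A ``lesion_area_fraction`` of zero yields an all-zero mask.
    """
    params = params or PhantomParams()
    if class_label not in LABELS:
        raise ValueError(f"unknown class label {class_label!r}; expected one of {LABELS}")
    rng = np.random.default_rng(params.seed)
    r, theta, r_in, r_out = _geometry(params)
    n = params.image_size

    brain = r < r_in
    skull = (r >= r_in) & (r < r_out)

    # smooth intra-brain texture: low-resolution noise field, smoothed and upsampled
    coarse = rng.standard_normal((8, 8))
    texture = ndimage.zoom(coarse, n / 8.0, order=3)[:n, :n]
    texture = texture / max(1e-9, np.abs(texture).max()) * TEXTURE_AMPLITUDE

    theta0 = rng.uniform(-math.pi, math.pi)
    target_px = int(round(params.lesion_area_fraction * brain.sum()))
    if target_px == 0:
        lesion = np.zeros((n, n), dtype=bool)
    elif class_label == "SDH":
        lesion = _sdh_mask(r, theta, r_in, theta0, params.sdh_arc_span, target_px)
    else:
        lesion = _edh_mask(r, theta, r_in, theta0, params.edh_lens_eccentricity,
                           target_px)

    img = np.full((n, n), BACKGROUND_LEVEL)
    img[brain] = BRAIN_LEVEL + texture[brain]
    img[skull] = SKULL_LEVEL
    img[lesion] = LESION_LEVEL
    img += rng.normal(0.0, params.noise_sigma, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)

    # the synthetic flag tracks SMOTE-interpolated augmentations downstream,
    # so phantom slices enter the pipeline as its "real" samples
    return SampleRecord(image=img.astype(np.float32),
                        mask=lesion.astype(np.uint8),
                        label=class_label, synthetic=False)


def generate_dataset(n_sdh: int, n_edh: int, params: PhantomParams | None = None,
                     out_dir=None) -> DatasetManifest:
    """Generate a labeled phantom dataset, optionally writing it to disk.

    Per-record seeds are derived deterministically from ``params.seed`` via
    a NumPy SeedSequence, so equal (counts, params) reproduce the dataset
    byte-for-byte.  When ``out_dir`` is given the standard image/mask/
    manifest layout is written (see :func:`duralseg.io.save_dataset`).
    """
    if n_sdh < 0 or n_edh < 0:
        raise ValueError("counts must be nonnegative")
    params = params or PhantomParams()
    seeds = np.random.SeedSequence(params.seed).generate_state(n_sdh + n_edh)
    records = []
    for i in range(n_sdh):
        p = replace(params, seed=int(seeds[i] % (2**31)))
        rec = generate_slice("SDH", p)
        rec.id = f"sdh_{i:04d}"
        records.append(rec)
    for i in range(n_edh):
        p = replace(params, seed=int(seeds[n_sdh + i] % (2**31)))
        rec = generate_slice("EDH", p)
        rec.id = f"edh_{i:04d}"
        records.append(rec)
    manifest = DatasetManifest(records).validate()
    if out_dir is not None:
        from .io import save_dataset

        save_dataset(manifest, out_dir)
    return manifest
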
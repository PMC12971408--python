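"""Synthetic muzzle-pattern populations.

The muzzle surface of deer (planum nasolabiale) is a mosaic of raised skin
plaques separated by narrow grooves ("valleys"), individually unique in the
way human fingerprint minutiae are.  This module generates populations of
synthetic muzzle photographs with the statistical shape of a harvest-record
database — many individuals, only 2-3 photographs each, two capture angles
(frontal 0 deg and overhead 45 deg), three quality tiers — so that the whole
verification pipeline can be exercised without any real photographs.

The texture model is a seeded centroidal (Lloyd-relaxed) Voronoi
tessellation: bright plaques of per-plaque random albedo separated by dark
valley grooves, plus two dark nostril ellipses.  Every stage is a pure
function of its seeds; the same master seed reproduces a population
byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.transform import AffineTransform, ProjectiveTransform, resize, warp

from .annotations import Annotation, Circle, write_annotation
from .errors import ConfigurationError, GenerationError

# ---------------------------------------------------------------------------
# Defaults: canonical muzzle frame and photograph frame
# ---------------------------------------------------------------------------

#: (height, width) of the canonical base-pattern rendering.
BASE_SHAPE = (400, 300)
#: (height, width) of the synthetic photograph frame.
FRAME_SHAPE = (720, 960)

#: Vertical foreshortening of the 45-degree overhead view (cos 45 ~ 0.707,
#: slightly relaxed for the nose's own curvature) with a mild trapezoidal
#: taper of the far (upper) edge.
OVERHEAD_VSCALE = 0.68
OVERHEAD_TOP_TAPER = 0.84

SPECIES_PRESETS = {
    # n_cells, valley_width, contrast, nostril band (normalized coordinates)
    "red_deer": dict(n_cells=250, valley_width=3.0, contrast=0.7),
}

ANGLE_FRONTAL = "frontal_0"
ANGLE_OVERHEAD = "overhead_45"
ANGLE_DEGREES = {ANGLE_FRONTAL: "0", ANGLE_OVERHEAD: "45"}


@dataclass(frozen=True)
class PatternSpec:
    """Identity-level description of one animal's muzzle texture.

    ``seed`` fully determines the plaque tessellation, per-plaque albedo and
    nostril geometry; equal specs render byte-identical base patterns.
    ``nostril_geometry`` holds two ``(cx, cy, rx, ry)`` ellipses in
    normalized muzzle coordinates (x, y in [0, 1]).
    """

    individual_id: str
    seed: int
    species: str = "red_deer"
    sex: str = "female"
    n_cells: int = 250
    valley_width: float = 3.0
    contrast: float = 0.7
    nostril_geometry: tuple[tuple[float, float, float, float], ...] = (
        (0.30, 0.26, 0.085, 0.12),
        (0.70, 0.26, 0.085, 0.12),
    )


@dataclass(frozen=True)
class CaptureParams:
    """Per-photograph acquisition conditions.

    All perturbations are deterministic given ``capture_seed``; the
    parameters are physical (blur in pixels of Gaussian sigma, noise as
    intensity s.d. on the [0, 1] scale, occlusion as the fraction of the
    muzzle area covered by dirt/blood blobs, illumination tilt as the
    fractional brightness gradient across the frame).
    """

    angle: str = ANGLE_FRONTAL
    blur_sigma: float = 0.0
    illumination_tilt: float = 0.0
    noise_sd: float = 0.0
    occlusion_fraction: float = 0.0
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    capture_seed: int = 0


@dataclass(frozen=True)
class QualityThresholds:
    """Cut points of the deterministic quality-grading rule."""

    b1: float = 0.8   # max blur for "high"
    b2: float = 3.0   # min blur for "unusable"
    o1: float = 0.05  # max occlusion for "high"
    o2: float = 0.4   # min occlusion for "unusable"
    i1: float = 0.3   # max |illumination tilt| for "high"


DEFAULT_QUALITY_THRESHOLDS = QualityThresholds()


@dataclass
class CaptureRecord:
    """One photograph of one individual, with its ground-truth annotation."""

    individual_id: str
    species: str
    sex: str
    angle: str
    quality: str
    image: np.ndarray
    annotation: Annotation
    capture_seed: int
    image_path: str = ""


# ---------------------------------------------------------------------------
# Individuals and base patterns
# ---------------------------------------------------------------------------

def make_individual(seed: int, species: str = "red_deer", sex: str = "female") -> PatternSpec:
    """Create the identity-level pattern spec for one synthetic animal.

    Equal arguments return equal specs; distinct seeds give distinct plaque
    tessellations and slightly different nostril geometry.
    """
    if seed < 0:
        raise ConfigurationError(f"seed must be non-negative, got {seed}")
    if species not in SPECIES_PRESETS:
        raise ConfigurationError(
            f"unsupported species {species!r}; available: {sorted(SPECIES_PRESETS)}"
        )
    if sex not in ("male", "female"):
        raise ConfigurationError(f"sex must be 'male' or 'female', got {sex!r}")
    preset = SPECIES_PRESETS[species]
    rng = np.random.default_rng([int(seed), 0x6D75])  # per-identity stream
    nostrils = []
    for base_cx in (0.30, 0.70):
        cx = base_cx + rng.uniform(-0.03, 0.03)
        cy = 0.26 + rng.uniform(-0.03, 0.03)
        rx = 0.085 + rng.uniform(-0.012, 0.012)
        ry = 0.12 + rng.uniform(-0.015, 0.015)
        nostrils.append((cx, cy, rx, ry))
    return PatternSpec(
        individual_id=f"{species}-{seed:06d}",
        seed=int(seed),
        species=species,
        sex=sex,
        n_cells=preset["n_cells"],
        valley_width=preset["valley_width"],
        contrast=preset["contrast"],
        nostril_geometry=(tuple(nostrils[0]), tuple(nostrils[1])),
    )


def _tessellation_sites(spec: PatternSpec, shape: tuple[int, int]) -> np.ndarray:
    """Seeded Lloyd-relaxed plaque sites in pixel coordinates, shape (n, 2)."""
    h, w = shape
    rng = np.random.default_rng([spec.seed, 0x7061])
    sites = np.column_stack(
        [rng.uniform(0, h, spec.n_cells), rng.uniform(0, w, spec.n_cells)]
    )
    if spec.n_cells == 1:
        return sites
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([yy.ravel(), xx.ravel()]).astype(np.float64)
    for _ in range(2):  # two Lloyd iterations -> approximately centroidal
        labels = cKDTree(sites).query(pix, k=1)[1]
        counts = np.bincount(labels, minlength=spec.n_cells)
        sum_y = np.bincount(labels, weights=pix[:, 0], minlength=spec.n_cells)
        sum_x = np.bincount(labels, weights=pix[:, 1], minlength=spec.n_cells)
        occupied = counts > 0
        sites[occupied, 0] = sum_y[occupied] / counts[occupied]
        sites[occupied, 1] = sum_x[occupied] / counts[occupied]
    return sites


def render_base_pattern(spec: PatternSpec, size: tuple[int, int] = BASE_SHAPE) -> np.ndarray:
    """Render the canonical (undistorted, frontal) muzzle texture.

    Returns a float image in [0, 1] of the given ``(height, width)`` whose
    intensity range spans exactly ``spec.contrast`` of full scale: bright
    plaques with per-plaque albedo, dark valley grooves of width
    ``spec.valley_width``, and two dark nostril ellipses.
    """
    h, w = size
    if h < 64 or w < 64:
        raise GenerationError(f"base pattern size must be at least 64x64, got {size}")
    for cx, cy, rx, ry in spec.nostril_geometry:
        if not (rx < cx < 1 - rx and ry < cy < 1 - ry):
            raise GenerationError(
                f"nostril ellipse {(cx, cy, rx, ry)} extends outside the muzzle frame"
            )
    rng = np.random.default_rng([spec.seed, 0x616C])  # albedo stream
    sites = _tessellation_sites(spec, size)
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([yy.ravel(), xx.ravel()]).astype(np.float64)

    if spec.n_cells == 1:
        labels = np.zeros(h * w, dtype=np.intp)
        edge = np.minimum.reduce([yy, xx, h - 1 - yy, w - 1 - xx])
        valley = (edge < spec.valley_width).ravel()
    else:
        dist, idx = cKDTree(sites).query(pix, k=2)
        labels = idx[:, 0]
        valley = (dist[:, 1] - dist[:, 0]) < spec.valley_width

    albedo = rng.uniform(0.55, 1.0, spec.n_cells)
    raw = albedo[labels]
    raw[valley] = 0.0
    raw = raw.reshape(h, w)

    # identity-static skin micro-texture: plaque interiors are speckled, not
    # flat, so every patch of the pattern is individually distinctive
    speckle = gaussian_filter(rng.standard_normal((h, w)), 1.2)
    speckle /= max(np.abs(speckle).max(), 1e-12)
    raw = np.clip(raw * (1.0 + 0.22 * speckle), 0.0, 1.0)

    for cx, cy, rx, ry in spec.nostril_geometry:
        mask = ((xx - cx * w) / (rx * w)) ** 2 + ((yy - cy * h) / (ry * h)) ** 2 <= 1.0
        raw[mask] = 0.02

    lo, hi = float(raw.min()), float(raw.max())
    if hi <= lo:  # pragma: no cover - cannot happen with valleys present
        raise GenerationError("degenerate flat base pattern")
    unit = (raw - lo) / (hi - lo)
    c = float(spec.contrast)
    return (0.5 - c / 2.0) + unit * c


# ---------------------------------------------------------------------------
# Captures
# ---------------------------------------------------------------------------

def grade_quality(
    params: CaptureParams, thresholds: QualityThresholds = DEFAULT_QUALITY_THRESHOLDS
) -> str:
    """Deterministic, monotone quality grading of a capture.

    high    iff blur <= b1 and occlusion <= o1 and |tilt| <= i1;
    unusable iff blur >= b2 or occlusion >= o2;
    medium  otherwise.
    """
    t = thresholds
    if params.blur_sigma >= t.b2 or params.occlusion_fraction >= t.o2:
        return "unusable"
    if (
        params.blur_sigma <= t.b1
        and params.occlusion_fraction <= t.o1
        and abs(params.illumination_tilt) <= t.i1
    ):
        return "high"
    return "medium"


def _capture_transform(
    params: CaptureParams, base_shape: tuple[int, int], frame_shape: tuple[int, int]
) -> ProjectiveTransform:
    """Map base-pattern (x, y) pixel coordinates into the photograph frame."""
    bh, bw = base_shape
    fh, fw = frame_shape
    src = np.array([[0, 0], [bw, 0], [bw, bh], [0, bh]], dtype=float)

    if params.angle == ANGLE_OVERHEAD:
        # fixed projective foreshortening of the 45-degree overhead view:
        # vertical compression plus taper of the far (top) edge
        half = bw / 2.0
        dst = np.array(
            [
                [half - half * OVERHEAD_TOP_TAPER, 0],
                [half + half * OVERHEAD_TOP_TAPER, 0],
                [bw, bh * OVERHEAD_VSCALE],
                [0, bh * OVERHEAD_VSCALE],
            ],
            dtype=float,
        )
        persp = ProjectiveTransform.from_estimate(src, dst)
        if not persp:
            raise GenerationError("overhead foreshortening estimation failed")
    elif params.angle == ANGLE_FRONTAL:
        persp = ProjectiveTransform(matrix=np.eye(3))
    else:
        raise ConfigurationError(f"unknown capture angle {params.angle!r}")

    warped_corners = persp(src)
    center = warped_corners.mean(axis=0)
    theta = math.radians(params.rotation_deg)
    tx = (fw - 0.0) / 2.0 - center[0] + params.translation[0]
    ty = (fh - 0.0) / 2.0 - center[1] + params.translation[1]
    rot = (
        AffineTransform(translation=(-center[0], -center[1]))
        + AffineTransform(rotation=theta)
        + AffineTransform(translation=(center[0] + tx, center[1] + ty))
    )
    return ProjectiveTransform(matrix=rot.params @ persp.params)


def _background(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Low-frequency seeded clutter standing in for fur, ground and sky."""
    coarse = rng.uniform(0.15, 0.85, size=(9, 12))
    bg = resize(coarse, shape, order=3, mode="reflect", anti_aliasing=False)
    return np.clip(bg, 0.0, 1.0)


def render_capture(
    spec: PatternSpec,
    params: CaptureParams,
    base: np.ndarray | None = None,
    frame_shape: tuple[int, int] = FRAME_SHAPE,
) -> tuple[CaptureRecord, Annotation]:
    """Photograph a synthetic animal once.

    The base pattern is warped by the capture angle and in-plane jitter,
    composited into seeded background clutter, then degraded by occlusion,
    illumination tilt, blur and sensor noise — in that order (dirt sits on
    the muzzle, optics blur everything, noise is added last).  The returned
    ground-truth annotation bounds the warped pattern and marks the rendered
    nostrils.  Deterministic given ``(spec.seed, params.capture_seed)``.
    """
    if base is None:
        base = render_base_pattern(spec)
    bh, bw = base.shape
    fh, fw = frame_shape
    rng = np.random.default_rng([spec.seed, params.capture_seed, 0x6361])
    img = _background(rng, frame_shape)

    tform = _capture_transform(params, (bh, bw), frame_shape)
    identity_paste = (
        params.angle == ANGLE_FRONTAL
        and params.rotation_deg == 0.0
        and float(params.translation[0]).is_integer()
        and float(params.translation[1]).is_integer()
    )
    if identity_paste:
        x0 = int(round((fw - bw) / 2.0 + params.translation[0]))
        y0 = int(round((fh - bh) / 2.0 + params.translation[1]))
        if not (0 <= x0 and x0 + bw <= fw and 0 <= y0 and y0 + bh <= fh):
            raise GenerationError("muzzle placement falls outside the frame")
        img[y0 : y0 + bh, x0 : x0 + bw] = base
        corners = np.array([[x0, y0], [x0 + bw, y0], [x0 + bw, y0 + bh], [x0, y0 + bh]], float)
        pattern_tf = None
    else:
        inv = tform.inverse
        pattern = warp(base, inv, output_shape=frame_shape, order=1, cval=0.0)
        mask = warp(np.ones((bh, bw)), inv, output_shape=frame_shape, order=1, cval=0.0)
        inside = mask > 0.5
        img[inside] = pattern[inside]
        corners = tform(np.array([[0, 0], [bw, 0], [bw, bh], [0, bh]], float))
        pattern_tf = tform

    x0r = float(np.floor(corners[:, 0].min()))
    y0r = float(np.floor(corners[:, 1].min()))
    x1r = float(np.ceil(corners[:, 0].max()))
    y1r = float(np.ceil(corners[:, 1].max()))
    x0r, y0r = max(x0r, 0.0), max(y0r, 0.0)
    x1r, y1r = min(x1r, float(fw)), min(y1r, float(fh))
    if x1r <= x0r or y1r <= y0r:
        raise GenerationError("warped muzzle lies entirely outside the frame")

    # nostril circles in frame coordinates
    nostrils = []
    for cx, cy, rx, ry in spec.nostril_geometry:
        pt = np.array([[cx * bw, cy * bh]])
        if pattern_tf is not None:
            fx, fy = pattern_tf(pt)[0]
            edge = pattern_tf(pt + [rx * bw, 0.0])[0]
            radius = float(np.hypot(*(edge - [fx, fy])))
        else:
            fx = corners[0, 0] + cx * bw
            fy = corners[0, 1] + cy * bh
            radius = rx * bw
        nostrils.append(Circle(float(fx), float(fy), radius))

    antlers: tuple = ()
    if spec.sex == "male" and params.angle == ANGLE_FRONTAL:
        # two token antler boxes above the muzzle, clipped to the frame
        aw, ah = 0.25 * bw, 0.30 * bh
        top = max(y0r - ah - 10, 0.0)
        antlers = (
            (max(x0r - aw, 0.0), top, max(x0r - aw, 0.0) + aw, top + ah),
            (min(x1r, fw - aw), top, min(x1r, fw - aw) + aw, top + ah),
        )

    # --- degradations -----------------------------------------------------
    if params.occlusion_fraction > 0:
        _occlude(img, rng, (x0r, y0r, x1r, y1r), params.occlusion_fraction)
    if params.illumination_tilt != 0.0:
        xgrad = np.linspace(-1.0, 1.0, fw)[None, :]
        img = img * (1.0 + params.illumination_tilt * xgrad)
    if params.blur_sigma > 0:
        img = gaussian_filter(img, params.blur_sigma)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    annotation = Annotation(
        muzzle_rect=(x0r, y0r, x1r, y1r),
        nostrils=(nostrils[0], nostrils[1]),
        antlers=antlers,
        image_size=(fw, fh),
    )
    record = CaptureRecord(
        individual_id=spec.individual_id,
        species=spec.species,
        sex=spec.sex,
        angle=params.angle,
        quality=grade_quality(params),
        image=img,
        annotation=annotation,
        capture_seed=params.capture_seed,
    )
    return record, annotation


def _occlude(
    img: np.ndarray,
    rng: np.random.Generator,
    rect: tuple[float, float, float, float],
    fraction: float,
) -> None:
    """Paint dark elliptical dirt/blood blobs over ~``fraction`` of the ROI."""
    x0, y0, x1, y1 = (int(round(v)) for v in rect)
    rh, rw = y1 - y0, x1 - x0
    covered = np.zeros((rh, rw), dtype=bool)
    yy, xx = np.mgrid[0:rh, 0:rw]
    target = fraction * rh * rw
    for _ in range(200):
        if covered.sum() >= target:
            break
        cx, cy = rng.uniform(0, rw), rng.uniform(0, rh)
        ax = rng.uniform(0.05, 0.14) * rw
        ay = rng.uniform(0.05, 0.14) * rh
        blob = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
        covered |= blob
        img[y0:y1, x0:x1][blob] = rng.uniform(0.03, 0.2)


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

#: Per-capture quality-tier mix: ~4.4% of field photographs are unusable,
#: the remainder split toward "high" (clean post-mortem close-ups).
DEFAULT_TIER_MIX = {"high": 0.55, "medium": 0.406, "unusable": 0.044}

#: Images per individual: mostly the two-shot protocol, sometimes a third.
DEFAULT_IMAGES_PER_INDIVIDUAL = ((2, 0.75), (3, 0.25))

#: Captures of the same animal share a photo session; a capture keeps the
#: session tier with this probability (else an independent redraw), giving
#: within-individual quality correlation while preserving the marginal mix.
TIER_STICKINESS = 0.8


def _draw_params_for_tier(
    tier: str, angle: str, rng: np.random.Generator, noise: str
) -> CaptureParams:
    """Sample capture conditions that grade to ``tier`` by construction."""
    if noise == "noiseless":
        return CaptureParams(angle=angle, capture_seed=int(rng.integers(2**31)))
    if tier == "high":
        blur = rng.uniform(0.0, 0.6)
        occ = rng.uniform(0.0, 0.04)
        tilt = rng.uniform(-0.25, 0.25)
    elif tier == "medium":
        blur = rng.uniform(1.0, 2.4)
        occ = rng.uniform(0.0, 0.15)
        tilt = rng.uniform(-0.3, 0.3)
    else:  # unusable
        blur = rng.uniform(3.5, 6.0)
        occ = rng.uniform(0.1, 0.35)
        tilt = rng.uniform(-0.3, 0.3)
    return CaptureParams(
        angle=angle,
        blur_sigma=float(blur),
        illumination_tilt=float(tilt),
        noise_sd=float(rng.uniform(0.005, 0.02)),
        occlusion_fraction=float(occ),
        rotation_deg=float(np.clip(rng.normal(0.0, 1.2), -3.0, 3.0)),
        translation=(float(rng.uniform(-10, 10)), float(rng.uniform(-10, 10))),
        capture_seed=int(rng.integers(2**31)),
    )


def sample_population(
    n_individuals: int,
    out_dir: str | Path,
    images_per_individual: Sequence[tuple[int, float]] = DEFAULT_IMAGES_PER_INDIVIDUAL,
    tier_mix: dict[str, float] | None = None,
    angle_protocol: str = "paired",
    master_seed: int = 0,
    species: str = "red_deer",
    noise: str = "default",
):
    """Generate a synthetic population and write it to ``out_dir``.

    Writes one 8-bit greyscale PNG and one LabelMe-compatible JSON per
    capture plus ``manifest.csv``; returns the manifest DataFrame.  Under
    the ``paired`` protocol every individual gets a frontal capture and an
    overhead capture (a third capture, when drawn, is frontal); the
    ``frontal_only`` protocol makes every capture frontal.  The ``noiseless``
    noise preset zeroes all perturbations (every capture grades "high"),
    giving the perfectly separable limit.

    Fully reproducible from ``master_seed``.
    """
    import pandas as pd

    from .annotations import MANIFEST_COLUMNS, write_manifest

    if n_individuals < 2:
        raise ConfigurationError("population needs at least 2 individuals")
    if angle_protocol not in ("paired", "frontal_only"):
        raise ConfigurationError(f"unknown angle protocol {angle_protocol!r}")
    tier_mix = dict(DEFAULT_TIER_MIX if tier_mix is None else tier_mix)
    probs = np.array([tier_mix.get(t, 0.0) for t in ("high", "medium", "unusable")])
    if (probs < 0).any() or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ConfigurationError(f"tier mix must be non-negative and sum to 1, got {tier_mix}")
    counts, cprobs = zip(*images_per_individual)
    if not math.isclose(sum(cprobs), 1.0, abs_tol=1e-9):
        raise ConfigurationError("images-per-individual probabilities must sum to 1")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([int(master_seed), 0x706F])
    tiers = ("high", "medium", "unusable")
    rows = []
    for i in range(n_individuals):
        seed = int(master_seed) * 1_000_003 + i
        sex = "male" if rng.random() < 0.5 else "female"
        spec = make_individual(seed, species=species, sex=sex)
        base = render_base_pattern(spec)
        n_images = int(rng.choice(counts, p=cprobs))
        session_tier = str(rng.choice(tiers, p=probs))
        for k in range(n_images):
            if angle_protocol == "paired" and k == 1:
                angle = ANGLE_OVERHEAD
            else:
                angle = ANGLE_FRONTAL
            if noise == "noiseless":
                tier = "high"
            elif rng.random() < TIER_STICKINESS:
                tier = session_tier
            else:
                tier = str(rng.choice(tiers, p=probs))
            params = _draw_params_for_tier(tier, angle, rng, noise)
            record, annotation = render_capture(spec, params, base=base)
            stem = f"{spec.individual_id}_{k}"
            img_path = out_dir / f"{stem}.png"
            Image.fromarray(
                np.round(record.image * 255).astype(np.uint8), mode="L"
            ).save(img_path)
            write_annotation(annotation, out_dir / f"{stem}.json", image_path=f"{stem}.png")
            rows.append(
                {
                    "individual_id": spec.individual_id,
                    "image_path": str(img_path),
                    "species": species,
                    "sex": sex,
                    "angle": ANGLE_DEGREES[angle],
                    "quality": record.quality,
                    "blacklisted": False,
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
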
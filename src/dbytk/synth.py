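"""Synthetic hyperspectral belt scenes with box annotations.

The generator emulates the structure the pipeline assumes about real
sorting-belt imagery: a dark conveyor background, many overlapping tobacco
leaves, and three classes of contaminant (weed, rubber ring, feather) whose
reflectance curves differ from tobacco mainly around 450 nm and across
550-850 nm (green peak, chlorophyll absorption, red edge, NIR plateau).
Every pixel carries the jittered spectrum of its material, so spectral
analysis, band selection and image enhancement downstream all see realistic
signal.  Scenes are bitwise reproducible for a fixed seed.

Materials are indexed 0..4 = belt, tobacco, weed, rubber_ring, feather;
detection classes are materials 2..4 (class_id = material - 2).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage.draw import ellipse as _draw_ellipse

from .cube import (
    CLASS_NAMES,
    DEFAULT_WAVELENGTHS,
    AnnotatedScene,
    BoundingBox,
    SpectralCube,
)

MATERIAL_NAMES = ("belt", "tobacco") + CLASS_NAMES

#: Per-class NTRM totals of the study's dataset (all splits, pre-augmentation
#: rate 4.203 boxes per scene); used as the default class mix.
DEFAULT_CLASS_MIX = (4539.0, 3243.0, 4827.0)

#: Average number of NTRMs per scene in the study (4,203 boxes / 1,000 scenes).
BOXES_PER_SCENE = 4.203


@dataclasses.dataclass
class MaterialSpectrum:
    """A reflectance template (length-101) with per-band jitter SD."""

    name: str
    curve: np.ndarray
    jitter_sd: float

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=np.float64)
        if self.curve.min() < 0.0 or self.curve.max() > 1.0:
            raise ValueError(f"{self.name}: template outside [0, 1]")
        if np.max(np.abs(np.diff(self.curve))) >= 0.05:
            raise ValueError(f"{self.name}: template not smooth (step >= 0.05)")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def make_spectra_bank(seed: int = 0) -> list[MaterialSpectrum]:
    """Five material templates on the default 400-900 nm grid.

    Shapes follow the qualitative structure of belt-scene reflectance:

    * belt — flat and dark (< 0.1 everywhere);
    * tobacco — green peak near 550 nm, chlorophyll trough near 680 nm,
      red-edge rise over 680-750 nm, NIR plateau >= 0.4;
    * weed — same red edge but a stronger 550 nm peak and a lower plateau;
    * rubber ring — spectrally flat mid-gray (SD across bands < 0.03);
    * feather — bright, gently rising, featureless.

    The seed adds a small smooth perturbation (amplitude <= 0.005) so banks
    from different seeds are distinct while every shape constraint holds;
    all constraints are re-validated before returning.
    """
    wl = DEFAULT_WAVELENGTHS
    rng = np.random.default_rng(seed)

    def wobble():
        phase = rng.uniform(0, 2 * math.pi)
        return 0.004 * np.sin(2 * math.pi * (wl - 400.0) / 500.0 + phase)

    green = np.exp(-(((wl - 550.0) / 35.0) ** 2))
    red_edge = _sigmoid((wl - 715.0) / 15.0)
    curves = {
        "belt": 0.05 + 0.015 * np.sin(2 * math.pi * (wl - 400.0) / 900.0) + wobble(),
        "tobacco": 0.08 + 0.17 * green + 0.47 * red_edge + wobble(),
        "weed": 0.08 + 0.28 * np.exp(-(((wl - 550.0) / 40.0) ** 2))
        + 0.27 * red_edge + wobble(),
        "rubber_ring": 0.22 + 0.01 * (wl - 650.0) / 500.0 + wobble(),
        "feather": 0.45 + 0.25 * _sigmoid((wl - 500.0) / 60.0) + wobble(),
    }
    jitter = {
        "belt": 0.02,
        "tobacco": 0.04,
        "weed": 0.04,
        "rubber_ring": 0.02,
        "feather": 0.03,
    }
    bank = [MaterialSpectrum(n, curves[n], jitter[n]) for n in MATERIAL_NAMES]
    _validate_bank(bank)
    return bank


def _validate_bank(bank: list[MaterialSpectrum]) -> None:
    wl = DEFAULT_WAVELENGTHS
    by = {m.name: m.curve for m in bank}
    if by["belt"].max() >= 0.1:
        raise ValueError("belt template must stay below 0.1")
    nir = wl >= 750.0
    if by["tobacco"][nir].min() < 0.4:
        raise ValueError("tobacco NIR plateau below 0.4")
    if by["rubber_ring"].std() >= 0.03:
        raise ValueError("rubber template not spectrally flat")
    # Separability: tobacco-NTRM contrast must concentrate in 550-850 nm
    # rather than the 455-545 nm window, for at least 2 of 3 NTRM classes.
    inner = (wl >= 455.0) & (wl <= 545.0)
    outer = (wl >= 550.0) & (wl <= 850.0)
    n_ok = sum(
        np.abs(by["tobacco"] - by[c])[outer].mean()
        > np.abs(by["tobacco"] - by[c])[inner].mean()
        for c in CLASS_NAMES
    )
    if n_ok < 2:
        raise ValueError("NTRM/tobacco contrast not concentrated in 550-850 nm")


@dataclasses.dataclass
class SceneConfig:
    """Parameters of one synthetic belt scene.

    Defaults give a desk-scale 640 x 640 scene; the study's native frame
    (3024 x 2464) is available by overriding ``height``/``width``.
    ``blur_px`` is the along-belt motion-blur kernel length in pixels
    (belt transport direction = image x axis); ``gain_range`` models
    illumination-intensity variation as a global multiplicative factor.
    ``spectral=False`` skips the cube and paints the RGB render directly
    (annotation-fidelity mode for large augmentation fixtures).
    """

    height: int = 640
    width: int = 640
    n_leaves: int = 25
    n_ntrms_per_class: tuple[int, int, int] = (2, 1, 2)
    occlusion_prob: float = 0.3
    blur_px: int = 1
    seed: int = 0
    gain_range: tuple[float, float] = (0.7, 1.3)
    size_range: tuple[float, float] = (0.05, 0.12)
    spectral: bool = True


def _ellipse_mask(shape, cy, cx, ry, rx, rot):
    rr, cc = _draw_ellipse(cy, cx, ry, rx, shape=shape, rotation=rot)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def _object_mask(rng, cls: int, shape, size_range) -> np.ndarray | None:
    """Random mask for one NTRM; None if it would touch the border."""
    h, w = shape
    s = min(h, w)
    lo, hi = size_range
    r = rng.uniform(lo, hi) * s
    cy = rng.uniform(0.12 * h, 0.88 * h)
    cx = rng.uniform(0.12 * w, 0.88 * w)
    rot = rng.uniform(0, math.pi)
    if cls == 0:  # weed: union of a few overlapping lobes
        m = np.zeros(shape, dtype=bool)
        for _ in range(3):
            dy, dx = rng.uniform(-0.4 * r, 0.4 * r, size=2)
            m |= _ellipse_mask(
                shape, cy + dy, cx + dx, r * rng.uniform(0.5, 0.9),
                r * rng.uniform(0.5, 0.9), rng.uniform(0, math.pi),
            )
    elif cls == 1:  # rubber ring: annulus
        outer = _ellipse_mask(shape, cy, cx, r, r * rng.uniform(0.85, 1.0), rot)
        inner = _ellipse_mask(shape, cy, cx, 0.55 * r, 0.55 * r, rot)
        m = outer & ~inner
    else:  # feather: elongated thin ellipse
        m = _ellipse_mask(shape, cy, cx, 1.6 * r, 0.35 * r, rot)
    ys, xs = np.nonzero(m)
    if ys.size == 0:
        return None
    if ys.min() < 1 or xs.min() < 1 or ys.max() >= h - 1 or xs.max() >= w - 1:
        return None  # must sit fully inside the frame
    return m


def _tight_box(mask: np.ndarray, cls: int) -> BoundingBox:
    h, w = mask.shape
    ys, xs = np.nonzero(mask)
    y1, y2 = ys.min(), ys.max() + 1
    x1, x2 = xs.min(), xs.max() + 1
    return BoundingBox(
        cls, (x1 + x2) / (2 * w), (y1 + y2) / (2 * h), (x2 - x1) / w, (y2 - y1) / h
    )


@dataclasses.dataclass
class SceneObject:
    """Ground-truth record of one placed NTRM (pre-occlusion mask)."""

    class_id: int
    mask: np.ndarray
    box: BoundingBox


def render_scene(cfg: SceneConfig, bank: list[MaterialSpectrum]) -> AnnotatedScene:
    """Composite one annotated scene from the material bank.

    Leaves are painted first, NTRMs over them, then optional partial
    occlusion by extra leaves painted over each NTRM with probability
    ``cfg.occlusion_prob``.  Boxes are tight to the pre-occlusion object
    masks (occlusion never deletes a ground-truth box).  NTRMs are placed by
    rejection sampling; an over-full scene raises after 100 attempts.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    shape = (h, w)
    label = np.zeros(shape, dtype=np.int8)  # belt everywhere

    s = min(h, w)
    for _ in range(cfg.n_leaves):
        m = _ellipse_mask(
            shape,
            rng.uniform(0, h),
            rng.uniform(0, w),
            rng.uniform(0.06, 0.16) * s,
            rng.uniform(0.03, 0.09) * s,
            rng.uniform(0, math.pi),
        )
        label[m] = 1

    objects: list[SceneObject] = []
    taken = np.zeros(shape, dtype=bool)
    for cls, n in enumerate(cfg.n_ntrms_per_class):
        for _ in range(n):
            for attempt in range(100):
                m = _object_mask(rng, cls, shape, cfg.size_range)
                if m is not None and not (m & taken).any():
                    break
            else:
                raise ValueError(
                    "scene too small to place requested objects "
                    f"(class {CLASS_NAMES[cls]} after 100 attempts)"
                )
            taken |= m
            label[m] = cls + 2
            objects.append(SceneObject(cls, m, _tight_box(m, cls)))

    # Partial occlusion: a leaf painted over one side of the object.
    for obj in objects:
        if rng.uniform() < cfg.occlusion_prob:
            ys, xs = np.nonzero(obj.mask)
            i = rng.integers(ys.size)
            r = 0.6 * math.sqrt(ys.size)
            m = _ellipse_mask(
                shape, ys[i], xs[i], max(2.0, r), max(2.0, 0.7 * r),
                rng.uniform(0, math.pi),
            )
            label[m] = 1

    gain = rng.uniform(*cfg.gain_range)
    boxes = [obj.box for obj in objects]

    # Pixel-to-pixel reflectance variation is spectrally smooth (brightness
    # and spectral-tilt modes scaled to jitter_sd per band) plus a small
    # spectrally white component, as in real leaf/material imagery.
    wl_t = ((DEFAULT_WAVELENGTHS - 650.0) / 250.0).astype(np.float32)  # [-1,1]

    def _noise_field(sd_map, n_bands_t):
        a = rng.standard_normal(shape, dtype=np.float32)
        b = rng.standard_normal(shape, dtype=np.float32)
        white = rng.standard_normal(shape + (n_bands_t.size,), dtype=np.float32)
        return 1.0 + sd_map[..., None] * (
            a[..., None] + 0.5 * b[..., None] * n_bands_t + 0.1 * white
        )

    if cfg.spectral:
        curves = np.stack([m.curve for m in bank]).astype(np.float32)
        sds = np.array([m.jitter_sd for m in bank], dtype=np.float32)
        cube_data = curves[label] * gain
        noise = _noise_field(sds[label], wl_t)
        cube_data = np.clip(cube_data * noise, 0.0, 1.49).astype(np.float32)
        if cfg.blur_px > 1:
            cube_data = uniform_filter1d(cube_data, cfg.blur_px, axis=1)
        cube = SpectralCube(cube_data, DEFAULT_WAVELENGTHS.copy())
        rgb = np.stack(
            [cube.data[:, :, cube.band_index(lam)] for lam in (650.0, 550.0, 450.0)],
            axis=-1,
        )
        rgb = np.round(np.clip(rgb, 0.0, 1.0) * 255.0).astype(np.uint8)
    else:
        cube = None
        idx = [int(np.argmin(np.abs(DEFAULT_WAVELENGTHS - lam)))
               for lam in (650.0, 550.0, 450.0)]
        colors = np.stack([m.curve[idx] for m in bank]).astype(np.float32)
        sds = np.array([m.jitter_sd for m in bank], dtype=np.float32)
        img = colors[label] * gain
        img *= _noise_field(sds[label], wl_t[idx])
        if cfg.blur_px > 1:
            img = uniform_filter1d(img, cfg.blur_px, axis=1)
        rgb = np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)

    scene = AnnotatedScene(rgb=rgb, boxes=boxes, cube=cube, label_map=label)
    scene.objects = objects  # per-object masks for ROI extraction and tests
    return scene


def largest_remainder(total: int, proportions) -> list[int]:
    """Integer apportionment of ``total`` by the largest-remainder rule."""
    p = np.asarray(proportions, dtype=np.float64)
    p = p / p.sum()
    raw = p * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base.tolist()


def assign_splits(n_scenes: int, ratio=(0.6, 0.2, 0.2)) -> list[str]:
    """Split tags for ``n_scenes`` scenes in a 6:2:2 ratio (largest remainder)."""
    sizes = largest_remainder(n_scenes, ratio)
    return ["train"] * sizes[0] + ["val"] * sizes[1] + ["test"] * sizes[2]


def make_dataset(
    n_scenes: int,
    class_mix=DEFAULT_CLASS_MIX,
    seed: int = 0,
    total_boxes: int | None = None,
    bank: list[MaterialSpectrum] | None = None,
    **scene_kwargs,
) -> list[AnnotatedScene]:
    """Generate ``n_scenes`` annotated scenes split 6:2:2.

    Per-class box totals follow ``class_mix`` exactly (largest remainder of
    ``total_boxes``, default the study's rate of 4.203 boxes per scene), and
    each class's boxes are spread as evenly as possible over scenes with the
    seeded remainder placed at random.  Extra keyword arguments are passed to
    :class:`SceneConfig` (e.g. ``height=64, width=64, spectral=False``).
    """
    if n_scenes < 5:
        raise ValueError("need at least 5 scenes to populate a 6:2:2 split")
    if total_boxes is None:
        total_boxes = int(round(BOXES_PER_SCENE * n_scenes))
    rng = np.random.default_rng(seed)
    per_class = largest_remainder(total_boxes, class_mix)
    counts = np.zeros((n_scenes, 3), dtype=int)
    for c, tot in enumerate(per_class):
        counts[:, c] = tot // n_scenes
        extra = tot - counts[:, c].sum()
        counts[rng.choice(n_scenes, size=extra, replace=False), c] += 1

    if bank is None:
        bank = make_spectra_bank(seed)
    tags = assign_splits(n_scenes)
    seeds = np.random.SeedSequence(seed).generate_state(n_scenes) % (2**31)
    scenes = []
    for i in range(n_scenes):
        cfg = SceneConfig(
            n_ntrms_per_class=tuple(int(x) for x in counts[i]),
            seed=int(seeds[i]),
            **scene_kwargs,
        )
        scene = render_scene(cfg, bank)
        scene.scene_id = scene.source_id = f"scene{i:05d}"
        scene.split_tag = tags[i]
        scenes.append(scene)
    return scenes


def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Spectral angle (radians) between two spectra."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    cos = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.arccos(np.clip(cos, -1.0, 1.0)))


def classify_by_template(spectrum: np.ndarray, bank: list[MaterialSpectrum]) -> str:
    """Name of the bank template with the smallest spectral angle."""
    angles = [spectral_angle(spectrum, m.curve) for m in bank]
    return bank[int(np.argmin(angles))].name
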
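"""Parametric blood-smear simulator with pixel-exact ground truth.

Cells are rendered as anti-aliased ellipse-derived shapes: each archetype
is a polar boundary function (base moment ellipse times low-order ripple
and notch terms) plus an intensity program (central pallor, target rings,
planted inclusions, lobed nuclei).  Because the geometry is analytic, the
generator returns exact masks, tight boxes and archetype labels, so every
downstream stage — detection, morphometry, the anomaly rule engine — can
be tested against known truth without any external data.

The default archetype parameter table defines the simulated study
conditions: normal discocytes of 6–8 µm with round central pallor, and
the fourteen abnormal erythrocyte forms rendered with their defining
geometry placed well inside the rule-engine acceptance regions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy import ndimage

from .io_formats import (
    Calibration,
    LabelSchema,
    YoloRecord,
    box_from_mask,
    save_image,
    write_label_file,
)

# ---------------------------------------------------------------------------
# Taxonomy and palette
# ---------------------------------------------------------------------------

#: The 15 recognized erythrocyte shape archetypes (includes Normal).
RBC_ARCHETYPES: tuple[str, ...] = (
    "Elliptocyte",
    "Fragments",
    "Heinz bodies",
    "Hemoglobin-C",
    "Howell-Jolly",
    "Hyperchromasia",
    "Macrocyte",
    "Microcircle",
    "Normal",
    "Oval",
    "Pencil",
    "Pikilocyte",
    "Spleen",
    "Stomatocyte",
    "Target",
)

RBC_RIM = (0.78, 0.44, 0.44)
RBC_PALLOR = (0.92, 0.72, 0.72)
RBC_DARK = (0.45, 0.24, 0.30)      # hyperchromic interior
INCLUSION = (0.22, 0.10, 0.30)
WBC_CYTO = (0.80, 0.78, 0.90)
WBC_NUCLEUS = (0.36, 0.26, 0.55)
PLATELET = (0.62, 0.52, 0.78)
INTRUSION = (0.58, 0.57, 0.53)
BACKGROUND = (0.89, 0.87, 0.90)


class GenerationError(RuntimeError):
    """Raised when a requested smear cannot be rendered (packing, overlap)."""


@dataclass(frozen=True)
class CellSpec:
    """Complete recipe for one rendered cell.

    Axes are semi-axes in µm; ``center`` is (row, col) in pixels;
    ``pallor_ratio`` is the radial fraction of the central pallor,
    ``inclusions`` a list of planted blobs in cell-local coordinates
    (dx, dy as fractions of the semi-major axis, semi-axes in µm, angle).
    """

    class_name: str
    archetype: str | None
    center: tuple[float, float]
    a_um: float
    b_um: float
    rotation: float = 0.0
    pallor_ratio: float = 0.0
    pallor_kind: str = "round"          # round | slit | none | target | uniform-dark
    ripple: tuple[tuple[float, float, float], ...] = ()   # (freq, amp, phase)
    notches: tuple[tuple[float, float, float], ...] = ()  # (angle, width, depth)
    inclusions: tuple[tuple[float, float, float, float, float], ...] = ()
    nucleus_lobes: int = 0
    nucleus_scale: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a_um >= self.b_um > 0):
            raise ValueError("require a >= b > 0")
        if not 0 <= self.pallor_ratio < 1:
            raise ValueError("pallor_ratio must be in [0, 1)")
        if self.archetype is not None and self.class_name != "rbc":
            raise ValueError("RBC shape archetypes only apply to class 'rbc'")


@dataclass
class GroundTruthInstance:
    """One rendered cell with pixel-exact truth."""

    class_id: int
    mask: np.ndarray
    box: YoloRecord
    archetype: str | None = None
    nucleus_mask: np.ndarray | None = None


@dataclass
class SmearSample:
    image: np.ndarray
    calibration: Calibration
    instances: list[GroundTruthInstance]


# ---------------------------------------------------------------------------
# Low-level rendering
# ---------------------------------------------------------------------------

def _boundary_radius(theta: np.ndarray, a_px: float, b_px: float, spec: CellSpec) -> np.ndarray:
    """Polar boundary radius (px) of the shape in the cell-local frame."""
    r = a_px * b_px / np.sqrt((b_px * np.cos(theta)) ** 2 + (a_px * np.sin(theta)) ** 2)
    mod = np.ones_like(theta)
    for freq, amp, phase in spec.ripple:
        mod += amp * np.cos(freq * theta + phase)
    for ang, width, depth in spec.notches:
        d = np.angle(np.exp(1j * (theta - ang)))
        mod -= depth * np.exp(-((d / width) ** 2))
    return r * np.clip(mod, 0.15, None)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    return np.clip(x + 0.5, 0.0, 1.0)


def render_cell(
    spec: CellSpec, canvas_shape: tuple[int, int], calibration: Calibration
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    """Render one cell onto a transparent canvas.

    Returns (alpha, rgb, mask, nucleus_mask); ``mask`` is alpha >= 0.5.
    """
    mpp = calibration.microns_per_pixel
    a_px, b_px = spec.a_um / mpp, spec.b_um / mpp
    H, W = canvas_shape
    pad = a_px * 1.6 + 3
    r0 = max(int(spec.center[0] - pad), 0)
    r1 = min(int(spec.center[0] + pad) + 1, H)
    c0 = max(int(spec.center[1] - pad), 0)
    c1 = min(int(spec.center[1] + pad) + 1, W)
    if r0 >= r1 or c0 >= c1:
        raise GenerationError("cell center outside canvas")
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr - spec.center[0]
    dx = cc - spec.center[1]
    cosr, sinr = math.cos(spec.rotation), math.sin(spec.rotation)
    x = dx * cosr + dy * sinr          # along major axis
    y = -dx * sinr + dy * cosr
    theta = np.arctan2(y, x)
    rho = np.hypot(x, y)
    R = _boundary_radius(theta, a_px, b_px, spec)
    alpha_patch = _smoothstep(R - rho)
    mask_patch = alpha_patch >= 0.5

    t = np.where(R > 0, rho / R, 1.0)   # normalized radial position in [0, 1+]
    rgb_patch = _paint(spec, x, y, t, a_px, b_px, mpp)

    nucleus_patch = None
    if spec.nucleus_lobes > 0:
        nucleus_patch = _paint_nucleus(spec, x, y, a_px, b_px, rgb_patch, mask_patch)

    alpha = np.zeros(canvas_shape)
    rgb = np.zeros(canvas_shape + (3,))
    mask = np.zeros(canvas_shape, dtype=bool)
    alpha[r0:r1, c0:c1] = alpha_patch
    rgb[r0:r1, c0:c1] = rgb_patch
    mask[r0:r1, c0:c1] = mask_patch
    nucleus = None
    if nucleus_patch is not None:
        nucleus = np.zeros(canvas_shape, dtype=bool)
        nucleus[r0:r1, c0:c1] = nucleus_patch & mask_patch
    return alpha, rgb, mask, nucleus


def _paint(spec, x, y, t, a_px, b_px, mpp) -> np.ndarray:
    """Per-pixel RGB inside the cell (cell-local coordinates)."""
    shape = x.shape
    if spec.class_name == "rbc":
        base, pale = np.array(RBC_RIM), np.array(RBC_PALLOR)
        if spec.pallor_kind == "uniform-dark":
            rgb = np.broadcast_to(np.array(RBC_DARK), shape + (3,)).copy()
        elif spec.pallor_kind == "none":
            rgb = np.broadcast_to(base, shape + (3,)).copy()
        elif spec.pallor_kind == "target":
            w = (_smoothstep((t - 0.30) * 6) * _smoothstep((0.64 - t) * 6))[..., None]
            rgb = base + (pale - base) * w
        elif spec.pallor_kind == "slit":
            pa, pb = 0.55 * a_px, 0.16 * a_px
            inside = (x / pa) ** 2 + (y / pb) ** 2
            w = _smoothstep((1.0 - inside) * 3)[..., None]
            rgb = base + (pale - base) * w
        else:  # round central pallor
            w = _smoothstep((spec.pallor_ratio - t) * 8)[..., None]
            rgb = base + (pale - base) * w
    elif spec.class_name == "platelet":
        rgb = np.broadcast_to(np.array(PLATELET), shape + (3,)).copy()
    elif spec.class_name == "intrusion":
        rgb = np.broadcast_to(np.array(INTRUSION), shape + (3,)).copy()
    else:  # leukocyte-lineage cytoplasm
        rgb = np.broadcast_to(np.array(WBC_CYTO), shape + (3,)).copy()

    for dxf, dyf, ia_um, ib_um, ang in spec.inclusions:
        ia, ib = ia_um / mpp, ib_um / mpp
        cx, cy = dxf * a_px, dyf * a_px
        ca, sa = math.cos(ang), math.sin(ang)
        u = (x - cx) * ca + (y - cy) * sa
        v = -(x - cx) * sa + (y - cy) * ca
        inside = (u / ia) ** 2 + (v / ib) ** 2
        w = _smoothstep((1.0 - inside) * 3)[..., None]
        rgb = rgb + (np.array(INCLUSION) - rgb) * w
    return rgb


def _paint_nucleus(spec, x, y, a_px, b_px, rgb_patch, mask_patch) -> np.ndarray:
    """Paint a (possibly lobed) nucleus; lobes are disjoint blobs."""
    k = spec.nucleus_lobes
    scale = spec.nucleus_scale or 0.6
    nuc = np.zeros(x.shape, dtype=bool)
    if k == 1:
        ra, rb = scale * a_px, scale * b_px
        inside = (x / ra) ** 2 + (y / rb) ** 2 <= 1.0
        nuc |= inside
    else:
        ring = 0.45 * min(a_px, b_px)
        lobe_r = scale * min(a_px, b_px) * 0.55
        for i in range(k):
            ang = 2 * math.pi * i / k + 0.3
            cx, cy = ring * math.cos(ang), ring * math.sin(ang)
            inside = ((x - cx) ** 2 + (y - cy) ** 2) <= lobe_r**2
            nuc |= inside
    nuc &= mask_patch
    rgb_patch[nuc] = np.array(WBC_NUCLEUS)
    return nuc


# ---------------------------------------------------------------------------
# Archetype condition table
# ---------------------------------------------------------------------------

def sample_cell_spec(
    class_name: str,
    rng: np.random.Generator,
    center: tuple[float, float],
    archetype: str | None = None,
) -> CellSpec:
    """Draw a cell recipe from the default study conditions."""
    if class_name == "rbc":
        return _sample_rbc(archetype or "Normal", rng, center)
    rot = rng.uniform(0, math.pi)
    if class_name == "platelet":
        d = rng.uniform(2.2, 3.0)
        return CellSpec(class_name, None, center, d / 2, d / 2 * rng.uniform(0.85, 1.0), rot)
    if class_name == "intrusion":
        d = rng.uniform(3.5, 6.0)
        ripple = tuple((f, rng.uniform(0.08, 0.16), rng.uniform(0, 2 * math.pi)) for f in (3, 5))
        return CellSpec(class_name, None, center, d / 2, d / 2 * rng.uniform(0.7, 0.95), rot, ripple=ripple)
    wbc = {
        "lymphocyte": (8.5, 10.0, 1, 0.80),
        "monocyte": (12.0, 15.0, 1, 0.62),
        "myelocyte": (10.0, 14.0, 1, 0.68),
        "erythroblast": (7.0, 9.0, 1, 0.72),
        "basophil": (9.0, 12.0, 2, 0.62),
        "eosinophil": (10.0, 13.0, 2, 0.62),
        "neutrophil": (10.0, 13.0, rng.integers(3, 5), 0.62),
    }
    if class_name not in wbc:
        raise ValueError(f"unknown class {class_name!r}")
    lo, hi, lobes, nscale = wbc[class_name]
    d = rng.uniform(lo, hi)
    b = d / 2 * rng.uniform(0.9, 1.0)
    return CellSpec(class_name, None, center, d / 2, b, rot, nucleus_lobes=int(lobes), nucleus_scale=nscale)


def _sample_rbc(archetype: str, rng: np.random.Generator, center) -> CellSpec:
    rot = rng.uniform(0, math.pi)
    mk = lambda **kw: CellSpec("rbc", archetype, center, rotation=rot, **kw)

    def axes_from(d_um: float, ecc: float) -> tuple[float, float]:
        # preserve the area of a circle of diameter d
        ratio = 1.0 / math.sqrt(1.0 - ecc**2)
        b = d_um / 2 / math.sqrt(ratio)
        return b * ratio, b

    if archetype == "Normal":
        d = rng.uniform(6.8, 7.6)
        return mk(a_um=d / 2, b_um=d / 2 * rng.uniform(0.985, 1.0),
                  pallor_ratio=rng.uniform(0.40, 0.50))
    if archetype == "Macrocyte":
        d = rng.uniform(9.6, 10.6)
        return mk(a_um=d / 2, b_um=d / 2 * rng.uniform(0.985, 1.0),
                  pallor_ratio=rng.uniform(0.40, 0.50))
    if archetype == "Microcircle":
        d = rng.uniform(4.8, 5.5)
        return mk(a_um=d / 2, b_um=d / 2 * rng.uniform(0.985, 1.0),
                  pallor_ratio=rng.uniform(0.35, 0.45))
    if archetype == "Oval":
        a, b = axes_from(rng.uniform(6.8, 7.6), rng.uniform(0.41, 0.47))
        return mk(a_um=a, b_um=b, pallor_ratio=rng.uniform(0.38, 0.46))
    if archetype == "Elliptocyte":
        a, b = axes_from(rng.uniform(6.8, 7.6), rng.uniform(0.64, 0.72))
        return mk(a_um=a, b_um=b, pallor_ratio=rng.uniform(0.38, 0.46))
    if archetype == "Pencil":
        ar = rng.uniform(3.3, 3.8)
        ecc = math.sqrt(1.0 - 1.0 / ar**2)
        a, b = axes_from(rng.uniform(5.8, 6.4), ecc)
        return mk(a_um=a, b_um=b, pallor_kind="none")
    if archetype == "Stomatocyte":
        d = rng.uniform(6.8, 7.6)
        ripple = tuple(
            (f, rng.uniform(0.075, 0.095), rng.uniform(0, 2 * math.pi)) for f in (10, 13)
        )
        return mk(a_um=d / 2, b_um=d / 2, pallor_kind="slit", ripple=ripple)
    if archetype == "Target":
        d = rng.uniform(6.8, 7.6)
        return mk(a_um=d / 2, b_um=d / 2 * rng.uniform(0.985, 1.0), pallor_kind="target")
    if archetype == "Spleen":
        d = rng.uniform(6.4, 7.6)
        return mk(a_um=d / 2, b_um=d / 2 * rng.uniform(0.985, 1.0), pallor_kind="none")
    if archetype == "Hyperchromasia":
        d = rng.uniform(6.4, 7.6)
        return mk(a_um=d / 2, b_um=d / 2 * rng.uniform(0.985, 1.0), pallor_kind="uniform-dark")
    if archetype == "Howell-Jolly":
        d = rng.uniform(6.8, 7.6)
        ang = rng.uniform(0, 2 * math.pi)
        off = 0.42
        inc = (off * math.cos(ang), off * math.sin(ang), 0.62, 0.58, rng.uniform(0, math.pi))
        return mk(a_um=d / 2, b_um=d / 2, pallor_ratio=rng.uniform(0.40, 0.48),
                  inclusions=(inc,))
    if archetype == "Heinz bodies":
        d = rng.uniform(6.8, 7.6)
        ang = rng.uniform(0, 2 * math.pi)
        off = 0.84
        inc = (off * math.cos(ang), off * math.sin(ang), 0.48, 0.45, rng.uniform(0, math.pi))
        return mk(a_um=d / 2, b_um=d / 2, pallor_ratio=rng.uniform(0.40, 0.48),
                  inclusions=(inc,))
    if archetype == "Hemoglobin-C":
        d = rng.uniform(6.8, 7.6)
        inc = (0.0, 0.0, 1.8, 0.38, rng.uniform(0, math.pi))
        return mk(a_um=d / 2, b_um=d / 2, pallor_kind="none", inclusions=(inc,))
    if archetype == "Fragments":
        d = rng.uniform(4.6, 5.4)
        base = rng.uniform(0, 2 * math.pi)
        notches = tuple(
            (base + i * 2.1 + rng.uniform(-0.2, 0.2), 0.9, rng.uniform(0.72, 0.8))
            for i in range(3)
        )
        return mk(a_um=d / 2, b_um=d / 2 * rng.uniform(0.85, 0.95),
                  pallor_kind="none", notches=notches)
    if archetype == "Pikilocyte":
        # frequencies chosen so no pair differs by 2: boundary lumps then
        # contribute no quadrupole, keeping moment eccentricity low
        d = rng.uniform(6.6, 7.6)
        ripple = tuple(
            (f, rng.uniform(0.12, 0.17), rng.uniform(0, 2 * math.pi)) for f in (3, 6, 9)
        )
        return mk(a_um=d / 2, b_um=d / 2, pallor_ratio=rng.uniform(0.38, 0.46), ripple=ripple)
    raise ValueError(f"unknown RBC archetype {archetype!r}")


# ---------------------------------------------------------------------------
# Smear composition
# ---------------------------------------------------------------------------

def render_smear(
    specs: list[CellSpec],
    image_dims: tuple[int, int],
    calibration: Calibration,
    seed: int,
    max_overlap: float = 0.05,
    noise_sigma: float = 0.012,
) -> SmearSample:
    """Compose cells onto a textured background; pixel-exact ground truth.

    Raises :class:`GenerationError` when a cell's mask overlaps previously
    placed cells by more than ``max_overlap`` of its area.
    """
    rng = np.random.default_rng(seed)
    H, W = image_dims
    image = _background(image_dims, rng)
    occupied = np.zeros(image_dims, dtype=bool)
    instances: list[GroundTruthInstance] = []
    for i, spec in enumerate(specs):
        alpha, rgb, mask, nucleus = render_cell(spec, image_dims, calibration)
        if not mask.any():
            raise GenerationError(f"cell {i} rendered empty")
        overlap = (mask & occupied).sum() / mask.sum()
        if overlap > max_overlap:
            raise GenerationError(f"cell {i} overlaps previous cells by {overlap:.2f}")
        image = image * (1 - alpha[..., None]) + rgb * alpha[..., None]
        occupied |= mask
        x_c, y_c, w, h = box_from_mask(mask)
        box = YoloRecord(LabelSchema.id_of(spec.class_name), x_c, y_c, w, h)
        instances.append(
            GroundTruthInstance(box.class_id, mask, box, spec.archetype, nucleus)
        )
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, image.shape)
    return SmearSample(np.clip(image, 0.0, 1.0), calibration, instances)


def _background(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Seeded smooth plasma-like texture around the base background color."""
    low = rng.normal(0.0, 1.0, (shape[0] // 16 + 2, shape[1] // 16 + 2))
    smooth = ndimage.zoom(ndimage.gaussian_filter(low, 1.0), 16, order=1)[
        : shape[0], : shape[1]
    ]
    img = np.empty(shape + (3,))
    for ch, base in enumerate(BACKGROUND):
        img[..., ch] = base + 0.02 * smooth
    return np.clip(img, 0.0, 1.0)


def render_single_cell(
    archetype_or_class: str,
    calibration: Calibration,
    seed: int,
    canvas: tuple[int, int] = (128, 128),
) -> tuple[SmearSample, CellSpec]:
    """One cell centered on its own small canvas (unit-test workhorse)."""
    rng = np.random.default_rng(seed)
    center = (canvas[0] / 2, canvas[1] / 2)
    if archetype_or_class in RBC_ARCHETYPES:
        spec = sample_cell_spec("rbc", rng, center, archetype=archetype_or_class)
    else:
        spec = sample_cell_spec(archetype_or_class, rng, center)
    sample = render_smear([spec], canvas, calibration, seed=seed + 1)
    return sample, spec


# ---------------------------------------------------------------------------
# Dataset-level operations
# ---------------------------------------------------------------------------

@dataclass
class ImageEntry:
    image: np.ndarray
    instances: list[GroundTruthInstance]
    name: str


@dataclass
class DatasetManifest:
    """In-memory dataset with per-class bookkeeping."""

    entries: list[ImageEntry]
    class_counts: dict[str, int]
    seed: int
    params: dict = field(default_factory=dict)

    def recount(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            for inst in e.instances:
                name = LabelSchema.name_of(inst.class_id)
                counts[name] = counts.get(name, 0) + 1
        return counts

    def to_json(self) -> str:
        """Deterministic serialization (image content via perceptual hash)."""
        payload = {
            "seed": self.seed,
            "params": self.params,
            "class_counts": {k: self.class_counts[k] for k in sorted(self.class_counts)},
            "images": [
                {
                    "name": e.name,
                    "dhash": dhash(e.image),
                    "records": [
                        [
                            inst.class_id,
                            round(inst.box.x_center, 6),
                            round(inst.box.y_center, 6),
                            round(inst.box.width, 6),
                            round(inst.box.height, 6),
                            inst.archetype,
                        ]
                        for inst in e.instances
                    ],
                }
                for e in self.entries
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def generate_dataset(
    class_counts: dict[str, int],
    archetype_mix: dict[str, float] | None = None,
    seed: int = 0,
    calibration: Calibration | None = None,
    image_dims: tuple[int, int] = (384, 384),
    cells_per_image: int = 5,
    max_place_tries: int = 400,
) -> DatasetManifest:
    """Generate a dataset matching ``class_counts`` exactly.

    ``archetype_mix`` gives the shape-archetype probabilities for RBCs
    (must sum to 1); the default is an all-Normal population.
    """
    calibration = calibration or Calibration(0.1)
    rng = np.random.default_rng(seed)
    if any(v < 0 for v in class_counts.values()):
        raise ValueError("counts must be >= 0")
    mix = archetype_mix or {"Normal": 1.0}
    unknown = set(mix) - set(RBC_ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes {sorted(unknown)}")
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("archetype mix must sum to 1")
    mix_names = sorted(mix)
    mix_p = np.array([mix[n] for n in mix_names])

    queue: list[tuple[str, str | None]] = []
    for name in sorted(class_counts):
        if name not in LabelSchema.names:
            raise ValueError(f"unknown class {name!r}")
        for _ in range(class_counts[name]):
            arch = (
                str(rng.choice(mix_names, p=mix_p)) if name == "rbc" else None
            )
            queue.append((name, arch))
    order = rng.permutation(len(queue))
    queue = [queue[i] for i in order]

    entries: list[ImageEntry] = []
    idx = 0
    img_no = 0
    while idx < len(queue):
        batch = queue[idx : idx + cells_per_image]
        specs, n_placed = _place_batch(batch, rng, image_dims, calibration, max_place_tries)
        if n_placed == 0:
            raise GenerationError(
                f"cannot place a {batch[0][0]} cell alone on a "
                f"{image_dims[0]}x{image_dims[1]} canvas"
            )
        idx += n_placed
        sample = render_smear(
            specs, image_dims, calibration, seed=int(rng.integers(2**31))
        )
        entries.append(ImageEntry(sample.image, sample.instances, f"smear_{img_no:05d}"))
        img_no += 1
    manifest = DatasetManifest(
        entries,
        dict(class_counts),
        seed,
        params={
            "image_dims": list(image_dims),
            "cells_per_image": cells_per_image,
            "microns_per_pixel": calibration.microns_per_pixel,
            "archetype_mix": {k: mix[k] for k in sorted(mix)},
        },
    )
    assert manifest.recount() == {k: v for k, v in class_counts.items() if v > 0}
    return manifest


def _place_batch(batch, rng, image_dims, calibration, max_tries):
    """Rejection-sample non-overlapping centers; returns (specs, n_placed).

    Stops at the first cell that cannot be placed, so the caller can
    overflow the remainder onto a fresh image.
    """
    H, W = image_dims
    mpp = calibration.microns_per_pixel
    placed: list[tuple[float, float, float]] = []  # (row, col, radius_px)
    specs: list[CellSpec] = []
    for name, arch in batch:
        ok = False
        for attempt in range(max_tries):
            probe = sample_cell_spec(name, rng, (0.0, 0.0), archetype=arch)
            r_px = probe.a_um / mpp * 1.25 + 2
            if 2 * (r_px + 1) >= min(H, W):
                continue
            row = rng.uniform(r_px + 1, H - r_px - 1)
            col = rng.uniform(r_px + 1, W - r_px - 1)
            if all(np.hypot(row - pr, col - pc) > r_px + prad for pr, pc, prad in placed):
                placed.append((row, col, r_px))
                specs.append(replace(probe, center=(row, col)))
                ok = True
                break
        if not ok:
            break
    return specs, len(specs)


def write_manifest(manifest: DatasetManifest, out_dir) -> None:
    """Write images (PNG), YOLO label files and the manifest JSON."""
    from pathlib import Path

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    for e in manifest.entries:
        save_image(e.image, out / "images" / f"{e.name}.png")
        write_label_file([i.box for i in e.instances], out / "labels" / f"{e.name}.txt")
    (out / "manifest.json").write_text(manifest.to_json() + "\n")


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

MAX_ROTATE_DEG = 15.0
MAX_SHEAR_RAD = 0.2
MIN_RETAINED_FRACTION = 0.2


def augment(
    image: np.ndarray,
    instances: list[GroundTruthInstance],
    op: str,
    angle_deg: float = 0.0,
    shear_rad: float = 0.0,
) -> tuple[np.ndarray, list[GroundTruthInstance]]:
    """Apply a geometric augmentation to an image and its ground truth.

    ``op`` is one of ``hflip``, ``vflip``, ``rotate``, ``shear``; rotation
    is limited to ±15° and shear to ±0.2 rad.  Boxes are recomputed from
    the transformed masks; cells whose transformed mask retains less than
    20% of its original area are dropped.  Nearest-neighbor resampling is
    used throughout so the identity transforms are exact.
    """
    if op == "hflip":
        tf = lambda arr: arr[:, ::-1]
    elif op == "vflip":
        tf = lambda arr: arr[::-1]
    elif op == "rotate":
        if abs(angle_deg) > MAX_ROTATE_DEG:
            raise ValueError(f"rotation angle {angle_deg} outside ±{MAX_ROTATE_DEG}°")
        tf = lambda arr: _affine(arr, angle_deg=angle_deg)
    elif op == "shear":
        if abs(shear_rad) > MAX_SHEAR_RAD:
            raise ValueError(f"shear {shear_rad} outside ±{MAX_SHEAR_RAD} rad")
        tf = lambda arr: _affine(arr, shear_rad=shear_rad)
    else:
        raise ValueError(f"unknown augmentation {op!r}")

    new_image = np.ascontiguousarray(tf(image))
    new_instances: list[GroundTruthInstance] = []
    for inst in instances:
        new_mask = np.ascontiguousarray(tf(inst.mask.astype(np.uint8))).astype(bool)
        if new_mask.sum() < MIN_RETAINED_FRACTION * inst.mask.sum():
            continue
        x_c, y_c, w, h = box_from_mask(new_mask)
        nuc = None
        if inst.nucleus_mask is not None:
            nuc = np.ascontiguousarray(tf(inst.nucleus_mask.astype(np.uint8))).astype(bool)
        new_instances.append(
            GroundTruthInstance(
                inst.class_id,
                new_mask,
                YoloRecord(inst.class_id, x_c, y_c, w, h),
                inst.archetype,
                nuc,
            )
        )
    return new_image, new_instances


def _affine(arr: np.ndarray, angle_deg: float = 0.0, shear_rad: float = 0.0) -> np.ndarray:
    from skimage import transform as sktf

    H, W = arr.shape[:2]
    center = np.array([W / 2 - 0.5, H / 2 - 0.5])
    t = (
        sktf.AffineTransform(translation=center)
        + sktf.AffineTransform(rotation=np.deg2rad(angle_deg), shear=shear_rad)
        + sktf.AffineTransform(translation=-center)
    )
    out = sktf.warp(
        arr.astype(float), t.inverse, order=0, preserve_range=True, mode="constant"
    )
    return out.astype(arr.dtype) if arr.dtype == np.uint8 else out


# ---------------------------------------------------------------------------
# Perceptual hashing / deduplication / rebalancing / normalization
# ---------------------------------------------------------------------------

def dhash(image: np.ndarray, hash_size: int = 8) -> str:
    """Difference hash: horizontal gradient signs of a downscaled grayscale."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    if arr.ndim == 3:
        arr = arr @ np.array([0.299, 0.587, 0.114])
    im = Image.fromarray((arr * 255).astype(np.uint8))
    small = np.asarray(
        im.resize((hash_size + 1, hash_size), Image.Resampling.LANCZOS), dtype=int
    )
    bits = (small[:, 1:] > small[:, :-1]).flatten()
    return "".join("1" if b else "0" for b in bits)


def hash_distance(h1: str, h2: str) -> int:
    return sum(c1 != c2 for c1, c2 in zip(h1, h2))


def deduplicate(images: list[np.ndarray], threshold: int = 0) -> list[int]:
    """Indices of images retained after perceptual-hash deduplication.

    An image is removed when its hash distance to an earlier retained
    image is <= ``threshold`` (default 0: exact hash duplicates only).
    """
    retained: list[int] = []
    hashes: list[str] = []
    for i, img in enumerate(images):
        h = dhash(img)
        if any(hash_distance(h, prev) <= threshold for prev in hashes):
            continue
        retained.append(i)
        hashes.append(h)
    return retained


def rebalance(
    manifest: DatasetManifest, target_counts: dict[str, int], seed: int
) -> DatasetManifest:
    """Oversample minority classes by seeded crop-duplication + augmentation.

    Each oversample crops one cell of the deficient class out of a source
    image, applies a random flip/rotation, and appends it as a new
    single-cell image, so per-class counts hit the targets exactly.
    Majority classes are untouched.
    """
    rng = np.random.default_rng(seed)
    current = manifest.recount()
    for name, target in target_counts.items():
        if target < current.get(name, 0):
            raise ValueError(f"target for {name!r} below current count")
    entries = list(manifest.entries)
    counts = dict(manifest.class_counts)
    for name in sorted(target_counts):
        deficit = target_counts[name] - current.get(name, 0)
        sources = [
            (e, inst)
            for e in manifest.entries
            for inst in e.instances
            if LabelSchema.name_of(inst.class_id) == name
        ]
        if deficit > 0 and not sources:
            raise ValueError(f"no source cells of class {name!r} to oversample")
        for j in range(deficit):
            entry, inst = sources[int(rng.integers(len(sources)))]
            crop_img, crop_inst = _crop_cell(entry.image, inst)
            op = ("hflip", "vflip", "rotate")[int(rng.integers(3))]
            ang = float(rng.uniform(-MAX_ROTATE_DEG, MAX_ROTATE_DEG)) if op == "rotate" else 0.0
            aug_img, aug_insts = augment(crop_img, [crop_inst], op, angle_deg=ang)
            entries.append(
                ImageEntry(aug_img, aug_insts, f"oversample_{name}_{j:04d}")
            )
            counts[name] = counts.get(name, 0) + 1
    return DatasetManifest(entries, counts, manifest.seed, dict(manifest.params))


def _crop_cell(image: np.ndarray, inst: GroundTruthInstance, margin: int = 6):
    rows = np.flatnonzero(inst.mask.any(axis=1))
    cols = np.flatnonzero(inst.mask.any(axis=0))
    r0, r1 = max(rows[0] - margin, 0), min(rows[-1] + margin + 1, image.shape[0])
    c0, c1 = max(cols[0] - margin, 0), min(cols[-1] + margin + 1, image.shape[1])
    crop = image[r0:r1, c0:c1].copy()
    mask = inst.mask[r0:r1, c0:c1].copy()
    x_c, y_c, w, h = box_from_mask(mask)
    nuc = inst.nucleus_mask[r0:r1, c0:c1].copy() if inst.nucleus_mask is not None else None
    return crop, GroundTruthInstance(
        inst.class_id, mask, YoloRecord(inst.class_id, x_c, y_c, w, h), inst.archetype, nuc
    )


def normalize_pixels(image: np.ndarray) -> np.ndarray:
    """Per-channel min–max scaling to [0, 1]; constant channels are an error."""
    arr = np.asarray(image, dtype=float)
    channels = arr.reshape(-1, arr.shape[-1]) if arr.ndim == 3 else arr.reshape(-1, 1)
    lo = channels.min(axis=0)
    hi = channels.max(axis=0)
    if np.any(hi - lo < 1e-12):
        bad = int(np.argmin(hi - lo))
        raise ValueError(f"channel {bad} is constant; min–max scaling undefined")
    return (arr - lo) / (hi - lo)
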
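"""Morphometric descriptor extraction for single blood cells.

The module owns the 50-entry descriptor registry — the single source of
truth for descriptor names, order, units and grouping — and computes the
full vector from a cell's image crop, binary mask and (optional) nucleus
mask.  Grouping: geometric (20), nuclear/cytoplasmic (10), texture (8),
color (6), specialized hematology (6).

Conventions
-----------
* Shape statistics (axes, orientation, eccentricity) come from central
  second moments of the mask, i.e. the moment ellipse.
* Perimeter is the sub-pixel marching-squares contour length; raw
  pixel-edge counting biases circularity above 1.
* Physical units are attached through a :class:`~hemamorph.io_formats.Calibration`
  (µm per pixel); areas scale with its square, volumes with its cube.
* Rule-engine evidence that is not part of the registry (central-pallor
  geometry, inclusion blobs, the radial intensity profile) is returned in
  ``MorphometryVector.extras``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import measure
from skimage.feature import graycomatrix

from .io_formats import Calibration

# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

# (name, unit, group); unit is one of um, um2, um3, ratio, rad, intensity, count
_REGISTRY_SPEC: tuple[tuple[str, str, str], ...] = (
    # geometric (20)
    ("cell_area", "um2", "geometric"),
    ("cell_perimeter", "um", "geometric"),
    ("circularity", "ratio", "geometric"),
    ("eccentricity", "ratio", "geometric"),
    ("nucleus_area", "um2", "geometric"),
    ("nucleus_perimeter", "um", "geometric"),
    ("nucleus_circularity", "ratio", "geometric"),
    ("nucleus_eccentricity", "ratio", "geometric"),
    ("cytoplasm_area", "um2", "geometric"),
    ("cytoplasm_thickness", "um", "geometric"),
    ("aspect_ratio", "ratio", "geometric"),
    ("elongation", "ratio", "geometric"),
    ("compactness", "ratio", "geometric"),
    ("convex_hull_area", "um2", "geometric"),
    ("solidity", "ratio", "geometric"),
    ("feret_diameter", "um", "geometric"),
    ("min_feret_diameter", "um", "geometric"),
    ("major_axis_length", "um", "geometric"),
    ("minor_axis_length", "um", "geometric"),
    ("orientation", "rad", "geometric"),
    # nuclear / cytoplasmic (10)
    ("chromatin_density", "intensity", "nuclear"),
    ("nuclear_shape_factor", "ratio", "nuclear"),
    ("nuclear_cytoplasmic_ratio", "ratio", "nuclear"),
    ("nuclear_texture_variance", "intensity", "nuclear"),
    ("cell_volume", "um3", "nuclear"),
    ("nuclear_volume", "um3", "nuclear"),
    ("symmetry", "ratio", "nuclear"),
    ("roundness", "ratio", "nuclear"),
    ("nuclear_solidity", "ratio", "nuclear"),
    ("nuclear_displacement", "ratio", "nuclear"),
    # texture (8)
    ("texture_entropy", "intensity", "texture"),
    ("texture_contrast", "intensity", "texture"),
    ("texture_correlation", "intensity", "texture"),
    ("texture_energy", "intensity", "texture"),
    ("texture_homogeneity", "intensity", "texture"),
    ("edge_gradient", "intensity", "texture"),
    ("boundary_roughness", "ratio", "texture"),
    ("nuclear_edge_contrast", "intensity", "texture"),
    # color (6)
    ("mean_red", "intensity", "color"),
    ("mean_green", "intensity", "color"),
    ("mean_blue", "intensity", "color"),
    ("mean_hue", "intensity", "color"),
    ("mean_saturation", "intensity", "color"),
    ("mean_value", "intensity", "color"),
    # specialized hematology (6)
    ("granularity_index", "intensity", "specialized"),
    ("vacuolation_level", "ratio", "specialized"),
    ("inclusion_presence", "count", "specialized"),
    ("membrane_integrity", "ratio", "specialized"),
    ("cytoplasmic_granularity", "intensity", "specialized"),
    ("lobe_count", "count", "specialized"),
)


class DescriptorRegistry:
    """Ordered registry of the 50 morphometric descriptors."""

    names: tuple[str, ...] = tuple(n for n, _, _ in _REGISTRY_SPEC)
    units: dict[str, str] = {n: u for n, u, _ in _REGISTRY_SPEC}
    groups: dict[str, str] = {n: g for n, _, g in _REGISTRY_SPEC}

    @classmethod
    def __len__(cls) -> int:
        return len(cls.names)

    @classmethod
    def index(cls, name: str) -> int:
        return cls.names.index(name)

    @classmethod
    def group_counts(cls) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in cls.groups.values():
            out[g] = out.get(g, 0) + 1
        return out


REGISTRY = DescriptorRegistry()
assert len(REGISTRY.names) == 50 and len(set(REGISTRY.names)) == 50


@dataclass
class MorphometryVector:
    """The 50 registry descriptors for one cell, plus rule-engine evidence.

    ``values`` is keyed and ordered by :class:`DescriptorRegistry`;
    ``extras`` carries auxiliary hematology measurements (central-pallor
    geometry, inclusion blob statistics, radial-profile inversions) that
    the anomaly rule engine consumes as evidence.
    """

    values: dict[str, float]
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in REGISTRY.names if n not in self.values]
        extra = [n for n in self.values if n not in REGISTRY.names]
        if missing or extra:
            raise ValueError(f"registry mismatch: missing={missing[:3]} extra={extra[:3]}")
        self.values = {n: float(self.values[n]) for n in REGISTRY.names}
        bad = [n for n, v in self.values.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite descriptors: {bad}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in REGISTRY.names], dtype=float)

    @property
    def equivalent_diameter(self) -> float:
        """Diameter (µm) of the circle with the cell's area."""
        return 2.0 * math.sqrt(self.values["cell_area"] / math.pi)


# ---------------------------------------------------------------------------
# Closed-form primitives
# ---------------------------------------------------------------------------

def eccentricity(a: float, b: float) -> float:
    """Ellipse eccentricity e = sqrt(1 - (b/a)^2) from semi-axes a >= b."""
    if a <= 0:
        raise ValueError("semi-major axis must be positive")
    if b < 0 or a < b:
        raise ValueError("require a >= b >= 0")
    return math.sqrt(1.0 - (b / a) ** 2)


def circularity(area: float, perimeter: float) -> float:
    """4*pi*area / perimeter^2; 1 for an ideal circle."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 4.0 * math.pi * area / perimeter**2


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def contour_perimeter(mask: np.ndarray, smooth_window: int = 5) -> float:
    """Sub-pixel perimeter of the largest outer contour.

    The marching-squares contour is lightly smoothed with a circular
    moving average before summing segment lengths; the raw staircase
    polygon overestimates the perimeter of smooth shapes by ~5%, which
    would bias circularity visibly below 1 for an ideal disc.
    """
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("mask has no contour")
    best, best_len = None, -1.0
    for c in contours:
        raw = np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1))
        if raw > best_len:
            best, best_len = c, raw
    pts = best[:-1] if np.allclose(best[0], best[-1]) else best
    n = len(pts)
    if n >= smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        sm = np.empty_like(pts)
        for d in range(2):
            ext = np.concatenate([pts[-(smooth_window // 2):, d], pts[:, d], pts[: smooth_window // 2, d]])
            sm[:, d] = np.convolve(ext, kernel, mode="valid")
        pts = sm
    closed = np.vstack([pts, pts[:1]])
    return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


def _min_feret(points: np.ndarray) -> float:
    """Minimum caliper width of a point set via convex-hull edge normals."""
    from scipy.spatial import ConvexHull

    if len(points) < 3:
        return 0.0
    hull = points[ConvexHull(points).vertices]
    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    norms = np.linalg.norm(edges, axis=1)
    keep = norms > 0
    edges, norms = edges[keep], norms[keep]
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1) / norms[:, None]
    widths = np.ptp(hull @ normals.T, axis=0)
    return float(widths.min())


def _glcm_stats(gray: np.ndarray, mask: np.ndarray, levels: int = 32) -> dict[str, float]:
    """Co-occurrence texture stats on a quantized image, restricted to a mask.

    Pixels outside the mask are assigned level 0 and all pairs touching
    level 0 are discarded before normalization, so the statistics describe
    only within-mask pairs.
    """
    vals = gray[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-12:
        q = np.where(mask, 1, 0).astype(np.uint8)
    else:
        q = np.zeros(gray.shape, dtype=np.uint8)
        q[mask] = 1 + np.minimum(
            (levels - 1), ((gray[mask] - lo) / (hi - lo) * levels).astype(int)
        )
    glcm = graycomatrix(
        q,
        distances=[1],
        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=levels + 1,
        symmetric=True,
    ).astype(float)
    glcm = glcm[1:, 1:, 0, :].sum(axis=2)  # drop outside-mask level, pool angles
    total = glcm.sum()
    if total == 0:
        return {"entropy": 0.0, "contrast": 0.0, "correlation": 0.0, "energy": 1.0, "homogeneity": 1.0}
    p = glcm / total
    i, j = np.mgrid[0:levels, 0:levels].astype(float)
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    contrast = float((p * (i - j) ** 2).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    mu_i, mu_j = (p * i).sum(), (p * j).sum()
    sd_i = math.sqrt(max((p * (i - mu_i) ** 2).sum(), 0.0))
    sd_j = math.sqrt(max((p * (j - mu_j) ** 2).sum(), 0.0))
    if sd_i * sd_j < 1e-12:
        correlation = 1.0
    else:
        correlation = float((p * (i - mu_i) * (j - mu_j)).sum() / (sd_i * sd_j))
    return {
        "entropy": entropy,
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
    }


def _radial_profile(gray: np.ndarray, mask: np.ndarray, n_bins: int = 12) -> np.ndarray:
    """Mean intensity from rim (depth 0) to center (depth 1), by EDT depth bins."""
    depth = ndimage.distance_transform_edt(mask)
    dmax = depth.max()
    if dmax <= 0:
        return np.array([float(gray[mask].mean())])
    d = depth[mask] / dmax
    vals = gray[mask]
    bins = np.minimum((d * n_bins).astype(int), n_bins - 1)
    prof = np.array(
        [vals[bins == k].mean() if np.any(bins == k) else np.nan for k in range(n_bins)]
    )
    # fill empty bins by neighbor interpolation
    idx = np.arange(n_bins)
    ok = ~np.isnan(prof)
    return np.interp(idx, idx[ok], prof[ok])


def count_profile_inversions(profile: np.ndarray, prominence: float = 0.06) -> int:
    """Interior local extrema of the mirrored (rim→center→rim) profile.

    A normal disc with central pallor (monotone brightening toward the
    center) scores 1 (the central maximum); a target-form profile
    (dark center, bright ring, dark rim) scores 3.
    """
    if len(profile) < 3:
        return 0
    # smooth lightly, then mirror about the center
    kernel = np.array([0.25, 0.5, 0.25])
    p = np.convolve(np.pad(profile, 1, mode="edge"), kernel, mode="valid")
    mirrored = np.concatenate([p, p[-2::-1]])
    # hysteresis turning-point count: a reversal only registers once the
    # signal moves more than `prominence` away from the running extremum,
    # so plateaus and noise below the threshold never split a peak
    direction = 0
    ref = mirrored[0]
    count = 0
    for v in mirrored[1:]:
        if direction == 0:
            if v > ref + prominence:
                direction, ref = 1, v
            elif v < ref - prominence:
                direction, ref = -1, v
        elif direction == 1:
            if v > ref:
                ref = v
            elif ref - v > prominence:
                count += 1
                direction, ref = -1, v
        else:
            if v < ref:
                ref = v
            elif v - ref > prominence:
                count += 1
                direction, ref = 1, v
    return count


def _inclusion_stats(
    gray: np.ndarray, mask: np.ndarray, min_size_px: int = 2
) -> dict:
    """Dark intracellular blobs: count, sizes, elongation, rim contact."""
    vals = gray[mask]
    thresh = float(np.median(vals)) - 0.25
    blobs = mask & (gray < thresh)
    labeled, n = ndimage.label(blobs)
    depth = ndimage.distance_transform_edt(mask)
    dmax = max(depth.max(), 1.0)
    stats = []
    for lab in range(1, n + 1):
        blob = labeled == lab
        size = int(blob.sum())
        if size < min_size_px:
            continue
        ecc = 0.0
        if size >= 5:
            props = measure.regionprops(blob.astype(int))[0]
            ecc = float(props.eccentricity)
        min_depth = float(depth[blob].min() / dmax)
        stats.append({"size_px": size, "eccentricity": ecc, "rim_depth": min_depth})
    return {
        "inclusion_count": len(stats),
        "inclusions": stats,
        "max_inclusion_eccentricity": max((s["eccentricity"] for s in stats), default=0.0),
        "has_peripheral_inclusion": any(s["rim_depth"] <= 0.15 for s in stats),
    }


def _pallor_stats(gray: np.ndarray, mask: np.ndarray) -> dict:
    """Central-pallor geometry: area fraction and moment eccentricity."""
    depth = ndimage.distance_transform_edt(mask)
    dmax = depth.max()
    if dmax <= 0:
        return {"pallor_ratio": 0.0, "pallor_eccentricity": 0.0}
    rim = mask & (depth / dmax < 0.25)
    interior = mask & (depth / dmax >= 0.25)
    if not rim.any() or not interior.any():
        return {"pallor_ratio": 0.0, "pallor_eccentricity": 0.0}
    rim_ref = float(gray[rim].mean())
    pallor = interior & (gray > rim_ref + 0.12)
    ratio = float(pallor.sum() / mask.sum())
    ecc = 0.0
    if pallor.sum() >= 5:
        labeled, _ = ndimage.label(pallor)
        sizes = ndimage.sum_labels(pallor, labeled, np.arange(1, labeled.max() + 1))
        main = labeled == (1 + int(np.argmax(sizes)))
        if main.sum() >= 5:
            ecc = float(measure.regionprops(main.astype(int))[0].eccentricity)
    return {"pallor_ratio": ratio, "pallor_eccentricity": ecc}


# ---------------------------------------------------------------------------
# Main extraction
# ---------------------------------------------------------------------------

def extract_descriptors(
    image: np.ndarray,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray | None,
    calibration: Calibration,
) -> MorphometryVector:
    """Compute the full 50-descriptor vector for one cell.

    Parameters
    ----------
    image : RGB array in [0, 1], same spatial shape as the masks.
    cell_mask : boolean mask of the whole cell (nonempty).
    nucleus_mask : boolean mask of the nucleus, a subset of ``cell_mask``;
        ``None`` requests automatic Otsu segmentation of the dominant-stain
        channel within the cell, an all-False array declares the cell
        anuclear (RBC, platelet).
    calibration : physical pixel size.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    if image.shape[:2] != cell_mask.shape:
        raise ValueError("image and mask shapes differ")
    mpp = calibration.microns_per_pixel
    gray = skcolor.rgb2gray(image)
    hsv = skcolor.rgb2hsv(image)

    if nucleus_mask is None:
        nucleus_mask = _auto_nucleus(image, cell_mask)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if (nucleus_mask & ~cell_mask).any():
        raise ValueError("nucleus mask extends outside the cell mask")

    props = measure.regionprops(cell_mask.astype(int))[0]
    area_px = float(props.area)
    perim_px = contour_perimeter(cell_mask)
    area = area_px * mpp**2
    perim = perim_px * mpp
    major = float(props.axis_major_length) * mpp
    minor = float(props.axis_minor_length) * mpp
    ecc = float(props.eccentricity)
    solidity = float(props.solidity)
    hull_area = float(props.area_convex) * mpp**2
    feret = float(props.feret_diameter_max) * mpp
    coords = np.argwhere(cell_mask).astype(float)
    min_feret = _min_feret(coords) * mpp
    circ = circularity(area, perim)

    # nucleus geometry (zeros for anuclear cells)
    if nucleus_mask.any():
        nprops = measure.regionprops(nucleus_mask.astype(int))[0]
        n_area = float(nprops.area) * mpp**2
        n_perim = contour_perimeter(nucleus_mask) * mpp
        n_circ = circularity(n_area, n_perim)
        n_ecc = float(nprops.eccentricity)
        n_major = float(nprops.axis_major_length) * mpp
        n_minor = max(float(nprops.axis_minor_length) * mpp, 1e-9)
        n_shape_factor = n_major / n_minor
        n_solidity = float(nprops.solidity)
        disp = (
            np.hypot(*(np.array(nprops.centroid) - np.array(props.centroid)))
            / max(math.sqrt(area_px / math.pi), 1.0)
        )
        n_vol = (4.0 / 3.0) * math.pi * (n_major / 2) * (n_minor / 2) ** 2
        chromatin = float((1.0 - gray[nucleus_mask]).mean())
        n_tex_var = float(gray[nucleus_mask].var())
        eroded_n = ndimage.binary_erosion(nucleus_mask)
        _, lobes = ndimage.label(eroded_n)
        lobes = max(int(lobes), 1)
        dil = ndimage.binary_dilation(nucleus_mask, iterations=2) & cell_mask
        shell = dil & ~nucleus_mask
        n_edge_contrast = (
            abs(float(gray[nucleus_mask].mean()) - float(gray[shell].mean()))
            if shell.any()
            else 0.0
        )
    else:
        n_area = n_perim = 0.0
        n_circ = n_ecc = 0.0
        n_shape_factor = n_solidity = 0.0
        disp = n_vol = chromatin = n_tex_var = n_edge_contrast = 0.0
        lobes = 0

    cyt_mask = cell_mask & ~nucleus_mask
    cyt_area = area - n_area
    r_cell = math.sqrt(area / math.pi)
    r_nuc = math.sqrt(n_area / math.pi)
    thickness = max(r_cell - r_nuc, 0.0)
    nc_ratio = n_area / cyt_area if cyt_area > 1e-9 else 0.0

    # symmetry: overlap of the mask with its 180-degree rotation about centroid
    sym = _rotation_symmetry(cell_mask)

    tex = _glcm_stats(gray, cell_mask)
    if cyt_mask.any():
        cyt_tex = _glcm_stats(gray, cyt_mask)
        lap = ndimage.laplace(gray)
        granularity = float(lap[cyt_mask].var())
        cvals = gray[cyt_mask]
        bright = cyt_mask & (gray > cvals.mean() + 2.0 * max(cvals.std(), 1e-9))
        vacuolation = float(bright.sum() / cyt_mask.sum())
        cyt_energy = cyt_tex["energy"]
    else:
        granularity = vacuolation = 0.0
        cyt_energy = 0.0

    gy, gx = np.gradient(gray)
    grad_mag = np.hypot(gx, gy)
    boundary = cell_mask & ~ndimage.binary_erosion(cell_mask)
    edge_gradient = float(grad_mag[boundary].mean()) if boundary.any() else 0.0
    membrane = (
        float((grad_mag[boundary] > 0.05).mean()) if boundary.any() else 0.0
    )
    hull_perim = contour_perimeter(ndimage.binary_fill_holes(props.image_convex))
    # place convex image in full frame for perimeter comparability
    roughness = perim_px / max(hull_perim, 1e-9)

    inc = _inclusion_stats(gray, cell_mask)
    pal = _pallor_stats(gray, cell_mask)
    profile = _radial_profile(gray, cell_mask)
    inversions = count_profile_inversions(profile)

    values = {
        "cell_area": area,
        "cell_perimeter": perim,
        "circularity": circ,
        "eccentricity": ecc,
        "nucleus_area": n_area,
        "nucleus_perimeter": n_perim,
        "nucleus_circularity": n_circ,
        "nucleus_eccentricity": n_ecc,
        "cytoplasm_area": cyt_area,
        "cytoplasm_thickness": thickness,
        "aspect_ratio": major / max(minor, 1e-9),
        "elongation": 1.0 - minor / max(major, 1e-9),
        "compactness": perim**2 / (4.0 * math.pi * area),
        "convex_hull_area": hull_area,
        "solidity": solidity,
        "feret_diameter": feret,
        "min_feret_diameter": min_feret,
        "major_axis_length": major,
        "minor_axis_length": minor,
        "orientation": float(props.orientation),
        "chromatin_density": chromatin,
        "nuclear_shape_factor": n_shape_factor,
        "nuclear_cytoplasmic_ratio": nc_ratio,
        "nuclear_texture_variance": n_tex_var,
        "cell_volume": (4.0 / 3.0) * math.pi * (major / 2) * (minor / 2) ** 2,
        "nuclear_volume": n_vol,
        "symmetry": sym,
        "roundness": 4.0 * area / (math.pi * max(major, 1e-9) ** 2),
        "nuclear_solidity": n_solidity,
        "nuclear_displacement": float(disp),
        "texture_entropy": tex["entropy"],
        "texture_contrast": tex["contrast"],
        "texture_correlation": tex["correlation"],
        "texture_energy": tex["energy"],
        "texture_homogeneity": tex["homogeneity"],
        "edge_gradient": edge_gradient,
        "boundary_roughness": roughness,
        "nuclear_edge_contrast": n_edge_contrast,
        "mean_red": float(image[..., 0][cell_mask].mean()),
        "mean_green": float(image[..., 1][cell_mask].mean()),
        "mean_blue": float(image[..., 2][cell_mask].mean()),
        "mean_hue": float(hsv[..., 0][cell_mask].mean()),
        "mean_saturation": float(hsv[..., 1][cell_mask].mean()),
        "mean_value": float(hsv[..., 2][cell_mask].mean()),
        "granularity_index": granularity,
        "vacuolation_level": vacuolation,
        "inclusion_presence": float(inc["inclusion_count"] > 0),
        "membrane_integrity": membrane,
        "cytoplasmic_granularity": cyt_energy,
        "lobe_count": float(lobes),
    }
    extras = {
        "interior_intensity": float(gray[cell_mask].mean()),
        "radial_inversions": inversions,
        "radial_profile": profile.tolist(),
        **inc,
        **pal,
    }
    return MorphometryVector(values=values, extras=extras)


def _auto_nucleus(image: np.ndarray, cell_mask: np.ndarray) -> np.ndarray:
    """Otsu split of the dominant-stain channel within the cell.

    Nuclei stain dark blue-purple, so the nucleus is the low side of the
    blue-weighted intensity.  Returns all-False when the split is not
    bimodal enough to be credible (anuclear cells).
    """
    from skimage.filters import threshold_otsu

    stain = 1.0 - np.asarray(image)[..., 2]  # blue absorbance
    vals = stain[cell_mask]
    if vals.max() - vals.min() < 0.1:
        return np.zeros_like(cell_mask)
    t = threshold_otsu(vals)
    nucleus = cell_mask & (stain > t)
    hi, lo = vals[vals > t], vals[vals <= t]
    if hi.size == 0 or lo.size == 0 or hi.mean() - lo.mean() < 0.15:
        return np.zeros_like(cell_mask)
    nucleus = ndimage.binary_opening(nucleus)
    return nucleus & cell_mask


def _rotation_symmetry(mask: np.ndarray) -> float:
    props = measure.regionprops(mask.astype(int))[0]
    r0, c0, r1, c1 = props.bbox
    crop = mask[r0:r1, c0:c1]
    rot = crop[::-1, ::-1]
    inter = np.logical_and(crop, rot).sum()
    union = np.logical_or(crop, rot).sum()
    return float(inter / union) if union else 0.0
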
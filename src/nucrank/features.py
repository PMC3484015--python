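"""Feature families for candidate nucleus segmentations.

Four families are computed per candidate: morphological (shape of the
segmentation boundary), texture (intensity statistics inside the
nucleus), FISH (number and layout of the labelled gene spots) and
contextual (layout of the nuclei within the image).  Contextual
features are computed on request but disabled by default: they rank
low in importance, are costly, and depend on whole-image context.

Several features have no single canonical formulation (corner
severity, polar-histogram isotropy, the erosion-profile statistic,
box-counting details); the conventions used here are fixed in
:class:`FeatureConfig` and documented per function.

Missing-value policy: a feature that cannot be computed (e.g. the
spot convex hull with fewer than three spots) is imputed as 0 and a
companion ``<name>_missing`` flag column is set — this keeps the
downstream regression linear and total on all candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, Delaunay, QhullError
from scipy.spatial.distance import pdist
from skimage import draw as skdraw
from skimage import measure as skmeasure

from .core_io import CandidateObject, ImageRecord, SpotRecord, boundary_pixels

log = logging.getLogger("nucrank")


@dataclass
class FeatureConfig:
    """Tunable constants of the under-specified features."""

    pairwise_max_points: int = 256   # contour subsample for O(n^2) bound
    polar_bins: int = 36
    corner_window: int = 2           # 5-point turning-angle window
    corner_angle_deg: float = 60.0
    erosion_area_frac: float = 0.05
    efd_area_tol: float = 0.10
    efd_max_harmonics: int = 20
    entropy_bins: int = 64
    glcm_levels: int = 32
    band_width: int = 5              # annulus for the intensity ratio
    graph_prune_factor: float = 3.0  # x median nucleus diameter
    degenerate_area: int = 9


MORPHOLOGICAL = [
    "area", "perimeter", "perimeter_area_ratio", "solidity",
    "ch_perimeter_ratio", "max_circle_ratio", "eccentricity",
    "ellipse_error_ratio", "length", "width", "mean_pairwise_distance",
    "polar_isotropy", "num_severe_corners", "box_dimension",
    "erosion_profile", "efd_harmonics",
]
TEXTURE = [
    "mean_intensity", "intensity_range", "entropy", "glcm_contrast",
    "glcm_correlation", "glcm_energy", "glcm_homogeneity",
]
FISH = [
    "num_fish", "fish_per_area", "fish_hull_area_ratio", "fish_boundary",
    "mean_fish_distance",
]
CONTEXTUAL = [
    "num_nuclei", "intensity_band_ratio", "betweenness", "num_neighbors",
    "mean_edge_distance",
]
FAMILIES: dict[str, list[str]] = {
    "morphological": MORPHOLOGICAL, "texture": TEXTURE, "fish": FISH,
    "contextual": CONTEXTUAL,
}
ALL_FEATURES = MORPHOLOGICAL + TEXTURE + FISH + CONTEXTUAL

#: features that can be structurally missing (imputed 0 + flag column)
MISSING_CAPABLE = {
    "morphological": ["ellipse_error_ratio", "box_dimension",
                      "efd_harmonics"],
    "texture": [],
    "fish": ["fish_hull_area_ratio", "fish_boundary", "mean_fish_distance"],
    "contextual": ["intensity_band_ratio", "mean_edge_distance"],
}


# ---------------------------------------------------------------------------
# Elliptical Fourier descriptors (Kuhl-Giardina)
# ---------------------------------------------------------------------------

def efd_coefficients(contour_xy: np.ndarray, order: int,
                     ) -> tuple[np.ndarray, float, float]:
    """Elliptical Fourier coefficients of a closed pixel contour.

    ``contour_xy`` is (K, 2) of (x, y); returns (coeffs[order, 4],
    A0, C0) where each row is (a_n, b_n, c_n, d_n) for x resp. y.
    """
    pts = np.asarray(contour_xy, dtype=float)
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T == 0:
        raise ValueError("degenerate contour")
    phi = 2 * np.pi * t / T
    n = np.arange(1, order + 1)[:, None]
    const = T / (2 * n ** 2 * np.pi ** 2)
    cos_d = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    sin_d = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    dx_dt = d[:, 0] / dt
    dy_dt = d[:, 1] / dt
    a = const[:, 0] * (dx_dt * cos_d).sum(axis=1)
    b = const[:, 0] * (dx_dt * sin_d).sum(axis=1)
    c = const[:, 0] * (dy_dt * cos_d).sum(axis=1)
    dd = const[:, 0] * (dy_dt * sin_d).sum(axis=1)
    # DC components
    xi = np.cumsum(d[:, 0]) - d[:, 0] / dt * t[1:]
    delta = np.cumsum(d[:, 1]) - d[:, 1] / dt * t[1:]
    A0 = (1 / T) * ((d[:, 0] / (2 * dt)) * np.diff(t ** 2) +
                    xi * dt).sum() + pts[0, 0]
    C0 = (1 / T) * ((d[:, 1] / (2 * dt)) * np.diff(t ** 2) +
                    delta * dt).sum() + pts[0, 1]
    return np.column_stack([a, b, c, dd]), float(A0), float(C0)


def efd_reconstruct(coeffs: np.ndarray, a0: float, c0: float,
                    n_harmonics: int, n_points: int = 256) -> np.ndarray:
    """Reconstruct (x, y) contour points from the first ``n_harmonics``."""
    phi = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    x = np.full(n_points, a0)
    y = np.full(n_points, c0)
    for k in range(n_harmonics):
        n = k + 1
        a, b, c, d = coeffs[k]
        x = x + a * np.cos(n * phi) + b * np.sin(n * phi)
        y = y + c * np.cos(n * phi) + d * np.sin(n * phi)
    return np.column_stack([x, y])


def _rasterize_polygon(xy: np.ndarray, shape: tuple[int, int],
                       offset: tuple[float, float] = (0.0, 0.0),
                       ) -> np.ndarray:
    rows = xy[:, 1] - offset[0]
    cols = xy[:, 0] - offset[1]
    rr, cc = skdraw.polygon(rows, cols, shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def efd_harmonic_count(obj: CandidateObject, config: FeatureConfig,
                       ) -> tuple[int, bool]:
    """Smallest number of harmonics whose reconstruction matches the mask
    to within the configured symmetric-difference area tolerance;
    returns (count, capped)."""
    contour = obj.contour.astype(float)
    if len(contour) < 4:
        return 0, True
    xy = np.column_stack([contour[:, 1], contour[:, 0]])  # (x, y), global
    coeffs, a0, c0 = efd_coefficients(xy, config.efd_max_harmonics)
    pad = 6
    shape = (obj.mask.shape[0] + 2 * pad, obj.mask.shape[1] + 2 * pad)
    ref = np.zeros(shape, dtype=bool)
    ref[pad:pad + obj.mask.shape[0], pad:pad + obj.mask.shape[1]] = obj.mask
    offset = (obj.offset[0] - pad, obj.offset[1] - pad)
    area = ref.sum()
    for k in range(1, config.efd_max_harmonics + 1):
        rec = efd_reconstruct(coeffs, a0, c0, k)
        ras = _rasterize_polygon(rec, shape, offset)
        sym = np.logical_xor(ras, ref).sum()
        if sym / area <= config.efd_area_tol:
            return k, False
    return config.efd_max_harmonics, True


# ---------------------------------------------------------------------------
# Morphological family
# ---------------------------------------------------------------------------

def chain_perimeter(contour: np.ndarray) -> float:
    """8-connected chain-code boundary length with steps of 1 and sqrt 2."""
    if len(contour) < 2:
        return 1.0
    d = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _moment_ellipse_mask(obj: CandidateObject, props,
                         pad: int = 8) -> tuple[np.ndarray, np.ndarray]:
    h, w = obj.mask.shape
    shape = (h + 2 * pad, w + 2 * pad)
    ref = np.zeros(shape, dtype=bool)
    ref[pad:pad + h, pad:pad + w] = obj.mask
    cy, cx = props.centroid
    rr, cc = skdraw.ellipse(cy + pad, cx + pad,
                            props.axis_major_length / 2,
                            props.axis_minor_length / 2,
                            shape=shape,
                            rotation=-props.orientation - np.pi / 2)
    ell = np.zeros(shape, dtype=bool)
    ell[rr, cc] = True
    return ell, ref


def polar_isotropy(obj: CandidateObject, bins: int) -> float:
    """Coefficient of variation of boundary-point counts over angular
    bins about the centroid (0 = perfectly isotropic)."""
    pts = np.unique(obj.contour, axis=0).astype(float)
    cy = obj.centroid[1]
    cx = obj.centroid[0]
    ang = np.arctan2(pts[:, 0] - cy, pts[:, 1] - cx)
    hist, _ = np.histogram(ang, bins=bins, range=(-np.pi, np.pi))
    m = hist.mean()
    return float(hist.std() / m) if m > 0 else 0.0


def severe_corners(obj: CandidateObject, window: int,
                   angle_deg: float) -> int:
    """Count of strong turns of the contour: turning angle over a
    (2*window+1)-point window above the threshold, with non-maximum
    suppression inside the window."""
    c = obj.contour.astype(float)
    k = len(c)
    if k < 2 * window + 2:
        return 0
    v1 = c - np.roll(c, window, axis=0)
    v2 = np.roll(c, -window, axis=0) - c
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = (v1 * v2).sum(axis=1)
    ang = np.abs(np.degrees(np.arctan2(cross, dot)))
    severe = ang > angle_deg
    order = np.argsort(-ang)
    suppressed = np.zeros(k, dtype=bool)
    count = 0
    for i in order:
        if not severe[i] or suppressed[i]:
            continue
        count += 1
        for d in range(-window, window + 1):
            suppressed[(i + d) % k] = True
    return count


def box_counting_dimension(obj: CandidateObject) -> tuple[float, bool]:
    """Least-squares slope of log N(s) vs log(1/s) over dyadic box sizes
    on the contour point set; (value, missing)."""
    pts = np.unique(obj.contour, axis=0)
    pts = pts - pts.min(axis=0)
    side = int(pts.max() + 1) if pts.size else 1
    sizes = []
    s = 2
    while s <= max(side // 4, 2):
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        return 0.0, True
    counts = []
    for s in sizes:
        boxes = {(int(r // s), int(c // s)) for r, c in pts}
        counts.append(len(boxes))
    slope = np.polyfit(np.log(1.0 / np.array(sizes, dtype=float)),
                       np.log(np.array(counts, dtype=float)), 1)[0]
    return float(slope), False


_DIAMOND = ndimage.generate_binary_structure(2, 1)


def erosion_profile(obj: CandidateObject, area_frac: float) -> int:
    """Maximum, over iterative unit-disk erosions, of the number of
    connected components retaining at least ``area_frac`` of the
    original area — separates dumbbells (narrow necks joining large
    bodies) from compact blobs."""
    mask = np.pad(obj.mask, 1)
    min_area = max(area_frac * mask.sum(), 1.0)
    best = 1
    cur = mask
    while cur.any():
        comps, n = ndimage.label(cur, structure=np.ones((3, 3), bool))
        if n:
            sizes = ndimage.sum_labels(cur, comps,
                                       index=np.arange(1, n + 1))
            best = max(best, int((sizes >= min_area).sum()))
        cur = ndimage.binary_erosion(cur, structure=_DIAMOND)
    return best


def morphological_features(obj: CandidateObject,
                           config: FeatureConfig = FeatureConfig(),
                           ) -> tuple[dict[str, float], dict[str, int]]:
    """All 16 boundary-shape features; returns (values, missing flags)."""
    if obj.area == 0:
        raise ValueError("empty mask")
    vals: dict[str, float] = {}
    flags: dict[str, int] = {k: 0 for k in MISSING_CAPABLE["morphological"]}
    area = float(obj.area)
    perim = chain_perimeter(obj.contour)
    vals["area"] = area
    vals["perimeter"] = perim
    vals["perimeter_area_ratio"] = perim / area

    degenerate = obj.area < config.degenerate_area
    props = skmeasure.regionprops(obj.mask.astype(np.uint8))[0]
    vals["solidity"] = float(props.solidity)
    vals["eccentricity"] = float(props.eccentricity)
    vals["length"] = float(props.axis_major_length)
    vals["width"] = float(props.axis_minor_length)

    bpts = np.argwhere(boundary_pixels(obj.mask)).astype(float)
    try:
        hull = ConvexHull(bpts[:, ::-1])  # (x, y)
        ch_perim = float(hull.area)  # in 2-D, .area is the perimeter
        vals["ch_perimeter_ratio"] = ch_perim / perim
    except (QhullError, IndexError):
        vals["ch_perimeter_ratio"] = 1.0

    r_in = float(ndimage.distance_transform_edt(
        np.pad(obj.mask, 1)).max())
    vals["max_circle_ratio"] = np.pi * r_in ** 2 / area

    if degenerate or props.axis_minor_length <= 0:
        vals["ellipse_error_ratio"] = 0.0
        flags["ellipse_error_ratio"] = 1
    else:
        ell, ref = _moment_ellipse_mask(obj, props)
        vals["ellipse_error_ratio"] = float(
            np.logical_xor(ell, ref).sum() / area)

    contour = obj.contour.astype(float)
    if len(contour) > config.pairwise_max_points:
        idx = np.linspace(0, len(contour) - 1, config.pairwise_max_points,
                          dtype=int)
        contour_sub = contour[idx]
    else:
        contour_sub = contour
    vals["mean_pairwise_distance"] = (
        float(pdist(contour_sub).mean()) if len(contour_sub) > 1 else 0.0)

    vals["polar_isotropy"] = polar_isotropy(obj, config.polar_bins)
    vals["num_severe_corners"] = float(severe_corners(
        obj, config.corner_window, config.corner_angle_deg))
    bdim, miss = box_counting_dimension(obj)
    vals["box_dimension"] = bdim
    flags["box_dimension"] = int(miss)
    vals["erosion_profile"] = float(erosion_profile(
        obj, config.erosion_area_frac))
    if degenerate:
        vals["efd_harmonics"] = 0.0
        flags["efd_harmonics"] = 1
    else:
        k, capped = efd_harmonic_count(obj, config)
        vals["efd_harmonics"] = float(k)
        flags["efd_harmonics"] = int(capped)
    return vals, flags


# ---------------------------------------------------------------------------
# Texture family
# ---------------------------------------------------------------------------

def _glcm(quant: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Symmetric distance-1 co-occurrence matrix averaged over the four
    orientations, restricted to in-mask pixel pairs, normalised."""
    P = np.zeros((levels, levels), dtype=float)
    offsets = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
    h, w = quant.shape
    for dr, dc in offsets:
        r0 = max(0, -dr)
        r1 = h - max(0, dr)
        c0 = max(0, -dc)
        c1 = w - max(0, dc)
        a = quant[r0:r1, c0:c1]
        b = quant[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        np.add.at(P, (a[ok], b[ok]), 1.0)
        np.add.at(P, (b[ok], a[ok]), 1.0)
    s = P.sum()
    return P / s if s > 0 else P


def glcm_statistics(P: np.ndarray) -> dict[str, float]:
    levels = P.shape[0]
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    contrast = float((P * (i - j) ** 2).sum())
    homogeneity = float((P / (1.0 + (i - j) ** 2)).sum())
    energy = float(np.sqrt((P ** 2).sum()))
    mu_i = float((P * i).sum())
    mu_j = float((P * j).sum())
    var_i = float((P * (i - mu_i) ** 2).sum())
    var_j = float((P * (j - mu_j) ** 2).sum())
    if var_i <= 0 or var_j <= 0:
        corr = 1.0  # constant region: perfectly correlated by convention
    else:
        corr = float((P * (i - mu_i) * (j - mu_j)).sum() /
                     np.sqrt(var_i * var_j))
    return {"glcm_contrast": contrast, "glcm_correlation": corr,
            "glcm_energy": energy, "glcm_homogeneity": homogeneity}


def texture_features(obj: CandidateObject, image: ImageRecord,
                     config: FeatureConfig = FeatureConfig(),
                     ) -> tuple[dict[str, float], dict[str, int]]:
    """Intensity statistics inside the mask: mean, range, histogram
    entropy (bits) and GLCM contrast/correlation/energy/homogeneity."""
    r0, c0 = obj.offset
    h, w = obj.mask.shape
    crop = np.asarray(image.grayscale[r0:r0 + h, c0:c0 + w], dtype=float)
    if crop.shape != obj.mask.shape:
        raise ValueError("mask extends beyond the image")
    pix = crop[obj.mask]
    if pix.size == 0:
        raise ValueError("mask selects no image pixels")
    vals: dict[str, float] = {}
    vals["mean_intensity"] = float(pix.mean())
    rng_val = float(pix.max() - pix.min())
    vals["intensity_range"] = rng_val
    if rng_val == 0:
        vals["entropy"] = 0.0
        quant = np.zeros_like(crop, dtype=np.intp)
    else:
        scaled = (pix - pix.min()) / rng_val
        hist, _ = np.histogram(scaled, bins=config.entropy_bins,
                               range=(0, 1))
        p = hist[hist > 0] / pix.size
        vals["entropy"] = float(-(p * np.log2(p)).sum())
        quant = np.clip(((crop - pix.min()) / rng_val *
                         config.glcm_levels).astype(np.intp),
                        0, config.glcm_levels - 1)
    P = _glcm(quant, obj.mask, config.glcm_levels)
    vals.update(glcm_statistics(P))
    return vals, {}


# ---------------------------------------------------------------------------
# FISH family
# ---------------------------------------------------------------------------

def fish_features(obj: CandidateObject, spots: Sequence[SpotRecord],
                  config: FeatureConfig = FeatureConfig(),
                  ) -> tuple[dict[str, float], dict[str, int]]:
    """Spot-count and spot-layout features for the spots assigned to the
    object.  An abnormally large spot count or a spot hull touching the
    contour hints at a multi-nuclear merge."""
    mine = [s for s in spots if s.assigned_object == obj.object_id]
    n = len(mine)
    vals: dict[str, float] = {"num_fish": float(n),
                              "fish_per_area": n / float(obj.area)}
    flags = {k: 0 for k in MISSING_CAPABLE["fish"]}
    pts = np.array([[s.x, s.y] for s in mine], dtype=float)
    if n >= 2:
        vals["mean_fish_distance"] = float(pdist(pts).mean())
    else:
        vals["mean_fish_distance"] = 0.0
        flags["mean_fish_distance"] = 1
    hull_poly = None
    if n >= 3:
        try:
            hull = ConvexHull(pts)
            vals["fish_hull_area_ratio"] = float(hull.volume) / obj.area
            hull_poly = pts[hull.vertices]
        except QhullError:
            pass
    if hull_poly is None:
        vals["fish_hull_area_ratio"] = 0.0
        flags["fish_hull_area_ratio"] = 1
        vals["fish_boundary"] = 0.0
        flags["fish_boundary"] = 1
    else:
        from shapely.geometry import LineString, Polygon
        poly = Polygon(hull_poly)
        contour_xy = np.column_stack(
            [obj.contour[:, 1], obj.contour[:, 0]]).astype(float)
        ring = LineString(np.vstack([contour_xy, contour_xy[:1]]))
        vals["fish_boundary"] = float(poly.intersects(ring))
    return vals, flags


# ---------------------------------------------------------------------------
# Contextual family
# ---------------------------------------------------------------------------

def contextual_features(candidates: Sequence[CandidateObject],
                        image: ImageRecord,
                        config: FeatureConfig = FeatureConfig(),
                        ) -> dict[str, tuple[dict[str, float],
                                             dict[str, int]]]:
    """Per-image layout features on the centroid neighbourhood graph
    (Delaunay triangulation pruned at 3x the median nucleus diameter;
    collinear or tiny layouts fall back to a nearest-chain graph)."""
    import networkx as nx
    if not candidates:
        raise ValueError("need at least one candidate")
    n = len(candidates)
    any_mask = np.zeros(image.shape, dtype=bool)
    for obj in candidates:
        r0, c0 = obj.offset
        h, w = obj.mask.shape
        any_mask[r0:r0 + h, c0:c0 + w] |= obj.mask

    centroids = np.array([[o.centroid[0], o.centroid[1]]
                          for o in candidates])  # (x, y)
    diam = 2.0 * np.sqrt(np.median([o.area for o in candidates]) / np.pi)
    cutoff = config.graph_prune_factor * diam

    G = nx.Graph()
    G.add_nodes_from(range(n))
    edges: set[tuple[int, int]] = set()
    if n >= 3:
        try:
            tri = Delaunay(centroids)
            for simplex in tri.simplices:
                for i in range(3):
                    e = tuple(sorted((simplex[i], simplex[(i + 1) % 3])))
                    edges.add(e)
        except QhullError:
            edges = set()
    if not edges and n >= 2:
        # collinear / too few points: chain along the principal axis
        center = centroids.mean(axis=0)
        X = centroids - center
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        order = np.argsort(X @ vt[0])
        edges = {tuple(sorted((order[i], order[i + 1])))
                 for i in range(n - 1)}
    for i, j in edges:
        dist = float(np.linalg.norm(centroids[i] - centroids[j]))
        if dist <= cutoff:
            G.add_edge(i, j, weight=dist)
    btw = nx.betweenness_centrality(G, normalized=True)

    out = {}
    for i, obj in enumerate(candidates):
        vals: dict[str, float] = {"num_nuclei": float(n)}
        flags = {k: 0 for k in MISSING_CAPABLE["contextual"]}
        full = obj.full_mask(image.shape)
        band = ndimage.binary_dilation(full, iterations=config.band_width)
        band &= ~any_mask
        if band.any():
            inside = float(np.asarray(image.grayscale, float)[full].mean())
            ratio = (float(np.asarray(image.grayscale, float)[band].mean())
                     / inside) if inside > 0 else 0.0
            vals["intensity_band_ratio"] = ratio
        else:
            vals["intensity_band_ratio"] = 0.0
            flags["intensity_band_ratio"] = 1
        vals["betweenness"] = float(btw[i])
        vals["num_neighbors"] = float(G.degree[i])
        incident = [G.edges[e]["weight"] for e in G.edges(i)]
        if incident:
            vals["mean_edge_distance"] = float(np.mean(incident))
        else:
            vals["mean_edge_distance"] = 0.0
            flags["mean_edge_distance"] = 1
        out[obj.object_id] = (vals, flags)
    return out


# ---------------------------------------------------------------------------
# Assembly and importance
# ---------------------------------------------------------------------------

DEFAULT_FAMILIES = ("morphological", "texture", "fish")


def extract_all(candidates_by_image: Mapping[str,
                                             Sequence[CandidateObject]],
                images: Mapping[str, ImageRecord],
                spots: Sequence[SpotRecord] = (),
                families: Sequence[str] = DEFAULT_FAMILIES,
                config: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """One row per candidate with the enabled feature families in fixed
    column order, plus the missing-flag columns."""
    for fam in families:
        if fam not in FAMILIES:
            raise ValueError(f"unknown feature family {fam!r}")
    if "fish" in families and spots is None:
        raise ValueError("fish family requested but no spots supplied")
    spots = list(spots or ())

    rows = []
    for image_id, candidates in candidates_by_image.items():
        if image_id not in images:
            raise ValueError(f"no image record for {image_id}")
        image = images[image_id]
        ctx = (contextual_features(candidates, image, config)
               if "contextual" in families and candidates else {})
        for obj in candidates:
            row: dict[str, float] = {"object_id": obj.object_id}
            flagrow: dict[str, int] = {}
            if "morphological" in families:
                v, f = morphological_features(obj, config)
                row.update(v)
                flagrow.update(f)
            if "texture" in families:
                v, f = texture_features(obj, image, config)
                row.update(v)
                flagrow.update(f)
            if "fish" in families:
                v, f = fish_features(obj, spots, config)
                row.update(v)
                flagrow.update(f)
            if "contextual" in families:
                v, f = ctx[obj.object_id]
                row.update(v)
                flagrow.update(f)
            row.update({f"{k}_missing": int(fv)
                        for k, fv in flagrow.items()})
            rows.append(row)
    cols = ["object_id"]
    for fam in ("morphological", "texture", "fish", "contextual"):
        if fam in families:
            cols.extend(FAMILIES[fam])
    for fam in ("morphological", "texture", "fish", "contextual"):
        if fam in families:
            cols.extend(f"{k}_missing" for k in MISSING_CAPABLE[fam])
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=cols)
    return df[cols]


@dataclass
class ImportanceReport:
    """Out-of-bag permutation importances, ranked (1 = most important)."""

    table: pd.DataFrame   # feature, importance, rank
    method: str
    seed: int
    collinear_pairs: list[tuple[str, str]] = field(default_factory=list)


def feature_importance(X: pd.DataFrame, y: Sequence[float], seed: int = 0,
                       n_trees: int = 100,
                       ) -> ImportanceReport:
    """Random-forest out-of-bag permutation importance.

    For each bootstrap tree, the mean-squared error on its out-of-bag
    rows is compared before and after permuting one feature; the
    importance is the mean error increase across trees.  Deterministic
    given ``seed``.
    """
    from sklearn.tree import DecisionTreeRegressor
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("labels are constant; importance is undefined")
    feats = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    n, m = Xv.shape
    rng = np.random.default_rng(seed)
    deltas = np.zeros((n_trees, m))
    for t in range(n_trees):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0:
            continue
        tree = DecisionTreeRegressor(
            random_state=int(rng.integers(0, 2 ** 31 - 1)),
            max_features="sqrt")
        tree.fit(Xv[idx], y[idx])
        base = np.mean((tree.predict(Xv[oob]) - y[oob]) ** 2)
        for j in range(m):
            Xp = Xv[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            err = np.mean((tree.predict(Xp) - y[oob]) ** 2)
            deltas[t, j] = err - base
    imp = deltas.mean(axis=0)
    order = np.argsort(-imp, kind="stable")
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)
    table = pd.DataFrame({"feature": feats, "importance": imp,
                          "rank": rank}).sort_values("rank")
    collinear = []
    with np.errstate(invalid="ignore"):
        cmat = np.corrcoef(Xv, rowvar=False)
    for a in range(m):
        for b in range(a + 1, m):
            if np.isfinite(cmat[a, b]) and abs(cmat[a, b]) > 0.98:
                collinear.append((feats[a], feats[b]))
    if collinear:
        log.warning("collinear feature pairs detected: %s", collinear)
    return ImportanceReport(table=table.reset_index(drop=True),
                            method="oob-permutation", seed=seed,
                            collinear_pairs=collinear)
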
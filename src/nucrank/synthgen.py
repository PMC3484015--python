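"""Seeded synthetic cohorts of DAPI-like nuclei with candidate
segmentations of controlled quality and FISH spots at a prescribed
radial law.

The generator emulates the failure taxonomy seen in candidate
segmentations of tissue nuclei: well-outlined single nuclei, boundary
jitter, multi-nuclear merges, fragments, border clipping and debris.
Each candidate carries a derived quality label on the reviewer scale
(1 = good, 0.5 = maybe, 0 = reject) plus its IoU against the
generating truth nucleus, so every downstream stage (features, the
logistic ranking, centrality, the repositioning test) is testable
end-to-end without real data.

Nuclei are rough ellipses: a radial function
``r(theta) = ellipse(theta) * (1 + sum_k c_k cos(k theta + phi_k))``
with low-order Fourier perturbations.  FISH spots are placed inside
the truth mask so that their normalised-EDT values follow a
Beta(a, b) law, via inverse-CDF sampling over the discrete pixel nEDT
population (exact at pixel resolution).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from . import core_io
from .core_io import (CandidateObject, ImageRecord, SpotRecord,
                      boundary_pixels, candidate_from_mask)

log = logging.getLogger("nucrank")

MODES = ("good", "jitter", "merge", "fragment", "clip", "debris")

#: derived reviewer label for each perturbation mode; "clip" is split
#: into minor (<= 25% area removed -> maybe) and major (-> reject).
MODE_LABELS = {"good": 1.0, "jitter": 0.5, "merge": 0.0,
               "fragment": 0.0, "clip_minor": 0.5, "clip_major": 0.0,
               "debris": 0.0}

#: IoU bands used as proxies for the reviewer classes ("boundary is
#: almost perfect" vs "minor errors"); no numeric tolerance exists for
#: the manual criteria, so these are package conventions.
GOOD_IOU = 0.9
MAYBE_IOU = 0.7


@dataclass
class SynthesisSpec:
    """Parameters of a synthetic cohort.

    Clutter fractions are per candidate-slot probabilities of each
    perturbation mode; the remainder is "good".  ``spot_radial_law``
    is the Beta(a, b) distribution of spot nEDT values (Beta(2, 2)
    puts spots mid-radially, as interstitial gene loci typically sit).
    """

    n_subjects: int = 4
    cores_per_subject: int = 2
    images_per_core: int = 2
    nuclei_per_image: int = 12
    image_size: int = 256
    nucleus_radius_px: tuple[float, float] = (12.0, 2.5)  # mean, sd
    aspect_range: tuple[float, float] = (1.0, 1.8)
    boundary_roughness: float = 0.08
    jitter_fraction: float = 0.14
    clump_fraction: float = 0.22
    fragment_fraction: float = 0.20
    debris_fraction: float = 0.15
    clip_fraction: float = 0.13
    texture_contrast: float = 0.3
    background_level: float = 20.0
    nucleus_level: float = 120.0
    noise_sd: float = 4.0
    spots_per_nucleus: int = 4
    genes: tuple[str, ...] = ("FRA2", "HES5")
    spot_radial_law: tuple[float, float] = (2.0, 2.0)  # Beta(a, b) on nEDT
    spot_subpixel_jitter: float = 0.0
    pixel_size_um: float = core_io.DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        total = (self.jitter_fraction + self.clump_fraction +
                 self.fragment_fraction + self.debris_fraction +
                 self.clip_fraction)
        if total > 1.0 + 1e-9:
            raise ValueError("clutter fractions must sum to <= 1")
        a, b = self.spot_radial_law
        if not (a > 0 and b > 0):
            raise ValueError("Beta parameters must be positive")

    @property
    def good_fraction(self) -> float:
        return 1.0 - (self.jitter_fraction + self.clump_fraction +
                      self.fragment_fraction + self.debris_fraction +
                      self.clip_fraction)

    def mode_probs(self) -> np.ndarray:
        return np.array([self.good_fraction, self.jitter_fraction,
                         self.clump_fraction, self.fragment_fraction,
                         self.clip_fraction, self.debris_fraction])


def separable_spec(seed: int = 0, **overrides) -> SynthesisSpec:
    """A cohort whose two candidate classes (clean nuclei vs debris)
    form disjoint clusters in feature space — useful for checking that
    the ranking machinery reaches perfect retrieval when the problem is
    trivially separable."""
    kw = dict(n_subjects=2, cores_per_subject=2, images_per_core=4,
              nuclei_per_image=25, jitter_fraction=0.0, clump_fraction=0.0,
              fragment_fraction=0.0, clip_fraction=0.0, debris_fraction=0.5,
              seed=seed)
    kw.update(overrides)
    return SynthesisSpec(**kw)


@dataclass
class GroundTruthRecord:
    object_id: str
    perturbation_mode: str
    derived_label: float
    iou_with_truth: float


# ---------------------------------------------------------------------------
# Nucleus shapes
# ---------------------------------------------------------------------------

@dataclass
class _NucleusShape:
    center: tuple[float, float]   # (row, col)
    axes: tuple[float, float]     # (a, b) semi-axes, a >= b
    phi: float
    fourier: list[tuple[int, float, float]]  # (k, c_k, psi_k)

    def radius(self, theta: np.ndarray) -> np.ndarray:
        a, b = self.axes
        t = theta - self.phi
        r = a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
        mod = np.ones_like(theta)
        for k, c, psi in self.fourier:
            mod += c * np.cos(k * theta + psi)
        return r * np.clip(mod, 0.3, None)

    @property
    def max_radius(self) -> float:
        theta = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        return float(self.radius(theta).max())


def _random_shape(rng: np.random.Generator, center: tuple[float, float],
                  radius: float, aspect_range: tuple[float, float],
                  roughness: float) -> _NucleusShape:
    aspect = rng.uniform(*aspect_range)
    b = radius / np.sqrt(aspect)
    a = radius * np.sqrt(aspect)
    phi = rng.uniform(0, np.pi)
    fourier = [(k, rng.normal(0, roughness / k), rng.uniform(0, 2 * np.pi))
               for k in range(2, 6)]
    return _NucleusShape(center=center, axes=(a, b), phi=phi, fourier=fourier)


def _render_shape(shape: _NucleusShape, grid: tuple[int, int],
                  n_vertices: int = 180) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = shape.radius(theta)
    rows = shape.center[0] + r * np.sin(theta)
    cols = shape.center[1] + r * np.cos(theta)
    rr, cc = skdraw.polygon(rows, cols, shape=grid)
    mask = np.zeros(grid, dtype=bool)
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# Perturbations (candidate segmentations from truth)
# ---------------------------------------------------------------------------

def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter / union) if union else 0.0


def _largest_component(mask: np.ndarray) -> np.ndarray:
    comps, n = ndimage.label(mask, structure=core_io.STRUCT_8)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, comps, index=np.arange(1, n + 1))
    return comps == (1 + int(np.argmax(sizes)))


def _jitter_once(mask: np.ndarray, amp: float, noise: np.ndarray) -> np.ndarray:
    """Perturb a boundary by thresholding signed distance + smooth noise."""
    d_in = ndimage.distance_transform_edt(mask)
    d_out = ndimage.distance_transform_edt(~mask)
    sd = d_in - d_out
    cand = (sd + amp * noise) > 0
    cand = _largest_component(cand)
    cand = ndimage.binary_fill_holes(cand)
    return cand


def _bbox_crop(mask: np.ndarray, pad: int) -> tuple[np.ndarray, tuple]:
    rows, cols = np.nonzero(mask)
    r0 = max(rows.min() - pad, 0)
    r1 = min(rows.max() + pad + 1, mask.shape[0])
    c0 = max(cols.min() - pad, 0)
    c1 = min(cols.max() + pad + 1, mask.shape[1])
    return mask[r0:r1, c0:c1], (r0, r1, c0, c1)


def _embed(local: np.ndarray, box: tuple, shape: tuple) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    r0, r1, c0, c1 = box
    out[r0:r1, c0:c1] = local
    return out


def jittered_mask(truth: np.ndarray, rng: np.random.Generator,
                  iou_band: tuple[float, float],
                  noise_sigma: float = 3.0,
                  max_iter: int = 12) -> np.ndarray:
    """Boundary-jittered copy of ``truth`` whose IoU with it falls in
    ``iou_band``, found by bisection on the jitter amplitude against a
    fixed smooth noise field."""
    local, box = _bbox_crop(truth, pad=10)
    noise = ndimage.gaussian_filter(rng.standard_normal(local.shape),
                                    noise_sigma)
    noise /= noise.std() + 1e-12
    lo, hi = 0.05, 8.0
    best = local
    target_lo, target_hi = iou_band
    for _ in range(max_iter):
        amp = 0.5 * (lo + hi)
        cand = _jitter_once(local, amp, noise)
        if cand.sum() == 0:
            hi = amp
            continue
        v = _iou(local, cand)
        best = cand
        if v < target_lo:        # too much jitter
            hi = amp
        elif v >= target_hi:     # too little
            lo = amp
        else:
            break
    return _embed(best, box, truth.shape)


def jitter_fixed_amplitude(truth: np.ndarray, rng: np.random.Generator,
                           amp: float, noise_sigma: float = 3.0,
                           ) -> np.ndarray:
    """Boundary jitter of a fixed amplitude in pixels (the typical
    boundary displacement), without targeting an IoU band."""
    local, box = _bbox_crop(truth, pad=int(np.ceil(amp)) + 8)
    noise = ndimage.gaussian_filter(rng.standard_normal(local.shape),
                                    noise_sigma)
    noise /= noise.std() + 1e-12
    return _embed(_jitter_once(local, amp, noise), box, truth.shape)


def boundary_stability_experiment(n_spots: int = 1000,
                                  nucleus_radius: float = 40.0,
                                  jitter_px: float = 2.0,
                                  spots_per_nucleus: int = 6,
                                  radial_law: tuple[float, float] = (2.0, 2.0),
                                  seed: int = 0):
    """Matched centrality measurements from reference vs boundary-
    jittered masks.

    Rough-ellipse nuclei are generated, each boundary perturbed by
    ``jitter_px`` of smooth jitter, and the same spots are measured
    against both outlines.  Returns two lists of
    :class:`~nucrank.centrality.CentralityResult` matched by spot id,
    ready for :func:`~nucrank.centrality.stability_compare`.
    """
    from . import centrality as ctr
    rng = np.random.default_rng(seed)
    ref: list = []
    pert: list = []
    k = 0
    side = int(2 * nucleus_radius * 1.6) + 10
    a, b = radial_law
    while len(ref) < n_spots:
        k += 1
        shape = _random_shape(rng, (side / 2, side / 2), nucleus_radius,
                              (1.0, 1.8), 0.08)
        truth = _render_shape(shape, (side, side))
        jit = jitter_fixed_amplitude(truth, rng, jitter_px)
        pts = sample_spot_positions(truth, spots_per_nucleus, a, b, rng)
        ot = candidate_from_mask(truth, f"o{k}", "img")
        op = candidate_from_mask(jit, f"o{k}", "img")
        ft, fp = ctr.edt_map(ot), ctr.edt_map(op)
        for j, (x, y) in enumerate(pts):
            sid = f"s{k}_{j}"
            try:
                ra = ctr.CentralityResult(sid, ot.object_id, "gene",
                                          ctr.edt_at(ft, x, y),
                                          ctr.nedt_at(ft, x, y),
                                          ctr.cedt_at(ft, x, y))
                rb = ctr.CentralityResult(sid, op.object_id, "gene",
                                          ctr.edt_at(fp, x, y),
                                          ctr.nedt_at(fp, x, y),
                                          ctr.cedt_at(fp, x, y))
            except ValueError:  # spot fell outside the jittered outline
                continue
            ref.append(ra)
            pert.append(rb)
            if len(ref) >= n_spots:
                break
    return ref, pert


def clipped_mask(truth: np.ndarray, rng: np.random.Generator,
                 frac: float) -> np.ndarray:
    """Remove the ``frac`` of the mask beyond a half-plane cut, as when a
    nucleus is truncated by the image-border strip."""
    rows, cols = np.nonzero(truth)
    angle = rng.uniform(0, 2 * np.pi)
    u = np.array([np.sin(angle), np.cos(angle)])
    proj = rows * u[0] + cols * u[1]
    thr = np.quantile(proj, 1.0 - frac)
    keep = truth.copy()
    keep[rows[proj > thr], cols[proj > thr]] = False
    keep = _largest_component(keep)
    return keep


def fragmented_masks(truth: np.ndarray, rng: np.random.Generator,
                     cut_halfwidth: float = 1.0,
                     angle: float | None = None,
                     ) -> list[np.ndarray]:
    """Split a nucleus by a straight cut through its centroid; returns
    one mask per resulting piece (pieces of < 5 px are dropped)."""
    rows, cols = np.nonzero(truth)
    cy, cx = rows.mean(), cols.mean()
    if angle is None:
        angle = rng.uniform(0, np.pi)
    n = np.array([np.sin(angle), np.cos(angle)])  # cut normal
    d = (rows - cy) * n[0] + (cols - cx) * n[1]
    keep = truth.copy()
    keep[rows[np.abs(d) <= cut_halfwidth], cols[np.abs(d) <= cut_halfwidth]] \
        = False
    comps, ncomp = ndimage.label(keep, structure=core_io.STRUCT_8)
    out = []
    for k in range(1, ncomp + 1):
        piece = comps == k
        if piece.sum() >= 5:
            out.append(piece)
    return out or [truth.copy()]


def merged_mask(a: np.ndarray, b: np.ndarray,
                centroid_a: tuple[float, float],
                centroid_b: tuple[float, float]) -> np.ndarray:
    """Union of two adjacent nuclei bridged into a single component, as a
    watershed under-segmentation would produce."""
    out = np.logical_or(a, b)
    rr, cc = skdraw.line(int(round(centroid_a[0])), int(round(centroid_a[1])),
                         int(round(centroid_b[0])), int(round(centroid_b[1])))
    bridge = np.zeros_like(out)
    bridge[rr, cc] = True
    out |= ndimage.binary_dilation(bridge, iterations=2)
    return _largest_component(out)


def debris_mask(rng: np.random.Generator, grid: tuple[int, int],
                center: tuple[float, float], radius: float) -> np.ndarray:
    """Small, rough non-nuclear blob."""
    shape = _random_shape(rng, center, radius, aspect_range=(1.0, 2.5),
                          roughness=0.35)
    return _render_shape(shape, grid)


# ---------------------------------------------------------------------------
# Spot placement
# ---------------------------------------------------------------------------

def mask_nedt_population(mask: np.ndarray,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """nEDT value of every mask pixel plus the pixel coordinates,
    using boundary-pixel centers as the zero set."""
    boundary = boundary_pixels(mask)
    dist = ndimage.distance_transform_edt(~boundary)
    rows, cols = np.nonzero(mask)
    vals = dist[rows, cols]
    mx = vals.max()
    nedt = 1.0 - vals / mx if mx > 0 else np.ones_like(vals)
    return nedt, rows, cols


def sample_spot_positions(mask: np.ndarray, n: int, beta_a: float,
                          beta_b: float, rng: np.random.Generator,
                          subpixel_jitter: float = 0.0,
                          ) -> np.ndarray:
    """Sample ``n`` points inside ``mask`` whose nEDT values follow
    Beta(a, b), by inverse-CDF over the sorted pixel nEDT population.

    Returns an ``(n, 2)`` array of (x, y).  ``subpixel_jitter`` adds a
    uniform offset within +/- that many pixels (kept < 0.5 so the
    rounded pixel, and hence mask membership, is unchanged).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.empty((0, 2))
    if mask.sum() == 0:
        raise ValueError("cannot place spots in an empty mask")
    nedt, rows, cols = mask_nedt_population(mask)
    order = np.argsort(nedt, kind="stable")
    u = rng.beta(beta_a, beta_b, size=n)
    idx = order[np.clip((u * order.size).astype(int), 0, order.size - 1)]
    x = cols[idx].astype(float)
    y = rows[idx].astype(float)
    if subpixel_jitter > 0:
        j = min(subpixel_jitter, 0.49)
        x = x + rng.uniform(-j, j, size=n)
        y = y + rng.uniform(-j, j, size=n)
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# Image and cohort generation
# ---------------------------------------------------------------------------

@dataclass
class ImageBundle:
    """Everything generated for one synthetic image."""

    image: ImageRecord
    truth_mask: np.ndarray
    candidate_mask: np.ndarray
    truth_objects: list[CandidateObject]
    candidates: list[CandidateObject]
    spots: list[SpotRecord]
    truth_records: list[GroundTruthRecord]


def _place_nuclei(spec: SynthesisSpec, modes: list[str],
                  rng: np.random.Generator) -> list[_NucleusShape]:
    """Place nucleus centers with separation; merge-designated nuclei are
    placed in adjacent pairs so a union candidate is geometrically
    plausible."""
    size = spec.image_size
    mu, sd = spec.nucleus_radius_px
    placed: list[tuple[_NucleusShape, float]] = []
    shapes: list[_NucleusShape | None] = [None] * len(modes)
    margin = 4.0

    def fits(center, radius, slack=margin):
        r, c = center
        lim = radius + 2
        if not (lim <= r <= size - 1 - lim and lim <= c <= size - 1 - lim):
            return False
        for s, rad in placed:
            dr = s.center[0] - r
            dc = s.center[1] - c
            if np.hypot(dr, dc) < radius + rad + slack:
                return False
        return True

    i = 0
    order = list(range(len(modes)))
    while i < len(order):
        idx = order[i]
        radius = float(np.clip(rng.normal(mu, sd), 5.0, mu + 3 * sd))
        pair_partner = None
        if modes[idx] == "merge":
            # find the next merge slot to pair with
            for j in order[i + 1:]:
                if modes[j] == "merge" and shapes[j] is None:
                    pair_partner = j
                    break
            if pair_partner is None:
                log.warning("merge requested without an adjacent partner; "
                            "falling back to good")
                modes[idx] = "good"
        ok = False
        for _ in range(300):
            center = (rng.uniform(0, size - 1), rng.uniform(0, size - 1))
            if fits(center, radius):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "could not place nuclei without excess overlap; reduce "
                "nuclei_per_image or the nucleus radius")
        shape = _random_shape(rng, center, radius, spec.aspect_range,
                              spec.boundary_roughness)
        shapes[idx] = shape
        placed.append((shape, shape.max_radius))
        if pair_partner is not None:
            rad2 = float(np.clip(rng.normal(mu, sd), 5.0, mu + 3 * sd))
            ok2 = False
            for _ in range(300):
                ang = rng.uniform(0, 2 * np.pi)
                gap = shape.max_radius + rad2 + 3.0
                center2 = (center[0] + gap * np.sin(ang),
                           center[1] + gap * np.cos(ang))
                if fits(center2, rad2, slack=-2.0):
                    ok2 = True
                    break
            if not ok2:
                log.warning("could not place merge partner; falling back "
                            "to good")
                modes[idx] = "good"
                modes[pair_partner] = "good"
            else:
                shape2 = _random_shape(rng, center2, rad2, spec.aspect_range,
                                       spec.boundary_roughness)
                shapes[pair_partner] = shape2
                placed.append((shape2, shape2.max_radius))
                order.remove(pair_partner)
                order.insert(i + 1, pair_partner)
                i += 1  # partner handled
        i += 1
    return shapes  # type: ignore[return-value]


def generate_image(spec: SynthesisSpec, image_id: str, subject_id: str,
                   core_id: str, rng: np.random.Generator) -> ImageBundle:
    """Render one synthetic image with its truth mask, candidate mask,
    spots and derived quality labels."""
    size = spec.image_size
    grid = (size, size)
    n = spec.nuclei_per_image
    modes = list(np.array(MODES)[rng.choice(len(MODES), size=n,
                                            p=spec.mode_probs())])
    shapes = _place_nuclei(spec, modes, rng)

    truth_mask = np.zeros(grid, dtype=np.int32)
    truth_nuclei: list[np.ndarray] = []
    for j, shape in enumerate(shapes):
        m = _render_shape(shape, grid)
        m &= truth_mask == 0
        truth_mask[m] = j + 1
        truth_nuclei.append(m)

    # --- candidate masks with provenance -----------------------------
    cand_masks: list[tuple[np.ndarray, str, float, float]] = []
    consumed = [False] * n
    merge_pairs: list[tuple[int, int]] = []
    pend = [j for j in range(n) if modes[j] == "merge"]
    while len(pend) >= 2:
        merge_pairs.append((pend.pop(0), pend.pop(0)))
    for j in pend:  # unpaired leftovers
        modes[j] = "good"

    for j, mode in enumerate(modes):
        if consumed[j]:
            continue
        truth = truth_nuclei[j]
        if truth.sum() < 20:
            mode = "good"
        if mode == "good":
            cand = jittered_mask(truth, rng, (0.93, 0.995))
            cand_masks.append((cand, "good", MODE_LABELS["good"],
                               _iou(truth, cand)))
        elif mode == "jitter":
            cand = jittered_mask(truth, rng, (0.72, 0.88))
            cand_masks.append((cand, "jitter", MODE_LABELS["jitter"],
                               _iou(truth, cand)))
        elif mode == "merge":
            pair = next((p for p in merge_pairs if j in p), None)
            if pair is None:
                cand = jittered_mask(truth, rng, (0.93, 0.995))
                cand_masks.append((cand, "good", 1.0, _iou(truth, cand)))
                continue
            a, b = pair
            consumed[a] = consumed[b] = True
            cand = merged_mask(truth_nuclei[a], truth_nuclei[b],
                               shapes[a].center, shapes[b].center)
            iou = max(_iou(truth_nuclei[a], cand),
                      _iou(truth_nuclei[b], cand))
            cand_masks.append((cand, "merge", MODE_LABELS["merge"], iou))
        elif mode == "fragment":
            for piece in fragmented_masks(truth, rng):
                cand_masks.append((piece, "fragment",
                                   MODE_LABELS["fragment"],
                                   _iou(truth, piece)))
        elif mode == "clip":
            frac = float(rng.uniform(0.08, 0.5))
            cand = clipped_mask(truth, rng, frac)
            key = "clip_minor" if frac <= 0.25 else "clip_major"
            cand_masks.append((cand, "clip", MODE_LABELS[key],
                               _iou(truth, cand)))
        elif mode == "debris":
            mu = spec.nucleus_radius_px[0]
            radius = float(rng.uniform(0.25, 0.5) * mu)
            placed = False
            for _ in range(200):
                center = (rng.uniform(radius + 2, size - radius - 3),
                          rng.uniform(radius + 2, size - radius - 3))
                deb = debris_mask(rng, grid, center, radius)
                if deb.sum() and not np.any(deb & (truth_mask > 0)) and \
                        not any(np.any(deb & m) for m, *_ in cand_masks):
                    placed = True
                    break
            if placed:
                cand_masks.append((deb, "debris", MODE_LABELS["debris"], 0.0))

    # --- rasterise ----------------------------------------------------
    candidate_mask = np.zeros(grid, dtype=np.int32)
    candidates: list[CandidateObject] = []
    records: list[GroundTruthRecord] = []
    k = 0
    for cand, mode, label, iou in cand_masks:
        cand = cand & (candidate_mask == 0)  # later candidates never steal
        cand = _largest_component(cand)
        if cand.sum() < 5:
            continue
        k += 1
        oid = f"{image_id}:c{k}"
        candidate_mask[cand] = k
        candidates.append(candidate_from_mask(cand, oid, image_id))
        records.append(GroundTruthRecord(oid, mode, label,
                                         float(np.clip(iou, 0, 1))))

    truth_objects = [candidate_from_mask(m, f"{image_id}:t{j + 1}", image_id)
                     for j, m in enumerate(truth_nuclei) if m.sum() >= 5]

    # --- intensity image ----------------------------------------------
    img = spec.background_level + spec.noise_sd * rng.standard_normal(grid)
    chroma = ndimage.gaussian_filter(rng.standard_normal(grid), 2.0)
    chroma /= np.abs(chroma).max() + 1e-12
    body = truth_mask > 0
    img[body] = (spec.nucleus_level *
                 (1.0 + spec.texture_contrast * chroma[body]))
    for cand, mode, *_ in cand_masks:
        if mode == "debris":
            img[cand] = (0.6 * spec.nucleus_level *
                         (1.0 + spec.texture_contrast * chroma[cand]))
    img = np.clip(img, 0, 65535).astype(np.uint16)
    image = ImageRecord(image_id=image_id, subject_id=subject_id,
                        core_id=core_id, grayscale=img,
                        pixel_size_um=spec.pixel_size_um)

    # --- spots ---------------------------------------------------------
    a, b = spec.spot_radial_law
    spots: list[SpotRecord] = []
    sid = 0
    per_gene = max(spec.spots_per_nucleus // max(len(spec.genes), 1), 1)
    for j, m in enumerate(truth_nuclei):
        if m.sum() < 5:
            continue
        for gene in spec.genes:
            pts = sample_spot_positions(m, per_gene, a, b, rng,
                                        spec.spot_subpixel_jitter)
            for x, y in pts:
                sid += 1
                spots.append(SpotRecord(f"{image_id}:s{sid}", image_id,
                                        float(x), float(y), gene))
    spots = core_io.assign_spots(spots, candidates, image_shape=grid)

    return ImageBundle(image=image, truth_mask=truth_mask,
                       candidate_mask=candidate_mask,
                       truth_objects=truth_objects, candidates=candidates,
                       spots=spots, truth_records=records)


@dataclass
class Cohort:
    """An in-memory synthetic cohort (subject -> core -> image tree)."""

    spec: SynthesisSpec
    bundles: list[ImageBundle]

    @property
    def truth_records(self) -> list[GroundTruthRecord]:
        return [r for b in self.bundles for r in b.truth_records]

    def all_candidates(self) -> list[CandidateObject]:
        return [c for b in self.bundles for c in b.candidates]

    def candidates_by_image(self) -> dict[str, list[CandidateObject]]:
        return {b.image.image_id: b.candidates for b in self.bundles}

    def images_by_id(self) -> dict[str, ImageRecord]:
        return {b.image.image_id: b.image for b in self.bundles}

    def assigned_spots(self) -> list[SpotRecord]:
        return [s for b in self.bundles for s in b.spots]

    def truth_assigned_spots(self) -> list[SpotRecord]:
        """Spots re-assigned to the truth objects (for stability and
        oracle experiments)."""
        out = []
        for b in self.bundles:
            out.extend(core_io.assign_spots(
                [SpotRecord(s.spot_id, s.image_ref, s.x, s.y, s.gene)
                 for s in b.spots],
                b.truth_objects, image_shape=b.image.shape))
        return out

    def provenance(self) -> pd.DataFrame:
        rows = []
        for b in self.bundles:
            for c in b.candidates:
                rows.append({"object_id": c.object_id,
                             "image_id": b.image.image_id,
                             "core_id": b.image.core_id,
                             "subject_id": b.image.subject_id})
        return pd.DataFrame(rows)

    def labels(self) -> pd.Series:
        return pd.Series({r.object_id: r.derived_label
                          for r in self.truth_records})

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"subject_id": b.image.subject_id, "core_id": b.image.core_id,
              "image_id": b.image.image_id,
              "n_truth": len(b.truth_objects),
              "n_candidates": len(b.candidates),
              "n_spots": len(b.spots)} for b in self.bundles])

    def manifest_hash(self) -> str:
        return hashlib.sha256(
            self.manifest().to_csv(index=False).encode()).hexdigest()


def generate_cohort(spec: SynthesisSpec) -> Cohort:
    """Generate the full cohort tree deterministically from
    ``spec.seed``."""
    root = np.random.SeedSequence(spec.seed)
    bundles = []
    n_images = (spec.n_subjects * spec.cores_per_subject *
                spec.images_per_core)
    children = root.spawn(n_images)
    idx = 0
    for s in range(1, spec.n_subjects + 1):
        for c in range(1, spec.cores_per_subject + 1):
            for i in range(1, spec.images_per_core + 1):
                rng = np.random.default_rng(children[idx])
                idx += 1
                image_id = f"S{s:02d}C{c:02d}I{i:02d}"
                bundles.append(generate_image(
                    spec, image_id, f"S{s:02d}", f"S{s:02d}C{c:02d}", rng))
    return Cohort(spec=spec, bundles=bundles)


def write_cohort(cohort: Cohort, out_dir: str | Path,
                 overwrite: bool = False) -> Path:
    """Write the cohort as a subject/core/image tree with TIFF images and
    masks, per-image spot CSVs, plus truth_labels.csv and manifest.csv."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; pass "
                              "overwrite=True to replace it")
    out.mkdir(parents=True, exist_ok=True)
    for b in cohort.bundles:
        img = b.image
        d = out / img.subject_id / img.core_id
        d.mkdir(parents=True, exist_ok=True)
        core_io.write_image(d / f"{img.image_id}.tif", img.grayscale)
        core_io.write_image(d / f"{img.image_id}_truth.tif",
                            b.truth_mask.astype(np.uint16))
        core_io.write_image(d / f"{img.image_id}_cand.tif",
                            b.candidate_mask.astype(np.uint16))
        core_io.write_spots(d / f"{img.image_id}_spots.csv", b.spots)
    pd.DataFrame([asdict(r) for r in cohort.truth_records]).to_csv(
        out / "truth_labels.csv", index=False)
    cohort.manifest().to_csv(out / "manifest.csv", index=False)
    return out
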
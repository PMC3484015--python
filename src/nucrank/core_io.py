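"""Core data types and I/O for ranked retrieval of segmented nuclei.

Conventions used throughout the package:

* Image arrays are indexed ``[row, col]``; all *point* quantities (spot
  coordinates, centroids) are ``(x, y)`` with ``x = column`` and
  ``y = row``, 0-based, pixel centers at integer coordinates.
* Label masks are unsigned-integer grids with 0 = background.
* Candidate objects use 8-connectivity; a label whose pixels form more
  than one 8-connected component is split into several candidates.
* A *boundary pixel* is a mask pixel with at least one background pixel
  (or the image border) among its 8 neighbours.  Boundary pixels belong
  to the object and carry an Euclidean distance transform value of zero.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

log = logging.getLogger("nucrank")

#: 3x3 structuring element giving 8-connectivity.
STRUCT_8 = np.ones((3, 3), dtype=bool)

#: Reviewer labels allowed for a candidate segmentation:
#: 1 = good (usable), 0.5 = maybe, 0 = reject.
VALID_LABELS = (0.0, 0.5, 1.0)

#: Physical pixel pitch of the acquisition this package targets, in
#: micrometres per pixel.  Only affects absolute (µm) distances, never
#: the normalised radial measures.
DEFAULT_PIXEL_SIZE_UM = 0.074


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageRecord:
    """A single grayscale nuclear-channel image with cohort provenance."""

    image_id: str
    subject_id: str
    core_id: str
    grayscale: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.grayscale = np.asarray(self.grayscale)
        if self.grayscale.ndim != 2 or min(self.grayscale.shape) == 0:
            raise ValueError("grayscale must be a non-empty 2-D array")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grayscale.shape


@dataclass
class CandidateObject:
    """One candidate nucleus segmentation.

    ``mask`` is a boolean array cropped to the object's bounding box;
    ``offset`` is the (row, col) of the bounding box origin in the image.
    ``contour`` is the ordered Moore trace of boundary pixels, stored as
    an ``(K, 2)`` integer array of (row, col) in *image* coordinates.
    """

    object_id: str
    image_ref: str
    mask: np.ndarray
    offset: tuple[int, int]
    contour: np.ndarray
    centroid: tuple[float, float]  # (x, y)
    touches_edge: bool = False

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Paint the object into a full-size boolean image."""
        out = np.zeros(shape, dtype=bool)
        r0, c0 = self.offset
        h, w = self.mask.shape
        out[r0:r0 + h, c0:c0 + w] = self.mask
        return out

    def contains_point(self, x: float, y: float) -> bool:
        """Membership of a (possibly sub-pixel) point, decided on the
        nearest-integer pixel."""
        r = int(np.floor(y + 0.5)) - self.offset[0]
        c = int(np.floor(x + 0.5)) - self.offset[1]
        if r < 0 or c < 0 or r >= self.mask.shape[0] or c >= self.mask.shape[1]:
            return False
        return bool(self.mask[r, c])


@dataclass
class SpotRecord:
    """A FISH spot: a sub-pixel point labelled with its gene."""

    spot_id: str
    image_ref: str
    x: float
    y: float
    gene: str
    assigned_object: str | None = None


@dataclass
class AnnotationRecord:
    object_id: str
    reviewer_id: str
    label: float

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(
                f"label must be one of {VALID_LABELS}, got {self.label!r}")


@dataclass
class AggregateLabel:
    """Mean of the reviewer labels for one object, in [0, 1]."""

    object_id: str
    value: float
    n_reviewers: int


# ---------------------------------------------------------------------------
# Boundary extraction
# ---------------------------------------------------------------------------

def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Boolean image of mask pixels having >=1 background 8-neighbour.

    Pixels on the image border count as adjacent to background.
    """
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=STRUCT_8, border_value=0)
    return mask & ~interior


# Moore neighbourhood in clockwise order starting due north.
_MOORE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_MOORE_INDEX = {d: i for i, d in enumerate(_MOORE)}


def trace_contour(mask: np.ndarray) -> np.ndarray:
    """Ordered Moore-neighbour boundary trace of a single 8-connected object.

    Returns an ``(K, 2)`` integer array of (row, col).  One-pixel-wide
    arms are traversed in both directions, so pixels may repeat; the
    trace is a closed loop (last point is 8-adjacent to the first).
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("cannot trace an empty mask")
    if rows.size == 1:
        return np.array([[rows[0], cols[0]]], dtype=int)

    h, w = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    start = (int(rows[0]), int(cols[0]))  # raster-first pixel; west is bg
    trace = [start]
    cur = start
    backtrack = (start[0], start[1] - 1)
    start_backtrack = backtrack
    max_steps = 4 * int(mask.sum()) + 8
    for _ in range(max_steps):
        # search the Moore neighbourhood clockwise, starting just after
        # the backtrack position
        bdir = (backtrack[0] - cur[0], backtrack[1] - cur[1])
        k0 = _MOORE_INDEX[bdir]
        nxt = None
        prev = backtrack
        for j in range(1, 9):
            d = _MOORE[(k0 + j) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if fg(*cand):
                nxt = cand
                break
            prev = cand
        if nxt is None:  # isolated pixel (cannot happen for size > 1)
            break
        cur, backtrack = nxt, prev
        if cur == start and backtrack == start_backtrack:
            break
        trace.append(cur)
    return np.asarray(trace, dtype=int)


# ---------------------------------------------------------------------------
# Candidate construction
# ---------------------------------------------------------------------------

def load_candidates(label_mask: np.ndarray,
                    image: ImageRecord) -> list[CandidateObject]:
    """Build one :class:`CandidateObject` per 8-connected component of each
    non-zero label.

    Labels whose pixels split into several components yield several
    candidates with ``.1``, ``.2`` ... suffixed ids.  Objects touching
    the image border are retained and flagged.
    """
    label_mask = np.asarray(label_mask)
    if not np.issubdtype(label_mask.dtype, np.integer):
        if np.issubdtype(label_mask.dtype, np.floating) and \
                np.all(label_mask == np.round(label_mask)):
            label_mask = label_mask.astype(np.int64)
        else:
            raise ValueError("label mask must be an integer array")
    if label_mask.shape != image.shape:
        raise ValueError("label mask shape does not match image")
    if np.any(label_mask < 0):
        raise ValueError("labels must be non-negative")

    labels = np.unique(label_mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        log.warning("label mask for %s is empty", image.image_id)
        return []

    out: list[CandidateObject] = []
    for lab in labels:
        blob = label_mask == lab
        comps, n_comp = ndimage.label(blob, structure=STRUCT_8)
        for k in range(1, n_comp + 1):
            comp = comps == k
            oid = f"{image.image_id}:{int(lab)}"
            if n_comp > 1:
                oid = f"{oid}.{k}"
            out.append(_make_candidate(comp, oid, image))
    return out


def candidate_from_mask(mask: np.ndarray, object_id: str,
                        image_id: str) -> CandidateObject:
    """Build a candidate from a full-size boolean mask (largest component
    kept if disconnected)."""
    mask = np.asarray(mask, dtype=bool)
    comps, n = ndimage.label(mask, structure=STRUCT_8)
    if n == 0:
        raise ValueError("empty mask")
    if n > 1:
        sizes = ndimage.sum_labels(mask, comps, index=np.arange(1, n + 1))
        mask = comps == (1 + int(np.argmax(sizes)))

    class _Img:  # minimal stand-in carrying id and shape
        image_id = ""
        shape = mask.shape
    img = _Img()
    img.image_id = image_id
    return _make_candidate(mask, object_id, img)


def _make_candidate(comp: np.ndarray, object_id: str,
                    image) -> CandidateObject:
    rows, cols = np.nonzero(comp)
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    local = comp[r0:r1 + 1, c0:c1 + 1]
    contour_local = trace_contour(local)
    contour = contour_local + np.array([r0, c0])
    h, w = image.shape
    touches = bool(r0 == 0 or c0 == 0 or r1 == h - 1 or c1 == w - 1)
    centroid = (float(cols.mean()), float(rows.mean()))
    return CandidateObject(object_id=object_id, image_ref=image.image_id,
                           mask=local, offset=(int(r0), int(c0)),
                           contour=contour, centroid=centroid,
                           touches_edge=touches)


def render_label_mask(candidates: Sequence[CandidateObject],
                      shape: tuple[int, int]) -> np.ndarray:
    """Paint candidates into an integer label grid (1-based, in list order)."""
    out = np.zeros(shape, dtype=np.int32)
    for i, obj in enumerate(candidates, start=1):
        r0, c0 = obj.offset
        h, w = obj.mask.shape
        view = out[r0:r0 + h, c0:c0 + w]
        view[obj.mask] = i
    return out


# ---------------------------------------------------------------------------
# Spot assignment and annotation aggregation
# ---------------------------------------------------------------------------

def assign_spots(spots: Iterable[SpotRecord],
                 candidates: Sequence[CandidateObject],
                 image_shape: tuple[int, int] | None = None,
                 ) -> list[SpotRecord]:
    """Assign each spot to the candidate whose mask contains its rounded
    pixel; spots in background stay unassigned, spots out of bounds are
    dropped with a warning."""
    out: list[SpotRecord] = []
    by_image: dict[str, list[CandidateObject]] = {}
    for obj in candidates:
        by_image.setdefault(obj.image_ref, []).append(obj)
    for spot in spots:
        if image_shape is not None:
            h, w = image_shape
            if not (0 <= spot.x <= w - 1 and 0 <= spot.y <= h - 1):
                log.warning("spot %s out of image bounds; dropped",
                            spot.spot_id)
                continue
        assigned = None
        for obj in by_image.get(spot.image_ref, ()):
            if obj.contains_point(spot.x, spot.y):
                assigned = obj.object_id
                break
        out.append(SpotRecord(spot.spot_id, spot.image_ref, spot.x, spot.y,
                              spot.gene, assigned))
    return out


def aggregate_annotations(records: Iterable[AnnotationRecord],
                          ) -> list[AggregateLabel]:
    """Average the reviewer labels per object into a fractional target."""
    grouped: dict[str, list[float]] = {}
    for rec in records:
        if rec.label not in VALID_LABELS:
            raise ValueError(f"invalid label {rec.label!r} for "
                             f"object {rec.object_id}")
        grouped.setdefault(rec.object_id, []).append(rec.label)
    return [AggregateLabel(oid, float(np.mean(vals)), len(vals))
            for oid, vals in grouped.items()]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        return tifffile.imread(path)
    import imageio.v3 as iio
    return iio.imread(path)


def write_image(path: str | Path, array: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, array)
    else:
        import imageio.v3 as iio
        iio.imwrite(path, array)


def read_spots(path: str | Path) -> list[SpotRecord]:
    df = pd.read_csv(path)
    required = {"image_id", "x", "y", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spot table missing columns: {sorted(missing)}")
    spots = []
    for i, row in df.iterrows():
        sid = str(row["spot_id"]) if "spot_id" in df.columns else f"spot{i}"
        spots.append(SpotRecord(sid, str(row["image_id"]), float(row["x"]),
                                float(row["y"]), str(row["gene"])))
    return spots


def write_spots(path: str | Path, spots: Sequence[SpotRecord]) -> None:
    pd.DataFrame(
        {"spot_id": [s.spot_id for s in spots],
         "image_id": [s.image_ref for s in spots],
         "x": [s.x for s in spots],
         "y": [s.y for s in spots],
         "gene": [s.gene for s in spots],
         "assigned_object": [s.assigned_object for s in spots]},
    ).to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    df = pd.read_csv(path)
    required = {"object_id", "reviewer_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: "
                         f"{sorted(missing)}")
    return [AnnotationRecord(str(r["object_id"]), str(r["reviewer_id"]),
                             float(r["label"])) for _, r in df.iterrows()]


def write_model_json(path: str | Path, payload: Mapping) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_model_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run on a synthetic cohort.

    ``selection_rule`` is ``("threshold", tau)``, ``("top_n", N)`` or
    ``("weights",)``; the default threshold 0.1 is the screening value
    used for gene-localisation work.  ``control_subjects`` name the
    subjects whose pooled spot distributions act as the control; all
    remaining subjects are tested against that pool per gene.
    """

    seed: int = 0
    out_dir: str | Path = "nucrank_run"
    synthesis: "object | None" = None  # SynthesisSpec; default if None
    lambda_: float = 1e-4
    selection_rule: tuple = ("threshold", 0.1)
    control_subjects: tuple[str, ...] = ()
    alpha: float = 0.01
    weight_by_posterior: bool = False


def run_pipeline(config: PipelineConfig) -> dict:
    """Generate a synthetic cohort, extract features, fit and apply the
    ranking model, score dataset quality, measure gene centrality on the
    selected nuclei and compare each test subject to the pooled control.

    Writes ``features.csv``, ``ranking.csv``, ``quality.json``,
    ``centrality.csv`` and ``comparison.json`` under ``config.out_dir``
    and returns the in-memory artifacts.  Deterministic given the seed.
    """
    from . import centrality as ctr
    from . import features as feat
    from . import ranking as rk
    from . import synthgen

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    spec = config.synthesis or synthgen.SynthesisSpec(seed=config.seed)
    cohort = synthgen.generate_cohort(spec)

    table = feat.extract_all(cohort.candidates_by_image(),
                             cohort.images_by_id(),
                             cohort.assigned_spots())
    table = table.merge(cohort.provenance(), on="object_id", how="left")
    table.to_csv(out_dir / "features.csv", index=False)

    labels = pd.Series({g.object_id: float(g.derived_label)
                        for g in cohort.truth_records})
    feat_cols = [c for c in table.columns
                 if c in feat.ALL_FEATURES or c.endswith("_missing")]
    X = table.set_index("object_id")[feat_cols]
    y = labels.reindex(X.index)

    model = rk.fit_logistic(X, y, lambda_=config.lambda_, seed=config.seed)
    post = rk.predict_posterior(model, X)
    ranked = rk.rank_candidates(post)
    ranked.to_csv(out_dir / "ranking.csv", index=False)

    prov = table.set_index("object_id")
    quality = {}
    for (subj, core), grp in prov.groupby(["subject_id", "core_id"]):
        q = rk.dataset_quality(post.loc[grp.index])
        quality[f"{subj}/{core}"] = {"value": q.value, "n": q.n}
    for subj, grp in prov.groupby("subject_id"):
        q = rk.dataset_quality(post.loc[grp.index])
        quality[subj] = {"value": q.value, "n": q.n}
    with open(out_dir / "quality.json", "w") as fh:
        json.dump(quality, fh, indent=2, sort_keys=True)

    selected = rk.select_usable(ranked, config.selection_rule)
    zero_selection = len(selected) == 0
    if zero_selection:
        log.warning("no candidates survived selection")

    sel_objects = [o for o in cohort.all_candidates()
                   if o.object_id in set(selected)]
    weights = post if config.weight_by_posterior else None
    cent_rows = ctr.centrality_table(sel_objects, cohort.assigned_spots(),
                                     weights=weights,
                                     pixel_size_um=spec.pixel_size_um)
    cent_rows.to_csv(out_dir / "centrality.csv", index=False)

    comparison: dict = {"alpha": config.alpha,
                        "zero_selection": zero_selection, "tests": []}
    if not zero_selection and config.control_subjects:
        obj_subject = prov["subject_id"].to_dict()
        cent = cent_rows.assign(
            subject_id=cent_rows["object_id"].map(obj_subject))
        for gene, gg in cent.groupby("gene"):
            ctrl = gg[gg["subject_id"].isin(config.control_subjects)]
            if len(ctrl) == 0:
                continue
            control = ctr.PositionDistribution(
                sample_id="pooled-control", gene=str(gene),
                cedt=ctrl["cedt"].to_numpy(), nedt=ctrl["nedt"].to_numpy(),
                object_ids=list(ctrl["object_id"]))
            for subj, sg in gg.groupby("subject_id"):
                if subj in config.control_subjects or len(sg) == 0:
                    continue
                test = ctr.PositionDistribution(
                    sample_id=str(subj), gene=str(gene),
                    cedt=sg["cedt"].to_numpy(), nedt=sg["nedt"].to_numpy(),
                    object_ids=list(sg["object_id"]))
                res = ctr.compare_to_control(test, control,
                                             alpha=config.alpha)
                comparison["tests"].append({
                    "subject": str(subj), "gene": str(gene),
                    "statistic": res.statistic, "p_value": res.p_value,
                    "different": res.different,
                    "n_test": res.n_test, "n_control": res.n_control})
    with open(out_dir / "comparison.json", "w") as fh:
        json.dump(comparison, fh, indent=2, sort_keys=True)

    return {"features": table, "model": model, "ranking": ranked,
            "quality": quality, "centrality": cent_rows,
            "comparison": comparison, "selected": selected,
            "zero_selection": zero_selection}
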
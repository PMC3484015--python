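"""Radial gene-position measures on segmented nuclei.

Three successive centrality measures are computed for a point
:math:`x` inside a nucleus with contour :math:`C` and interior
:math:`M`:

* ``edt`` — Euclidean distance transform, the smallest distance from
  the point to any contour point, :math:`\\mathrm{edt}(x) = \\min_C d(x, C)`.
  Contour pixels have a value of exactly zero.
* ``nedt`` — normalised EDT, :math:`1 - \\mathrm{edt}(x)/\\max_M \\mathrm{edt}`,
  so the deepest interior point ("the origin") maps to 0 and the
  periphery to 1.
* ``cedt`` — cumulative EDT, the empirical probability
  :math:`P(\\mathrm{nedt}(M) \\le \\mathrm{nedt}(x))` over all mask
  pixels.  This is scale- and shape-invariant: for points drawn
  uniformly from the interior it is uniform on [0, 1] regardless of
  the nuclear outline (the probability-integral transform).

The EDT reference set is the set of *contour pixel centers* — mask
pixels adjacent to background — so boundary pixels are literally at
distance zero.  Sub-pixel spot positions are evaluated by bilinear
interpolation of the distance field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core_io import CandidateObject, SpotRecord, boundary_pixels


@dataclass
class DistanceField:
    """Per-pixel Euclidean distance to the nearest contour pixel center.

    ``edt`` covers the candidate's bounding box and is defined on every
    pixel of the box (values outside the mask are distances too, which
    makes bilinear interpolation near the boundary well behaved); only
    mask pixels belong to the population used for ``cedt``.
    """

    obj: CandidateObject
    edt: np.ndarray              # same shape as obj.mask
    max_edt: float
    argmax: tuple[int, int]      # (row, col), image coordinates
    _sorted_nedt: np.ndarray = field(repr=False, default=None)

    @property
    def mask_nedt(self) -> np.ndarray:
        """nEDT values of all mask pixels (unsorted, raster order)."""
        vals = 1.0 - self.edt[self.obj.mask] / self.max_edt \
            if self.max_edt > 0 else np.ones(self.obj.area)
        return np.clip(vals, 0.0, 1.0)

    @property
    def sorted_nedt(self) -> np.ndarray:
        if self._sorted_nedt is None:
            self._sorted_nedt = np.sort(self.mask_nedt)
        return self._sorted_nedt


def edt_map(obj: CandidateObject) -> DistanceField:
    """Exact Euclidean distance from each pixel to the nearest boundary
    pixel center of ``obj``."""
    if obj.area == 0:
        raise ValueError("cannot compute EDT of an empty mask")
    boundary = boundary_pixels(obj.mask)
    # distance_transform_edt measures to the nearest zero: zero the
    # boundary pixels so they (and only they) sit at distance 0 in-mask.
    dist = ndimage.distance_transform_edt(~boundary)
    in_mask = np.where(obj.mask, dist, -np.inf)
    flat = int(np.argmax(in_mask))
    argmax = np.unravel_index(flat, obj.mask.shape)
    max_edt = float(dist[argmax])
    return DistanceField(obj=obj, edt=dist, max_edt=max_edt,
                         argmax=(int(argmax[0]) + obj.offset[0],
                                 int(argmax[1]) + obj.offset[1]))


def _local_point(f: DistanceField, x: float, y: float) -> tuple[float, float]:
    r = y - f.obj.offset[0]
    c = x - f.obj.offset[1]
    rr = int(np.floor(r + 0.5))
    cc = int(np.floor(c + 0.5))
    h, w = f.obj.mask.shape
    if not (0 <= rr < h and 0 <= cc < w) or not f.obj.mask[rr, cc]:
        raise ValueError(f"point ({x}, {y}) is outside the mask of "
                         f"{f.obj.object_id}")
    return r, c


def edt_at(f: DistanceField, x: float, y: float) -> float:
    """Bilinearly interpolated EDT value at a sub-pixel point (image
    coordinates; the rounded pixel must lie in the mask)."""
    r, c = _local_point(f, x, y)
    val = ndimage.map_coordinates(f.edt, [[r], [c]], order=1,
                                  mode="nearest")[0]
    return float(val)


def nedt_at(f: DistanceField, x: float, y: float) -> float:
    """Normalised EDT at a point: 1 at the periphery, 0 at the deepest
    interior pixel; clipped to [0, 1]."""
    if f.max_edt == 0:  # degenerate object: everything is boundary
        _local_point(f, x, y)
        return 1.0
    val = 1.0 - edt_at(f, x, y) / f.max_edt
    return float(np.clip(val, 0.0, 1.0))


def cedt_at(f: DistanceField, x: float, y: float) -> float:
    """Cumulative EDT: right-continuous empirical CDF of the mask-pixel
    nEDT population evaluated at the point's nEDT."""
    v = nedt_at(f, x, y)
    s = f.sorted_nedt
    return float(np.searchsorted(s, v, side="right") / s.size)


@dataclass
class CentralityResult:
    spot_id: str
    object_id: str
    gene: str
    edt: float
    nedt: float
    cedt: float
    weight: float = 1.0


def spot_centrality(obj: CandidateObject, spots: Sequence[SpotRecord],
                    weight: float = 1.0,
                    f: DistanceField | None = None,
                    ) -> list[CentralityResult]:
    """edt/nedt/cedt for each spot assigned to ``obj``."""
    if f is None:
        f = edt_map(obj)
    out = []
    for s in spots:
        if s.assigned_object != obj.object_id:
            continue
        out.append(CentralityResult(
            spot_id=s.spot_id, object_id=obj.object_id, gene=s.gene,
            edt=edt_at(f, s.x, s.y), nedt=nedt_at(f, s.x, s.y),
            cedt=cedt_at(f, s.x, s.y), weight=weight))
    return out


def centrality_table(objects: Sequence[CandidateObject],
                     spots: Sequence[SpotRecord],
                     weights: "pd.Series | None" = None,
                     pixel_size_um: float | None = None) -> pd.DataFrame:
    """Per-spot centrality for every spot assigned to one of ``objects``.

    ``weights`` maps object_id to the posterior probability used as a
    per-spot weight; µm distances are attached when ``pixel_size_um``
    is given (edt only — nedt/cedt are unitless ratios).
    """
    rows = []
    by_obj: dict[str, list[SpotRecord]] = {}
    for s in spots:
        if s.assigned_object is not None:
            by_obj.setdefault(s.assigned_object, []).append(s)
    for obj in objects:
        mine = by_obj.get(obj.object_id, [])
        if not mine:
            continue
        w = 1.0 if weights is None else float(weights.get(obj.object_id, 1.0))
        rows.extend(spot_centrality(obj, mine, weight=w))
    df = pd.DataFrame(
        {"spot_id": [r.spot_id for r in rows],
         "object_id": [r.object_id for r in rows],
         "gene": [r.gene for r in rows],
         "edt_px": [r.edt for r in rows],
         "nedt": [r.nedt for r in rows],
         "cedt": [r.cedt for r in rows],
         "weight": [r.weight for r in rows]})
    if pixel_size_um is not None and len(df):
        df.insert(4, "edt_um", df["edt_px"] * pixel_size_um)
    elif pixel_size_um is not None:
        df["edt_um"] = pd.Series(dtype=float)
    return df


# ---------------------------------------------------------------------------
# Position distributions and the repositioning comparison
# ---------------------------------------------------------------------------

@dataclass
class PositionDistribution:
    """Pooled radial positions (cedt, and nedt alongside) of one gene in
    one sample."""

    sample_id: str
    gene: str
    cedt: np.ndarray
    nedt: np.ndarray
    object_ids: list[str] = field(default_factory=list)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cedt = np.asarray(self.cedt, dtype=float)
        self.nedt = np.asarray(self.nedt, dtype=float)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")

    @property
    def n(self) -> int:
        return int(self.cedt.size)


def gene_position_distribution(objects: Sequence[CandidateObject],
                               spots: Sequence[SpotRecord],
                               sample_id: str,
                               weights: "pd.Series | None" = None,
                               ) -> dict[str, PositionDistribution]:
    """Concatenate per-spot centralities of the selected objects into one
    distribution per gene, optionally weighted by the source object's
    posterior."""
    table = centrality_table(objects, spots, weights=weights)
    out: dict[str, PositionDistribution] = {}
    for gene, grp in table.groupby("gene"):
        out[str(gene)] = PositionDistribution(
            sample_id=sample_id, gene=str(gene),
            cedt=grp["cedt"].to_numpy(), nedt=grp["nedt"].to_numpy(),
            object_ids=list(grp["object_id"]),
            weights=grp["weight"].to_numpy() if weights is not None else None)
    if not out:
        out = {}
    return out


def pool_controls(distributions: Sequence[PositionDistribution],
                  sample_id: str = "pooled-control") -> PositionDistribution:
    """Concatenate same-gene distributions into a pooled control."""
    if len(distributions) == 0:
        raise ValueError("need at least one distribution to pool")
    genes = {d.gene for d in distributions}
    if len(genes) > 1:
        raise ValueError(f"cannot pool mixed genes: {sorted(genes)}")
    weights = None
    if all(d.weights is not None for d in distributions):
        weights = np.concatenate([d.weights for d in distributions])
    return PositionDistribution(
        sample_id=sample_id, gene=distributions[0].gene,
        cedt=np.concatenate([d.cedt for d in distributions]),
        nedt=np.concatenate([d.nedt for d in distributions]),
        object_ids=sum((d.object_ids for d in distributions), []),
        weights=weights)


@dataclass
class ComparisonResult:
    test_id: str
    control_id: str
    statistic: float
    p_value: float
    alpha: float
    different: bool
    n_test: int
    n_control: int


#: Test samples smaller than this give hypothesis tests with little
#: power for radial repositioning.
MIN_RECOMMENDED_N = 100


def compare_to_control(test: PositionDistribution,
                       control: PositionDistribution,
                       alpha: float = 0.01,
                       measure: str = "cedt") -> ComparisonResult:
    """Two-sample Kolmogorov–Smirnov comparison of a test sample's radial
    distribution against the pooled control.

    The sample is called *different* when the p-value of the null (no
    repositioning) falls below ``alpha``.  The asymptotic p-value is
    used except for very small combined samples (< 40), where the exact
    distribution is computed.
    """
    a = getattr(test, measure)
    b = getattr(control, measure)
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot compare empty distributions")
    if a.size < MIN_RECOMMENDED_N:
        import logging
        logging.getLogger("nucrank").warning(
            "test sample %s has only %d spots (< %d); the comparison "
            "may lack power", test.sample_id, a.size, MIN_RECOMMENDED_N)
    method = "exact" if a.size + b.size < 40 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    p = float(res.pvalue)
    return ComparisonResult(
        test_id=test.sample_id, control_id=control.sample_id,
        statistic=float(res.statistic), p_value=p, alpha=alpha,
        different=bool(p < alpha), n_test=int(a.size), n_control=int(b.size))


# ---------------------------------------------------------------------------
# Stability of the measures under boundary perturbation
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    n: int
    nedt_r: float
    nedt_mae: float
    cedt_r: float
    cedt_mae: float
    profile: pd.DataFrame  # binned |error| vs radial position


def stability_compare(a: Sequence[CentralityResult],
                      b: Sequence[CentralityResult],
                      n_bins: int = 10) -> StabilityReport:
    """Agreement of centrality measurements from two boundary sources
    (e.g. reference vs perturbed masks) on matched spots.

    Reports the Pearson correlation and mean absolute error separately
    for nedt and cedt, plus the absolute error binned by radial
    position (using source A's position as the reference axis).
    """
    bmap = {r.spot_id: r for r in b}
    pairs = [(ra, bmap[ra.spot_id]) for ra in a if ra.spot_id in bmap]
    if len(pairs) < 3:
        raise ValueError("need at least 3 matched spots")
    nedt_a = np.array([p[0].nedt for p in pairs])
    nedt_b = np.array([p[1].nedt for p in pairs])
    cedt_a = np.array([p[0].cedt for p in pairs])
    cedt_b = np.array([p[1].cedt for p in pairs])

    nedt_r = float(stats.pearsonr(nedt_a, nedt_b).statistic)
    cedt_r = float(stats.pearsonr(cedt_a, cedt_b).statistic)

    edges = np.linspace(0, 1, n_bins + 1)
    idx = np.clip(np.digitize(nedt_a, edges) - 1, 0, n_bins - 1)
    rows = []
    for k in range(n_bins):
        sel = idx == k
        rows.append({
            "bin_low": edges[k], "bin_high": edges[k + 1],
            "n": int(sel.sum()),
            "nedt_abs_err": float(np.abs(nedt_a - nedt_b)[sel].mean())
            if sel.any() else np.nan,
            "cedt_abs_err": float(np.abs(cedt_a - cedt_b)[sel].mean())
            if sel.any() else np.nan})
    return StabilityReport(
        n=len(pairs), nedt_r=nedt_r,
        nedt_mae=float(np.abs(nedt_a - nedt_b).mean()),
        cedt_r=cedt_r,
        cedt_mae=float(np.abs(cedt_a - cedt_b).mean()),
        profile=pd.DataFrame(rows))
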
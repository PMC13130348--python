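"""Range-position metrics: geographic and climatic distance to the range edge.

Two complementary metrics place a population within its species' range:

* **DRE** — distance (km) from the site to the *northernmost or southernmost*
  range edge, whichever is nearer. The range boundary is split at the site's
  latitude into a northern and a southern part; DRE is the smaller of the two
  point-to-boundary distances. East/west-facing boundary away from the site's
  latitude band therefore never dominates the metric.
* **DCE** — distance in climate space. Bioclimatic variables of all grid
  cells inside the range are z-scored, reduced to the first two principal
  components, and the convex hull of the cell scores represents the climatic
  niche; DCE is the Euclidean distance from a site's PC score to the nearest
  hull edge.

All coordinates are planar (projected) kilometres; no geodesy is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LineString, MultiLineString, Point, Polygon

__all__ = [
    "NichePCA",
    "distance_to_range_edge",
    "climatic_pca",
    "convex_hull_2d",
    "distance_to_climatic_edge",
    "site_range_position",
]


@dataclass
class NichePCA:
    """Principal-component summary of the climatic niche.

    Scaling (means/SDs) and loadings are derived from the range cells only
    and applied unchanged to the sampled sites, so site scores are
    projections into the niche space, not a refit.
    """

    variables: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # (k, n_components), columns orthonormal
    explained_variance_ratio: np.ndarray
    cell_scores: np.ndarray  # (n_cells, n_components)
    site_scores: np.ndarray  # (n_sites, n_components)


def _split_boundary_at_latitude(
    boundary: np.ndarray, y: float
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Split closed-boundary segments at latitude ``y`` into N and S parts."""
    north: list[np.ndarray] = []
    south: list[np.ndarray] = []
    n = len(boundary)
    for i in range(n):
        p, q = boundary[i], boundary[(i + 1) % n]
        if np.allclose(p, q):
            continue
        pieces = [(p, q)]
        if (p[1] - y) * (q[1] - y) < 0:  # segment straddles the latitude line
            t = (y - p[1]) / (q[1] - p[1])
            c = p + t * (q - p)
            pieces = [(p, c), (c, q)]
        for a, b in pieces:
            seg = np.array([a, b])
            mid_y = 0.5 * (a[1] + b[1])
            (north if mid_y >= y else south).append(seg)
    return north, south


def distance_to_range_edge(
    site_xy: tuple[float, float], boundary: np.ndarray | Polygon,
    site_id: str = "site",
) -> float:
    """DRE: distance (km) to the nearer of the northern/southern range edge.

    ``boundary`` is a closed polygon (vertex array in planar km, or a
    shapely Polygon). The site must lie inside the polygon or on its
    boundary.
    """
    if isinstance(boundary, Polygon):
        poly = boundary
        coords = np.asarray(poly.exterior.coords)[:-1]
    else:
        coords = np.asarray(boundary, dtype=float)
        if len(coords) < 3:
            raise ValueError("range boundary needs at least 3 vertices")
        poly = Polygon(coords)
    pt = Point(*site_xy)
    if not (poly.contains(pt) or poly.boundary.distance(pt) < 1e-9):
        raise ValueError(f"site {site_id!r} at {tuple(site_xy)} lies outside the range polygon")

    north, south = _split_boundary_at_latitude(coords, site_xy[1])
    dists = []
    for part in (north, south):
        if part:
            mls = MultiLineString([LineString(seg) for seg in part])
            dists.append(mls.distance(pt))
    return float(min(dists))


def climatic_pca(
    cell_climate: pd.DataFrame, site_climate: pd.DataFrame,
    variables: list[str] | None = None, n_components: int = 2,
) -> NichePCA:
    """PCA of z-scored range-cell climates, with sites projected in.

    Variables with zero variance across cells are dropped with a warning.
    Each loading vector is oriented so that its largest-magnitude entry is
    positive (sign convention for reproducibility).
    """
    if variables is None:
        variables = [c for c in cell_climate.columns if c in site_climate.columns
                     and np.issubdtype(cell_climate[c].dtype, np.number)]
    if len(cell_climate) < 3:
        raise ValueError("need at least 3 range cells for a climatic PCA")

    keep, means, sds = [], [], []
    for v in variables:
        sd = float(cell_climate[v].std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"dropping zero-variance climate variable {v!r}")
            continue
        keep.append(v)
        means.append(float(cell_climate[v].mean()))
        sds.append(sd)
    if len(keep) < 2:
        raise ValueError("need at least 2 non-constant climate variables")
    means_a, sds_a = np.array(means), np.array(sds)

    zc = (cell_climate[keep].to_numpy(float) - means_a) / sds_a
    zs = (site_climate[keep].to_numpy(float) - means_a) / sds_a

    # principal axes of the cell cloud via SVD of the centred z-scores
    zc_c = zc - zc.mean(axis=0)
    _, svals, vt = np.linalg.svd(zc_c, full_matrices=False)
    load = vt[:n_components].T  # (k, n_components)
    for j in range(load.shape[1]):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] = -load[:, j]
    var = svals**2
    evr = var[:n_components] / var.sum()

    center = zc.mean(axis=0)
    return NichePCA(
        variables=keep,
        means=means_a,
        sds=sds_a,
        loadings=load,
        explained_variance_ratio=evr,
        cell_scores=(zc - center) @ load,
        site_scores=(zs - center) @ load,
    )


def convex_hull_2d(points: np.ndarray) -> np.ndarray:
    """Convex hull of 2-D points as a counterclockwise vertex array.

    Raises
    ------
    ValueError
        If fewer than 3 distinct points are supplied or all points are
        collinear (degenerate hull).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 3:
        raise ValueError("convex hull needs at least 3 distinct points")
    try:
        hull = ConvexHull(uniq)
    except QhullError as err:
        raise ValueError("degenerate hull: points are collinear") from err
    verts = uniq[hull.vertices]  # scipy returns CCW order in 2-D
    return verts


def distance_to_climatic_edge(
    score: np.ndarray | tuple[float, float], hull: np.ndarray
) -> tuple[float, bool]:
    """DCE: minimum distance from a PC score to the hull's edge segments.

    Returns ``(distance, exterior)``; ``exterior`` is True when the score
    lies strictly outside the hull (possible for sampled sites whose climate
    falls outside the gridded niche).
    """
    hull = np.asarray(hull, dtype=float)
    pt = Point(float(score[0]), float(score[1]))
    poly = Polygon(hull)
    d = poly.exterior.distance(pt)
    exterior = not (poly.contains(pt) or d < 1e-12)
    return float(d), exterior


def site_range_position(
    sites: pd.DataFrame, boundary: np.ndarray, cell_climate: pd.DataFrame,
    site_climate: pd.DataFrame, variables: list[str] | None = None,
) -> pd.DataFrame:
    """DRE and DCE for every site.

    ``sites`` needs columns ``population, x, y`` (km); ``site_climate`` rows
    must align with ``sites`` rows.
    """
    pca = climatic_pca(cell_climate, site_climate, variables)
    hull = convex_hull_2d(pca.cell_scores)
    rows = []
    for i, rec in enumerate(sites.itertuples(index=False)):
        dre = distance_to_range_edge((rec.x, rec.y), boundary, site_id=str(rec.population))
        dce, ext = distance_to_climatic_edge(pca.site_scores[i], hull)
        rows.append({"population": rec.population, "DRE_km": dre,
                     "DCE": dce, "DCE_exterior": ext})
    return pd.DataFrame(rows)
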
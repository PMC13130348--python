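"""Landscape heterogeneity metrics inside a square buffer around a site.

Three metrics summarise the environment a plant population experiences
locally:

* **SHDI** — Shannon diversity of land-cover classes, compositional
  heterogeneity: ``-sum(p_i * ln p_i)`` over class proportions by cell count.
* **PAR** — mean perimeter-to-area ratio over land-cover patches (connected
  components of equal class), configurational heterogeneity, units 1/m.
* **ARE** — average roughness of elevation (the surface-metrology ``Sa``):
  mean absolute deviation of elevation from the buffer mean, metres.

All three are computed on the set of whole cells whose centres fall within a
square extending ``half_width_m`` (default 500 m) from the site in all
directions. Patches use 8-connectivity by default; cell sides on the buffer
boundary count toward patch perimeter (patches are closed at the clip edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .rasters import Raster

__all__ = [
    "BufferGrid",
    "PatchSet",
    "extract_square_buffer",
    "shannon_diversity",
    "delineate_patches",
    "patch_perimeter_area",
    "mean_perimeter_area_ratio",
    "average_roughness",
    "site_heterogeneity",
]


@dataclass
class BufferGrid:
    """Whole-cell square clip of a raster around one site."""

    site_id: str
    values: np.ndarray
    resolution_m: float
    categorical: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("buffer must be a non-empty 2-D grid")


@dataclass
class PatchSet:
    """Connected-component patches of a categorical buffer."""

    labels: np.ndarray  # per-cell patch id, 1..n_patches
    table: pd.DataFrame = field(repr=False)  # patch_id, class, area_m2, perimeter_m
    connectivity: int = 8


def extract_square_buffer(
    raster: Raster, site_xy: tuple[float, float], half_width_m: float = 500.0,
    site_id: str = "site",
) -> BufferGrid:
    """Clip the cells whose centres lie within the closed square buffer.

    Raises
    ------
    ValueError
        If the raster does not cover the full buffer extent (the message
        lists the missing extent).
    """
    sx, sy = site_xy
    res = raster.resolution_m
    x0, y0 = raster.origin
    eps = 1e-9 * res

    # column index range with |cx - sx| <= hw, cx = x0 + (j + .5) res
    jmin = int(np.ceil((sx - half_width_m - x0) / res - 0.5 - eps))
    jmax = int(np.floor((sx + half_width_m - x0) / res - 0.5 + eps))
    # row index: cy = y0 + (nrows - i - .5) res
    imin = int(np.ceil(raster.nrows - (sy + half_width_m - y0) / res - 0.5 - eps))
    imax = int(np.floor(raster.nrows - (sy - half_width_m - y0) / res - 0.5 + eps))

    missing = []
    if jmin < 0:
        missing.append(f"west of x={x0}")
    if jmax >= raster.ncols:
        missing.append(f"east of x={x0 + raster.ncols * res}")
    if imin < 0:
        missing.append(f"north of y={y0 + raster.nrows * res}")
    if imax >= raster.nrows:
        missing.append(f"south of y={y0}")
    if missing:
        raise ValueError(
            f"raster does not cover the {half_width_m} m buffer of {site_id}: "
            + "; ".join(missing)
        )
    if jmax < jmin or imax < imin:
        raise ValueError(f"buffer around {site_id} contains no cell centres")

    sub = raster.values[imin : imax + 1, jmin : jmax + 1].copy()
    categorical = np.issubdtype(sub.dtype, np.integer)
    return BufferGrid(site_id=site_id, values=sub, resolution_m=res,
                      categorical=categorical)


def shannon_diversity(buffer: BufferGrid | np.ndarray) -> float:
    """Shannon diversity index of class proportions, ``-sum p ln p``."""
    values = buffer.values if isinstance(buffer, BufferGrid) else np.asarray(buffer)
    _, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() + 0.0)  # +0.0 normalises -0.0


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError("connectivity must be 4 or 8")


def delineate_patches(
    buffer: BufferGrid | np.ndarray, connectivity: int = 8,
    resolution_m: float | None = None,
) -> PatchSet:
    """Label connected same-class patches and tabulate area and perimeter.

    Labels are assigned deterministically: classes in sorted order, and
    within a class in raster scan order (the order scipy's component
    labelling emits).
    """
    if isinstance(buffer, BufferGrid):
        values = buffer.values
        res = buffer.resolution_m
    else:
        values = np.asarray(buffer)
        res = 1.0 if resolution_m is None else resolution_m
    struct = _structure(connectivity)

    labels = np.zeros(values.shape, dtype=int)
    classes: list[int] = []
    offset = 0
    for cls in np.unique(values):
        lab, n = ndimage.label(values == cls, structure=struct)
        labels[lab > 0] = lab[lab > 0] + offset
        classes.extend([cls] * n)
        offset += n

    areas, perims = _patch_area_perimeter(labels, offset, res)
    table = pd.DataFrame(
        {
            "patch_id": np.arange(1, offset + 1),
            "class": classes,
            "area_m2": areas,
            "perimeter_m": perims,
        }
    )
    return PatchSet(labels=labels, table=table, connectivity=connectivity)


def _patch_area_perimeter(
    labels: np.ndarray, n_patches: int, res: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-patch cell counts and boundary-side counts."""
    areas = np.bincount(labels.ravel(), minlength=n_patches + 1)[1:] * res * res
    # pad with label -1 so outer sides of the buffer count as patch edges
    padded = np.pad(labels, 1, constant_values=-1)
    sides = np.zeros(n_patches + 1, dtype=int)
    core = padded[1:-1, 1:-1]
    for neigh in (
        padded[:-2, 1:-1],
        padded[2:, 1:-1],
        padded[1:-1, :-2],
        padded[1:-1, 2:],
    ):
        diff = core != neigh
        np.add.at(sides, core[diff].ravel(), 1)
    return areas, sides[1:] * res


def patch_perimeter_area(
    patch_mask: np.ndarray, resolution_m: float
) -> tuple[float, float]:
    """(perimeter m, area m²) of a single patch given as a boolean mask.

    Every cell side adjacent to a non-patch cell or to the grid boundary
    contributes one side of length ``resolution_m``.
    """
    mask = np.asarray(patch_mask, dtype=bool)
    if not mask.any():
        raise ValueError("patch is empty")
    area = float(mask.sum()) * resolution_m**2
    padded = np.pad(mask, 1, constant_values=False)
    sides = 0
    core = padded[1:-1, 1:-1]
    for neigh in (
        padded[:-2, 1:-1],
        padded[2:, 1:-1],
        padded[1:-1, :-2],
        padded[1:-1, 2:],
    ):
        sides += int(np.sum(core & ~neigh))
    return sides * resolution_m, area


def mean_perimeter_area_ratio(
    buffer: BufferGrid | np.ndarray, resolution_m: float | None = None,
    connectivity: int = 8,
) -> float:
    """Mean of perimeter/area over all land-cover patches, units 1/m."""
    patches = delineate_patches(buffer, connectivity=connectivity,
                                resolution_m=resolution_m)
    t = patches.table
    if len(t) == 0:
        raise ValueError("no patches in buffer")
    return float((t["perimeter_m"] / t["area_m2"]).mean())


def average_roughness(buffer: BufferGrid | np.ndarray) -> float:
    """Average roughness (Sa): mean |z - mean(z)| over the buffer, metres."""
    z = buffer.values if isinstance(buffer, BufferGrid) else np.asarray(buffer)
    z = z.astype(float)
    return float(np.abs(z - z.mean()).mean())


def site_heterogeneity(
    land_cover: Raster, elevation: Raster, site_xy: tuple[float, float],
    half_width_m: float = 500.0, site_id: str = "site", connectivity: int = 8,
) -> dict[str, float]:
    """SHDI, PAR and ARE for one site's square buffer."""
    lc = extract_square_buffer(land_cover, site_xy, half_width_m, site_id)
    dem = extract_square_buffer(elevation, site_xy, half_width_m, site_id)
    if not lc.categorical:
        raise ValueError("land-cover raster must be categorical (integer classes)")
    return {
        "population": site_id,
        "SHDI": shannon_diversity(lc),
        "PAR": mean_perimeter_area_ratio(lc, connectivity=connectivity),
        "ARE": average_roughness(dem),
    }
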
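"""Cone-mosaic spatial metrics: craters and the central-third ratio.

A *crater* is a circumscribed cone-free region in the flat-mount cone
mosaic.  It is delineated from the cone calls alone: the retina is covered
by discs of a density-scaled radius around every cone, the uncovered
remainder is split into 8-connected components, and each component is
dilated back by the coverage radius (the discs erode true crater boundaries
by exactly that radius, so the dilation removes the boundary bias).
Components below a minimum area are discarded.

The *central ratio* — cones within the central one-third of the retina,
measured from the optic nerve head, over all cones — normalizes the rescue
readout for variation in viral infection efficiency between eyes.  "One
third" defaults to the enclosed tissue-area third; a radius-based third is
available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import UndefinedRatioError, ValidationError

__all__ = [
    "CraterReport",
    "CentralRatio",
    "cone_coverage_mask",
    "detect_craters",
    "central_ratio",
    "median_nn_distance",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class CraterReport:
    n_craters: int
    crater_areas_px: list[int]
    total_crater_area_px: int
    percent_of_retina: float
    coverage_radius_px: float
    min_crater_area_px: float
    labels: np.ndarray  # int32 labelled crater mask, 0 = background

    def to_dict(self) -> dict:
        return {
            "n_craters": int(self.n_craters),
            "crater_areas_px": [int(a) for a in self.crater_areas_px],
            "total_crater_area_px": int(self.total_crater_area_px),
            "percent_of_retina": float(self.percent_of_retina),
            "coverage_radius_px": float(self.coverage_radius_px),
            "min_crater_area_px": float(self.min_crater_area_px),
        }


@dataclass
class CentralRatio:
    ratio: float
    n_central: int
    n_total: int
    central_radius_px: float
    definition: Literal["area_third", "radius_third"]

    def to_dict(self) -> dict:
        return {
            "ratio": float(self.ratio),
            "n_central": int(self.n_central),
            "n_total": int(self.n_total),
            "central_radius_px": float(self.central_radius_px),
            "definition": self.definition,
        }


def _as_centroids(cone_set) -> np.ndarray:
    """Accept a ConeSet, an (n, 2) array, or a sequence of (row, col)."""
    if hasattr(cone_set, "centroids"):
        pts = cone_set.centroids()
    else:
        pts = np.asarray(cone_set, dtype=float)
    if pts.size == 0:
        return np.empty((0, 2))
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 2:
        raise ValidationError("cone positions must be (row, col) pairs")
    return pts


def median_nn_distance(points: np.ndarray) -> float:
    """Median nearest-neighbour distance of a point set (n >= 2)."""
    from scipy.spatial import cKDTree

    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 2:
        raise ValidationError("need >= 2 points for a nearest-neighbour distance")
    d, _ = cKDTree(points).query(points, k=2)
    return float(np.median(d[:, 1]))


def cone_coverage_mask(
    cone_set, retina_mask: np.ndarray, coverage_radius_px: float
) -> np.ndarray:
    """Union of discs of ``coverage_radius_px`` around every cone call,
    intersected with the retina mask.  Empty cone set -> empty mask."""
    if coverage_radius_px <= 0:
        raise ValidationError("coverage_radius_px must be positive")
    retina_mask = np.asarray(retina_mask, dtype=bool)
    pts = _as_centroids(cone_set)
    if len(pts) == 0:
        return np.zeros_like(retina_mask)
    seeds = np.zeros(retina_mask.shape, dtype=bool)
    rr = np.clip(np.round(pts[:, 0]).astype(int), 0, retina_mask.shape[0] - 1)
    cc = np.clip(np.round(pts[:, 1]).astype(int), 0, retina_mask.shape[1] - 1)
    seeds[rr, cc] = True
    dist = ndi.distance_transform_edt(~seeds)
    return (dist <= coverage_radius_px) & retina_mask


def detect_craters(
    cone_set,
    retina_mask: np.ndarray,
    coverage_radius_px: float | None = None,
    min_crater_area_px: float | None = None,
    cone_area_px: float | None = None,
) -> CraterReport:
    """Detect cone-free craters and report count, areas, and % of retina.

    Defaults scale with mosaic density, not microscope settings:
    ``coverage_radius_px`` is chosen so a complete spatially random mosaic
    of the observed density saturates its own coverage (uncovered fraction
    exp(-density * pi * r^2) ~ 1e-5), so craters, not sampling gaps,
    dominate the complement; ``min_crater_area_px`` = 50x ``cone_area_px`` when a
    single-cone area is supplied, otherwise 1.5 * pi * r^2 (craters must
    exceed the scale of a single coverage disc).  An entirely cone-free
    retina is one crater at 100%.
    """
    retina_mask = np.asarray(retina_mask, dtype=bool)
    retina_area = int(retina_mask.sum())
    if retina_area == 0:
        raise ValidationError("retina mask is empty")
    pts = _as_centroids(cone_set)

    if len(pts) < 2:
        # no mosaic: the whole retina is uncovered
        r = float(coverage_radius_px) if coverage_radius_px else 0.0
        labels = retina_mask.astype(np.int32)
        area = retina_area
        min_area = float(min_crater_area_px) if min_crater_area_px is not None else 0.0
        if area < min_area:
            return CraterReport(0, [], 0, 0.0, r, min_area, np.zeros_like(labels))
        return CraterReport(1, [area], area, 100.0, r, min_area, labels)

    density = len(pts) / retina_area
    if coverage_radius_px is not None:
        r = float(coverage_radius_px)
    else:
        # radius at which a spatially random mosaic of this density leaves
        # an uncovered fraction of only ~1e-5: exp(-lambda pi r^2) = eps
        r = float(np.sqrt(np.log(1e5) / (np.pi * density)))
    if min_crater_area_px is not None:
        min_area = float(min_crater_area_px)
    elif cone_area_px is not None:
        min_area = 50.0 * float(cone_area_px)
    else:
        min_area = 1.5 * np.pi * r**2

    coverage = cone_coverage_mask(pts, retina_mask, r)
    raw = retina_mask & ~coverage
    if raw.any():
        # keep only uncovered components larger than incidental gaps of the
        # point process (a quarter coverage-disc), then dilate the survivors
        # back by r to undo the coverage-disc erosion of crater boundaries
        raw_labels, n_raw = ndi.label(raw, structure=_EIGHT)
        raw_areas = np.bincount(raw_labels.ravel())[1:]
        raw_floor = 0.25 * np.pi * r**2
        keep_raw = np.flatnonzero(raw_areas >= raw_floor) + 1
        core = np.isin(raw_labels, keep_raw)
        if core.any():
            # coverage discs erode the true crater boundary by r minus the
            # mean boundary-to-nearest-cone slack (0.5 / sqrt(density) for a
            # random mosaic); dilating by the net amount restores an
            # unbiased boundary
            slack = 0.5 / np.sqrt(density)
            dist = ndi.distance_transform_edt(~core)
            crater_mask = (dist <= max(r - slack, 0.0)) & retina_mask
        else:
            crater_mask = core
    else:
        crater_mask = raw
    labels, n = ndi.label(crater_mask, structure=_EIGHT)
    areas = np.bincount(labels.ravel())[1:] if n else np.empty(0, dtype=int)
    keep = np.flatnonzero(areas >= min_area) + 1
    out_labels = np.zeros_like(labels, dtype=np.int32)
    kept_areas: list[int] = []
    for new_id, lab in enumerate(keep, start=1):
        out_labels[labels == lab] = new_id
        kept_areas.append(int(areas[lab - 1]))
    total = int(sum(kept_areas))
    return CraterReport(
        n_craters=len(kept_areas),
        crater_areas_px=kept_areas,
        total_crater_area_px=total,
        percent_of_retina=100.0 * total / retina_area,
        coverage_radius_px=r,
        min_crater_area_px=min_area,
        labels=out_labels,
    )


def central_ratio(
    cone_set,
    onh_center: tuple[float, float],
    retina_mask: np.ndarray,
    definition: Literal["area_third", "radius_third"] = "area_third",
) -> CentralRatio:
    """Fraction of cones in the central one-third of the retina.

    ``area_third`` (default) picks the radius around the optic nerve head
    enclosing one third of the retina-mask area; ``radius_third`` uses one
    third of the maximum retinal radius.
    """
    if definition not in ("area_third", "radius_third"):
        raise ValidationError(f"unknown definition {definition!r}")
    retina_mask = np.asarray(retina_mask, dtype=bool)
    pts = _as_centroids(cone_set)
    n_total = len(pts)
    if n_total == 0:
        raise UndefinedRatioError("no cones: central ratio undefined")
    rr, cc = np.nonzero(retina_mask)
    if len(rr) == 0:
        raise ValidationError("retina mask is empty")
    dists = np.hypot(rr - onh_center[0], cc - onh_center[1])
    if definition == "area_third":
        r_c = float(np.quantile(dists, 1.0 / 3.0))
    else:
        r_c = float(dists.max() / 3.0)
    cone_d = np.hypot(pts[:, 0] - onh_center[0], pts[:, 1] - onh_center[1])
    n_central = int((cone_d <= r_c).sum())
    return CentralRatio(
        ratio=n_central / n_total,
        n_central=n_central,
        n_total=n_total,
        central_radius_px=r_c,
        definition=definition,
    )
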
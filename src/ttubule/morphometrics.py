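"""Hierarchical ROI bookkeeping and allometric regression.

Mirrors the manual-tracing workflow used on tiled electron-micrograph
mosaics: fibre outlines are traced first, myofibril bundles inside them,
then the furrow paths through which T-tubules thread.  The tracing rules
are enforced geometrically —

* fibre ROIs may not overlap: a new fibre is trimmed to abut the existing
  ones (order-dependent: earlier ROIs win);
* a myofibril is clipped to its parent fibre and named after it;
* a furrow polyline is clipped to its parent myofibril.

Areas come from the shoelace formula scaled by the pixel size; furrow
"length" is polyline arc length.  The extracted table feeds ordinary
least-squares fits (LINEST-style: coefficients plus classical standard
errors) that produce the allometric constants used by the surface-area
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiLineString, MultiPolygon, Polygon
from shapely.ops import unary_union

from .errors import ROIError, TTubuleError
from .geometry import AllometryCoefficients

__all__ = [
    "PolygonROI",
    "PolylineROI",
    "ROIHierarchy",
    "RegressionFit",
    "polygon_area",
    "polyline_length",
    "extract_table",
    "fit_allometry",
    "polyfit_linest",
]


@dataclass
class PolygonROI:
    """Closed traced region: a fibre outline or a myofibril bundle.

    Vertices are pixel-corner coordinates, origin top-left, x rightward,
    y downward (a w×h pixel rectangle has area w·h).
    """

    id: str
    vertices: list[tuple[float, float]]
    kind: str = "fibre"  # "fibre" | "myofibril"
    parent_id: str | None = None

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise ROIError(f"polygon ROI {self.id!r} needs >= 3 vertices")
        if self.kind not in ("fibre", "myofibril"):
            raise ROIError(f"unknown polygon kind {self.kind!r}")
        if self.kind == "myofibril" and self.parent_id is None:
            raise ROIError(f"myofibril ROI {self.id!r} needs a parent fibre")

    def shapely(self) -> Polygon:
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            poly = poly.buffer(0)
        return poly


@dataclass
class PolylineROI:
    """Open traced path: a myofibrillar furrow inside one myofibril."""

    id: str
    points: list[tuple[float, float]]
    parent_id: str = ""
    kind: str = "furrow"

    def __post_init__(self):
        if len(self.points) < 2:
            raise ROIError(f"polyline ROI {self.id!r} needs >= 2 points")
        if not self.parent_id:
            raise ROIError(f"furrow ROI {self.id!r} needs a parent myofibril")

    def shapely(self) -> LineString:
        return LineString(self.points)


def _polygon_to_rois(geom, template: PolygonROI) -> list[PolygonROI]:
    """Unpack a (Multi)Polygon clip result into concrete ROIs."""
    parts: list[Polygon] = []
    if isinstance(geom, Polygon):
        parts = [geom]
    elif isinstance(geom, MultiPolygon):
        parts = list(geom.geoms)
    parts = [p for p in parts if p.area > 1e-12]
    out = []
    for i, p in enumerate(parts):
        suffix = "" if len(parts) == 1 else f"#{i}"
        out.append(
            PolygonROI(
                id=template.id + suffix,
                vertices=[tuple(xy) for xy in p.exterior.coords[:-1]],
                kind=template.kind,
                parent_id=template.parent_id,
            )
        )
    return out


class ROIHierarchy:
    """Fibre → myofibril → furrow containment structure with trim-on-add."""

    def __init__(self, pixel_size_um: float = 1.0):
        if pixel_size_um <= 0:
            raise ROIError("pixel size must be positive")
        self.pixel_size_um = pixel_size_um
        self.fibres: dict[str, PolygonROI] = {}
        self.myofibrils: dict[str, PolygonROI] = {}
        self.furrows: dict[str, PolylineROI] = {}

    # -- addition with the tracing macro's trimming semantics ------------

    def add_roi(self, candidate: PolygonROI | PolylineROI) -> None:
        if isinstance(candidate, PolylineROI):
            self._add_furrow(candidate)
        elif candidate.kind == "fibre":
            self._add_fibre(candidate)
        else:
            self._add_myofibril(candidate)

    def _add_fibre(self, roi: PolygonROI) -> None:
        if roi.id in self.fibres:
            raise ROIError(f"duplicate fibre id {roi.id!r}")
        geom = roi.shapely()
        if self.fibres:
            existing = unary_union([f.shapely() for f in self.fibres.values()])
            geom = geom.difference(existing)
        if geom.is_empty or geom.area <= 1e-12:
            raise ROIError(f"fibre {roi.id!r} empty after trimming to abut others")
        for part in _polygon_to_rois(geom, roi):
            self.fibres[part.id] = part

    def _add_myofibril(self, roi: PolygonROI) -> None:
        parent = self.fibres.get(roi.parent_id)
        if parent is None:
            raise ROIError(f"myofibril parent fibre {roi.parent_id!r} not found")
        geom = roi.shapely().intersection(parent.shapely())
        if geom.is_empty or getattr(geom, "area", 0.0) <= 1e-12:
            raise ROIError(f"myofibril {roi.id!r} entirely outside its fibre")
        # auto-name after the parent, as the tracing macro does
        n = sum(1 for m in self.myofibrils.values() if m.parent_id == roi.parent_id)
        base = f"{roi.parent_id}-myo{n}"
        template = PolygonROI(base, roi.vertices, "myofibril", roi.parent_id)
        for part in _polygon_to_rois(geom, template):
            self.myofibrils[part.id] = part

    def _add_furrow(self, roi: PolylineROI) -> None:
        parent = self.myofibrils.get(roi.parent_id)
        if parent is None:
            raise ROIError(f"furrow parent myofibril {roi.parent_id!r} not found")
        clipped = roi.shapely().intersection(parent.shapely())
        if clipped.is_empty or clipped.length <= 1e-12:
            raise ROIError(f"furrow {roi.id!r} entirely outside its myofibril")
        n = sum(1 for f in self.furrows.values() if f.parent_id == roi.parent_id)
        lines = (
            list(clipped.geoms)
            if isinstance(clipped, MultiLineString)
            else [clipped]
        )
        for i, line in enumerate(lines):
            suffix = "" if len(lines) == 1 else f"#{i}"
            fid = f"{roi.parent_id}-furrow{n}{suffix}"
            self.furrows[fid] = PolylineROI(
                fid, [tuple(xy) for xy in line.coords], roi.parent_id
            )


def polygon_area(roi: PolygonROI, pixel_size: float) -> float:
    """Shoelace area in µm², orientation-independent."""
    v = np.asarray(roi.vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    area = abs(signed) * pixel_size**2
    if area == 0.0:
        warnings.warn(f"degenerate polygon {roi.id!r} has zero area", stacklevel=2)
    return float(area)


def polyline_length(roi: PolylineROI, pixel_size: float) -> float:
    """Sum of Euclidean segment lengths in µm."""
    p = np.asarray(roi.points, dtype=float)
    return float(np.sum(np.hypot(*np.diff(p, axis=0).T)) * pixel_size)


def extract_table(
    hierarchy: ROIHierarchy,
    pixel_size: float | None = None,
    stage: str = "",
) -> pd.DataFrame:
    """One row per myofibril: fibre area, myofibril area, summed furrow length.

    Raises :class:`ROIError` for furrows whose parent myofibril is missing.
    """
    px = hierarchy.pixel_size_um if pixel_size is None else pixel_size
    for f in hierarchy.furrows.values():
        if f.parent_id not in hierarchy.myofibrils:
            raise ROIError(f"orphan furrow {f.id!r}: parent {f.parent_id!r} missing")
    rows = []
    for mid, myo in hierarchy.myofibrils.items():
        fibre = hierarchy.fibres[myo.parent_id]
        furrow_len = sum(
            polyline_length(f, px)
            for f in hierarchy.furrows.values()
            if f.parent_id == mid
        )
        rows.append(
            {
                "fibre_id": fibre.id,
                "fibre_area_um2": polygon_area(fibre, px),
                "myofibril_area_um2": polygon_area(myo, px),
                "furrow_length_um": furrow_len,
                "stage": stage,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "fibre_id",
            "fibre_area_um2",
            "myofibril_area_um2",
            "furrow_length_um",
            "stage",
        ],
    )


@dataclass(frozen=True)
class RegressionFit:
    """Polynomial OLS fit: coefficients highest-degree-last per slot order.

    ``coefficients`` are ordered (slope..., intercept) for degree 1 —
    i.e. numpy polynomial convention, highest degree first.
    """

    coefficients: tuple[float, ...]
    degree: int
    r_squared: float
    standard_errors: tuple[float, ...]

    def __post_init__(self):
        if len(self.coefficients) != self.degree + 1:
            raise TTubuleError("coefficient count must equal degree + 1")


def polyfit_linest(x, y, degree: int = 1) -> RegressionFit:
    """Ordinary least-squares polynomial fit with classical standard errors.

    Reproduces spreadsheet LINEST output: coefficients (highest degree
    first), per-coefficient standard errors from the residual variance, and
    the coefficient of determination.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < degree + 1:
        raise TTubuleError(f"need >= {degree + 1} points for degree {degree}")
    X = np.vander(x, degree + 1)  # columns x^deg ... x^0
    if np.linalg.matrix_rank(X) < degree + 1:
        raise TTubuleError("rank-deficient design (collinear x values)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dof = n - degree - 1
    if dof > 0:
        sigma2 = ss_res / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = tuple(float(s) for s in np.sqrt(np.diag(cov)))
    else:
        se = tuple(0.0 for _ in beta)
    return RegressionFit(tuple(float(b) for b in beta), degree, max(0.0, min(1.0, r2)), se)


def fit_allometry(
    table: pd.DataFrame,
) -> tuple[RegressionFit, RegressionFit, AllometryCoefficients]:
    """Fit the two allometric lines from a morphometric table.

    Returns (fibre→myofibril fit, myofibril→furrow fit, coefficients) with
    the cubic somite polynomial left at its defaults.
    """
    if len(table) < 3:
        raise TTubuleError("need >= 3 rows to fit allometry")
    fit_myo = polyfit_linest(
        table["fibre_area_um2"], table["myofibril_area_um2"], degree=1
    )
    fit_furrow = polyfit_linest(
        table["myofibril_area_um2"], table["furrow_length_um"], degree=1
    )
    coeffs = AllometryCoefficients(
        myo_slope=fit_myo.coefficients[0],
        myo_intercept=fit_myo.coefficients[1],
        furrow_slope=fit_furrow.coefficients[0],
        furrow_intercept=fit_furrow.coefficients[1],
    )
    return fit_myo, fit_furrow, coeffs
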
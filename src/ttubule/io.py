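"""Readers and writers for the package's on-disk formats.

* multi-channel TIFF images with a JSON sidecar carrying channel names and
  the physical pixel size;
* ROI hierarchies as plain JSON polygons/polylines;
* circle/box ROI sets as JSON;
* flat key-value model configuration (YAML).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import InvalidInputError, ROIError
from .geometry import AllometryCoefficients, TubuleEllipse
from .image_quant import BoxROI, CircleROI, DomainROISet, IntensityImage
from .morphometrics import PolygonROI, PolylineROI, ROIHierarchy

__all__ = [
    "write_image",
    "read_image",
    "write_roi_hierarchy",
    "read_roi_hierarchy",
    "read_label_mask",
    "read_boxes",
    "read_circles",
    "load_model_config",
]


def write_image(path: str | Path, image: IntensityImage) -> None:
    """Write channels as a (C, H, W) TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    names = sorted(image.channels)
    stack = np.stack([image.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, stack)
    sidecar = {"channels": names, "pixel_size_um": image.pixel_size}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_image(
    path: str | Path,
    pixel_size: float | None = None,
    channel_names: list[str] | None = None,
) -> IntensityImage:
    """Read a TIFF; metadata comes from the sidecar unless given explicitly."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        pixel_size = pixel_size or meta.get("pixel_size_um")
        channel_names = channel_names or meta.get("channels")
    if pixel_size is None:
        raise InvalidInputError("pixel size not given and no sidecar found")
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(data.shape[0])]
    if len(channel_names) != data.shape[0]:
        raise InvalidInputError("channel name count does not match the stack")
    return IntensityImage(
        dict(zip(channel_names, data.astype(float))), pixel_size
    )


def write_roi_hierarchy(path: str | Path, hierarchy: ROIHierarchy) -> None:
    rois = []
    for r in list(hierarchy.fibres.values()) + list(hierarchy.myofibrils.values()):
        rois.append(
            {
                "id": r.id,
                "kind": r.kind,
                "parent_id": r.parent_id,
                "points": [list(p) for p in r.vertices],
            }
        )
    for f in hierarchy.furrows.values():
        rois.append(
            {
                "id": f.id,
                "kind": "furrow",
                "parent_id": f.parent_id,
                "points": [list(p) for p in f.points],
            }
        )
    Path(path).write_text(
        json.dumps({"pixel_size_um": hierarchy.pixel_size_um, "rois": rois}, indent=1)
    )


def read_roi_hierarchy(path: str | Path, trim: bool = False) -> ROIHierarchy:
    """Load an ROI JSON file.

    With ``trim=False`` (default) geometries are taken as already-trimmed
    and inserted verbatim; with ``trim=True`` each ROI passes through the
    trimming rules again, in file order.
    """
    doc = json.loads(Path(path).read_text())
    hier = ROIHierarchy(doc["pixel_size_um"])
    for r in doc["rois"]:
        pts = [tuple(p) for p in r["points"]]
        if r["kind"] == "furrow":
            roi = PolylineROI(r["id"], pts, parent_id=r["parent_id"])
        else:
            roi = PolygonROI(r["id"], pts, kind=r["kind"], parent_id=r.get("parent_id"))
        if trim:
            hier.add_roi(roi)
        else:
            if r["kind"] == "fibre":
                hier.fibres[roi.id] = roi
            elif r["kind"] == "myofibril":
                if roi.parent_id not in hier.fibres:
                    raise ROIError(f"myofibril {roi.id!r}: unknown fibre parent")
                hier.myofibrils[roi.id] = roi
            else:
                if roi.parent_id not in hier.myofibrils:
                    raise ROIError(f"furrow {roi.id!r}: unknown myofibril parent")
                hier.furrows[roi.id] = roi
    return hier


def read_label_mask(
    path_or_array, pixel_size_um: float = 1.0
) -> ROIHierarchy:
    """Import fibre ROIs from an integer-labelled 2D mask (TIFF or array).

    Each positive label becomes one fibre polygon traced around its pixel
    support.  Only fibres are imported; myofibrils and furrows are traced
    structures with no mask representation.
    """
    from skimage import measure

    if isinstance(path_or_array, (str, Path)):
        labels = tifffile.imread(path_or_array)
    else:
        labels = np.asarray(path_or_array)
    if labels.ndim != 2:
        raise InvalidInputError("label mask must be 2D")
    hier = ROIHierarchy(pixel_size_um)
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        contours = measure.find_contours((labels == lab).astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)  # (row, col) order
        verts = [(float(c), float(r)) for r, c in contour]
        hier.add_roi(PolygonROI(f"fibre{int(lab)}", verts))
    return hier


def read_boxes(path: str | Path) -> list[BoxROI]:
    doc = json.loads(Path(path).read_text())
    return [
        BoxROI(b["x0"], b["y0"], b["w"], b["h"], b.get("role", ""))
        for b in doc["boxes"]
    ]


def read_circles(path: str | Path) -> DomainROISet:
    doc = json.loads(Path(path).read_text())

    def circles(key):
        return [CircleROI(c["cx"], c["cy"], c["radius"]) for c in doc.get(key, [])]

    return DomainROISet(
        tt=circles("tt"), sl=circles("sl"), it=circles("it"),
        fibre_id=doc.get("fibre_id", ""),
    )


def load_model_config(path: str | Path | None) -> tuple[TubuleEllipse, AllometryCoefficients]:
    """Flat key-value config for the surface model; defaults where absent."""
    if path is None:
        return TubuleEllipse(), AllometryCoefficients()
    doc = yaml.safe_load(Path(path).read_text()) or {}
    ellipse = TubuleEllipse(
        d1=doc.get("d1_nm", 59.24),
        d2=doc.get("d2_nm", 96.47),
        sarcomere_s=doc.get("sarcomere_um", 1.9),
    )
    coeffs = AllometryCoefficients(
        myo_slope=doc.get("myo_slope", 0.95),
        myo_intercept=doc.get("myo_intercept", -13.55),
        furrow_slope=doc.get("furrow_slope", 1.26),
        furrow_intercept=doc.get("furrow_intercept", 6.06),
        somite_poly=tuple(doc.get("somite_poly", (0.2, -2.6, 17.0, 65.0))),
    )
    return ellipse, coeffs
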
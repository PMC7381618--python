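"""Seeded generators of ground-truthed synthetic inputs.

Two families of scenes stand in for the zebrafish imaging data:

* **fluorescence scenes** — two-channel confocal-like images of a striated
  fibre pair (an expressing cell beside a wildtype neighbour).  The general
  membrane channel ("caax") carries Gaussian-profile vertical stripes at
  the sarcomeric spacing (default 1.9 µm, apparent width 380 nm FWHM); the
  marker channel is piecewise-constant over the T-tubule / sarcolemma /
  inter-tubule domains at stated enrichments, so noiseless measurements
  recover the generating parameters exactly.  Noise is Poisson on the clean
  signal followed by additive Gaussian read noise.

* **morphometric scenes** — non-overlapping rectangular fibre ROIs, each
  containing a myofibril polygon and a serpentine furrow polyline whose
  exact areas/lengths follow the allometric relations (optionally with
  Gaussian scatter), for parameter-recovery tests of the tracing and
  fitting code.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError
from .geometry import AllometryCoefficients
from .image_quant import BoxROI, CircleROI, DomainROISet, IntensityImage
from .morphometrics import PolygonROI, PolylineROI, ROIHierarchy

__all__ = [
    "SceneParams",
    "SceneTruth",
    "MorphoSceneTruth",
    "make_fluorescence_scene",
    "make_morpho_scene",
    "make_marker_panel",
]


@dataclass(frozen=True)
class SceneParams:
    """Generative parameters of a two-cell striated fluorescence scene.

    Defaults emulate the measured biology: 1.9 µm inter-tubule spacing and
    an apparent tubule width of 380 nm at a 0.1 µm confocal pixel.
    Intensity levels are in arbitrary detector counts.
    """

    image_size_px: tuple[int, int] = (360, 110)  # (width, height)
    pixel_size_um: float = 0.1
    spacing_um: float = 1.9
    tubule_fwhm_um: float = 0.38
    sl_band: bool = True
    enrichment_tt: float = 2.0
    enrichment_sl: float = 1.5
    perturbation_factor: float = 1.0
    background_level: float = 100.0
    signal_level: float = 400.0
    poisson: bool = True
    gaussian_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.spacing_um <= self.tubule_fwhm_um:
            raise InvalidInputError("spacing must exceed the tubule width")
        if self.spacing_um / self.pixel_size_um < 2:
            raise InvalidInputError("spacing below 2 px cannot be rendered")
        if min(self.background_level, self.signal_level) < 0:
            raise InvalidInputError("intensity levels must be >= 0")
        if not 0 <= self.perturbation_factor <= 1:
            raise InvalidInputError("perturbation factor must lie in [0, 1]")


@dataclass
class SceneTruth:
    """Exact generative ground truth of one fluorescence scene."""

    params: SceneParams
    tubule_centers_px: dict[str, list[float]]  # per cell
    expressing_bounds: tuple[int, int]  # x range [x0, x1) of expressing cell
    wildtype_bounds: tuple[int, int]
    tt_mask: np.ndarray
    sl_mask: np.ndarray
    it_mask: np.ndarray
    expected_enrichment_tt: float
    expected_enrichment_sl: float
    expected_amplitude_percent: float

    def box(self, cell: str, n_tubules: int = 8) -> BoxROI:
        """Box spanning ``n_tubules`` stripes through the cell midline."""
        x0, x1 = (
            self.expressing_bounds if cell == "expressing" else self.wildtype_bounds
        )
        centers = self.tubule_centers_px[cell][:n_tubules]
        sp = self.params.spacing_um / self.params.pixel_size_um
        left = max(x0, int(math.floor(centers[0] - sp / 2)))
        right = min(x1, int(math.ceil(centers[-1] + sp / 2)))
        h = self.params.image_size_px[1]
        y0, y1 = int(h * 0.25), int(h * 0.75)
        return BoxROI(left, y0, right - left, y1 - y0, role=cell)

    def domain_rois(self, cell: str = "expressing", radius_px: int = 2) -> DomainROISet:
        """Circle ROIs centred on tubules (TT), between them (IT), on the SL band."""
        x0, x1 = (
            self.expressing_bounds if cell == "expressing" else self.wildtype_bounds
        )
        h = self.params.image_size_px[1]
        cy = h / 2.0
        centers = self.tubule_centers_px[cell]
        sp = self.params.spacing_um / self.params.pixel_size_um
        tt = [CircleROI(c, cy, radius_px) for c in centers[1:-1]]
        it = [CircleROI(c + sp / 2.0, cy, radius_px) for c in centers[1:-2]]
        band = _sl_band_px(self.params)
        sl = [
            CircleROI(c, band / 2.0, max(1, band // 2)) for c in centers[1:-1]
        ]
        return DomainROISet(tt=tt, sl=sl, it=it, fibre_id=cell)


def _sl_band_px(params: SceneParams) -> int:
    return max(2, round(params.tubule_fwhm_um / params.pixel_size_um))


def _stripe_profile(w: int, centers: np.ndarray, fwhm_px: float) -> np.ndarray:
    """Sum of unit-height Gaussians at the given centres, evaluated per column."""
    x = np.arange(w) + 0.5
    sigma = fwhm_px / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    prof = np.zeros(w)
    for c in centers:
        prof += np.exp(-0.5 * ((x - c) / sigma) ** 2)
    return np.clip(prof, 0.0, 1.0)


def make_fluorescence_scene(params: SceneParams) -> tuple[IntensityImage, SceneTruth]:
    """Render the two-cell scene and its exact ground truth.

    The "caax" channel carries the stripe pattern (contrast scaled by the
    perturbation factor in the expressing cell); the "marker" channel is
    piecewise-constant at ``background + signal·enrichment`` over each
    domain.  Identical parameters (seed included) give bit-identical output.
    """
    w, h = params.image_size_px
    px = params.pixel_size_um
    sp = params.spacing_um / px
    fwhm = params.tubule_fwhm_um / px
    gap = max(4, int(round(sp / 4)))
    half = (w - gap) // 2
    bounds = {"expressing": (0, half), "wildtype": (half + gap, w)}

    centers: dict[str, list[float]] = {}
    tt_mask = np.zeros((h, w), dtype=bool)
    band = _sl_band_px(params)
    sl_mask = np.zeros((h, w), dtype=bool)
    cell_mask = np.zeros((h, w), dtype=bool)
    stripe = np.zeros(w)
    for cell, (x0, x1) in bounds.items():
        cs = np.arange(x0 + sp, x1 - sp / 2.0, sp)
        centers[cell] = [float(c) for c in cs]
        stripe[x0:x1] = _stripe_profile(x1 - x0, cs - x0, fwhm)
        cell_mask[:, x0:x1] = True
        if params.sl_band:
            sl_mask[:band, x0:x1] = True
            sl_mask[h - band :, x0:x1] = True
        for c in cs:
            lo = int(math.floor(c - fwhm / 2))
            hi = int(math.ceil(c + fwhm / 2))
            tt_mask[:, max(x0, lo) : min(x1, hi)] = True
    tt_mask &= cell_mask & ~sl_mask
    it_mask = cell_mask & ~tt_mask & ~sl_mask

    # caax channel: stripes, expressing-side contrast scaled
    contrast = np.where(
        np.arange(w) < half, params.perturbation_factor, 1.0
    ) * cell_mask.any(axis=0)
    caax = params.background_level + params.signal_level * stripe * contrast
    caax = np.tile(caax, (h, 1))
    if params.sl_band:
        caax = np.where(sl_mask, params.background_level + params.signal_level, caax)

    # marker channel: piecewise-constant domain levels, IT baseline =
    # signal_level, so the ratio of domain means equals the enrichment
    # exactly; background only outside the cells
    marker = np.full((h, w), params.background_level)
    marker = np.where(it_mask, params.signal_level, marker)
    marker = np.where(tt_mask, params.signal_level * params.enrichment_tt, marker)
    marker = np.where(sl_mask, params.signal_level * params.enrichment_sl, marker)

    rng = np.random.default_rng(params.seed)
    channels = {}
    for name, clean in (("caax", caax), ("marker", marker)):
        noisy = clean.astype(float)
        if params.poisson:
            noisy = rng.poisson(noisy).astype(float)
        if params.gaussian_sd > 0:
            noisy = noisy + rng.normal(0.0, params.gaussian_sd, size=noisy.shape)
        channels[name] = np.clip(noisy, 0.0, None)

    truth = SceneTruth(
        params=params,
        tubule_centers_px=centers,
        expressing_bounds=bounds["expressing"],
        wildtype_bounds=bounds["wildtype"],
        tt_mask=tt_mask,
        sl_mask=sl_mask,
        it_mask=it_mask,
        expected_enrichment_tt=params.enrichment_tt,
        expected_enrichment_sl=params.enrichment_sl,
        expected_amplitude_percent=100.0 * params.perturbation_factor,
    )
    return IntensityImage(channels, px), truth


@dataclass
class MorphoSceneTruth:
    """Analytic areas/lengths of a generated ROI hierarchy."""

    pixel_size_um: float
    fibre_areas_um2: dict[str, float]
    myofibril_areas_um2: dict[str, float]
    furrow_lengths_um: dict[str, float]
    coeffs: AllometryCoefficients
    noise_sd: float
    seed: int


def _serpentine(x0, y0, w, h, target_len):
    """Zig-zag polyline of exact ``target_len`` inside the box (px units)."""
    n_rows = max(1, math.ceil(target_len / w))
    row_gap = min(4.0, h / n_rows) if n_rows > 1 else 0.0
    pts = [(x0, y0)]
    remaining = target_len
    x, y = x0, y0
    direction = 1
    while remaining > 0:
        run = min(remaining, w)
        nx = x + direction * run
        pts.append((nx, y))
        remaining -= run
        x = nx
        if remaining <= 0:
            break
        step = min(remaining, row_gap)
        if step <= 0 or y + step > y0 + h:
            raise InvalidInputError("furrow does not fit inside its myofibril")
        y += step
        pts.append((x, y))
        remaining -= step
        direction *= -1
    return pts


def make_morpho_scene(
    n_fibres: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    coeffs: AllometryCoefficients = AllometryCoefficients(),
    pixel_size_um: float = 0.25,
    fibre_area_range_um2: tuple[float, float] = (60.0, 600.0),
) -> tuple[ROIHierarchy, MorphoSceneTruth]:
    """Lay out ``n_fibres`` rectangular fibres with nested myofibrils/furrows.

    Fibre areas are drawn uniformly from ``fibre_area_range_um2``; each
    myofibril area follows ``myo_slope·A + myo_intercept`` and each furrow
    length ``furrow_slope·M + furrow_intercept``, plus N(0, noise_sd²)
    scatter when requested.  Geometry realises the drawn values exactly, so
    the recorded truth is an analytic property of the generated polygons.
    """
    if n_fibres < 1:
        raise InvalidInputError("need at least one fibre")
    rng = np.random.default_rng(seed)
    px = pixel_size_um
    hier = ROIHierarchy(px)
    truth = MorphoSceneTruth(px, {}, {}, {}, coeffs, noise_sd, seed)

    cursor_x = 0.0  # fibres placed in one non-overlapping row
    for i in range(n_fibres):
        A = float(rng.uniform(*fibre_area_range_um2))
        M = coeffs.myo_slope * A + coeffs.myo_intercept
        F = coeffs.furrow_slope * M + coeffs.furrow_intercept
        if noise_sd > 0:
            M += float(rng.normal(0.0, noise_sd))
            F += float(rng.normal(0.0, noise_sd))
        M = max(M, 1.0)
        F = max(F, 1.0)
        # the fibre rectangle must wrap the myofibril with a 1 px border
        margin = 4.0 * px * math.sqrt(M) + 4.0 * px * px + 1.0
        if M > A - margin:
            M = A - margin

        # myofibril first (square of exact area M), fibre wraps around it
        mw = math.sqrt(M) / px
        mh = (M / px**2) / mw
        fw = mw + 2.0
        fh = (A / px**2) / fw
        if fh < mh + 2.0:  # very small allometric gap: stretch the fibre
            fh = mh + 2.0
            fw = (A / px**2) / fh
            mw = fw - 2.0
            mh = (M / px**2) / mw
        gx, gy = cursor_x, 0.0
        cursor_x += fw + 8.0
        fid = f"fibre{i}"
        hier.add_roi(
            PolygonROI(fid, [(gx, gy), (gx + fw, gy), (gx + fw, gy + fh), (gx, gy + fh)])
        )
        truth.fibre_areas_um2[fid] = A
        mx, my = gx + 1.0, gy + 1.0
        hier.add_roi(
            PolygonROI(
                "candidate",
                [(mx, my), (mx + mw, my), (mx + mw, my + mh), (mx, my + mh)],
                kind="myofibril",
                parent_id=fid,
            )
        )
        mid = f"{fid}-myo0"
        truth.myofibril_areas_um2[mid] = M
        # furrow: serpentine of exact length F inside the myofibril
        pts = _serpentine(mx + 1.0, my + 1.0, mw - 2.0, mh - 2.0, F / px)
        hier.add_roi(PolylineROI("candidate", pts, parent_id=mid))
        truth.furrow_lengths_um[f"{mid}-furrow0"] = F
    return hier, truth


def make_marker_panel(
    enrichments: list[float],
    params: SceneParams = SceneParams(),
    seed: int = 0,
    names: list[str] | None = None,
) -> list[tuple[str, IntensityImage, SceneTruth]]:
    """One scene per marker, common geometry, per-marker TT enrichment."""
    if len(enrichments) < 2:
        raise InvalidInputError("need at least two markers for a panel")
    if names is None:
        names = [f"marker{i:02d}" for i in range(len(enrichments))]
    if len(names) != len(enrichments):
        raise InvalidInputError("names and enrichments must align")
    rng = np.random.default_rng(seed)
    panel = []
    for name, enr in zip(names, enrichments):
        p = replace(params, enrichment_tt=enr, seed=int(rng.integers(0, 2**31 - 1)))
        img, truth = make_fluorescence_scene(p)
        panel.append((name, img, truth))
    return panel
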
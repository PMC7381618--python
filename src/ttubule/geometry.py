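"""Closed-form geometric model of T-tubule and sarcolemmal membrane area.

A skeletal muscle fibre is idealised as a perfect cylinder of length ``L``
(µm) and diameter ``D`` (µm).  T-tubules run transversely at every Z-line
(one per sarcomere of length ``s``), threading through the furrows between
myofibrils.  Two empirical allometric regressions link fibre size to tubule
length:

* myofibril cross-sectional area  M = 0.95·C − 13.55   (C = fibre area, µm²)
* combined furrow length per Z-line  F = 1.26·M + 6.06  (µm)

Each tubule is an elliptical cylinder whose cross-sectional perimeter is
given by Ramanujan's approximation for the ellipse with axes ``d1``, ``d2``
(nm).  Total T-tubule surface area is then

    SA_TT = perimeter · (L/s) · F(M(C))        [µm²]

and the sarcolemma is the cylinder wall plus two end caps,

    SA_SL = 2π(D/2)² + 2πL(D/2).               [µm²]

The intercept — the fibre size at which the internal T-system equals the
plasma membrane in area — follows in closed form from equating the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainValidityError, InvalidInputError

__all__ = [
    "FibreGeometry",
    "TubuleEllipse",
    "AllometryCoefficients",
    "SurfaceAreaResult",
    "StagePreset",
    "STAGE_PRESETS",
    "NO_INTERCEPT",
    "myofibril_cross_section",
    "furrow_length_per_zline",
    "zline_count",
    "tubule_perimeter",
    "tt_surface_area",
    "sarcolemma_surface_area",
    "surface_summary",
    "membrane_addition_rate",
    "intercept_length",
    "intercept_diameter",
    "diameter_from_area",
    "area_from_diameter",
    "somite_width",
]


def diameter_from_area(C: float) -> float:
    """Diameter (µm) of the circle with area ``C`` (µm²)."""
    if C <= 0:
        raise InvalidInputError(f"cross-sectional area must be positive, got {C}")
    return 2.0 * math.sqrt(C / math.pi)


def area_from_diameter(D: float) -> float:
    """Area (µm²) of the circle with diameter ``D`` (µm)."""
    if D <= 0:
        raise InvalidInputError(f"diameter must be positive, got {D}")
    return math.pi * (D / 2.0) ** 2


@dataclass(frozen=True)
class FibreGeometry:
    """Cylindrical fibre: length (µm) plus diameter (µm) or area (µm²).

    Exactly one of ``diameter_D`` / ``cross_section_C`` may be omitted;
    the missing one is derived assuming a circular cross-section.
    """

    length_L: float
    diameter_D: float | None = None
    cross_section_C: float | None = None

    def __post_init__(self):
        if self.length_L < 0:
            raise InvalidInputError(f"fibre length must be >= 0, got {self.length_L}")
        if self.diameter_D is None and self.cross_section_C is None:
            raise InvalidInputError("need diameter_D or cross_section_C")
        if self.diameter_D is None:
            object.__setattr__(
                self, "diameter_D", diameter_from_area(self.cross_section_C)
            )
        elif self.cross_section_C is None:
            object.__setattr__(
                self, "cross_section_C", area_from_diameter(self.diameter_D)
            )
        if self.diameter_D <= 0 or self.cross_section_C <= 0:
            raise InvalidInputError("fibre dimensions must be strictly positive")


@dataclass(frozen=True)
class TubuleEllipse:
    """Elliptical tubule cross-section axes (nm) and sarcomere length (µm).

    Defaults are the empirically measured zebrafish values.
    """

    d1: float = 59.24
    d2: float = 96.47
    sarcomere_s: float = 1.9

    def __post_init__(self):
        if self.d1 <= 0 or self.d2 <= 0:
            raise InvalidInputError("tubule axes must be positive")
        if self.sarcomere_s <= 0:
            raise InvalidInputError("sarcomere length must be positive")


@dataclass(frozen=True)
class AllometryCoefficients:
    """Empirical regression constants tying fibre size to tubule length.

    ``myo_*``:    myofibril area (µm²) vs fibre area (µm²), linear.
    ``furrow_*``: furrow length per Z-line (µm) vs myofibril area, linear.
    ``somite_poly``: cubic in days post fertilisation giving somite width (µm),
    highest degree first.
    """

    myo_slope: float = 0.95
    myo_intercept: float = -13.55
    furrow_slope: float = 1.26
    furrow_intercept: float = 6.06
    somite_poly: tuple[float, float, float, float] = (0.2, -2.6, 17.0, 65.0)


@dataclass(frozen=True)
class SurfaceAreaResult:
    """Predicted areas (µm²) for one fibre: T-system, sarcolemma and ratios."""

    tt_area: float
    sl_area: float

    @property
    def total(self) -> float:
        return self.tt_area + self.sl_area

    @property
    def tt_fraction(self) -> float:
        return self.tt_area / self.total

    @property
    def ratio_tt_to_sl(self) -> float:
        return self.tt_area / self.sl_area


@dataclass(frozen=True)
class StagePreset:
    stage_name: str
    length_L: float
    cross_section_C: float

    @property
    def geometry(self) -> FibreGeometry:
        return FibreGeometry(self.length_L, cross_section_C=self.cross_section_C)


#: Maximum fibre dimensions at the modelled developmental stages.
STAGE_PRESETS: tuple[StagePreset, ...] = (
    StagePreset("48 hpf", 90.23, 192.04),
    StagePreset("5 dpf", 107.77, 290.42),
    StagePreset("10 dpf", 158.83, 560.86),
    StagePreset("adult", 580.0, 1256.64),
)

#: Sentinel returned when the two membrane areas never meet at positive size.
NO_INTERCEPT = None


def myofibril_cross_section(
    C: float, coeffs: AllometryCoefficients = AllometryCoefficients()
) -> float:
    """Myofibril cross-sectional area (µm²) from fibre area ``C`` (µm²)."""
    if C <= 0:
        raise InvalidInputError(f"fibre cross-section must be positive, got {C}")
    M = coeffs.myo_slope * C + coeffs.myo_intercept
    if M <= 0:
        raise DomainValidityError(
            f"fibre area {C} µm² is below the allometric validity range "
            f"(myofibril area would be {M:.4g} µm²)",
            value=C,
        )
    return M


def furrow_length_per_zline(
    M: float, coeffs: AllometryCoefficients = AllometryCoefficients()
) -> float:
    """Combined furrow (= T-tubule) length at one Z-line (µm)."""
    if M < 0:
        raise InvalidInputError(f"myofibril area must be >= 0, got {M}")
    return coeffs.furrow_slope * M + coeffs.furrow_intercept


def zline_count(L: float, s: float) -> float:
    """Number of Z-lines in a fibre of length ``L``: L/s, real-valued."""
    if s <= 0:
        raise InvalidInputError(f"sarcomere length must be positive, got {s}")
    if L < 0:
        raise InvalidInputError(f"fibre length must be >= 0, got {L}")
    return L / s


def tubule_perimeter(ellipse: TubuleEllipse = TubuleEllipse()) -> float:
    """Ramanujan perimeter of the tubule ellipse, converted nm → µm."""
    a = ellipse.d1 / 2.0
    b = ellipse.d2 / 2.0
    p_nm = math.pi * (3.0 * (a + b) - math.sqrt((3.0 * a + b) * (a + 3.0 * b)))
    return p_nm / 1000.0


def tt_surface_area(
    geom: FibreGeometry,
    ellipse: TubuleEllipse = TubuleEllipse(),
    coeffs: AllometryCoefficients = AllometryCoefficients(),
) -> float:
    """Total T-tubule surface area (µm²) of one fibre.

    Composed as perimeter × Z-line count × furrow length per Z-line; the
    furrow intercept sits inside the bracket multiplied by L/s.
    """
    if geom.length_L == 0:
        return 0.0
    M = myofibril_cross_section(geom.cross_section_C, coeffs)
    F = furrow_length_per_zline(M, coeffs)
    n = zline_count(geom.length_L, ellipse.sarcomere_s)
    return tubule_perimeter(ellipse) * n * F


def sarcolemma_surface_area(geom: FibreGeometry) -> float:
    """Sarcolemmal area (µm²): cylinder wall plus two end caps."""
    r = geom.diameter_D / 2.0
    return 2.0 * math.pi * r * r + 2.0 * math.pi * geom.length_L * r


def surface_summary(
    geom: FibreGeometry,
    ellipse: TubuleEllipse = TubuleEllipse(),
    coeffs: AllometryCoefficients = AllometryCoefficients(),
) -> SurfaceAreaResult:
    """Both membrane areas for one fibre, packaged with fraction and ratio."""
    return SurfaceAreaResult(
        tt_area=tt_surface_area(geom, ellipse, coeffs),
        sl_area=sarcolemma_surface_area(geom),
    )


def membrane_addition_rate(
    summary_a: SurfaceAreaResult,
    summary_b: SurfaceAreaResult,
    elapsed_minutes: float,
) -> float:
    """Mean rate of total membrane growth between two states (µm²/min)."""
    if elapsed_minutes <= 0:
        raise InvalidInputError(
            f"elapsed time must be positive, got {elapsed_minutes}"
        )
    return (summary_b.total - summary_a.total) / elapsed_minutes


def _tt_slope_per_length(
    D: float, ellipse: TubuleEllipse, coeffs: AllometryCoefficients
) -> float:
    """d(SA_TT)/dL at fixed diameter: perimeter/s × furrow(myofibril(C))."""
    C = area_from_diameter(D)
    M = coeffs.myo_slope * C + coeffs.myo_intercept
    F = coeffs.furrow_slope * M + coeffs.furrow_intercept
    return tubule_perimeter(ellipse) / ellipse.sarcomere_s * F


def intercept_length(
    D: float,
    ellipse: TubuleEllipse = TubuleEllipse(),
    coeffs: AllometryCoefficients = AllometryCoefficients(),
) -> float | None:
    """Fibre length at which SA_TT equals SA_SL for diameter ``D`` (µm).

    Equating the closed forms gives L·g(D) = πD²/2 + πLD with
    g(D) = d(SA_TT)/dL, hence L = (πD²/2)/(g(D) − πD).  Returns
    ``NO_INTERCEPT`` (None) when the solution is non-positive (short, thin
    fibres whose tubule system can never catch the sarcolemma).

    Exact (unrounded) coefficients are used throughout so the two areas
    agree to machine precision at the returned length.
    """
    if D <= 0:
        raise InvalidInputError(f"diameter must be positive, got {D}")
    g = _tt_slope_per_length(D, ellipse, coeffs)
    denom = g - math.pi * D
    if denom <= 0:
        return NO_INTERCEPT
    L = (math.pi * D * D / 2.0) / denom
    return L if L > 0 else NO_INTERCEPT


def intercept_diameter(
    L: float,
    ellipse: TubuleEllipse = TubuleEllipse(),
    coeffs: AllometryCoefficients = AllometryCoefficients(),
) -> float | None:
    """Fibre diameter at which SA_TT equals SA_SL for length ``L`` (µm).

    Substituting C = π(D/2)² turns the equality into a quadratic in D:

        (k·mπ/4 − π/2)·D² − πL·D − L·k·c0 = 0

    with k = perimeter·L/s per furrow-µm, m and c0 the composed allometry
    slope/intercept.  Returns the unique positive root or ``NO_INTERCEPT``;
    if both roots were positive the smaller is returned with a warning.
    """
    if L <= 0:
        raise InvalidInputError(f"length must be positive, got {L}")
    p = tubule_perimeter(ellipse)
    m = coeffs.furrow_slope * coeffs.myo_slope  # composed slope on C
    c0 = coeffs.furrow_slope * coeffs.myo_intercept + coeffs.furrow_intercept
    k = p * L / ellipse.sarcomere_s
    a = k * m * math.pi / 4.0 - math.pi / 2.0
    b = -math.pi * L
    c = k * c0
    if a == 0:
        if b == 0:
            return NO_INTERCEPT
        D = -c / b
        return D if D > 0 else NO_INTERCEPT
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return NO_INTERCEPT
    sq = math.sqrt(disc)
    roots = sorted(r for r in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)) if r > 0)
    if not roots:
        return NO_INTERCEPT
    if len(roots) > 1:
        import warnings

        warnings.warn(
            "both intercept roots positive; returning the smaller", stacklevel=2
        )
    return roots[0]


def somite_width(
    dpf: float, coeffs: AllometryCoefficients = AllometryCoefficients()
) -> float:
    """Somite width (µm, a proxy for fibre length) from the cubic regression.

    The published cubic coefficients are rounded, so widths computed here
    differ by a few percent from the canonical stage presets at 5 and 10 dpf;
    the presets are authoritative for the stage table.
    """
    if dpf < 0:
        raise InvalidInputError(f"dpf must be >= 0, got {dpf}")
    a3, a2, a1, a0 = coeffs.somite_poly
    return ((a3 * dpf + a2) * dpf + a1) * dpf + a0
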
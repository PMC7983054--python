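"""Quadratic-Stark conic solver for the in-plane chromophore field.

The dipole-moment change of the chromophore responds linearly to the
protein field in the principal frame of the polarizability-change tensor:

    Δμx = Δμ0x + Δαxx·Ex,      Δμy = Δμ0y + Δαyy·Ey,

so the field follows from the solved Δμ components,

    Ex = (Δμx − Δμ0x)/Δαxx,    Ey = (Δμy − Δμ0y)/Δαyy.

Two measurements constrain (Δμx, Δμy): the Stark-shifted 0–0 absorption
wavenumber ν̄ places it on a conic (hyperbola for mixed-sign Δα),

    Δμx²/Δαxx + Δμy²/Δαyy = Δμ0x²/Δαxx + Δμ0y²/Δαyy − 2hc(ν̄ − ν̄0),

and the 2PA-derived magnitude |Δμ| places it on a circle.  The pair is a
linear 2×2 system in the squared components, giving up to four
sign-symmetric candidates; quadrant disambiguation uses the known
direction of the transition dipole μ (β prior, a bidirectional axis) and
optionally a prior on the field itself (e.g. from MD simulation).

Coordinate convention: x runs along the line joining the imidazolinone
and phenolate ring centers (positive Ex points from imidazolinone toward
phenolate), y is the in-plane perpendicular toward the acylimine.  The
chromophore is taken as planar.

Unit bookkeeping: D²/Å³ = 1e-12 erg, so the conic is solved directly in
Debye/Å³ practical units with the 2hcΔν̄ term rescaled by 1e12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .units import CONSTANTS

__all__ = [
    "VacuumChromophore",
    "DipoleCandidate",
    "FieldEstimate",
    "conic_candidates",
    "select_candidate",
    "field_from_dipole",
    "dipole_from_field",
    "stark_frequency",
    "critical_flip_field",
    "MVCM_PER_D_PER_A3",
]

# 1 D/A^3 = 1e6 statvolt/cm = 299.792458 MV/cm
MVCM_PER_D_PER_A3 = CONSTANTS.statvolt_per_cm_in_V_per_cm
_D2_PER_A3_IN_ERG = 1e-12


@dataclass(frozen=True)
class VacuumChromophore:
    """QM-derived constants of the isolated (vacuum) RFP chromophore.

    Defaults are the ZINDO/PR-CIS(Ds) values for the planar anionic
    acylimine-extended chromophore: Δμ0 = (5.53, −3.17) D,
    Δα = diag(−61.3, 6.9) Å³, ν̄0 = 16,260 cm⁻¹.
    """

    dmu0_x: float = 5.53      # D
    dmu0_y: float = -3.17     # D
    dalpha_xx: float = -61.3  # A^3
    dalpha_yy: float = 6.9    # A^3
    nu0: float = 16260.0      # cm^-1

    def __post_init__(self) -> None:
        if self.dalpha_xx == 0 or self.dalpha_yy == 0:
            raise ValueError("polarizability-change components must be nonzero")
        if self.dalpha_xx == self.dalpha_yy:
            raise ValueError(
                "degenerate dalpha_xx == dalpha_yy: circle-circle system has "
                "no unique squared-component solution"
            )
        if not self.nu0 > 0:
            raise ValueError("vacuum transition wavenumber must be positive")

    @property
    def dmu0_abs(self) -> float:
        return math.hypot(self.dmu0_x, self.dmu0_y)


def _quadrant(x: float, y: float) -> str:
    if x >= 0:
        return "I" if y >= 0 else "IV"
    return "II" if y >= 0 else "III"


@dataclass(frozen=True)
class DipoleCandidate:
    dmu_x: float               # D
    dmu_y: float               # D
    quadrant: str
    delta_angle: float         # deg, angle of Δμ to +x axis in (−180, 180]
    mu_directions: Optional[tuple[float, float]] = None  # deg, δ ± γ


@dataclass(frozen=True)
class FieldEstimate:
    ex: float                  # MV/cm
    ey: float                  # MV/cm
    ex_sd: Optional[float] = None
    ey_sd: Optional[float] = None
    chosen_quadrant: Optional[str] = None
    selection_rule: Optional[str] = None


def conic_candidates(dmu_abs: float, nu: float,
                     ref: VacuumChromophore) -> list[DipoleCandidate]:
    """All real intersections of the Stark conic and the |Δμ| circle.

    Returns up to four sign combinations; mirror candidates collapse when
    a squared component is exactly zero.  Raises when the circle misses
    the conic (either squared component negative beyond a 1e-9·|Δμ|²
    tolerance), reporting both residuals.
    """
    if not dmu_abs > 0:
        raise ValueError(f"|dmu| must be positive, got {dmu_abs}")
    if not nu > 0:
        raise ValueError(f"transition wavenumber must be positive, got {nu}")
    r2 = dmu_abs * dmu_abs
    rhs = (
        ref.dmu0_x ** 2 / ref.dalpha_xx
        + ref.dmu0_y ** 2 / ref.dalpha_yy
        - 2.0 * CONSTANTS.hc * (nu - ref.nu0) / _D2_PER_A3_IN_ERG
    )
    inv_xx = 1.0 / ref.dalpha_xx
    inv_yy = 1.0 / ref.dalpha_yy
    # a + b = r2 ; a*inv_xx + b*inv_yy = rhs  with a = dmu_x^2, b = dmu_y^2
    a = (rhs - r2 * inv_yy) / (inv_xx - inv_yy)
    b = r2 - a
    tol = 1e-9 * r2
    if a < -tol or b < -tol:
        raise ValueError(
            "no real intersection of the Stark conic and the |dmu| circle: "
            f"dmu_x^2 = {a:.6g} D^2, dmu_y^2 = {b:.6g} D^2"
        )
    a = max(a, 0.0)
    b = max(b, 0.0)
    x0, y0 = math.sqrt(a), math.sqrt(b)
    xs = (x0, -x0) if x0 > 0 else (0.0,)
    ys = (y0, -y0) if y0 > 0 else (0.0,)
    out = []
    for x in xs:
        for y in ys:
            out.append(
                DipoleCandidate(
                    dmu_x=x,
                    dmu_y=y,
                    quadrant=_quadrant(x, y),
                    delta_angle=math.degrees(math.atan2(y, x)),
                )
            )
    return out


def _axis_distance(a: float, b: float) -> float:
    """Angular distance between two bidirectional axes, degrees in [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


_QUADRANT_PREFERENCE = {"IV": 0, "I": 1, "II": 2, "III": 3}


def select_candidate(
    candidates: Sequence[DipoleCandidate],
    gamma: float,
    beta_prior: float = -10.0,
    field_prior: Optional[tuple[float, float]] = None,
    ref: Optional[VacuumChromophore] = None,
) -> DipoleCandidate:
    """Pick the physically plausible Δμ candidate.

    For each candidate the two admissible transition-dipole axes are
    δ ± γ; the score is the smaller axial distance to ``beta_prior``
    (degrees, normalized by 90).  If ``field_prior`` = (Ex, Ey) in MV/cm
    is given (``ref`` then required), the Euclidean distance of the
    candidate's implied field to the prior, normalized by the prior's
    norm, is added.  Ties break toward quadrant IV.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    scored = []
    for cand in candidates:
        dirs = (cand.delta_angle + gamma, cand.delta_angle - gamma)
        angle_score = min(_axis_distance(d, beta_prior) for d in dirs) / 90.0
        rule = f"beta prior {beta_prior} deg"
        score = angle_score
        if field_prior is not None:
            if ref is None:
                raise ValueError("field_prior requires the vacuum reference")
            est = field_from_dipole(cand.dmu_x, cand.dmu_y, ref)
            norm = math.hypot(*field_prior)
            if norm == 0:
                raise ValueError("field_prior must be nonzero")
            score += math.hypot(est.ex - field_prior[0],
                                est.ey - field_prior[1]) / norm
            rule += f" + field prior {field_prior} MV/cm"
        scored.append((score, _QUADRANT_PREFERENCE.get(cand.quadrant, 9),
                       rule, cand))
    scored.sort(key=lambda t: (round(t[0], 9), t[1]))
    _, _, rule, best = scored[0]
    dirs = (best.delta_angle + gamma, best.delta_angle - gamma)
    return DipoleCandidate(
        dmu_x=best.dmu_x,
        dmu_y=best.dmu_y,
        quadrant=best.quadrant,
        delta_angle=best.delta_angle,
        mu_directions=dirs,
    )


def field_from_dipole(dmu_x: float, dmu_y: float, ref: VacuumChromophore,
                      dmu_rel_err: Optional[float] = None,
                      quadrant: Optional[str] = None,
                      rule: Optional[str] = None) -> FieldEstimate:
    """In-plane field components (MV/cm) from Δμ components (D).

    When ``dmu_rel_err`` is given, first-order uncertainties are
    propagated through the linear relations (the error on the vacuum
    constants is not modelled).
    """
    ex_da3 = (dmu_x - ref.dmu0_x) / ref.dalpha_xx
    ey_da3 = (dmu_y - ref.dmu0_y) / ref.dalpha_yy
    ex = ex_da3 * MVCM_PER_D_PER_A3
    ey = ey_da3 * MVCM_PER_D_PER_A3
    ex_sd = ey_sd = None
    if dmu_rel_err is not None:
        ex_sd = abs(dmu_rel_err * dmu_x / ref.dalpha_xx) * MVCM_PER_D_PER_A3
        ey_sd = abs(dmu_rel_err * dmu_y / ref.dalpha_yy) * MVCM_PER_D_PER_A3
    return FieldEstimate(ex=ex, ey=ey, ex_sd=ex_sd, ey_sd=ey_sd,
                         chosen_quadrant=quadrant or _quadrant(dmu_x, dmu_y),
                         selection_rule=rule)


def dipole_from_field(ex: float, ey: float,
                      ref: VacuumChromophore) -> tuple[float, float]:
    """Forward linear response: Δμ components (D) at a field (MV/cm)."""
    ex_da3 = ex / MVCM_PER_D_PER_A3
    ey_da3 = ey / MVCM_PER_D_PER_A3
    return (ref.dmu0_x + ref.dalpha_xx * ex_da3,
            ref.dmu0_y + ref.dalpha_yy * ey_da3)


def stark_frequency(ex: float, ey: float, ref: VacuumChromophore) -> float:
    """0–0 absorption wavenumber (cm⁻¹) of the chromophore at field (MV/cm).

    Quadratic Stark shift: hcν̄ = hcν̄0 − Δμ0·E − ½ E·Δα·E.
    """
    ex_da3 = ex / MVCM_PER_D_PER_A3
    ey_da3 = ey / MVCM_PER_D_PER_A3
    shift_d2a3 = (
        ref.dmu0_x * ex_da3
        + ref.dmu0_y * ey_da3
        + 0.5 * ref.dalpha_xx * ex_da3 ** 2
        + 0.5 * ref.dalpha_yy * ey_da3 ** 2
    )
    return ref.nu0 - shift_d2a3 * _D2_PER_A3_IN_ERG / CONSTANTS.hc


def critical_flip_field(ref: VacuumChromophore) -> float:
    """Field Ex* (MV/cm) at which Δμx changes sign: Ex* = −Δμ0x/Δαxx."""
    return -ref.dmu0_x / ref.dalpha_xx * MVCM_PER_D_PER_A3
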
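"""Field-modulated Marcus model of TICT quenching.

The nonradiative decay of the RFP chromophore is treated as a twisted
intramolecular charge transfer (TICT) whose rate obeys high-temperature
Marcus kinetics,

    kNR = B · exp(−(ΔG⁰ + λ)² / (4 λ kB T)),

where the driving force combines a vacuum term with the electrostatic
work done on the transferred charge q moving by (Δx, Δy) against the
protein field:

    ΔG⁰ = ΔG⁰_vac − q·Δx·(Ex + η·Ey),      η = Δy/Δx.

ln kNR is therefore a quadratic in the collective field variable
x = Ex + η·Ey with coefficients

    b0 = ln B − λ/(4kBT) − ΔG⁰_vac/(2kBT) − (ΔG⁰_vac)²/(4λkBT),
    b1 = qΔx/(2kBT) · (1 + ΔG⁰_vac/λ),
    b2 = −(qΔx)²/(4λkBT).

Fitting the quadratic at each η on a grid and minimizing the residual sum
of squares selects η; inverting the coefficient algebra with literature
values of q and ΔG⁰_vac then yields λ, Δx and B.  The inversion reduces to
a quadratic in u = qΔx/(2kBT):

    u² − b1·u − (ΔG⁰_vac/kBT)·b2 = 0,

whose positive root corresponds to Δx > 0 (charge flowing from the
phenolate toward the imidazolinone/acylimine end).  Substituting the
extracted parameters back into the b-expressions reproduces the input
coefficients exactly, which is used as a round-trip check throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fieldsolver import VacuumChromophore, dipole_from_field, stark_frequency
from .units import CONSTANTS, thermal_energy

__all__ = [
    "MarcusConstants",
    "QuadraticFieldFit",
    "MarcusParameters",
    "electrostatic_energy",
    "marcus_rate",
    "eta_scan_fit",
    "extract_tict_parameters",
    "coefficients_from_parameters",
    "coupling_from_prefactor",
    "design_surfaces",
    "DEFAULT_ETA_GRID",
]

# 1 MV/cm in statvolt/cm
_MVCM = 1e6 / CONSTANTS.statvolt_per_cm_in_V_per_cm
DEFAULT_ETA_GRID = tuple(np.round(np.arange(-0.20, 0.1001, 0.05), 10))


@dataclass(frozen=True)
class MarcusConstants:
    """Literature constants of the TICT charge-transfer step.

    q = 0.32 e is the transferred charge and ΔG⁰_vac the vacuum free-energy
    change of the P-twist, both from excited-state QM of the isolated
    chromophore; T defaults to ambient (298.15 K).
    """

    q: float = 1.54e-10          # esu
    dG_vac: float = -7.9         # kcal/mol
    T: float = 298.15            # K

    def __post_init__(self) -> None:
        if not self.q > 0:
            raise ValueError("transferred charge must be positive")
        if not self.T > 0:
            raise ValueError("temperature must be positive")

    @property
    def kBT_kcal(self) -> float:
        return thermal_energy(self.T).kcal_per_mol

    @property
    def kBT_erg(self) -> float:
        return thermal_energy(self.T).erg


def electrostatic_energy(ex: float, ey: float, q: float, dx: float,
                         eta: float) -> float:
    """ΔU = −q·Δx·(Ex + ηEy) in kcal/mol.

    ``ex``/``ey`` in MV/cm, ``q`` in esu, ``dx`` in Å.
    """
    du_erg = -q * (dx * 1e-8) * (ex + eta * ey) * _MVCM
    return du_erg / CONSTANTS.kcal_per_mol_in_erg


def marcus_rate(dG0: float, lambda_reorg: float, B: float, T: float) -> float:
    """High-temperature Marcus rate (s⁻¹); energies in kcal/mol."""
    if not lambda_reorg > 0:
        raise ValueError("reorganization energy must be positive")
    if not B > 0:
        raise ValueError("prefactor must be positive")
    kbt = thermal_energy(T).kcal_per_mol
    return B * math.exp(-((dG0 + lambda_reorg) ** 2) / (4.0 * lambda_reorg * kbt))


@dataclass(frozen=True)
class QuadraticFieldFit:
    """OLS quadratic of ln(kNR, s⁻¹) in x = Ex + η·Ey."""

    eta: float
    b0: float          # dimensionless
    b1: float          # per MV/cm
    b2: float          # per (MV/cm)^2
    rss: float
    points: tuple[tuple[float, float], ...]  # (x, ln kNR) pairs used


def _fit_quadratic(x: np.ndarray, y: np.ndarray,
                   weights: Optional[np.ndarray]) -> tuple[np.ndarray, float]:
    design = np.vstack([np.ones_like(x), x, x * x]).T
    if weights is not None:
        w = np.sqrt(weights)
        coeffs, *_ = np.linalg.lstsq(design * w[:, None], y * w, rcond=None)
    else:
        coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coeffs
    if weights is not None:
        rss = float(weights @ (resid * resid))
    else:
        rss = float(resid @ resid)
    return coeffs, rss


def eta_scan_fit(
    proteins: Sequence[tuple[float, float, float]],
    eta_grid: Sequence[float] = DEFAULT_ETA_GRID,
    weights: Optional[Sequence[float]] = None,
) -> tuple[QuadraticFieldFit, list[QuadraticFieldFit]]:
    """Scan η, fitting ln kNR quadratically in Ex + η·Ey at each value.

    ``proteins`` is a sequence of (kNR in ns⁻¹, Ex in MV/cm, Ey in MV/cm).
    Returns the RSS-minimizing fit and the full scan table.  Unweighted
    ordinary least squares by default; optional 1/σ² weights.
    """
    if len(proteins) < 4:
        raise ValueError(
            f"need at least 4 proteins for a 3-parameter fit, got {len(proteins)}"
        )
    knr = np.array([p[0] for p in proteins], dtype=float)
    if np.any(knr <= 0):
        raise ValueError("nonradiative rates must be positive")
    ex = np.array([p[1] for p in proteins], dtype=float)
    ey = np.array([p[2] for p in proteins], dtype=float)
    w = None if weights is None else np.asarray(weights, dtype=float)
    y = np.log(knr * 1e9)
    scan: list[QuadraticFieldFit] = []
    for eta in eta_grid:
        x = ex + eta * ey
        if np.ptp(x) == 0 or len(np.unique(np.round(x, 12))) < 3:
            raise ValueError(
                f"degenerate design at eta={eta}: collapsed field variable "
                f"(distinct x values: {np.unique(np.round(x, 12))})"
            )
        coeffs, rss = _fit_quadratic(x, y, w)
        scan.append(
            QuadraticFieldFit(
                eta=float(eta),
                b0=float(coeffs[0]),
                b1=float(coeffs[1]),
                b2=float(coeffs[2]),
                rss=rss,
                points=tuple(zip(x.tolist(), y.tolist())),
            )
        )
    best = min(scan, key=lambda f: f.rss)
    return best, scan


@dataclass(frozen=True)
class MarcusParameters:
    """TICT parameters extracted from the quadratic field fit."""

    lambda_reorg: float        # kcal/mol
    dx: float                  # Angstrom
    dy: float                  # Angstrom (= eta * dx)
    B: float                   # s^-1
    eta: float
    u_roots: tuple[float, float] = field(default=(math.nan, math.nan))
    V_erg: Optional[float] = None
    kappa_note: str = ""


def extract_tict_parameters(fit: QuadraticFieldFit,
                            const: MarcusConstants) -> MarcusParameters:
    """Invert (b0, b1, b2) for (λ, Δx, Δy, B) given q and ΔG⁰_vac.

    Requires normal-region curvature b2 < 0.  The positive root of the
    u-quadratic is used (Δx > 0); both roots are reported in
    ``u_roots`` for diagnostics.
    """
    if fit.b2 >= 0:
        raise ValueError(
            f"b2 = {fit.b2} >= 0: inverted/flat curvature, parameters "
            "unidentifiable"
        )
    kbt = const.kBT_kcal
    c = -(const.dG_vac / kbt) * fit.b2  # constant term of u^2 - b1 u + c = 0
    disc = fit.b1 * fit.b1 - 4.0 * c
    if disc < 0:
        raise ValueError(
            f"negative discriminant {disc:.6g} in the u-quadratic; complex "
            f"roots {fit.b1 / 2:.6g} ± {math.sqrt(-disc) / 2:.6g}i per MV/cm"
        )
    root = math.sqrt(disc)
    u_pos = (fit.b1 + root) / 2.0
    u_neg = (fit.b1 - root) / 2.0
    if u_pos <= 0:
        raise ValueError(f"no positive root: u roots are ({u_pos}, {u_neg})")
    lam = -u_pos * u_pos * kbt / fit.b2
    # u is per MV/cm: u = q * dx_cm * (1 MV/cm in statvolt/cm) / (2 kB T)
    dx_cm = 2.0 * const.kBT_erg * u_pos / (const.q * _MVCM)
    dx = dx_cm * 1e8
    log_B = (
        fit.b0
        + lam / (4.0 * kbt)
        + const.dG_vac / (2.0 * kbt)
        + const.dG_vac ** 2 / (4.0 * lam * kbt)
    )
    B = math.exp(log_B)
    kappa = (
        "B is far below typical coupled-mode frequencies (1e11-1e13 s^-1), "
        "indicating non-adiabatic transfer (kappa << 1)"
        if B < 1e11
        else "B approaches vibrational frequencies; adiabaticity uncertain"
    )
    return MarcusParameters(
        lambda_reorg=lam,
        dx=dx,
        dy=fit.eta * dx,
        B=B,
        eta=fit.eta,
        u_roots=(u_pos, u_neg),
        kappa_note=kappa,
    )


def coefficients_from_parameters(params: MarcusParameters,
                                 const: MarcusConstants) -> tuple[float, float, float]:
    """Forward map (λ, Δx, B) → (b0, b1, b2); inverse of the extraction."""
    kbt = const.kBT_kcal
    u = const.q * (params.dx * 1e-8) * _MVCM / (2.0 * const.kBT_erg)
    lam = params.lambda_reorg
    b0 = (
        math.log(params.B)
        - lam / (4.0 * kbt)
        - const.dG_vac / (2.0 * kbt)
        - const.dG_vac ** 2 / (4.0 * lam * kbt)
    )
    b1 = u * (1.0 + const.dG_vac / lam)
    b2 = -u * u * kbt / lam
    return b0, b1, b2


def coupling_from_prefactor(B: float, lambda_reorg: float,
                            T: float) -> tuple[float, float]:
    """Electronic coupling V from the non-adiabatic prefactor.

    B = (4π²/h) V² (4π kB T λ)^(−1/2); returns V in erg and cm⁻¹.
    """
    if B <= 0 or lambda_reorg <= 0 or T <= 0:
        raise ValueError("B, lambda and T must all be positive")
    lam_erg = lambda_reorg * CONSTANTS.kcal_per_mol_in_erg
    kbt_erg = thermal_energy(T).erg
    v2 = B * CONSTANTS.h * math.sqrt(4.0 * math.pi * kbt_erg * lam_erg) / (
        4.0 * math.pi ** 2
    )
    v_erg = math.sqrt(v2)
    return v_erg, v_erg / CONSTANTS.hc


def design_surfaces(
    ex_grid: np.ndarray,
    ey_grid: np.ndarray,
    params: MarcusParameters,
    const: MarcusConstants,
    kR_mean: float,
    ref: VacuumChromophore,
) -> dict[str, np.ndarray]:
    """Quantum-yield, Stark-shift and 2P-brightness landscapes over a field grid.

    ``kR_mean`` in s⁻¹.  Returns 2D arrays (len(ey), len(ex)) keyed
    ``phi``, ``nu_shift`` (cm⁻¹ relative to vacuum), ``dmu2`` (D²) and
    ``brightness2p`` (D², ∝ Δμ²·φ).  Every node is a pure function of
    (Ex, Ey).
    """
    if not kR_mean > 0:
        raise ValueError("mean radiative rate must be positive")
    ex_grid = np.asarray(ex_grid, dtype=float)
    ey_grid = np.asarray(ey_grid, dtype=float)
    if not (np.all(np.isfinite(ex_grid)) and np.all(np.isfinite(ey_grid))):
        raise ValueError("field grids must be finite")
    exm, eym = np.meshgrid(ex_grid, ey_grid)
    kbt = const.kBT_kcal
    du = -const.q * (params.dx * 1e-8) * (exm + params.eta * eym) * _MVCM \
        / CONSTANTS.kcal_per_mol_in_erg
    dg0 = const.dG_vac + du
    knr = params.B * np.exp(-((dg0 + params.lambda_reorg) ** 2)
                            / (4.0 * params.lambda_reorg * kbt))
    phi = kR_mean / (kR_mean + knr)
    dmx, dmy = dipole_from_field(exm, eym, ref)
    dmu2 = dmx * dmx + dmy * dmy
    nu = stark_frequency(exm, eym, ref)
    return {
        "ex": exm,
        "ey": eym,
        "phi": phi,
        "nu_shift": nu - ref.nu0,
        "dmu2": dmu2,
        "brightness2p": dmu2 * phi,
    }
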
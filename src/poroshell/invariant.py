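"""Scattering invariant and two-phase composition analysis.

The invariant Q = ∫₀^∞ I(q) q² dq is, for a sharp two-phase system,
2π² Δρ² φ(1−φ) — independent of structural detail.  The measured window
never reaches q = 0 or q = ∞, so the integral is completed with a Guinier
extrapolation below q_min and a Porod (K_p q⁻⁴) extrapolation above q_max.

When the scattering structure occupies only a fraction f of the irradiated
volume (here: the porous hydrogel shells of coated droplets), absolute
normalization to the *total* volume modifies the relation to

    Q = 2π² Δρ² f φ(1−φ),

and with the volume balance f·φ = φ_total (the overall polymer volume
fraction known from preparation) the polymer fraction φ inside the porous
phase follows directly from the measured invariant:

    φ = 1 − Q / (2π² Δρ² φ_total).

Internal invariant units are Å⁻⁴; absolute intensities in cm⁻¹ are
converted with 1 cm⁻¹ = 1e-8 Å⁻¹.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import N_A, physical_constants
from scipy.special import erf

from .curves import ScatteringCurve

__all__ = [
    "CM_TO_A",
    "InvariantResult",
    "Material",
    "CompositionEstimate",
    "WATER",
    "CELLULOSE",
    "CELLULOSE_SLD_PAPER",
    "WATER_SLD_PAPER",
    "guinier_low_q_tail",
    "porod_high_q_tail",
    "invariant",
    "sld_from_material",
    "phi_from_invariant",
    "two_phase_invariant",
    "volume_fraction_from_weight",
]

#: Intensity unit conversion: 1 cm⁻¹ = 1e-8 Å⁻¹.
CM_TO_A = 1e-8

#: SLD values as conventionally quoted for cellulose and water at mass
#: densities 1.5 and 1.0 g/cm³ (Å⁻²).  Note electron counting at the same
#: densities gives ≈1.35e-5 for cellulose; both routes are available.
CELLULOSE_SLD_PAPER = 1.45e-5
WATER_SLD_PAPER = 9.47e-6

_R_E_ANGSTROM = physical_constants["classical electron radius"][0] * 1e10

# minimal element table (atomic number, standard atomic weight)
_ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "F": (9, 18.998), "Na": (11, 22.990), "Mg": (12, 24.305),
    "Si": (14, 28.085), "P": (15, 30.974), "S": (16, 32.06),
    "Cl": (17, 35.45), "K": (19, 39.098), "Ca": (20, 40.078),
}


@dataclass(frozen=True)
class Material:
    """A condensed phase defined by formula and mass density.

    ``formula`` uses element symbols with optional (possibly fractional)
    counts, e.g. ``"C6H10O5"`` for the cellulose monomer or ``"H2O"``.
    If ``sld`` is given it overrides the electron-counting computation.
    """

    name: str
    formula: str
    density: float  # g/cm^3
    sld: float | None = None  # A^-2


WATER = Material("water", "H2O", 1.0)
CELLULOSE = Material("cellulose", "C6H10O5", 1.5)

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def _parse_formula(formula: str) -> list[tuple[str, float]]:
    parsed = []
    consumed = 0
    for match in _FORMULA_RE.finditer(formula):
        symbol, count = match.group(1), match.group(2)
        if symbol not in _ELEMENTS:
            raise ValueError(f"unknown element {symbol!r} in formula {formula!r}")
        parsed.append((symbol, float(count) if count else 1.0))
        consumed += len(match.group(0))
    if consumed != len(formula.replace(" ", "")) or not parsed:
        raise ValueError(f"could not parse formula {formula!r}")
    return parsed


def sld_from_material(material: Material) -> float:
    """X-ray scattering length density of a material, Å⁻².

    SLD = r_e · n_e with n_e the electron number density,
    n_e = N_A · ρ · (Σ Z per formula unit) / M.  If the material carries an
    explicit ``sld`` it is returned unchanged.
    """
    if material.sld is not None:
        return float(material.sld)
    if not np.isfinite(material.density) or material.density <= 0:
        raise ValueError("material density must be positive")
    electrons = 0.0
    mass = 0.0
    for symbol, count in _parse_formula(material.formula):
        z, m = _ELEMENTS[symbol]
        electrons += z * count
        mass += m * count
    n_e_per_cm3 = N_A * material.density * electrons / mass
    return _R_E_ANGSTROM * n_e_per_cm3 * 1e-24  # cm^-3 -> A^-3


# ---------------------------------------------------------------------------
# tail extrapolations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GuinierTail:
    G: float  # cm^-1
    Rg: float  # A
    integral: float  # A^-4, over [0, q_min]
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class PorodTail:
    porod_constant: float  # cm^-1 A^-4
    integral: float  # A^-4, over [q_max, inf)
    warnings: tuple[str, ...] = ()


def _guinier_integral(g_cm: float, rg: float, q_upper: float) -> float:
    """∫₀^{q_upper} G e^{−q²Rg²/3} q² dq in Å⁻⁴ (G in cm⁻¹)."""
    g = g_cm * CM_TO_A
    a = rg**2 / 3.0
    x2 = a * q_upper**2
    if x2 < 1e-10:  # flat-intensity limit
        return g * q_upper**3 / 3.0 * (1.0 - 0.6 * x2)
    root_a = np.sqrt(a)
    return g * (
        np.sqrt(np.pi) * erf(root_a * q_upper) / (4.0 * a * root_a)
        - q_upper * np.exp(-x2) / (2.0 * a)
    )


def guinier_low_q_tail(
    curve: ScatteringCurve, window: tuple[float, float] | None = None
) -> GuinierTail:
    """Guinier extrapolation of the invariant integrand below q_min.

    Fits ln I vs q² over the lowest-q window (default: the lowest decade,
    refined once to q·Rg ≤ 1.3) and integrates G' e^{−q²Rg'²/3} q² over
    [0, q_min] in closed form.  An upward-curving Guinier plot toward low q
    (aggregation signature) attaches a warning rather than failing.
    """
    q, intensity = curve.q, curve.intensity
    notes: list[str] = []

    def fit(mask: np.ndarray) -> tuple[float | None, float]:
        sub_q, sub_i = q[mask], intensity[mask]
        if mask.sum() < 5 or np.any(sub_i <= 0):
            raise ValueError("Guinier window needs >= 5 points with I > 0")
        slope, intercept = np.polyfit(sub_q**2, np.log(sub_i), 1)
        if slope >= 0:  # no measurable decay: flat extrapolation
            return None, float(np.mean(sub_i))
        return float(np.sqrt(-3.0 * slope)), float(np.exp(intercept))

    if window is not None:
        mask = (q >= window[0]) & (q <= window[1])
        rg, g = fit(mask)
    else:
        mask = q <= q[0] * 10.0
        if mask.sum() < 5:
            mask = np.zeros_like(q, dtype=bool)
            mask[:5] = True
        rg, g = fit(mask)
        if rg is not None:
            refined = q * rg <= 1.3
            if refined.sum() >= 5:
                rg, g = fit(refined)
                mask = refined
            else:
                notes.append("q_min*Rg > 1.3: Guinier window could not be refined")
    if rg is None:
        notes.append(
            "no measurable Guinier decay in the low-q window; "
            "flat extrapolation below q_min"
        )
        rg = 0.0

    # curvature check on the fitted window (convex ln I vs q^2 -> upturn)
    x = q[mask] ** 2
    y = np.log(intensity[mask])
    if mask.sum() >= 6:
        c2 = np.polyfit(x, y, 2)[0]
        if c2 * (x[-1] - x[0]) ** 2 > 0.1:
            notes.append("upward-curving Guinier region (possible aggregation)")

    return GuinierTail(G=g, Rg=rg, integral=_guinier_integral(g, rg, q[0]),
                       warnings=tuple(notes))


def porod_high_q_tail(
    curve: ScatteringCurve, window: tuple[float, float] | None = None
) -> PorodTail:
    """Porod extrapolation of the invariant integrand above q_max.

    Fits the Porod constant K_p as the least-squares constant of I·q⁴ over
    the high-q window (default: the top 20% of the q range, log-spaced) and
    returns the closed-form tail ∫_{q_max}^∞ K_p q⁻² dq... i.e.
    K_p/q_max in Å units.  The curve must be background-subtracted.  A
    log–log slope far from −4 in the window attaches a mismatch warning.
    """
    q, intensity = curve.q, curve.intensity
    if window is None:
        q_lo = q[-1] * (q[-1] / q[0]) ** (-0.2)
        window = (q_lo, q[-1])
    mask = (q >= window[0]) & (q <= window[1])
    if mask.sum() < 5:
        raise ValueError("Porod window needs at least 5 points")
    sub_q, sub_i = q[mask], intensity[mask]
    kp = float(np.mean(sub_i * sub_q**4))  # cm^-1 A^-4
    if kp <= 0:
        raise ValueError("fitted Porod constant is non-positive; tail not Porod-like")
    notes: list[str] = []
    pos = sub_i > 0
    if pos.sum() >= 5:
        slope, _ = np.polyfit(np.log(sub_q[pos]), np.log(sub_i[pos]), 1)
        if abs(slope + 4.0) > 0.5:
            notes.append(
                f"high-q slope {slope:.2f} deviates from the Porod exponent -4"
            )
    tail = kp * CM_TO_A / q[-1]  # A^-4
    return PorodTail(porod_constant=kp, integral=tail, warnings=tuple(notes))


# ---------------------------------------------------------------------------
# the invariant
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InvariantResult:
    """Invariant decomposition; all integral parts in Å⁻⁴."""

    q_measured: float
    q_low_tail: float
    q_high_tail: float
    porod_constant: float | None = None  # cm^-1 A^-4
    clipped_fraction: float = 0.0
    warnings: tuple[str, ...] = ()

    @property
    def q_total(self) -> float:
        return self.q_measured + self.q_low_tail + self.q_high_tail

    @property
    def q_total_cm(self) -> float:
        """Total invariant in cm⁻¹·Å⁻³ (the unit system of absolute intensities)."""
        return self.q_total / CM_TO_A

    @property
    def tail_fractions(self) -> tuple[float, float]:
        total = self.q_total
        if total == 0:
            return (0.0, 0.0)
        return (self.q_low_tail / total, self.q_high_tail / total)


def invariant(
    curve: ScatteringCurve,
    low_tail: GuinierTail | None = None,
    high_tail: PorodTail | None = None,
) -> InvariantResult:
    """Integrate I q² over the measured range and add the extrapolated tails.

    The measured-range part is a trapezoidal integral of I(q) q² on the
    native grid after converting intensities to Å⁻¹.  The curve must be
    background-subtracted and in absolute units.  Net-negative intensities
    beyond −3σ of a stated uncertainty raise; smaller negative excursions
    are clipped to zero with a warning and a reported clipped fraction.
    """
    intensity = curve.intensity.copy()
    notes: list[str] = []
    negative = intensity < 0
    if np.any(negative):
        if curve.uncertainty is not None and np.any(
            intensity < -3.0 * curve.uncertainty
        ):
            raise ValueError(
                "intensities below -3 sigma after subtraction; "
                "curve is not a valid net signal"
            )
        clipped = float(np.mean(negative))
        warnings.warn(
            f"{clipped:.1%} of points negative; clipped to zero", stacklevel=2
        )
        notes.append(f"clipped {clipped:.4f} fraction of negative points")
        intensity = np.clip(intensity, 0.0, None)
    else:
        clipped = 0.0

    q_meas = float(np.trapezoid(intensity * CM_TO_A * curve.q**2, curve.q))
    q_low = low_tail.integral if low_tail is not None else 0.0
    q_high = high_tail.integral if high_tail is not None else 0.0
    if low_tail is not None:
        notes.extend(low_tail.warnings)
    if high_tail is not None:
        notes.extend(high_tail.warnings)
    return InvariantResult(
        q_measured=q_meas,
        q_low_tail=q_low,
        q_high_tail=q_high,
        porod_constant=high_tail.porod_constant if high_tail else None,
        clipped_fraction=clipped,
        warnings=tuple(notes),
    )


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def two_phase_invariant(delta_rho: float, phi: float) -> float:
    """Ideal two-phase invariant 2π² Δρ² φ(1−φ), Å⁻⁴."""
    return 2.0 * np.pi**2 * delta_rho**2 * phi * (1.0 - phi)


def volume_fraction_from_weight(
    weight_fraction: float, density_phase: float, density_medium: float
) -> float:
    """Convert a weight fraction to a volume fraction via the mass densities."""
    if not 0 < weight_fraction < 1:
        raise ValueError("weight fraction must lie in (0, 1)")
    v_phase = weight_fraction / density_phase
    v_medium = (1.0 - weight_fraction) / density_medium
    return v_phase / (v_phase + v_medium)


@dataclass(frozen=True)
class CompositionEstimate:
    """Composition of a porous two-phase region occupying part of the sample."""

    delta_rho: float  # A^-2
    phi_total: float  # overall polymer volume fraction in the sample
    phi_cell: float  # polymer volume fraction inside the porous region
    f: float  # volume fraction of the sample occupied by the porous region
    flags: tuple[str, ...] = field(default_factory=tuple)


def phi_from_invariant(
    q_total: float,
    delta_rho: float,
    phi_total: float,
    q_units: str = "A^-4",
) -> CompositionEstimate:
    """Polymer fraction of the porous phase from the measured invariant.

    φ = 1 − Q / (2π² Δρ² φ_total) and f = φ_total / φ, from the modified
    two-phase invariant with the volume balance f·φ = φ_total.  ``q_units``
    is ``"A^-4"`` or ``"cm^-1A^-3"``.  A Q large enough to drive φ below 0
    (or a negative Q driving it above 1) yields a clamped value carrying an
    ``out_of_range`` flag rather than a silent clamp.
    """
    if q_units == "cm^-1A^-3":
        q_total = q_total * CM_TO_A
    elif q_units != "A^-4":
        raise ValueError(f"unknown invariant units {q_units!r}")
    if q_total < 0:
        raise ValueError("invariant must be non-negative")
    if not 0 < phi_total < 1:
        raise ValueError("phi_total must lie in (0, 1)")
    if delta_rho == 0:
        raise ValueError("delta_rho must be nonzero")

    phi_cell = 1.0 - q_total / (2.0 * np.pi**2 * delta_rho**2 * phi_total)
    flags: list[str] = []
    if phi_cell < 0.0 or phi_cell > 1.0:
        flags.append("out_of_range")
        phi_cell_clamped = float(np.clip(phi_cell, 0.0, 1.0))
    else:
        phi_cell_clamped = phi_cell
    f = phi_total / phi_cell if phi_cell > 0 else np.inf
    if f > 1.0:
        flags.append("shell_fraction_above_unity")
    return CompositionEstimate(
        delta_rho=float(delta_rho),
        phi_total=float(phi_total),
        phi_cell=float(phi_cell_clamped) if flags else float(phi_cell),
        f=float(f),
        flags=tuple(flags),
    )
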
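"""Forward scattering models.

Three model families used throughout the package:

* the unified Guinier/power-law (Beaucage) intensity for one or more
  structural levels, the workhorse for fractal-like porous networks;
* concentric multi-shell sphere form factors, used as gross models of a
  coated droplet (core + porous shell + thin dense coat);
* the Stuhrmann split of a particle's scattering into a homogeneous
  "shape" term and an internal-heterogeneity term (plus an optional
  cross term), which justifies analysing only the internal structure
  when the shape term decays below the noise inside the measured window.

All intensities are absolute (cm⁻¹); q is in Å⁻¹ throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "QGrid",
    "UnifiedLevel",
    "UnifiedModel",
    "LayeredSphereProfile",
    "StuhrmannTerms",
    "NegligibilityReport",
    "instrument_grid",
    "unified_intensity",
    "layered_sphere_intensity",
    "stuhrmann_total",
    "shape_term_negligibility",
]

#: Instrument window of the measurements this package emulates (Å⁻¹).
Q_MIN_INSTRUMENT = 7.5e-3
Q_MAX_INSTRUMENT = 0.264


@dataclass(frozen=True)
class QGrid:
    """A strictly increasing, positive grid of scattering-vector magnitudes (Å⁻¹)."""

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 1 or q.size == 0:
            raise ValueError("q grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(q)) or np.any(q <= 0):
            raise ValueError("q grid must be finite and strictly positive")
        if np.any(np.diff(q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        object.__setattr__(self, "q", q)

    def __len__(self) -> int:
        return self.q.size


def instrument_grid(n: int = 200, q_min: float = Q_MIN_INSTRUMENT,
                    q_max: float = Q_MAX_INSTRUMENT) -> QGrid:
    """Log-spaced grid spanning the instrument window [7.5e-3, 0.264] Å⁻¹."""
    return QGrid(np.geomspace(q_min, q_max, n))


@dataclass(frozen=True)
class UnifiedLevel:
    """One structural level of the unified Guinier/power-law model.

    Parameters
    ----------
    G : float
        Guinier prefactor, cm⁻¹ (forward intensity of the level).
    Rg : float
        Radius of gyration of the level's compact structural unit, Å.
    B : float
        Power-law prefactor, cm⁻¹·Å⁻ᴾ.
    P : float
        Power-law exponent; 1 < P < 3 mass fractal, 3 < P < 4 surface
        fractal, P = 4 smooth-interface (Porod) scattering.
    """

    G: float
    Rg: float
    B: float
    P: float

    def __post_init__(self) -> None:
        for name in ("G", "Rg", "B", "P"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"unified level parameter {name} must be finite")
        if self.G < 0 or self.B < 0:
            raise ValueError("prefactors G and B must be non-negative")
        if self.Rg <= 0:
            raise ValueError("Rg must be positive")
        if not 1.0 < self.P < 4.0:
            raise ValueError("power-law exponent P must lie in (1, 4)")


@dataclass(frozen=True)
class UnifiedModel:
    """An ordered set of unified levels (level 1 = smallest scale) plus a flat background."""

    levels: tuple[UnifiedLevel, ...]
    background: float = 0.0

    def __post_init__(self) -> None:
        levels = tuple(self.levels)
        if not levels:
            raise ValueError("a unified model needs at least one level")
        if not np.isfinite(self.background) or self.background < 0:
            raise ValueError("background must be finite and non-negative")
        object.__setattr__(self, "levels", levels)

    @classmethod
    def single_level(cls, G: float, Rg: float, B: float, P: float,
                     background: float = 0.0) -> "UnifiedModel":
        return cls((UnifiedLevel(G, Rg, B, P),), background)

    @property
    def level1(self) -> UnifiedLevel:
        return self.levels[0]


def unified_intensity(grid: QGrid, model: UnifiedModel) -> np.ndarray:
    """Evaluate the unified Guinier/power-law intensity on a grid.

    For one level,

        I(q) = G exp(-q² Rg²/3) + B [erf(q Rg / √6)]^{3P} q^{-P} + bkg.

    For multiple levels the contributions are summed; by the standard
    unified convention the power-law term of level i > 1 is damped by the
    Guinier factor exp(-q² Rg²_{i-1}/3) of the next-smaller level, so the
    power law of a large-scale level cuts off where the smaller structure
    takes over.  Level 1 is undamped.
    """
    q = grid.q
    total = np.full_like(q, float(model.background))
    for i, lvl in enumerate(model.levels):
        guinier = lvl.G * np.exp(-(q**2) * lvl.Rg**2 / 3.0)
        damping = 1.0 if i == 0 else np.exp(-(q**2) * model.levels[i - 1].Rg**2 / 3.0)
        powerlaw = lvl.B * damping * erf(q * lvl.Rg / np.sqrt(6.0)) ** (3.0 * lvl.P) * q ** (-lvl.P)
        total += guinier + powerlaw
    return total


# ---------------------------------------------------------------------------
# layered spheres
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayeredSphereProfile:
    """Concentric sphere with per-layer scattering length densities.

    ``radii`` are the outer radii of each layer from the core outward (Å,
    strictly increasing); ``layer_slds`` the corresponding SLDs (Å⁻²).  A
    2-layer profile is a core–shell sphere; 3 layers model a core with two
    shells (e.g. oil core, porous hydrogel shell, thin dense coat).
    ``number_density`` is particles per Å³ of irradiated volume.
    """

    radii: tuple[float, ...]
    layer_slds: tuple[float, ...]
    solvent_sld: float
    number_density: float

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        slds = tuple(float(s) for s in self.layer_slds)
        if len(radii) != len(slds) or not radii:
            raise ValueError("need one SLD per layer and at least one layer")
        arr = np.array(radii)
        if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
            raise ValueError("radii must be positive and strictly increasing")
        if not np.isfinite(self.solvent_sld):
            raise ValueError("solvent SLD must be finite")
        if not np.isfinite(self.number_density) or self.number_density < 0:
            raise ValueError("number density must be finite and non-negative")
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "layer_slds", slds)

    def scaled(self, factor: float) -> "LayeredSphereProfile":
        """Same profile with all radii multiplied by ``factor`` (contrasts fixed)."""
        return LayeredSphereProfile(
            tuple(r * factor for r in self.radii),
            self.layer_slds,
            self.solvent_sld,
            self.number_density,
        )

    @property
    def outer_radius(self) -> float:
        return self.radii[-1]

    def forward_amplitude(self) -> float:
        """A(0) = Σ_j Δρ_j V_j with Δρ_j the step contrast of layer j (Å)."""
        total = 0.0
        outs = list(self.layer_slds[1:]) + [self.solvent_sld]
        for r, rho, rho_out in zip(self.radii, self.layer_slds, outs):
            total += (rho - rho_out) * (4.0 / 3.0) * np.pi * r**3
        return total


def _sphere_kernel(x: np.ndarray) -> np.ndarray:
    """3 [sin x − x cos x] / x³, the normalized uniform-sphere amplitude."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    small = np.abs(x) < 1e-4
    xs = x[~small]
    out[~small] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    # series for tiny arguments avoids cancellation
    out[small] = 1.0 - x[small] ** 2 / 10.0
    return out


def layered_sphere_intensity(grid: QGrid, profile: LayeredSphereProfile) -> np.ndarray:
    """Intensity of a dilute suspension of concentric multi-shell spheres (cm⁻¹).

    The amplitude superposes uniform spheres of step contrast:

        A(q) = Σ_j (ρ_j − ρ_out,j) V_j · 3[sin(qR_j) − qR_j cos(qR_j)]/(qR_j)³

    with ρ_out,j the SLD immediately outside layer j, and
    I(q) = n_d A(q)², converted from Å⁻¹ to cm⁻¹.
    """
    q = grid.q
    amp = np.zeros_like(q)
    outs = list(profile.layer_slds[1:]) + [profile.solvent_sld]
    for r, rho, rho_out in zip(profile.radii, profile.layer_slds, outs):
        volume = (4.0 / 3.0) * np.pi * r**3
        amp += (rho - rho_out) * volume * _sphere_kernel(q * r)
    if np.all(amp == 0.0):
        warnings.warn("all layers contrast-matched: intensity identically zero", stacklevel=2)
    # n_d [Å⁻³] · A² [Å²] = Å⁻¹; 1 Å⁻¹ = 1e8 cm⁻¹
    return profile.number_density * amp**2 * 1e8


# ---------------------------------------------------------------------------
# Stuhrmann decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StuhrmannTerms:
    """Shape, internal-heterogeneity and optional cross intensity terms on one grid."""

    grid: QGrid
    shape_term: np.ndarray
    hetero_term: np.ndarray
    cross_term: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.grid)
        for name in ("shape_term", "hetero_term"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} does not match the grid length")
            object.__setattr__(self, name, arr)
        if self.cross_term is not None:
            arr = np.asarray(self.cross_term, dtype=float)
            if arr.shape != (n,):
                raise ValueError("cross_term does not match the grid length")
            object.__setattr__(self, "cross_term", arr)


def stuhrmann_total(terms: StuhrmannTerms) -> np.ndarray:
    """Pointwise sum of the decomposition terms (cross term only if present)."""
    total = terms.shape_term + terms.hetero_term
    if terms.cross_term is not None:
        total = total + terms.cross_term
    return total


# ---------------------------------------------------------------------------
# shape-term negligibility
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NegligibilityReport:
    """Outcome of comparing the smeared shape term with a noise floor."""

    max_intensity: float
    q_at_max: float
    noise_floor: float
    ratio: float
    negligible: bool
    warnings: tuple[str, ...] = field(default_factory=tuple)

    @property
    def verdict(self) -> str:
        return "negligible" if self.negligible else "not negligible"


def smeared_layered_sphere_intensity(
    grid: QGrid,
    profile: LayeredSphereProfile,
    polydispersity: float = 0.2,
    n_quad: int = 401,
) -> np.ndarray:
    """Layered-sphere intensity averaged over a lognormal size distribution.

    All radii are scaled by a common lognormal factor with unit mean and
    relative width ``polydispersity`` (σ/μ); the number density is held
    fixed.  The average is a deterministic trapezoidal quadrature over the
    underlying normal variate, with the node count scaled to resolve the
    fastest form-factor oscillation (phase ~ q·R·σ), so the result is a
    smooth envelope free of form-factor nulls and aliasing artifacts.
    """
    if polydispersity < 0:
        raise ValueError("polydispersity must be non-negative")
    if polydispersity == 0:
        return layered_sphere_intensity(grid, profile)
    sigma = np.sqrt(np.log1p(polydispersity**2))
    mu = -0.5 * sigma**2  # unit-mean lognormal
    n = int(np.clip(64 * sigma * grid.q[-1] * profile.outer_radius, n_quad, 8001))
    x = np.linspace(-5.0, 5.0, n)
    weights = np.exp(-0.5 * x**2)
    weights /= weights.sum()
    scales = np.exp(mu + sigma * x)

    q = grid.q[:, None]
    amp = np.zeros((len(grid), n))
    outs = list(profile.layer_slds[1:]) + [profile.solvent_sld]
    for r, rho, rho_out in zip(profile.radii, profile.layer_slds, outs):
        radii = r * scales[None, :]
        volume = (4.0 / 3.0) * np.pi * radii**3
        amp += (rho - rho_out) * volume * _sphere_kernel(q * radii)
    if np.all(amp == 0.0):
        warnings.warn("all layers contrast-matched: intensity identically zero",
                      stacklevel=2)
    intensity = profile.number_density * amp**2 * 1e8
    return intensity @ weights


def shape_term_negligibility(
    profile: LayeredSphereProfile,
    grid: QGrid,
    noise_floor: float,
    polydispersity: float = 0.2,
) -> NegligibilityReport:
    """Judge whether the particle-shape term can be neglected in the q window.

    The layered-sphere ("shape") intensity is smeared over a lognormal size
    distribution (default σ/μ = 0.2) so the verdict reflects the envelope
    decay rather than an accidental form-factor null, then its maximum over
    the grid is compared with ``noise_floor`` (cm⁻¹).  The verdict is
    "negligible" iff that maximum falls below the floor.

    A warning is attached when the particle is not larger than 1/q_min, in
    which case the large-particle argument does not apply at all.
    """
    if noise_floor <= 0:
        raise ValueError("noise floor must be positive")
    notes: list[str] = []
    if profile.outer_radius <= 1.0 / grid.q[0]:
        notes.append(
            "particle outer radius is not larger than 1/q_min; the "
            "large-particle negligibility argument does not apply"
        )
    smeared = smeared_layered_sphere_intensity(grid, profile, polydispersity)
    idx = int(np.argmax(smeared))
    max_i = float(smeared[idx])
    ratio = max_i / noise_floor if np.isfinite(noise_floor) else 0.0
    return NegligibilityReport(
        max_intensity=max_i,
        q_at_max=float(grid.q[idx]),
        noise_floor=float(noise_floor),
        ratio=float(ratio),
        negligible=bool(max_i < noise_floor),
        warnings=tuple(notes),
    )
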
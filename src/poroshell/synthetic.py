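"""Synthetic scattering curves with the statistical structure the analysis assumes.

The generator produces curves on the instrument window 7.5e-3 < q < 0.264 Å⁻¹
with level-1 unified-model structure matching the published structural
parameters of thirteen coated-emulsion and hydrogel samples, additive flat
background and configurable multiplicative-Gaussian or counting noise.  The
published table gives Rg and P but not the prefactors, so fixtures adopt the
convention G = 1 cm⁻¹ with B chosen to place the Guinier/power-law crossover
at mid-grid; the convention is recorded in each fixture's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import erf

from .curves import ScatteringCurve
from .models import (
    LayeredSphereProfile,
    QGrid,
    UnifiedModel,
    instrument_grid,
    smeared_layered_sphere_intensity,
    unified_intensity,
)

__all__ = [
    "NoiseSpec",
    "SampleFixture",
    "TABLE1",
    "crossover_prefactor",
    "simulate_curve",
    "table1_fixtures",
    "simulate_emulsion_sample",
    "simulate_dilute_spheres",
    "simulate_known_composition",
]

#: Published structural parameters per sample: label -> (Rg [Å], P,
#: invariant Q [1e-4 cm⁻¹·Å⁻³], % cellulose as printed).
TABLE1: dict[str, tuple[float, float, float, float]] = {
    "1:1 decane 70": (144.0, 2.60, 1.84, 18.0),
    "1:4 decane 70": (153.0, 2.60, 0.95, 58.0),
    "1:1 decane 14": (142.0, 2.50, 1.21, 46.0),
    "1:4 decane 14": (151.0, 2.50, 0.74, 67.0),
    "1:1 hexadecane 70": (154.0, 2.60, 1.59, 30.0),
    "1:4 hexadecane 70": (167.0, 2.60, 1.26, 44.0),
    "1:1 hexadecane 14": (151.0, 2.50, 1.26, 44.0),
    "1:4 hexadecane 14": (156.0, 2.50, 1.12, 50.0),
    "1:1 castor 70": (146.0, 2.60, 0.92, 59.0),
    "1:4 castor 70": (146.0, 2.60, 0.86, 62.0),
    "1:4 canola 70": (149.0, 2.60, 0.96, 57.0),
    "hydrogel mechanical homogenizer": (143.0, 2.50, 1.55, 31.0),
    "hydrogel HPH 70": (153.0, 2.50, 1.21, 46.0),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for simulated curves.

    ``mode`` is "none", "multiplicative" (Gaussian with σ = level·I) or
    "counting" (Poisson counts at expectation I·incident_scale, with
    ``level`` interpreted as the incident scale in counts per cm⁻¹).
    The same seed and spec always reproduce the same curve.
    """

    mode: str = "none"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "multiplicative", "counting"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.level < 0:
            raise ValueError("noise level must be non-negative")
        if self.mode != "none" and self.level == 0:
            raise ValueError(f"noise mode {self.mode!r} requires a positive level")


def crossover_prefactor(G: float, Rg: float, P: float,
                        q_star: float | None = None,
                        grid: QGrid | None = None) -> float:
    """Power-law prefactor B placing the Guinier/power-law crossover at ``q_star``.

    ``q_star`` defaults to the geometric mid-point of the grid (or of the
    instrument window).  The crossover is defined as equality of the full
    Guinier and damped power-law terms of the level.
    """
    if q_star is None:
        g = grid if grid is not None else instrument_grid(2)
        q_star = float(np.sqrt(g.q[0] * g.q[-1]))
    damping = erf(q_star * Rg / np.sqrt(6.0)) ** (3.0 * P)
    return G * np.exp(-(q_star**2) * Rg**2 / 3.0) * q_star**P / damping


def _apply_noise(
    q: np.ndarray, intensity: np.ndarray, noise: NoiseSpec
) -> tuple[np.ndarray, np.ndarray | None]:
    if noise.mode == "none":
        return intensity, None
    rng = np.random.default_rng(noise.seed)
    if noise.mode == "multiplicative":
        sigma = noise.level * intensity
        return intensity * (1.0 + noise.level * rng.standard_normal(q.size)), sigma
    # counting statistics
    expected = intensity * noise.level
    if np.any(expected < 0):
        raise ValueError("negative expected counts; intensity must be non-negative")
    counts = rng.poisson(expected)
    sigma = np.maximum(np.sqrt(counts), 1.0) / noise.level
    return counts / noise.level, sigma


def simulate_curve(
    model: UnifiedModel,
    grid: QGrid | None = None,
    noise: NoiseSpec | None = None,
    label: str = "synthetic",
) -> ScatteringCurve:
    """Evaluate a unified model on a grid and apply the noise model.

    With noise mode "none" the returned intensities equal the model
    evaluation exactly; noisy modes attach per-point uncertainties
    consistent with the generating distribution and are reproducible for a
    fixed seed.
    """
    grid = grid or instrument_grid()
    noise = noise or NoiseSpec()
    clean = unified_intensity(grid, model)
    noisy, sigma = _apply_noise(grid.q, clean, noise)
    lvl = model.level1
    meta = {
        "label": label,
        "generator": "unified",
        "true_G": lvl.G, "true_Rg": lvl.Rg, "true_B": lvl.B, "true_P": lvl.P,
        "true_background": model.background,
        "noise_mode": noise.mode, "noise_level": noise.level,
        "noise_seed": noise.seed,
        "history": [f"simulated unified level-1 curve ({noise.mode} noise)"],
    }
    return ScatteringCurve(grid.q, noisy, sigma, meta)


def droplet_profile(
    layers: int = 3,
    number_density: float = 5e-20,
    core_radius: float = 5000.0,
    shell_outer_radius: float = 8000.0,
    coat_thickness: float = 200.0,
    shell_phi_cell: float = 0.45,
) -> LayeredSphereProfile:
    """Canonical coated-droplet profile for shape-term studies.

    Geometry follows the microscopy picture of the emulsions this package
    emulates: an oil core (decane SLD 7.14e-6 Å⁻²), a thick porous
    hydrogel shell (SLD mixed from cellulose/water at ``shell_phi_cell``)
    and, for ``layers=3``, a thin dense cellulose coat; water outside.

    ``number_density`` is expressed on the same arbitrary intensity scale
    as the unified fixtures (G = 1 cm⁻¹ convention): the published
    invariant pins the real power-law prefactor near 1.7e-4 cm⁻¹·Å⁻ᴾ,
    about 6e5 times the fixture crossover prefactor, and the default
    number density scales the droplet concentration implied by the oil
    content (≈3e-14 Å⁻³) down by the same factor so shape and internal
    structure terms live on one consistent scale.
    """
    cellulose_sld, water_sld, oil_sld = 1.45e-5, 9.47e-6, 7.14e-6
    shell_sld = shell_phi_cell * cellulose_sld + (1 - shell_phi_cell) * water_sld
    if layers == 2:
        return LayeredSphereProfile(
            (core_radius, shell_outer_radius), (oil_sld, shell_sld),
            water_sld, number_density,
        )
    if layers == 3:
        return LayeredSphereProfile(
            (core_radius, shell_outer_radius, shell_outer_radius + coat_thickness),
            (oil_sld, shell_sld, cellulose_sld), water_sld, number_density,
        )
    raise ValueError("layers must be 2 or 3")


@dataclass(frozen=True)
class SampleFixture:
    """A regenerable synthetic sample: generating model, grid and noise."""

    label: str
    model: UnifiedModel
    grid: QGrid
    noise: NoiseSpec
    true_invariant_cm: float  # cm^-1 A^-3, as published
    true_pct_cellulose: float  # %, as published

    def curve(self) -> ScatteringCurve:
        return simulate_curve(self.model, self.grid, self.noise, label=self.label)


def table1_fixtures(
    noise: NoiseSpec | None = None,
    grid: QGrid | None = None,
    G: float = 1.0,
) -> list[SampleFixture]:
    """One fixture per published sample row, on a shared instrument grid.

    Each fixture is generated with the row's Rg and P, G = 1 cm⁻¹ and B at
    the mid-grid crossover; noisy fixtures derive per-row seeds from the
    given spec's seed so all thirteen differ only in parameters and seed.
    """
    grid = grid or instrument_grid()
    noise = noise or NoiseSpec()
    fixtures = []
    for i, (label, (rg, p, q_inv, pct)) in enumerate(TABLE1.items()):
        b = crossover_prefactor(G, rg, p, grid=grid)
        model = UnifiedModel.single_level(G=G, Rg=rg, B=b, P=p)
        row_noise = NoiseSpec(noise.mode, noise.level, noise.seed + i) \
            if noise.mode != "none" else noise
        fixtures.append(SampleFixture(label, model, grid, row_noise,
                                      q_inv * 1e-4, pct))
    return fixtures


def simulate_emulsion_sample(
    profile: LayeredSphereProfile,
    inner_model: UnifiedModel,
    grid: QGrid | None = None,
    noise: NoiseSpec | None = None,
    polydispersity: float = 0.2,
) -> ScatteringCurve:
    """Total curve of a coated-droplet suspension: shape term plus inner structure.

    The homogeneous "shape" term is the polydispersity-smeared layered-sphere
    intensity of the droplet profile; the heterogeneity term is the unified
    model of the porous inner shell; the cross term is neglected (small-scale
    inhomogeneities against a micron-scale envelope).  When the shape term is
    negligible inside the grid, analysis of the total curve recovers the
    inner model.
    """
    grid = grid or instrument_grid()
    noise = noise or NoiseSpec()
    shape = smeared_layered_sphere_intensity(grid, profile, polydispersity)
    hetero = unified_intensity(grid, inner_model)
    total = shape + hetero
    noisy, sigma = _apply_noise(grid.q, total, noise)
    lvl = inner_model.level1
    meta = {
        "label": "synthetic emulsion",
        "generator": "emulsion",
        "true_Rg": lvl.Rg, "true_P": lvl.P,
        "profile_radii": profile.radii,
        "noise_mode": noise.mode, "noise_level": noise.level,
        "noise_seed": noise.seed,
        "history": ["simulated droplet shape + inner-structure curve"],
    }
    return ScatteringCurve(grid.q, noisy, sigma, meta)


def _sphere_form_factor(q: np.ndarray, radius: float) -> np.ndarray:
    x = q * radius
    kernel = np.where(
        np.abs(x) < 1e-4,
        1.0 - x**2 / 10.0,
        3.0 * (np.sin(x) - x * np.cos(x)) / np.maximum(x, 1e-300) ** 3,
    )
    return kernel**2


def simulate_dilute_spheres(
    radius: float,
    delta_rho: float,
    volume_fraction: float,
    grid: QGrid,
    polydispersity: float = 0.0,
    noise: NoiseSpec | None = None,
) -> ScatteringCurve:
    """Dilute uniform spheres at a given contrast and volume fraction (cm⁻¹).

    I(q) = n_d (Δρ V)² P(q), n_d = φ/V.  Optional lognormal polydispersity
    (σ/μ) is averaged by quadrature at fixed total volume fraction, which
    removes form-factor nulls while leaving the invariant unchanged.  The
    total invariant of the noiseless curve is 2π² Δρ² φ exactly (over all
    reciprocal space, dilute limit).
    """
    noise = noise or NoiseSpec()
    q = grid.q
    if polydispersity == 0:
        volume = (4.0 / 3.0) * np.pi * radius**3
        intensity = volume_fraction * volume * delta_rho**2 * _sphere_form_factor(q, radius)
    else:
        sigma = np.sqrt(np.log1p(polydispersity**2))
        mu = -0.5 * sigma**2
        nodes, weights = np.polynomial.hermite_e.hermegauss(101)
        weights = weights / weights.sum()
        scales = np.exp(mu + sigma * nodes)
        # fixed total phi: weight each size class by its volume share
        vol_weights = weights * scales**3
        vol_weights = vol_weights / vol_weights.sum()
        intensity = np.zeros_like(q)
        for w, s in zip(vol_weights, scales):
            r = radius * s
            volume = (4.0 / 3.0) * np.pi * r**3
            intensity += w * volume_fraction * volume * delta_rho**2 \
                * _sphere_form_factor(q, r)
    intensity = intensity * 1e8  # A^-1 -> cm^-1
    noisy, sigma_i = _apply_noise(q, intensity, noise)
    meta = {
        "label": "dilute spheres",
        "generator": "spheres",
        "radius": radius, "delta_rho": delta_rho,
        "volume_fraction": volume_fraction,
        "polydispersity": polydispersity,
        "noise_mode": noise.mode, "noise_level": noise.level,
        "noise_seed": noise.seed,
        "history": ["simulated dilute-sphere curve"],
    }
    return ScatteringCurve(q, noisy, sigma_i, meta)


def simulate_known_composition(
    phi_cell: float,
    phi_total: float,
    delta_rho: float,
    grid: QGrid,
    pore_radius: float = 100.0,
    polydispersity: float = 0.1,
    noise: NoiseSpec | None = None,
) -> ScatteringCurve:
    """Curve of a porous two-phase phase of known composition.

    Emulates scattering from a porous polymer region (polymer fraction
    ``phi_cell``) that occupies the fraction f = φ_total/φ_cell of the
    sample: structurally a dilute-sphere curve whose exact all-space
    invariant equals the modified two-phase value
    2π² Δρ² φ_total (1 − φ_cell), so the composition analysis applied to
    the simulated curve should recover ``phi_cell``.
    """
    if not 0 < phi_cell < 1:
        raise ValueError("phi_cell must lie in (0, 1)")
    effective_phi = phi_total * (1.0 - phi_cell)
    curve = simulate_dilute_spheres(
        pore_radius, delta_rho, effective_phi, grid,
        polydispersity=polydispersity, noise=noise,
    )
    curve.metadata.update({
        "label": "known composition",
        "true_phi_cell": phi_cell,
        "true_phi_total": phi_total,
    })
    return curve
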
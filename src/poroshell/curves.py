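"""One-dimensional reduced scattering curves and their plain-text I/O.

A :class:`ScatteringCurve` holds a measured or simulated 1-D SAXS profile:
the scattering-vector grid ``q`` (Å⁻¹, strictly increasing), the absolute
intensity ``intensity`` (cm⁻¹) and an optional per-point uncertainty.  Every
transformation applied to a curve (unit conversion, background subtraction,
absolute calibration, clipping) is appended to ``metadata['history']`` so a
processed file records its own provenance.

The file dialect is the de-facto interchange format for reduced SAXS data:
whitespace-separated columns ``q  I  [sigma]`` with ``#`` comment lines and
non-numeric header lines silently skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = [
    "ScatteringCurve",
    "read_curve",
    "write_curve",
    "subtract_background",
    "absolute_calibration",
]


@dataclass
class ScatteringCurve:
    """A 1-D scattering curve in absolute units.

    Parameters
    ----------
    q : array
        Scattering-vector magnitudes, Å⁻¹; strictly increasing, positive.
    intensity : array
        Differential scattering cross-section per unit volume, cm⁻¹.
    uncertainty : array, optional
        One-sigma uncertainty of ``intensity``, cm⁻¹; non-negative.
    metadata : dict
        Free-form label/units/provenance record.  ``history`` is a list of
        strings describing transformations in order of application.
    """

    q: np.ndarray
    intensity: np.ndarray
    uncertainty: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        self._validate()
        self.metadata.setdefault("history", [])

    def _validate(self) -> None:
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("q must be a non-empty 1-D array")
        if self.intensity.shape != self.q.shape:
            raise ValueError("q and intensity must have identical shapes")
        if not np.all(np.isfinite(self.q)):
            raise ValueError("q contains non-finite values")
        if np.any(self.q <= 0):
            raise ValueError("q must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.uncertainty is not None:
            if self.uncertainty.shape != self.q.shape:
                raise ValueError("uncertainty must match q in shape")
            if np.any(self.uncertainty < 0):
                raise ValueError("uncertainty must be non-negative")

    # -- convenience -------------------------------------------------------
    def __len__(self) -> int:
        return self.q.size

    def copy(self) -> "ScatteringCurve":
        return ScatteringCurve(
            self.q.copy(),
            self.intensity.copy(),
            None if self.uncertainty is None else self.uncertainty.copy(),
            {**self.metadata, "history": list(self.metadata.get("history", []))},
        )

    def log_history(self, entry: str) -> None:
        self.metadata.setdefault("history", []).append(entry)


def _parse_numeric_rows(path: Path) -> tuple[np.ndarray, int, dict[str, str]]:
    """Parse whitespace-separated numeric rows, skipping comments/headers.

    Returns the row array (n, ncols), the count of rows dropped because
    they contained non-finite values, and any ``# key: value`` metadata
    found in comment lines.
    """
    rows: list[list[float]] = []
    dropped = 0
    ncols = None
    comments: dict[str, str] = {}
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key = key.strip()
                if key and " " not in key and key not in comments:
                    comments[key] = value.strip()
            continue
        parts = stripped.split()
        try:
            values = [float(p) for p in parts]
        except ValueError:
            continue  # non-numeric header line
        if ncols is None:
            ncols = len(values)
        if len(values) != ncols:
            continue
        if not all(np.isfinite(v) for v in values):
            dropped += 1
            continue
        rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no numeric data rows found")
    return np.array(rows, dtype=float), dropped, comments


def read_curve(path: str | Path, units: str = "1/A") -> ScatteringCurve:
    """Read a 2- or 3-column curve file.

    Parameters
    ----------
    path : path-like
        Plain-text file with columns ``q I`` or ``q I sigma``.
    units : {"1/A", "1/nm"}
        Units of the q column on input; nm⁻¹ values are divided by 10.

    Raises
    ------
    ValueError
        If fewer than 10 valid rows remain, or the file has fewer than two
        columns.  Duplicate q values are averaged with a warning.
    """
    path = Path(path)
    if units not in ("1/A", "1/nm"):
        raise ValueError(f"unknown q units {units!r}; expected '1/A' or '1/nm'")
    data, dropped, comments = _parse_numeric_rows(path)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least two columns (q, I)")
    q = data[:, 0]
    intensity = data[:, 1]
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    if units == "1/nm":
        q = q / 10.0

    order = np.argsort(q, kind="stable")
    q, intensity = q[order], intensity[order]
    if sigma is not None:
        sigma = sigma[order]

    if np.any(np.diff(q) <= 0):
        warnings.warn(f"{path}: duplicate q values averaged", stacklevel=2)
        uq, inverse = np.unique(q, return_inverse=True)
        counts = np.bincount(inverse)
        intensity = np.bincount(inverse, weights=intensity) / counts
        if sigma is not None:
            # quadrature mean of uncertainties of averaged points
            sigma = np.sqrt(np.bincount(inverse, weights=sigma**2)) / counts
        q = uq

    if q.size < 10:
        raise ValueError(f"{path}: only {q.size} valid rows; need at least 10")

    meta: dict[str, Any] = {
        "source": str(path),
        "input_units": units,
        "dropped_rows": dropped,
        "history": [f"read from {path} (q units {units}, {dropped} rows dropped)"],
    }
    for key, value in comments.items():
        if key not in ("history", "columns") and key not in meta:
            meta[key] = value
    return ScatteringCurve(q, intensity, sigma, meta)


def write_curve(curve: ScatteringCurve, path: str | Path, header: str | None = None) -> None:
    """Write a curve as ``q I [sigma]`` columns with a ``#`` metadata header."""
    path = Path(path)
    lines = ["# poroshell scattering curve", "# columns: q[1/A] I[1/cm]"
             + (" sigma[1/cm]" if curve.uncertainty is not None else "")]
    if header:
        lines.append(f"# {header}")
    for key, value in curve.metadata.items():
        if key == "history":
            for entry in value:
                lines.append(f"# history: {entry}")
        else:
            lines.append(f"# {key}: {value}")
    cols = [curve.q, curve.intensity]
    if curve.uncertainty is not None:
        cols.append(curve.uncertainty)
    for row in zip(*cols):
        lines.append("  ".join(f"{v:.12e}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def subtract_background(
    sample: ScatteringCurve,
    background: ScatteringCurve,
    scale: float = 1.0,
) -> ScatteringCurve:
    """Subtract a scaled background curve: ``I_out = I_sample - scale * I_bg``.

    If the grids differ, the background is linearly interpolated onto the
    sample grid (recorded in the history); its grid must cover the sample's
    q range.  Uncertainties combine in quadrature when both are present.
    """
    out = sample.copy()
    if background.q.shape == sample.q.shape and np.allclose(background.q, sample.q, rtol=0, atol=0):
        bg_i = background.intensity
        bg_s = background.uncertainty
        interp_note = ""
    else:
        if background.q[0] > sample.q[0] or background.q[-1] < sample.q[-1]:
            raise ValueError("background grid does not cover the sample q range")
        bg_i = np.interp(sample.q, background.q, background.intensity)
        bg_s = (
            np.interp(sample.q, background.q, background.uncertainty)
            if background.uncertainty is not None
            else None
        )
        interp_note = ", background interpolated"
    out.intensity = sample.intensity - scale * bg_i
    if sample.uncertainty is not None and bg_s is not None:
        out.uncertainty = np.sqrt(sample.uncertainty**2 + (scale * bg_s) ** 2)
    out.log_history(f"background subtracted (scale {scale:g}{interp_note})")
    return out


def absolute_calibration(curve: ScatteringCurve, reference_factor: float) -> ScatteringCurve:
    """Scale a curve to absolute units by a calibration-standard factor.

    The factor comes from a pre-calibrated standard (e.g. glassy carbon);
    intensities and uncertainties are multiplied by it and the curve is
    marked absolute in its metadata.
    """
    if not np.isfinite(reference_factor) or reference_factor <= 0:
        raise ValueError("reference_factor must be positive and finite")
    out = curve.copy()
    out.intensity = curve.intensity * reference_factor
    if curve.uncertainty is not None:
        out.uncertainty = curve.uncertainty * reference_factor
    out.metadata["absolute_units"] = True
    out.log_history(f"absolute calibration applied (factor {reference_factor:g})")
    return out
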
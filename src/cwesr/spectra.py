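"""Spectrum container, file I/O, baselines, normalization and alignment.

The universal currency of the package is the first-derivative CW-ESR
spectrum: a strictly increasing, uniformly spaced magnetic-field axis in
Gauss and the field-modulated (derivative of absorption) intensity in
arbitrary units.  All field quantities in the package are expressed in
Gauss; any Tesla input must be converted at this I/O boundary.

The sign convention is the standard CW display: the low-field lobe of each
resonance line is positive.

The number of spins contributing to a spectrum is proportional to its
double integral — the trapezoidal integral of the running (cumulative
trapezoidal) integral of the derivative signal.  ``normalize_to_unit_spins``
rescales a spectrum so this double integral is exactly 1, which puts
spectra of the same sample on a common "equal number of spins" footing and
makes amplitudes of a linear decomposition directly interpretable as spin
fractions.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .exceptions import AlignmentError, InvalidSpectrumError, SpectrumIOError

__all__ = [
    "AcquisitionMeta",
    "Spectrum",
    "read_spectrum",
    "write_spectrum",
    "double_integral",
    "normalize_to_unit_spins",
    "baseline_correct",
    "resample_align",
]

#: Minimum number of field points for a spectrum to be meaningful.
MIN_POINTS = 64

#: Relative tolerance on field-grid uniformity (fraction of the mean step).
GRID_RTOL = 1e-6

_DIALECT_DELIMS = {"csv": ",", "tsv": "\t", "whitespace": None}


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition settings carried alongside a spectrum.

    Defaults mirror a typical X-band protocol: 1.0 G modulation amplitude,
    100 kHz modulation frequency, 160 G field range.  ``label`` is free text
    identifying probe / lipid / condition.
    """

    modulation_amplitude_G: float = 1.0
    modulation_frequency_kHz: float = 100.0
    field_range_G: float = 160.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("modulation_amplitude_G", "modulation_frequency_kHz", "field_range_G"):
            v = getattr(self, name)
            if not (v > 0):
                raise InvalidSpectrumError(f"{name} must be > 0, got {v!r}")


@dataclass(frozen=True)
class Spectrum:
    """A first-derivative CW-ESR spectrum on a uniform field grid.

    Parameters
    ----------
    field_G : array_like
        Magnetic field axis in Gauss; strictly increasing, uniformly spaced
        (to within :data:`GRID_RTOL` of the mean step), at least
        :data:`MIN_POINTS` points.
    intensity : array_like
        First-derivative absorption signal, arbitrary units, same length.
    meta : AcquisitionMeta
        Acquisition metadata.
    """

    field_G: np.ndarray
    intensity: np.ndarray
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        f = np.asarray(self.field_G, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if f.ndim != 1 or y.ndim != 1 or f.size != y.size:
            raise InvalidSpectrumError("field_G and intensity must be 1-D and equal length")
        if f.size < MIN_POINTS:
            raise InvalidSpectrumError(
                f"spectrum needs at least {MIN_POINTS} points, got {f.size}"
            )
        steps = np.diff(f)
        if np.any(steps <= 0):
            raise InvalidSpectrumError("non-monotone field axis")
        mean_step = float(steps.mean())
        if np.max(np.abs(steps - mean_step)) > GRID_RTOL * mean_step:
            raise InvalidSpectrumError(
                "field axis is not uniform; resample before constructing a Spectrum"
            )
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(y))):
            raise InvalidSpectrumError("non-finite values in spectrum")
        object.__setattr__(self, "field_G", f)
        object.__setattr__(self, "intensity", y)

    # -- convenience -------------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.field_G.size)

    @property
    def step_G(self) -> float:
        """Mean field increment in Gauss."""
        return float((self.field_G[-1] - self.field_G[0]) / (self.n - 1))

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with a replaced intensity array."""
        return replace(self, intensity=np.asarray(intensity, dtype=float))

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_META_FIELDS = {
    "modulation_amplitude_G": float,
    "modulation_frequency_kHz": float,
    "field_range_G": float,
    "label": str,
}


def read_spectrum(path: str | os.PathLike, dialect: str = "whitespace") -> Spectrum:
    """Read a two-column plain-text spectrum file.

    Column 1 is the field in Gauss, column 2 the derivative intensity;
    extra columns are ignored.  ``#``-prefixed header lines of the form
    ``# key=value`` populate :class:`AcquisitionMeta`.

    Parameters
    ----------
    path : path-like
    dialect : {"csv", "tsv", "whitespace"}

    Raises
    ------
    SpectrumIOError
        Missing file, fewer than 64 rows, non-numeric rows, or a
        non-monotone field axis.
    """
    if dialect not in _DIALECT_DELIMS:
        raise ValueError(f"unknown dialect {dialect!r}")
    delim = _DIALECT_DELIMS[dialect]
    if not os.path.exists(path):
        raise SpectrumIOError(f"no such spectrum file: {path}")

    meta_kw: dict = {}
    fields: list[float] = []
    intens: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip()
                    if key in _META_FIELDS:
                        conv = _META_FIELDS[key]
                        try:
                            meta_kw[key] = conv(val.strip())
                        except ValueError:
                            pass
                continue
            parts = line.split(delim) if delim else line.split()
            if len(parts) < 2:
                raise SpectrumIOError(f"line {lineno}: expected >=2 columns")
            try:
                fields.append(float(parts[0]))
                intens.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumIOError(f"line {lineno}: non-numeric row") from exc

    if len(fields) < MIN_POINTS:
        raise SpectrumIOError(
            f"spectrum file has {len(fields)} data rows; need at least {MIN_POINTS}"
        )
    f = np.asarray(fields)
    if np.any(np.diff(f) <= 0):
        raise SpectrumIOError("non-monotone field axis")
    try:
        return Spectrum(f, np.asarray(intens), AcquisitionMeta(**meta_kw))
    except InvalidSpectrumError as exc:
        raise SpectrumIOError(str(exc)) from exc


def write_spectrum(s: Spectrum, path: str | os.PathLike, dialect: str = "whitespace") -> None:
    """Write a spectrum as plain text with ``# key=value`` metadata headers.

    Values are written with 17 significant digits so a write → read round
    trip reproduces the spectrum to double precision.
    """
    if dialect not in _DIALECT_DELIMS:
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = _DIALECT_DELIMS[dialect] or " "
    m = s.meta
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# modulation_amplitude_G={m.modulation_amplitude_G:.17g}\n")
        fh.write(f"# modulation_frequency_kHz={m.modulation_frequency_kHz:.17g}\n")
        fh.write(f"# field_range_G={m.field_range_G:.17g}\n")
        if m.label:
            fh.write(f"# label={m.label}\n")
        for b, y in zip(s.field_G, s.intensity):
            fh.write(f"{b:.17g}{sep}{y:.17g}\n")


# ---------------------------------------------------------------------------
# Integration & normalization
# ---------------------------------------------------------------------------

def double_integral(s: Spectrum) -> float:
    """Double integral of the derivative spectrum (proportional to spins).

    First pass: cumulative trapezoidal integration of the derivative signal
    gives the absorption curve; second pass: trapezoidal area under the
    absorption.  Exact for piecewise-linear data.
    """
    absorption = cumulative_trapezoid(s.intensity, s.field_G, initial=0.0)
    return float(np.trapezoid(absorption, s.field_G))


def normalize_to_unit_spins(s: Spectrum) -> Spectrum:
    """Rescale so the double integral is exactly 1.

    Idempotent, and invariant to positive rescaling of the input.  Requires
    a baseline-corrected spectrum whose double integral is positive.

    Raises
    ------
    InvalidSpectrumError
        If the double integral is not positive (inverted or empty signal).
    """
    di = double_integral(s)
    if not (di > 0) or not math.isfinite(di):
        raise InvalidSpectrumError(
            f"double integral must be positive to normalize, got {di!r}"
        )
    return s.with_intensity(s.intensity / di)


def baseline_correct(s: Spectrum, order: int = 0, edge_fraction: float = 0.05) -> Spectrum:
    """Subtract a polynomial baseline fitted to the sweep edges.

    The polynomial (degree ``order``, 0–3) is least-squares fitted to the
    outer ``edge_fraction`` of points on each end of the sweep — regions
    where a well-centred spectrum has returned to baseline — and subtracted
    from the whole sweep.
    """
    if not (0 <= order <= 3):
        raise ValueError(f"baseline order must be in 0..3, got {order}")
    if not (0 < edge_fraction < 0.5):
        raise ValueError("edge_fraction must be in (0, 0.5)")
    k = max(order + 1, int(round(edge_fraction * s.n)))
    idx = np.r_[0:k, s.n - k : s.n]
    # centred/scaled fit for conditioning on absolute field values
    coeffs = np.polynomial.polynomial.polyfit(
        s.field_G[idx] - s.field_G[0], s.intensity[idx], deg=order
    )
    base = np.polynomial.polynomial.polyval(s.field_G - s.field_G[0], coeffs)
    return s.with_intensity(s.intensity - base)


# ---------------------------------------------------------------------------
# Resampling / alignment
# ---------------------------------------------------------------------------

def _parabolic_offset(ym1: float, y0: float, yp1: float) -> float:
    """Sub-sample offset of a parabola vertex through three equispaced points."""
    denom = ym1 - 2.0 * y0 + yp1
    if denom == 0:
        return 0.0
    off = 0.5 * (ym1 - yp1) / denom
    return float(np.clip(off, -0.5, 0.5))


def resample_align(
    a: Spectrum,
    b: Spectrum,
    max_shift_G: float = 5.0,
) -> Tuple[Spectrum, Spectrum, float]:
    """Put two spectra on one uniform grid and remove a small field offset.

    ``b`` is shifted along the field axis by the offset that maximizes its
    cross-correlation with ``a`` (integer-step search refined by a parabolic
    fit through the correlation peak).  The returned ``shift_G`` is the
    amount *added to b's field axis*: if ``b`` equals ``a`` displaced by
    +1.2 G, ``shift_G`` is −1.2 G.

    Free-versus-bound nitroxide centre shifts are sub-Gauss, so the default
    search window is ±5 G; a larger required shift indicates a data problem
    and raises.

    Raises
    ------
    AlignmentError
        If the overlap covers less than 80% of either sweep, or the best
        shift sits at the edge of the search window.
    """
    lo = max(a.field_G[0], b.field_G[0])
    hi = min(a.field_G[-1], b.field_G[-1])
    span_a = a.field_G[-1] - a.field_G[0]
    span_b = b.field_G[-1] - b.field_G[0]
    if hi - lo < 0.8 * max(span_a, span_b):
        raise AlignmentError(
            f"insufficient overlap: [{lo:.2f}, {hi:.2f}] G covers less than 80% of each sweep"
        )
    step = min(a.step_G, b.step_G)
    npts = int(math.floor((hi - lo) / step)) + 1
    if npts < MIN_POINTS:
        raise AlignmentError("overlap region too short after resampling")
    grid = lo + step * np.arange(npts)

    ai = np.interp(grid, a.field_G, a.intensity)
    bi = np.interp(grid, b.field_G, b.intensity)

    max_lag = int(round(max_shift_G / step))
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(lags.size)
    for j, k in enumerate(lags):
        if k >= 0:
            x, y = ai[k:], bi[: npts - k]
        else:
            x, y = ai[:npts + k], bi[-k:]
        corr[j] = float(np.dot(x, y)) / x.size
    jbest = int(np.argmax(corr))
    if jbest in (0, lags.size - 1) and max_lag > 0:
        raise AlignmentError(
            f"required field shift exceeds the ±{max_shift_G} G search window"
        )
    frac = (
        _parabolic_offset(corr[jbest - 1], corr[jbest], corr[jbest + 1])
        if 0 < jbest < lags.size - 1
        else 0.0
    )
    # corr(k) pairs a(x + k*step) with b(x); if b lags a by d (b = a displaced
    # +d along the field axis) the peak sits at k*step = -d, which is exactly
    # the offset to add to b's axis.
    shift_G = (lags[jbest] + frac) * step
    b_shifted = np.interp(grid, b.field_G + shift_G, b.intensity)

    meta_a, meta_b = a.meta, b.meta
    return (
        Spectrum(grid, ai, meta_a),
        Spectrum(grid, b_shifted, meta_b),
        float(shift_G),
    )
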
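"""Synthetic CW-ESR nitroxide spectra with known ground truth.

Because no raw spectra are deposited with typical spin-label studies, every
measurement routine in this package is validated against simulated spectra
whose ground-truth parameters are known exactly.  Three generators are
provided:

``simulate_isotropic_triplet``
    The fast-motion (motionally narrowed) regime of a nitroxide: three
    first-derivative Lorentzian lines of equal integrated intensity at
    B0 − m·a_N for the nitrogen manifolds m = +1, 0, −1 (m = +1 is the
    low-field line), with an m-dependent peak-to-peak width
    W(m) = W0 + B·m + C·m².  The quadratic coefficient C encodes the
    rotational correlation time through the motional-narrowing relation
    used by :func:`cwesr.params.correlation_time` (see
    :func:`c_coef_for_tau`).

``simulate_axial_powder``
    The ordered, anisotropically averaged regime of a membrane-embedded
    probe (e.g. 5-doxyl stearic acid in a micelle): an axially symmetric
    hyperfine powder pattern with effective splittings A∥ ≥ A⊥, computed by
    Gauss–Legendre quadrature over the director orientation and convolved
    with a Lorentzian of the intrinsic width.  g-anisotropy is neglected
    (single centre field): at X-band the nitrogen hyperfine term dominates
    the outer splitting that the order-parameter analysis uses.

``simulate_mixture``
    Fraction-weighted sums of unit-spin-normalized component spectra with
    seeded additive Gaussian noise — the two-population (mobile +
    immobilized) composites seen when a protein restricts part of the
    probe population.

Lineshapes are Lorentzian by default because the height-ratio analysis of
the correlation time assumes the Lorentzian peak-to-peak height ∝ 1/width²
relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np

from .exceptions import AxisTooNarrowError, InvalidSpectrumError
from .spectra import AcquisitionMeta, Spectrum, normalize_to_unit_spins

__all__ = [
    "IsotropicTripletParams",
    "AxialPowderParams",
    "MixtureSpec",
    "MixtureResult",
    "field_axis",
    "simulate_isotropic_triplet",
    "simulate_axial_powder",
    "simulate_mixture",
    "c_coef_for_tau",
    "powder_params_for_order",
    "noise_sigma_for_snr",
]

_SQRT3 = math.sqrt(3.0)

#: Default X-band centre field (g ≈ 2.006 at ~9.4 GHz), Gauss.
DEFAULT_CENTER_G = 3350.0

_M_VALUES = (1, 0, -1)  # low-field, centre, high-field nitrogen manifolds


def _deriv_lorentzian(B: np.ndarray, center: float | np.ndarray, w_pp) -> np.ndarray:
    """First derivative of a unit-area absorption Lorentzian.

    ``w_pp`` is the peak-to-peak width of the derivative line; the
    absorption half-width at half-maximum is Γ = √3·w_pp/2.  The low-field
    lobe is positive (standard CW display).
    """
    gamma = 0.5 * _SQRT3 * np.asarray(w_pp, dtype=float)
    x = np.asarray(B, dtype=float) - center
    return -(2.0 / math.pi) * gamma * x / (gamma * gamma + x * x) ** 2


def _deriv_gaussian(B: np.ndarray, center: float | np.ndarray, w_pp) -> np.ndarray:
    """First derivative of a unit-area absorption Gaussian.

    The derivative extrema of a Gaussian sit at ±σ, so σ = w_pp/2.
    Useful when negligible far tails matter more than the Lorentzian
    height-width relation (e.g. strict area bookkeeping on finite sweeps).
    """
    sigma = 0.5 * np.asarray(w_pp, dtype=float)
    x = np.asarray(B, dtype=float) - center
    return -x / (sigma**3 * math.sqrt(2.0 * math.pi)) * np.exp(-0.5 * (x / sigma) ** 2)


_LINESHAPES = {"lorentzian": _deriv_lorentzian, "gaussian": _deriv_gaussian}


def field_axis(center_G: float, half_span_G: float, step_G: float = 0.02) -> np.ndarray:
    """Symmetric uniform field grid ``center ± half_span`` with spacing ``step``."""
    if half_span_G <= 0 or step_G <= 0:
        raise ValueError("half_span_G and step_G must be positive")
    n = int(math.ceil(half_span_G / step_G))
    return center_G + step_G * np.arange(-n, n + 1)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotropicTripletParams:
    """Fast-motion three-line nitroxide parameters (all Gauss).

    a_N is constrained to the physically sensible nitroxide range 13–17 G;
    W(m) = W0 + B·m + C·m² must be positive for every manifold.
    """

    a_N_G: float
    W0_G: float
    center_G: float = DEFAULT_CENTER_G
    B_coef_G: float = 0.0
    C_coef_G: float = 0.0

    def __post_init__(self) -> None:
        if not (13.0 <= self.a_N_G <= 17.0):
            raise ValueError(f"a_N_G must be in [13, 17] G, got {self.a_N_G}")
        if not self.W0_G > 0:
            raise ValueError("W0_G must be positive")
        for m in _M_VALUES:
            if self.width(m) <= 0:
                raise ValueError(f"non-positive linewidth W({m:+d})")

    def width(self, m: int) -> float:
        """Peak-to-peak width of manifold m."""
        return self.W0_G + self.B_coef_G * m + self.C_coef_G * m * m


@dataclass(frozen=True)
class AxialPowderParams:
    """Ordered axial powder-pattern parameters (all Gauss)."""

    A_par_G: float
    A_perp_G: float
    intrinsic_width_G: float
    center_G: float = DEFAULT_CENTER_G

    def __post_init__(self) -> None:
        if not (self.A_par_G >= self.A_perp_G > 0):
            raise ValueError("require A_par_G >= A_perp_G > 0")
        if not self.intrinsic_width_G > 0:
            raise ValueError("intrinsic_width_G must be positive")


ComponentParams = Union[IsotropicTripletParams, AxialPowderParams]


@dataclass(frozen=True)
class MixtureSpec:
    """Two-or-more component mixture: (params, fraction) pairs, noise, seed."""

    components: Sequence[Tuple[ComponentParams, float]]
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = np.array([f for _, f in self.components], dtype=float)
        if fracs.size == 0:
            raise ValueError("mixture needs at least one component")
        if np.any(fracs < 0):
            raise ValueError("fractions must be >= 0")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {fracs.sum()!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class MixtureResult:
    """A simulated mixture plus its ground truth."""

    spectrum: Spectrum
    components: Tuple[Spectrum, ...]  # unit-spin normalized, noiseless
    fractions: Tuple[float, ...]
    noise_sigma: float
    seed: int


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _check_span(axis: np.ndarray, center: float, needed: float, what: str) -> None:
    if axis[0] > center - needed or axis[-1] < center + needed:
        raise AxisTooNarrowError(
            f"axis [{axis[0]:.1f}, {axis[-1]:.1f}] G too narrow for {what}: "
            f"need center ± {needed:.1f} G"
        )


def simulate_isotropic_triplet(
    p: IsotropicTripletParams,
    axis: np.ndarray,
    meta: AcquisitionMeta | None = None,
    lineshape: str = "lorentzian",
) -> Spectrum:
    """Three equal-population derivative lines (Lorentzian by default).

    Line m sits at B0 − m·a_N with peak-to-peak width W(m); each line has
    unit double integral, so peak-to-peak height scales as 1/W(m)².
    """
    shape = _LINESHAPES[lineshape]
    axis = np.asarray(axis, dtype=float)
    _check_span(axis, p.center_G, p.a_N_G + 10.0 * p.W0_G, "isotropic triplet")
    y = np.zeros_like(axis)
    for m in _M_VALUES:
        y += shape(axis, p.center_G - m * p.a_N_G, p.width(m))
    return Spectrum(axis, y, meta or AcquisitionMeta(label="simulated triplet"))


def simulate_axial_powder(
    p: AxialPowderParams,
    axis: np.ndarray,
    n_theta: int = 800,
    meta: AcquisitionMeta | None = None,
    lineshape: str = "lorentzian",
) -> Spectrum:
    """Axially symmetric hyperfine powder pattern (first derivative).

    The absorption is ∫₀^{π/2} sinθ Σ_m L(B − B_m(θ)) dθ with
    B_m(θ) = B0 − m·A_eff(θ) and A_eff(θ) = √(A∥²cos²θ + A⊥²sin²θ);
    the returned spectrum is its field derivative.  The orientation
    integral is evaluated by Gauss–Legendre quadrature on u = cosθ
    (``n_theta`` nodes; the integrand is smooth in u so convergence is
    spectral).  The m = 0 manifold is orientation-independent and is added
    as a single line.
    """
    if n_theta < 100:
        raise ValueError("n_theta must be >= 100 for a converged powder average")
    shape = _LINESHAPES[lineshape]
    axis = np.asarray(axis, dtype=float)
    _check_span(
        axis, p.center_G, p.A_par_G + 10.0 * p.intrinsic_width_G, "axial powder pattern"
    )
    nodes, weights = np.polynomial.legendre.leggauss(n_theta)
    u = 0.5 * (nodes + 1.0)          # cosθ ∈ (0, 1)
    wt = 0.5 * weights               # ∫₀¹ du
    a_eff = np.sqrt(p.A_perp_G**2 + (p.A_par_G**2 - p.A_perp_G**2) * u**2)

    y = shape(axis, p.center_G, p.intrinsic_width_G)  # m = 0
    w = p.intrinsic_width_G
    chunk = 128
    for start in range(0, n_theta, chunk):
        a = a_eff[start : start + chunk]
        ww = wt[start : start + chunk]
        for m in (1, -1):
            centers = p.center_G - m * a
            contrib = shape(axis[None, :], centers[:, None], w)
            y += ww @ contrib
    return Spectrum(axis, y, meta or AcquisitionMeta(label="simulated powder"))


def _simulate_component(params: ComponentParams, axis: np.ndarray) -> Spectrum:
    if isinstance(params, IsotropicTripletParams):
        return simulate_isotropic_triplet(params, axis)
    if isinstance(params, AxialPowderParams):
        return simulate_axial_powder(params, axis)
    raise TypeError(f"unsupported component parameter type {type(params).__name__}")


def simulate_mixture(m: MixtureSpec, axis: np.ndarray) -> MixtureResult:
    """Fraction-weighted sum of unit-spin components plus seeded noise.

    Components are normalized to unit double integral before weighting, so
    the stated fractions are spin-count fractions.  Noise is i.i.d.
    Gaussian per field point drawn from ``default_rng(seed)``.
    """
    axis = np.asarray(axis, dtype=float)
    comps = tuple(
        normalize_to_unit_spins(_simulate_component(params, axis))
        for params, _ in m.components
    )
    fracs = tuple(float(f) for _, f in m.components)
    y = np.zeros_like(axis)
    for comp, f in zip(comps, fracs):
        y += f * comp.intensity
    if m.noise_sigma > 0:
        rng = np.random.default_rng(m.seed)
        y = y + rng.normal(0.0, m.noise_sigma, size=y.size)
    spec = Spectrum(axis, y, AcquisitionMeta(label="simulated mixture"))
    return MixtureResult(spec, comps, fracs, float(m.noise_sigma), int(m.seed))


# ---------------------------------------------------------------------------
# Ground-truth helpers
# ---------------------------------------------------------------------------

def c_coef_for_tau(tau_ns: float, k_s_per_G: float = 6.5e-10) -> float:
    """Quadratic width coefficient C giving a target correlation time.

    For equal-area Lorentzian lines, h₀/h_m = (W(m)/W0)², so the
    motional-narrowing expression τ_C = k·W0·(√(h₀/h₊₁) + √(h₀/h₋₁) − 2)
    reduces to τ_C = 2·k·C — independent of W0 and of the linear (B)
    coefficient.  Inverting it keeps simulator ground truth and the
    measured τ_C non-circular at the lineshape level: heights and widths
    are measured off the spectrum, not assumed.
    """
    if tau_ns < 0:
        raise ValueError("tau_ns must be >= 0")
    if k_s_per_G <= 0:
        raise ValueError("k_s_per_G must be positive")
    return tau_ns * 1e-9 / (2.0 * k_s_per_G)


def powder_params_for_order(
    S: float,
    tensor=None,
    center_G: float = DEFAULT_CENTER_G,
    intrinsic_width_G: float = 0.4,
) -> AxialPowderParams:
    """Effective (A∥, A⊥) whose base-form order parameter equals ``S``.

    Solves S = (A∥ − A⊥)/(Azz − (Axx+Ayy)/2) together with preservation of
    the isotropic coupling (A∥ + 2A⊥)/3 = (Axx + Ayy + Azz)/3, the
    motional-averaging constraint for a probe whose local polarity matches
    the rigid-limit tensor.
    """
    from .params import DEFAULT_TENSOR  # local import to avoid a cycle

    t = tensor if tensor is not None else DEFAULT_TENSOR
    if not (0 < S <= 1):
        raise ValueError("S must be in (0, 1]")
    denom = t.Azz_G - 0.5 * (t.Axx_G + t.Ayy_G)
    a_iso = (t.Axx_G + t.Ayy_G + t.Azz_G) / 3.0
    a_perp = a_iso - S * denom / 3.0
    a_par = a_perp + S * denom
    return AxialPowderParams(
        A_par_G=a_par, A_perp_G=a_perp,
        intrinsic_width_G=intrinsic_width_G, center_G=center_G,
    )


def noise_sigma_for_snr(s: Spectrum, snr: float) -> float:
    """Noise sigma giving a stated signal-to-noise ratio.

    SNR is defined here as the maximum absolute derivative amplitude
    divided by the Gaussian noise sigma.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    amp = float(np.max(np.abs(s.intensity)))
    if amp == 0:
        raise InvalidSpectrumError("cannot set an SNR on an all-zero spectrum")
    return amp / snr
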
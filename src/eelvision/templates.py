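"""Closed-form A1/A2 visual-pigment absorbance templates.

The absorbance spectrum of a visual pigment is well described by a
chromophore-specific template parameterised only by its wavelength of
maximal absorbance (λ_max).  The template is the sum of a main α-band,

    S_α(x) = 1 / ( exp[A(a − x)] + exp[B(b − x)] + exp[C(c − x)] + D ),

evaluated at x = λ_max / λ, and a secondary short-wavelength Gaussian
β-band.  Constants differ between the A1 (11-cis-retinal) and A2
(3,4-didehydroretinal) chromophores; A2 pigments are broader at equal
λ_max.  All constants are read from a single data file shipped with the
package (``data/govardovskii_constants.txt``).

Two operations are exposed: forward evaluation of a peak-normalised
template, and numeric inversion of a single long-wavelength-limb point
to the λ_max whose template passes through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CHROMOPHORES",
    "LAMBDA_MAX_RANGE",
    "TemplateParams",
    "TemplateCurve",
    "load_constants",
    "evaluate_template",
    "invert_long_limb",
    "TemplateRangeError",
    "TemplateInversionError",
]

CHROMOPHORES = ("A1", "A2")

#: Supported λ_max range in nm; brackets all rod/cone values seen in
#: anguillid retinas with margin.
LAMBDA_MAX_RANGE = (400.0, 650.0)

#: Wavelength range accepted for evaluation, nm.
WAVELENGTH_RANGE = (330.0, 800.0)


class TemplateRangeError(ValueError):
    """λ_max or wavelength outside the supported range."""


class TemplateInversionError(RuntimeError):
    """No λ_max in the supported range reproduces the given limb point."""


@dataclass(frozen=True)
class TemplateParams:
    """Template constants for one chromophore family.

    ``A`` and ``a`` may be λ_max-dependent; they are resolved through
    :meth:`alpha_exponents`.
    """

    chromophore: str
    constants: Mapping[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        if self.chromophore not in CHROMOPHORES:
            raise ValueError(f"unknown chromophore {self.chromophore!r}")
        for v in self.constants.values():
            if not np.isfinite(v):
                raise ValueError("template constants must be finite")

    def alpha_exponents(self, lambda_max: float) -> tuple[float, float]:
        """Return (A, a) for this λ_max."""
        k = self.constants
        if self.chromophore == "A1":
            a = k["a0"] + k["a1"] * np.exp(-((lambda_max - k["a2"]) ** 2) / k["a3"])
            return k["A"], a
        a = k["a0"] + k["a1"] * np.exp((lambda_max - k["a2"]) / k["a3"])
        A = k["A0"] + k["A1"] * np.exp((lambda_max - k["A2"]) / k["A3"])
        return A, a

    def beta_params(self, lambda_max: float) -> tuple[float, float, float]:
        """Return (amplitude, peak wavelength, bandwidth) of the β-band."""
        k = self.constants
        lm = k["beta_lm0"] + k["beta_lm1"] * lambda_max
        bb = k["beta_bb0"] + k["beta_bb1"] * lambda_max
        if bb <= 0:
            raise ValueError(f"β bandwidth non-positive at λ_max={lambda_max}")
        return k["beta_amp"], lm, bb


@dataclass(frozen=True)
class TemplateCurve:
    """A template evaluated on a wavelength grid, peak-normalised to 1."""

    lambda_max: float
    chromophore: str
    wavelengths: np.ndarray
    relative_absorbance: np.ndarray

    def __post_init__(self) -> None:
        if len(self.wavelengths) != len(self.relative_absorbance):
            raise ValueError("wavelength/absorbance length mismatch")
        if np.any(self.relative_absorbance < 0):
            raise ValueError("negative relative absorbance")


def _parse_constants(text: str) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {"a1": {}, "a2": {}}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        family, _, name = key.strip().partition(".")
        out[family][name] = float(val)
    return out


def load_constants() -> dict[str, TemplateParams]:
    """Load template constants from the packaged data file."""
    text = (
        resources.files("eelvision.data")
        .joinpath("govardovskii_constants.txt")
        .read_text()
    )
    raw = _parse_constants(text)
    return {
        "A1": TemplateParams("A1", raw["a1"]),
        "A2": TemplateParams("A2", raw["a2"]),
    }


_PARAMS: dict[str, TemplateParams] | None = None


def get_params(chromophore: str) -> TemplateParams:
    global _PARAMS
    if _PARAMS is None:
        _PARAMS = load_constants()
    try:
        return _PARAMS[chromophore]
    except KeyError:
        raise ValueError(f"unknown chromophore {chromophore!r}") from None


def _raw_template(
    lambda_max: float,
    params: TemplateParams,
    wavelengths: np.ndarray,
    include_beta: bool,
) -> np.ndarray:
    """Un-normalised α(+β) absorbance at the given wavelengths."""
    k = params.constants
    A, a = params.alpha_exponents(lambda_max)
    x = lambda_max / wavelengths
    alpha = 1.0 / (
        np.exp(A * (a - x))
        + np.exp(k["B"] * (k["b"] - x))
        + np.exp(k["C"] * (k["c"] - x))
        + k["D"]
    )
    if not include_beta:
        return alpha
    amp, lm, bb = params.beta_params(lambda_max)
    beta = amp * np.exp(-(((wavelengths - lm) / bb) ** 2))
    return alpha + beta


def _peak_value(lambda_max: float, params: TemplateParams, include_beta: bool) -> float:
    """Maximum of the raw template over a dense 0.1 nm grid near λ_max.

    The α-band peak sits at λ_max by construction; the β-band can nudge
    it very slightly blue, so the maximum is searched on a bracketing
    window rather than assumed.
    """
    grid = np.arange(max(WAVELENGTH_RANGE[0], lambda_max - 60.0),
                     lambda_max + 40.0, 0.1)
    return float(_raw_template(lambda_max, params, grid, include_beta).max())


def _check_lambda_max(lambda_max: float) -> None:
    lo, hi = LAMBDA_MAX_RANGE
    if not (lo <= lambda_max <= hi):
        raise TemplateRangeError(
            f"λ_max={lambda_max} nm outside supported range [{lo}, {hi}] nm"
        )


def evaluate_template(
    lambda_max: float,
    chromophore: str,
    wavelengths,
    include_beta: bool = True,
) -> TemplateCurve:
    """Evaluate the peak-normalised template at the given wavelengths.

    Parameters
    ----------
    lambda_max
        Wavelength of maximal absorbance, nm, within ``LAMBDA_MAX_RANGE``.
    chromophore
        ``"A1"`` or ``"A2"``.
    wavelengths
        Strictly ascending wavelengths in nm, within 330–800 nm.
    include_beta
        Include the short-wavelength β-band (default).  Switch off to fit
        the α-band alone.

    Returns
    -------
    TemplateCurve
        Relative absorbance normalised so the template maximum over a
        dense internal grid equals 1.
    """
    _check_lambda_max(lambda_max)
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size == 0:
        raise ValueError("empty wavelength vector")
    if wl.ndim != 1 or (wl.size > 1 and np.any(np.diff(wl) <= 0)):
        raise ValueError("wavelengths must be a strictly ascending 1-D vector")
    if wl[0] < WAVELENGTH_RANGE[0] or wl[-1] > WAVELENGTH_RANGE[1]:
        raise TemplateRangeError(
            f"wavelengths must lie within {WAVELENGTH_RANGE} nm"
        )
    params = get_params(chromophore)
    raw = _raw_template(lambda_max, params, wl, include_beta)
    peak = _peak_value(lambda_max, params, include_beta)
    return TemplateCurve(lambda_max, chromophore, wl, raw / peak)


def template_value(
    lambda_max: float, chromophore: str, wavelength: float, include_beta: bool = True
) -> float:
    """Scalar peak-normalised template value at one wavelength."""
    curve = evaluate_template(lambda_max, chromophore, [wavelength], include_beta)
    return float(curve.relative_absorbance[0])


def invert_long_limb(
    absorbance: float,
    wavelength: float,
    chromophore: str,
    include_beta: bool = True,
    tol: float = 0.05,
) -> float:
    """λ_max whose template passes through a long-limb point.

    On the long-wavelength limb (λ > λ_max) the peak-normalised template
    value at a fixed wavelength increases monotonically with λ_max, so
    the root is unique and bracketed by bisection to ``tol`` nm.

    Parameters
    ----------
    absorbance
        Peak-normalised absorbance in (0, 1) at ``wavelength``.
    wavelength
        Wavelength of the limb point, nm.
    chromophore
        Template family to invert.

    Raises
    ------
    TemplateInversionError
        If no λ_max in the supported range reproduces the point on the
        long limb.
    """
    if not (0.0 < absorbance < 1.0):
        raise ValueError("limb absorbance must lie strictly in (0, 1)")
    lo, hi = LAMBDA_MAX_RANGE
    hi = min(hi, wavelength)  # long limb: λ_max at or below the point
    if hi <= lo:
        raise TemplateInversionError(
            f"wavelength {wavelength} nm leaves no long-limb λ_max range"
        )

    def f(lm: float) -> float:
        return template_value(lm, chromophore, wavelength, include_beta) - absorbance

    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise TemplateInversionError(
            f"no λ_max in [{lo}, {hi}] nm yields absorbance {absorbance} "
            f"at {wavelength} nm on the long limb"
        )
    return float(brentq(f, lo, hi, xtol=tol))


def half_bandwidth(lambda_max: float, chromophore: str) -> float:
    """Full width at half maximum of the α-band template, nm."""
    grid = np.arange(WAVELENGTH_RANGE[0], WAVELENGTH_RANGE[1], 0.1)
    curve = evaluate_template(lambda_max, chromophore, grid, include_beta=False)
    above = grid[curve.relative_absorbance >= 0.5]
    return float(above[-1] - above[0])
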
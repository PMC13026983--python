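"""Random-variate expressions in the Arena input-modelling dialect.

Interarrival and processing times in the department model are specified as
shifted/scaled textual expressions such as ``"9 + Expo(5.69)"`` or
``"52 * Beta(0.576, 2.12)"``.  This module parses those expressions into
:class:`DistributionSpec` objects, computes their analytic moments, and draws
reproducible samples from them.

Argument conventions follow the Arena simulation package, in which the source
model was specified:

=========  =======================  ==========================
Family     Arguments                Mean
=========  =======================  ==========================
Expo       (mean)                   mean
Gamma      (beta, alpha)            alpha * beta
Erlang     (beta, k)                k * beta
Beta       (alpha1, alpha2)         alpha1 / (alpha1 + alpha2)   on [0, 1]
UNIF       (low, high)              (low + high) / 2
CONST      (value)                  value
=========  =======================  ==========================

The optional leading multiplier (``52 * Beta(...)``) rescales the unit-interval
Beta variate and is accepted for Beta only.  Samples are clamped from below at
``floor`` (default 0) so that a negative shift such as ``-0.5 +`` can never
produce a negative duration; the analytic mean deliberately ignores this
truncation (the induced bias is bounded and tiny for every expression used).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistributionSpec",
    "ParseError",
    "parse_distribution",
    "analytic_mean",
    "analytic_var",
    "sample",
]

#: canonical token used when serializing each family
_FAMILY_TOKEN = {
    "exponential": "Expo",
    "gamma": "Gamma",
    "erlang": "Erlang",
    "beta": "Beta",
    "uniform": "UNIF",
    "constant": "CONST",
}

_TOKEN_FAMILY = {t.lower(): f for f, t in _FAMILY_TOKEN.items()}

_ARITY = {
    "exponential": 1,
    "gamma": 2,
    "erlang": 2,
    "beta": 2,
    "uniform": 2,
    "constant": 1,
}


class ParseError(ValueError):
    """Raised when a distribution expression cannot be parsed."""


@dataclass(frozen=True)
class DistributionSpec:
    """A parsed shifted/scaled random-variate expression.

    Parameters
    ----------
    family:
        One of ``exponential``, ``gamma``, ``erlang``, ``beta``, ``uniform``,
        ``constant``.
    params:
        Family-specific positive reals (see module docstring for the argument
        order of each family).
    shift:
        Additive offset in minutes; may be negative.
    scale:
        Positive multiplier on the base variate; only Beta expressions carry a
        scale other than 1.
    floor:
        Minimum admissible sample; draws below it are clamped up.
    """

    family: str
    params: tuple[float, ...]
    shift: float = 0.0
    scale: float = 1.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in _ARITY:
            raise ParseError(f"unknown distribution family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if len(self.params) != _ARITY[self.family]:
            raise ParseError(
                f"{_FAMILY_TOKEN[self.family]} takes {_ARITY[self.family]} "
                f"parameter(s), got {len(self.params)}"
            )
        if self.scale <= 0:
            raise ParseError(f"scale must be positive, got {self.scale}")
        if self.family == "uniform":
            low, high = self.params
            if low < 0 or low > high:
                raise ParseError(f"UNIF requires 0 <= low <= high, got ({low}, {high})")
        elif self.family == "constant":
            if self.params[0] < 0:
                raise ParseError(f"CONST requires a non-negative value, got {self.params[0]}")
        else:
            for p in self.params:
                if p <= 0:
                    raise ParseError(
                        f"{_FAMILY_TOKEN[self.family]} parameters must be positive, got {p}"
                    )
        if self.family == "erlang":
            k = self.params[1]
            if k != int(k) or k < 1:
                raise ParseError(f"Erlang phase count must be a positive integer, got {k}")
        if self.family != "beta" and self.scale != 1.0:
            raise ParseError("a scale multiplier is only supported for Beta expressions")

    # -- serialization ----------------------------------------------------

    def __str__(self) -> str:
        args = ", ".join(_fmt(p) for p in self.params)
        out = f"{_FAMILY_TOKEN[self.family]}({args})"
        if self.scale != 1.0:
            out = f"{_fmt(self.scale)} * {out}"
        if self.shift != 0.0:
            out = f"{_fmt(self.shift)} + {out}"
        return out


def _fmt(x: float) -> str:
    # repr gives the shortest string that round-trips the float exactly
    s = repr(float(x))
    return s[:-2] if s.endswith(".0") else s


# grammar: [shift +] [scale *] Family(p1[, p2]); unicode minus and times accepted
_EXPR_RE = re.compile(
    r"""^\s*
        (?:(?P<shift>[+-]?\d*\.?\d+(?:[eE][+-]?\d+)?)\s*\+\s*)?
        (?:(?P<scale>\d*\.?\d+(?:[eE][+-]?\d+)?)\s*\*\s*)?
        (?P<family>[A-Za-z]+)\s*
        \(\s*(?P<args>[^()]*)\)\s*$""",
    re.VERBOSE,
)


def parse_distribution(expr: str, floor: float = 0.0) -> DistributionSpec:
    """Parse a textual random-variate expression into a :class:`DistributionSpec`.

    Accepts optional whitespace, the unicode minus (U+2212) and multiplication
    sign (U+00D7) glyphs, e.g. ``"−0.5 + 54 × Beta (0.729, 3.86)"``.

    Raises
    ------
    ParseError
        On an unknown family, wrong arity, a non-numeric or non-positive
        parameter, or any other malformed input; the message names the
        offending token.
    """
    if not isinstance(expr, str):
        raise ParseError(f"expected a string expression, got {type(expr).__name__}")
    normalized = expr.replace("−", "-").replace("×", "*")
    m = _EXPR_RE.match(normalized)
    if m is None:
        raise ParseError(f"cannot parse distribution expression {expr!r}")
    token = m.group("family")
    family = _TOKEN_FAMILY.get(token.lower())
    if family is None:
        raise ParseError(f"unknown distribution family {token!r} in {expr!r}")
    raw_args = m.group("args").strip()
    if not raw_args:
        raise ParseError(f"{token} requires {_ARITY[family]} parameter(s), got none")
    params = []
    for tok in raw_args.split(","):
        tok = tok.strip()
        try:
            params.append(float(tok))
        except ValueError:
            raise ParseError(f"non-numeric parameter {tok!r} in {expr!r}") from None
    shift = float(m.group("shift")) if m.group("shift") else 0.0
    scale = float(m.group("scale")) if m.group("scale") else 1.0
    return DistributionSpec(family, tuple(params), shift=shift, scale=scale, floor=floor)


def _base_mean(spec: DistributionSpec) -> float:
    p = spec.params
    if spec.family == "exponential":
        return p[0]
    if spec.family == "gamma":
        return p[0] * p[1]  # beta * alpha
    if spec.family == "erlang":
        return p[0] * p[1]  # beta * k
    if spec.family == "beta":
        return p[0] / (p[0] + p[1])
    if spec.family == "uniform":
        return (p[0] + p[1]) / 2.0
    return p[0]  # constant


def _base_var(spec: DistributionSpec) -> float:
    p = spec.params
    if spec.family == "exponential":
        return p[0] ** 2
    if spec.family == "gamma":
        return p[1] * p[0] ** 2  # alpha * beta^2
    if spec.family == "erlang":
        return p[1] * p[0] ** 2
    if spec.family == "beta":
        a, b = p
        return a * b / ((a + b) ** 2 * (a + b + 1.0))
    if spec.family == "uniform":
        return (p[1] - p[0]) ** 2 / 12.0
    return 0.0


def analytic_mean(spec: DistributionSpec) -> float:
    """Mean of the shifted/scaled variate in minutes, ignoring floor truncation."""
    return spec.shift + spec.scale * _base_mean(spec)


def analytic_var(spec: DistributionSpec) -> float:
    """Variance of the shifted/scaled variate, ignoring floor truncation."""
    return spec.scale**2 * _base_var(spec)


def sample(spec: DistributionSpec, rng: np.random.Generator, size: int | None = None):
    """Draw from ``spec`` using ``rng``; scalar if ``size`` is None, else ndarray.

    The draw is ``shift + scale * base`` clamped from below at ``spec.floor``.
    Identical (seed, spec) pairs produce identical draws.
    """
    p = spec.params
    if spec.family == "exponential":
        base = rng.exponential(p[0], size)
    elif spec.family == "gamma":
        base = rng.gamma(shape=p[1], scale=p[0], size=size)
    elif spec.family == "erlang":
        base = rng.gamma(shape=p[1], scale=p[0], size=size)
    elif spec.family == "beta":
        base = rng.beta(p[0], p[1], size)
    elif spec.family == "uniform":
        base = rng.uniform(p[0], p[1], size)
    else:  # constant: burn no randomness
        base = p[0] if size is None else np.full(size, p[0])
    value = spec.shift + spec.scale * base
    if size is None:
        return max(float(value), spec.floor)
    return np.maximum(value, spec.floor)


def clamp_bias_bound(spec: DistributionSpec, n_mc: int = 200_000, seed: int = 0) -> float:
    """Upper bound on the mean bias introduced by floor clamping.

    The clamp raises any draw below ``floor`` up to ``floor``, so the bias is at
    most ``(floor - shift) * P(shifted draw < floor)`` when the shift is the only
    way to go below the floor.  Estimated by Monte Carlo on the un-clamped
    variate.
    """
    if spec.shift >= spec.floor:
        return 0.0
    rng = np.random.default_rng(seed)
    unclamped = DistributionSpec(
        spec.family, spec.params, shift=spec.shift, scale=spec.scale, floor=-math.inf
    )
    draws = sample(unclamped, rng, n_mc)
    p_below = float(np.mean(draws < spec.floor))
    return (spec.floor - spec.shift) * p_below
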
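"""Bayesian ideal observer of speed perception with a semi-parametric slow-speed prior.

The observer combines a Gaussian sensory likelihood with a locally log-linear
prior over speed.  Within a narrow speed range the prior is ``p(v) = exp(a*v + b)``,
where the local log-slope ``a`` varies with speed; it is specified at a small set
of knot speeds and linearly interpolated in between.  The likelihood width is
separable, ``sigma(v, c) = g(v) * h(c)``: a speed-dependent factor ``g`` (also
knot-interpolated) times a contrast gain ``h`` that follows the reciprocal of a
hyperbolic-ratio (Naka-Rushton) contrast response.  Under these assumptions the
posterior over perceived speed is Gaussian with

    E[v_hat]   = v + a(v) * sigma^2(v, c)        (perceived speed, posterior mode)
    Var[v_hat] = sigma^2(v, c)

so a negative prior slope biases perceived speed downward, more strongly at low
contrast where the likelihood is broad -- the Thompson effect.

An optional temporal-filter front end (the "ratio model") replaces the veridical
likelihood mean ``v`` with a nonlinear function ``f(v, c)``: the ratio of a
contrast-saturating band-pass to a contrast-saturating low-pass temporal filter,
evaluated at the stimulus temporal frequency ``omega = v * spatial_frequency``.

All speeds are in deg/s, temporal frequencies in Hz, contrasts as Michelson
fractions in [0, 1] (percent values are accepted only at I/O boundaries).
Functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import IO, Optional, Union

import numpy as np
from scipy.special import ndtr

__all__ = [
    "PriorModel",
    "ContrastResponse",
    "LikelihoodModel",
    "RatioParams",
    "ObserverSpec",
    "slope_at",
    "contrast_gain",
    "likelihood_sigma",
    "posterior_mean",
    "posterior_var",
    "ratio_output",
    "choice_probability",
    "observer_to_json",
    "observer_from_json",
]

SCHEMA_VERSION = 1

DEFAULT_KNOT_SPEEDS = (1.0, 4.0, 8.0, 12.0)

ArrayLike = Union[float, np.ndarray]


def _as_positive(x: ArrayLike, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError(f"{name} must be strictly positive")
    return x


def _as_nonnegative(x: ArrayLike, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"{name} must be non-negative")
    return x


@dataclass(frozen=True)
class PriorModel:
    """Local log-slopes a(v) of the speed prior at knot speeds.

    The intercept of the log-linear prior is not stored: it is absorbed into
    the integration constant when the prior density is reconstructed.
    Outside the knot range the slope is clamped to the nearest knot value
    (the extracted slope functions flatten at the extreme speeds).
    """

    knot_slopes: tuple = (-0.3, -0.15, -0.08, -0.05)
    knot_speeds: tuple = DEFAULT_KNOT_SPEEDS

    def __post_init__(self):
        speeds = np.asarray(self.knot_speeds, dtype=float)
        slopes = np.asarray(self.knot_slopes, dtype=float)
        if speeds.ndim != 1 or speeds.size < 1:
            raise ValueError("knot_speeds must be a non-empty 1-D sequence")
        if np.any(speeds <= 0):
            raise ValueError("knot_speeds must be positive")
        if np.any(np.diff(speeds) <= 0):
            raise ValueError("knot_speeds must be strictly increasing")
        if slopes.shape != speeds.shape:
            raise ValueError("knot_slopes must have one value per knot")
        object.__setattr__(self, "knot_speeds", tuple(speeds))
        object.__setattr__(self, "knot_slopes", tuple(slopes))

    def slope_at(self, v: ArrayLike) -> ArrayLike:
        """Interpolated log-prior slope at speed ``v`` (units 1/(deg/s))."""
        v = _as_positive(v, "speed")
        out = np.interp(v, self.knot_speeds, self.knot_slopes)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ContrastResponse:
    """Contrast gain h(c) of the likelihood width.

    ``h(c) = 1 / (r_max * c^q / (c^q + c50^q) + r_base)`` -- the reciprocal of a
    hyperbolic-ratio firing-rate curve, so the sensory noise shrinks as the
    contrast response saturates.  ``r_max`` and ``r_base`` are fixed to 1 and
    0.2 by convention, bounding h in (1/1.2, 5].
    """

    q: float = 2.0
    c50: float = 0.1
    r_max: float = 1.0
    r_base: float = 0.2

    def __post_init__(self):
        if self.q <= 0:
            raise ValueError("q must be positive")
        if not 0 < self.c50 < 1:
            raise ValueError("c50 must lie in (0, 1)")
        if self.r_max <= 0 or self.r_base <= 0:
            raise ValueError("r_max and r_base must be positive")

    def gain(self, c: ArrayLike) -> ArrayLike:
        c = _as_nonnegative(c, "contrast")
        cq = np.power(c, self.q)
        response = self.r_max * cq / (cq + self.c50**self.q) + self.r_base
        out = 1.0 / response
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LikelihoodModel:
    """Separable likelihood width sigma(v, c) = g(v) * h(c)."""

    knot_g: tuple = (0.2, 0.8, 1.6, 2.4)
    knot_speeds: tuple = DEFAULT_KNOT_SPEEDS
    contrast: ContrastResponse = field(default_factory=ContrastResponse)

    def __post_init__(self):
        speeds = np.asarray(self.knot_speeds, dtype=float)
        g = np.asarray(self.knot_g, dtype=float)
        if np.any(speeds <= 0) or np.any(np.diff(speeds) <= 0):
            raise ValueError("knot_speeds must be positive and strictly increasing")
        if g.shape != speeds.shape:
            raise ValueError("knot_g must have one value per knot")
        if np.any(g <= 0):
            raise ValueError("knot_g must be strictly positive")
        object.__setattr__(self, "knot_speeds", tuple(speeds))
        object.__setattr__(self, "knot_g", tuple(g))

    def g_at(self, v: ArrayLike) -> ArrayLike:
        v = _as_positive(v, "speed")
        out = np.interp(v, self.knot_speeds, self.knot_g)
        return float(out) if out.ndim == 0 else out

    def sigma(self, v: ArrayLike, c: ArrayLike) -> ArrayLike:
        return self.g_at(v) * self.contrast.gain(c)


# Combined-model filter constants; the originals from the temporal-filter
# literature are 0.0072 s, 0.0043 s and gain 4.
@dataclass(frozen=True)
class RatioParams:
    """Parameters of the band-pass / low-pass temporal-filter ratio stage."""

    tau1: float = 0.0353  # s, low-pass cascade time constant (order 9)
    tau2: float = 0.0211  # s, second cascade time constant (order 10)
    k: float = 0.55  # dimensionless band-pass gain
    s_p: float = 0.5  # low-pass semi-saturation
    s_m: float = 0.5  # band-pass semi-saturation

    def __post_init__(self):
        for name in ("tau1", "tau2", "k", "s_p", "s_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def literature(cls) -> "RatioParams":
        """Original filter constants from the speed-tuning literature."""
        return cls(tau1=0.0072, tau2=0.0043, k=4.0, s_p=0.5, s_m=0.5)


@dataclass(frozen=True)
class ObserverSpec:
    """Full generative model of a subject.

    With ``ratio`` absent the perceived-speed mean is ``v + a(v) sigma^2``;
    with a ratio front end it is ``f(v, c) + a(v) sigma^2`` where ``f`` is the
    filter-ratio output at ``omega = v * spatial_frequency``.
    """

    prior: PriorModel = field(default_factory=PriorModel)
    likelihood: LikelihoodModel = field(default_factory=LikelihoodModel)
    ratio: Optional[RatioParams] = None
    spatial_frequency: float = 2.0  # cycles/deg

    def __post_init__(self):
        if self.spatial_frequency <= 0:
            raise ValueError("spatial_frequency must be positive")

    def with_ratio(self, ratio: Optional[RatioParams]) -> "ObserverSpec":
        return replace(self, ratio=ratio)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def slope_at(prior: PriorModel, v: ArrayLike) -> ArrayLike:
    """Log-prior slope a(v), piecewise-linear between knots, clamped outside."""
    return prior.slope_at(v)


def contrast_gain(cr: ContrastResponse, c: ArrayLike) -> ArrayLike:
    """Contrast factor h(c) of the likelihood width; strictly decreasing in c."""
    return cr.gain(c)


def likelihood_sigma(lik: LikelihoodModel, v: ArrayLike, c: ArrayLike) -> ArrayLike:
    """Likelihood standard deviation sigma(v, c) = g(v) h(c), in deg/s."""
    return lik.sigma(v, c)


def _front_end(observer: ObserverSpec, v: ArrayLike, c: ArrayLike) -> ArrayLike:
    if observer.ratio is None:
        v = _as_positive(v, "speed")
        return float(v) if v.ndim == 0 else v
    return ratio_output(observer.ratio, v, c, observer.spatial_frequency)


def posterior_mean(observer: ObserverSpec, v: ArrayLike, c: ArrayLike) -> ArrayLike:
    """Perceived speed: posterior mode (= mean for a Gaussian posterior).

    ``f(v, c) + a(v) * sigma^2(v, c)`` where ``f`` is the identity without a
    ratio front end.  The second term is the prior-induced bias.
    """
    sigma = observer.likelihood.sigma(v, c)
    return _front_end(observer, v, c) + observer.prior.slope_at(v) * sigma**2


def posterior_var(observer: ObserverSpec, v: ArrayLike, c: ArrayLike) -> ArrayLike:
    """Posterior variance of perceived speed: sigma^2(v, c), independent of the prior."""
    return observer.likelihood.sigma(v, c) ** 2


def ratio_filter_amplitudes(params: RatioParams, omega: ArrayLike):
    """Unsaturated filter amplitudes (pbar, mbar) at temporal frequency omega (Hz).

    ``pbar = sqrt(a^2 + b^2)`` with ``a = ((2 pi omega tau1)^2 + 1)^(-9/2)`` and
    ``b = ((2 pi omega tau2)^2 + 1)^(-10/2)`` (amplitude responses of 9- and
    10-stage exponential low-pass cascades); the band-pass amplitude is the
    temporal-derivative form ``mbar = k * omega * pbar``.
    """
    omega = np.asarray(omega, dtype=float)
    a = ((2 * np.pi * omega * params.tau1) ** 2 + 1) ** -4.5
    b = ((2 * np.pi * omega * params.tau2) ** 2 + 1) ** -5.0
    pbar = np.hypot(a, b)
    mbar = params.k * omega * pbar
    return pbar, mbar


def ratio_output(
    params: RatioParams, v: ArrayLike, c: ArrayLike, sf: float
) -> ArrayLike:
    """Perceived speed from the filter-ratio front end, in deg/s.

    ``m(omega, c) / p(omega, c)`` with each filter contrast-saturating:
    ``p = pbar c / (pbar c + s_p)``, ``m = mbar c / (mbar c + s_m)``.  In the
    unsaturated regime (``pbar c << s_p``, reached at high temporal frequency)
    the output tends to ``k * omega``, i.e. approximately veridical speed for
    ``k ~ 1/sf``; toward low speeds the saturation of the low-pass filter makes
    the output *decrease* with contrast.

    Zero contrast is a domain error (both filter outputs vanish).
    """
    v = _as_positive(v, "speed")
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("ratio_output requires contrast > 0")
    if np.any(c > 1):
        raise ValueError("contrast must be a fraction in (0, 1]")
    if sf <= 0:
        raise ValueError("spatial frequency must be positive")
    omega = v * sf
    pbar, mbar = ratio_filter_amplitudes(params, omega)
    p = pbar * c / (pbar * c + params.s_p)
    m = mbar * c / (mbar * c + params.s_m)
    out = m / p
    return float(out) if np.ndim(out) == 0 else out


def choice_probability(observer: ObserverSpec, stim1, stim2) -> ArrayLike:
    """Probability that stimulus 2 is judged faster than stimulus 1.

    The observer draws one sample from each Gaussian posterior and picks the
    larger; hence ``P = Phi((E2 - E1) / sqrt(Var1 + Var2))``.  ``stim1`` and
    ``stim2`` are ``(speed, contrast)`` pairs.
    """
    v1, c1 = stim1
    v2, c2 = stim2
    e1 = posterior_mean(observer, v1, c1)
    e2 = posterior_mean(observer, v2, c2)
    var1 = posterior_var(observer, v1, c1)
    var2 = posterior_var(observer, v2, c2)
    out = ndtr((np.asarray(e2) - e1) / np.sqrt(var1 + var2))
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def observer_to_dict(observer: ObserverSpec) -> dict:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "units": {
            "knot_speeds": "deg/s",
            "knot_slopes": "1/(deg/s)",
            "knot_g": "deg/s",
            "contrast": "fraction",
            "tau": "s",
            "spatial_frequency": "cycles/deg",
        },
        "prior": {
            "knot_speeds": list(observer.prior.knot_speeds),
            "knot_slopes": list(observer.prior.knot_slopes),
        },
        "likelihood": {
            "knot_speeds": list(observer.likelihood.knot_speeds),
            "knot_g": list(observer.likelihood.knot_g),
            "contrast": {
                "q": observer.likelihood.contrast.q,
                "c50": observer.likelihood.contrast.c50,
                "r_max": observer.likelihood.contrast.r_max,
                "r_base": observer.likelihood.contrast.r_base,
            },
        },
        "spatial_frequency": observer.spatial_frequency,
    }
    if observer.ratio is not None:
        r = observer.ratio
        doc["ratio"] = {
            "tau1": r.tau1,
            "tau2": r.tau2,
            "k": r.k,
            "s_p": r.s_p,
            "s_m": r.s_m,
        }
    return doc


def observer_from_dict(doc: dict) -> ObserverSpec:
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported observer schema version: {version!r}")
    prior = PriorModel(
        knot_slopes=tuple(doc["prior"]["knot_slopes"]),
        knot_speeds=tuple(doc["prior"]["knot_speeds"]),
    )
    cdoc = doc["likelihood"]["contrast"]
    likelihood = LikelihoodModel(
        knot_g=tuple(doc["likelihood"]["knot_g"]),
        knot_speeds=tuple(doc["likelihood"]["knot_speeds"]),
        contrast=ContrastResponse(
            q=cdoc["q"], c50=cdoc["c50"], r_max=cdoc["r_max"], r_base=cdoc["r_base"]
        ),
    )
    ratio = None
    if "ratio" in doc:
        ratio = RatioParams(**doc["ratio"])
    return ObserverSpec(
        prior=prior,
        likelihood=likelihood,
        ratio=ratio,
        spatial_frequency=doc["spatial_frequency"],
    )


def observer_to_json(observer: ObserverSpec, fp: Optional[IO[str]] = None) -> str:
    text = json.dumps(observer_to_dict(observer), indent=2)
    if fp is not None:
        fp.write(text)
    return text


def observer_from_json(source: Union[str, IO[str]]) -> ObserverSpec:
    if hasattr(source, "read"):
        source = source.read()
    return observer_from_dict(json.loads(source))
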
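"""Dose/time-response model families used for gene-wise alert derivation.

The six candidate families are the standard dose-finding parameterizations:

==============  =========================================================
name            f(x, params)
==============  =========================================================
linear          E0 + delta * x
quadratic       E0 + b1 * x + b2 * x**2
exponential     E0 + E1 * (exp(x / delta) - 1)
emax            E0 + Emax * x / (ET50 + x)
sigEmax         E0 + Emax * x**h / (ET50**h + x**h)
betaMod         E0 + Emax * B(d1, d2) * (x/scal)**d1 * (1 - x/scal)**d2
==============  =========================================================

For ``betaMod`` the constant ``B(d1, d2) = (d1+d2)**(d1+d2) /
(d1**d1 * d2**d2)`` scales the kernel so that its maximum equals ``Emax``;
for ``x >= scal`` the response is defined as ``E0`` (continuous limit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

MODEL_NAMES = ("linear", "quadratic", "exponential", "emax", "sigEmax", "betaMod")

#: number of parameters (including E0) per model family
PARAM_COUNTS = {
    "linear": 2,
    "quadratic": 3,
    "exponential": 3,
    "emax": 3,
    "sigEmax": 4,
    "betaMod": 5,
}


def _beta_norm(d1: float, d2: float) -> float:
    s = d1 + d2
    return s**s / (d1**d1 * d2**d2)


def evaluate_model(name: str, x, params) -> np.ndarray | float:
    """Evaluate f(x, params) for one of the six candidate families.

    ``x`` may be a scalar or array of non-negative condition values.
    Raises ``ValueError`` for an unknown model name or wrong arity.
    """
    if name not in PARAM_COUNTS:
        raise ValueError(f"unknown model name: {name!r}")
    params = np.asarray(params, dtype=float)
    if params.shape != (PARAM_COUNTS[name],):
        raise ValueError(
            f"model {name!r} needs {PARAM_COUNTS[name]} parameters, got {params.size}"
        )
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if name == "linear":
        e0, delta = params
        out = e0 + delta * x
    elif name == "quadratic":
        e0, b1, b2 = params
        out = e0 + b1 * x + b2 * x**2
    elif name == "exponential":
        e0, e1, delta = params
        out = e0 + e1 * (np.exp(x / delta) - 1.0)
    elif name == "emax":
        e0, emax, et50 = params
        out = e0 + emax * x / (et50 + x)
    elif name == "sigEmax":
        e0, emax, et50, h = params
        xh = np.power(x, h)
        out = e0 + emax * xh / (et50**h + xh)
    else:  # betaMod
        e0, emax, d1, d2, scal = params
        t = np.clip(x / scal, 0.0, 1.0)
        kern = np.where(t >= 1.0, 0.0, t**d1 * (1.0 - t) ** d2)
        out = e0 + emax * _beta_norm(d1, d2) * kern
    return float(out[0]) if scalar else out


@dataclass
class CandidateModel:
    """One candidate family: guesstimate shape, and (after fitting) estimates.

    ``shape_parameters`` are the guesstimates used only for building the
    optimal contrast in the MCP step; ``fitted_parameters`` and
    ``information_criterion`` are populated by least-squares fitting.
    """

    name: str
    shape_parameters: tuple = ()
    fitted_parameters: np.ndarray | None = None
    information_criterion: float | None = None

    def __post_init__(self):
        if self.name not in PARAM_COUNTS:
            raise ValueError(f"unknown model name: {self.name!r}")

    def predict(self, x):
        if self.fitted_parameters is None:
            raise ValueError("model is not fitted")
        return evaluate_model(self.name, x, self.fitted_parameters)


def default_candidates(x0: float, cmax: float) -> list[CandidateModel]:
    """Shipped default guesstimates, scaled to the tested condition range.

    One shape per family, spanning shallow (linear, exponential) to steep
    (emax with small ET50, sigEmax) and non-monotone (quadratic, betaMod)
    profiles.  Only the shape matters for the contrasts, so location/scale
    are standardized to E0=0 and unit effect.
    """
    span = cmax - x0
    return [
        CandidateModel("linear", (0.0, 1.0 / span)),
        CandidateModel("quadratic", (0.0, 1.0, -1.0 / (1.2 * span))),
        CandidateModel("exponential", (0.0, 1.0, 0.3 * span)),
        CandidateModel("emax", (0.0, 1.0, 0.1 * span)),
        CandidateModel("sigEmax", (0.0, 1.0, 0.4 * span, 4.0)),
        CandidateModel("betaMod", (0.0, 1.0, 2.0, 2.0, 1.2 * cmax if cmax > 0 else 1.2)),
    ]


# ---------------------------------------------------------------------------
# least-squares fitting


def _starts(name: str, x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Small fixed set of multi-start initial values derived from data range."""
    cmax = float(x.max())
    e0 = float(y[x == x.min()].mean())
    rng_y = float(y.max() - y.min()) or 1.0
    sgn_delta = 1.0 if float(y[x == cmax].mean()) >= e0 else -1.0
    emax0 = sgn_delta * rng_y
    starts = []
    if name == "exponential":
        for d in (0.1, 0.25, 0.5, 1.0):
            starts.append(np.array([e0, emax0 * 0.2, d * cmax]))
    elif name == "emax":
        for f in (0.05, 0.1, 0.25, 0.5, 1.0):
            starts.append(np.array([e0, emax0, f * cmax]))
    elif name == "sigEmax":
        for f in (0.1, 0.3, 0.6):
            for h in (1.0, 3.0, 5.0):
                starts.append(np.array([e0, emax0, f * cmax, h]))
    elif name == "betaMod":
        for d1, d2 in ((1.0, 1.0), (2.0, 2.0), (0.5, 2.0), (2.0, 0.5)):
            starts.append(np.array([e0, emax0, d1, d2, 1.2 * cmax]))
    return starts


def fit_model(name: str, x: np.ndarray, y: np.ndarray) -> CandidateModel | None:
    """Least-squares fit of one family; ``None`` if no start converges.

    Linear and quadratic are solved exactly; nonlinear families use
    multi-start Levenberg-Marquardt/TRF.  The information criterion is AIC
    under a Gaussian likelihood: ``n*log(RSS/n) + 2*(p+1)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = y.size
    cmax = float(x.max())

    if name in ("linear", "quadratic"):
        deg = 1 if name == "linear" else 2
        coefs = np.polyfit(x, y, deg)
        params = coefs[::-1]  # ascending powers: E0 first
        resid = y - np.polyval(coefs, x)
        rss = float(resid @ resid)
        best = np.asarray(params, float)
    else:
        lo = -np.inf * np.ones(PARAM_COUNTS[name])
        hi = np.inf * np.ones(PARAM_COUNTS[name])
        if name == "exponential":
            lo[2], hi[2] = 1e-3 * cmax, 10 * cmax
        elif name == "emax":
            lo[2], hi[2] = 1e-3 * cmax, 20 * cmax
        elif name == "sigEmax":
            lo[2], hi[2] = 1e-3 * cmax, 20 * cmax
            lo[3], hi[3] = 0.25, 20.0
        elif name == "betaMod":
            lo[2], hi[2] = 0.05, 20.0
            lo[3], hi[3] = 0.05, 20.0
            lo[4], hi[4] = cmax * 1.0001, 10 * cmax

        def f(xv, *p):
            return evaluate_model(name, xv, p)

        best, rss = None, np.inf
        for p0 in _starts(name, x, y):
            p0 = np.clip(p0, lo + 1e-12, hi - 1e-12) if np.all(np.isfinite(lo)) else p0
            p0 = np.minimum(np.maximum(p0, np.where(np.isfinite(lo), lo + 1e-9, p0)),
                            np.where(np.isfinite(hi), hi - 1e-9, p0))
            try:
                popt, _ = curve_fit(f, x, y, p0=p0, bounds=(lo, hi), maxfev=2000)
            except (RuntimeError, ValueError):
                continue
            r = y - evaluate_model(name, x, popt)
            this = float(r @ r)
            if this < rss:
                rss, best = this, popt
        if best is None:
            return None

    k = PARAM_COUNTS[name]
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * (k + 1)
    return CandidateModel(name, fitted_parameters=np.asarray(best, float),
                          information_criterion=float(aic))
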
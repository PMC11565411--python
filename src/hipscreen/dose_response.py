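"""Four-parameter logistic (4PL) dose-response fitting with EC50 censoring.

Model (ascending agonist curve, fitted on log10 dose for conditioning):

    y = bottom + (top - bottom) / (1 + (ec50 / x) ** hill)

EC50s beyond the tested dose range cannot be estimated, only bounded; a fit
is censored (reported as "> max dose") when the fitted EC50 exceeds the
highest tested dose or the curve has not approached its plateau there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = ["DoseResponseFit", "fit_4pl", "classify_potency", "pooled_ec50"]


@dataclass(frozen=True)
class DoseResponseFit:
    bottom: float
    top: float
    hill: float
    ec50: float
    censored: bool
    r_squared: float
    max_dose: float
    converged: bool
    message: str = ""

    @property
    def span(self) -> float:
        return self.top - self.bottom


def _4pl(logx: np.ndarray, bottom: float, top: float, log_ec50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logx) * hill))


def fit_4pl(
    doses: Sequence[float],
    responses: Sequence[float],
    plateau_fraction: float = 0.8,
    span_floor_sd: float = 2.0,
    error_model: str = "additive",
) -> DoseResponseFit:
    """Nonlinear least-squares 4PL fit of responses against doses.

    Zero-dose wells constrain the bottom asymptote directly rather than
    entering as log-dose points.  Initialisation is data-driven: bottom =
    min response, top = max response, EC50 = geometric mid-dose, hill = 1.
    Non-convergence and span-less (flat) data are flagged, not raised.

    ``error_model='additive'`` minimises raw residuals; ``'proportional'``
    minimises log-scale residuals, the right choice for luminescence
    readouts whose noise is multiplicative (requires positive responses).
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("doses and responses must align")
    if np.any(x < 0):
        raise ValueError("doses must be non-negative")
    zero_mask = x == 0
    y0 = y[zero_mask]
    x, y = x[~zero_mask], y[~zero_mask]
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct positive doses")
    logx = np.log10(x)
    max_dose = float(x.max())

    if error_model not in ("additive", "proportional"):
        raise ValueError(f"unknown error model {error_model!r}")
    if error_model == "proportional" and (np.any(y <= 0) or np.any(y0 <= 0)):
        raise ValueError("proportional error model requires positive responses")

    b0 = float(y0.mean()) if len(y0) else float(y.min())
    t0 = float(y.max())
    mid0 = float((logx.min() + logx.max()) / 2.0)

    def residuals(p: np.ndarray) -> np.ndarray:
        bottom, top, log_ec50, hillc = p
        yhat = _4pl(logx, bottom, top, log_ec50, hillc)
        if error_model == "proportional":
            r = np.log(np.clip(yhat, 1e-12, None)) - np.log(y)
            if len(y0):
                r = np.concatenate([r, np.log(max(bottom, 1e-12)) - np.log(y0)])
        else:
            r = yhat - y
            if len(y0):
                r = np.concatenate([r, bottom - y0])
        return r

    lower_b = 0.0 if error_model == "proportional" else -np.inf
    p0 = np.array([max(b0, 1e-9) if error_model == "proportional" else b0, t0, mid0, 1.0])
    sol = optimize.least_squares(
        residuals,
        p0,
        bounds=(
            [lower_b, lower_b, logx.min() - 6.0, 0.1],
            [np.inf, np.inf, logx.max() + 6.0, 10.0],
        ),
        max_nfev=2000,
    )
    bottom, top, log_ec50, hillc = sol.x
    yhat = _4pl(logx, bottom, top, log_ec50, hillc)
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    ec50 = float(10.0**log_ec50)

    resid_sd = math.sqrt(ss_res / max(len(y) - 4, 1))
    span = top - bottom
    flat = span <= span_floor_sd * max(resid_sd, 1e-12)
    # plateau check: the curve must reach >= plateau_fraction of its span
    # at the highest tested dose, else the EC50 is only a lower bound
    reached = _4pl(np.array([math.log10(max_dose)]), bottom, top, log_ec50, hillc)[0]
    approach = (reached - bottom) / span if span > 0 else 0.0
    censored = bool(flat or ec50 > max_dose or approach < plateau_fraction)
    converged = bool(sol.success) and not flat
    msg = "" if sol.success else sol.message
    if flat:
        msg = (msg + "; " if msg else "") + "flat response (span within noise): fit unreliable"
    return DoseResponseFit(
        bottom=float(bottom),
        top=float(top),
        hill=float(hillc),
        ec50=ec50,
        censored=censored,
        r_squared=r2,
        max_dose=max_dose,
        converged=converged,
        message=msg,
    )


def pooled_ec50(fits: Sequence[DoseResponseFit]) -> float:
    """Geometric-mean EC50 over independent experiments (EC50s are
    log-normally distributed across repeats); censored fits are excluded."""
    values = [f.ec50 for f in fits if not f.censored]
    if not values:
        raise ValueError("no uncensored fits to pool")
    return float(np.exp(np.mean(np.log(values))))


def classify_potency(fit: DoseResponseFit) -> str:
    """Human-readable potency: the EC50 in molar, or a censored bound
    '> <max dose>' when the EC50 lies beyond the tested range."""
    if fit.censored:
        return f"> {fit.max_dose:.3g} M"
    return f"{fit.ec50:.3g} M"
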
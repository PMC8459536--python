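"""Invert fitted gd-only logit models to barrier-completeness thresholds.

For a two-parameter model logit(p) = b0 + b1 * gd with a positive slope,
the genetic distance at which the barrier reaches completeness level p is

    gd* = (logit(p) - b0) / b1

computed analytically on the logit scale.  Levels default to 99.0% and
99.9% ("nearly complete" isolation).  The inversion routinely
extrapolates beyond the observed range of genetic distances — the
published prezygotic thresholds (0.475-0.657) lie far above the data's
maximum distance of 0.075 — so estimates carry an ``extrapolated`` flag
rather than being suppressed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .qglm import GlmFit

DEFAULT_LEVELS = (0.99, 0.999)


class InversionError(ValueError):
    """Threshold undefined (non-positive slope or invalid level)."""


@dataclass(frozen=True)
class ThresholdEstimate:
    """Genetic distance at which a fitted barrier reaches level ``p``."""

    barrier: str
    p: float
    gd_star: float
    extrapolated: bool = False
    ci: Optional[tuple[float, float]] = None


def logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def invert(fit: GlmFit, p: float, barrier: str = "", ci: bool = False,
           ci_level: float = 0.95) -> ThresholdEstimate:
    """Genetic distance at which ``fit`` predicts barrier completeness ``p``.

    Requires an {intercept, gd} model with a strictly positive slope.
    ``ci=True`` adds a delta-method confidence interval; this is an
    extension — the standard report carries point estimates only.
    """
    if not 0.0 < p < 1.0:
        raise InversionError(f"completeness level must be in (0, 1), got {p}")
    if set(fit.names) != {"intercept", "gd"}:
        raise InversionError("inversion requires a gd-only {intercept, gd} model")
    b0, b1 = fit.coef("intercept"), fit.coef("gd")
    if b1 <= 0:
        raise InversionError(
            "barrier does not increase with distance; no finite completeness threshold"
        )
    gd_star = (logit(p) - b0) / b1
    extrap = gd_star > fit.gd_range[1] or gd_star < fit.gd_range[0]
    interval = None
    if ci:
        if fit.cov is None:
            raise InversionError("fit carries no covariance; cannot form a CI")
        i0, i1 = fit.names.index("intercept"), fit.names.index("gd")
        grad = np.zeros(len(fit.names))
        grad[i0] = -1.0 / b1
        grad[i1] = -gd_star / b1
        var = float(grad @ fit.cov @ grad)
        from scipy import stats

        z = stats.norm.ppf(0.5 + ci_level / 2.0)
        half = z * math.sqrt(max(var, 0.0))
        interval = (gd_star - half, gd_star + half)
    return ThresholdEstimate(barrier=barrier or "barrier", p=p, gd_star=gd_star,
                             extrapolated=extrap, ci=interval)


def table3_report(
    fits: Mapping[str, GlmFit], levels: Sequence[float] = DEFAULT_LEVELS
) -> pd.DataFrame:
    """Threshold table for a set of gd-only barrier fits.

    One row per barrier with the model coefficients (Estimate, SE, t, P
    for intercept and slope) and one ``gd_<level>`` column per
    completeness level, rounded to 3 decimals in formatted output.
    """
    rows = []
    for barrier, fit in fits.items():
        i0, i1 = fit.names.index("intercept"), fit.names.index("gd")
        row = {
            "barrier": barrier,
            "intercept": float(fit.beta[i0]),
            "intercept_se": float(fit.se[i0]),
            "intercept_t": float(fit.t[i0]),
            "intercept_p": float(fit.p_values[i0]),
            "slope": float(fit.beta[i1]),
            "slope_se": float(fit.se[i1]),
            "slope_t": float(fit.t[i1]),
            "slope_p": float(fit.p_values[i1]),
        }
        for p in levels:
            est = invert(fit, p, barrier)
            row[f"gd_{p:g}"] = est.gd_star
            row[f"extrapolated_{p:g}"] = est.extrapolated
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, tsv_path: str | Path | None = None,
                 json_path: str | Path | None = None) -> None:
    """Write the threshold table as TSV (3-decimal) and/or full-precision JSON."""
    if tsv_path is not None:
        out = df.copy()
        for c in out.columns:
            if out[c].dtype.kind == "f":
                out[c] = out[c].map(lambda x: f"{x:.3f}")
        out.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2)
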
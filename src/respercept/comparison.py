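"""AIC model comparison across the four model variants.

All variants are fitted to the same non-missing rating bins, so their AICs
are commensurable.  The least-squares (Gaussian) AIC form is used, with the
residual variance counted as one extra parameter uniformly across variants;
the convention shifts every AIC equally and does not affect rankings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExperimentTrace
from .estimators import FitOptions, FitResult, fit_model, fit_linear

__all__ = ["compute_aic", "select_best", "compare_models", "ComparisonTable"]

#: Fit order: restricted variants first so the full model can be
#: warm-started from the no-activity solution (its exact superset).
COMPARISON_VARIANTS = ("no_activity", "no_memory", "linear_regression", "full")


def select_best(aic: dict, k_free: dict) -> str:
    """Variant with the lowest AIC; ties break toward fewer parameters."""
    return min(aic, key=lambda v: (aic[v], k_free[v]))


def compute_aic(rss: float, n_obs: int, k_free: int) -> float:
    """Akaike Information Criterion for a least-squares fit.

    AIC = n ln(RSS/n) + 2 (k + 1), natural log; the +1 counts the residual
    variance.  Lower is better.  A perfect fit (RSS = 0) returns -inf with
    a warning.
    """
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if n_obs <= k_free + 2:
        raise ValueError("need n_obs > k_free + 2 for a meaningful AIC")
    if rss == 0:
        warnings.warn("perfect fit (rss = 0): AIC is -inf", stacklevel=2)
        return -np.inf
    return float(n_obs * np.log(rss / n_obs) + 2.0 * (k_free + 1))


@dataclass
class ComparisonTable:
    """Per-variant fits, AICs and the winning variant for one trace."""

    fits: dict[str, FitResult]
    aic: dict[str, float]
    delta_aic: dict[str, float]
    best: str

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant": v,
                "rss": self.fits[v].rss,
                "n_obs": self.fits[v].n_obs,
                "k_free": self.fits[v].k_free,
                "aic": self.aic[v],
                "delta_aic": self.delta_aic[v],
            }
            for v in COMPARISON_VARIANTS
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        obj = {
            "best": self.best,
            "variants": {
                v: {
                    **self.fits[v].to_dict(),
                    "aic": float(self.aic[v]),
                    "delta_aic": float(self.delta_aic[v]),
                }
                for v in COMPARISON_VARIANTS
            },
        }
        if path is None:
            return obj
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=2)


def compare_models(
    trace: ExperimentTrace, options: FitOptions | None = None
) -> ComparisonTable:
    """Fit all four variants to one trace and rank them by AIC.

    Shared optimizer options and seed; identical rating bins for every
    variant.  Ties in AIC break toward the variant with fewer parameters.
    """
    options = options or FitOptions()
    fits: dict[str, FitResult] = {}
    fits["no_activity"] = fit_model(trace, "no_activity", options)
    fits["no_memory"] = fit_model(trace, "no_memory", options)
    fits["linear_regression"] = fit_linear(trace)
    # Warm-start the full model from the no-activity optimum (a nested
    # special case) so rss(full) <= rss(no_activity) up to polish.
    fits["full"] = fit_model(
        trace,
        "full",
        options,
        extra_starts=[{**fits["no_activity"].coef, "activity": 0.0}],
    )
    aic = {
        v: compute_aic(r.rss, r.n_obs, r.k_free) for v, r in fits.items()
    }
    best = select_best(aic, {v: r.k_free for v, r in fits.items()})
    amin = aic[best]
    delta = {v: a - amin for v, a in aic.items()}
    return ComparisonTable(fits=fits, aic=aic, delta_aic=delta, best=best)
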
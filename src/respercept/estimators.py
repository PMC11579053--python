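"""Per-participant parameter estimation, scikit-learn style.

:class:`BreathlessnessPerceptionModel` regresses 0-100 breathlessness
ratings on binned end-tidal CO2 through the perceptual model (or, for the
``linear_regression`` variant, through ordinary least squares).  The state
space variants are fitted by bounded nonlinear least squares
(``scipy.optimize.least_squares``) with Latin-hypercube multi-start, since
the objective surface is multimodal; the linear baseline has a closed-form
solution.  Missing ratings (NaN) are dropped from the objective, never
imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin

from .data_io import ExperimentTrace
from .model import (
    VARIANTS,
    LatentTrajectory,
    ModelParams,
    forward_model,
)

__all__ = [
    "DEFAULT_BOUNDS",
    "FREE_PARAMS",
    "FitOptions",
    "FitResult",
    "BreathlessnessPerceptionModel",
    "fit_model",
    "fit_linear",
]

#: Free parameters per variant (the linear baseline has intercept/slope).
FREE_PARAMS = {
    "full": ("rho", "w_c", "activity", "gain", "offset"),
    "no_activity": ("rho", "w_c", "gain", "offset"),
    "no_memory": ("rho", "w_c", "activity", "gain", "offset"),
    "linear_regression": ("intercept", "slope"),
}

#: Default box constraints; rho is searched in log10 space for conditioning.
#: The spans cover every plausible behaviour on the 0-100 rating scale.
DEFAULT_BOUNDS = {
    "log10_rho": (-3.0, 4.0),
    "rho": (1e-3, 1e4),
    "w_c": (0.0, 50.0),
    "activity": (-100.0, 100.0),
    "gain": (0.0, 50.0),
    "offset": (-100.0, 100.0),
}


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for the nonlinear fits."""

    n_starts: int = 20
    seed: int = 0
    bounds: dict | None = None
    tolerance: float = 1e-10
    log_rho: bool = True

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for name, (lo, hi) in (self.bounds or {}).items():
            if not lo < hi:
                raise ValueError(f"bounds for {name}: need lower < upper")


@dataclass
class FitResult:
    """Outcome of fitting one model variant to one trace."""

    variant: str
    params: ModelParams | None      #: fitted params (state-space variants)
    coef: dict = field(default_factory=dict)  #: free parameters by name
    rss: float = np.nan             #: residual sum of squares, rating^2
    n_obs: int = 0                  #: non-missing rating bins
    k_free: int = 0
    converged: bool = False
    start_rss: np.ndarray | None = None  #: best RSS per restart

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "coef": {k: float(v) for k, v in self.coef.items()},
            "params": self.params.to_dict() if self.params else None,
            "rss": float(self.rss),
            "n_obs": int(self.n_obs),
            "k_free": int(self.k_free),
            "converged": bool(self.converged),
            "start_rss": (
                None
                if self.start_rss is None
                else [float(v) for v in self.start_rss]
            ),
        }


class BreathlessnessPerceptionModel(RegressorMixin, BaseEstimator):
    """Kalman-filter model of breathlessness perception as a regressor.

    Predicts a 0-100 breathlessness rating from a binned end-tidal CO2
    series.  ``fit`` estimates the variant's free parameters by minimising
    the sum of squared rating residuals; ``predict`` runs the fitted
    forward model.  Rows of ``X`` are consecutive 10 s bins of a single
    recording (the model is a time-series filter: row order matters).

    Parameters
    ----------
    variant : {"full", "no_activity", "no_memory", "linear_regression"}
        Model structure.  ``no_activity`` pins the activity context to 0
        (4 free parameters); ``no_memory`` removes the carry-over from the
        previous breath (5 free parameters); ``linear_regression`` is the
        affine baseline rating ~ CO2 (2 free parameters).
    alpha, tau_a, c_ref : float
        Structural constants of the perceptual model (state persistence per
        bin, activity time constant in s, CO2 reference in %).
    bin_s : float
        Bin width in seconds of the input grid.
    n_starts, seed, bounds, tol, log_rho
        Multi-start optimizer settings; see :class:`FitOptions`.
    extra_starts : list of dict, optional
        Additional start points (free-parameter name -> value), e.g. a
        fitted restricted variant used to warm-start the full model.

    Attributes
    ----------
    params_ : ModelParams
        Fitted parameters (state-space variants only).
    coef_ : dict
        Fitted free parameters by name.
    rss_, n_obs_, k_free_, converged_, start_rss_ :
        Fit diagnostics; ``rss_`` is the best restart's residual sum of
        squares over the non-missing rating bins.
    """

    def __init__(
        self,
        variant: str = "full",
        alpha: float = 0.8,
        tau_a: float = 40.0,
        c_ref: float = 5.0,
        bin_s: float = 10.0,
        n_starts: int = 20,
        seed: int = 0,
        bounds: dict | None = None,
        tol: float = 1e-10,
        log_rho: bool = True,
        init_var: float = 1e3,
        extra_starts: list | None = None,
    ):
        self.variant = variant
        self.alpha = alpha
        self.tau_a = tau_a
        self.c_ref = c_ref
        self.bin_s = bin_s
        self.n_starts = n_starts
        self.seed = seed
        self.bounds = bounds
        self.tol = tol
        self.log_rho = log_rho
        self.init_var = init_var
        self.extra_starts = extra_starts

    # -- helpers -----------------------------------------------------------

    def _validate_X(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError(
                    "X must be a single etCO2 series: shape (n,) or (n, 1)"
                )
            x = x[:, 0]
        elif x.ndim != 1:
            raise ValueError("X must be 1-D or a single-column 2-D array")
        if x.size == 0 or not np.all(np.isfinite(x)):
            raise ValueError("etCO2 series must be nonempty and finite")
        return x

    def _bound(self, name):
        merged = dict(DEFAULT_BOUNDS)
        merged.update(self.bounds or {})
        return merged[name]

    def _free_names(self):
        names = list(FREE_PARAMS[self.variant])
        if self.log_rho and "rho" in names:
            names[names.index("rho")] = "log10_rho"
        return names

    def _theta_to_params(self, theta, names) -> ModelParams:
        d = dict(zip(names, theta))
        rho = 10.0 ** d["log10_rho"] if "log10_rho" in d else d["rho"]
        return ModelParams(
            rho=rho,
            w_c=d["w_c"],
            activity=d.get("activity", 0.0),
            gain=d["gain"],
            offset=d["offset"],
            alpha=self.alpha,
            tau_a=self.tau_a,
            c_ref=self.c_ref,
        )

    def _coef_from_params(self, p: ModelParams) -> dict:
        return {k: getattr(p, k) for k in FREE_PARAMS[self.variant]}

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        x = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape != x.shape:
            raise ValueError("y must have one rating (or NaN) per bin")
        mask = np.isfinite(y)
        n_obs = int(mask.sum())
        k = len(FREE_PARAMS[self.variant])
        if self.variant == "linear_regression":
            if n_obs < 3:
                raise ValueError("need >= 3 non-missing ratings")
        elif n_obs < k + 2:
            raise ValueError(
                f"need >= {k + 2} non-missing ratings, got {n_obs}"
            )
        yo = y[mask]
        if n_obs and np.ptp(yo) == 0 and self.variant != "linear_regression":
            warnings.warn(
                "all ratings identical: gain is unidentifiable", stacklevel=2
            )
        self.n_features_in_ = 1
        self.n_obs_ = n_obs
        self.k_free_ = k
        if self.variant == "linear_regression":
            self._fit_linear(x, yo, mask)
        else:
            self._fit_state_space(x, yo, mask)
        return self

    def _fit_linear(self, x, yo, mask) -> None:
        xo = x[mask]
        if np.ptp(xo) == 0:
            raise ValueError("constant etCO2: linear regression is singular")
        design = np.column_stack([np.ones_like(xo), xo])
        beta, *_ = np.linalg.lstsq(design, yo, rcond=None)
        resid = yo - design @ beta
        self.coef_ = {"intercept": float(beta[0]), "slope": float(beta[1])}
        self.params_ = None
        self.rss_ = float(resid @ resid)
        self.converged_ = True
        self.start_rss_ = np.array([self.rss_])

    def _fit_state_space(self, x, yo, mask) -> None:
        names = self._free_names()
        lo = np.array([self._bound(n)[0] for n in names])
        hi = np.array([self._bound(n)[1] for n in names])

        def residuals(theta):
            p = self._theta_to_params(theta, names)
            traj = forward_model(
                x, p, self.variant, self.bin_s, init_var=self.init_var
            )
            return traj.b_pred[mask] - yo

        starts = qmc.scale(
            qmc.LatinHypercube(d=len(names), seed=self.seed).random(
                self.n_starts
            ),
            lo,
            hi,
        )
        extra = []
        for d in self.extra_starts or []:
            t0 = []
            for n in names:
                if n == "log10_rho" and "rho" in d:
                    t0.append(np.log10(d["rho"]))
                else:
                    t0.append(d[n])
            extra.append(np.clip(t0, lo, hi))
        if extra:
            starts = np.vstack([starts, extra])

        best = None
        start_rss = np.empty(len(starts))
        for i, t0 in enumerate(starts):
            sol = least_squares(
                residuals,
                t0,
                bounds=(lo, hi),
                method="trf",
                ftol=self.tol,
                xtol=self.tol,
                gtol=self.tol,
            )
            start_rss[i] = 2.0 * sol.cost  # cost is 0.5 * sum of squares
            if best is None or start_rss[i] < 2.0 * best.cost:
                best = sol
        p = self._theta_to_params(best.x, names)
        self.params_ = p
        self.coef_ = self._coef_from_params(p)
        self.rss_ = float(2.0 * best.cost)
        self.converged_ = bool(best.success)
        self.start_rss_ = start_rss

    # -- prediction --------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        x = self._validate_X(X)
        if self.variant == "linear_regression":
            return self.coef_["intercept"] + self.coef_["slope"] * x
        return self.latent(x).b_pred

    def latent(self, X) -> LatentTrajectory:
        """Full latent trajectory under the fitted parameters."""
        self._check_fitted()
        if self.variant == "linear_regression":
            raise ValueError("linear baseline has no latent trajectory")
        x = self._validate_X(X)
        return forward_model(
            x, self.params_, self.variant, self.bin_s, init_var=self.init_var
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise AttributeError("estimator is not fitted yet")

    def result_(self) -> FitResult:
        """Fit diagnostics bundled as a :class:`FitResult`."""
        self._check_fitted()
        return FitResult(
            variant=self.variant,
            params=self.params_,
            coef=dict(self.coef_),
            rss=self.rss_,
            n_obs=self.n_obs_,
            k_free=self.k_free_,
            converged=self.converged_,
            start_rss=self.start_rss_,
        )


def _estimator(variant, options: FitOptions | None, **kw):
    opt = options or FitOptions()
    return BreathlessnessPerceptionModel(
        variant=variant,
        n_starts=opt.n_starts,
        seed=opt.seed,
        bounds=opt.bounds,
        tol=opt.tolerance,
        log_rho=opt.log_rho,
        **kw,
    )


def fit_model(
    trace: ExperimentTrace,
    variant: str = "full",
    options: FitOptions | None = None,
    **estimator_kw,
) -> FitResult:
    """Fit one state-space variant to a trace; thin wrapper over the
    estimator class."""
    est = _estimator(variant, options, **estimator_kw)
    est.fit(trace.etco2, trace.rating)
    return est.result_()


def fit_linear(trace: ExperimentTrace) -> FitResult:
    """Closed-form linear-regression baseline: rating ~ binned etCO2."""
    est = BreathlessnessPerceptionModel(variant="linear_regression")
    est.fit(trace.etco2, trace.rating)
    return est.result_()
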
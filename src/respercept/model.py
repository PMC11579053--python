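"""Perceptual model of breathlessness: Kalman CO2 estimation, respiratory
state dynamics with activity context, and linear readout to a 0-100 rating.

The model assumes the brain tracks arterial CO2 through a scalar random-walk
Kalman filter applied to noisy end-tidal CO2 measurements, feeds the CO2
estimate (as deviation from a reference level) into a single latent
"respiratory state" that also carries over from the previous breath and
receives a slowly saturating drive from the current activity context, and
reads the state out linearly onto the visual-analog rating scale.

Five parameters are free per individual: the measurement-to-process noise
ratio ``rho``, the CO2 update weight ``w_c``, the activity-context level
``activity``, and the readout ``gain`` and ``offset``.  The remaining
constants (state persistence ``alpha``, activity time constant ``tau_a``,
CO2 reference ``c_ref``) are structural and shared across individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, asdict

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "VARIANTS",
    "ModelParams",
    "LatentTrajectory",
    "steady_state_gain",
    "kalman_filter",
    "activity_trajectory",
    "respiratory_state",
    "readout",
    "forward_model",
    "apply_variant",
]

#: Model variants: the full model, the ablations (no activity context /
#: no carry-over from the previous breath), and the linear-regression
#: baseline (rating as an affine function of measured CO2).
VARIANTS = ("full", "no_activity", "no_memory", "linear_regression")

RATING_MIN = 0.0
RATING_MAX = 100.0


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the perceptual model.

    Parameters
    ----------
    rho : float
        Ratio of measurement-noise variance to process-noise variance of the
        internal CO2 random walk (dimensionless, > 0). High ``rho`` means an
        unreliable sensor: the CO2 estimate leans on the prediction.
    w_c : float
        Weight of the estimated CO2 deviation on the respiratory state, per
        10 s step (state units per % CO2).
    activity : float
        Activity-context level (respiratory-state units). Its effect on the
        state builds up with time constant ``tau_a`` and saturates at
        ``activity``.
    gain, offset : float
        Linear readout from respiratory state to the 0-100 rating scale.
    alpha : float
        Respiratory-state persistence per step, structural constant in
        [0, 1).
    tau_a : float
        Activity-effect time constant in seconds, structural constant.
    c_ref : float
        CO2 reference level in % CO2; the state is driven by deviations from
        it.
    """

    rho: float
    w_c: float
    activity: float
    gain: float
    offset: float
    alpha: float = 0.8
    tau_a: float = 40.0
    c_ref: float = 5.0

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError(f"rho must be > 0, got {self.rho}")
        if not self.tau_a > 0:
            raise ValueError(f"tau_a must be > 0, got {self.tau_a}")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass
class LatentTrajectory:
    """Per-bin internal series produced by the forward model."""

    c_hat: np.ndarray   #: posterior mean of internal CO2 (% CO2)
    kgain: np.ndarray   #: Kalman gain per bin, in (0, 1]
    a: np.ndarray       #: activity effect (respiratory-state units)
    x: np.ndarray       #: respiratory state
    b_pred: np.ndarray  #: predicted rating, clipped to [0, 100]

    def __len__(self) -> int:
        return len(self.b_pred)

    def to_frame(self, time_s=None):
        import pandas as pd

        if time_s is None:
            time_s = np.arange(len(self), dtype=float)
        return pd.DataFrame(
            {
                "time_s": np.asarray(time_s, dtype=float),
                "c_hat": self.c_hat,
                "kgain": self.kgain,
                "a": self.a,
                "x": self.x,
                "b_pred": self.b_pred,
            }
        )

    def to_csv(self, path, time_s=None) -> None:
        self.to_frame(time_s).to_csv(path, index=False)


def apply_variant(params: ModelParams, variant: str) -> ModelParams:
    """Pin the structural restriction of a model variant onto ``params``.

    ``no_activity`` sets the activity context to zero; ``no_memory`` removes
    the carry-over from the previous breath by setting ``alpha = 0``.
    """
    if variant not in VARIANTS or variant == "linear_regression":
        raise ValueError(f"not a state-space variant: {variant!r}")
    if variant == "no_activity":
        return replace(params, activity=0.0)
    if variant == "no_memory":
        return replace(params, alpha=0.0)
    return params


def steady_state_gain(rho: float) -> float:
    """Steady-state Kalman gain of the scalar random-walk filter.

    For state noise q = 1 and measurement noise r = rho, the prior variance
    fixed point of the Riccati recursion M = P + 1, P = (1 - K) M solves
    M^2 = M + rho, i.e. M = (1 + sqrt(1 + 4 rho)) / 2, and the gain is
    K = M / (M + rho).  Strictly decreasing in rho, with K -> 1 as rho -> 0
    (perfect sensor) and K ~ 1/sqrt(rho) -> 0 as rho -> inf.
    """
    if not rho > 0:
        raise ValueError(f"rho must be > 0, got {rho}")
    m = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * rho))
    return float(m / (m + rho))


def kalman_filter(
    etco2,
    rho: float,
    init_mean: float | None = None,
    init_var: float = 1e3,
):
    """Scalar Kalman filter for the internal CO2 estimate.

    Random-walk state with process-noise variance q = 1 (only the ratio
    r/q = rho is identifiable) and measurement-noise variance r = rho.
    Each step: prior mean = previous posterior mean, prior variance
    M = P + 1, gain K = M / (M + rho), posterior mean updated by K times
    the innovation, posterior variance P = (1 - K) M.

    ``(init_mean, init_var)`` is the posterior before the first bin; the
    defaults (first observation, 1e3) give a diffuse start whose first-bin
    estimate equals the first observation.

    Returns
    -------
    c_hat, kgain : ndarray
        Posterior means (% CO2) and Kalman gains, same length as ``etco2``.
    """
    y = np.asarray(etco2, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("etco2 must be a nonempty 1-D series")
    if not np.all(np.isfinite(y)):
        raise ValueError("etco2 contains non-finite values")
    if not rho > 0:
        raise ValueError(f"rho must be > 0, got {rho}")
    if init_var < 0:
        raise ValueError(f"init_var must be >= 0, got {init_var}")

    mean = y[0] if init_mean is None else float(init_mean)
    p = float(init_var)
    c_hat = np.empty_like(y)
    kgain = np.empty_like(y)
    for t in range(y.size):
        m = p + 1.0
        k = m / (m + rho)
        mean = mean + k * (y[t] - mean)
        p = (1.0 - k) * m
        c_hat[t] = mean
        kgain[t] = k
    return c_hat, kgain


def activity_trajectory(
    activity: float, tau_a: float, n_bins: int, bin_s: float = 10.0
) -> np.ndarray:
    """Saturating effect of a constant activity context.

    First-order relaxation toward the context level: starting from zero, the
    effect at bin t is ``activity * (1 - (1 - bin_s/tau_a)**t)``.  With the
    default constants the effect reaches ~95% of its plateau after about two
    minutes.
    """
    if not tau_a > 0:
        raise ValueError(f"tau_a must be > 0, got {tau_a}")
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    if bin_s >= tau_a:
        warnings.warn(
            f"bin_s ({bin_s}) >= tau_a ({tau_a}): relaxation step overshoots",
            stacklevel=2,
        )
    lam = 1.0 - bin_s / tau_a
    t = np.arange(n_bins, dtype=float)
    return activity * (1.0 - lam**t)


def respiratory_state(
    c_hat, a, params: ModelParams, variant: str = "full"
) -> np.ndarray:
    """Latent respiratory state driven by estimated CO2 and activity.

    x_t = alpha x_{t-1} + w_c (c_hat_t - c_ref) + (1 - alpha) a_t, starting
    from x = 0 before the first bin.  ``no_memory`` runs with alpha = 0
    (pure per-bin drive), ``no_activity`` with the activity effect zeroed.
    The (1 - alpha) scaling makes the saturated activity contribution equal
    the context level in state units, independent of alpha.
    """
    p = apply_variant(params, variant)
    c_hat = np.asarray(c_hat, dtype=float)
    a = np.asarray(a, dtype=float)
    if c_hat.shape != a.shape:
        raise ValueError(
            f"length mismatch: c_hat has {c_hat.shape}, a has {a.shape}"
        )
    if variant == "no_activity":
        a = np.zeros_like(a)
    drive = p.w_c * (c_hat - p.c_ref) + (1.0 - p.alpha) * a
    # x_t = alpha x_{t-1} + drive_t  <=>  IIR filter 1 / (1 - alpha z^-1)
    return lfilter([1.0], [1.0, -p.alpha], drive)


def readout(x, gain: float, offset: float) -> np.ndarray:
    """Affine map from respiratory state to the rating scale, clipped to
    the instrument's hard limits [0, 100]."""
    x = np.asarray(x, dtype=float)
    return np.clip(gain * x + offset, RATING_MIN, RATING_MAX)


def forward_model(
    etco2,
    params: ModelParams,
    variant: str = "full",
    bin_s: float = 10.0,
    init_mean: float | None = None,
    init_var: float = 1e3,
) -> LatentTrajectory:
    """Run the full perceptual cascade on a binned end-tidal CO2 series.

    Composition of :func:`kalman_filter`, :func:`activity_trajectory`,
    :func:`respiratory_state` and :func:`readout`; deterministic, returns
    every intermediate series.
    """
    p = apply_variant(params, variant)
    c_hat, kgain = kalman_filter(etco2, p.rho, init_mean, init_var)
    a = activity_trajectory(p.activity, p.tau_a, c_hat.size, bin_s)
    x = respiratory_state(c_hat, a, p, variant="full")  # p already pinned
    b_pred = readout(x, p.gain, p.offset)
    return LatentTrajectory(c_hat=c_hat, kgain=kgain, a=a, x=x, b_pred=b_pred)
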
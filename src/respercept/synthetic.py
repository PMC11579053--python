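"""Synthetic rebreathing experiments with known ground truth.

Generates protocol-realistic end-tidal CO2 trajectories (baseline plateau,
linear rise during rebreathing, exponential return during recovery), raw
50 Hz trapezoid capnograms for exercising the breath-detection path, and
virtual participants whose ratings come from the perceptual model itself
plus Gaussian rating noise.  Because generation and fitting share one
forward-model implementation, recovery experiments probe the estimation
procedure, not model drift.

The three named profiles encode the heterogeneity seen across real
participants: ``sensory_dominated`` (ratings track CO2 and recover),
``persistent`` (ratings stay high after CO2 has returned to baseline —
breathlessness decoupled from the stimulus), and ``low_responder`` (weak
ratings throughout).  ``memoryless`` generates from the no-memory variant
for model-selection studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .data_io import Capnogram, ExperimentTrace, Protocol
from .estimators import FREE_PARAMS, FitOptions, fit_model
from .model import LatentTrajectory, ModelParams, forward_model

__all__ = [
    "SyntheticProfile",
    "PROFILES",
    "get_profile",
    "generate_co2_trace",
    "generate_capnogram",
    "generate_participant",
    "recovery_experiment",
    "RecoveryReport",
    "selection_experiment",
]


@dataclass(frozen=True)
class SyntheticProfile:
    """Ground truth for one virtual participant.

    CO2 settings: baseline level (%), rebreathing ramp slope (%/min),
    recovery decay time constant (s) and additive per-bin noise SD (%).
    ``rating_noise_sd`` is the SD of the Gaussian noise added to the model's
    predicted rating (rating units), clipped afterwards to [0, 100].
    """

    name: str
    params: ModelParams
    variant: str = "full"
    rating_noise_sd: float = 0.0
    baseline_pct: float = 5.2
    ramp_pct_per_min: float = 0.9
    recovery_tau_s: float = 30.0
    co2_noise_sd_pct: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rating_noise_sd < 0 or self.co2_noise_sd_pct < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 3.0 <= self.baseline_pct <= 7.0:
            raise ValueError("baseline_pct must lie in [3, 7] %")
        if self.recovery_tau_s <= 0:
            raise ValueError("recovery_tau_s must be > 0")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticProfile":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        d["params"] = ModelParams(**d["params"])
        return cls(**d)


def _profiles() -> dict[str, SyntheticProfile]:
    return {
        # tracks CO2 with a reliable sensor and no activity drive;
        # ratings rise and fall with the stimulus
        "sensory_dominated": SyntheticProfile(
            name="sensory_dominated",
            params=ModelParams(
                rho=0.1, w_c=2.0, activity=0.0, gain=3.0, offset=5.0
            ),
            variant="no_activity",
            rating_noise_sd=2.0,
        ),
        # unreliable sensor plus a strong activity context: breathlessness
        # builds through the run and stays high after CO2 normalises
        "persistent": SyntheticProfile(
            name="persistent",
            params=ModelParams(
                rho=100.0, w_c=2.0, activity=60.0, gain=1.0, offset=5.0
            ),
            variant="full",
            rating_noise_sd=2.0,
        ),
        # weak coupling throughout: low, flat-ish ratings
        "low_responder": SyntheticProfile(
            name="low_responder",
            params=ModelParams(
                rho=1.0, w_c=0.5, activity=5.0, gain=1.0, offset=2.0
            ),
            variant="full",
            rating_noise_sd=2.0,
        ),
        # no carry-over from the previous breath (memoryless variant)
        "memoryless": SyntheticProfile(
            name="memoryless",
            params=ModelParams(
                rho=1.0, w_c=3.0, activity=20.0, gain=2.0, offset=5.0
            ),
            variant="no_memory",
            rating_noise_sd=2.0,
        ),
    }


PROFILES = tuple(_profiles())


def get_profile(name: str, **overrides) -> SyntheticProfile:
    """Named profile, optionally with fields overridden
    (e.g. ``get_profile("persistent", rating_noise_sd=5.0, seed=7)``)."""
    table = _profiles()
    if name not in table:
        raise KeyError(f"unknown profile {name!r}; known: {sorted(table)}")
    prof = table[name]
    return replace(prof, **overrides) if overrides else prof


def _co2_mean(profile: SyntheticProfile, protocol: Protocol) -> np.ndarray:
    """Noise-free per-bin etCO2 at bin centers."""
    t = protocol.bin_centers()
    base = profile.baseline_pct
    slope = profile.ramp_pct_per_min / 60.0
    t_on = protocol.baseline_s
    t_off = protocol.baseline_s + protocol.rebreathing_s
    excursion = slope * protocol.rebreathing_s
    out = np.full_like(t, base)
    ramp = (t >= t_on) & (t < t_off)
    out[ramp] = base + slope * (t[ramp] - t_on)
    rec = t >= t_off
    out[rec] = base + excursion * np.exp(
        -(t[rec] - t_off) / profile.recovery_tau_s
    )
    return out


def generate_co2_trace(
    profile: SyntheticProfile,
    protocol: Protocol | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Per-bin etCO2 series: baseline plateau, linear rebreathing ramp,
    exponential recovery, plus Gaussian noise clipped to >= 0.

    Deterministic given the seed (``profile.seed`` when not supplied).
    """
    protocol = protocol or Protocol()
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    out = _co2_mean(profile, protocol)
    if profile.co2_noise_sd_pct > 0:
        out = out + rng.normal(0.0, profile.co2_noise_sd_pct, out.size)
    return np.clip(out, 0.0, None)


def generate_capnogram(
    etco2_targets,
    protocol: Protocol | None = None,
    breath_period_s: float = 4.0,
    inspired_frac: float = 0.4,
) -> Capnogram:
    """Trapezoid-wave capnogram whose per-breath maxima are the targets.

    Each cycle rises from the inspiratory trough to an expiratory plateau at
    the breath's target end-tidal value, then falls back.  The trough is
    0 % during baseline and recovery; during rebreathing it rises linearly
    to ``inspired_frac`` of the plateau (a deliberately wide inspired/
    end-tidal gap that keeps trough-crossing breath detection valid).
    """
    protocol = protocol or Protocol()
    targets = np.asarray(etco2_targets, dtype=float)
    if targets.size == 0:
        raise ValueError("empty capnogram: no breaths requested")
    if breath_period_s < 2.0 / protocol.sample_rate_hz:
        raise ValueError("breath_period_s below twice the sample interval")
    spb = int(round(breath_period_s * protocol.sample_rate_hz))
    t_on = protocol.baseline_s
    t_off = protocol.baseline_s + protocol.rebreathing_s
    # piecewise-linear cycle: trough -> rise -> plateau -> fall -> trough
    knots = np.array([0.0, 0.15, 0.35, 0.75, 0.9, 1.0])
    frac = np.arange(spb) / spb
    segs = []
    for i, target in enumerate(targets):
        t0 = i * breath_period_s
        if t_on <= t0 < t_off:
            trough = inspired_frac * target * (t0 - t_on) / (t_off - t_on)
        else:
            trough = 0.0
        levels = np.array([trough, trough, target, target, trough, trough])
        segs.append(np.interp(frac, knots, levels))
    co2 = np.concatenate(segs)
    time = np.arange(co2.size) / protocol.sample_rate_hz
    return Capnogram(time=time, co2=co2)


def generate_participant(
    profile: SyntheticProfile,
    protocol: Protocol | None = None,
    seed: int | None = None,
) -> tuple[ExperimentTrace, LatentTrajectory]:
    """Simulate one virtual participant.

    Ratings are the forward model's prediction under the profile's true
    parameters and variant, plus Gaussian rating noise, clipped to [0, 100].
    Returns the trace together with the noise-free latent trajectory.
    """
    protocol = protocol or Protocol()
    seed = profile.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    etco2 = _co2_mean(profile, protocol)
    if profile.co2_noise_sd_pct > 0:
        etco2 = etco2 + rng.normal(0.0, profile.co2_noise_sd_pct, etco2.size)
    etco2 = np.clip(etco2, 0.0, None)
    traj = forward_model(
        etco2, profile.params, profile.variant, bin_s=protocol.bin_s
    )
    rating = traj.b_pred.copy()
    if profile.rating_noise_sd > 0:
        rating = rating + rng.normal(
            0.0, profile.rating_noise_sd, rating.size
        )
    rating = np.clip(rating, 0.0, 100.0)
    trace = ExperimentTrace(
        t=protocol.bin_centers(),
        phase=protocol.phase_labels(),
        etco2=etco2,
        rating=rating,
        protocol=protocol,
    )
    return trace, traj


@dataclass
class RecoveryReport:
    """Truth-vs-estimate statistics of a parameter-recovery experiment.

    Besides the raw free parameters, the report covers the identifiable
    combinations ``gain*w_c`` and ``gain*activity``: the readout scale
    trades off exactly against the state-drive weights (predictions are
    invariant under gain -> gain/s, w_c -> s w_c, activity -> s activity),
    so only these products — together with rho and offset — are determined
    by the data.
    """

    profile: SyntheticProfile
    n_reps: int
    truth: dict[str, float]
    estimates: pd.DataFrame  #: one row per replicate, one column per param

    def _with_products(self):
        truth = dict(self.truth)
        est = self.estimates.copy()
        if {"gain", "w_c"} <= set(truth):
            truth["gain*w_c"] = truth["gain"] * truth["w_c"]
            est["gain*w_c"] = est["gain"] * est["w_c"]
        if {"gain", "activity"} <= set(truth):
            truth["gain*activity"] = truth["gain"] * truth["activity"]
            est["gain*activity"] = est["gain"] * est["activity"]
        return truth, est

    def to_frame(self) -> pd.DataFrame:
        """Bias, RMSE and relative-error quantiles per free parameter and
        per identifiable combination."""
        truth_all, est_all = self._with_products()
        rows = []
        for name, true_val in truth_all.items():
            est = est_all[name].to_numpy(dtype=float)
            err = est - true_val
            scale = abs(true_val) if true_val != 0 else 1.0
            rel = np.abs(err) / scale
            rows.append(
                {
                    "param": name,
                    "truth": true_val,
                    "mean_estimate": est.mean(),
                    "bias": err.mean(),
                    "rmse": float(np.sqrt(np.mean(err**2))),
                    "rel_err_q25": float(np.quantile(rel, 0.25)),
                    "rel_err_median": float(np.quantile(rel, 0.5)),
                    "rel_err_q75": float(np.quantile(rel, 0.75)),
                }
            )
        return pd.DataFrame(rows).set_index("param")

    def median_rel_error(self, name: str) -> float:
        return float(self.to_frame().loc[name, "rel_err_median"])


def recovery_experiment(
    profile: SyntheticProfile,
    n_reps: int,
    options: FitOptions | None = None,
    protocol: Protocol | None = None,
) -> RecoveryReport:
    """Simulate ``n_reps`` participants from one profile and refit the
    generating variant; deterministic given ``profile.seed``
    (replicate i uses seed ``profile.seed + i``)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    options = options or FitOptions()
    names = FREE_PARAMS[profile.variant]
    truth = {k: getattr(profile.params, k) for k in names}
    rows = []
    for i in range(n_reps):
        trace, _ = generate_participant(
            profile, protocol, seed=profile.seed + i
        )
        res = fit_model(trace, profile.variant, options)
        rows.append({k: res.coef[k] for k in names})
    return RecoveryReport(
        profile=profile,
        n_reps=n_reps,
        truth=truth,
        estimates=pd.DataFrame(rows),
    )


def selection_experiment(
    profile: SyntheticProfile,
    n_reps: int,
    options: FitOptions | None = None,
    protocol: Protocol | None = None,
) -> pd.Series:
    """Model-selection recovery: simulate from one profile, run the
    four-way AIC comparison per replicate, count which variant wins."""
    from .comparison import compare_models

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    options = options or FitOptions()
    wins = []
    for i in range(n_reps):
        trace, _ = generate_participant(
            profile, protocol, seed=profile.seed + i
        )
        wins.append(compare_models(trace, options).best)
    return pd.Series(wins, name="best").value_counts()
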
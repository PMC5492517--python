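"""Seeded simulator of steering/yaw telemetry under three fatigue regimes.

No public dataset of labelled real-road steering recordings exists for this
problem, so the package ships a generative stand-in that reproduces the
qualitative operation signatures of the three fatigue levels:

* **awake** — frequent small-range steering corrections;
* **drowsy** — infrequent corrections of larger amplitude and higher
  angular velocity;
* **very drowsy** — long flat plateaus (the wheel held still) punctuated
  by quick, large-amplitude corrections.

Steering (SWA) is modelled as a piecewise-linear correction process: event
times follow a Poisson process, each event ramps the wheel toward a fresh
target angle drawn around straight-ahead (making the process mean-reverting
and hence bounded), at the regime's slew rate. The very-drowsy regime adds
exponentially distributed zero-derivative plateaus between events. Yaw (YA)
is a first-order low-pass response to the steering input scaled by a gain,
as a minimal surrogate for lateral vehicle dynamics. Both channels carry
additive Gaussian sensor noise. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import DriveSample, FatigueLabel, TimeSeriesSignal

__all__ = [
    "RegimeParams",
    "default_regime_params",
    "generate_sample",
    "generate_dataset",
]


@dataclass(frozen=True)
class RegimeParams:
    """Generative parameters of one fatigue regime.

    Attributes
    ----------
    correction_rate : float
        Steering-correction events per second (Poisson rate).
    amplitude_deg : float
        Scale of the target-angle distribution (degrees); corrections move
        the wheel toward N(0, amplitude_deg) targets.
    slew_deg_per_s : float
        Typical angular velocity of a correction ramp (deg/s); each event's
        slew is jittered by +/-25 %.
    plateau_s : float
        Mean duration of the flat holds inserted between events (seconds);
        0 disables plateaus (used for the awake and drowsy regimes).
    noise_deg : float
        SD of additive Gaussian sensor noise on both channels (degrees);
        0 gives a noiseless signal.
    ya_gain : float
        Static gain from steering angle to yaw angle.
    ya_smooth_s : float
        Time constant of the first-order low-pass from SWA to YA (seconds).
    """

    correction_rate: float
    amplitude_deg: float
    slew_deg_per_s: float
    plateau_s: float = 0.0
    noise_deg: float = 0.1
    ya_gain: float = 0.1
    ya_smooth_s: float = 0.5

    def __post_init__(self) -> None:
        for name in ("correction_rate", "amplitude_deg", "slew_deg_per_s",
                     "ya_gain", "ya_smooth_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.plateau_s < 0 or self.noise_deg < 0:
            raise ValueError("plateau_s and noise_deg must be non-negative")


_DEFAULTS = {
    FatigueLabel.AWAKE: RegimeParams(
        correction_rate=1.5, amplitude_deg=1.5, slew_deg_per_s=10.0),
    FatigueLabel.DROWSY: RegimeParams(
        correction_rate=0.4, amplitude_deg=6.0, slew_deg_per_s=30.0),
    FatigueLabel.VERY_DROWSY: RegimeParams(
        correction_rate=0.2, amplitude_deg=10.0, slew_deg_per_s=60.0,
        plateau_s=4.0),
}


def default_regime_params(level: FatigueLabel) -> RegimeParams:
    """Default generative parameters for a fatigue level."""
    return _DEFAULTS[FatigueLabel(level)]


def _steering_breakpoints(
    duration_s: float, params: RegimeParams, rng: np.random.Generator
) -> tuple[list[float], list[float]]:
    """Event-driven piecewise-linear steering trajectory as breakpoints."""
    times = [0.0]
    angles = [0.0]
    t = 0.0
    angle = 0.0
    while t <= duration_s:
        gap = rng.exponential(1.0 / params.correction_rate)
        if params.plateau_s > 0:
            gap += rng.exponential(params.plateau_s)
        t_event = t + gap
        # truncated draw keeps the noiseless trajectory within
        # +/- 3 * amplitude_deg of straight-ahead (bounded steering)
        target = params.amplitude_deg * float(np.clip(rng.normal(), -3.0, 3.0))
        slew = params.slew_deg_per_s * rng.uniform(0.75, 1.25)
        ramp = abs(target - angle) / slew
        times.extend([t_event, t_event + ramp])
        angles.extend([angle, target])
        angle = target
        t = t_event + ramp
    return times, angles


def _lowpass(x: np.ndarray, fs: float, tau_s: float) -> np.ndarray:
    """Causal first-order low-pass with time constant tau_s."""
    alpha = (1.0 / fs) / (tau_s + 1.0 / fs)
    y = np.empty_like(x)
    acc = 0.0
    for k in range(x.size):
        acc += alpha * (x[k] - acc)
        y[k] = acc
    return y


def generate_sample(
    level: FatigueLabel,
    duration_s: float = 60.0,
    fs: float = 100.0,
    params: RegimeParams | None = None,
    seed: int = 0,
) -> DriveSample:
    """Generate one labelled SWA/YA sample for a fatigue regime.

    Deterministic given (level, duration, fs, params, seed): the same call
    reproduces bitwise-identical channels.
    """
    if not duration_s > 0 or not fs > 0:
        raise ValueError("duration_s and fs must be positive")
    level = FatigueLabel(level)
    if params is None:
        params = default_regime_params(level)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t_grid = np.arange(n) / fs

    times, angles = _steering_breakpoints(duration_s, params, rng)
    swa_clean = np.interp(t_grid, times, angles)
    ya_clean = _lowpass(params.ya_gain * swa_clean, fs, params.ya_smooth_s)

    if params.noise_deg:
        swa = swa_clean + rng.normal(0.0, params.noise_deg, n)
        # yaw sensing is cleaner than the steering encoder; its noise floor
        # scales with the channel gain
        ya = ya_clean + rng.normal(0.0, params.ya_gain * params.noise_deg, n)
    else:
        swa, ya = swa_clean, ya_clean

    return DriveSample(
        swa=TimeSeriesSignal(swa, fs, "SWA"),
        ya=TimeSeriesSignal(ya, fs, "YA"),
        start_time=0.0,
        label=level,
    )


def generate_dataset(
    n_per_level: int,
    duration_s: float = 60.0,
    fs: float = 100.0,
    seed: int = 0,
    params_by_level: dict[FatigueLabel, RegimeParams] | None = None,
) -> list[DriveSample]:
    """Generate a balanced labelled dataset across the three regimes.

    Per-sample seeds are derived deterministically from the master seed, so
    two calls with the same arguments produce identical datasets. Samples
    are ordered level-major (all awake, then drowsy, then very drowsy).
    """
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=3 * n_per_level)
    samples: list[DriveSample] = []
    for li, level in enumerate(FatigueLabel):
        params = None if params_by_level is None else params_by_level.get(level)
        for k in range(n_per_level):
            samples.append(
                generate_sample(
                    level,
                    duration_s=duration_s,
                    fs=fs,
                    params=params,
                    seed=int(child_seeds[li * n_per_level + k]),
                )
            )
    return samples
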
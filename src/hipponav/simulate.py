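"""Synthetic virtual-driving behaviour and speed-coupled sEEG.

The generator emulates a keyboard-controlled delivery-driving task: a
vehicle accelerates at a steady rate while the forward key is held,
decelerates by friction otherwise, and tips over (speed reset to zero for
a short delay) when turning too fast.  The matching multichannel sEEG is
a 1/f (pink) noise background plus per-channel theta and gamma
oscillations whose amplitude grows linearly with the instantaneous
virtual speed.  Every stage is deterministic given the config seed, so
downstream decoding code can be tested against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConfigError",
    "SimConfig",
    "BehavioralTrace",
    "RecordingSession",
    "simulate_drive",
    "simulate_seeg",
    "generate_session",
]


class ConfigError(ValueError):
    """Raised when a simulation config violates its invariants."""


# Mean dwell times (s) of the seeded Markov key-press policy.  Chosen so a
# session visits the whole speed range, from standstill to v_max.
_DWELL_MEANS = {"accelerate": 4.0, "coast": 2.0, "turn": 1.5}

# Probability of tipping over per second spent turning above v_tip.
_TIP_HAZARD_PER_S = 0.5


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the behavioural task and the sEEG generative model.

    Durations are seconds, speeds are arbitrary game units/s, amplitudes
    are arbitrary signal units.  ``g_theta``/``g_gamma`` are dimensionless
    gains: oscillation amplitude is ``a * (1 + g * v / v_max)``.
    """

    duration_s: float = 652.0
    fs: float = 1024.0
    n_channels: int = 14
    v_max: float = 50.0
    accel: float = 10.0
    friction: float = 5.0
    v_tip: float = 35.0
    tip_delay_s: float = 2.0
    behavior_dt: float = 0.05
    f_theta_range: tuple[float, float] = (4.0, 8.0)
    f_gamma_range: tuple[float, float] = (60.0, 90.0)
    a_theta: float = 1.0
    a_gamma: float = 0.3
    g_theta: float = 0.5
    g_gamma: float = 0.5
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ConfigError(f"duration_s must be > 0, got {self.duration_s}")
        if not self.behavior_dt > 0:
            raise ConfigError(f"behavior_dt must be > 0, got {self.behavior_dt}")
        if not self.fs > 0:
            raise ConfigError(f"fs must be > 0, got {self.fs}")
        if self.n_channels < 1:
            raise ConfigError(f"n_channels must be >= 1, got {self.n_channels}")
        if not 0 < self.v_tip <= self.v_max:
            raise ConfigError(
                f"need 0 < v_tip <= v_max, got v_tip={self.v_tip}, v_max={self.v_max}"
            )
        for name in ("a_theta", "a_gamma", "g_theta", "g_gamma", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        nyq = self.fs / 2.0
        for name in ("f_theta_range", "f_gamma_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi < nyq):
                raise ConfigError(
                    f"{name}=({lo}, {hi}) must lie inside (0, fs/2)={nyq}"
                )

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class BehavioralTrace:
    """Virtual speed on a uniform time grid, with key-press/tip events.

    ``events`` is a list of ``(time_s, tag)`` with tags in
    ``{"accel_on", "accel_off", "tip_over", "reorient"}``.
    """

    t: np.ndarray
    speed: np.ndarray
    events: list[tuple[float, str]] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        dt = self.t[1] - self.t[0] if len(self.t) > 1 else 0.0
        return float(self.t[-1] + dt) if len(self.t) else 0.0


@dataclass
class RecordingSession:
    """Multichannel raw sEEG: channel x sample matrix plus metadata."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_names: list[str]
    hippocampal_mask: np.ndarray  # bool per channel
    reference_note: str = "common white-matter reference (simulated)"

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _drive_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), 0])


def _seeg_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), 1])


def simulate_drive(config: SimConfig) -> BehavioralTrace:
    """Simulate the vehicle's speed trace under a seeded key-press policy.

    The driver is modelled as a three-state Markov policy (accelerate,
    coast, turn) with exponential dwell times.  While accelerating,
    dv/dt = +accel clipped at v_max; otherwise dv/dt = -friction clipped
    at 0.  Turning above ``v_tip`` risks a tip-over (hazard 0.5/s) that
    zeroes the speed for ``tip_delay_s``.
    """
    rng = _drive_rng(config)
    dt = config.behavior_dt
    n = int(round(config.duration_s / dt))
    if n < 1:
        raise ConfigError("duration_s shorter than one behaviour step")
    t = np.arange(n) * dt
    speed = np.empty(n)
    events: list[tuple[float, str]] = []

    # per-step tip probability matching a 0.5/s hazard
    p_tip = 1.0 - (1.0 - _TIP_HAZARD_PER_S) ** dt

    state = "accelerate"
    events.append((0.0, "accel_on"))
    dwell = rng.exponential(_DWELL_MEANS[state])
    tip_timer = 0.0
    v = 0.0

    for i in range(n):
        ti = float(t[i])
        if tip_timer > 0.0:
            v = 0.0
            tip_timer -= dt
            if tip_timer <= 0.0:
                events.append((ti, "reorient"))
                state = "coast"
                dwell = rng.exponential(_DWELL_MEANS[state])
        else:
            if state == "accelerate":
                v = min(v + config.accel * dt, config.v_max)
            else:
                v = max(v - config.friction * dt, 0.0)
            if state == "turn" and v > config.v_tip and rng.random() < p_tip:
                events.append((ti, "tip_over"))
                v = 0.0
                tip_timer = config.tip_delay_s
            else:
                dwell -= dt
                if dwell <= 0.0:
                    others = [s for s in _DWELL_MEANS if s != state]
                    new_state = others[rng.integers(len(others))]
                    if state == "accelerate":
                        events.append((ti, "accel_off"))
                    if new_state == "accelerate":
                        events.append((ti, "accel_on"))
                    state = new_state
                    dwell = rng.exponential(_DWELL_MEANS[state])
        speed[i] = v

    return BehavioralTrace(t=t, speed=speed, events=events)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-power noise via spectral shaping with random phases."""
    n_fft = int(n)
    freqs = np.fft.rfftfreq(n_fft, d=1.0)  # d cancels in the normalization
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])  # power ~ 1/f
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(freqs))
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n_fft % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, n=n_fft)
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def simulate_seeg(trace: BehavioralTrace, config: SimConfig) -> RecordingSession:
    """Synthesize multichannel sEEG whose theta/gamma amplitude tracks speed.

    Per channel c:
        x_c(t) = noise_sigma * pink(t)
               + a_theta * (1 + g_theta * v(t)/v_max) * sin(2*pi*f_theta_c*t + phi_c)
               + a_gamma * (1 + g_gamma * v(t)/v_max) * sin(2*pi*f_gamma_c*t + psi_c)
    with per-channel carrier frequencies drawn uniformly from the
    configured bands and v(t) the trace linearly interpolated onto the
    sEEG sample grid.
    """
    if trace.duration_s + 1e-9 < config.duration_s:
        raise ValueError(
            f"behavioural trace covers {trace.duration_s:.3f} s but the "
            f"session needs {config.duration_s:.3f} s"
        )
    rng = _seeg_rng(config)
    n_samples = int(round(config.duration_s * config.fs))
    t = np.arange(n_samples) / config.fs
    v = np.interp(t, trace.t, trace.speed)
    v_rel = v / config.v_max

    data = np.empty((config.n_channels, n_samples), dtype=np.float32)
    f_th = rng.uniform(*config.f_theta_range, size=config.n_channels)
    f_ga = rng.uniform(*config.f_gamma_range, size=config.n_channels)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=config.n_channels)
    psi = rng.uniform(0.0, 2.0 * np.pi, size=config.n_channels)
    theta_env = config.a_theta * (1.0 + config.g_theta * v_rel)
    gamma_env = config.a_gamma * (1.0 + config.g_gamma * v_rel)
    for c in range(config.n_channels):
        x = config.noise_sigma * _pink_noise(rng, n_samples)
        x += theta_env * np.sin(2.0 * np.pi * f_th[c] * t + phi[c])
        x += gamma_env * np.sin(2.0 * np.pi * f_ga[c] * t + psi[c])
        data[c] = x.astype(np.float32)

    names = [f"H{c + 1:02d}" for c in range(config.n_channels)]
    mask = np.ones(config.n_channels, dtype=bool)
    return RecordingSession(
        data=data, fs=config.fs, channel_names=names, hippocampal_mask=mask
    )


def generate_session(config: SimConfig) -> tuple[RecordingSession, BehavioralTrace]:
    """Simulate behaviour and the matching sEEG from a single seed."""
    trace = simulate_drive(config)
    session = simulate_seeg(trace, config)
    return session, trace
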
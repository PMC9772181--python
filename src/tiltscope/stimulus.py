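"""Rotation-stage stimulus trajectories and the accelerations they impose.

The microscope tilts the objective + specimen with a motorized rotation
stage.  Three protocols are used:

``tilt90``
    still 5 s, rotate +90°, hold 5 s, rotate back, hold 5 s, rotate −90°,
    hold 5 s, rotate back, hold 5 s; trapezoidal velocity profile with
    v_max = 25°/s and |α| = 24.9°/s².
``tilt360``
    still 3 s, rotate +360°, hold 6 s, rotate −360°, hold 3 s;
    v_max = 15°/s, |α| = 24.9°/s².
``vibration``
    bidirectional 2° trapezoidal position cycles at 2.2 Hz for 18 s with
    v_max = 1000°/s and |α| = 1000°/s².

Because the specimen sits off the rotation axis, stage motion also imposes
inertial acceleration: tangential r·α and centripetal r·ω².  Gravity seen
by the specimen decomposes into a centripetal component g·cosθ and a
tangential component g·sinθ.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

G0 = 9.806  # standard gravity, m/s²

__all__ = [
    "G0",
    "StageTrajectory",
    "GravityComponents",
    "InertialAcceleration",
    "AmplitudeSpectrum",
    "UnreachableProfileError",
    "make_tilt_trajectory",
    "make_vibration_trajectory",
    "gravity_components",
    "inertial_acceleration",
    "acceleration_spectrum",
]


class UnreachableProfileError(ValueError):
    """A rotation segment cannot be realised under the velocity/acceleration limits."""


@dataclass
class StageTrajectory:
    """Sampled angular kinematics of the rotation stage.

    ``theta`` is the realised stage angle (including any stop ringing);
    ``omega``/``alpha`` are the nominal trapezoid velocity/acceleration
    profiles in °/s and °/s².  Positive theta means nose-down (pitch
    sessions) or lateral-down (roll sessions) by package convention.
    """

    t: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    protocol: str
    sample_rate: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dt = np.diff(self.t)
        if len(dt) and (dt.min() <= 0 or np.ptp(dt) > 1e-9):
            raise ValueError("time grid must be strictly increasing and uniform")

    @property
    def duration(self) -> float:
        return float(self.t[-1])

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def motion_mask(self, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask of samples where the nominal profile is moving."""
        return np.abs(self.omega) > tol

    def first_motion_time(self) -> float:
        idx = np.nonzero(self.motion_mask())[0]
        if len(idx) == 0:
            return float(self.t[-1])
        return float(self.t[idx[0]])

    def last_motion_time(self) -> float:
        idx = np.nonzero(self.motion_mask())[0]
        if len(idx) == 0:
            return float(self.t[0])
        return float(self.t[idx[-1]])

    def decimate(self, rate: float) -> "StageTrajectory":
        """Resample to a lower rate (e.g. the 10 /s camera rate) by picking samples."""
        step = self.sample_rate / rate
        if step < 1:
            raise ValueError("can only decimate to a lower rate")
        idx = np.round(np.arange(0, len(self.t), step)).astype(int)
        idx = idx[idx < len(self.t)]
        return StageTrajectory(
            t=self.t[idx].copy(),
            theta=self.theta[idx].copy(),
            omega=self.omega[idx].copy(),
            alpha=self.alpha[idx].copy(),
            protocol=self.protocol,
            sample_rate=rate,
            params=dict(self.params),
        )

    def to_csv(self, path) -> None:
        header = "# protocol=%s sample_rate=%g %s\n" % (
            self.protocol,
            self.sample_rate,
            " ".join("%s=%r" % kv for kv in sorted(self.params.items())),
        )
        body = np.column_stack([self.t, self.theta, self.omega, self.alpha])
        with open(path, "w") as fh:
            fh.write(header)
            fh.write("t_s,theta_deg,omega_degps,alpha_degps2\n")
            np.savetxt(fh, body, delimiter=",", fmt="%.9g")

    @classmethod
    def from_csv(cls, path) -> "StageTrajectory":
        with open(path) as fh:
            first = fh.readline()
            protocol = "unknown"
            rate = None
            if first.startswith("#"):
                for tok in first[1:].split():
                    if tok.startswith("protocol="):
                        protocol = tok.split("=", 1)[1]
                    elif tok.startswith("sample_rate="):
                        rate = float(tok.split("=", 1)[1])
                rest = fh.read()
            else:
                rest = first + fh.read()
            data = np.loadtxt(_io.StringIO(rest), delimiter=",", skiprows=1)
        t = data[:, 0]
        if rate is None:
            rate = 1.0 / (t[1] - t[0])
        return cls(t=t, theta=data[:, 1], omega=data[:, 2], alpha=data[:, 3],
                   protocol=protocol, sample_rate=rate)


@dataclass
class GravityComponents:
    """In-plane gravity components in g-units: X centripetal, Y tangential."""

    X_centripetal: np.ndarray
    Y_tangential: np.ndarray
    g0: float = G0

    @property
    def X_mps2(self) -> np.ndarray:
        return self.X_centripetal * self.g0

    @property
    def Y_mps2(self) -> np.ndarray:
        return self.Y_tangential * self.g0


@dataclass
class InertialAcceleration:
    """Inertial acceleration of an off-axis specimen, m/s²."""

    tangential: np.ndarray
    centripetal: np.ndarray
    radius: float


@dataclass
class AmplitudeSpectrum:
    """One-sided discrete-Fourier amplitude spectrum of an acceleration series."""

    frequency: np.ndarray
    amplitude: np.ndarray
    resolution: float
    n_samples: int  # un-padded input length, for Parseval checks

    def lowest_peak(self, min_height_frac: float = 0.1,
                    min_separation_hz: float = 1.0) -> float:
        """Frequency of the lowest-frequency local maximum above a noise floor.

        The floor is ``min_height_frac`` times the global maximum amplitude
        (DC excluded).  ``min_separation_hz`` merges maxima closer than
        this, so rectangular-window sidelobes are not reported as peaks.
        """
        amp = self.amplitude.copy()
        amp[0] = 0.0
        height = min_height_frac * amp.max()
        dist = max(1, int(round(min_separation_hz / self.resolution)))
        peaks, _ = find_peaks(amp, height=height, distance=dist)
        if len(peaks) == 0:
            raise ValueError("no spectral peak above the noise floor")
        return float(self.frequency[peaks[0]])


# ---------------------------------------------------------------------------
# trapezoid kinematics


def _trapezoid_move(delta: float, vmax: float, amax: float):
    """Closed-form trapezoidal (or triangular) move profile.

    Returns (duration, vpeak, t_ramp, t_cruise) for a move of signed angle
    ``delta`` under limits vmax (°/s) and amax (°/s²).
    """
    d = abs(delta)
    if d == 0:
        return 0.0, 0.0, 0.0, 0.0
    if vmax <= 0 or amax <= 0:
        raise UnreachableProfileError(
            f"segment of {delta}°: velocity/acceleration limits must be positive"
        )
    t_ramp = vmax / amax
    d_ramp = 0.5 * amax * t_ramp**2
    if 2 * d_ramp >= d:  # triangular profile, vmax never reached
        t_ramp = np.sqrt(d / amax)
        vpeak = amax * t_ramp
        t_cruise = 0.0
    else:
        vpeak = vmax
        t_cruise = (d - 2 * d_ramp) / vmax
    return 2 * t_ramp + t_cruise, vpeak, t_ramp, t_cruise


def _eval_move(tau: np.ndarray, delta: float, vpeak: float, t_ramp: float,
               t_cruise: float):
    """Analytic θ, ω, α of a trapezoid move at local times ``tau`` (≥ 0)."""
    s = np.sign(delta)
    amax = vpeak / t_ramp if t_ramp > 0 else 0.0
    theta = np.zeros_like(tau)
    omega = np.zeros_like(tau)
    alpha = np.zeros_like(tau)
    t1, t2, t3 = t_ramp, t_ramp + t_cruise, 2 * t_ramp + t_cruise

    m = tau < t1
    theta[m] = 0.5 * amax * tau[m] ** 2
    omega[m] = amax * tau[m]
    alpha[m] = amax

    m = (tau >= t1) & (tau < t2)
    theta[m] = 0.5 * amax * t1**2 + vpeak * (tau[m] - t1)
    omega[m] = vpeak

    m = (tau >= t2) & (tau < t3)
    td = tau[m] - t2
    theta[m] = 0.5 * amax * t1**2 + vpeak * t_cruise + vpeak * td - 0.5 * amax * td**2
    omega[m] = vpeak - amax * td
    alpha[m] = -amax

    m = tau >= t3
    theta[m] = abs(delta)
    return s * theta, s * omega, s * alpha


class _Builder:
    """Piecewise segment assembler on a uniform time grid."""

    def __init__(self, sample_rate: float):
        self.rate = sample_rate
        self.segments = []  # (kind, duration, payload)
        self.theta0 = 0.0

    def hold(self, duration: float):
        if duration > 0:
            self.segments.append(("hold", duration, None))
        return self

    def move(self, delta: float, vmax: float, amax: float, name: str = "move"):
        try:
            dur, vpeak, t_ramp, t_cruise = _trapezoid_move(delta, vmax, amax)
        except UnreachableProfileError as exc:
            raise UnreachableProfileError(f"{name}: {exc}") from None
        if delta != 0:
            self.segments.append(("move", dur, (delta, vpeak, t_ramp, t_cruise)))
        return self

    def build(self, protocol: str, params: dict, ring: dict | None = None):
        total = sum(d for _, d, _ in self.segments)
        n = int(round(total * self.rate)) + 1
        t = np.arange(n) / self.rate
        theta = np.full(n, self.theta0)
        omega = np.zeros(n)
        alpha = np.zeros(n)
        stop_times = []
        t0 = 0.0
        base = self.theta0
        for kind, dur, payload in self.segments:
            m = (t >= t0 - 1e-12) & (t < t0 + dur - 1e-12)
            if kind == "hold":
                theta[m] = base
            else:
                delta, vpeak, t_ramp, t_cruise = payload
                th, om, al = _eval_move(t[m] - t0, delta, vpeak, t_ramp, t_cruise)
                theta[m] = base + th
                omega[m] = om
                alpha[m] = al
                base += delta
                stop_times.append(t0 + dur)
            t0 += dur
        theta[t >= t0 - 1e-12] = base
        if ring is not None and ring.get("amplitude", 0) > 0:
            theta = theta + _ring_series(t, stop_times, **ring)
        return StageTrajectory(t=t, theta=theta, omega=omega, alpha=alpha,
                               protocol=protocol, sample_rate=self.rate,
                               params=params)


def _ring_series(t, stop_times, amplitude=0.02, frequency=80.0, tau=0.05):
    """Exponentially decaying oscillation injected at every move stop.

    Emulates mechanical ringing of the real stage at motion end, which
    spreads the stimulus spectrum up to ~100 Hz.
    """
    out = np.zeros_like(t)
    for ts in stop_times:
        m = t >= ts
        dt = t[m] - ts
        out[m] += amplitude * np.exp(-dt / tau) * np.sin(2 * np.pi * frequency * dt)
    return out


DEFAULT_RING = {"amplitude": 0.02, "frequency": 80.0, "tau": 0.05}


def make_tilt_trajectory(
    protocol: str = "tilt90",
    *,
    vmax: float | None = None,
    amax: float = 24.9,
    hold: float | None = None,
    pre_still: float | None = None,
    angle: float | None = None,
    sample_rate: float = 1000.0,
    ring: dict | None | bool = True,
) -> StageTrajectory:
    """Build a 90° or 360° static-tilt trajectory.

    ``tilt90``: still 5 s → +90° → hold 5 s → back → hold 5 s → −90° →
    hold 5 s → back → hold 5 s, at 25°/s and ±24.9°/s².
    ``tilt360``: still 3 s → +360° → hold 6 s → −360° → hold 3 s, at 15°/s.
    """
    if protocol not in ("tilt90", "tilt360"):
        raise ValueError(f"unknown tilt protocol {protocol!r}")
    if ring is True:
        ring = dict(DEFAULT_RING)
    elif ring is False:
        ring = None
    if protocol == "tilt90":
        vmax = 25.0 if vmax is None else vmax
        hold = 5.0 if hold is None else hold
        pre = 5.0 if pre_still is None else pre_still
        a = 90.0 if angle is None else angle
        b = _Builder(sample_rate)
        b.hold(pre)
        b.move(+a, vmax, amax, "tilt90 +rotation").hold(hold)
        b.move(-a, vmax, amax, "tilt90 return").hold(hold)
        b.move(-a, vmax, amax, "tilt90 -rotation").hold(hold)
        b.move(+a, vmax, amax, "tilt90 return").hold(hold)
    else:
        vmax = 15.0 if vmax is None else vmax
        hold = 6.0 if hold is None else hold
        pre = 3.0 if pre_still is None else pre_still
        a = 360.0 if angle is None else angle
        b = _Builder(sample_rate)
        b.hold(pre)
        b.move(+a, vmax, amax, "tilt360 +rotation").hold(hold)
        b.move(-a, vmax, amax, "tilt360 -rotation").hold(pre)
    params = dict(vmax=vmax, amax=amax, hold=hold, pre_still=pre, angle=a,
                  ring=bool(ring))
    return b.build(protocol, params, ring)


def make_vibration_trajectory(
    *,
    step: float = 2.0,
    rate: float = 2.2,
    vmax: float = 1000.0,
    amax: float = 1000.0,
    duration: float = 18.0,
    pre_still: float = 5.0,
    post_still: float = 5.0,
    sample_rate: float = 1000.0,
    ring: dict | None | bool = False,
) -> StageTrajectory:
    """Bidirectional 2° trapezoidal position cycles at ``rate`` Hz.

    Each cycle is: move +step, dwell, move −step, dwell, with the dwells
    chosen so one full back-and-forth takes 1/rate seconds.
    """
    if ring is True:
        ring = dict(DEFAULT_RING)
    elif ring is False:
        ring = None
    params = dict(step=step, rate=rate, vmax=vmax, amax=amax, duration=duration,
                  pre_still=pre_still, post_still=post_still, ring=bool(ring))
    b = _Builder(sample_rate)
    b.hold(pre_still)
    if step == 0 or duration == 0:
        b.hold(duration + post_still)
        return b.build("vibration", params, ring)
    move_dur, vpeak, t_ramp, t_cruise = _trapezoid_move(step, vmax, amax)
    period = 1.0 / rate
    dwell = period / 2 - move_dur
    if dwell < 0:
        raise UnreachableProfileError(
            f"vibration: a {step}° step takes {move_dur:.4f}s, longer than the "
            f"half-period {period / 2:.4f}s at {rate} Hz under the given limits"
        )
    n_cycles = int(round(duration * rate))
    for _ in range(n_cycles):
        b.move(+step, vmax, amax, "vibration up").hold(dwell)
        b.move(-step, vmax, amax, "vibration down").hold(dwell)
    b.hold(post_still)
    return b.build("vibration", params, ring)


def gravity_components(theta_deg) -> GravityComponents:
    """Decompose gravity into centripetal/tangential components in g-units.

    X(centripetal) = cosθ, Y(tangential) = sinθ; multiply by 9.806 for m/s².
    """
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    if not np.all(np.isfinite(th)):
        raise ValueError("theta must be finite")
    return GravityComponents(X_centripetal=np.cos(th), Y_tangential=np.sin(th))


def inertial_acceleration(traj: StageTrajectory, radius: float) -> InertialAcceleration:
    """Tangential (r·α) and centripetal (r·ω²) acceleration at offset ``radius``.

    Kinematics are obtained from the realised θ series by central differences
    (one-sided at the ends), so stop ringing contributes if enabled.
    """
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    if len(traj.t) < 3:
        raise ValueError("trajectory must have at least 3 samples")
    th = np.deg2rad(traj.theta)
    om = np.gradient(th, traj.dt)
    al = np.gradient(om, traj.dt)
    return InertialAcceleration(tangential=radius * al,
                                centripetal=radius * om**2,
                                radius=radius)


def acceleration_spectrum(series, sample_rate: float, t=None) -> AmplitudeSpectrum:
    """One-sided rectangular-window amplitude spectrum, zero-padded to 2^k.

    Amplitudes are scaled so a pure sinusoid of amplitude A appears as a
    peak of height ≈ A (split across bins when off-grid).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("series must be 1-D with at least 2 samples")
    if t is not None:
        dt = np.diff(np.asarray(t, dtype=float))
        if np.ptp(dt) > 1e-9 * max(abs(dt[0]), 1e-30):
            raise ValueError("non-uniform sampling")
    n = len(x)
    nfft = 1 << int(np.ceil(np.log2(n)))
    spec = np.fft.rfft(x, n=nfft)
    amp = np.abs(spec) * 2.0 / n
    amp[0] /= 2.0
    if nfft % 2 == 0:
        amp[-1] /= 2.0
    freq = np.fft.rfftfreq(nfft, d=1.0 / sample_rate)
    return AmplitudeSpectrum(frequency=freq, amplitude=amp,
                             resolution=sample_rate / nfft, n_samples=n)
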
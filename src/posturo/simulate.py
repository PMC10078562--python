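"""Synthetic cohorts, chaotic fixtures and an independent Lyapunov oracle.

The cohort generator emulates a quiet-standing CO2-challenge study: 10
subjects x 2 inhalation types (AIR, CO2) x 4 time points (5, 10, 15 min
and post-inhalation) x 5 repetitions of 30-s COP trials at 50 Hz, plus a
respiration trace per design cell.

Each COP axis is the sum of

* a mean-reverting Ornstein-Uhlenbeck process, zero-phase low-pass
  smoothed to emulate the mechanical filtering of the standing body — its
  diffusion (``ou_noise_scale``, mm/sqrt(s)) sets the sway path length; and
* a variance-normalised chaotic component sampled from a Lorenz
  trajectory — its gain (``chaos_blend_gain``, mm) sets the local dynamic
  stability (larger gain, larger Lyapunov exponent).

Both are scaled by a per-subject log-normal multiplier, so condition
effects can be injected independently on the two study outcomes while
between-subject variability stays positive and multiplicative.

The module also provides deterministic chaotic fixtures (logistic map,
Lorenz system) and :func:`lyapunov_oracle`, a tangent-space (analytic /
Benettin) largest-exponent computation that shares no code with the
Rosenstein estimator it validates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .core import CopTrial, DataError, DesignError, RespSignal

LOGISTIC = "LOGISTIC"
LORENZ = "LORENZ"

#: Lorenz time units advanced per COP sample in the chaotic blend.  At
#: 50 Hz this maps the Lorenz largest exponent (~0.906 per time unit) to
#: ~0.45 1/s, slow enough that neighbour divergence of a 30-s trial does
#: not saturate inside the 0-0.75 s slope-fit window.
LORENZ_DT_PER_SAMPLE = 0.01
#: Internal Lorenz integration step (time units); samples are taken every
#: LORENZ_DT_PER_SAMPLE / LORENZ_INTEGRATION_DT steps.
LORENZ_INTEGRATION_DT = 0.005


@dataclass(frozen=True)
class ChaoticFixture:
    """A deterministic chaotic test system and its parameters."""

    system: str
    parameters: dict = field(default_factory=dict)
    n_samples: int = 10_000
    transient_discard: int = 1_000

    def __post_init__(self) -> None:
        if self.system not in (LOGISTIC, LORENZ):
            raise DesignError(f"unknown chaotic system {self.system!r}")
        if self.n_samples <= 0 or self.transient_discard < 0:
            raise DataError("n_samples > 0 and transient_discard >= 0 required")
        p = self.params
        if self.system == LOGISTIC and not 0 < p["x0"] < 1:
            raise DataError("logistic x0 must lie in (0, 1)")
        if self.system == LORENZ and p["dt"] <= 0:
            raise DataError("Lorenz dt must be positive")

    @property
    def params(self) -> dict:
        defaults = (
            {"r": 4.0, "x0": 0.3}
            if self.system == LOGISTIC
            else {"sigma": 10.0, "rho": 28.0, "beta": 8.0 / 3.0, "dt": 0.01,
                  "initial": (1.0, 1.0, 20.0)}
        )
        return {**defaults, **self.parameters}


def _logistic_orbit(r: float, x0: float, n: int) -> np.ndarray:
    out = np.empty(n)
    x = x0
    for i in range(n):
        x = r * x * (1.0 - x)
        out[i] = x
    return out


def _lorenz_rhs(state, sigma, rho, beta):
    x, y, z = state
    return (sigma * (y - x), x * (rho - z) - y, x * y - beta * z)


def _lorenz_rk4_step(state, dt, sigma, rho, beta):
    k1 = _lorenz_rhs(state, sigma, rho, beta)
    s2 = tuple(s + 0.5 * dt * k for s, k in zip(state, k1))
    k2 = _lorenz_rhs(s2, sigma, rho, beta)
    s3 = tuple(s + 0.5 * dt * k for s, k in zip(state, k2))
    k3 = _lorenz_rhs(s3, sigma, rho, beta)
    s4 = tuple(s + dt * k for s, k in zip(state, k3))
    k4 = _lorenz_rhs(s4, sigma, rho, beta)
    return tuple(
        s + dt / 6.0 * (a + 2 * b + 2 * c + d)
        for s, a, b, c, d in zip(state, k1, k2, k3, k4)
    )


def _lorenz_orbit(params: dict, n: int, return_all: bool = False) -> np.ndarray:
    sigma, rho, beta, dt = params["sigma"], params["rho"], params["beta"], params["dt"]
    state = tuple(float(v) for v in params["initial"])
    out = np.empty((n, 3))
    for i in range(n):
        state = _lorenz_rk4_step(state, dt, sigma, rho, beta)
        if not all(math.isfinite(s) for s in state):
            raise ArithmeticError(f"Lorenz integration diverged at step {i}")
        out[i] = state
    return out if return_all else out[:, 0]


def chaotic_fixture_series(fixture: ChaoticFixture) -> np.ndarray:
    """Scalar series of a chaotic fixture, transient discarded.

    Logistic: iterates ``x <- r x (1 - x)``.  Lorenz: fixed-step RK4
    integration of the standard equations, returning the first coordinate.
    Bit-identical on rerun for fixed parameters.
    """
    n_total = fixture.n_samples + fixture.transient_discard
    p = fixture.params
    if fixture.system == LOGISTIC:
        series = _logistic_orbit(p["r"], p["x0"], n_total)
    else:
        series = _lorenz_orbit(p, n_total)
    return series[fixture.transient_discard :]


def lyapunov_oracle(fixture: ChaoticFixture) -> float:
    """Independent largest-Lyapunov-exponent computation for a fixture.

    Logistic map: the exact orbit average of ``ln |r (1 - 2x)|`` (nats per
    iteration).  Lorenz: the Benettin tangent-space method — the linearised
    flow is integrated alongside the orbit and the tangent vector is
    renormalised periodically; the exponent is the average log growth per
    time unit.  Shares no code with the Rosenstein estimator.
    """
    p = fixture.params
    if fixture.system == LOGISTIC:
        orbit = _logistic_orbit(p["r"], p["x0"], fixture.n_samples + fixture.transient_discard)
        orbit = orbit[fixture.transient_discard :]
        return float(np.mean(np.log(np.abs(p["r"] * (1.0 - 2.0 * orbit)))))

    sigma, rho, beta, dt = p["sigma"], p["rho"], p["beta"], p["dt"]
    state = tuple(float(v) for v in p["initial"])
    for _ in range(fixture.transient_discard):
        state = _lorenz_rk4_step(state, dt, sigma, rho, beta)
    v = (1.0, 0.0, 0.0)
    log_sum = 0.0
    renorm_every = 10
    n = fixture.n_samples
    for i in range(n):
        x, y, z = state
        # joint RK4 step of the flow and its Jacobian action on v
        def rhs(s, w):
            sx, sy, sz = s
            wx, wy, wz = w
            ds = (sigma * (sy - sx), sx * (rho - sz) - sy, sx * sy - beta * sz)
            dw = (
                sigma * (wy - wx),
                (rho - sz) * wx - wy - sx * wz,
                sy * wx + sx * wy - beta * wz,
            )
            return ds, dw

        k1s, k1v = rhs(state, v)
        s2 = tuple(a + 0.5 * dt * b for a, b in zip(state, k1s))
        v2 = tuple(a + 0.5 * dt * b for a, b in zip(v, k1v))
        k2s, k2v = rhs(s2, v2)
        s3 = tuple(a + 0.5 * dt * b for a, b in zip(state, k2s))
        v3 = tuple(a + 0.5 * dt * b for a, b in zip(v, k2v))
        k3s, k3v = rhs(s3, v3)
        s4 = tuple(a + dt * b for a, b in zip(state, k3s))
        v4 = tuple(a + dt * b for a, b in zip(v, k3v))
        k4s, k4v = rhs(s4, v4)
        state = tuple(
            a + dt / 6.0 * (b + 2 * c + 2 * d + e)
            for a, b, c, d, e in zip(state, k1s, k2s, k3s, k4s)
        )
        v = tuple(
            a + dt / 6.0 * (b + 2 * c + 2 * d + e)
            for a, b, c, d, e in zip(v, k1v, k2v, k3v, k4v)
        )
        if (i + 1) % renorm_every == 0 or i == n - 1:
            norm = math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
            log_sum += math.log(norm)
            v = (v[0] / norm, v[1] / norm, v[2] / norm)
    return log_sum / (n * dt)


# ---------------------------------------------------------------------------
# cohort generation


def _label_index(label: str, labels: tuple[str, ...], kind: str) -> int:
    try:
        return labels.index(label)
    except ValueError:
        raise DesignError(f"{kind} {label!r} not in design {labels}") from None


def _subject_multiplier(config: SimulationConfig, subject_idx: int) -> float:
    """Log-normal between-subject multiplier, stable across the subject's trials."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 101, subject_idx])
    )
    return float(np.exp(rng.normal(0.0, config.subject_sd)))


def subject_id(subject_idx: int) -> str:
    return f"S{subject_idx + 1:02d}"


def _ou_series(rng: np.random.Generator, n: int, dt: float, theta: float, sigma: float) -> np.ndarray:
    """Exact-discretisation Ornstein-Uhlenbeck path started at equilibrium 0."""
    from scipy.signal import lfilter

    decay = math.exp(-theta * dt)
    step_sd = sigma * math.sqrt((1.0 - decay**2) / (2.0 * theta))
    shocks = rng.normal(0.0, step_sd, n)
    return lfilter([1.0], [1.0, -decay], shocks)


def _smooth_baseline(
    rng: np.random.Generator, n: int, rate: float, theta: float, sigma: float,
    corner_hz: float,
) -> np.ndarray:
    """Low-pass-smoothed OU path: the stochastic component of COP sway.

    A burn-in margin is simulated on both sides so the zero-phase filter
    has no edge transient inside the returned window.
    """
    from scipy.signal import butter, filtfilt

    margin = int(round(4.0 * rate / corner_hz)) if corner_hz > 0 else 0
    raw = _ou_series(rng, n + 2 * margin, 1.0 / rate, theta, sigma)
    b, a = butter(4, corner_hz, fs=rate)
    smooth = filtfilt(b, a, raw)
    return smooth[margin : margin + n]


def simulate_cop_trial(
    config: SimulationConfig,
    subject: int,
    inhalation_type: str,
    timepoint: str,
    rep: int,
    seed_offset: int = 0,
) -> CopTrial:
    """One synthetic quiet-standing COP trial for a design cell.

    Fully reproducible from ``(config.seed, subject, inhalation_type,
    timepoint, rep, seed_offset)``.  ``subject`` and ``rep`` are 0-based
    indices into the configured design.
    """
    t_idx = _label_index(inhalation_type, config.inhalation_types, "inhalation type")
    tp_idx = _label_index(timepoint, config.timepoints, "timepoint")
    if not 0 <= subject < config.n_subjects:
        raise DesignError(f"subject index {subject} outside 0..{config.n_subjects - 1}")
    if not 0 <= rep < config.reps_per_timepoint:
        raise DesignError(f"rep index {rep} outside 0..{config.reps_per_timepoint - 1}")
    if config.trial_duration <= 0:
        raise DataError("trial_duration must be positive")

    rng = np.random.default_rng(
        np.random.SeedSequence(
            [config.seed & 0x7FFFFFFF, 1, subject, t_idx, tp_idx, rep,
             seed_offset & 0x7FFFFFFF]
        )
    )
    n = config.n_samples
    dt = 1.0 / config.cop_sampling_rate
    mult = _subject_multiplier(config, subject)
    sigma = config.ou_noise_scale[inhalation_type] * mult
    gain = config.chaos_blend_gain[inhalation_type] * mult

    x = _smooth_baseline(rng, n, config.cop_sampling_rate, config.ou_reversion,
                         sigma, config.cop_smoothing_hz)
    y = _smooth_baseline(rng, n, config.cop_sampling_rate, config.ou_reversion,
                         sigma, config.cop_smoothing_hz)

    if gain > 0:
        steps_per_sample = max(
            1, int(round(LORENZ_DT_PER_SAMPLE / LORENZ_INTEGRATION_DT))
        )
        initial = tuple(np.array([1.0, 1.0, 20.0]) + rng.normal(0, 2.0, 3))
        orbit = _lorenz_orbit(
            {"sigma": 10.0, "rho": 28.0, "beta": 8.0 / 3.0,
             "dt": LORENZ_INTEGRATION_DT, "initial": initial},
            1000 + n * steps_per_sample,
            return_all=True,
        )[1000::steps_per_sample][:n]
        for axis, col in ((y, 0), (x, 1)):  # Lorenz x -> AP, y -> ML
            comp = orbit[:, col]
            comp = (comp - comp.mean()) / comp.std()
            axis += gain * comp

    return CopTrial(
        subject=subject_id(subject),
        inhalation_type=inhalation_type,
        timepoint=timepoint,
        rep=rep,
        sampling_rate=config.cop_sampling_rate,
        x=x,
        y=y,
    )


def simulate_cohort(config: SimulationConfig) -> tuple[list[CopTrial], pd.DataFrame]:
    """Balanced cohort of COP trials plus a ground-truth parameter table.

    Returns one trial per (subject, inhalation type, timepoint, rep) cell
    and a long-format table of the generating parameters of each cell,
    for parameter-recovery tests.
    """
    trials: list[CopTrial] = []
    rows = []
    for s in range(config.n_subjects):
        mult = _subject_multiplier(config, s)
        for itype in config.inhalation_types:
            for tp in config.timepoints:
                for rep in range(config.reps_per_timepoint):
                    trials.append(simulate_cop_trial(config, s, itype, tp, rep))
                rows.append(
                    {
                        "subject": subject_id(s),
                        "inhalation_type": itype,
                        "inhalation_time": tp,
                        "subject_multiplier": mult,
                        "ou_noise_scale": config.ou_noise_scale[itype] * mult,
                        "chaos_blend_gain": config.chaos_blend_gain[itype] * mult,
                        "resp_rate_mean": config.resp_rate_mean[itype][
                            "POST" if tp == "POST" else "DURING"
                        ],
                    }
                )
    return trials, pd.DataFrame(rows)


def simulate_resp_signal(
    rate_bpm: float,
    duration: float,
    sampling_rate: float = 2000.0,
    noise: float = 0.05,
    seed: int = 0,
) -> RespSignal:
    """Quasi-periodic respiration trace at a target breathing rate.

    Breath cycles are laid down sequentially; ``noise`` sets the relative
    cycle-to-cycle variability (0 gives an exactly periodic trace with
    ``rate_bpm * duration / 60`` full cycles).  Resting respiration varies
    far more in depth than in timing, so the amplitude CV is
    ``1.5 * noise`` while the cycle-length CV is ``0.5 * noise``; a small
    additive measurement-noise floor of ``0.2 * noise`` relative amplitude
    is added on top.  Reproducible from ``seed``.
    """
    if rate_bpm <= 0 or duration <= 0 or sampling_rate <= 0:
        raise DataError("rate, duration and sampling rate must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 2]))
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    base_period = 60.0 / rate_bpm

    # piecewise phase: each cycle gets a jittered period and amplitude
    n_cycles = int(math.ceil(duration / base_period)) + 2
    periods = base_period * (1.0 + 0.5 * noise * rng.standard_normal(n_cycles))
    periods = np.clip(periods, 0.2 * base_period, 5.0 * base_period)
    # renormalise so the realised long-run rate equals rate_bpm exactly;
    # noise then jitters individual cycles around the nominal rhythm
    periods *= n_cycles * base_period / periods.sum()
    amps = np.clip(1.0 + 1.5 * noise * rng.standard_normal(n_cycles), 0.1, None)
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    cycle_idx = np.clip(np.searchsorted(boundaries, t, side="right") - 1, 0, n_cycles - 1)
    phase_in_cycle = (t - boundaries[cycle_idx]) / periods[cycle_idx]
    samples = amps[cycle_idx] * np.sin(2.0 * np.pi * phase_in_cycle)
    if noise > 0:
        samples = samples + 0.2 * noise * rng.standard_normal(n)
    return RespSignal(samples=samples, sampling_rate=float(sampling_rate))


def simulate_null_outcomes(
    n_cohorts: int,
    n_subjects: int = 10,
    n_a: int = 2,
    n_b: int = 4,
    subject_sd: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Cell-level outcomes under the null: no condition effects.

    Each cohort is ``subject random effect + iid noise`` over an
    ``n_a x n_b`` within-subject design (compound-symmetric covariance,
    sphericity satisfied).  Shape: ``(n_cohorts, n_subjects, n_a, n_b)``.
    Used for type-I-error calibration of the repeated-measures ANOVA.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 3]))
    subj = rng.normal(0.0, subject_sd, (n_cohorts, n_subjects, 1, 1))
    noise = rng.normal(0.0, noise_sd, (n_cohorts, n_subjects, n_a, n_b))
    return subj + noise
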
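"""Two-stage stochastic gene expression with a photoconvertible reporter.

The model is the standard linear kinetic scheme

    0 -> mRNA -> mRNA + protein,   mRNA -> 0,   protein -> 0

with transcription rate ``v0`` (mRNA/h), mRNA degradation ``d0`` (1/h),
translation rate ``v1`` (protein per mRNA per h) and protein degradation
``d1`` (1/h). Cell-to-cell (extrinsic) variability enters as a per-cell
random translation rate, held constant over the observation window
(quasi-static extrinsic noise). A photoconversion event at a chosen time
instantaneously relabels the whole green pool as red; the red pool then
only decays, which makes it a pulse-chase readout of protein stability,
while regrowing green reports new synthesis.

This module provides exact stochastic simulation of that scheme, closed
form/ODE moment oracles, the non-stationary auto-correlation of the
post-conversion green pool (Monte Carlo, plus the birth-death closed-form
lower bound), and decay-rate estimation from paired pulse-chase intensity
measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .errors import EstimationError, ParameterError, UndefinedCorrelationError

__all__ = [
    "TwoStageParams",
    "ExtrinsicSpec",
    "Trajectory",
    "Moments",
    "AutocorrEstimate",
    "DecayEstimate",
    "draw_translation_rate",
    "ssa_two_stage",
    "stationary_state",
    "moments_two_stage",
    "autocorr_birth_death",
    "autocorr_two_stage_mc",
    "estimate_decay_rate",
]

#: Burn-in length used to draw stationary initial states, in units of the
#: protein lifetime 1/d1. Protein is the slowest species, so ten lifetimes
#: leaves no detectable memory of the deterministic starting point.
BURNIN_LIFETIMES = 10.0

_MAX_KERNEL_SEED = 2**28  # kernel seeds are multiplied by 8 and must stay < 2**31


@dataclass(frozen=True)
class TwoStageParams:
    """Kinetic rates of the two-stage expression model (all per hour)."""

    transcription_rate: float  # v0, mRNA molecules per hour
    mrna_decay: float          # d0, per hour
    translation_rate: float    # v1, protein per mRNA per hour (cell mean)
    protein_decay: float       # d1, per hour

    def __post_init__(self) -> None:
        for name in ("transcription_rate", "mrna_decay", "translation_rate", "protein_decay"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")

    def require_stationary(self) -> None:
        if self.mrna_decay <= 0 or self.protein_decay <= 0:
            raise ParameterError("stationary moments require mrna_decay > 0 and protein_decay > 0")

    @property
    def stationary_mrna_mean(self) -> float:
        self.require_stationary()
        return self.transcription_rate / self.mrna_decay

    def stationary_protein_mean(self, translation_rate: float | None = None) -> float:
        self.require_stationary()
        v1 = self.translation_rate if translation_rate is None else translation_rate
        return self.transcription_rate * v1 / (self.mrna_decay * self.protein_decay)


@dataclass(frozen=True)
class ExtrinsicSpec:
    """Cell-to-cell distribution of the translation rate.

    Only the mean and variance are constrained by the model; the sampling
    law is a gamma distribution matched to them, which guarantees positive
    rates without truncation bias. ``variance = 0`` degenerates to a point
    mass at the mean.
    """

    mean: float
    variance: float
    distribution: str = "gamma"

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ParameterError(f"mean translation rate must be >= 0, got {self.mean}")
        if self.variance < 0:
            raise ParameterError(f"translation-rate variance must be >= 0, got {self.variance}")
        if self.distribution != "gamma":
            raise ParameterError(f"unknown translation-rate distribution {self.distribution!r}")

    @property
    def cv(self) -> float:
        """Coefficient of variation sqrt(Var)/mean."""
        if self.mean == 0:
            return 0.0
        return math.sqrt(self.variance) / self.mean


@dataclass
class Trajectory:
    """One cell's sampled stochastic time course.

    Copy numbers are recorded on a fixed sampling grid; the conversion event
    (green pool relabelled red) is applied between grid points.
    """

    times: np.ndarray
    mrna: np.ndarray
    green: np.ndarray
    red: np.ndarray
    conversion_time: float
    params_used: TwoStageParams
    v1_drawn: float
    cell_id: str = "cell_0"

    def to_frame(self):
        """Tidy export: time_h, mrna, green, red, cell_id, v1, conversion_time_h."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.times,
                "mrna": self.mrna,
                "green": self.green,
                "red": self.red,
                "cell_id": self.cell_id,
                "v1": self.v1_drawn,
                "conversion_time_h": self.conversion_time,
            }
        )


class Moments(NamedTuple):
    mean_mrna: float
    var_mrna: float
    mean_protein: float
    var_protein: float
    cov_mrna_protein: float


class AutocorrEstimate(NamedTuple):
    r: float
    se: float
    n_traj: int


class DecayEstimate(NamedTuple):
    rate: float
    se: float
    n_used: int
    n_excluded: int


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def draw_translation_rate(spec: ExtrinsicSpec, seed, size: int | None = None):
    """Sample per-cell translation rates from the extrinsic-noise law.

    Deterministic given ``seed`` (an int or a numpy Generator). With
    ``size=None`` returns a scalar.
    """
    rng = _rng(seed)
    n = 1 if size is None else size
    if spec.variance == 0:
        out = np.full(n, spec.mean)
    else:
        shape = spec.mean**2 / spec.variance
        scale = spec.variance / spec.mean
        out = rng.gamma(shape, scale, n)
    return float(out[0]) if size is None else out


def stationary_state(params: TwoStageParams, translation_rate: float | None = None,
                     seed=0) -> tuple[int, int]:
    """Draw an (mRNA, protein) state from the stationary distribution.

    The mRNA marginal of the linear scheme is exactly Poisson(v0/d0); the
    joint law has no simple closed form, so the protein coordinate is
    relaxed from its stationary mean by a burn-in of ``BURNIN_LIFETIMES/d1``
    hours of exact simulation.
    """
    params.require_stationary()
    v1 = params.translation_rate if translation_rate is None else translation_rate
    rng = _rng(seed)
    kseed = int(rng.integers(0, _MAX_KERNEL_SEED)) * 8
    burn = BURNIN_LIFETIMES / params.protein_decay
    m, g = _kernels.stationary_burnin(
        params.transcription_rate, params.mrna_decay, v1, params.protein_decay, burn, kseed
    )
    return int(m), int(g)


def ssa_two_stage(params: TwoStageParams, translation_rate: float | None = None,
                  t_conversion: float = 0.0, t_end: float = 6.0,
                  initial_state: tuple[int, int, int] | None = None,
                  seed=0, sample_dt: float = 0.05) -> Trajectory:
    """Exact simulation of one cell with a conversion event.

    Parameters
    ----------
    translation_rate:
        The cell's drawn v1; defaults to ``params.translation_rate``.
    t_conversion, t_end:
        Conversion happens at ``t_conversion`` (must be <= ``t_end``): the
        entire green pool is relabelled red, conserving total protein.
    initial_state:
        ``(mrna, green, red)`` at t=0. Default: stationary draw for
        (mrna, green) and red = 0.
    sample_dt:
        Spacing of the output grid; only grid states are stored.
    """
    if t_conversion > t_end:
        raise ParameterError("t_conversion must be <= t_end")
    v1 = params.translation_rate if translation_rate is None else translation_rate
    if v1 < 0:
        raise ParameterError("translation rate must be >= 0")
    rng = _rng(seed)
    if initial_state is None:
        m0, g0 = stationary_state(params, v1, rng)
        r0 = 0
    else:
        m0, g0, r0 = (int(x) for x in initial_state)
        if m0 < 0 or g0 < 0 or r0 < 0:
            raise ParameterError("initial copy numbers must be non-negative")

    v0, d0, d1 = params.transcription_rate, params.mrna_decay, params.protein_decay
    times = np.arange(0.0, t_end + 0.5 * sample_dt, sample_dt)
    pre_mask = times < t_conversion  # the conversion-time sample shows the converted state
    t_pre = times[pre_mask]
    t_post = times[~pre_mask]

    s = int(rng.integers(0, _MAX_KERNEL_SEED)) * 8

    # pre-conversion segment (green accumulates, red only decays)
    m_pre, g_pre = _kernels.sim_mg_grid(v0, d0, v1, d1, m0, g0, t_pre, s)
    dts_pre = np.diff(np.concatenate([[0.0], t_pre]))
    r_pre = _kernels.thin_death(r0, d1, dts_pre, s + 1)

    # state exactly at the conversion instant
    mc, gc = _kernels.sim_mg(v0, d0, v1, d1,
                             int(m_pre[-1]) if len(t_pre) else m0,
                             int(g_pre[-1]) if len(t_pre) else g0,
                             float(t_pre[-1]) if len(t_pre) else 0.0,
                             t_conversion, s + 2)
    rc = _kernels.thin_death(
        int(r_pre[-1]) if len(t_pre) else r0, d1,
        np.array([t_conversion - (t_pre[-1] if len(t_pre) else 0.0)]), s + 3)[0]

    # conversion: green pool -> red pool, total protein conserved
    rc = int(rc) + int(gc)
    gc = 0

    m_post, g_post = _kernels.sim_mg_grid(v0, d0, v1, d1, mc, gc,
                                          t_post - t_conversion, s + 4)
    dts_post = np.diff(np.concatenate([[t_conversion], t_post]))
    r_post = _kernels.thin_death(rc, d1, dts_post, s + 5)

    return Trajectory(
        times=times,
        mrna=np.concatenate([m_pre, m_post]),
        green=np.concatenate([g_pre, g_post]),
        red=np.concatenate([r_pre, r_post]),
        conversion_time=t_conversion,
        params_used=params,
        v1_drawn=v1,
    )


def _mean_protein_t(v0, d0, v1, d1, m0, g0, t):
    """E[protein](t) from a deterministic initial state (m0, g0)."""
    mbar = v0 / d0
    if abs(d0 - d1) < 1e-12 * max(d0, d1, 1.0):
        transfer = t * np.exp(-d1 * t)
    else:
        transfer = (np.exp(-d1 * t) - np.exp(-d0 * t)) / (d0 - d1)
    return (
        g0 * np.exp(-d1 * t)
        + v1 * mbar * -np.expm1(-d1 * t) / d1
        + v1 * (m0 - mbar) * transfer
    )


def moments_two_stage(params: TwoStageParams, t: float,
                      initial_state: tuple[int, int] = (0, 0),
                      translation_rate: float | None = None) -> Moments:
    """Mean and variance of mRNA and protein at time t.

    The first moments are closed forms of the linear kinetics (with the
    degenerate-limit branch at d0 == d1); the second moments come from the
    closed linear moment ODEs integrated to machine accuracy, which is the
    same exact object in a less error-prone form. ``t = inf`` returns the
    stationary values, including the classic stationary protein variance
    mean * (1 + v1/(d0+d1)).
    """
    params.require_stationary()
    v0, d0, d1 = params.transcription_rate, params.mrna_decay, params.protein_decay
    v1 = params.translation_rate if translation_rate is None else translation_rate
    m0, g0 = initial_state
    if m0 < 0 or g0 < 0:
        raise ParameterError("initial copy numbers must be non-negative")

    if math.isinf(t):
        mean_m = v0 / d0
        mean_g = v0 * v1 / (d0 * d1)
        var_g = mean_g * (1.0 + v1 / (d0 + d1))
        cov = v1 * mean_m / (d0 + d1)
        return Moments(mean_m, mean_m, mean_g, var_g, cov)

    mean_m = m0 * np.exp(-d0 * t) + (v0 / d0) * -np.expm1(-d0 * t)
    mean_g = _mean_protein_t(v0, d0, v1, d1, m0, g0, t)

    def rhs(_t, y):
        mu_m, mu_g, vm, c, vg = y
        return [
            v0 - d0 * mu_m,
            v1 * mu_m - d1 * mu_g,
            v0 + d0 * mu_m - 2 * d0 * vm,
            v1 * vm - (d0 + d1) * c,
            v1 * mu_m + d1 * mu_g + 2 * v1 * c - 2 * d1 * vg,
        ]

    if t == 0:
        vm = c = vg = 0.0
    else:
        sol = solve_ivp(rhs, (0.0, t), [m0, g0, 0.0, 0.0, 0.0],
                        rtol=1e-10, atol=1e-10, dense_output=False)
        _, _, vm, c, vg = sol.y[:, -1]
    return Moments(float(mean_m), float(vm), float(mean_g), float(vg), float(c))


def autocorr_birth_death(d: float, t1: float, t2: float) -> float:
    """Non-stationary auto-correlation of a birth-death process started at 0.

    c0(t2, t1) = exp(-d (t2-t1)) * sqrt((1-exp(-d t1)) / (1-exp(-d t2))),
    the correlation of the regrowing post-conversion pool under constant
    production; it lower-bounds the two-stage auto-correlation. The d -> 0
    continuous limit is sqrt(t1/t2).
    """
    if d < 0:
        raise ParameterError("decay rate must be >= 0")
    if t1 <= 0:
        raise ParameterError("t1 must be > 0")
    if t1 > t2:
        raise ParameterError("t1 must be <= t2")
    if t1 == t2:
        return 1.0
    if d == 0:
        return math.sqrt(t1 / t2)
    return math.exp(-d * (t2 - t1)) * math.sqrt(-math.expm1(-d * t1) / -math.expm1(-d * t2))


def autocorr_two_stage_mc(params: TwoStageParams, spec: ExtrinsicSpec,
                          t1: float, t2: float, n_traj: int, seed=0) -> AutocorrEstimate:
    """Monte-Carlo auto-correlation of the post-conversion green pool.

    Each trajectory draws its own translation rate, starts from the
    pre-conversion stationary state (exact Poisson mRNA; green is zero
    immediately after conversion, so no protein burn-in is needed) and is
    simulated exactly to t2; the Pearson correlation of green counts between
    t1 and t2 across trajectories is returned with its large-sample standard
    error (1 - r^2)/sqrt(n).
    """
    if n_traj < 100:
        raise ParameterError("n_traj must be >= 100")
    if not 0 < t1 <= t2:
        raise ParameterError("need 0 < t1 <= t2")
    params.require_stationary()
    rng = _rng(seed)
    v1s = draw_translation_rate(spec, rng, size=n_traj)
    m0s = rng.poisson(params.stationary_mrna_mean, n_traj).astype(np.int64)
    seeds = rng.integers(0, _MAX_KERNEL_SEED, n_traj) * 8
    g1, g2 = _kernels.ensemble_green_pair(
        params.transcription_rate, params.mrna_decay, params.protein_decay,
        np.asarray(v1s, dtype=np.float64), m0s, t1, t2, seeds,
    )
    if g1.std() == 0 or g2.std() == 0:
        raise UndefinedCorrelationError("degenerate ensemble: zero variance at a sampling time")
    r = float(np.corrcoef(g1, g2)[0, 1])
    se = (1.0 - r * r) / math.sqrt(n_traj)
    return AutocorrEstimate(r, se, n_traj)


def estimate_decay_rate(red_t1: Sequence[float], red_t2: Sequence[float],
                        dt: float) -> DecayEstimate:
    """Protein decay rate from paired pulse-chase intensities.

    For each nucleus with both values positive, the per-nucleus rate is
    ln(R(t1)/R(t2))/dt; the central estimate is the unweighted mean over
    nuclei with its standard error. Non-positive pairs are excluded and
    counted.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    a = np.asarray(red_t1, dtype=float)
    b = np.asarray(red_t2, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("red_t1 and red_t2 must have the same length")
    ok = (a > 0) & (b > 0)
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise EstimationError("all records excluded: no positive intensity pairs")
    rates = np.log(a[ok] / b[ok]) / dt
    n = int(ok.sum())
    se = float(rates.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return DecayEstimate(float(rates.mean()), se, n, n_excluded)
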
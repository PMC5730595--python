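"""How much neighbour coupling does cell division alone explain?

At division, a mother's mRNA and protein content is copied to both
daughters, so siblings start stochastically identical and decorrelate as
the copied molecules turn over. Two inheritance modes bracket the effect:

* ``state_only`` -- daughters copy the molecular state but each draws a
  fresh translation rate (the extrinsic parameter is NOT inherited); the
  sibling coupling then decays with the time since division.
* ``full`` -- daughters additionally keep the mother's translation rate
  forever; they remain statistically identical at every age, so the
  covariance-normalized sibling coupling is 1 regardless of the
  division-age law (the within-cell and cross-sibling covariances are the
  same extrinsic variance). This mode is the absolute upper bound of the
  inheritance contribution.

The sibling coupling statistic is the same covariance-normalized
cross-reporter estimator used for spatial neighbours, applied to sibling
pairs. The time since division is exponential with a configurable mean;
``calibrate_mean_division_age`` inverts the closed-form state-only decay
for the mean age that yields a target coupling, and that calibrated value
is the package default (the division rate itself is a free parameter of
the tissue, not of the expression model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .errors import ParameterError, UndefinedCorrelationError
from .model import BURNIN_LIFETIMES, ExtrinsicSpec, TwoStageParams, draw_translation_rate

__all__ = [
    "InheritanceConfig",
    "DivisionEnsemble",
    "simulate_division_pairs",
    "sibling_correlation",
    "state_only_coupling_closed_form",
    "calibrate_mean_division_age",
]

MODES = ("state_only", "full")

#: Target sibling coupling used to calibrate the default mean division age.
DEFAULT_COUPLING_TARGET = 0.16


def state_only_coupling_closed_form(protein_decay: float, mean_age: float) -> float:
    """Expected state-only sibling coupling for an exponential division-age law.

    For a daughter of age t, the copied protein pool retains a fraction
    e^(-d1 t) of the mother's extrinsic signal, so the cross-sibling
    covariance is e^(-2 d1 t) * Var_ext while the within-cell covariance is
    (e^(-2 d1 t) + (1 - e^(-d1 t))^2) * Var_ext (memory of the mother's rate
    plus the daughter's own fresh rate). Averaging both over
    t ~ Exp(mean_age) and taking the ratio of expectations:

        r(a) = u / (u + w),   a = d1 * mean_age,
        u = 1/(1+2a),   w = 1 - 2/(1+a) + 1/(1+2a).

    (The mRNA stage only enters through its stationary mean and cancels.)
    """
    a = protein_decay * mean_age
    u = 1.0 / (1.0 + 2.0 * a)
    w = 1.0 - 2.0 / (1.0 + a) + u
    return u / (u + w)


def calibrate_mean_division_age(protein_decay: float,
                                target: float = DEFAULT_COUPLING_TARGET) -> float:
    """Mean division age (h) at which state-only siblings couple at ``target``."""
    if not 0 < target < 1:
        raise ParameterError("target coupling must be in (0, 1)")
    f = lambda T: state_only_coupling_closed_form(protein_decay, T) - target
    return float(brentq(f, 1e-9 / protein_decay, 1e4 / protein_decay))


@dataclass(frozen=True)
class InheritanceConfig:
    params: TwoStageParams
    spec: ExtrinsicSpec
    mode: str = "state_only"
    mean_division_age_h: float | None = None  # None -> calibrated default
    n_pairs: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_pairs < 100:
            raise ParameterError("n_pairs must be >= 100")
        if self.mean_division_age_h is not None and self.mean_division_age_h < 0:
            raise ParameterError("mean_division_age_h must be >= 0")

    def resolved_mean_age(self) -> float:
        if self.mean_division_age_h is not None:
            return self.mean_division_age_h
        return calibrate_mean_division_age(self.params.protein_decay)


class DivisionEnsemble(NamedTuple):
    """Final dual-reporter counts of both daughters of each pair."""

    c1: np.ndarray
    y1: np.ndarray
    c2: np.ndarray
    y2: np.ndarray
    ages: np.ndarray
    mean_age_used: float
    mode: str


def simulate_division_pairs(config: InheritanceConfig,
                            fixed_age: float | None = None) -> DivisionEnsemble:
    """Simulate daughter pairs of the dual-reporter two-stage model.

    Each mother draws one translation rate (shared by both its reporters)
    and is relaxed to stationarity; both daughters copy its exact mRNA and
    protein counts, then evolve independently for a common age drawn from
    the exponential division-age law (or ``fixed_age`` if given).
    """
    p = config.params
    p.require_stationary()
    rng = np.random.default_rng(config.seed)
    n = config.n_pairs
    v1_mother = np.asarray(draw_translation_rate(config.spec, rng, size=n), dtype=float)
    if config.mode == "full":
        v1_d1 = v1_mother
        v1_d2 = v1_mother
    else:
        v1_d1 = np.asarray(draw_translation_rate(config.spec, rng, size=n), dtype=float)
        v1_d2 = np.asarray(draw_translation_rate(config.spec, rng, size=n), dtype=float)
    mean_age = config.resolved_mean_age()
    if fixed_age is not None:
        ages = np.full(n, float(fixed_age))
    else:
        ages = rng.exponential(mean_age, n)
    g0_means = p.transcription_rate * v1_mother / (p.mrna_decay * p.protein_decay)
    seeds = rng.integers(0, 2**28, n) * 8
    burn = BURNIN_LIFETIMES / p.protein_decay
    out = _kernels.ensemble_division_pairs(
        p.transcription_rate, p.mrna_decay, p.protein_decay,
        v1_mother, v1_d1, v1_d2, g0_means, ages, burn, seeds,
    )
    return DivisionEnsemble(out[:, 0].astype(float), out[:, 1].astype(float),
                            out[:, 2].astype(float), out[:, 3].astype(float),
                            ages, mean_age, config.mode)


def sibling_correlation(ensemble: DivisionEnsemble) -> float:
    """Covariance-normalized cross-reporter coupling over sibling pairs.

    Numerator: Cov(C_1, Y_2) and Cov(Y_1, C_2) pooled over pairs (both
    sibling orderings); denominator: within-cell Cov(C, Y) over all
    daughters -- the extrinsic-variance estimate, as for spatial neighbours.
    """
    c1, y1, c2, y2 = ensemble.c1, ensemble.y1, ensemble.c2, ensemble.y2
    if c1.size < 100:
        raise ParameterError("need at least 100 pairs")
    call = np.concatenate([c1, c2])
    yall = np.concatenate([y1, y2])
    cm, ym = call.mean(), yall.mean()
    within = float(np.mean((call - cm) * (yall - ym)))
    if within <= 0:
        raise UndefinedCorrelationError(
            "within-cell cross-reporter covariance <= 0: degenerate ensemble"
        )
    num = 0.5 * (np.mean((c1 - cm) * (y2 - ym)) + np.mean((y1 - ym) * (c2 - cm)))
    return float(num / within)
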
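"""Synthetic measurement tables with known ground truth.

No public dataset of nucleus-level dual-reporter measurements exists for
this kind of tissue analysis, so every pipeline stage is exercised on
generated tables whose statistical structure is known exactly:

* ``generate_tissue`` emits a dual-reporter tissue snapshot: cells on a
  jittered hexagonal grid, a per-cell lognormal extrinsic factor shared by
  both channels (optionally spatially correlated through a Gaussian random
  field with exponential covariance), independent lognormal intrinsic
  factors per channel, ploidy-like nuclear-area classes, additive technical
  noise, and duplicate measurements. The analytic intrinsic/extrinsic noise
  and the neighbour-coupling-by-distance curve are returned alongside.

* ``generate_kik_timecourse`` emits a photoconversion pulse-chase time
  course: each cell is an exact two-stage simulation with its own drawn
  translation rate, converted at t = 0 and measured (green and red) at
  0/3/6 h with duplicate lognormal measurement noise.

Identical config + seed gives byte-identical CSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .errors import ParameterError
from .measurements import REQUIRED_COLUMNS, NucleusTable
from .model import BURNIN_LIFETIMES, ExtrinsicSpec, TwoStageParams, draw_translation_rate
from .noise import NOISE_SCALE

__all__ = [
    "TissueGenConfig",
    "TissueGroundTruth",
    "KikGroundTruth",
    "generate_tissue",
    "generate_kik_timecourse",
]


@dataclass(frozen=True)
class TissueGenConfig:
    """Ground-truth parameters of a synthetic dual-reporter tissue.

    ``extrinsic_sd`` / ``intrinsic_sd`` are lognormal sigmas; the defaults
    give analytic extrinsic/intrinsic noise of about 40 and 11 on the x100
    reported scale, the regime of young-leaf epidermis. ``coupling`` is the
    target covariance-normalized coupling between cells one grid spacing
    apart, realized through a Gaussian field with exponential correlation of
    length ``corr_length_um`` plus a white (nugget) component.
    """

    n_cells: int = 2000
    grid_spacing_um: float = 20.0
    jitter_sd_um: float = 2.0
    extrinsic_sd: float = 0.58
    intrinsic_sd: float = 0.28
    coupling: float = 0.0
    corr_length_um: float = 40.0
    #: relative gain of the extrinsic sd with nuclear area:
    #: sigma_i = extrinsic_sd * (1 + gain * (area_i/mean_area - 1)), floored at 0
    extrinsic_area_gain: float = 0.0
    ploidy_classes: tuple[int, ...] = (2, 4, 8, 16)
    ploidy_weights: tuple[float, ...] = (0.35, 0.35, 0.2, 0.1)
    base_area_um2: float = 40.0
    area_jitter_sd: float = 0.15  # lognormal sigma within a ploidy class
    scale_grey: float = 10.0
    background_grey: float = 10.0
    measurement_noise_sd: float = 1.0  # additive grey units per replicate
    n_replicates: int = 2
    channels: tuple[str, str] = ("CFP", "YFP")
    tissue: str = "young_leaf"
    image_id: str = "synthetic_img"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_spacing_um <= 0:
            raise ParameterError("grid_spacing_um must be > 0")
        for name in ("extrinsic_sd", "intrinsic_sd", "jitter_sd_um",
                     "measurement_noise_sd", "area_jitter_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0 <= self.coupling <= 1:
            raise ParameterError("coupling must be in [0, 1]")
        if self.corr_length_um <= 0:
            raise ParameterError("corr_length_um must be > 0")
        if len(self.ploidy_classes) != len(self.ploidy_weights):
            raise ParameterError("ploidy_classes and ploidy_weights must match")
        if self.n_cells < 2:
            raise ParameterError("need at least 2 cells")
        # grey headroom: 99.9th percentile of the signal must stay below 255
        sig = math.hypot(self.extrinsic_sd * (1 + abs(self.extrinsic_area_gain)),
                         self.intrinsic_sd)
        q999 = self.scale_grey * math.exp(3.09 * sig) + self.background_grey \
            + 3 * self.measurement_noise_sd
        if q999 >= 255:
            raise ParameterError(
                f"grey 99.9th percentile {q999:.0f} would exceed the 8-bit range; "
                "lower scale_grey or the noise sigmas"
            )


@dataclass
class TissueGroundTruth:
    """What the generator actually drew, plus the analytic targets.

    ``eta2_*_analytic`` are on the x100 reported scale and include the
    technical-noise contribution to the intrinsic component; they are exact
    only for a homogeneous extrinsic sd (``extrinsic_area_gain = 0``) and
    are NaN otherwise. ``coupling_at(d)`` gives the expected
    covariance-normalized coupling between cells at distance d (µm).
    """

    cells: pd.DataFrame
    eta2_int_analytic: float
    eta2_ext_analytic: float
    eta2_tot_analytic: float
    nugget: float
    corr_length_um: float
    grid_spacing_um: float
    extrinsic_sd: float

    def coupling_at(self, d) -> np.ndarray:
        rho = self.nugget * np.exp(-np.asarray(d, dtype=float) / self.corr_length_um)
        s2 = self.extrinsic_sd**2
        return np.expm1(rho * s2) / np.expm1(s2) if s2 > 0 else np.zeros_like(rho)


def _hex_positions(n: int, spacing: float, jitter: float, rng) -> np.ndarray:
    ncol = int(math.ceil(math.sqrt(n)))
    rows = int(math.ceil(n / ncol))
    xs, ys = [], []
    for i in range(rows):
        for j in range(ncol):
            xs.append(spacing * (j + 0.5 * (i % 2)))
            ys.append(spacing * i * math.sqrt(3) / 2)
    pos = np.column_stack([xs, ys])[:n]
    return pos + rng.normal(0.0, jitter, pos.shape)


def _extrinsic_field(pos: np.ndarray, sigma: np.ndarray, coupling: float,
                     corr_length: float, spacing: float, rng) -> tuple[np.ndarray, float]:
    """Zero-mean unit-variance Gaussian field with rho(d) = a * exp(-d/L),
    scaled per cell by sigma. Returns (field * sigma, nugget a)."""
    n = pos.shape[0]
    if coupling == 0 or np.all(sigma == 0):
        return sigma * rng.standard_normal(n), 0.0
    s2 = float(np.mean(sigma) ** 2)
    # invert the lognormal coupling at one grid spacing for the Gaussian rho
    rho_nn = math.log1p(coupling * math.expm1(s2)) / s2
    a = rho_nn * math.exp(spacing / corr_length)
    if a > 1:
        raise ParameterError(
            f"coupling {coupling} at spacing {spacing} needs field weight {a:.2f} > 1; "
            "increase corr_length_um or lower the coupling"
        )
    d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2))
    cov = a * np.exp(-d / corr_length)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    return sigma * (chol @ rng.standard_normal(n)), a


def _area_draw(cfg: TissueGenConfig, rng, n: int) -> np.ndarray:
    w = np.asarray(cfg.ploidy_weights, dtype=float)
    w = w / w.sum()
    cls = rng.choice(len(cfg.ploidy_classes), size=n, p=w)
    c = np.asarray(cfg.ploidy_classes, dtype=float)[cls]
    # nuclear area scales like (DNA content)^(2/3) (volume times ploidy)
    return cfg.base_area_um2 * (c / 2.0) ** (2.0 / 3.0) * np.exp(
        rng.normal(0.0, cfg.area_jitter_sd, n)
    )


def generate_tissue(config: TissueGenConfig) -> tuple[NucleusTable, TissueGroundTruth]:
    """Generate one synthetic dual-reporter tissue image (raw grey table)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    pos = _hex_positions(n, config.grid_spacing_um, config.jitter_sd_um, rng)
    areas = _area_draw(config, rng, n)
    sigma = np.full(n, config.extrinsic_sd)
    if config.extrinsic_area_gain != 0:
        sigma = config.extrinsic_sd * (
            1.0 + config.extrinsic_area_gain * (areas / areas.mean() - 1.0)
        )
        sigma = np.clip(sigma, 0.0, None)
    g_field, nugget = _extrinsic_field(pos, sigma, config.coupling,
                                       config.corr_length_um, config.grid_spacing_um, rng)
    extrinsic = np.exp(g_field)
    intr = {ch: np.exp(rng.normal(0.0, config.intrinsic_sd, n)) for ch in config.channels}

    rows = []
    for ch in config.channels:
        signal = config.scale_grey * extrinsic * intr[ch]
        for rep in range(config.n_replicates):
            noise = rng.normal(0.0, config.measurement_noise_sd, n)
            rows.append(pd.DataFrame({
                "image_id": config.image_id,
                "cell_id": [f"cell_{i:05d}" for i in range(n)],
                "tissue": config.tissue,
                "x_um": pos[:, 0],
                "y_um": pos[:, 1],
                "area_um2": areas,
                "channel": ch,
                "time_h": 0.0,
                "replicate": rep,
                "mean_grey": config.background_grey + signal + noise,
                "background_mean_grey": config.background_grey,
            }))
    table = NucleusTable(pd.concat(rows, ignore_index=True)[REQUIRED_COLUMNS])

    if config.extrinsic_area_gain == 0:
        s2 = config.extrinsic_sd**2
        i2 = config.intrinsic_sd**2
        mean_signal = config.scale_grey * math.exp((s2 + i2) / 2.0)
        tech = config.measurement_noise_sd**2 / (config.n_replicates * mean_signal**2)
        eta_ext = math.expm1(s2)
        eta_int = math.exp(s2) * math.expm1(i2) + tech
    else:
        eta_ext = eta_int = float("nan")
    truth = TissueGroundTruth(
        cells=pd.DataFrame({
            "cell_id": [f"cell_{i:05d}" for i in range(n)],
            "x_um": pos[:, 0], "y_um": pos[:, 1], "area_um2": areas,
            "sigma_ext": sigma, "extrinsic": extrinsic,
            "intrinsic_a": intr[config.channels[0]],
            "intrinsic_b": intr[config.channels[1]],
        }),
        eta2_int_analytic=NOISE_SCALE * eta_int,
        eta2_ext_analytic=NOISE_SCALE * eta_ext,
        eta2_tot_analytic=NOISE_SCALE * (eta_int + eta_ext),
        nugget=nugget,
        corr_length_um=config.corr_length_um,
        grid_spacing_um=config.grid_spacing_um,
        extrinsic_sd=config.extrinsic_sd,
    )
    return table, truth


@dataclass
class KikGroundTruth:
    """Per-cell latent state of a photoconversion time course."""

    cells: pd.DataFrame  # cell_id, v1, green/red counts per time point
    params: TwoStageParams
    count_to_grey: float


def generate_kik_timecourse(params: TwoStageParams, spec: ExtrinsicSpec,
                            n_cells: int = 400,
                            noise_sigma: float = 0.1,
                            seed: int = 0,
                            times: Sequence[float] = (0.0, 3.0, 6.0),
                            n_replicates: int = 2,
                            count_to_grey: float = 0.09,
                            background_grey: float = 10.0,
                            grid_spacing_um: float = 20.0,
                            tissue: str = "young_leaf",
                            image_id: str = "synthetic_kik") -> tuple[NucleusTable, KikGroundTruth]:
    """Photoconversion pulse-chase table: green regrowth and red decay.

    Each cell draws its own translation rate, is relaxed to the
    pre-conversion stationary state by exact simulation, converted at t = 0
    (the whole green pool becomes red), and sampled at ``times``. Counts map
    affinely to grey (``background + count_to_grey * count``, calibrated so
    a stationary pool of ~1000 molecules sits mid-range of 8 bit) with
    multiplicative lognormal measurement noise of sigma ``noise_sigma`` per
    replicate.
    """
    if params.mrna_decay <= 0:
        raise ParameterError("mrna_decay must be > 0")
    if n_cells < 2:
        raise ParameterError("need at least 2 cells")
    times = np.asarray(sorted(times), dtype=float)
    if times[0] < 0:
        raise ParameterError("sampling times are measured from conversion; need t >= 0")
    rng = np.random.default_rng(seed)
    v1s = np.asarray(draw_translation_rate(spec, rng, size=n_cells), dtype=float)
    seeds = rng.integers(0, 2**28, n_cells) * 8
    if params.protein_decay > 0:
        burn = BURNIN_LIFETIMES / params.protein_decay
        g0_means = params.transcription_rate * v1s / (
            params.mrna_decay * params.protein_decay)
    else:
        # a non-degrading protein has no stationary pool; take the amount
        # accumulated from zero over 20 mRNA lifetimes as the converted pool
        burn = 20.0 / params.mrna_decay
        g0_means = np.zeros(n_cells)
    m0s, g0s = _kernels.ensemble_stationary(
        params.transcription_rate, params.mrna_decay, params.protein_decay,
        v1s, g0_means, burn, seeds
    )
    seeds2 = rng.integers(0, 2**28, n_cells) * 8
    green, red = _kernels.ensemble_conversion_timecourse(
        params.transcription_rate, params.mrna_decay, params.protein_decay,
        v1s, m0s, g0s, times, seeds2,
    )

    pos = _hex_positions(n_cells, grid_spacing_um, 0.1 * grid_spacing_um, rng)
    areas = np.full(n_cells, 60.0)
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    rows = []
    for ch, counts in (("KikG", green), ("KikR", red)):
        for j, t in enumerate(times):
            for rep in range(n_replicates):
                noise = np.exp(rng.normal(0.0, noise_sigma, n_cells)) if noise_sigma > 0 else 1.0
                rows.append(pd.DataFrame({
                    "image_id": image_id,
                    "cell_id": cell_ids,
                    "tissue": tissue,
                    "x_um": pos[:, 0],
                    "y_um": pos[:, 1],
                    "area_um2": areas,
                    "channel": ch,
                    "time_h": t,
                    "replicate": rep,
                    "mean_grey": background_grey + count_to_grey * counts[:, j] * noise,
                    "background_mean_grey": background_grey,
                }))
    table = NucleusTable(pd.concat(rows, ignore_index=True)[REQUIRED_COLUMNS])

    truth_cols = {"cell_id": cell_ids, "v1": v1s, "green_preconversion": g0s}
    for j, t in enumerate(times):
        truth_cols[f"green_{t:g}h"] = green[:, j]
        truth_cols[f"red_{t:g}h"] = red[:, j]
    truth = KikGroundTruth(pd.DataFrame(truth_cols), params, count_to_grey)
    return table, truth
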
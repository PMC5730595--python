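"""Dual-reporter decomposition of expression noise into intrinsic and
extrinsic components.

Two spectrally distinct reporters driven by identical promoters in the same
cell fluctuate together under cell-global (extrinsic) influences and
independently under gene-local (intrinsic) ones. On mean-normalized paired
values c, y the moment estimators are

    eta2_int = <(c - y)^2> / (2 <c><y>)
    eta2_ext = (<c y> - <c><y>) / (<c><y>)
    eta2_tot = eta2_int + eta2_ext

(the squared-coefficient-of-variation scale). Results are reported x100,
matching the convention under which tissue medians land in the tens.
Decomposition is done per image; tissues are compared by the median/mean of
per-image values and a Wilcoxon rank-sum test. Nuclear-area quartiles serve
as an ordinal proxy for ploidy (endoreduplication) classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, ParameterError
from .measurements import NORMALIZED, NucleusTable, cell_matrix

__all__ = [
    "NOISE_SCALE",
    "NoiseResult",
    "decompose_noise",
    "aggregate_noise",
    "compare_groups",
    "area_quartile_noise",
    "bootstrap_noise_se",
]

#: Reported scale: noise values are squared CVs multiplied by this factor.
NOISE_SCALE = 100.0

#: Group sizes up to which the rank-sum test is computed by exact enumeration.
EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class NoiseResult:
    """Intrinsic/extrinsic/total noise of one image (reported x100 scale).

    ``eta2_ext`` can be slightly negative at small n; it is reported as
    computed, not clipped, so that group medians stay unbiased.
    """

    image_id: str
    n_cells: int
    eta2_int: float
    eta2_ext: float
    eta2_tot: float


def _moments(c: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Raw (unscaled) intrinsic, extrinsic, total noise. 1/n convention."""
    cm = c.mean()
    ym = y.mean()
    denom = cm * ym
    eta_int = float(np.mean((c - y) ** 2) / (2.0 * denom))
    eta_ext = float((np.mean(c * y) - denom) / denom)
    return eta_int, eta_ext, eta_int + eta_ext


def decompose_noise(c: Sequence[float], y: Sequence[float],
                    image_id: str = "") -> NoiseResult:
    """Dual-reporter noise decomposition of one image's paired cell values.

    ``c`` and ``y`` are the two channels' mean-normalized per-cell values.
    By construction eta2_tot = eta2_int + eta2_ext exactly.
    """
    c = np.asarray(c, dtype=float)
    y = np.asarray(y, dtype=float)
    if c.shape != y.shape:
        raise ParameterError("channel vectors must have the same length")
    if c.size < 5:
        raise ParameterError("need at least 5 paired cells")
    eta_int, eta_ext, eta_tot = _moments(c, y)
    return NoiseResult(image_id, int(c.size), NOISE_SCALE * eta_int,
                       NOISE_SCALE * eta_ext, NOISE_SCALE * eta_tot)


def aggregate_noise(tables: Sequence[NucleusTable] | NucleusTable,
                    channels: tuple[str, str] = ("CFP", "YFP"),
                    time_h: float | None = None):
    """Per-image noise decomposition plus group summary.

    Accepts one (possibly multi-image) normalized table or a list of them.
    Returns ``(results, summary)`` where ``results`` is a list of
    NoiseResult, one per image, and ``summary`` is a one-row-per-tissue
    DataFrame with the median and mean of each noise component across
    images, mirroring the box-plot presentation of per-image values.
    """
    if isinstance(tables, NucleusTable):
        tables = [tables]
    if not tables:
        raise EstimationError("empty group: no tables to aggregate")
    rows = []
    results: list[NoiseResult] = []
    for table in tables:
        table.require_state(NORMALIZED)
        wide = cell_matrix(table, channels=channels, time_h=time_h)
        for image_id, img in wide.groupby("image_id", sort=False):
            res = decompose_noise(img[channels[0]].to_numpy(),
                                  img[channels[1]].to_numpy(), image_id=str(image_id))
            results.append(res)
            rows.append({"image_id": res.image_id,
                         "tissue": img["tissue"].iloc[0],
                         "n_cells": res.n_cells,
                         "eta2_int": res.eta2_int,
                         "eta2_ext": res.eta2_ext,
                         "eta2_tot": res.eta2_tot})
    if not results:
        raise EstimationError("empty group: no images with both channels")
    per_image = pd.DataFrame(rows)
    summary = per_image.groupby("tissue", sort=False)[["eta2_int", "eta2_ext", "eta2_tot"]].agg(
        ["median", "mean"]
    )
    summary.columns = [f"{comp}_{stat}" for comp, stat in summary.columns]
    summary = summary.reset_index().assign(
        n_images=per_image.groupby("tissue", sort=False).size().to_numpy()
    )
    return results, summary


def compare_groups(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two groups of per-image
    noise values.

    Exact enumeration for groups of at most 12 without ties; the
    tie-corrected normal approximation otherwise. Two completely tied
    groups have no evidence of a shift: p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ParameterError("need at least 3 values per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= EXACT_RANKSUM_MAX_N and b.size <= EXACT_RANKSUM_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def area_quartile_noise(table: NucleusTable, channels: tuple[str, str] = ("CFP", "YFP"),
                        min_cells: int = 5) -> dict[int, NoiseResult | None]:
    """Noise decomposition within nuclear-area quartiles.

    Cells are binned by the empirical 25/50/75 area percentiles. A value
    equal to a boundary falls in the lower bin (so fully tied areas collapse
    into quartile 1). Quartiles with fewer than ``min_cells`` cells are
    reported as None. Returns {1: ..., 2: ..., 3: ..., 4: ...}.
    """
    table.require_state(NORMALIZED)
    wide = cell_matrix(table, channels=channels)
    if len(wide) < 20:
        raise ParameterError("need at least 20 cells for a quartile analysis")
    areas = wide["area_um2"].to_numpy()
    bounds = np.percentile(areas, [25, 50, 75])
    # number of boundaries strictly below the value: boundary ties -> lower bin
    bins = (areas[:, None] > bounds[None, :]).sum(axis=1)
    out: dict[int, NoiseResult | None] = {}
    for q in range(4):
        sel = bins == q
        if sel.sum() < min_cells:
            out[q + 1] = None
            continue
        out[q + 1] = decompose_noise(wide.loc[sel, channels[0]].to_numpy(),
                                     wide.loc[sel, channels[1]].to_numpy(),
                                     image_id=f"Q{q + 1}")
    return out


def bootstrap_noise_se(c: Sequence[float], y: Sequence[float],
                       n_boot: int = 1000, seed: int = 0) -> NoiseResult:
    """Bootstrap standard errors (over cells) of the three noise components.

    Returns a NoiseResult whose fields hold the SEs, on the reported scale.
    """
    c = np.asarray(c, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = c.size
    vals = np.empty((n_boot, 3))
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        vals[i] = _moments(c[idx], y[idx])
    se = vals.std(axis=0, ddof=1) * NOISE_SCALE
    return NoiseResult("bootstrap_se", n, float(se[0]), float(se[1]), float(se[2]))
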
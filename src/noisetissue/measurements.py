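"""Nucleus-level fluorescence measurement tables and their preprocessing.

The raw unit of data is one row per nucleus, channel, time point and
technical replicate: a background-corrected mean grey value (8-bit scale,
0-255) of the nuclear region of interest, with the nucleus position (µm)
and maximal area (µm²). Preprocessing follows the standard recipe for such
tables: average technical duplicates, subtract the per-image per-channel
background, normalize by the per-image per-channel mean, and drop images
whose two channel distributions are skewed against each other
(two-sample Kolmogorov-Smirnov screen).

Normalization state is a one-way machine raw -> mean_normalized; operations
that require a particular state raise ``NormalizationStateError`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NormalizationStateError, ParameterError, UndefinedCorrelationError

__all__ = [
    "REQUIRED_COLUMNS",
    "NucleusTable",
    "KSDecision",
    "average_duplicates",
    "normalize_table",
    "timepoint_correlation",
    "ks_skew_filter",
    "cell_matrix",
]

REQUIRED_COLUMNS = [
    "image_id",
    "cell_id",
    "tissue",
    "x_um",
    "y_um",
    "area_um2",
    "channel",
    "time_h",
    "replicate",
    "mean_grey",
    "background_mean_grey",
]

RAW = "raw"
NORMALIZED = "mean_normalized"

_GROUP_KEYS = [c for c in REQUIRED_COLUMNS if c not in ("replicate", "mean_grey")]


@dataclass
class NucleusTable:
    """A long-format measurement table plus its normalization state.

    ``data`` holds one row per (nucleus, channel, time point, replicate);
    ``excluded_counts`` records, per (image_id, channel), how many rows were
    dropped because their background-subtracted value was non-positive.
    """

    data: pd.DataFrame
    state: str = RAW
    excluded_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            from .errors import SchemaError

            raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_cells(self) -> int:
        return self.data.groupby(["image_id", "cell_id"], sort=False).ngroups

    def require_state(self, state: str) -> None:
        if self.state != state:
            raise NormalizationStateError(
                f"operation requires a {state!r} table, got {self.state!r}"
            )


class KSDecision(NamedTuple):
    keep: bool
    p_value: float
    statistic: float


def average_duplicates(table: NucleusTable) -> NucleusTable:
    """Replace technical replicate measurements by their arithmetic mean.

    Rows are grouped by everything except the replicate index; single
    measurements pass through unchanged. The returned table has one row per
    (nucleus, channel, time point) with ``replicate = 0``.
    """
    df = table.data
    out = (
        df.groupby(_GROUP_KEYS, sort=False, as_index=False)["mean_grey"]
        .mean()
        .assign(replicate=0)
    )
    return NucleusTable(out[REQUIRED_COLUMNS], state=table.state,
                        excluded_counts=dict(table.excluded_counts))


def normalize_table(table: NucleusTable) -> NucleusTable:
    """Background-subtract and mean-normalize, per image and channel.

    Each value becomes (mean_grey - background); rows left non-positive are
    excluded (not clamped -- clamping would bias the normalization mean) and
    counted in ``excluded_counts``. The remaining values are divided by
    their per-(image, channel) mean, pooling all time points and replicates
    of that channel so that within-channel ratios (e.g. decay between time
    points) are preserved. The per-channel mean of the result is exactly 1.
    """
    table.require_state(RAW)
    df = table.data.copy()
    df["mean_grey"] = df["mean_grey"] - df["background_mean_grey"]
    bad = df["mean_grey"] <= 0
    excluded = dict(table.excluded_counts)
    if bad.any():
        for (img, ch), cnt in df[bad].groupby(["image_id", "channel"]).size().items():
            excluded[(img, ch)] = excluded.get((img, ch), 0) + int(cnt)
        df = df[~bad]
    if df.empty:
        raise NormalizationStateError("no positive background-subtracted values remain")
    means = df.groupby(["image_id", "channel"], sort=False)["mean_grey"].transform("mean")
    df["mean_grey"] = df["mean_grey"] / means
    return NucleusTable(df.reset_index(drop=True), state=NORMALIZED, excluded_counts=excluded)


def timepoint_correlation(values_a, values_b, method: str = "pearson") -> float:
    """Pearson or Spearman correlation between two paired intensity vectors.

    Used for the temporal analysis (e.g. green reporter at 3 h vs 6 h after
    conversion). Per-leaf coefficients are summarized across replicates by
    an unweighted mean, which the caller applies. Spearman uses average
    ranks for ties.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("paired vectors must have the same length")
    if a.size < 3:
        raise ParameterError("need at least 3 paired values")
    if a.std() == 0 or b.std() == 0:
        raise UndefinedCorrelationError("correlation undefined on zero-variance input")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ParameterError(f"unknown method {method!r}")


def ks_skew_filter(channel_a, channel_b, alpha: float = 0.05) -> KSDecision:
    """Two-sample Kolmogorov-Smirnov screen for channel skew.

    An image whose two (normalized) channel distributions differ at level
    ``alpha`` is excluded from noise analysis, since a systematic skew
    between channels would masquerade as intrinsic noise. ``alpha = 0``
    keeps everything.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ParameterError("need at least 5 values per channel")
    res = stats.ks_2samp(a, b)
    return KSDecision(keep=not (res.pvalue < alpha), p_value=float(res.pvalue),
                      statistic=float(res.statistic))


def cell_matrix(table: NucleusTable, channels: tuple[str, str] = ("CFP", "YFP"),
                time_h: float | None = None) -> pd.DataFrame:
    """Wide per-cell view: one row per (image, cell) with a column per channel.

    Replicates are averaged first if still present. Cells lacking either
    channel (e.g. one channel excluded during normalization) are dropped.
    Returns columns: image_id, cell_id, tissue, x_um, y_um, area_um2, and
    one value column per requested channel.
    """
    df = table.data
    if time_h is not None:
        df = df[df["time_h"] == time_h]
    df = df[df["channel"].isin(channels)]
    agg = df.groupby(["image_id", "cell_id", "tissue", "x_um", "y_um", "area_um2", "channel"],
                     sort=False, as_index=False)["mean_grey"].mean()
    wide = agg.pivot_table(index=["image_id", "cell_id", "tissue", "x_um", "y_um", "area_um2"],
                           columns="channel", values="mean_grey")
    wide = wide.dropna(subset=list(channels)).reset_index()
    wide.columns.name = None
    return wide
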
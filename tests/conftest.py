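import numpy as np
import pandas as pd
import pytest

from noisetissue import ExtrinsicSpec, NucleusTable, TwoStageParams
from noisetissue.measurements import NORMALIZED, REQUIRED_COLUMNS


@pytest.fixture(scope="session")
def reference_params() -> TwoStageParams:
    """Reference kinetic rates of the photoconvertible reporter analysis."""
    return TwoStageParams(transcription_rate=2.25, mrna_decay=1.125,
                          translation_rate=45.0, protein_decay=0.09)


@pytest.fixture(scope="session")
def reference_extrinsic() -> ExtrinsicSpec:
    return ExtrinsicSpec(mean=45.0, variance=100.0)


def make_raw_table(mean_grey, channel="CFP", background=10.0, image_id="img0",
                   x=None, y=None, area=None, replicate=0, time_h=0.0,
                   tissue="young_leaf", cell_ids=None) -> pd.DataFrame:
    """One-channel raw rows with sensible defaults, as a DataFrame."""
    vals = np.asarray(mean_grey, dtype=float)
    n = vals.size
    return pd.DataFrame({
        "image_id": image_id,
        "cell_id": cell_ids if cell_ids is not None else [f"c{i}" for i in range(n)],
        "tissue": tissue,
        "x_um": x if x is not None else np.arange(n, dtype=float),
        "y_um": y if y is not None else np.zeros(n),
        "area_um2": area if area is not None else np.full(n, 50.0),
        "channel": channel,
        "time_h": time_h,
        "replicate": replicate,
        "mean_grey": vals,
        "background_mean_grey": background,
    })[REQUIRED_COLUMNS]


def make_normalized_table(c, y, x=None, yy=None, image_id="img0") -> NucleusTable:
    """A mean_normalized dual-channel table from per-cell value vectors."""
    c = np.asarray(c, dtype=float)
    y = np.asarray(y, dtype=float)
    n = c.size
    xs = np.asarray(x, dtype=float) if x is not None else np.arange(n, dtype=float)
    ys = np.asarray(yy, dtype=float) if yy is not None else np.zeros(n)
    frames = [
        make_raw_table(c, channel="CFP", background=0.0, image_id=image_id, x=xs, y=ys),
        make_raw_table(y, channel="YFP", background=0.0, image_id=image_id, x=xs, y=ys),
    ]
    return NucleusTable(pd.concat(frames, ignore_index=True), state=NORMALIZED)
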
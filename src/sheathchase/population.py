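"""Population-level summaries: morphology/dynamics fractions, the
sheath-length vs cell-diameter regression, and per-cell sheath event counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats


class Morphology(str, Enum):
    ROD = "rod"
    SPHEROPLAST = "spheroplast"
    LYSED = "lysed"


@dataclass
class CellRecord:
    cell_id: str
    morphology: Morphology
    dynamic_t6ss: bool
    diameter_um: float | None = None
    surface_area_um2: float | None = None
    longest_sheath_um: float | None = None
    n_sheath_events_2min: int | None = None

    def __post_init__(self) -> None:
        self.morphology = Morphology(self.morphology)
        if (self.morphology is Morphology.SPHEROPLAST
                and self.longest_sheath_um is not None
                and self.diameter_um is not None
                and self.longest_sheath_um > self.diameter_um + 0.2):
            raise ValueError("sheath longer than the spheroplast diameter "
                             "beyond measurement tolerance")
        if self.n_sheath_events_2min is not None and self.n_sheath_events_2min < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    if "morphology" in df:
        df["morphology"] = df["morphology"].map(
            lambda m: Morphology(m).value)
    return df


def summarize_dynamics(records) -> pd.DataFrame:
    """Fraction of cells per morphology x T6SS-dynamics category, as
    percentages rounded to 2 decimals."""
    df = _as_frame(records)
    if len(df) == 0:
        raise ValueError("no records")
    counts = df.groupby(["morphology", "dynamic_t6ss"]).size()
    pct = (100.0 * counts / len(df)).round(2).rename("percent").reset_index()
    pct["n"] = counts.values
    return pct


def regress_length_vs_diameter(records) -> RegressionResult:
    """OLS of the longest sheath length on cell diameter over spheroplast
    records."""
    df = _as_frame(records)
    df = df[df["morphology"] == Morphology.SPHEROPLAST.value].dropna(
        subset=["diameter_um", "longest_sheath_um"])
    if len(df) < 3:
        raise ValueError("need at least 3 spheroplast records")
    x = df["diameter_um"].to_numpy(float)
    y = df["longest_sheath_um"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in diameter")
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue**2), len(df))


def count_sheath_events(event_log: pd.DataFrame, duration_s: float,
                        window_s: float = 120.0, t0_s: float = 0.0,
                        cell_ids=None) -> pd.Series:
    """Distinct nucleation events per cell within [t0, t0 + window].

    ``event_log`` needs columns cell_id, time_s, event; counts only
    ``event == "nucleation"`` rows. Pass ``cell_ids`` (the full roster of
    observed cells) so that cells without any event count as zero — a cell
    with no events leaves no rows in the log and would otherwise silently
    drop out, biasing the mean upward.
    """
    if t0_s + window_s > duration_s + 1e-9:
        raise ValueError("window exceeds the acquisition duration")
    df = event_log
    nuc = df[(df["event"] == "nucleation") & (df["time_s"] >= t0_s)
             & (df["time_s"] < t0_s + window_s)]
    counts = nuc.groupby("cell_id").size()
    if cell_ids is None:
        cell_ids = df["cell_id"].unique()
    all_cells = pd.Index(cell_ids, name="cell_id")
    return counts.reindex(all_cells, fill_value=0).astype(int)
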
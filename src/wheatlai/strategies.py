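"""Strategy enumeration, validation metrics and ranking.

Twenty-five retrieval strategies are screened: the 15 non-empty subsets of
the four bands and the 10 vegetation indices.  Each strategy is scored
against plot measurements with the squared Pearson correlation (R^2) and
the root-mean-square error (RMSE, LAI units); ranking is RMSE-first with
R^2 as the tie-break, mirroring how the lowest-RMSE strategy is selected
as "best" even when its R^2 is not the highest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .indices import VI_NAMES
from .lut import LUT, Strategy, invert_batch
from .priors import FREE_NAMES

# Band-subset menu order (the two-band pair printed as "B4, B5" in the
# study's table is the (B3, B4) pair: there is no band 5 and (B3, B4) is
# the unique missing pair among the six two-band combinations).
_BAND_SUBSETS = (
    ("B1",), ("B2",), ("B3",), ("B4",),
    ("B1", "B2"), ("B1", "B3"), ("B1", "B4"),
    ("B2", "B3"), ("B2", "B4"), ("B3", "B4"),
    ("B1", "B2", "B3"), ("B1", "B2", "B4"),
    ("B1", "B3", "B4"), ("B2", "B3", "B4"),
    ("B1", "B2", "B3", "B4"),
)


def enumerate_strategies() -> list[Strategy]:
    """All 25 strategies: 15 band subsets then the 10 VIs, in menu order."""
    out = [Strategy(kind="bands", bands=s) for s in _BAND_SUBSETS]
    out.extend(Strategy(kind="vi", vi=v) for v in VI_NAMES)
    return out


@dataclass(frozen=True)
class PlotRecord:
    """One validation plot: measured LAI (and optionally SPAD) plus the
    observed band signature at the plot location."""

    plot_id: str
    x: float
    y: float
    lai_measured: float
    bands: np.ndarray
    spad: float | None = None

    def __post_init__(self) -> None:
        if self.lai_measured < 0:
            raise DataError(f"plot {self.plot_id}: measured LAI must be >= 0")
        b = np.asarray(self.bands, float)
        if b.shape != (4,) or np.any((b < 0) | (b > 1)):
            raise DataError(f"plot {self.plot_id}: bands must be 4 values in [0, 1]")


@dataclass(frozen=True)
class StrategyScore:
    strategy: Strategy
    r2: float
    rmse: float
    n_plots: int


def r_squared(estimated, observed) -> float:
    """Coefficient of determination as the squared Pearson correlation."""
    y = np.asarray(estimated, float)
    o = np.asarray(observed, float)
    if y.shape != o.shape or y.size < 2:
        raise DataError("r_squared needs two equal-length sequences, n >= 2")
    yc = y - y.mean()
    oc = o - o.mean()
    vy = np.sum(yc ** 2)
    vo = np.sum(oc ** 2)
    if vy <= 0 or vo <= 0:
        raise DataError("r_squared undefined for zero-variance input")
    r = np.sum(yc * oc) / np.sqrt(vy * vo)
    return float(r ** 2)


def rmse(estimated, observed) -> float:
    """Root-mean-square error between estimates and observations."""
    y = np.asarray(estimated, float)
    o = np.asarray(observed, float)
    if y.shape != o.shape or y.size < 1:
        raise DataError("rmse needs two equal-length sequences, n >= 1")
    return float(np.sqrt(np.mean((y - o) ** 2)))


def evaluate_strategies(
    plots: list[PlotRecord],
    lut: LUT,
    strategies: list[Strategy] | None = None,
    fraction: float = 0.10,
) -> list[StrategyScore]:
    """Score every strategy on the validation plots.

    Each plot's observation is inverted per strategy; plots whose cost is
    undefined under a strategy are excluded from that strategy's score (and
    counted via n_plots).  A strategy with fewer than two usable plots
    raises DataError.
    """
    if len(plots) < 2:
        raise DataError("need at least two validation plots")
    strategies = strategies if strategies is not None else enumerate_strategies()
    obs = np.stack([p.bands for p in plots])
    measured = np.array([p.lai_measured for p in plots])
    lai_col = FREE_NAMES.index("lai")

    scores = []
    for strat in strategies:
        means, _ = invert_batch(obs, strat, lut, fraction)
        est = means[:, lai_col]
        ok = np.isfinite(est)
        if ok.sum() < 2:
            raise DataError(f"strategy {strat.label}: fewer than two plots "
                            "with defined cost")
        scores.append(StrategyScore(
            strategy=strat,
            r2=r_squared(est[ok], measured[ok]),
            rmse=rmse(est[ok], measured[ok]),
            n_plots=int(ok.sum()),
        ))
    return scores


def rank_strategies(scores: list[StrategyScore]) -> list[StrategyScore]:
    """Order by ascending RMSE, ties broken by descending R^2; the first
    element is the selected optimal strategy."""
    if not scores:
        raise DataError("no scores to rank")
    return sorted(scores, key=lambda s: (s.rmse, -s.r2))


def scores_to_frame(scores: list[StrategyScore]) -> pd.DataFrame:
    return pd.DataFrame({
        "strategy": [s.strategy.label for s in scores],
        "kind": [s.strategy.kind for s in scores],
        "r2": [s.r2 for s in scores],
        "rmse": [s.rmse for s in scores],
        "n": [s.n_plots for s in scores],
    })


def read_plots_csv(path) -> list[PlotRecord]:
    """Plot CSV dialect: plot_id, x, y, lai_measured, b1..b4[, spad]."""
    tab = pd.read_csv(path)
    need = {"plot_id", "x", "y", "lai_measured", "b1", "b2", "b3", "b4"}
    if not need.issubset(tab.columns):
        raise DataError(f"plot CSV missing columns {sorted(need - set(tab.columns))}")
    plots = []
    for _, row in tab.iterrows():
        plots.append(PlotRecord(
            plot_id=str(row["plot_id"]), x=float(row["x"]), y=float(row["y"]),
            lai_measured=float(row["lai_measured"]),
            bands=np.array([row["b1"], row["b2"], row["b3"], row["b4"]], float),
            spad=float(row["spad"]) if "spad" in tab.columns and pd.notna(row.get("spad")) else None,
        ))
    return plots


def write_plots_csv(plots: list[PlotRecord], path) -> None:
    rows = []
    for p in plots:
        rows.append({"plot_id": p.plot_id, "x": p.x, "y": p.y,
                     "lai_measured": p.lai_measured,
                     "b1": p.bands[0], "b2": p.bands[1],
                     "b3": p.bands[2], "b4": p.bands[3],
                     "spad": p.spad if p.spad is not None else np.nan})
    pd.DataFrame(rows).to_csv(path, index=False)
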
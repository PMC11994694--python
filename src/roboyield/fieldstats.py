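"""Field-trial statistics: moving-grid spatial adjustment, yield
normalization, and selection-threshold ranking metrics.

Breeding trials lay plots out on a (range, pass) grid; soil and other
environmental gradients add spatial noise to every phenotype measured on that
grid. The moving-grid method removes it: each plot's neighbourhood mean x_i is
computed over a 5x5 window with the four corners and the center excluded
(20 cells), a single coefficient b is fit by ordinary least squares of the
observed phenotype on x_i, and the adjusted value is

    p_adj = p_obs - b * (x_i - x_bar)

with x_bar the grand mean of the moving means. Selection-threshold ranking
then asks how well an estimated phenotype recovers the true top q-fraction of
plots, summarised as accuracy, sensitivity and specificity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FieldStatsError(ValueError):
    pass


def _grid_mask_offsets() -> tuple[tuple[int, int], ...]:
    """5x5 neighbourhood minus the 4 corners and the center: 20 offsets."""
    offsets = []
    for dr in range(-2, 3):
        for dp in range(-2, 3):
            if (dr, dp) == (0, 0):
                continue
            if abs(dr) == 2 and abs(dp) == 2:
                continue
            offsets.append((dr, dp))
    return tuple(offsets)


#: (d_range, d_pass) offsets of the moving-grid neighbourhood.
GRID_MASK: tuple[tuple[int, int], ...] = _grid_mask_offsets()


class FieldLayout:
    """A (range, pass) grid of plots with one or more phenotype columns.

    Thin wrapper around a tidy DataFrame with columns
    ``range``, ``pass``, ``entry`` plus value columns. Missing plots are
    simply absent rows (or NaN values) and are excluded from moving means.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"range", "pass"}
        if not required.issubset(df.columns):
            raise FieldStatsError(f"layout needs columns {sorted(required)}")
        if df.duplicated(subset=["range", "pass"]).any():
            raise FieldStatsError("duplicate (range, pass) plot indices")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "FieldLayout":
        return FieldLayout(self.df.copy())

    def pivot(self, value_col: str) -> pd.DataFrame:
        return self.df.pivot(index="range", columns="pass", values=value_col)

    @classmethod
    def from_csv(cls, path) -> "FieldLayout":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def moving_mean(
    layout: FieldLayout, value_col: str = "value"
) -> pd.DataFrame:
    """Per-plot moving mean over the masked neighbourhood.

    Edge plots average whatever masked neighbours are in bounds. Returns a
    DataFrame with ``range``, ``pass``, ``moving_mean`` and ``n_neighbors``.
    """
    values = {
        (r, p): v
        for r, p, v in zip(layout.df["range"], layout.df["pass"], layout.df[value_col])
    }
    rows = []
    for r, p in zip(layout.df["range"], layout.df["pass"]):
        neigh = [
            values[(r + dr, p + dp)]
            for dr, dp in GRID_MASK
            if (r + dr, p + dp) in values
            and not pd.isna(values[(r + dr, p + dp)])
        ]
        if not neigh:
            raise FieldStatsError(
                f"plot (range={r}, pass={p}) has no in-bounds masked neighbours"
            )
        rows.append({"range": r, "pass": p, "moving_mean": float(np.mean(neigh)),
                     "n_neighbors": len(neigh)})
    return pd.DataFrame(rows)


@dataclass
class SpatialAdjustmentModel:
    """Fitted moving-grid adjustment: slope ``b`` and moving means."""

    b: float
    x_bar: float
    moving_means: pd.DataFrame  # range, pass, moving_mean, n_neighbors
    value_col: str


def fit_adjustment(layout: FieldLayout, value_col: str = "value") -> SpatialAdjustmentModel:
    """Fit b as the OLS slope (with intercept) of the phenotype on the
    plot moving means."""
    mm = moving_mean(layout, value_col)
    merged = layout.df.merge(mm, on=["range", "pass"])
    mask = ~(merged[value_col].isna() | merged["moving_mean"].isna())
    if mask.sum() < 3:
        raise FieldStatsError("need at least 3 plots with defined moving means")
    x = merged.loc[mask, "moving_mean"].to_numpy(float)
    y = merged.loc[mask, value_col].to_numpy(float)
    if np.ptp(x) == 0:
        warnings.warn("zero variance in moving means; b set to 0", stacklevel=2)
        b = 0.0
    else:
        A = np.column_stack([x - x.mean(), np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        b = float(coef[0])
    return SpatialAdjustmentModel(
        b=b, x_bar=float(x.mean()), moving_means=mm, value_col=value_col
    )


def adjust(
    layout: FieldLayout,
    model: SpatialAdjustmentModel,
    out_col: str | None = None,
) -> FieldLayout:
    """Apply p_adj = p_obs - b * (x_i - x_bar); returns a new layout with the
    adjusted column (default ``<value_col>_adj``).

    Because x_bar is the mean of the x_i, the adjustment preserves the grand
    mean of the phenotype.
    """
    out_col = out_col or f"{model.value_col}_adj"
    df = layout.df.merge(model.moving_means, on=["range", "pass"], how="left")
    df[out_col] = df[model.value_col] - model.b * (df["moving_mean"] - model.x_bar)
    return FieldLayout(df.drop(columns=["moving_mean", "n_neighbors"]))


def normalize_yield(raw_mass_kg: float, moisture_pct: float, plot_area_m2: float) -> float:
    """Convert a plot combine mass to MT/ha at 13 % standard moisture.

    The harvested mass is rescaled to its 13 %-moisture equivalent by
    dry-matter proportionality, mass * (100 - moisture) / (100 - 13), then
    divided by the plot area in hectares.
    """
    if not 0 <= moisture_pct < 100:
        raise FieldStatsError(f"moisture {moisture_pct}% outside [0, 100)")
    if plot_area_m2 <= 0:
        raise FieldStatsError("plot area must be positive")
    mass_13 = raw_mass_kg * (100.0 - moisture_pct) / 87.0
    return (mass_13 / 1000.0) / (plot_area_m2 / 10_000.0)


@dataclass(frozen=True)
class ConfusionCounts:
    """Plot counts at a selection threshold."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _top_set(values: np.ndarray, k: int) -> set[int]:
    # stable: ties broken toward the earlier plot index
    order = np.lexsort((np.arange(len(values)), -values))
    return set(order[:k].tolist())


def confusion_at_threshold(
    truth: np.ndarray, estimate: np.ndarray, q: float
) -> ConfusionCounts:
    """Confusion counts for selecting the top ``q`` fraction by the estimate.

    The top set holds the ceil(q*N) largest values in each vector
    independently; ties are broken by stable plot order. NaNs are excluded
    pairwise with a warning.
    """
    if not 0 < q < 1:
        raise FieldStatsError(f"selection fraction q={q} outside (0, 1)")
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if t.shape != e.shape:
        raise FieldStatsError("truth and estimate must cover the same plots")
    valid = ~(np.isnan(t) | np.isnan(e))
    if not valid.all():
        warnings.warn(f"excluding {int((~valid).sum())} plots with NaN values",
                      stacklevel=2)
        t, e = t[valid], e[valid]
    n = len(t)
    k = math.ceil(q * n)
    true_top = _top_set(t, k)
    est_top = _top_set(e, k)
    tp = len(true_top & est_top)
    fp = len(est_top - true_top)
    fn = len(true_top - est_top)
    tn = n - tp - fp - fn
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def selection_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity and specificity from confusion counts.

    accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
    A zero denominator yields NaN with a warning rather than a silent 0.
    """
    out: dict[str, float] = {}
    pairs = {
        "accuracy": (c.TP + c.TN, c.n),
        "sensitivity": (c.TP, c.TP + c.FN),
        "specificity": (c.TN, c.TN + c.FP),
    }
    for name, (num, den) in pairs.items():
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=2)
            out[name] = float("nan")
        else:
            out[name] = num / den
    return out
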
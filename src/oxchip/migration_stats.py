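"""Cell-migration and proliferation statistics from 3-D track tables.

Tracks are consumed as tidy tables (track_id, t_min, x_um, y_um, z_um,
plus optional condition and device_id columns), one row per 10-min frame
over a 24-h time-lapse.  Speeds are 3-D Euclidean step distances per
interval in um/h; the population splits into slow/fast subpopulations at a
15 um/h threshold (about twice the frequency-distribution peak).  The gel
channel (-450 <= x <= 450 um) is divided into three equal regions L/M/R
for cell-count increases, and condition comparisons use Kruskal-Wallis
with Dunn's post-hoc z tests, Welch's t for proliferation folds, and a
two-way ANOVA (condition x 4-h time window) for normalized speed series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SPEED_THRESHOLD_UM_PER_H",
    "REGION_BOUNDS_UM",
    "SpeedSeries",
    "RegionCounts",
    "load_tracks",
    "compute_speeds",
    "split_subpopulations",
    "region_increase",
    "compare_conditions",
    "dunn_posthoc",
    "welch_test",
    "speed_window_anova",
]

SPEED_THRESHOLD_UM_PER_H = 15.0
REGION_BOUNDS_UM = (-450.0, -150.0, 150.0, 450.0)
FRAME_INTERVAL_MIN = 10.0

TRACK_COLUMNS = ["track_id", "t_min", "x_um", "y_um", "z_um"]


def load_tracks(path) -> pd.DataFrame:
    """Read a delimited track table and validate the schema."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns {missing}")
    return df


@dataclass
class SpeedSeries:
    """Derived migration speeds at several aggregation levels.

    intervals : per-track per-interval table (track_id, t_min, speed,
        dt_min, gap) where ``gap`` flags intervals longer than the nominal
        frame spacing (speed is computed over the actual gap).
    per_time : cross-track mean speed at each time point (pooled across
        tracks, then averaged).
    per_window : mean speed in consecutive 4-h windows.
    normalized : per_window divided by the first window (first element 1).
    """

    intervals: pd.DataFrame
    per_time: pd.DataFrame
    per_window: pd.DataFrame
    normalized: pd.DataFrame

    def track_medians(self) -> pd.Series:
        return self.intervals.groupby("track_id")["speed"].median()


def compute_speeds(
    tracks: pd.DataFrame,
    frame_interval_min: float = FRAME_INTERVAL_MIN,
    window_h: float = 4.0,
) -> SpeedSeries:
    """Per-interval 3-D migration speeds in um/h and their aggregates.

    Speed over an interval is the Euclidean displacement divided by the
    actual elapsed time, so a missing frame yields one (flagged) speed over
    the doubled gap rather than an artificial zero.
    """
    df = tracks.sort_values(["track_id", "t_min"])
    counts = df.groupby("track_id").size()
    bad = counts[counts < 2]
    if len(bad):
        raise ValueError(f"tracks with < 2 observations: {list(bad.index)}")
    g = df.groupby("track_id")
    dt = g["t_min"].diff()
    disp = np.sqrt(
        g["x_um"].diff() ** 2 + g["y_um"].diff() ** 2 + g["z_um"].diff() ** 2
    )
    if np.any(dt.dropna() <= 0):
        raise ValueError("timestamps must be strictly increasing within a track")
    intervals = pd.DataFrame(
        {
            "track_id": df["track_id"],
            "t_min": df["t_min"],
            "speed": disp / dt * 60.0,
            "dt_min": dt,
            "gap": dt > frame_interval_min * 1.5,
        }
    ).dropna(subset=["speed"])

    per_time = (
        intervals.groupby("t_min")["speed"].mean().rename("mean_speed").reset_index()
    )
    window_min = window_h * 60.0
    intervals = intervals.assign(window=(intervals["t_min"] - 1e-9) // window_min)
    per_window = (
        intervals.groupby("window")["speed"].mean().rename("mean_speed").reset_index()
    )
    first = per_window["mean_speed"].iloc[0]
    normalized = per_window.assign(mean_speed=per_window["mean_speed"] / first)
    return SpeedSeries(
        intervals=intervals.drop(columns="window"),
        per_time=per_time,
        per_window=per_window,
        normalized=normalized,
    )


def _histogram_peak(values: np.ndarray, bin_width: float) -> float:
    """Center of the most populated histogram bin (first on ties)."""
    if values.size == 0:
        return float("nan")
    hi = max(values.max(), bin_width)
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def split_subpopulations(
    speeds: SpeedSeries,
    threshold: float = SPEED_THRESHOLD_UM_PER_H,
    bin_width: float = 2.5,
) -> dict:
    """Split tracks into slow/fast movers at the speed threshold.

    Each track is summarized by its median interval speed (robust to
    single-frame jumps); the threshold (default 15 um/h, about twice the
    frequency-distribution peak) separates the subpopulations.  Returns
    track-id sets and each subpopulation's histogram peak speed.
    """
    medians = speeds.track_medians()
    if medians.empty:
        raise ValueError("no speeds to split")
    fast = medians[medians >= threshold]
    slow = medians[medians < threshold]
    return {
        "slow_tracks": list(slow.index),
        "fast_tracks": list(fast.index),
        "slow_peak": _histogram_peak(slow.to_numpy(), bin_width),
        "fast_peak": _histogram_peak(fast.to_numpy(), bin_width),
        "threshold": threshold,
    }


@dataclass
class RegionCounts:
    """Cell counts in the L/M/R thirds of the gel channel at two times."""

    table: pd.DataFrame  # rows L, M, R, outside; columns n_t0, n_t24, increase
    fold: float  # whole-gel N24 / N0


def _region_of(x: np.ndarray) -> np.ndarray:
    """L/M/R assignment on [-450,-150), [-150,150), [150,450]; ties at
    -150/150 fall to the region on the right (M and R respectively)."""
    lo, m1, m2, hi = REGION_BOUNDS_UM
    out = np.full(x.shape, "outside", dtype=object)
    out[(x >= lo) & (x < m1)] = "L"
    out[(x >= m1) & (x < m2)] = "M"
    out[(x >= m2) & (x <= hi)] = "R"
    return out


def region_increase(tracks: pd.DataFrame, t0: float, t24: float) -> RegionCounts:
    """Per-region cell counts at two time points and their increase.

    Cells are counted by their position at each time point (divisions
    create new track ids, so live-cell counts at the endpoints capture
    proliferation).  Cells outside +-450 um go to an "outside" bucket; the
    whole-gel fold change counts only cells inside.
    """
    rows = {}
    for label, t in (("n_t0", t0), ("n_t24", t24)):
        frame = tracks[tracks["t_min"] == t]
        if frame.empty:
            raise ValueError(f"no observations at t = {t} min")
        regions = _region_of(frame["x_um"].to_numpy(dtype=float))
        rows[label] = pd.Series(regions).value_counts()
    table = (
        pd.DataFrame(rows)
        .reindex(["L", "M", "R", "outside"])
        .fillna(0)
        .astype(int)
    )
    table["increase"] = table["n_t24"] - table["n_t0"]
    inside0 = table.loc[["L", "M", "R"], "n_t0"].sum()
    inside24 = table.loc[["L", "M", "R"], "n_t24"].sum()
    fold = inside24 / inside0 if inside0 else float("nan")
    return RegionCounts(table=table, fold=float(fold))


# ---------------------------------------------------------------------------
# hypothesis tests


def kruskal_wallis(groups: dict) -> tuple[float, float]:
    """Kruskal-Wallis H and p over a label -> sample mapping."""
    H, p = stats.kruskal(*groups.values())
    return float(H), float(p)


def dunn_posthoc(groups: dict, adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T] (1/n_i + 1/n_j)) with
    the tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided normal
    p-values with Holm (default), Bonferroni, or no adjustment.
    """
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    pooled = np.concatenate(samples)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    T = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    mean_ranks, sizes = {}, {}
    start = 0
    for k, s in zip(labels, samples):
        mean_ranks[k] = ranks[start : start + s.size].mean()
        sizes[k] = s.size
        start += s.size
    var0 = N * (N + 1) / 12.0 - T
    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt(var0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": min(p, 1.0)})
    table = pd.DataFrame(rows)
    m = len(table)
    if adjust == "holm":
        order = np.argsort(table["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * table["p_raw"].iloc[i])
            adj[i] = min(running, 1.0)
        table["p_adj"] = adj
    elif adjust == "bonferroni":
        table["p_adj"] = np.minimum(table["p_raw"] * m, 1.0)
    elif adjust in (None, "none"):
        table["p_adj"] = table["p_raw"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table


def welch_test(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t test (two-sided)."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(t), float(p)


def speed_window_anova(series: pd.DataFrame) -> pd.DataFrame:
    """Two-way ANOVA of normalized speed: factors condition x time window.

    ``series`` columns: condition, window, value (one row per device or
    replicate per window).  Returns the statsmodels ANOVA table.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = series.rename(columns=str).copy()
    for col in ("condition", "window", "value"):
        if col not in df.columns:
            raise ValueError(f"series must have a {col!r} column")
    model = smf.ols("value ~ C(condition) * C(window)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def compare_conditions(
    speeds_by_condition: dict,
    adjust: str = "holm",
    alpha: float = 0.05,
    min_group: int = 3,
) -> dict:
    """Kruskal-Wallis across conditions with Dunn's pairwise follow-up.

    Groups with fewer than ``min_group`` observations are dropped with a
    warning.  Returns H, p, the pairwise Dunn table with significance
    calls at ``alpha``, and the group sizes used.
    """
    groups = {}
    for label, vals in speeds_by_condition.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < min_group:
            warnings.warn(
                f"condition {label!r} dropped: {arr.size} < {min_group} observations",
                stacklevel=2,
            )
            continue
        groups[label] = arr
    if len(groups) < 2:
        raise ValueError("need >= 2 conditions with enough observations")
    H, p = kruskal_wallis(groups)
    pairs = dunn_posthoc(groups, adjust=adjust)
    pairs["significant"] = pairs["p_adj"] < alpha
    return {
        "H": H,
        "p": p,
        "pairwise": pairs,
        "sizes": {k: v.size for k, v in groups.items()},
        "alpha": alpha,
    }
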
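"""Station-level vegetation covariates, diversity indices, and collinearity
screening.

Plot geometry: one 30 m x 30 m plot (900 m^2 = 0.09 ha) per station holding
the large-tree tally (DBH > 10 cm), with 3 m x 3 m (9 m^2) sapling subplots.
Densities are scaled to per-hectare using these nominal areas.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

PLOT_AREA_HA = 900.0 / 10_000.0
SUBPLOT_AREA_HA = 9.0 / 10_000.0


# ---------------------------------------------------------------------------
# diversity indices
# ---------------------------------------------------------------------------

def shannon_h(species_counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log, positive counts)."""
    counts = np.asarray(list(species_counts), dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("at least one positive count required")
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def pielou_j(species_counts) -> float:
    """Pielou evenness J = H / ln S; undefined for a single species."""
    counts = np.asarray(list(species_counts), dtype=float)
    s = int((counts > 0).sum())
    if s < 2:
        raise ValueError("Pielou's J requires at least two species")
    return shannon_h(counts) / np.log(s)


def fishers_alpha(s: int, n: int, tol: float = 1e-9) -> float:
    """Fisher's alpha: the root of S = alpha * ln(1 + N/alpha).

    Solved by bracketed root finding to |S_fit - S| < ``tol``.
    """
    if not 1 <= s <= n:
        raise ValueError("need 1 <= S <= N")
    if s == n:
        raise ValueError("S == N has no finite Fisher's alpha")

    def f(alpha: float) -> float:
        return alpha * np.log1p(n / alpha) - s

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("Fisher's alpha did not bracket; S too close to N")
    alpha = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    assert abs(f(alpha)) < tol
    return float(alpha)


# ---------------------------------------------------------------------------
# plot tallies -> station covariates
# ---------------------------------------------------------------------------

@dataclass
class PlotTally:
    """Raw vegetation measurements for one station's habitat plot.

    tree_records: (species, dbh_cm, height_m) for every tree with DBH > 10 cm.
    sapling_counts: stems per 9 m^2 subplot.
    undergrowth_proportions: covered fraction in [0, 1] per measurement.
    """

    station_id: str
    tree_records: list[tuple[str, float, float]] = field(default_factory=list)
    sapling_counts: list[int] = field(default_factory=list)
    canopy_heights: list[float] = field(default_factory=list)
    canopy_covers: list[float] = field(default_factory=list)
    trail_widths: list[float] = field(default_factory=list)
    undergrowth_proportions: list[float] = field(default_factory=list)
    season: str = "wet"

    def __post_init__(self) -> None:
        for sp, dbh, _height in self.tree_records:
            if dbh <= 10:
                raise ValueError(
                    f"station {self.station_id}: tree {sp} has DBH {dbh} <= 10 cm"
                )
        for u in self.undergrowth_proportions:
            if not 0 <= u <= 1:
                raise ValueError("undergrowth proportions must lie in [0, 1]")


def _mean_sd(values) -> tuple[float, float]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return 0.0, 0.0
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def station_covariates(tally: PlotTally) -> dict:
    """Station covariate row: stem densities (/ha), structure means/SDs, and
    large-tree diversity indices."""
    n_trees = len(tally.tree_records)
    large_stems = n_trees / PLOT_AREA_HA
    if tally.sapling_counts:
        small_stems = sum(tally.sapling_counts) / (
            len(tally.sapling_counts) * SUBPLOT_AREA_HA
        )
    else:
        small_stems = 0.0

    ch_mean, ch_sd = _mean_sd(tally.canopy_heights)
    cc_mean, cc_sd = _mean_sd(tally.canopy_covers)
    un_mean, un_sd = _mean_sd(tally.undergrowth_proportions)
    widths = np.asarray(tally.trail_widths, dtype=float)
    tw_mean = float(widths.mean()) if widths.size else 0.0
    tw_max = float(widths.max()) if widths.size else 0.0

    counts = Counter(sp for sp, _, _ in tally.tree_records)
    if counts:
        h = shannon_h(counts.values())
        j = pielou_j(counts.values()) if len(counts) > 1 else float("nan")
        s, total = len(counts), sum(counts.values())
        alpha = fishers_alpha(s, total) if s < total else float("nan")
    else:
        h, j, alpha = 0.0, float("nan"), float("nan")

    return {
        "station": tally.station_id,
        "large_stem_density": large_stems,
        "small_stem_density": small_stems,
        "canopy_height_mean": ch_mean,
        "canopy_height_sd": ch_sd,
        "canopy_cover_mean": cc_mean,
        "canopy_cover_sd": cc_sd,
        "undergrowth_mean": un_mean,
        "undergrowth_sd": un_sd,
        "trail_width_mean": tw_mean,
        "trail_width_max": tw_max,
        "shannon_h": h,
        "pielou_j": j,
        "fishers_alpha": alpha,
        "season": tally.season,
    }


def covariate_table(tallies: list[PlotTally]) -> pd.DataFrame:
    return pd.DataFrame([station_covariates(t) for t in tallies]).set_index("station")


# ---------------------------------------------------------------------------
# collinearity screening
# ---------------------------------------------------------------------------

def screen_collinear(covariates: pd.DataFrame, scores: dict[str, float],
                     threshold: float = 0.70) -> list[str]:
    """Drop the lower-scoring member of every covariate pair with |r| > threshold.

    ``scores`` assigns each covariate a cross-species significance score (the
    pipeline uses the mean |estimate/SE| from univariate occupancy fits).
    Constant covariates (undefined r) are dropped first with a warning. The
    procedure removes the worst offender and re-checks until no pair exceeds
    the threshold, which makes the result deterministic.
    """
    numeric = covariates.select_dtypes(include=[np.number])
    retained = [c for c in numeric.columns if c in scores]
    for col in list(retained):
        if numeric[col].std(ddof=0) == 0:
            warnings.warn(f"covariate {col} is constant; dropped", stacklevel=2)
            retained.remove(col)

    while True:
        if len(retained) < 2:
            break
        corr = numeric[retained].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= threshold:
            break
        a, b = retained[i], retained[j]
        drop = a if scores[a] < scores[b] else b
        # deterministic tie-break: drop the lexicographically later name
        if scores[a] == scores[b]:
            drop = max(a, b)
        retained.remove(drop)
    return retained


def standardize(covariates: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Z-score continuous covariates so model coefficients are comparable."""
    out = covariates.copy()
    cols = columns or out.select_dtypes(include=[np.number]).columns
    for col in cols:
        sd = out[col].std(ddof=0)
        if sd > 0:
            out[col] = (out[col] - out[col].mean()) / sd
        else:
            out[col] = 0.0
    return out
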
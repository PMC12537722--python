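"""Seasonal temperature summaries, Welch t-tests, and methane fold changes.

Summer here is 1 June - 22 September 2021 and winter 21 December 2021 -
20 March 2022 (logger windows); fold changes compare methane concentrations
between seasons (same site and bay) or between bays (same site and season)
at matched depths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .flux import PorewaterProfile

__all__ = [
    "SeasonWindow",
    "DEFAULT_SUMMER",
    "DEFAULT_WINTER",
    "SummaryStats",
    "FoldChangeRecord",
    "seasonal_summary",
    "welch_t_test",
    "fold_change",
    "fold_change_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeasonWindow:
    label: str
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if self.end <= self.start:
            raise ValueError(f"window end must follow start: {self.start} .. {self.end}")


DEFAULT_SUMMER = SeasonWindow("summer", pd.Timestamp("2021-06-01"), pd.Timestamp("2021-09-22"))
DEFAULT_WINTER = SeasonWindow("winter", pd.Timestamp("2021-12-21"), pd.Timestamp("2022-03-20"))


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    min: float
    max: float
    n: int


@dataclass(frozen=True)
class FoldChangeRecord:
    """Ratio of methane under one (bay, season) context to a matched one."""

    site: str
    depth: float
    numerator_context: tuple[str, str]  # (bay, season)
    denominator_context: tuple[str, str]
    ratio: float
    floor_applied: bool = False

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("fold-change ratio must be positive")


def seasonal_summary(series: pd.Series, window: SeasonWindow) -> SummaryStats:
    """Mean, sample sd, min, max of a temperature series within a window.

    ``series`` must be timestamp-indexed (degC); observations with timestamps
    in [start, end] inclusive are used.
    """
    mask = (series.index >= window.start) & (series.index <= window.end)
    values = series.loc[mask].to_numpy(dtype=float)
    if values.size < 2:
        raise ValueError(
            f"window {window.label!r} ({window.start.date()}..{window.end.date()}) "
            f"contains {values.size} observations (need >= 2)"
        )
    return SummaryStats(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        min=float(values.min()),
        max=float(values.max()),
        n=int(values.size),
    )


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, Welch-Satterthwaite df, p).

    Degenerate case: both samples constant with equal means gives t = 0, p = 1
    by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both variances are zero with unequal means; t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _methane_at_depth(
    profile: PorewaterProfile, depth: float, tolerance: float
) -> float | None:
    methane = profile.analytes.get("methane")
    if methane is None:
        return None
    offsets = np.abs(profile.depths - depth)
    i = int(np.argmin(offsets))
    if offsets[i] > tolerance:
        return None
    return float(methane[i])


def fold_change(
    profiles: list[PorewaterProfile],
    contrast: str,
    depth: float,
    floor: float = 1e-4,
    depth_tolerance: float = 1.0,
    numerator: str = "summer",
    denominator: str = "winter",
    match_sites: bool = True,
) -> list[FoldChangeRecord]:
    """Per-site methane fold changes at a matched depth.

    contrast="season" pairs profiles sharing (site, bay) and divides the
    ``numerator`` season by the ``denominator`` season; contrast="bay" pairs
    on (site, season) with numerator/denominator naming bays.  When the bays
    have disjoint site labels, ``match_sites=False`` instead averages the
    concentration across sites within each remaining group and emits one
    ratio-of-means record per group (site="mean").  Denominators below
    ``floor`` (mM) are floored and the record flagged; depths match to the
    nearest profile midpoint within ``depth_tolerance`` cm.
    """
    if contrast == "season":
        group_of = lambda p: (p.site, p.bay) if match_sites else ("mean", p.bay)  # noqa: E731
        level_of = lambda p: p.season  # noqa: E731
    elif contrast == "bay":
        group_of = lambda p: (p.site, p.season) if match_sites else ("mean", p.season)  # noqa: E731
        level_of = lambda p: p.bay  # noqa: E731
    else:
        raise ValueError(f"contrast must be 'season' or 'bay', got {contrast!r}")

    if not match_sites:
        return _fold_change_of_means(
            profiles, group_of, level_of, depth, floor, depth_tolerance, numerator, denominator
        )

    by_group: dict[tuple[str, str], dict[str, PorewaterProfile]] = {}
    for p in profiles:
        by_group.setdefault(group_of(p), {})[level_of(p)] = p

    records: list[FoldChangeRecord] = []
    for key, levels in sorted(by_group.items()):
        if numerator not in levels or denominator not in levels:
            logger.info("fold_change: group %s lacks both contexts; skipped", key)
            continue
        p_num, p_den = levels[numerator], levels[denominator]
        c_num = _methane_at_depth(p_num, depth, depth_tolerance)
        c_den = _methane_at_depth(p_den, depth, depth_tolerance)
        if c_num is None or c_den is None:
            logger.info(
                "fold_change: group %s has no methane within %.1f cm of %.1f cm; skipped",
                key, depth_tolerance, depth,
            )
            continue
        floored = c_den < floor
        num_floored = c_num < floor
        ratio = max(c_num, floor) / max(c_den, floor)
        records.append(
            FoldChangeRecord(
                site=p_num.site,
                depth=depth,
                numerator_context=(p_num.bay, p_num.season),
                denominator_context=(p_den.bay, p_den.season),
                ratio=ratio,
                floor_applied=floored or num_floored,
            )
        )
    return records


def _fold_change_of_means(
    profiles, group_of, level_of, depth, floor, depth_tolerance, numerator, denominator
) -> list[FoldChangeRecord]:
    """Ratio of across-site mean concentrations for each group (site='mean')."""
    groups: dict[tuple[str, str], dict[str, list[float]]] = {}
    for p in profiles:
        c = _methane_at_depth(p, depth, depth_tolerance)
        if c is None:
            continue
        groups.setdefault(group_of(p), {}).setdefault(level_of(p), []).append(c)
    contexts: dict[str, dict[str, tuple[str, str]]] = {}
    for p in profiles:
        contexts.setdefault(group_of(p)[1], {})[level_of(p)] = (p.bay, p.season)
    records = []
    for (tag, key), levels in sorted(groups.items()):
        if numerator not in levels or denominator not in levels:
            logger.info("fold_change: group %s lacks both contexts; skipped", key)
            continue
        c_num = float(np.mean(levels[numerator]))
        c_den = float(np.mean(levels[denominator]))
        floored = c_den < floor or c_num < floor
        records.append(
            FoldChangeRecord(
                site=tag,
                depth=depth,
                numerator_context=contexts[key][numerator],
                denominator_context=contexts[key][denominator],
                ratio=max(c_num, floor) / max(c_den, floor),
                floor_applied=floored,
            )
        )
    return records


def fold_change_summary(records: list[FoldChangeRecord]) -> dict[str, float]:
    """Max ("up to"), mean-of-ratios, and n for a set of fold-change records.

    Both max and mean are reported because an "average fold change" can mean
    either; callers wanting a ratio-of-means should compute it from the raw
    concentrations.
    """
    if not records:
        raise ValueError("no fold-change records to summarize")
    ratios = np.array([r.ratio for r in records], dtype=float)
    return {
        "max_fold": float(ratios.max()),
        "mean_fold": float(ratios.mean()),
        "n_records": int(ratios.size),
    }
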
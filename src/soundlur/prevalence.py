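"""Per-clip detections -> per-site-date-period sound-type prevalence.

Also hosts the category ontology (fine class label -> category), the
fixed-site day subsampler used to rebalance year-long deployments against
week-long ones, and the classifier validation arithmetic.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_city import (
    CATEGORIES,
    DAY_END_HOUR,
    DAY_START_HOUR,
    FINE_CLASSES,
    ClipLabel,
)

__all__ = [
    "ALL_CATEGORIES",
    "MODELLED_CATEGORIES",
    "default_ontology",
    "map_clip_to_categories",
    "assign_period",
    "compute_prevalence",
    "build_model_table",
    "subsample_fixed_site_days",
    "validate_classifier",
    "ClassifierValidationReport",
]

#: Every category a clip can map to (includes the two non-modelled ones).
ALL_CATEGORIES = tuple(CATEGORIES) + ("other",)

#: Categories used as model targets by default. Airplane sounds and the
#: miscellaneous 'other' bucket are excluded; geophysical nature is fitted
#: but flagged downstream (see lur module).
MODELLED_CATEGORIES = (
    "road_transport",
    "animal_insect",
    "music",
    "speech",
    "geophysical_nature",
)

#: Clips scheduled per period on a fully captured day (6 per hour).
SCHEDULED_CLIPS = {"day": (DAY_END_HOUR - DAY_START_HOUR) * 6, "night": (24 - (DAY_END_HOUR - DAY_START_HOUR)) * 6}


def default_ontology() -> dict[str, str]:
    """Total mapping fine class label -> category."""
    ontology = {}
    for cat, labels in FINE_CLASSES.items():
        for label in labels:
            ontology[label] = cat
    return ontology


def map_clip_to_categories(clip: ClipLabel, ontology: dict[str, str]) -> set[str]:
    """Union of categories of the clip's detected classes.

    The mapping is total: labels absent from the ontology fall into
    ``other``, so the result is never empty.
    """
    return {ontology.get(label, "other") for label in clip.detected_classes if label}


def assign_period(timestamp) -> str:
    """'day' iff the clock time falls in [06:00, 22:00), else 'night'."""
    ts = pd.Timestamp(timestamp)
    return "day" if DAY_START_HOUR <= ts.hour < DAY_END_HOUR else "night"


def _period_date(ts: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Vectorized (period, attributed date) for clip timestamps.

    A night period is attached to the date on which it begins: clips between
    midnight and 05:59 belong to the night of the previous calendar date.
    """
    hours = ts.dt.hour
    is_day = (hours >= DAY_START_HOUR) & (hours < DAY_END_HOUR)
    period = np.where(is_day, "day", "night")
    date = ts.dt.normalize()
    date = date.where(~(hours < DAY_START_HOUR), date - pd.Timedelta(days=1))
    return pd.Series(period, index=ts.index), date.dt.date


def compute_prevalence(
    clips: pd.DataFrame,
    ontology: dict[str, str],
    categories: tuple[str, ...] = ALL_CATEGORIES,
    min_clip_fraction: float = 0.5,
) -> pd.DataFrame:
    """Prevalence (%) of each category per site x date x period.

    Parameters
    ----------
    clips
        Frame with columns ``site_id, timestamp, class1, class2, class3``.
    ontology
        Fine label -> category mapping (total; unknowns become ``other``).
    categories
        Categories to emit; each gets a row per cell, zero when absent.
    min_clip_fraction
        Cells with fewer than this fraction of the scheduled clips for their
        period (96 day / 48 night) are dropped: prevalences from a handful
        of clips on partial deployment days are not informative.

    Returns
    -------
    Frame with columns
    ``site_id, date, period, category, n_clips, n_present, prevalence``.
    """
    if clips.empty:
        return pd.DataFrame(
            columns=["site_id", "date", "period", "category", "n_clips", "n_present", "prevalence"]
        )
    clips = clips.copy()
    clips["timestamp"] = pd.to_datetime(clips["timestamp"])
    period, date = _period_date(clips["timestamp"])
    clips["period"] = period
    clips["date"] = date

    keys = ["site_id", "date", "period"]
    cell_sizes = clips.groupby(keys, sort=True).size().rename("n_clips")

    # presence per clip per category: melt the three class columns
    long = clips.melt(
        id_vars=keys + ["timestamp"],
        value_vars=["class1", "class2", "class3"],
        value_name="label",
    )
    long = long[long["label"].astype(str) != ""]
    long["category"] = long["label"].map(lambda s: ontology.get(s, "other"))
    present = (
        long.drop_duplicates(subset=keys + ["timestamp", "category"])
        .groupby(keys + ["category"], sort=True)
        .size()
        .rename("n_present")
    )

    cells = cell_sizes.reset_index()
    # one row per cell x requested category, zero-filled
    cells = cells.merge(pd.DataFrame({"category": list(categories)}), how="cross")
    out = cells.merge(present.reset_index(), on=keys + ["category"], how="left")
    out["n_present"] = out["n_present"].fillna(0).astype(int)

    scheduled = out["period"].map(SCHEDULED_CLIPS)
    out = out[out["n_clips"] >= min_clip_fraction * scheduled].copy()
    out["prevalence"] = 100.0 * out["n_present"] / out["n_clips"]
    return out.reset_index(drop=True)


def build_model_table(
    prevalence_table: pd.DataFrame,
    sites: pd.DataFrame,
    categories: tuple[str, ...] = MODELLED_CATEGORIES,
    collapse: str = "site_date",
) -> pd.DataFrame:
    """Attach site_type and restrict to model-target categories.

    ``collapse='site'`` averages the dated rows into one per-site period mean
    (the alternative reading of the training-row granularity); the default
    keeps site-date rows.
    """
    if collapse not in ("site_date", "site"):
        raise ValueError("collapse must be 'site_date' or 'site'")
    table = prevalence_table[prevalence_table["category"].isin(categories)].merge(
        sites[["site_id", "site_type"]], on="site_id", how="left"
    )
    if table["site_type"].isna().any():
        missing = table.loc[table["site_type"].isna(), "site_id"].unique()
        raise ValueError(f"sites missing from site table: {sorted(missing)[:5]}")
    if collapse == "site":
        table = (
            table.groupby(["site_id", "period", "category", "site_type"], sort=True)[
                "prevalence"
            ]
            .mean()
            .reset_index()
        )
    return table.reset_index(drop=True)


def _site_rng(seed: int, site_id: str) -> np.random.Generator:
    import zlib

    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(site_id.encode())])
    )


def subsample_fixed_site_days(
    table: pd.DataFrame, n_days: int = 30, seed: int = 0
) -> pd.DataFrame:
    """Keep min(n_days, available) random distinct dates per fixed site.

    Rotating-site rows pass through untouched. Dates are sampled without
    replacement with a per-site stream derived from ``seed``, so the same
    dates are retained no matter how the table is split by category/period.
    """
    if "date" not in table.columns:
        return table
    out = []
    for (site_id, site_type), group in table.groupby(
        ["site_id", "site_type"], sort=True
    ):
        if site_type != "fixed":
            out.append(group)
            continue
        dates = np.array(sorted(group["date"].unique()))
        if len(dates) > n_days:
            rng = _site_rng(seed, site_id)
            dates = dates[np.sort(rng.choice(len(dates), size=n_days, replace=False))]
        out.append(group[group["date"].isin(dates)])
    return pd.concat(out, ignore_index=True)


@dataclass
class ClassifierValidationReport:
    """Per-category confusion counts and derived metrics (percent).

    Undefined ratios (zero denominator) are reported as ``None`` and listed
    in ``flags`` rather than silently coerced to 0.
    """

    counts: dict[str, dict[str, int]]
    accuracy: dict[str, float]
    ppv: dict[str, float | None]
    npv: dict[str, float | None]
    flags: list[str]

    def as_dict(self) -> dict:
        return {
            "counts": self.counts,
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
            "flags": self.flags,
        }


def validate_classifier(
    predicted: pd.DataFrame, manual: pd.DataFrame
) -> ClassifierValidationReport:
    """Agreement of predicted presence against manual labels.

    Both frames carry one row per clip and one boolean column per category;
    rows are matched positionally (same clip order) or on a shared
    ``clip_id`` column when present.
    """
    if "clip_id" in predicted.columns and "clip_id" in manual.columns:
        predicted = predicted.set_index("clip_id").sort_index()
        manual = manual.set_index("clip_id").sort_index()
        if not predicted.index.equals(manual.index):
            raise ValueError("clip_id sets differ between predicted and manual labels")
    elif len(predicted) != len(manual):
        raise ValueError("predicted and manual label frames differ in length")

    categories = [c for c in predicted.columns if c in manual.columns]
    counts, accuracy, ppv, npv, flags = {}, {}, {}, {}, []
    for cat in categories:
        p = np.asarray(predicted[cat], dtype=bool)
        m = np.asarray(manual[cat], dtype=bool)
        tp = int(np.sum(p & m))
        fp = int(np.sum(p & ~m))
        fn = int(np.sum(~p & m))
        tn = int(np.sum(~p & ~m))
        counts[cat] = {"TP": tp, "FP": fp, "FN": fn, "TN": tn}
        accuracy[cat] = 100.0 * (tp + tn) / (tp + fp + fn + tn)
        if tp + fp == 0:
            ppv[cat] = None
            flags.append(f"{cat}: PPV undefined (no predicted positives)")
        else:
            ppv[cat] = 100.0 * tp / (tp + fp)
        if tn + fn == 0:
            npv[cat] = None
            flags.append(f"{cat}: NPV undefined (no predicted negatives)")
        else:
            npv[cat] = 100.0 * tn / (tn + fn)
    if flags:
        warnings.warn("; ".join(flags), stacklevel=2)
    return ClassifierValidationReport(counts, accuracy, ppv, npv, flags)
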
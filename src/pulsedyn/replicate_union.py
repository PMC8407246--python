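"""Union of biological replicates, time binning, and within-bin ranking.

Replicates are combined per protein and time point: a value measured in a
single replicate is kept as-is (confidence class I), the arithmetic mean is
taken over two (class II) or three (class III) replicates. Time points are
then pooled into configurable bins by the median, and proteins are ranked
into quartile categories within each bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigError
from .quant_io import ExperimentDesign, ProteinQuantRecord, format_hours

logger = logging.getLogger(__name__)


class ConfidenceClass(str, Enum):
    """Replicate support of a merged value: I = 1 replicate, II = 2, III = 3."""

    I = "I"
    II = "II"
    III = "III"


_CLASS_BY_COUNT = {1: ConfidenceClass.I, 2: ConfidenceClass.II, 3: ConfidenceClass.III}


class QuartileCategory(str, Enum):
    TOP25 = "top25"
    P25_50 = "p25_50"
    P50_75 = "p50_75"
    BOTTOM25 = "bottom25"
    MISSING = "missing"


@dataclass
class MergedTimeCourse:
    """Per-protein time series of merged H/L ratios with confidence classes."""

    protein_id: str
    values: dict[float, tuple[float, ConfidenceClass]] = field(default_factory=dict)

    def ratio_at(self, time_h: float) -> float | None:
        entry = self.values.get(time_h)
        return entry[0] if entry else None


@dataclass
class BinScheme:
    """Ordered, disjoint grouping of time points into labeled bins."""

    bins: list[tuple[str, list[float]]]
    condition: str = "persistence"

    def __post_init__(self) -> None:
        seen: set[float] = set()
        for label, members in self.bins:
            if not members:
                raise ConfigError(f"bin {label!r} has no member time points")
            overlap = seen & set(members)
            if overlap:
                raise ConfigError(
                    f"bin {label!r} reuses time point(s): "
                    + ", ".join(format_hours(t) for t in sorted(overlap))
                )
            seen |= set(members)

    def validate_against(self, design: ExperimentDesign) -> None:
        known = set(design.time_points_h)
        unknown = sorted(
            {t for _, members in self.bins for t in members} - known
        )
        if unknown:
            raise ConfigError(
                "bin scheme references time point(s) absent from the design: "
                + ", ".join(format_hours(t) for t in unknown)
            )

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.bins]


def default_bin_scheme(condition: str, pulse_times_h: list[float]) -> BinScheme:
    """Shipped default bin schemes.

    Resuscitation uses the five reported bins (10–30 min, 45–90 min, 2–3 h,
    4–5 h, 6–8 h) intersected with the available time points. The six
    persistence bins are a reconstruction: the post-pulse time points are
    split into contiguous groups of sizes (3, 3, 3, 3, 2, 2).
    """
    ts = sorted(pulse_times_h)
    if condition == "resuscitation":
        windows = [
            ("bin1_10-30min", 10 / 60, 30 / 60),
            ("bin2_45-90min", 45 / 60, 90 / 60),
            ("bin3_2-3h", 2.0, 3.0),
            ("bin4_4-5h", 4.0, 5.0),
            ("bin5_6-8h", 6.0, 8.0),
        ]
        bins = []
        for label, lo, hi in windows:
            members = [t for t in ts if lo - 1e-9 <= t <= hi + 1e-9]
            if members:
                bins.append((label, members))
        return BinScheme(bins=bins, condition=condition)
    sizes = (3, 3, 3, 3, 2, 2)
    if len(ts) != sum(sizes):
        # uneven designs: distribute as evenly as possible over six bins
        base, extra = divmod(len(ts), 6)
        sizes = tuple(base + (1 if i < extra else 0) for i in range(6))
    bins = []
    pos = 0
    for i, size in enumerate(s for s in sizes if s > 0):
        members = ts[pos : pos + size]
        bins.append((f"bin{i + 1}", members))
        pos += size
    return BinScheme(bins=bins, condition=condition)


@dataclass
class BinnedRankMatrix:
    """Per protein, per bin: median merged ratio and quartile category."""

    bin_labels: list[str]
    median_ratio: dict[str, dict[str, float | None]]
    quartile: dict[str, dict[str, QuartileCategory]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid in sorted(self.median_ratio):
            row: dict[str, object] = {"protein_id": pid}
            for label in self.bin_labels:
                row[f"median_{label}"] = self.median_ratio[pid][label]
                row[f"rank_{label}"] = self.quartile[pid][label].value
            rows.append(row)
        return pd.DataFrame(rows)


def merge_replicates(records: Iterable[ProteinQuantRecord]) -> list[MergedTimeCourse]:
    """Combine replicates as a union with confidence classes.

    Per protein and time point, replicate ratios are averaged; the class
    records how many replicates contributed. Time points measured in no
    replicate are omitted entirely.
    """
    merged: list[MergedTimeCourse] = []
    for rec in records:
        by_time: dict[float, list[float]] = {}
        for (_, t), r in rec.ratio_hl.items():
            by_time.setdefault(t, []).append(r)
        course = MergedTimeCourse(protein_id=rec.protein_id)
        for t in sorted(by_time):
            vals = by_time[t]
            if len(vals) > 3:
                raise ConfigError(
                    f"protein {rec.protein_id}: {len(vals)} replicate values at "
                    f"t={format_hours(t)} h; at most 3 supported"
                )
            course.values[t] = (sum(vals) / len(vals), _CLASS_BY_COUNT[len(vals)])
        merged.append(course)
    return merged


def assign_time_bins(
    merged: MergedTimeCourse,
    scheme: BinScheme,
    design: ExperimentDesign | None = None,
) -> dict[str, float | None]:
    """Median merged ratio of each bin's member time points (None if empty)."""
    if design is not None:
        scheme.validate_against(design)
    out: dict[str, float | None] = {}
    for label, members in scheme.bins:
        vals = sorted(
            v for t in members if (v := merged.ratio_at(t)) is not None
        )
        if not vals:
            out[label] = None
        else:
            n = len(vals)
            mid = n // 2
            out[label] = vals[mid] if n % 2 else (vals[mid - 1] + vals[mid]) / 2.0
    return out


def rank_within_bins(
    binned: Mapping[str, Mapping[str, float | None]],
    bin_labels: list[str] | None = None,
) -> BinnedRankMatrix:
    """Partition proteins into quartile categories within each bin.

    Proteins are sorted by ratio descending (ties broken by protein id,
    lexicographic); quartile boundaries sit at ranks ceil(n/4), ceil(n/2)
    and ceil(3n/4). Bins with fewer than 4 quantified proteins are ranked
    as missing, with a warning.
    """
    if bin_labels is None:
        labels_seen: list[str] = []
        for per_bin in binned.values():
            for label in per_bin:
                if label not in labels_seen:
                    labels_seen.append(label)
        bin_labels = labels_seen

    medians: dict[str, dict[str, float | None]] = {
        pid: {label: per_bin.get(label) for label in bin_labels}
        for pid, per_bin in binned.items()
    }
    quartile: dict[str, dict[str, QuartileCategory]] = {
        pid: {label: QuartileCategory.MISSING for label in bin_labels}
        for pid in binned
    }

    for label in bin_labels:
        present = [
            (pid, v) for pid in binned if (v := medians[pid][label]) is not None
        ]
        n = len(present)
        if n < 4:
            if n:
                logger.warning(
                    "bin %s has only %d quantified protein(s); ranks set missing",
                    label, n,
                )
            continue
        present.sort(key=lambda item: (-item[1], item[0]))
        q1 = math.ceil(n / 4)
        q2 = math.ceil(n / 2)
        q3 = math.ceil(3 * n / 4)
        for rank, (pid, _) in enumerate(present, start=1):
            if rank <= q1:
                cat = QuartileCategory.TOP25
            elif rank <= q2:
                cat = QuartileCategory.P25_50
            elif rank <= q3:
                cat = QuartileCategory.P50_75
            else:
                cat = QuartileCategory.BOTTOM25
            quartile[pid][label] = cat

    return BinnedRankMatrix(
        bin_labels=list(bin_labels), median_ratio=medians, quartile=quartile
    )


def merged_to_frame(courses: Iterable[MergedTimeCourse]) -> pd.DataFrame:
    """Long-format serialization: protein_id, time_h, ratio_hl, confidence_class."""
    rows = [
        {
            "protein_id": c.protein_id,
            "time_h": t,
            "ratio_hl": ratio,
            "confidence_class": cls.value,
        }
        for c in courses
        for t, (ratio, cls) in sorted(c.values.items())
    ]
    return pd.DataFrame(rows, columns=["protein_id", "time_h", "ratio_hl", "confidence_class"])


def merged_from_frame(df: pd.DataFrame) -> list[MergedTimeCourse]:
    """Inverse of :func:`merged_to_frame`."""
    courses: dict[str, MergedTimeCourse] = {}
    for row in df.itertuples(index=False):
        course = courses.setdefault(
            row.protein_id, MergedTimeCourse(protein_id=row.protein_id)
        )
        course.values[float(row.time_h)] = (
            float(row.ratio_hl),
            ConfidenceClass(row.confidence_class),
        )
    return list(courses.values())
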
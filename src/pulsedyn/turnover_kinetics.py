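"""Label-incorporation kinetics: turnover rates, half-lives and reliability.

The turnover rate is the closed-form through-origin least-squares slope of
``y = ln(r + 1)`` on time::

    k = sum_i ln(r_i + 1) * t_i / sum_i t_i**2

with ``r`` the protein H/L ratio. The half-life is ``T1/2 = ln 2 / k``. Fit
quality is the uncentered coefficient of determination
``R^2 = 1 - sum (y - k t)^2 / sum y^2`` (the centered variant is misleading
for a model without intercept). A fit is reliable when it rests on at least
``min_points`` time points and exceeds ``min_r2``.

An optional labeled-pool-purity estimator from partially labeled
missed-cleavage peptides is provided: under binomial labeling with purity
``p``, two-lysine peptides are fully heavy with probability ``p**2`` and
mixed with probability ``2 p (1 - p)``, giving ``p_hat = 2 HH / (2 HH + HL)``.
The corrected rate is ``k / p_hat``. This reconstruction is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Serialized stand-in for an infinite half-life (empty cell in TSV output).
INFINITE_HALF_LIFE = math.inf

DEFAULT_MIN_POINTS = 5
DEFAULT_MIN_R2 = 0.70


@dataclass
class IncorporationProfile:
    """Per-protein heavy-label incorporation fractions over time."""

    protein_id: str
    points: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, f in self.points.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(
                    f"incorporation fraction {f} at t={t} outside [0, 1]"
                )


@dataclass
class TurnoverFit:
    protein_id: str
    k: float
    half_life_h: float
    r_squared: float  # NaN when undefined (all-zero signal)
    n_points: int
    reliable: bool


@dataclass
class RecyclingEstimate:
    pool_purity: float
    n_peptides_used: int
    note: str = "binomial label-state estimator on 2-Lys missed-cleavage peptides"


def incorporation_fraction(ratio_hl: float) -> float:
    """Heavy fraction of total intensity, ``r / (1 + r)`` for ``r = H/L``."""
    if not math.isfinite(ratio_hl) or ratio_hl < 0:
        raise ValueError(f"ratio must be finite and >= 0, got {ratio_hl}")
    return ratio_hl / (1.0 + ratio_hl)


def ratio_from_fraction(fraction: float) -> float:
    """Inverse of :func:`incorporation_fraction` on [0, 1)."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"fraction must lie in [0, 1), got {fraction}")
    return fraction / (1.0 - fraction)


def fit_turnover_rate(
    times: Sequence[float],
    ratios: Sequence[float],
    protein_id: str = "",
    min_points: int = DEFAULT_MIN_POINTS,
    min_r2: float = DEFAULT_MIN_R2,
) -> TurnoverFit:
    """Closed-form turnover-rate fit from (time, H/L ratio) pairs.

    The t=0 control must be excluded and missing pairs dropped before the
    call. Ratios of exactly 0 are legitimate (ln 1 = 0, slow turnover).
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if t.size != r.size:
        raise ValueError("times and ratios must have equal length")
    if t.size == 0:
        raise ValueError("empty input: at least one (time, ratio) pair required")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("times must be finite and > 0 (t=0 control excluded)")
    if np.any(~np.isfinite(r)) or np.any(r < 0):
        raise ValueError("ratios must be finite and >= 0")

    y = np.log1p(r)
    k = float(np.sum(y * t) / np.sum(t * t))
    ss_tot = float(np.sum(y * y))
    if ss_tot == 0.0:
        r2 = math.nan  # zero signal: R^2 undefined
    else:
        ss_res = float(np.sum((y - k * t) ** 2))
        r2 = 1.0 - ss_res / ss_tot
    n = int(t.size)
    reliable = n >= min_points and math.isfinite(r2) and r2 > min_r2
    return TurnoverFit(
        protein_id=protein_id,
        k=k,
        half_life_h=half_life_from_rate(k),
        r_squared=r2,
        n_points=n,
        reliable=reliable,
    )


def half_life_from_rate(k: float) -> float:
    """``T1/2 = ln 2 / k``; infinity for ``k = 0``."""
    if k < 0:
        raise ValueError(f"rate must be >= 0, got {k}")
    if k == 0:
        return INFINITE_HALF_LIFE
    return math.log(2.0) / k


def select_reliable_fits(
    fits: Iterable[TurnoverFit],
    min_points: int = DEFAULT_MIN_POINTS,
    min_r2: float = DEFAULT_MIN_R2,
) -> list[TurnoverFit]:
    """Keep fits with ``n_points >= min_points`` and ``R^2 > min_r2``."""
    out = []
    for fit in fits:
        ok = (
            fit.n_points >= min_points
            and math.isfinite(fit.r_squared)
            and fit.r_squared > min_r2
        )
        fit.reliable = ok
        if ok:
            out.append(fit)
    return out


def fit_merged_courses(
    courses,
    min_points: int = DEFAULT_MIN_POINTS,
    min_r2: float = DEFAULT_MIN_R2,
) -> list[TurnoverFit]:
    """Fit every merged time course (t=0 excluded, missing points dropped)."""
    fits = []
    for course in courses:
        pairs = [(t, v[0]) for t, v in sorted(course.values.items()) if t > 0]
        if not pairs:
            continue
        times, ratios = zip(*pairs)
        fits.append(
            fit_turnover_rate(
                times, ratios, protein_id=course.protein_id,
                min_points=min_points, min_r2=min_r2,
            )
        )
    return fits


def profiles_from_records(records) -> list[IncorporationProfile]:
    """Incorporation profiles from per-replicate ratios.

    Each replicate's ratio is converted to a fraction ``r / (1 + r)`` and the
    median over replicates is taken per time point (the t=0 control carries
    no heavy signal and yields no point).
    """
    profiles = []
    for rec in records:
        by_time: dict[float, list[float]] = {}
        for (_, t), r in rec.ratio_hl.items():
            if t > 0:
                by_time.setdefault(t, []).append(incorporation_fraction(r))
        points: dict[float, float] = {}
        for t, vals in by_time.items():
            vals.sort()
            n = len(vals)
            mid = n // 2
            points[t] = vals[mid] if n % 2 else (vals[mid - 1] + vals[mid]) / 2.0
        if points:
            profiles.append(IncorporationProfile(protein_id=rec.protein_id, points=points))
    return profiles


def estimate_recycling_factor(
    missed_cleavage_counts: tuple[int, int],
) -> RecyclingEstimate:
    """Labeled-pool purity from heavy-heavy vs heavy-light peptide counts."""
    n_hh, n_hl = missed_cleavage_counts
    if n_hh < 0 or n_hl < 0:
        raise ValueError("peptide counts must be >= 0")
    if n_hh == 0 and n_hl == 0:
        raise ValueError("at least one labeled missed-cleavage peptide required")
    p_hat = 2.0 * n_hh / (2.0 * n_hh + n_hl)
    return RecyclingEstimate(pool_purity=p_hat, n_peptides_used=n_hh + n_hl)


def correct_rate_for_recycling(k: float, estimate: RecyclingEstimate) -> float:
    """Rate corrected for labeled-pool impurity: ``k / p_hat``."""
    if estimate.pool_purity <= 0:
        raise ValueError("pool purity must be > 0 to correct a rate")
    return k / estimate.pool_purity


def fits_to_frame(fits: Iterable[TurnoverFit]) -> pd.DataFrame:
    """TSV-ready frame; infinite half-lives serialize as empty cells."""
    rows = []
    for f in fits:
        rows.append(
            {
                "protein_id": f.protein_id,
                "k_per_h": f.k,
                "half_life_h": (
                    None if math.isinf(f.half_life_h) else f.half_life_h
                ),
                "r_squared": None if math.isnan(f.r_squared) else f.r_squared,
                "n_points": f.n_points,
                "reliable": f.reliable,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "k_per_h", "half_life_h", "r_squared", "n_points", "reliable"],
    )
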
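"""Fisher-exact over/underrepresentation testing with BH FDR control.

Each functional category is tested against a 2x2 table::

                    annotated   not annotated
    in set              a            b
    background only     c            d

with a two-sided exact p-value (sum of hypergeometric probabilities of
tables at most as probable as the observed one). Categories are adjusted
per annotation source with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

logger = logging.getLogger(__name__)

DEFAULT_MIN_CATEGORY_SIZE = 3


@dataclass
class AnnotationSet:
    """One functional category and its member proteins."""

    category_id: str
    category_name: str
    members: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)


@dataclass
class EnrichmentResult:
    category_id: str
    category_name: str
    source: str
    a: int  # in set, annotated
    b: int  # in set, not annotated
    c: int  # background only, annotated
    d: int  # background only, not annotated
    odds_ratio: float
    p_value: float
    q_value: float
    direction: str  # "over" | "under"


def read_gmt(path) -> list[AnnotationSet]:
    """Read a GMT-like TSV: category_id <tab> name <tab> member ids..."""
    sets: list[AnnotationSet] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                continue
            sets.append(
                AnnotationSet(
                    category_id=parts[0],
                    category_name=parts[1],
                    members=frozenset(p for p in parts[2:] if p),
                )
            )
    return sets


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c), with Haldane 0.5 continuity correction iff any cell is 0."""
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
        return (a2 * d2) / (b2 * c2)
    return (a * d) / (b * c)


def fisher_overrepresentation(
    protein_set: Iterable[str],
    universe: Iterable[str],
    annotations: Sequence[AnnotationSet],
    min_category_size: int = DEFAULT_MIN_CATEGORY_SIZE,
) -> list[EnrichmentResult]:
    """Test every category for over/underrepresentation of *protein_set*.

    Categories are first intersected with the universe; those below
    ``min_category_size`` are skipped. q-values are BH-adjusted within each
    annotation source.
    """
    sset = set(protein_set)
    uni = set(universe)
    offenders = sorted(sset - uni)
    if offenders:
        raise ValueError(
            "protein set contains ids absent from the universe: "
            + ", ".join(offenders[:20])
            + ("..." if len(offenders) > 20 else "")
        )

    results: list[EnrichmentResult] = []
    for ann in annotations:
        cat = ann.members & uni
        if not cat:
            logger.info("category %s has no members in the universe; skipped", ann.category_id)
            continue
        if len(cat) < min_category_size:
            continue
        a = len(sset & cat)
        b = len(sset) - a
        c = len(cat) - a
        d = len(uni) - len(sset) - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        in_rate = a / (a + b) if (a + b) else 0.0
        bg_rate = c / (c + d) if (c + d) else 0.0
        results.append(
            EnrichmentResult(
                category_id=ann.category_id,
                category_name=ann.category_name,
                source=ann.source,
                a=a, b=b, c=c, d=d,
                odds_ratio=_odds_ratio(a, b, c, d),
                p_value=float(p),
                q_value=float("nan"),
                direction="over" if in_rate > bg_rate else "under",
            )
        )

    # BH within each annotation source
    by_source: dict[str, list[int]] = {}
    for i, res in enumerate(results):
        by_source.setdefault(res.source, []).append(i)
    for idxs in by_source.values():
        qs = adjust_fdr_bh([results[i].p_value for i in idxs])
        for i, q in zip(idxs, qs):
            results[i].q_value = q
    return results


def adjust_fdr_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    ``q(i) = min_{j >= i} p(j) * m / j`` over the ascending ordering,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce step-up monotonicity from the largest rank down
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q.tolist()


def enrichment_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    cols = [
        "category_id", "category_name", "source", "a", "b", "c", "d",
        "odds_ratio", "p_value", "q_value", "direction",
    ]
    return pd.DataFrame([vars(r) for r in results], columns=cols)
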
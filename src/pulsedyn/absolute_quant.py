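"""Heavy-channel iBAQ: heavy intensity over the observable Lys-C peptide count.

Lys-C cleaves C-terminally of every lysine, including Lys-Pro bonds (unlike
trypsin). The in-silico digest enumerates all contiguous joins of up to
``max_missed + 1`` fragments; a peptide is observable when its length falls
in the configured window (default 7-30 residues). The iBAQ estimate for a
protein is its heavy-channel intensity divided by the number of distinct
observable peptide sequences, with the median over replicates reported per
time point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .quant_io import ProteinQuantRecord

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISSED = 2
DEFAULT_MIN_LEN = 7
DEFAULT_MAX_LEN = 30


@dataclass
class Peptide:
    sequence: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    missed_cleavages: int


@dataclass
class DigestResult:
    protein_id: str
    peptides: list[Peptide]
    observable_count: int


@dataclass
class IbaqEstimate:
    protein_id: str
    time_h: float
    ibaq_heavy: float


def digest_lysc(
    sequence: str,
    max_missed: int = DEFAULT_MAX_MISSED,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    protein_id: str = "",
) -> DigestResult:
    """In-silico Lys-C digest with missed cleavages.

    ``observable_count`` counts *unique* peptide sequences whose length lies
    in ``[min_len, max_len]`` — a sequence produced by several fragment
    joins is one observable species.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    seq = sequence.upper()

    # fragment boundaries: cut after every K (K-P bonds included)
    cuts = [i + 1 for i, aa in enumerate(seq) if aa == "K"]
    starts = [0] + [c for c in cuts if c < len(seq)]
    ends = [c for c in cuts if c < len(seq)] + [len(seq)]
    fragments = list(zip(starts, ends))

    peptides: list[Peptide] = []
    for i in range(len(fragments)):
        for n_joined in range(1, max_missed + 2):
            j = i + n_joined - 1
            if j >= len(fragments):
                break
            start = fragments[i][0]
            end = fragments[j][1]
            peptides.append(
                Peptide(
                    sequence=seq[start:end],
                    start=start + 1,
                    end=end,
                    missed_cleavages=n_joined - 1,
                )
            )
    observable = {
        p.sequence for p in peptides if min_len <= len(p.sequence) <= max_len
    }
    return DigestResult(
        protein_id=protein_id, peptides=peptides, observable_count=len(observable)
    )


def digest_proteome(
    sequences: Mapping[str, str],
    max_missed: int = DEFAULT_MAX_MISSED,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> dict[str, DigestResult]:
    return {
        pid: digest_lysc(seq, max_missed, min_len, max_len, protein_id=pid)
        for pid, seq in sequences.items()
    }


def compute_ibaq_heavy(
    records: Iterable[ProteinQuantRecord],
    digests: Mapping[str, DigestResult],
) -> tuple[list[IbaqEstimate], list[str]]:
    """Per protein and time point, median over replicates of H / observable_count.

    Returns the estimates plus the skip report: proteins without a digest or
    with zero observable peptides.
    """
    estimates: list[IbaqEstimate] = []
    skipped: list[str] = []
    for rec in records:
        digest = digests.get(rec.protein_id)
        if digest is None:
            logger.warning("no digest for %s; skipped", rec.protein_id)
            skipped.append(rec.protein_id)
            continue
        if digest.observable_count == 0:
            logger.warning(
                "%s has no observable peptide; iBAQ undefined", rec.protein_id
            )
            skipped.append(rec.protein_id)
            continue
        by_time: dict[float, list[float]] = {}
        for (_, t), h in rec.intensity_heavy.items():
            by_time.setdefault(t, []).append(h / digest.observable_count)
        for t in sorted(by_time):
            vals = sorted(by_time[t])
            n = len(vals)
            mid = n // 2
            median = vals[mid] if n % 2 else (vals[mid - 1] + vals[mid]) / 2.0
            estimates.append(
                IbaqEstimate(protein_id=rec.protein_id, time_h=t, ibaq_heavy=median)
            )
    return estimates, skipped


def ibaq_to_frame(estimates: Iterable[IbaqEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(e) for e in estimates],
        columns=["protein_id", "time_h", "ibaq_heavy"],
    )
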
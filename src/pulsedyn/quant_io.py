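"""Reading, validation and writing of protein-groups quantification tables.

Input tables follow the MaxQuant ``proteinGroups.txt`` dialect: one row per
protein group, with per-experiment heavy/light intensities, H/L ratios and
ratio counts, plus the three quality-control flag columns (``+`` = flagged).
Column names are resolved through a configurable :class:`ColumnMap` because
the exact labels drift between software versions.

Conventions adopted here:

* intensity cells equal to ``0`` are treated as *missing* ("not detected"),
  never as an abundance of zero;
* unparseable numeric cells become missing, not zero;
* flag cells are true iff the cell equals ``+``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ConfigError, SchemaError

if TYPE_CHECKING:  # pragma: no cover - import only for typing
    from .replicate_union import BinScheme

logger = logging.getLogger(__name__)

#: Residues considered standard for FASTA validation (20 canonical + X).
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

CellKey = tuple[str, float]


def format_hours(t: float) -> str:
    """Canonical compact rendering of a time point in hours (``0.25`` not ``0.250``)."""
    return format(float(t), "g")


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from logical fields to table column names.

    Per-experiment columns are built from ``*_template`` strings where
    ``{exp}`` expands to ``experiment_template`` rendered with the replicate
    identifier and the canonical time label.
    """

    protein_id: str = "Protein IDs"
    gene_name: str = "Gene names"
    contaminant: str = "Potential contaminant"
    reverse: str = "Reverse"
    only_by_site: str = "Only identified by site"
    ratio_template: str = "Ratio H/L {exp}"
    ratio_count_template: str = "Ratio H/L count {exp}"
    intensity_heavy_template: str = "Intensity H {exp}"
    intensity_light_template: str = "Intensity L {exp}"
    experiment_template: str = "{replicate}_{time}h"

    def experiment_label(self, replicate: str, time_h: float) -> str:
        return self.experiment_template.format(
            replicate=replicate, time=format_hours(time_h)
        )

    def ratio(self, replicate: str, time_h: float) -> str:
        return self.ratio_template.format(exp=self.experiment_label(replicate, time_h))

    def ratio_count(self, replicate: str, time_h: float) -> str:
        return self.ratio_count_template.format(
            exp=self.experiment_label(replicate, time_h)
        )

    def intensity_heavy(self, replicate: str, time_h: float) -> str:
        return self.intensity_heavy_template.format(
            exp=self.experiment_label(replicate, time_h)
        )

    def intensity_light(self, replicate: str, time_h: float) -> str:
        return self.intensity_light_template.format(
            exp=self.experiment_label(replicate, time_h)
        )


@dataclass
class ExperimentDesign:
    """Sampling layout of one pulse-labeling experiment.

    ``time_points_h`` must be strictly increasing and include ``0`` — the
    pre-pulse control. ``bin_scheme`` may be attached later (it belongs to
    the binning stage).
    """

    condition: str
    replicates: list[str]
    time_points_h: list[float]
    bin_scheme: "BinScheme | None" = None

    def __post_init__(self) -> None:
        if self.condition not in ("persistence", "resuscitation"):
            raise ConfigError(
                f"condition must be 'persistence' or 'resuscitation', got {self.condition!r}"
            )
        if not self.replicates:
            raise ConfigError("design needs at least one replicate")
        if len(set(self.replicates)) != len(self.replicates):
            raise ConfigError("replicate identifiers must be unique")
        ts = [float(t) for t in self.time_points_h]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ConfigError("time_points_h must be strictly increasing")
        if not ts or ts[0] != 0.0:
            raise ConfigError("time_points_h must start with the t=0 control")
        self.time_points_h = ts

    @property
    def pulse_times_h(self) -> list[float]:
        """Time points after label addition (excludes the t=0 control)."""
        return [t for t in self.time_points_h if t > 0.0]


@dataclass
class ProteinQuantRecord:
    """One protein group's per-replicate, per-time-point quantification.

    All per-cell mappings are keyed by ``(replicate, time_h)``. Missing
    cells are simply absent from the mapping.
    """

    protein_id: str
    gene_name: str = ""
    intensity_heavy: dict[CellKey, float] = field(default_factory=dict)
    intensity_light: dict[CellKey, float] = field(default_factory=dict)
    ratio_hl: dict[CellKey, float] = field(default_factory=dict)
    ratio_count: dict[CellKey, int] = field(default_factory=dict)
    contaminant: bool = False
    reverse: bool = False
    only_by_site: bool = False

    @property
    def flagged(self) -> bool:
        return self.contaminant or self.reverse or self.only_by_site


def _parse_number(value: object) -> float | None:
    """Parse a numeric cell; unparseable or non-finite values become missing."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    try:
        x = float(value)
    except (TypeError, ValueError):
        return None
    if not math.isfinite(x):
        return None
    return x


def _parse_flag(value: object) -> bool:
    return isinstance(value, str) and value.strip() == "+"


def required_columns(design: ExperimentDesign, columns: ColumnMap) -> list[str]:
    """All column names a conforming table must contain for *design*."""
    cols = [
        columns.protein_id,
        columns.contaminant,
        columns.reverse,
        columns.only_by_site,
    ]
    for rep in design.replicates:
        for t in design.time_points_h:
            cols.append(columns.ratio(rep, t))
            cols.append(columns.ratio_count(rep, t))
            cols.append(columns.intensity_heavy(rep, t))
            cols.append(columns.intensity_light(rep, t))
    return cols


def read_protein_groups(
    path: str | Path,
    design: ExperimentDesign,
    columns: ColumnMap | None = None,
) -> list[ProteinQuantRecord]:
    """Read a protein-groups TSV into :class:`ProteinQuantRecord` objects.

    Raises
    ------
    SchemaError
        If a required column is absent (named in the message) or protein
        identifiers are duplicated (duplicates listed).
    """
    columns = columns or ColumnMap()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    missing = [c for c in required_columns(design, columns) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    ids = df[columns.protein_id].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise SchemaError(f"duplicate protein ids: {', '.join(dupes)}")

    has_gene = columns.gene_name in df.columns
    records: list[ProteinQuantRecord] = []
    for _, row in df.iterrows():
        rec = ProteinQuantRecord(
            protein_id=row[columns.protein_id],
            gene_name=row[columns.gene_name] if has_gene else "",
            contaminant=_parse_flag(row[columns.contaminant]),
            reverse=_parse_flag(row[columns.reverse]),
            only_by_site=_parse_flag(row[columns.only_by_site]),
        )
        for rep in design.replicates:
            for t in design.time_points_h:
                key = (rep, t)
                h = _parse_number(row[columns.intensity_heavy(rep, t)])
                l = _parse_number(row[columns.intensity_light(rep, t)])
                # MaxQuant writes 0 for "not detected"
                if h is not None and h > 0:
                    rec.intensity_heavy[key] = h
                if l is not None and l > 0:
                    rec.intensity_light[key] = l
                r = _parse_number(row[columns.ratio(rep, t)])
                if r is not None and r >= 0:
                    rec.ratio_hl[key] = r
                    n = _parse_number(row[columns.ratio_count(rep, t)])
                    rec.ratio_count[key] = int(n) if n is not None and n >= 0 else 0
                elif r is not None and r < 0:
                    logger.warning(
                        "negative ratio %s for %s at %s treated as missing",
                        r, rec.protein_id, key,
                    )
        records.append(rec)
    return records


def apply_quality_filters(
    records: Iterable[ProteinQuantRecord], min_ratio_count: int = 2
) -> list[ProteinQuantRecord]:
    """Remove flagged rows and mask under-supported ratio cells.

    Rows with any of the contaminant/reverse/only-by-site flags are dropped.
    Each ratio cell whose paired ratio count is below ``min_ratio_count`` is
    masked (set missing) — the masking is cell-level, so a row survives as
    long as at least one ratio cell does. Intensities are never modified.
    The operation is idempotent.
    """
    out: list[ProteinQuantRecord] = []
    n_flagged = 0
    for rec in records:
        if rec.flagged:
            n_flagged += 1
            continue
        keep = {
            key: r
            for key, r in rec.ratio_hl.items()
            if rec.ratio_count.get(key, 0) >= min_ratio_count
        }
        if not keep:
            logger.info(
                "protein %s has no ratio cell with count >= %d; dropped",
                rec.protein_id, min_ratio_count,
            )
            continue
        out.append(
            ProteinQuantRecord(
                protein_id=rec.protein_id,
                gene_name=rec.gene_name,
                intensity_heavy=dict(rec.intensity_heavy),
                intensity_light=dict(rec.intensity_light),
                ratio_hl=keep,
                ratio_count={k: rec.ratio_count[k] for k in keep},
                contaminant=rec.contaminant,
                reverse=rec.reverse,
                only_by_site=rec.only_by_site,
            )
        )
    if n_flagged and not out:
        logger.warning("all %d records were flagged; empty output", n_flagged)
    return out


def nonstandard_residues(sequence: str) -> set[str]:
    """Characters in *sequence* outside the 20 canonical residues plus X."""
    return set(sequence.upper()) - STANDARD_RESIDUES


def read_fasta(path: str | Path, id_mode: str = "uniprot") -> dict[str, str]:
    """Read a protein FASTA into ``{protein_id: uppercase sequence}``.

    ``id_mode='uniprot'`` extracts the accession from pipe-delimited headers
    (``sp|P0A7D1|RAIA_ECOLI`` -> ``P0A7D1``); ``'full'`` keeps the first
    whitespace-delimited token. Sequences with residues outside the canonical
    alphabet are retained and logged.
    """
    if id_mode not in ("uniprot", "full"):
        raise ConfigError(f"id_mode must be 'uniprot' or 'full', got {id_mode!r}")
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        token = rec.id  # first whitespace-delimited token of the header
        if id_mode == "uniprot" and "|" in token:
            parts = token.split("|")
            pid = parts[1] if len(parts) >= 2 and parts[1] else token
        else:
            pid = token
        if pid in sequences:
            raise SchemaError(f"duplicate FASTA id: {pid}")
        seq = str(rec.seq).upper()
        odd = nonstandard_residues(seq)
        if odd:
            logger.warning(
                "sequence %s contains nonstandard residue(s): %s",
                pid, "".join(sorted(odd)),
            )
        sequences[pid] = seq
    if not sequences:
        raise SchemaError(f"empty FASTA file: {path}")
    return sequences


def records_to_frame(
    records: Sequence[ProteinQuantRecord],
    design: ExperimentDesign,
    columns: ColumnMap | None = None,
) -> pd.DataFrame:
    """Serialize records back to the protein-groups dialect.

    Missing intensities are written as 0 and missing ratios as empty cells,
    so ``read_protein_groups`` round-trips the output.
    """
    columns = columns or ColumnMap()
    table: dict[str, list] = {
        columns.protein_id: [r.protein_id for r in records],
        columns.gene_name: [r.gene_name for r in records],
    }
    for rep in design.replicates:
        for t in design.time_points_h:
            key = (rep, t)
            table[columns.intensity_heavy(rep, t)] = [
                r.intensity_heavy.get(key, 0.0) for r in records
            ]
            table[columns.intensity_light(rep, t)] = [
                r.intensity_light.get(key, 0.0) for r in records
            ]
            table[columns.ratio(rep, t)] = [
                r.ratio_hl.get(key) for r in records
            ]
            table[columns.ratio_count(rep, t)] = [
                r.ratio_count.get(key, 0) for r in records
            ]
    table[columns.contaminant] = ["+" if r.contaminant else "" for r in records]
    table[columns.reverse] = ["+" if r.reverse else "" for r in records]
    table[columns.only_by_site] = ["+" if r.only_by_site else "" for r in records]
    return pd.DataFrame(table)


def write_table(rows: pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    """Write tabular results as TSV: header row, empty string for missing,
    UTF-8, newline-terminated, floats at 12 significant digits."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(
        path,
        sep="\t",
        index=False,
        na_rep="",
        float_format="%.12g",
        encoding="utf-8",
        lineterminator="\n",
    )
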
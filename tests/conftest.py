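import numpy as np
import pytest

from pulsedyn.quant_io import ColumnMap, ExperimentDesign


@pytest.fixture
def columns():
    return ColumnMap()


@pytest.fixture
def toy_design():
    """Two replicates, control plus two sampling times."""
    return ExperimentDesign(
        condition="persistence",
        replicates=["r1", "r2"],
        time_points_h=[0.0, 1.0, 2.0],
    )


@pytest.fixture
def three_rep_design():
    return ExperimentDesign(
        condition="persistence",
        replicates=["r1", "r2", "r3"],
        time_points_h=[0.0, 1.0, 2.0, 4.0],
    )


def write_toy_table(path, design, rows, columns=None):
    """Write a protein-groups TSV from compact row dicts.

    Each row: {"id": ..., "gene": ..., "flags": "CRS" subset,
               "cells": {(rep, t): (heavy, light, ratio, count)}}
    Missing cells are serialized as 0 intensity / empty ratio.
    """
    columns = columns or ColumnMap()
    header = [columns.protein_id, columns.gene_name]
    for rep in design.replicates:
        for t in design.time_points_h:
            header += [
                columns.intensity_heavy(rep, t),
                columns.intensity_light(rep, t),
                columns.ratio(rep, t),
                columns.ratio_count(rep, t),
            ]
    header += [columns.contaminant, columns.reverse, columns.only_by_site]
    lines = ["\t".join(header)]
    for row in rows:
        cells = row.get("cells", {})
        flags = row.get("flags", "")
        fields = [row["id"], row.get("gene", "")]
        for rep in design.replicates:
            for t in design.time_points_h:
                h, l, r, c = cells.get((rep, t), (0, 0, None, 0))
                fields += [
                    str(h),
                    str(l),
                    "" if r is None else str(r),
                    str(c),
                ]
        fields += [
            "+" if "C" in flags else "",
            "+" if "R" in flags else "",
            "+" if "S" in flags else "",
        ]
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260903)
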
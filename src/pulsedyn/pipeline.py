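"""Stage orchestration: run analysis stages in dependency order with a manifest.

Every stage writes one or more TSV artifacts into the output directory plus
a small JSON provenance sidecar (config hash, package version, seed). A
stage whose upstream artifact is neither produced in the current run nor
already on disk raises :class:`DependencyError` naming the missing file.
Outputs are a pure function of (input files, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .absolute_quant import compute_ibaq_heavy, digest_proteome, ibaq_to_frame
from .config import PipelineConfig
from .enrichment_stats import enrichment_to_frame, fisher_overrepresentation, read_gmt
from .errors import ConfigError, DependencyError
from .profile_clustering import build_profile_matrix, cluster_profiles
from .quant_io import (
    apply_quality_filters,
    read_fasta,
    read_protein_groups,
    records_to_frame,
    write_table,
)
from .replicate_union import (
    assign_time_bins,
    merge_replicates,
    merged_from_frame,
    merged_to_frame,
    rank_within_bins,
)
from .turnover_kinetics import (
    fit_merged_courses,
    fits_to_frame,
    profiles_from_records,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("filter", "merge", "bin", "turnover", "cluster", "enrich", "ibaq")

STAGE_DEPS = {
    "filter": (),
    "merge": ("filtered.tsv",),
    "bin": ("merged.tsv",),
    "turnover": ("merged.tsv",),
    "cluster": ("filtered.tsv",),
    "enrich": ("clusters.tsv",),
    "ibaq": ("filtered.tsv",),
}


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class PipelineRun:
    """One pipeline execution over a fixed config."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out_dir = Path(config.out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.design = config.design()
        self.hash = config_hash(config)
        self.artifacts: dict[str, Path] = {}
        self.timings: dict[str, float] = {}

    # -- artifact plumbing -------------------------------------------------

    def _emit(self, name: str, frame: pd.DataFrame, stage: str) -> None:
        path = self.out_dir / name
        write_table(frame, path)
        sidecar = {
            "stage": stage,
            "config_hash": self.hash,
            "seed": self.config.seed,
            "pulsedyn_version": __version__,
            "rows": int(len(frame)),
        }
        (self.out_dir / f"{name}.prov.json").write_text(
            json.dumps(sidecar, indent=2) + "\n", encoding="utf-8"
        )
        self.artifacts[name] = path

    def _require(self, stage: str) -> None:
        for name in STAGE_DEPS[stage]:
            if name in self.artifacts:
                continue
            path = self.out_dir / name
            if path.exists():
                self.artifacts[name] = path
                continue
            raise DependencyError(
                f"stage '{stage}' requires missing upstream artifact: {path}"
            )

    def _load_filtered(self):
        return read_protein_groups(self.artifacts["filtered.tsv"], self.design)

    def _load_merged(self):
        df = pd.read_csv(self.artifacts["merged.tsv"], sep="\t")
        return merged_from_frame(df)

    # -- stages ------------------------------------------------------------

    def stage_filter(self) -> None:
        if self.config.input_table is None:
            raise ConfigError("config has no input_table; run 'simulate' or point to a table")
        records = read_protein_groups(self.config.input_table, self.design)
        n_in = len(records)
        records = apply_quality_filters(records, self.config.min_ratio_count)
        logger.info("filter: %d -> %d proteins", n_in, len(records))
        self._emit("filtered.tsv", records_to_frame(records, self.design), "filter")

    def stage_merge(self) -> None:
        self._require("merge")
        records = self._load_filtered()
        merged = merge_replicates(records)
        logger.info("merge: %d time courses", len(merged))
        self._emit("merged.tsv", merged_to_frame(merged), "merge")

    def stage_bin(self) -> None:
        self._require("bin")
        merged = self._load_merged()
        scheme = self.config.resolved_bin_scheme()
        binned = {
            course.protein_id: assign_time_bins(course, scheme, self.design)
            for course in merged
        }
        matrix = rank_within_bins(binned, scheme.labels)
        logger.info("bin: %d proteins x %d bins", len(binned), len(scheme.labels))
        self._emit("binned_ranks.tsv", matrix.to_frame(), "bin")

    def stage_turnover(self) -> None:
        self._require("turnover")
        merged = self._load_merged()
        fits = fit_merged_courses(
            merged, min_points=self.config.min_points, min_r2=self.config.min_r2
        )
        n_reliable = sum(f.reliable for f in fits)
        logger.info("turnover: %d fits, %d reliable", len(fits), n_reliable)
        self._emit("turnover.tsv", fits_to_frame(fits), "turnover")

    def stage_cluster(self) -> None:
        self._require("cluster")
        records = self._load_filtered()
        profiles = profiles_from_records(records)
        matrix = build_profile_matrix(profiles, self.design)
        result = cluster_profiles(
            matrix, n_clusters=self.config.k_clusters, span=self.config.span
        )
        logger.info(
            "cluster: %d complete profiles -> %d clusters",
            matrix.n_proteins, result.n_clusters,
        )
        assign = pd.DataFrame(
            sorted(result.assignment.items()), columns=["protein_id", "cluster"]
        )
        self._emit("clusters.tsv", assign, "cluster")
        curve_rows = [
            {"cluster": label, "time_h": t, "smoothed_mean": v}
            for label, (grid, smoothed) in sorted(result.curves.items())
            for t, v in zip(grid, smoothed)
        ]
        self._emit(
            "cluster_curves.tsv",
            pd.DataFrame(curve_rows, columns=["cluster", "time_h", "smoothed_mean"]),
            "cluster",
        )
        summary_rows = [
            {
                "cluster": label,
                "size": len(result.members(label)),
                "t50_h": None if math.isnan(result.t50_h[label]) else result.t50_h[label],
            }
            for label in sorted(result.t50_h)
        ]
        self._emit(
            "cluster_summary.tsv",
            pd.DataFrame(summary_rows, columns=["cluster", "size", "t50_h"]),
            "cluster",
        )

    def stage_enrich(self) -> None:
        self._require("enrich")
        assign = pd.read_csv(self.artifacts["clusters.tsv"], sep="\t")
        annotations = read_gmt(self.config.annotations)
        universe = assign["protein_id"].tolist()
        frames = []
        for label, group in assign.groupby("cluster"):
            results = fisher_overrepresentation(
                group["protein_id"].tolist(),
                universe,
                annotations,
                min_category_size=self.config.min_category_size,
            )
            frame = enrichment_to_frame(results)
            frame.insert(0, "cluster", label)
            frame["significant"] = frame["q_value"] <= self.config.fdr
            frames.append(frame)
        table = (
            pd.concat(frames, ignore_index=True)
            if frames
            else enrichment_to_frame([])
        )
        logger.info("enrich: %d tests", len(table))
        self._emit("enrichment.tsv", table, "enrich")

    def stage_ibaq(self) -> None:
        self._require("ibaq")
        records = self._load_filtered()
        sequences = read_fasta(self.config.fasta)
        digests = digest_proteome(
            sequences,
            max_missed=self.config.max_missed,
            min_len=self.config.min_pep_len,
            max_len=self.config.max_pep_len,
        )
        estimates, skipped = compute_ibaq_heavy(records, digests)
        logger.info("ibaq: %d estimates, %d proteins skipped", len(estimates), len(skipped))
        self._emit("ibaq.tsv", ibaq_to_frame(estimates), "ibaq")

    # -- driver ------------------------------------------------------------

    def run(self, stages) -> dict:
        unknown = [s for s in stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s): {', '.join(unknown)}")
        todo = [s for s in ALL_STAGES if s in set(stages)]
        for stage in todo:
            if stage == "enrich" and self.config.annotations is None:
                if set(stages) != {stage}:
                    logger.warning("no annotations configured; skipping enrich stage")
                    continue
                raise ConfigError("enrich stage requires an annotations file")
            if stage == "ibaq" and self.config.fasta is None:
                if set(stages) != {stage}:
                    logger.warning("no FASTA configured; skipping ibaq stage")
                    continue
                raise ConfigError("ibaq stage requires a FASTA file")
            t0 = time.perf_counter()
            getattr(self, f"stage_{stage}")()
            self.timings[stage] = time.perf_counter() - t0
            logger.info("stage %s done in %.2f s", stage, self.timings[stage])
        return self.write_manifest()

    def write_manifest(self) -> dict:
        manifest = {
            "config_hash": self.hash,
            "seed": self.config.seed,
            "pulsedyn_version": __version__,
            "artifacts": sorted(self.artifacts),
            "timings_s": {k: round(v, 3) for k, v in self.timings.items()},
        }
        (self.out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
        )
        return manifest


def run_pipeline(config: PipelineConfig, stages=ALL_STAGES) -> dict:
    """Run the requested *stages* in dependency order; returns the manifest."""
    return PipelineRun(config).run(stages)
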
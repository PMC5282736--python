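"""End-to-end disparity analysis from a single configuration.

Stages run in a fixed order — load/simulate, outlier filter, pairwise
dissimilarity, PCoA with Broken-Stick axis retention, jackknife +
permutation disparity, KDE hypervolumes (overlap, centroids, inclusion
tests), neighbour joining and k-means assessment — and their outputs are
collected into a results bundle plus, optionally, a directory of CSV /
Newick / JSON files. A single run seed fans out deterministically to
per-stage child seeds, so each stochastic stage can be rerun in isolation
and a rerun with the same configuration reproduces the bundle exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .clustering import KMeansAssessment, NeighborJoining, deduplicate
from .disparity import DisparityResampler, DisparityResult, _coords_and_labels
from .dissimilarity import CategoricalDissimilarity, DissimilarityMatrix
from .hypervolume import (
    KDEHypervolume,
    centroid_distances,
    group_centroids,
    min_group_size,
    overlap_table,
)
from .io import read_groups, read_matrix
from .matrix import CharacterMatrix, TaxonGrouping, filter_outliers
from .ordination import PCoA, Ordination
from .synthetic import SyntheticSpec, generate_matrix, lobopodian_preset

__all__ = ["PipelineConfig", "PipelineResult", "StageError", "run"]

_PRESETS = ("lobopodian", "study-shape")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one pipeline run (all defaults recorded)."""

    matrix_path: str | None = None
    groups_path: str | None = None
    groups_of_interest: tuple[str, ...] = ()
    preset: str | None = None
    synthetic_spec: SyntheticSpec | None = None
    dissimilarity_method: str = "mord"
    polymorphism_rule: str = "min"
    outlier_threshold: float = 0.75
    pcoa_correction: str = "none"
    n_axes: int | None = None  # None: Broken-Stick retained axes
    disparity_metric: str = "sum_of_ranges"
    n_iterations: int = 5000
    subsample_size: int | None = None
    hv_samples: int = 20000
    hv_quantile: float = 0.05
    hv_bandwidth: Any = "silverman"
    dedup_tolerance: float = 0.0
    kmeans_range: tuple[int, int] = (2, 6)
    seed: int = 0
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic_spec is not None:
            d["synthetic_spec"] = dataclasses.asdict(self.synthetic_spec)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if isinstance(data.get("synthetic_spec"), dict):
            data["synthetic_spec"] = SyntheticSpec(**data["synthetic_spec"])
        for key in ("groups_of_interest", "kmeans_range"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PipelineResult:
    """Results bundle of one pipeline run."""

    config: PipelineConfig
    matrix: CharacterMatrix
    grouping: TaxonGrouping
    removed_taxa: list
    dissimilarity: DissimilarityMatrix
    ordination: Ordination
    n_axes_used: int
    disparity: DisparityResult
    hypervolumes: dict[str, KDEHypervolume]
    skipped_groups: list[str]
    overlaps: pd.DataFrame
    centroids: pd.DataFrame
    centroid_distances: pd.DataFrame
    inclusion: pd.DataFrame
    newick: str
    merged_taxa: dict[str, list[str]]
    kmeans: KMeansAssessment
    manifest: dict = field(default_factory=dict)


def run(config: PipelineConfig) -> PipelineResult:
    """Execute every stage of the analysis under ``config``."""
    log: list[str] = []
    seeds = _stage_seeds(config.seed)

    matrix, grouping = _stage("load", log, _load, config, seeds["synthetic"])

    def _filter():
        filtered, removed = filter_outliers(matrix, config.outlier_threshold)
        kept_grouping = grouping.restrict_to(filtered.taxon_labels)
        return filtered, kept_grouping, removed

    matrix, grouping, removed = _stage("filter_outliers", log, _filter)
    grouping.validate_against(matrix)

    dis = _stage(
        "dissimilarity",
        log,
        lambda: CategoricalDissimilarity(
            config.dissimilarity_method, config.polymorphism_rule
        ).fit_transform(matrix),
    )

    def _ordinate():
        dis.require_complete()
        return PCoA(correction=config.pcoa_correction).fit(dis).ordination_

    ordination = _stage("pcoa", log, _ordinate)
    n_axes = config.n_axes or ordination.n_retained
    n_axes = min(n_axes, ordination.n_axes)
    log.append(f"pcoa: retained {ordination.n_retained} axes, using {n_axes}")

    def _disparity():
        X, y = _coords_and_labels(ordination, grouping, n_axes)
        est = DisparityResampler(
            config.disparity_metric,
            config.n_iterations,
            config.subsample_size,
            seeds["disparity"],
        ).fit(X, y)
        return est.result_

    disparity = _stage("disparity", log, _disparity)

    def _hypervolumes():
        coords = ordination.retained_coordinates(n_axes)
        taxa = list(ordination.taxon_labels)
        models, skipped = {}, []
        hv_rng = np.random.default_rng(seeds["hypervolume"])
        for g in grouping.groups_of_interest:
            idx = [taxa.index(t) for t in grouping.members(g)]
            if len(idx) < min_group_size(n_axes):
                skipped.append(g)
                continue
            models[g] = KDEHypervolume(
                bandwidth=config.hv_bandwidth,
                threshold_quantile=config.hv_quantile,
                n_samples=config.hv_samples,
                random_state=int(hv_rng.integers(2**31)),
            ).fit(coords[idx])
        return models, skipped

    models, skipped = _stage("hypervolume", log, _hypervolumes)
    if skipped:
        log.append(f"hypervolume: skipped too-small groups {skipped}")

    overlaps = _stage(
        "overlap",
        log,
        lambda: overlap_table(models) if len(models) >= 2 else pd.DataFrame(),
    )
    centroids = _stage(
        "centroids", log, lambda: group_centroids(ordination, grouping, n_axes)
    )
    cdist = _stage("centroid_distances", log, lambda: centroid_distances(centroids))

    def _inclusion():
        coords = ordination.retained_coordinates(n_axes)
        taxa = list(ordination.taxon_labels)
        grouped = {t for g in grouping.groups_of_interest
                   for t in grouping.members(g)}
        queries = [t for t in taxa if t not in grouped]
        rows = {}
        for t in queries:
            x = coords[taxa.index(t)][None, :]
            rows[t] = {g: bool(m.predict(x)[0]) for g, m in models.items()}
        return pd.DataFrame.from_dict(rows, orient="index").astype(bool) \
            if rows else pd.DataFrame(columns=list(models))

    inclusion = _stage("inclusion", log, _inclusion)

    def _nj():
        reduced, merges = deduplicate(dis, config.dedup_tolerance)
        nj = NeighborJoining().fit(reduced)
        if nj.negative_branch_events_:
            log.append(
                f"neighbour_joining: clamped {nj.negative_branch_events_} "
                "negative branch length(s)"
            )
        return nj.newick_, merges

    newick, merges = _stage("neighbour_joining", log, _nj)

    def _kmeans():
        coords = ordination.retained_coordinates(n_axes)
        hi = min(config.kmeans_range[1], coords.shape[0] - 1)
        return KMeansAssessment(
            k_range=(config.kmeans_range[0], hi),
            random_state=seeds["kmeans"],
        ).fit(coords)

    kmeans = _stage("kmeans", log, _kmeans)

    manifest = {
        "package": "morphospace",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_taxa": matrix.n_taxa,
        "n_characters": matrix.n_characters,
        "removed_taxa": removed,
        "n_retained_axes": ordination.n_retained,
        "n_axes_used": n_axes,
        "kmeans_best_k": int(kmeans.best_k_),
        "log": log,
    }

    result = PipelineResult(
        config=config,
        matrix=matrix,
        grouping=grouping,
        removed_taxa=removed,
        dissimilarity=dis,
        ordination=ordination,
        n_axes_used=n_axes,
        disparity=disparity,
        hypervolumes=models,
        skipped_groups=skipped,
        overlaps=overlaps,
        centroids=centroids,
        centroid_distances=cdist,
        inclusion=inclusion,
        newick=newick,
        merged_taxa=merges,
        kmeans=kmeans,
        manifest=manifest,
    )
    if config.output_dir:
        _write_bundle(result, Path(config.output_dir))
    return result


# ----------------------------------------------------------------------
def _stage(name: str, log: list[str], fn, *args):
    try:
        out = fn(*args) if args else fn()
    except Exception as exc:
        log.append(f"{name}: FAILED ({exc})")
        raise StageError(name, exc) from exc
    log.append(f"{name}: ok")
    return out


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("synthetic", "disparity", "hypervolume", "kmeans")
    children = ss.spawn(len(names))
    return {
        n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)
    }


def _load(config: PipelineConfig, synth_seed: int):
    if config.matrix_path:
        matrix = read_matrix(config.matrix_path)
        if not config.groups_path:
            raise ValueError("matrix_path requires groups_path")
        grouping = read_groups(config.groups_path, config.groups_of_interest)
        grouping.validate_against(matrix)
        return matrix, grouping
    if config.synthetic_spec is not None:
        spec = config.synthetic_spec
        if spec.seed is None:
            spec = dataclasses.replace(spec, seed=synth_seed)
        matrix, grouping, _ = generate_matrix(spec)
        return matrix, grouping
    if config.preset in _PRESETS:
        matrix, grouping, _ = lobopodian_preset(seed=synth_seed)
        return matrix, grouping
    raise ValueError(
        "config needs matrix_path+groups_path, a synthetic_spec, or a "
        f"preset from {_PRESETS}"
    )


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    result.dissimilarity.to_csv(outdir / "dissimilarity.csv")
    result.ordination.to_dataframe().to_csv(
        outdir / "coordinates.csv", float_format=fmt, index_label="taxon"
    )
    result.ordination.eigenvalue_table().to_csv(
        outdir / "eigenvalues.csv", float_format=fmt, index_label="axis"
    )
    result.disparity.summary.to_csv(
        outdir / "disparity_summary.csv", float_format=fmt, index_label="group"
    )
    result.disparity.replicate_table().to_csv(
        outdir / "disparity_replicates.csv", float_format=fmt, index=False
    )
    result.disparity.pairwise_p.to_csv(
        outdir / "permutation_p.csv", float_format=fmt, index_label="group"
    )
    hv = pd.DataFrame(
        {
            g: {
                "volume": m.volume_,
                "threshold": m.threshold_,
                "n_random_points": len(m.random_points_),
                "point_density": m.point_density_,
            }
            for g, m in result.hypervolumes.items()
        }
    ).T
    hv.to_csv(outdir / "hypervolumes.csv", float_format=fmt, index_label="group")
    result.overlaps.to_csv(outdir / "overlap.csv", float_format=fmt, index=False)
    result.centroids.to_csv(
        outdir / "centroids.csv", float_format=fmt, index_label="group"
    )
    result.centroid_distances.to_csv(
        outdir / "centroid_distances.csv", float_format=fmt, index_label="group"
    )
    result.inclusion.to_csv(outdir / "inclusion.csv", index_label="taxon")
    (outdir / "tree.nwk").write_text(result.newick + "\n")
    result.kmeans.scores_.to_csv(
        outdir / "kmeans.csv", float_format=fmt, index_label="k"
    )
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
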
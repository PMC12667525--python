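"""End-to-end orchestration: simulate -> quantify -> matrix -> profile -> report.

A run is configured by a single JSON-serializable :class:`RunConfig`; every
run writes its resolved configuration and a manifest next to its outputs,
and identical (config, seed) reproduce all numeric outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .efficacy import compare_treatments, normalize_to_control, toxicity_flag
from .features import FeatureMatrix, build_matrix, extract_features, select_features, zscore
from .imaging import SegmentationParams, count_nuclei, max_intensity_projection, segment_stack
from .io import list_stacks, read_stack, write_stack
from .profiling import (
    cluster_composition,
    composition_similarity,
    fit_kmeans,
    pearson_similarity,
    treatment_profiles,
)
from .synthetic import OrganoidSpec, ScreenDesign, Treatment, iter_screen

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "design_from_dict", "quantify_stack"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (one JSON document)."""

    out_dir: str = "run"
    seed: int = 0
    control_label: str = "NC"
    # stage toggles / inputs
    design: dict | None = None      # simulate from this screen design...
    images_dir: str | None = None   # ...or quantify stacks from here...
    features_tsv: str | None = None  # ...or start from a feature table
    write_images: bool = False
    # segmentation
    smooth_sigma: float = 1.0
    opening_radius: int = 1
    min_object_px: int = 30
    min_sep_px: int = 3
    # matrix / profiling
    variance_quantile: float = 0.25
    k: int | str = "auto"
    # statistics
    batch_level_stats: bool = False
    per_batch_scaling: bool = False
    toxicity_threshold: float = 0.7

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(
            smooth_sigma=self.smooth_sigma,
            opening_radius=self.opening_radius,
            min_object_px=self.min_object_px,
            min_sep_px=self.min_sep_px,
        )

    def to_json(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        sources = [self.design, self.images_dir, self.features_tsv]
        if sum(s is not None for s in sources) != 1:
            raise ValueError(
                "exactly one of design / images_dir / features_tsv must be set"
            )
        if not self.control_label:
            raise ValueError("control_label must be set")
        if self.design is not None:
            design_from_dict(self.design, seed=self.seed).validate()


def design_from_dict(d: dict, seed: int | None = None) -> ScreenDesign:
    """Build a ScreenDesign from its JSON form."""
    spec = OrganoidSpec(**{
        **d.get("base_spec", {}),
        **({"image_shape": tuple(d["base_spec"]["image_shape"])}
           if "image_shape" in d.get("base_spec", {}) else {}),
    })
    return ScreenDesign(
        treatments=[Treatment(**t) for t in d["treatments"]],
        days=list(d["days"]),
        n_batches=int(d["n_batches"]),
        organoids_per_batch_per_treatment=int(d["organoids_per_batch_per_treatment"]),
        base_spec=spec,
        seed=int(d.get("seed", seed if seed is not None else 0)),
        batch_gain_log_sd=float(d.get("batch_gain_log_sd", 0.1)),
        control_label=d.get("control_label", "NC"),
    )


def quantify_stack(stack, params: SegmentationParams):
    """Projection -> segmentation -> counting -> features for one stack."""
    projection = max_intensity_projection(stack)
    masks = segment_stack(projection, params)
    n = count_nuclei(projection.nuclei, params, mask=masks.nuclei.mask)
    return extract_features(projection, masks, n)


def _stage(name: str, organoid_id: str | None = None):
    where = f" (organoid {organoid_id})" if organoid_id else ""
    return f"pipeline stage {name!r}{where}"


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Any stage failure is re-raised annotated with the stage name (and
    offending organoid id where applicable).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    params = config.segmentation_params()
    manifest: dict = {"fibroscreen_version": __version__, "stages": []}

    # --- acquire features -------------------------------------------------
    if config.features_tsv is not None:
        matrix = FeatureMatrix.from_tsv(config.features_tsv)
        manifest["stages"].append("load_features")
    else:
        if config.design is not None:
            design = design_from_dict(config.design, seed=config.seed)
            manifest["stages"].append("simulate")
            truths: list[dict] = []

            def _simulated():
                img_dir = out / "images"
                for stack, truth in iter_screen(design):
                    truths.append(truth.__dict__)
                    if config.write_images:
                        write_stack(stack, img_dir)
                    yield stack

            stack_iter = _simulated()
        else:
            truths = []
            paths = list_stacks(config.images_dir)
            if not paths:
                raise ValueError(f"no stacks found under {config.images_dir}")
            stack_iter = (read_stack(p) for p in paths)
            manifest["stages"].append("load_images")

        feats = []
        current_id = None
        try:
            for stack in stack_iter:
                current_id = stack.metadata.organoid_id
                feats.append(quantify_stack(stack, params))
        except Exception as exc:
            raise RuntimeError(f"{_stage('quantify', current_id)} failed") from exc
        matrix = build_matrix(feats)
        manifest["stages"].append("quantify")
        if truths:
            pd.DataFrame(truths).to_csv(
                out / "ground_truth.tsv", sep="\t", index=False, float_format="%.10g"
            )

    matrix.to_tsv(out / "features.tsv")

    # --- matrix -----------------------------------------------------------
    try:
        scaled = zscore(matrix, per_batch=config.per_batch_scaling)
        scaled = select_features(scaled, config.variance_quantile)
    except Exception as exc:
        raise RuntimeError(f"{_stage('matrix')} failed") from exc
    scaled.to_tsv(out / "features_scaled.tsv")
    manifest["stages"].append("matrix")
    manifest["selected_features"] = scaled.selected_features
    manifest["n_organoids"] = scaled.n_organoids

    # --- profiling --------------------------------------------------------
    try:
        profiles = treatment_profiles(scaled)
        sim_mean = pearson_similarity(profiles)
        model = fit_kmeans(scaled, k=config.k, seed=config.seed)
        composition = cluster_composition(model, scaled.labels)
        sim_comp = composition_similarity(composition)
    except Exception as exc:
        raise RuntimeError(f"{_stage('profile')} failed") from exc
    sim_mean.r.to_csv(out / "similarity_mean_features.tsv", sep="\t", float_format="%.10g")
    sim_comp.r.to_csv(out / "similarity_composition.tsv", sep="\t", float_format="%.10g")
    composition.to_csv(out / "cluster_composition.tsv", sep="\t", float_format="%.10g")
    model.k_diagnostics.to_csv(out / "k_diagnostics.tsv", sep="\t", index=False,
                               float_format="%.10g")
    model.assignment.to_csv(out / "cluster_assignment.tsv", sep="\t")
    manifest["stages"].append("profile")
    manifest["k"] = model.k
    manifest["heatmap_ordering"] = {
        "mean_features": sim_mean.ordering,
        "composition": sim_comp.ordering,
        "linkage": "average on 1 - r",
    }

    # --- report -----------------------------------------------------------
    try:
        points = normalize_to_control(
            matrix, config.control_label, batch_means=config.batch_level_stats
        )
        comparisons = compare_treatments(points, config.control_label)
        toxicity = toxicity_flag(
            points, config.control_label, threshold=config.toxicity_threshold
        )
    except Exception as exc:
        raise RuntimeError(f"{_stage('report')} failed") from exc
    points.to_csv(out / "timecourse.tsv", sep="\t", index=False, float_format="%.10g")
    comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False, float_format="%.10g")
    toxicity.to_csv(out / "toxicity.tsv", sep="\t", index=False, float_format="%.10g")
    manifest["stages"].append("report")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
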
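"""Per-organoid feature extraction and the feature x organoid matrix.

Eighteen features summarise each organoid's two-channel projection: nine
from the fibrosis channel (total and distributional intensity, area, shape
of the fibrotic components), five from the nuclei channel (count, area,
intensity, density), three describing organoid geometry, and one
cross-channel ratio. The matrix over a screen is z-scored per feature, and
features are kept when their variation *between treatments* (variance of
per-treatment mean z-scores) exceeds a quantile threshold — features that
do not respond to treatment carry no profiling signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops

from .imaging import ChannelMask, ProjectedImage, StackMetadata

logger = logging.getLogger(__name__)

FEATURE_NAMES: tuple[str, ...] = (
    "fibrosis_intden",
    "fibrosis_mean_intensity",
    "fibrosis_intensity_sd",
    "fibrosis_intensity_p95",
    "fibrosis_area_px",
    "fibrosis_area_fraction",
    "fibrosis_n_components",
    "fibrosis_largest_component_px",
    "fibrosis_mean_eccentricity",
    "nuclei_count",
    "nuclei_area_px",
    "nuclei_mean_area_px",
    "nuclei_mean_intensity",
    "nuclei_density",
    "organoid_area_px",
    "organoid_equiv_diameter_px",
    "organoid_solidity",
    "fibrosis_intden_per_nucleus",
)

LABEL_COLUMNS = ("treatment", "day", "batch")

__all__ = [
    "FEATURE_NAMES",
    "OrganoidFeatures",
    "FeatureMatrix",
    "extract_features",
    "build_matrix",
    "zscore",
    "select_features",
]


@dataclass(frozen=True)
class OrganoidFeatures:
    """The named 18-feature vector of one organoid, plus its labels."""

    metadata: StackMetadata
    values: dict[str, float]
    empty_roi: bool = False  # nothing segmented in either channel

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(FEATURE_NAMES)
            raise ValueError(
                f"feature names mismatch (missing={sorted(missing)}, "
                f"extra={sorted(extra)})"
            )
        bad = {k: v for k, v in self.values.items() if not np.isfinite(v)}
        if bad:
            raise ValueError(f"non-finite features: {bad}")


@dataclass
class FeatureMatrix:
    """Organoids x features table with labels and scaling state.

    ``values`` is indexed by organoid_id; ``labels`` carries (treatment,
    day, batch) per organoid. ``selected_features`` is the currently active
    feature subset (all features until selection is applied).
    """

    values: pd.DataFrame
    labels: pd.DataFrame
    scaled: bool = False
    selected_features: list[str] = field(default_factory=list)
    constant_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.selected_features:
            self.selected_features = list(self.values.columns)
        if not self.values.index.equals(self.labels.index):
            raise ValueError("values and labels must share the organoid index")
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_organoids(self) -> int:
        return len(self.values)

    def selected(self) -> pd.DataFrame:
        return self.values[self.selected_features]

    def to_tsv(self, path) -> None:
        out = pd.concat([self.labels, self.values], axis=1)
        out.index.name = "organoid_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, scaled: bool = False) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="organoid_id")
        labels = df[list(LABEL_COLUMNS)]
        values = df.drop(columns=list(LABEL_COLUMNS))
        return cls(values=values, labels=labels, scaled=scaled)


def _mask_stats(image: np.ndarray, mask: np.ndarray) -> tuple[float, float, float, float]:
    """(sum, mean, sd, p95) of intensities inside a mask; zeros when empty."""
    vals = np.asarray(image, dtype=np.float64)[mask]
    if vals.size == 0:
        return 0.0, 0.0, 0.0, 0.0
    return (
        float(vals.sum()),
        float(vals.mean()),
        float(vals.std()),
        float(np.percentile(vals, 95)),
    )


def extract_features(
    projection: ProjectedImage,
    masks: ChannelMask,
    nuclei_count: int,
    intden_dilation_px: int = 1,
) -> OrganoidFeatures:
    """Compute the 18-feature vector for one organoid.

    The integrated fibrosis intensity (IntDen) is summed over the fibrosis
    mask dilated by ``intden_dilation_px`` so that signal the PSF spreads
    just beyond the half-max boundary is still counted; all other mask
    statistics use the mask itself. Features over empty masks take defined
    degenerate values (0 for sums, areas, counts and for means over empty
    sets); an organoid with an empty footprint is flagged via ``empty_roi``
    so matrix assembly can drop it.
    """
    fib_img, nuc_img = projection.fibrosis, projection.nuclei
    if masks.fibrosis.mask.shape != fib_img.shape:
        raise ValueError("mask shape does not match projection shape")

    fib = masks.fibrosis
    nuc = masks.nuclei
    roi = masks.organoid_roi
    roi_area = float(np.count_nonzero(roi))

    _, fib_mean, fib_sd, fib_p95 = _mask_stats(fib_img, fib.mask)
    if intden_dilation_px > 0 and fib.mask.any():
        support = ndimage.binary_dilation(fib.mask, iterations=intden_dilation_px)
    else:
        support = fib.mask
    fib_sum = float(np.asarray(fib_img, dtype=np.float64)[support].sum())
    fib_area = float(fib.area_px)

    fib_props = regionprops(fib.labels)
    largest = max((p.area for p in fib_props), default=0.0)
    mean_ecc = (
        float(np.mean([p.eccentricity for p in fib_props])) if fib_props else 0.0
    )

    _, nuc_mean, _, _ = _mask_stats(nuc_img, nuc.mask)
    nuc_area = float(nuc.area_px)

    if roi_area > 0:
        roi_props = regionprops(roi.astype(np.uint8))[0]
        equiv_diam = float(roi_props.equivalent_diameter_area)
        solidity = float(roi_props.solidity)
    else:
        equiv_diam, solidity = 0.0, 0.0

    values = {
        "fibrosis_intden": fib_sum,
        "fibrosis_mean_intensity": fib_mean,
        "fibrosis_intensity_sd": fib_sd,
        "fibrosis_intensity_p95": fib_p95,
        "fibrosis_area_px": fib_area,
        "fibrosis_area_fraction": fib_area / roi_area if roi_area > 0 else 0.0,
        "fibrosis_n_components": float(fib.n_components),
        "fibrosis_largest_component_px": float(largest),
        "fibrosis_mean_eccentricity": mean_ecc,
        "nuclei_count": float(nuclei_count),
        "nuclei_area_px": nuc_area,
        "nuclei_mean_area_px": nuc_area / nuclei_count if nuclei_count > 0 else 0.0,
        "nuclei_mean_intensity": nuc_mean,
        "nuclei_density": nuclei_count / roi_area if roi_area > 0 else 0.0,
        "organoid_area_px": roi_area,
        "organoid_equiv_diameter_px": equiv_diam,
        "organoid_solidity": solidity,
        "fibrosis_intden_per_nucleus": fib_sum / nuclei_count if nuclei_count > 0 else 0.0,
    }
    return OrganoidFeatures(
        metadata=projection.metadata, values=values, empty_roi=roi_area == 0
    )


def build_matrix(features: Iterable[OrganoidFeatures]) -> FeatureMatrix:
    """Assemble per-organoid feature vectors into a FeatureMatrix.

    Rows are organoids, columns the 18 features. Organoids with an empty
    footprint are dropped (and logged); duplicate organoid ids are an error.
    """
    rows, labels, ids = [], [], []
    n_dropped = 0
    for f in features:
        if f.empty_roi:
            logger.warning(
                "dropping organoid %s: empty organoid ROI", f.metadata.organoid_id
            )
            n_dropped += 1
            continue
        ids.append(f.metadata.organoid_id)
        rows.append(f.values)
        labels.append(
            {
                "treatment": f.metadata.treatment,
                "day": f.metadata.day,
                "batch": f.metadata.batch,
            }
        )
    if not rows:
        raise ValueError("no organoids with a non-empty ROI")
    index = pd.Index(ids, name="organoid_id")
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate organoid_id: {dupes}")
    if n_dropped:
        logger.info("build_matrix dropped %d organoids with empty ROI", n_dropped)
    values = pd.DataFrame(rows, index=index, columns=list(FEATURE_NAMES), dtype=float)
    return FeatureMatrix(values=values, labels=pd.DataFrame(labels, index=index))


def zscore(matrix: FeatureMatrix, per_batch: bool = False) -> FeatureMatrix:
    """Standardise each feature column to mean 0, sample SD 1.

    Constant columns become all-zero and are recorded in
    ``constant_features``. Scaling is global across the screen by default;
    ``per_batch=True`` standardises within each batch instead. Applying
    zscore to an already-scaled matrix is a no-op (idempotent).
    """
    if matrix.n_organoids < 2:
        raise ValueError("z-scoring needs at least 2 organoids")

    def _scale(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
        mean = df.mean(axis=0)
        sd = df.std(axis=0, ddof=1)
        # constant up to float accumulation error
        is_const = sd <= 1e-12 * (mean.abs() + 1.0)
        constant = sd[is_const].index.tolist()
        sd[is_const] = 1.0
        out = (df - mean) / sd
        out[constant] = 0.0
        return out, constant

    if per_batch:
        parts, constant = [], set()
        for _, idx in matrix.labels.groupby("batch").groups.items():
            scaled_part, const = _scale(matrix.values.loc[idx])
            parts.append(scaled_part)
            constant.update(const)
        values = pd.concat(parts).loc[matrix.values.index]
        constant_list = sorted(constant)
    else:
        values, constant_list = _scale(matrix.values)
    if constant_list:
        logger.warning("constant feature columns set to 0: %s", constant_list)
    return replace(
        matrix, values=values, scaled=True, constant_features=constant_list,
        selected_features=list(matrix.selected_features),
    )


def select_features(
    matrix: FeatureMatrix, variance_quantile: float = 0.25
) -> FeatureMatrix:
    """Keep features whose between-treatment variation clears a threshold.

    For each feature, the variance of per-treatment mean z-scores is
    computed; features above the ``variance_quantile`` quantile of these
    variances are retained (all non-constant features at quantile 0). At
    least two features are always kept. Selection is recorded in
    ``selected_features``; the stored values are untouched.
    """
    if not 0.0 <= variance_quantile < 1.0:
        raise ValueError("variance_quantile must be in [0, 1)")
    treatments = matrix.labels["treatment"]
    if treatments.nunique() < 2:
        raise ValueError("feature selection needs at least 2 treatments")

    z = matrix if matrix.scaled else zscore(matrix)
    between_var = (
        z.values.groupby(treatments).mean().var(axis=0, ddof=1)
    )
    nonconstant = [c for c in z.values.columns if c not in z.constant_features]
    var_nc = between_var[nonconstant]
    if variance_quantile == 0:
        keep = list(var_nc.index)
    else:
        thresh = float(np.quantile(var_nc.to_numpy(), variance_quantile))
        keep = [c for c in var_nc.index if var_nc[c] > thresh]
    if len(keep) < 2:
        keep = list(var_nc.sort_values(ascending=False).index[:2])
    logger.info(
        "selected %d/%d features at quantile %.2f", len(keep), z.values.shape[1],
        variance_quantile,
    )
    return replace(matrix, selected_features=[c for c in matrix.values.columns if c in keep])
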
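"""Synthetic two-channel organoid Z-stacks with known ground truth.

Real screens image one hepatic organoid per microwell in two fluorescence
channels: a collagen-I reporter ("fibrosis") and a DNA stain ("nuclei"),
as 20-40 plane Z-stacks per organoid per day. The raw imaging data of such
screens is rarely deposited, so this module renders organoid-like stacks
whose *statistical* structure matches what the downstream pipeline assumes:

* a roughly circular organoid footprint;
* a Poisson number of spheroidal nuclei, thinned by a per-treatment
  ``toxicity_effect``;
* a fibrosis channel built from random-walk filaments plus elliptical
  blobs; element count scales linearly with a per-treatment
  ``fibrosis_effect`` and elements composite additively, so the expected
  integrated intensity of the channel is proportional to the effect;
* physical image formation: per-plane Gaussian PSF blur, constant
  background, Poisson shot noise, Gaussian read noise, 16-bit clipping;
* a multiplicative per-batch gain applied to both channels.

Ground truth (nuclei count, fibrotic area, fibrotic integrated intensity)
is recorded from the pre-noise, pre-blur label/amplitude arrays, which
makes every stage of the analysis pipeline testable against construction.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_footprint

from .imaging import OrganoidStack, StackMetadata

U16_MAX = 65535

__all__ = [
    "OrganoidSpec",
    "Treatment",
    "ScreenDesign",
    "GroundTruth",
    "simulate_organoid",
    "simulate_screen",
    "child_seed",
]


@dataclass(frozen=True)
class OrganoidSpec:
    """Parameters of one simulated organoid acquisition.

    Intensity units are arbitrary detector counts in the unsigned 16-bit
    output range. Lateral distances are in pixels; ``z_step_px`` converts
    plane index differences into the same pixel units (plane spacing is an
    acquisition choice, not something the analysis can infer).
    """

    image_shape: tuple[int, int, int] = (20, 256, 256)  # (z, y, x)
    pixel_size_um: float = 1.0
    organoid_radius_px: float = 90.0
    n_nuclei_mean: float = 100.0
    nucleus_radius_px: float = 4.0
    fibrosis_effect: float = 1.0
    toxicity_effect: float = 0.0
    psf_sigma_px: float = 1.0
    background_level: float = 100.0
    gaussian_noise_sd: float = 25.0
    shot_noise: bool = True
    batch_gain: float = 1.0
    z_step_px: float = 2.0
    nucleus_amplitude: float = 3000.0
    fibrosis_amplitude: float = 3000.0
    filaments_per_effect: float = 12.0
    blobs_per_effect: float = 4.0
    filament_width_px: int = 5
    # minimum 3D center spacing between nuclei, in units of nucleus radii;
    # 1.0 lets nuclei overlap in projection (counting stays nontrivial),
    # larger values construct well-separated fixtures
    min_center_dist_factor: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        z, h, w = self.image_shape
        if z < 1 or h < 1 or w < 1:
            raise ValueError(f"non-positive image dimensions {self.image_shape}")
        if z > 64:
            raise ValueError(f"z_planes must be in [1, 64], got {z}")
        if self.organoid_radius_px <= 0:
            raise ValueError("organoid_radius_px must be positive")
        if self.organoid_radius_px > min(h, w) / 2:
            raise ValueError(
                "organoid_radius_px exceeds half the smaller image dimension"
            )
        if not (0.0 <= self.toxicity_effect <= 1.0):
            raise ValueError("toxicity_effect must be in [0, 1]")
        if self.fibrosis_effect < 0:
            raise ValueError("fibrosis_effect must be nonnegative")
        for name in ("pixel_size_um", "n_nuclei_mean", "nucleus_radius_px",
                     "batch_gain", "z_step_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("psf_sigma_px", "background_level", "gaussian_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class Treatment:
    label: str
    fibrosis_effect: float
    toxicity_effect: float = 0.0


@dataclass(frozen=True)
class ScreenDesign:
    """Layout of a simulated screen: treatments x days x batches x replicates."""

    treatments: Sequence[Treatment]
    days: Sequence[int]
    n_batches: int
    organoids_per_batch_per_treatment: int
    base_spec: OrganoidSpec = field(default_factory=OrganoidSpec)
    seed: int = 0
    batch_gain_log_sd: float = 0.1
    control_label: str = "NC"

    def validate(self) -> None:
        if not any(t.label == self.control_label for t in self.treatments):
            raise ValueError(
                f"design must contain the control treatment {self.control_label!r}"
            )
        if len(self.days) == 0:
            raise ValueError("days must be nonempty")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.organoids_per_batch_per_treatment < 1:
            raise ValueError("organoids_per_batch_per_treatment must be >= 1")
        labels = [t.label for t in self.treatments]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate treatment labels")

    @property
    def batch_labels(self) -> list[str]:
        return [f"B{i + 1}" for i in range(self.n_batches)]


@dataclass(frozen=True)
class GroundTruth:
    """Pre-noise construction truth for one organoid (the acceptance oracle)."""

    organoid_id: str
    treatment: str
    day: int
    batch: str
    true_nuclei_count: int
    true_fibrotic_area_px: int
    true_fibrosis_integrated_intensity: float


def child_seed(master_seed: int, *key) -> int:
    """Derive a stable per-organoid seed from a master seed and a hashable key.

    Stable across processes and generation order: the key is hashed with
    SHA-256 into a spawn key for numpy's SeedSequence. Result is < 2**31.
    """
    digest = hashlib.sha256(repr(tuple(key)).encode("utf-8")).digest()
    spawn = int.from_bytes(digest[:8], "little")
    state = np.random.SeedSequence(entropy=master_seed, spawn_key=(spawn,))
    return int(state.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# rendering primitives


def _place_nuclei(
    rng: np.random.Generator, spec: OrganoidSpec, n: int
) -> np.ndarray:
    """Sample n nucleus centers (z_px, y, x) inside the organoid disk.

    Enforces a minimum 3D center distance of one nucleus radius (z measured
    in pixel units via z_step_px). After 1000 rejections a center is accepted
    anyway so the Poisson-thinned count is never silently reduced.
    """
    z_planes, h, w = spec.image_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r_max = max(spec.organoid_radius_px - spec.nucleus_radius_px, 1.0)
    z_extent = (z_planes - 1) * spec.z_step_px
    min_d2 = (spec.min_center_dist_factor * spec.nucleus_radius_px) ** 2
    centers = np.empty((n, 3))
    for i in range(n):
        for _ in range(1000):
            rho = r_max * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            y = cy + rho * math.sin(theta)
            x = cx + rho * math.cos(theta)
            z = rng.uniform(0.0, z_extent) if z_extent > 0 else 0.0
            if i == 0:
                break
            d2 = np.sum((centers[:i] - (z, y, x)) ** 2, axis=1)
            if np.all(d2 >= min_d2):
                break
        centers[i] = (z, y, x)
    return centers


def _render_nuclei(spec: OrganoidSpec, centers: np.ndarray) -> np.ndarray:
    """Ideal nuclei channel: center-peaked spheroids composited by max.

    Each nucleus has a parabolic radial intensity profile
    ``A * (1 - (d/r)^2)`` (d = 3D distance to the center, z in pixel units),
    brightest at its center, as DNA stains appear; the max compositing
    keeps a local intensity maximum at each nucleus center in the MIP,
    which is what makes counting after projection solvable.
    """
    z_planes, h, w = spec.image_shape
    ideal = np.zeros((z_planes, h, w), dtype=np.float64)
    r = spec.nucleus_radius_px
    pad = int(math.ceil(r))
    for z_px, yc, xc in centers:
        zc = z_px / spec.z_step_px
        z_lo = max(int(math.ceil(zc - r / spec.z_step_px)), 0)
        z_hi = min(int(math.floor(zc + r / spec.z_step_px)), z_planes - 1)
        y_lo, y_hi = max(int(yc) - pad, 0), min(int(yc) + pad + 1, h)
        x_lo, x_hi = max(int(xc) - pad, 0), min(int(xc) + pad + 1, w)
        yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        d2_xy = (yy - yc) ** 2 + (xx - xc) ** 2
        for zi in range(z_lo, z_hi + 1):
            dz = (zi - zc) * spec.z_step_px
            profile = spec.nucleus_amplitude * (1.0 - (d2_xy + dz**2) / r**2)
            np.maximum(
                ideal[zi, y_lo:y_hi, x_lo:x_hi],
                np.clip(profile, 0.0, None),
                out=ideal[zi, y_lo:y_hi, x_lo:x_hi],
            )
    return ideal


def _render_filament(
    rng: np.random.Generator, spec: OrganoidSpec, shape: tuple[int, int]
) -> np.ndarray:
    """One thick random-walk filament as a 2D binary mask."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r0 = 0.85 * spec.organoid_radius_px
    rho = r0 * math.sqrt(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * math.pi)
    y, x = cy + rho * math.sin(theta), cx + rho * math.cos(theta)
    heading = rng.uniform(0.0, 2.0 * math.pi)
    n_steps = rng.integers(6, 13)
    step = rng.uniform(5.0, 9.0)
    rows, cols = [], []
    for _ in range(int(n_steps)):
        heading += rng.normal(0.0, 0.5)
        y2 = y + step * math.sin(heading)
        x2 = x + step * math.cos(heading)
        # keep the walk inside the organoid footprint
        if (y2 - cy) ** 2 + (x2 - cx) ** 2 > r0**2:
            heading += math.pi
            y2 = y + step * math.sin(heading)
            x2 = x + step * math.cos(heading)
        rr, cc = draw_line(
            int(round(np.clip(y, 0, h - 1))), int(round(np.clip(x, 0, w - 1))),
            int(round(np.clip(y2, 0, h - 1))), int(round(np.clip(x2, 0, w - 1))),
        )
        rows.append(rr)
        cols.append(cc)
        y, x = y2, x2
    rr = np.concatenate(rows)
    cc = np.concatenate(cols)
    # dilate on a cropped canvas: filaments cover a small part of the frame
    pad = spec.filament_width_px // 2 + 1
    r0_, r1_ = max(rr.min() - pad, 0), min(rr.max() + pad + 1, h)
    c0_, c1_ = max(cc.min() - pad, 0), min(cc.max() + pad + 1, w)
    crop = np.zeros((r1_ - r0_, c1_ - c0_), dtype=bool)
    crop[rr - r0_, cc - c0_] = True
    crop = ndimage.binary_dilation(
        crop, structure=disk_footprint(spec.filament_width_px // 2)
    )
    canvas = np.zeros(shape, dtype=bool)
    canvas[r0_:r1_, c0_:c1_] = crop
    return canvas


def _render_blob(
    rng: np.random.Generator, spec: OrganoidSpec, shape: tuple[int, int]
) -> np.ndarray:
    """One elliptical fibrotic blob as a 2D binary mask."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r0 = 0.85 * spec.organoid_radius_px
    rho = r0 * math.sqrt(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * math.pi)
    y, x = cy + rho * math.sin(theta), cx + rho * math.cos(theta)
    a = rng.uniform(4.0, 10.0)
    b = rng.uniform(4.0, 10.0)
    rot = rng.uniform(0.0, math.pi)
    canvas = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(y, x, a, b, shape=shape, rotation=rot)
    canvas[rr, cc] = True
    return canvas


def _render_fibrosis(
    rng: np.random.Generator, spec: OrganoidSpec
) -> np.ndarray:
    """Ideal fibrosis channel as a 2D additive intensity image.

    Element count ~ Poisson(rate * fibrosis_effect); elements composite
    additively (collagen fluorophore density adds), so the expected
    integrated intensity is exactly linear in fibrosis_effect. The channel
    is rendered z-uniform (each element spans the full stack depth): the
    analysis consumes only the maximum-intensity projection, and a
    z-uniform signal is the structure for which projection loses nothing —
    axial realism of the collagen network is out of scope.
    """
    _, h, w = spec.image_shape
    ideal = np.zeros((h, w), dtype=np.float64)
    n_fil = rng.poisson(spec.filaments_per_effect * spec.fibrosis_effect)
    n_blob = rng.poisson(spec.blobs_per_effect * spec.fibrosis_effect)
    for kind in ["filament"] * int(n_fil) + ["blob"] * int(n_blob):
        if kind == "filament":
            mask2d = _render_filament(rng, spec, (h, w))
        else:
            mask2d = _render_blob(rng, spec, (h, w))
        ideal += spec.fibrosis_amplitude * mask2d
    return ideal


def _form_image(
    rng: np.random.Generator, spec: OrganoidSpec, ideal: np.ndarray
) -> np.ndarray:
    """Physical image formation: PSF blur -> background -> shot -> read noise."""
    img = ideal
    if spec.psf_sigma_px > 0:
        img = ndimage.gaussian_filter(
            img, sigma=(0.0, spec.psf_sigma_px, spec.psf_sigma_px)
        )
    img = img + spec.background_level * spec.batch_gain
    if spec.shot_noise:
        img = rng.poisson(np.clip(img, 0.0, None)).astype(np.float64)
    if spec.gaussian_noise_sd > 0:
        img = img + rng.normal(0.0, spec.gaussian_noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, U16_MAX).astype(np.uint16)


# ---------------------------------------------------------------------------
# public API


def simulate_organoid(
    spec: OrganoidSpec,
    metadata: StackMetadata | None = None,
    render: bool = True,
) -> tuple[OrganoidStack | None, GroundTruth]:
    """Simulate one organoid acquisition.

    Returns the rendered stack and its construction ground truth. With
    ``render=False`` the noisy stack is skipped (returns ``None`` in its
    place) but the ground truth is bit-identical to a rendered run with the
    same spec, because all truth-determining random draws happen before any
    noise is sampled.
    """
    spec.validate()
    # independent substreams so skipping a rendering step never changes the
    # draws of another (truth is identical with render on or off)
    ss_place, ss_fib, ss_noise = np.random.SeedSequence(spec.seed).spawn(3)
    rng_place = np.random.default_rng(ss_place)
    rng_fib = np.random.default_rng(ss_fib)
    rng_noise = np.random.default_rng(ss_noise)
    meta = metadata or StackMetadata("organoid", "NA", 0, "NA")

    n_nuclei = int(
        rng_place.poisson(spec.n_nuclei_mean * (1.0 - spec.toxicity_effect))
    )
    fib_mip = _render_fibrosis(rng_fib, spec) * spec.batch_gain

    truth = GroundTruth(
        organoid_id=meta.organoid_id,
        treatment=meta.treatment,
        day=meta.day,
        batch=meta.batch,
        true_nuclei_count=n_nuclei,
        true_fibrotic_area_px=int(np.count_nonzero(fib_mip)),
        true_fibrosis_integrated_intensity=float(fib_mip.sum()),
    )
    if not render:
        return None, truth

    centers = _place_nuclei(rng_place, spec, n_nuclei)
    nuc_ideal = _render_nuclei(spec, centers) * spec.batch_gain
    fib_ideal = np.broadcast_to(
        fib_mip, (spec.image_shape[0],) + fib_mip.shape
    ).copy()
    stack = OrganoidStack(
        fibrosis=_form_image(rng_noise, spec, fib_ideal),
        nuclei=_form_image(rng_noise, spec, nuc_ideal),
        pixel_size_um=spec.pixel_size_um,
        metadata=meta,
    )
    return stack, truth


def iter_screen(
    design: ScreenDesign, render: bool = True
) -> Iterator[tuple[OrganoidStack | None, GroundTruth]]:
    """Lazily simulate every organoid of a screen design.

    One stack per (treatment x day x batch x replicate). The batch gain is
    drawn once per batch from lognormal(0, batch_gain_log_sd) and applied to
    both channels; per-organoid seeds are derived by stable hashing so the
    result does not depend on generation order.
    """
    design.validate()
    gains = {
        b: float(
            np.random.default_rng(
                child_seed(design.seed, "batch_gain", b)
            ).lognormal(0.0, design.batch_gain_log_sd)
        )
        for b in design.batch_labels
    }
    for t in design.treatments:
        for day in design.days:
            for b in design.batch_labels:
                for rep in range(design.organoids_per_batch_per_treatment):
                    seed = child_seed(design.seed, b, t.label, day, rep)
                    spec = replace(
                        design.base_spec,
                        fibrosis_effect=t.fibrosis_effect,
                        toxicity_effect=t.toxicity_effect,
                        batch_gain=design.base_spec.batch_gain * gains[b],
                        seed=seed,
                    )
                    meta = StackMetadata(
                        organoid_id=f"{t.label}_d{day}_{b}_r{rep}",
                        treatment=t.label,
                        day=day,
                        batch=b,
                    )
                    yield simulate_organoid(spec, metadata=meta, render=render)


def simulate_screen(
    design: ScreenDesign, render: bool = True
) -> tuple[list[OrganoidStack], pd.DataFrame]:
    """Simulate a whole screen; returns stacks and the ground-truth table."""
    stacks: list[OrganoidStack] = []
    rows = []
    for stack, truth in iter_screen(design, render=render):
        if stack is not None:
            stacks.append(stack)
        rows.append(truth.__dict__)
    return stacks, pd.DataFrame(rows)


def truth_features(truth: pd.DataFrame) -> "FeatureMatrix":
    """Ground-truth readouts as a raw FeatureMatrix (oracle analysis path).

    Maps true fibrosis integrated intensity and true nuclei count onto the
    fibrosis/cell-number feature columns the downstream statistics consume.
    Useful for exercising normalization and group comparisons at exactly
    the simulator's construction values, without rendering or measuring
    pixels.
    """
    from .features import FeatureMatrix

    index = pd.Index(truth["organoid_id"], name="organoid_id")
    values = pd.DataFrame(
        {
            "fibrosis_intden": truth["true_fibrosis_integrated_intensity"].to_numpy(),
            "nuclei_count": truth["true_nuclei_count"].to_numpy(dtype=float),
        },
        index=index,
    )
    labels = truth[["treatment", "day", "batch"]].set_index(index)
    return FeatureMatrix(values=values, labels=labels)
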
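"""Reading and writing organoid stacks (TIFF + sidecar JSON) and tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .imaging import OrganoidStack, StackMetadata

SIDECAR_SUFFIX = ".json"

__all__ = ["write_stack", "read_stack", "list_stacks"]


def write_stack(stack: OrganoidStack, directory: Path | str) -> Path:
    """Write one organoid stack as a multi-page TIFF plus a sidecar JSON.

    Pages are interleaved channel-major: all fibrosis planes, then all
    nuclei planes; the sidecar records the layout, channel order, pixel
    size and organoid metadata so the file is self-describing.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{stack.metadata.organoid_id}.tiff"
    pages = np.concatenate([stack.fibrosis, stack.nuclei], axis=0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "layout": "channel_major_pages",
        "channels": ["fibrosis", "nuclei"],
        "z_planes": stack.z_planes,
        "pixel_size_um": stack.pixel_size_um,
        "organoid_id": stack.metadata.organoid_id,
        "treatment": stack.metadata.treatment,
        "day": stack.metadata.day,
        "batch": stack.metadata.batch,
    }
    with open(path.with_suffix(SIDECAR_SUFFIX), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return path


def read_stack(path: Path | str) -> OrganoidStack:
    """Read a stack written by :func:`write_stack` (TIFF + sidecar JSON)."""
    path = Path(path)
    with open(path.with_suffix(SIDECAR_SUFFIX)) as fh:
        sidecar = json.load(fh)
    pages = tifffile.imread(path)
    z = int(sidecar["z_planes"])
    if pages.shape[0] != 2 * z:
        raise ValueError(
            f"{path}: expected {2 * z} pages per sidecar, found {pages.shape[0]}"
        )
    by_channel = {
        name: pages[i * z : (i + 1) * z]
        for i, name in enumerate(sidecar["channels"])
    }
    return OrganoidStack(
        fibrosis=by_channel["fibrosis"],
        nuclei=by_channel["nuclei"],
        pixel_size_um=float(sidecar["pixel_size_um"]),
        metadata=StackMetadata(
            organoid_id=sidecar["organoid_id"],
            treatment=sidecar["treatment"],
            day=int(sidecar["day"]),
            batch=sidecar["batch"],
        ),
    )


def list_stacks(directory: Path | str) -> list[Path]:
    """All stack TIFFs (with sidecars) under a directory, sorted by name."""
    directory = Path(directory)
    return sorted(
        p for p in directory.glob("*.tiff")
        if p.with_suffix(SIDECAR_SUFFIX).exists()
    )
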
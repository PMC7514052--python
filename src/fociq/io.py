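"""On-disk formats: 16-bit single-channel TIFFs with a JSON sidecar,
ground truth and foci tables as CSV."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detect import FocusRecord
from .geometry import FieldGeometry
from .synthetic import SimulatedField

AU_PER_COUNT_DEFAULT = 0.01   # one uint16 count = 0.01 AU (range 0–655 AU)


def write_field(out_dir, field: SimulatedField,
                au_per_count: float = AU_PER_COUNT_DEFAULT) -> Path:
    """Write one channel per TIFF plus sidecar JSON and ground-truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for channel, img in field.images.items():
        counts = np.clip(np.round(img / au_per_count), 0, 65535).astype(np.uint16)
        tifffile.imwrite(out / f"{channel}.tif", counts)
    geom = dataclasses.asdict(field.config.geometry)
    sidecar = dict(channels=sorted(field.images), au_per_count=au_per_count,
                   geometry=geom, seed=field.config.seed)
    (out / "field.json").write_text(json.dumps(sidecar, indent=2))
    field.truth.to_csv(out / "truth.csv", index=False)
    return out


def read_field(in_dir) -> tuple[dict, FieldGeometry, pd.DataFrame | None]:
    """Inverse of :func:`write_field`; returns (images in AU, geometry, truth)."""
    src = Path(in_dir)
    sidecar = json.loads((src / "field.json").read_text())
    geom_kw = dict(sidecar["geometry"])
    geom_kw["rna_yield_ug_per_mg"] = tuple(geom_kw["rna_yield_ug_per_mg"])
    geometry = FieldGeometry(**geom_kw)
    au = sidecar["au_per_count"]
    images = {c: tifffile.imread(src / f"{c}.tif").astype(float) * au
              for c in sidecar["channels"]}
    truth_path = src / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return images, geometry, truth


def foci_to_frame(records: list[FocusRecord]) -> pd.DataFrame:
    rows = [dict(channel=r.channel, x_um=r.centroid_um[0],
                 y_um=r.centroid_um[1], area_um2=r.area_um2,
                 integrated_intensity_au=r.integrated_intensity_au,
                 size_class=r.size_class, compartment=r.compartment,
                 touches_border=r.touches_border, n_pixels=r.n_pixels)
            for r in records]
    columns = ["channel", "x_um", "y_um", "area_um2",
               "integrated_intensity_au", "size_class", "compartment",
               "touches_border", "n_pixels"]
    return pd.DataFrame(rows, columns=columns)


def write_foci(records: list[FocusRecord], path) -> None:
    foci_to_frame(records).to_csv(path, index=False)
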
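"""Readers and writers: images, masks, manifests, reports, checkpoints.

Masks live on disk as 0/255 grayscale PNG and in memory as strict {0,1}
arrays (binarized at 128 on load).  All writes go through a temp-then-rename
step so interrupted runs never leave truncated files behind.  Coordinates
are row-major with the origin at the top-left pixel centre.
"""

from __future__ import annotations

import io as _io
import json
import os
import tempfile
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .metrics import MetricReport
from .model import ModelConfig, SegmentationUNet, build_segmentation_network
from .preprocessing import NormalizationStats
from .synthetic import RenderedSample

__all__ = [
    "atomic_write_bytes",
    "load_sample",
    "write_sample",
    "read_manifest",
    "write_manifest",
    "write_report",
    "save_checkpoint",
    "load_checkpoint",
]


def atomic_write_bytes(path: str | os.PathLike, data: bytes) -> None:
    path = os.fspath(path)
    directory = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _encode_png(arr: np.ndarray) -> bytes:
    buf = _io.BytesIO()
    iio.imwrite(buf, arr, extension=".png")
    return buf.getvalue()


def write_sample(
    sample: RenderedSample, image_path: str, mask_path: str
) -> None:
    atomic_write_bytes(image_path, _encode_png(sample.image))
    atomic_write_bytes(mask_path, _encode_png((sample.mask * 255).astype(np.uint8)))


def load_sample(
    image_path: str, mask_path: str | None = None, sample_id: str = ""
) -> RenderedSample:
    """Load an image (+ optional mask): RGB promoted, mask binarized at 128."""
    image = iio.imread(image_path)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.shape[-1] == 4:  # drop alpha
        image = image[..., :3]
    image = image.astype(np.uint8)
    if mask_path is None:
        mask = np.zeros(image.shape[:2], dtype=np.uint8)
    else:
        raw = iio.imread(mask_path)
        if raw.ndim == 3:
            raw = raw[..., 0]
        if raw.shape != image.shape[:2]:
            raise ValueError(
                f"mask shape {raw.shape} does not match image {image.shape[:2]}"
            )
        mask = (raw >= 128).astype(np.uint8)
    if not sample_id:
        sample_id = os.path.splitext(os.path.basename(image_path))[0]
    return RenderedSample(image=image, mask=mask, sample_id=sample_id)


MANIFEST_COLUMNS = ["sample_id", "image_path", "mask_path", "seed"]


def write_manifest(rows: Sequence[dict], path: str) -> None:
    df = pd.DataFrame(rows)
    cols = [c for c in MANIFEST_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in MANIFEST_COLUMNS
    ]
    atomic_write_bytes(path, df[cols].to_csv(index=False).encode())


def read_manifest(path: str, check_files: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df["sample_id"].duplicated().any():
        raise ValueError("manifest sample_ids must be unique")
    if check_files:
        for col in ("image_path", "mask_path"):
            if col in df.columns:
                for p in df[col].dropna():
                    if not os.path.exists(p):
                        raise FileNotFoundError(f"manifest references missing {p}")
    return df


def load_manifest_samples(path: str) -> list[RenderedSample]:
    df = read_manifest(path)
    return [
        load_sample(r.image_path, r.mask_path, sample_id=r.sample_id)
        for r in df.itertuples()
    ]


def write_report(report: MetricReport, out_dir: str) -> dict[str, str]:
    """CSV of per-sample rows + JSON aggregates (percentages, 2 decimals)."""
    os.makedirs(out_dir, exist_ok=True)
    csv_path = os.path.join(out_dir, "per_sample_metrics.csv")
    json_path = os.path.join(out_dir, "aggregate_metrics.json")
    atomic_write_bytes(
        csv_path, report.per_sample.round(6).to_csv().encode()
    )
    payload = {
        "aggregates_percent": report.aggregates_percent(),
        "aggregates_unit_scale": {
            k: round(v, 6) for k, v in report.aggregates.items()
        },
        "n_samples": int(len(report.per_sample)),
    }
    atomic_write_bytes(json_path, json.dumps(payload, indent=2).encode())
    return {"csv": csv_path, "json": json_path}


def save_checkpoint(
    path: str,
    network: SegmentationUNet,
    stats: NormalizationStats,
    extra: dict | None = None,
) -> None:
    """Persist weights + ModelConfig + NormalizationStats in one .npz file."""
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(network.all_layers()):
        for name, arr in layer.state_arrays().items():
            arrays[f"layer{i:03d}/{name}"] = arr
    meta = {
        "model_config": network.config.to_dict(),
        "normalization_stats": stats.to_dict(),
        "extra": extra or {},
    }
    buf = _io.BytesIO()
    np.savez(buf, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    atomic_write_bytes(path, buf.getvalue())


def load_checkpoint(path: str) -> tuple[SegmentationUNet, NormalizationStats, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = ModelConfig.from_dict(meta["model_config"])
        if "normalization_stats" not in meta or meta["normalization_stats"] is None:
            raise ValueError("checkpoint is missing normalization stats")
        stats = NormalizationStats.from_dict(meta["normalization_stats"])
        network = build_segmentation_network(config)
        for i, layer in enumerate(network.all_layers()):
            store = layer.state_arrays()
            for name in store:
                store[name][...] = data[f"layer{i:03d}/{name}"]
    return network, stats, meta.get("extra", {})
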
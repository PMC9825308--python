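"""Reading and writing the Kaggle-style dataset layout.

A dataset directory holds one label CSV plus, per sample id, four 8-bit
grayscale PNG files named ``<id>_red.png``, ``<id>_green.png``,
``<id>_blue.png`` and ``<id>_yellow.png``.  The label CSV comes in two
dialects:

* ``kaggle`` — columns ``Id,Target`` where Target is a space-separated list
  of integer class ids;
* ``wide`` — a headered table of 0/1 label columns, optionally with an
  ``Id`` column first.

Channel order everywhere in this package is (red, green, blue, yellow).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .augmentation import CHANNELS, MultiChannelImage
from .imbalance_metrics import LabelMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetHandle",
    "read_labels",
    "write_labels",
    "read_image",
    "write_image",
    "write_manifests",
    "read_manifests",
    "write_json_report",
    "load_yaml_config",
]

LabelFormat = Literal["kaggle", "wide"]


def _parse_kaggle(df: pd.DataFrame, n_labels: int | None) -> LabelMatrix:
    if "Id" not in df.columns or "Target" not in df.columns:
        raise ValueError("kaggle-format CSV must have columns Id,Target")
    ids = df["Id"].astype(str).tolist()
    dupes = df["Id"][df["Id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate Id values: {dupes[:5]}")
    sets: list[list[int]] = []
    max_label = -1
    for row_no, target in enumerate(df["Target"]):
        tokens = str(target).split() if not pd.isna(target) else []
        labels: list[int] = []
        for tok in tokens:
            try:
                v = int(tok)
            except ValueError:
                raise ValueError(
                    f"row {row_no}: malformed Target token {tok!r}"
                ) from None
            if v < 0:
                raise ValueError(f"row {row_no}: negative label id {v}")
            labels.append(v)
        if not labels:
            logger.warning("row %d (%s): empty Target field", row_no, ids[row_no])
        max_label = max(max_label, *labels) if labels else max_label
        sets.append(labels)
    L = n_labels if n_labels is not None else max_label + 1
    if max_label >= L:
        raise ValueError(f"label id {max_label} out of range for {L} labels")
    entries = np.zeros((len(ids), L), dtype=np.int8)
    for i, labels in enumerate(sets):
        entries[i, labels] = 1
    return LabelMatrix(entries, tuple(str(j) for j in range(L)), tuple(ids))


def _parse_wide(df: pd.DataFrame) -> LabelMatrix:
    if "Id" in df.columns:
        ids = df["Id"].astype(str).tolist()
        df = df.drop(columns=["Id"])
    else:
        ids = [str(i) for i in range(len(df))]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate Id values in wide CSV")
    entries = df.to_numpy()
    if not np.isin(entries, (0, 1)).all():
        raise ValueError("wide-format CSV must contain only 0/1 values")
    return LabelMatrix(entries.astype(np.int8), tuple(map(str, df.columns)), tuple(ids))


def read_labels(
    csv_path: str | Path,
    format: LabelFormat = "kaggle",
    n_labels: int | None = None,
) -> LabelMatrix:
    """Read a label CSV into a binary label matrix.

    ``n_labels`` fixes the number of columns for the kaggle dialect (else it
    is inferred as max label id + 1).
    """
    df = pd.read_csv(csv_path, dtype=str)
    if format == "kaggle":
        return _parse_kaggle(df, n_labels)
    if format == "wide":
        return _parse_wide(pd.read_csv(csv_path))
    raise ValueError(f"unknown label format {format!r}")


def write_labels(labels: LabelMatrix, csv_path: str | Path) -> None:
    """Write a label matrix as a kaggle-format ``Id,Target`` CSV.

    Target tokens are integer column indices (the dialect's convention);
    non-numeric label names are not preserved by a round trip.
    """
    rows = []
    for i, sid in enumerate(labels.instance_ids):
        active = np.flatnonzero(labels.entries[i])
        rows.append({"Id": sid, "Target": " ".join(str(j) for j in active)})
    pd.DataFrame(rows, columns=["Id", "Target"]).to_csv(csv_path, index=False)


@dataclass
class DatasetHandle:
    """Index over a dataset directory: id -> channel files + label set."""

    root: Path
    labels: LabelMatrix

    @classmethod
    def open(
        cls,
        root: str | Path,
        labels_csv: str | Path | None = None,
        format: LabelFormat = "kaggle",
        n_labels: int | None = None,
    ) -> "DatasetHandle":
        root = Path(root)
        csv_path = Path(labels_csv) if labels_csv else root / "train.csv"
        labels = read_labels(csv_path, format=format, n_labels=n_labels)
        return cls(root=root, labels=labels)

    def channel_paths(self, sample_id: str) -> dict[str, Path]:
        return {ch: self.root / f"{sample_id}_{ch}.png" for ch in CHANNELS}

    def validate(self) -> None:
        """Check every indexed id has all four channel files present."""
        for sid in self.labels.instance_ids:
            for ch, path in self.channel_paths(sid).items():
                if not path.exists():
                    raise FileNotFoundError(
                        f"sample {sid!r}: missing {ch} channel file {path}"
                    )

    def read_image(self, sample_id: str) -> MultiChannelImage:
        return read_image(self.root, sample_id)


def _read_channel(path: Path, channel: str) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"missing {channel} channel file: {path}")
    with Image.open(path) as im:
        if im.mode == "LA":
            logger.warning("%s: grayscale-with-alpha PNG, discarding alpha", path)
            im = im.getchannel("L")
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected single-channel image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    raise ValueError(f"{path}: unsupported PNG bit depth ({arr.dtype})")


def read_image(root: str | Path, sample_id: str) -> MultiChannelImage:
    """Read the four per-channel PNGs of one sample, scaled to [0, 1]."""
    root = Path(root)
    planes = [
        _read_channel(root / f"{sample_id}_{ch}.png", ch) for ch in CHANNELS
    ]
    return MultiChannelImage(np.stack(planes))


def write_image(image: MultiChannelImage, sample_id: str, out_dir: str | Path) -> list[Path]:
    """Write one sample as four 8-bit grayscale PNGs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, ch in enumerate(CHANNELS):
        data = np.round(image.channels[k] * 255.0).astype(np.uint8)
        path = out_dir / f"{sample_id}_{ch}.png"
        Image.fromarray(data, mode="L").save(path)
        paths.append(path)
    return paths


def write_manifests(manifests: Iterable, path: str | Path) -> int:
    """Write batch manifests as JSON Lines; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for m in manifests:
            record = m.to_dict() if hasattr(m, "to_dict") else m
            fh.write(json.dumps(record) + "\n")
            n += 1
    return n


def read_manifests(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_json_report(report: dict, path: str | Path | None) -> str:
    """Serialize a metrics report; writes to ``path`` unless it is None."""
    text = json.dumps(report, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: YAML config must be a mapping")
    return data
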
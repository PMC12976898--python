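"""File round-trips for slide bags and label tables.

Bags live in one HDF5 container with a dataset per slide ID (shape
N x embed_dim) and the label stored as a dataset attribute; labels travel
as TSV with columns sample_id/slide_id, label, high_confidence.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .morphology import SlideBag

__all__ = ["write_bags", "read_bags", "write_labels", "read_labels"]


def write_bags(bags: Sequence[SlideBag], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for b in bags:
            d = f.create_dataset(b.slide_id, data=np.asarray(b.embeddings, dtype=np.float32))
            if b.label is not None:
                d.attrs["label"] = int(b.label)


def read_bags(path: str | Path) -> list[SlideBag]:
    bags = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            d = f[sid]
            label = int(d.attrs["label"]) if "label" in d.attrs else None
            bags.append(SlideBag(sid, d[()], label))
    return bags


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    id_col = "sample_id" if "sample_id" in df.columns else "slide_id"
    if id_col not in df.columns:
        raise ValueError(f"labels file {path} lacks a sample_id/slide_id column")
    df[id_col] = df[id_col].astype(str)
    if "high_confidence" in df.columns:
        df["high_confidence"] = df["high_confidence"].astype(bool)
    return df
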
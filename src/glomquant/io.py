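"""File formats: multi-page TIFF stacks, labeled atlas + JSON name table,
expression TSVs, and JSONL result streams.

One channel per TIFF file (suffix convention ``_neuropil.tif``,
``_label.tif``, ``_protein.tif``); multi-sample (RGB) TIFFs are rejected.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Union

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, NameTableError
from .screen import ExpressionTable
from .types import GlomerulusAtlas, VoxelStack

logger = logging.getLogger("glomquant")

PathLike = Union[str, Path]

CHANNEL_SUFFIXES = ("neuropil", "label", "protein")


def write_stack(stack: VoxelStack, path: PathLike) -> None:
    """Write a single-channel stack as a multi-page grayscale TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack.data), photometric="minisblack")


def read_stack(path: PathLike) -> VoxelStack:
    """Read a multi-page single-channel TIFF as a ``(z, y, x)`` stack.

    A single-page file yields z = 1. RGB/multi-sample files are rejected:
    channels must be separate files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        axes = series.axes
        n_pages = len(tf.pages)
        if "S" in axes or "C" in axes:
            raise FormatError(
                f"{path.name}: multi-sample/RGB TIFF ({n_pages} page(s), axes "
                f"{axes!r}); channels must be separate single-channel files"
            )
        data = series.asarray()
    if data.ndim == 2:
        data = data[np.newaxis, ...]
    if data.ndim != 3:
        raise FormatError(
            f"{path.name}: expected a 3D single-channel stack, got ndim="
            f"{data.ndim} ({n_pages} page(s))"
        )
    return VoxelStack(data)


def write_atlas(atlas: GlomerulusAtlas, label_path: PathLike, names_path: PathLike) -> None:
    """Write the label volume as 16-bit TIFF and the name table as JSON."""
    tifffile.imwrite(
        str(label_path), atlas.labels.astype(np.uint16), photometric="minisblack"
    )
    with open(names_path, "w") as fh:
        json.dump({str(k): v for k, v in atlas.name_table.items()}, fh, indent=2)


def read_atlas(label_path: PathLike, names_path: PathLike) -> GlomerulusAtlas:
    """Read and validate a labeled atlas volume with its JSON name table.

    Every nonzero label present in the volume must be named; a name table
    entry for an absent label is tolerated with a warning.
    """
    stack = read_stack(label_path)
    labels = stack.data
    if not np.issubdtype(labels.dtype, np.integer):
        raise FormatError(
            f"{Path(label_path).name}: atlas labels must be integer-typed, "
            f"got {labels.dtype}"
        )
    with open(names_path) as fh:
        raw = json.load(fh)
    name_table = {int(k): str(v) for k, v in raw.items()}
    present = set(np.unique(labels)) - {0}
    unnamed = sorted(present - set(name_table))
    if unnamed:
        raise NameTableError(f"labels present but unnamed: {unnamed}")
    absent = sorted(set(name_table) - present)
    if absent:
        logger.warning("name table labels absent from volume: %s", absent)
    return GlomerulusAtlas(labels=labels.astype(np.int32), name_table=name_table)


def write_sample_channels(
    channels: Dict[str, VoxelStack], out_dir: PathLike, stem: str
) -> List[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for key, stack in channels.items():
        path = out_dir / f"{stem}_{key}.tif"
        write_stack(stack, path)
        written.append(path)
    return written


def read_sample_channels(stack_dir: PathLike, stem: str) -> Dict[str, VoxelStack]:
    stack_dir = Path(stack_dir)
    channels = {}
    for key in CHANNEL_SUFFIXES:
        path = stack_dir / f"{stem}_{key}.tif"
        if path.exists():
            channels[key] = read_stack(path)
    if not channels:
        raise FileNotFoundError(f"no channel TIFFs for stem {stem!r} in {stack_dir}")
    return channels


def find_sample_stems(stack_dir: PathLike) -> List[str]:
    """Sample stems inferred from ``*_label.tif`` files, sorted."""
    return sorted(
        p.name[: -len("_label.tif")]
        for p in Path(stack_dir).glob("*_label.tif")
    )


# ---------------------------------------------------------------------------
# tables and records


def write_expression(table: ExpressionTable, values_path: PathLike, meta_path: PathLike) -> None:
    table.values.to_csv(values_path, sep="\t", index_label="gene")
    table.meta.to_csv(meta_path, sep="\t", index_label="cell_type")


def read_expression(
    values_path: PathLike, meta_path: PathLike, is_cpm: bool = False
) -> ExpressionTable:
    values = pd.read_csv(values_path, sep="\t", index_col="gene")
    meta = pd.read_csv(meta_path, sep="\t", index_col="cell_type")
    return ExpressionTable(values=values, meta=meta, is_cpm=is_cpm)


def write_jsonl(records: Iterable[dict], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_jsonl(path: PathLike) -> List[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_json(obj: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_json(path: PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)
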
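"""Readers and writers for the TSV interchange layout.

A dataset is either four genes × samples TSV matrices (copy number,
methylation, gene expression, protein expression; header row of sample IDs,
first column gene labels) or one combined table whose row names carry the
type suffixes ``.c`` / ``.m`` / ``.g`` / ``.p``.  Blocks are aligned by
gene and sample label, so column order may differ between files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .sem import OmicsDataset

__all__ = ["load_dataset", "write_dataset", "dataset_from_frames"]

_BLOCKS = ("copy_number", "methylation", "expression", "protein")
_SUFFIX = {"copy_number": "c", "methylation": "m", "expression": "g", "protein": "p"}


def _read_block(path, block: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing block: no {block} file at {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene {dup!r} in {block} block ({path})")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric cell in {block} block ({path}): {err}") from None
    return df


def dataset_from_frames(
    copy_number: pd.DataFrame,
    methylation: pd.DataFrame,
    expression: pd.DataFrame,
    protein: pd.DataFrame,
) -> OmicsDataset:
    """Align four genes × samples frames into an :class:`OmicsDataset`.

    Genes and samples are matched by label (the gene/sample order of the
    expression block is kept); a gene or sample missing from any block is an
    error.
    """
    frames = {"copy_number": copy_number, "methylation": methylation,
              "expression": expression, "protein": protein}
    genes = list(expression.index)
    samples = list(expression.columns)
    for block, df in frames.items():
        missing_g = set(genes) - set(df.index)
        extra_g = set(df.index) - set(genes)
        if missing_g or extra_g:
            raise ValueError(
                f"gene mismatch in {block} block: missing {sorted(missing_g)}, "
                f"unexpected {sorted(extra_g)}")
        if set(df.columns) != set(samples):
            raise ValueError(
                f"sample mismatch in {block} block: expected {len(samples)} "
                f"samples {sorted(samples)[:5]}..., got {sorted(df.columns)[:5]}...")
        if len(df.columns) != len(samples):
            raise ValueError(f"sample-count mismatch in {block} block")
    aligned = {b: frames[b].loc[genes, samples].to_numpy(dtype=float)
               for b in frames}
    p, n = len(genes), len(samples)
    X = np.empty((2 * p, n))
    X[0::2] = aligned["copy_number"]
    X[1::2] = aligned["methylation"]
    return OmicsDataset(genes, X, aligned["expression"], aligned["protein"],
                        samples)


def load_dataset(
    paths,
    standardize: bool = True,
) -> OmicsDataset:
    """Load a dataset from four block TSVs or one combined TSV.

    ``paths`` is either a mapping with keys copy_number/methylation/
    expression/protein, a 4-sequence in that order, or a single path to a
    combined table with ``.c/.m/.g/.p`` row-name suffixes.
    """
    if isinstance(paths, (str, Path)):
        df = _read_block(paths, "combined")
        blocks = {}
        for block, sfx in _SUFFIX.items():
            rows = [r for r in df.index if str(r).endswith("." + sfx)]
            if not rows:
                raise ValueError(f"missing block: no rows with suffix .{sfx} "
                                 f"({block}) in combined table")
            sub = df.loc[rows]
            sub.index = [str(r)[: -2] for r in rows]
            blocks[block] = sub
        ds = dataset_from_frames(**blocks)
    else:
        if hasattr(paths, "keys"):
            missing = [b for b in _BLOCKS if b not in paths]
            if missing:
                raise ValueError(f"missing block path(s): {missing}")
            frames = {b: _read_block(paths[b], b) for b in _BLOCKS}
        else:
            paths = list(paths)
            if len(paths) != 4:
                raise ValueError(
                    "expected 4 paths (copy_number, methylation, expression, "
                    f"protein), got {len(paths)}")
            frames = {b: _read_block(pth, b) for b, pth in zip(_BLOCKS, paths)}
        ds = dataset_from_frames(**frames)
    return ds.standardize() if standardize else ds


def write_dataset(data: OmicsDataset, outdir, prefix: str = "data") -> dict:
    """Write the four block TSVs; returns the path of each block."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = (data.sample_labels if data.sample_labels is not None
               else [f"s{k + 1}" for k in range(data.n)])
    blocks = {
        "copy_number": data.X[0::2],
        "methylation": data.X[1::2],
        "expression": data.Y,
        "protein": data.Z,
    }
    paths = {}
    for block, arr in blocks.items():
        df = pd.DataFrame(arr, index=data.gene_labels, columns=samples)
        df.index.name = "gene"
        path = outdir / f"{prefix}_{block}.tsv"
        df.to_csv(path, sep="\t", float_format="%.10g")
        paths[block] = path
    return paths
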
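"""Readers and writers for the pipeline's tab-separated interchange files.

Variants travel as a long TSV (patient, sample, chrom, pos, ref, alt,
ref_reads, alt_reads); copy-number segments as a SEG-like TSV (sample,
chrom, start, end, total, major, minor; 1-based inclusive coordinates);
trees as Newick; simulation ground truth as a YAML sidecar.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .trees import RootedTree

VARIANT_COLUMNS = ["patient", "sample", "chrom", "pos", "ref", "alt",
                   "ref_reads", "alt_reads"]
SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "total", "major", "minor"]


def write_variants(table: pd.DataFrame, path) -> None:
    missing = [c for c in VARIANT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"variant table is missing columns {missing}")
    cols = VARIANT_COLUMNS + [c for c in table.columns if c not in VARIANT_COLUMNS]
    table[cols].to_csv(path, sep="\t", index=False)


def read_variants(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in VARIANT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return table


def write_segments(table: pd.DataFrame, path) -> None:
    missing = [c for c in SEGMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"segment table is missing columns {missing}")
    table[SEGMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEGMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return table


def write_tree(tree: RootedTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_tree(path) -> RootedTree:
    return RootedTree.from_newick(Path(path).read_text())
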
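"""File-format I/O for the pipeline: FASTA, Newick, TSV, TIFF, masks.

Write-then-read is an identity on the data model: sequence content and IDs;
tree topology, branch lengths and supports; table values; pixel values and
stack shape.  Parsers raise with the offending record/position where the
underlying library reports one.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO


def write_fasta(records: dict[str, str], path: str | Path, wrap: int = 80) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            if wrap and wrap > 0:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i : i + wrap] + "\n")
            else:
                fh.write(seq + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA ID {rec.id!r} at record {idx} in {path}")
        out[rec.id] = str(rec.seq)
    if not out:
        raise IOError(f"no FASTA records in {path}")
    return out


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Newick with bootstrap supports as internal-node labels."""
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=False,
        unquoted_underscores=True,
    )


def read_newick(path: str | Path) -> dendropy.Tree:
    """Accepts supports as internal labels or as comments."""
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise IOError(f"malformed Newick in {path}: {exc}") from exc


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise IOError(f"malformed TSV in {path}: {exc}") from exc


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(stack))


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_mask_rle(mask: np.ndarray, path: str | Path) -> None:
    """Run-length TSV encoding of a boolean mask: rows (row, start, end).

    ``start``/``end`` are 0-based column indices, end exclusive.  The header
    carries the mask shape so decoding restores it exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    rows = []
    for r in range(mask.shape[0]):
        line = mask[r]
        edges = np.flatnonzero(np.diff(np.concatenate(([0], line.view(np.int8), [0]))))
        for start, end in zip(edges[::2], edges[1::2]):
            rows.append((r, int(start), int(end)))
    with Path(path).open("w") as fh:
        fh.write(f"# shape\t{mask.shape[0]}\t{mask.shape[1]}\n")
        fh.write("row\tstart\tend\n")
        for r, s, e in rows:
            fh.write(f"{r}\t{s}\t{e}\n")


def read_mask_rle(path: str | Path) -> np.ndarray:
    with Path(path).open() as fh:
        header = fh.readline().strip().split("\t")
        if header[0] != "# shape" or len(header) != 3:
            raise IOError(f"malformed mask RLE header in {path}: {header}")
        shape = (int(header[1]), int(header[2]))
        tab = pd.read_csv(fh, sep="\t")
    mask = np.zeros(shape, dtype=bool)
    for _, row in tab.iterrows():
        mask[int(row["row"]), int(row["start"]) : int(row["end"])] = True
    return mask


def read_calibrations(path: str | Path) -> dict[tuple[str, str], float]:
    """Calibration TSV (taxonA, taxonB, time_mya) -> symmetric pair dict."""
    tab = read_table(path)
    need = {"taxonA", "taxonB", "time_mya"}
    if not need <= set(tab.columns):
        raise IOError(f"calibration table {path} must have columns {sorted(need)}")
    out: dict[tuple[str, str], float] = {}
    for _, row in tab.iterrows():
        t = float(row["time_mya"])
        if t <= 0:
            raise ValueError(f"nonpositive calibration time for {row['taxonA']}/{row['taxonB']}")
        out[(row["taxonA"], row["taxonB"])] = t
        out[(row["taxonB"], row["taxonA"])] = t
    return out
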
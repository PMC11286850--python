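"""Reading and writing 4DN ``.pairs`` files.

The 4DN pairs format is a headered, tab-separated text format with 1-based
positions.  Everything downstream of this module works in 0-based half-open
coordinates; the 1-based -> 0-based conversion happens exactly once, here, at
parse time (and the reverse conversion exactly once at write time).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd

PAIRS_VERSION_LINE = "## pairs format v1.0"

#: canonical column order used by this package when writing
DEFAULT_COLUMNS = [
    "readID",
    "chrom1",
    "pos1",
    "chrom2",
    "pos2",
    "strand1",
    "strand2",
    "mapq1",
    "mapq2",
]

_POSITION_COLUMNS = ("pos1", "pos2")
_INT_COLUMNS = ("pos1", "pos2", "mapq1", "mapq2")


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_pairs(path):
    """Parse a 4DN .pairs file.

    Returns
    -------
    (DataFrame, dict)
        Records with 0-based positions, and the ``#chromsize`` entries as an
        ordered ``{chrom: size}`` dict.  The ``#columns`` header is required.
    """
    chromsizes: dict[str, int] = {}
    columns = None
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#chromsize:"):
                    _, chrom, size = line.split()
                    chromsizes[chrom] = int(size)
                elif line.startswith("#columns:"):
                    columns = line.split()[1:]
                continue
            rows.append(line.split("\t"))
    if columns is None:
        raise ValueError(f"{path}: missing #columns header; not a 4DN .pairs file")
    df = pd.DataFrame(rows, columns=columns)
    for col in _INT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    # 1-based (file) -> 0-based (in memory); done exactly once.
    for col in _POSITION_COLUMNS:
        if col in df.columns:
            df[col] = df[col] - 1
    return df, chromsizes


def write_pairs(path, df, chromsizes, extra_header=()):
    """Write records (0-based positions in memory) as a 1-based 4DN .pairs file.

    Records are sorted by (chrom1, pos1, chrom2, pos2) as the format requires.
    """
    columns = [c for c in DEFAULT_COLUMNS if c in df.columns]
    out = df[columns].copy()
    for col in _POSITION_COLUMNS:
        out[col] = out[col].astype(int) + 1
    order = [c for c in ("chrom1", "pos1", "chrom2", "pos2") if c in out.columns]
    out = out.sort_values(order, kind="stable")
    with _open_text(path, "wt") as fh:
        fh.write(PAIRS_VERSION_LINE + "\n")
        for line in extra_header:
            fh.write(f"#{line}\n")
        for chrom, size in chromsizes.items():
            fh.write(f"#chromsize: {chrom} {size}\n")
        fh.write("#columns: " + " ".join(columns) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)
    return Path(path)
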
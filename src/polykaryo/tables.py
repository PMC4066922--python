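"""Site-matrix (variant table) input/output.

A site matrix is the compact form in which per-locus polymorphisms are
published: rows are isolates (or isolate groups), columns are 1-based
alignment positions, cells are the observed states.  ``.`` or the
typographic bullet denote a deletion, ``N`` missing data.  The package
bundles the ITS1-5.8S-ITS2 variant matrix of the Vietnamese
*Filoboletus manipularis* collections (positions 195, 338, 538 and 669 of
the 669-column ITS alignment, plus the Japanese reference sequence with a
missing ITS1 region) as a worked desk dataset.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .seqio import MultipleAlignment

__all__ = [
    "read_site_matrix",
    "write_site_matrix",
    "load_its_matrix",
    "ITS_ALIGNMENT_LENGTH",
    "alignment_from_site_matrix",
]

ITS_ALIGNMENT_LENGTH = 669

_DELETION_CHARS = {".", "•", "-"}


def _clean_state(cell: str) -> str:
    cell = cell.strip().upper()
    if cell in _DELETION_CHARS:
        return "-"
    return cell


def read_site_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV variant table: first column isolate, rest positions."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame.columns = [int(c) for c in frame.columns]
    return frame.apply(lambda col: col.map(_clean_state))


def write_site_matrix(
    matrix: pd.DataFrame, path: str | Path, deletion_char: str = "•"
) -> None:
    """Write a variant table; deletions rendered as ``deletion_char``."""
    out = matrix.apply(
        lambda col: col.map(lambda s: deletion_char if set(s) == {"-"} else s)
    )
    out.to_csv(path, sep="\t", index_label="isolate")


def load_its_matrix(include_reference: bool = True) -> pd.DataFrame:
    """The bundled ITS variant matrix.

    ``include_reference=False`` drops the Japanese reference row
    (AB509828, missing ITS1), leaving the Vietnamese isolates only.
    """
    with resources.files("polykaryo.data").joinpath("its_site_matrix.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
    frame.columns = [int(c) for c in frame.columns]
    frame = frame.apply(lambda col: col.map(_clean_state))
    if not include_reference:
        frame = frame.drop(index="AB509828")
    return frame


def alignment_from_site_matrix(
    matrix: pd.DataFrame, length: int, fill: str = "A"
) -> MultipleAlignment:
    """Embed a variant table into a full-length alignment.

    Invariant columns are filled with ``fill``; every statistic that only
    looks at variable columns (site detection, classification, haplotype
    grouping, networks) is unaffected by the filler.  Multi-character
    states occupy consecutive columns starting at their position.
    """
    records = []
    for rid, row in matrix.iterrows():
        seq = [fill] * length
        for pos, state in row.items():
            for offset, char in enumerate(str(state)):
                seq[int(pos) - 1 + offset] = char
        records.append((str(rid), "".join(seq)))
    return MultipleAlignment(tuple(records))
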
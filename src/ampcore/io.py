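"""Text formats: token/label training files and family tables.

The token/label format is the multi-column dialect used by common CRF
toolkits: one residue per line, whitespace-separated columns in the fixed
order PRIMARY SS DOMAIN ALIGN AMPA AGGR CHARGE AMPH [LABEL], with a blank
line between sequences.  Coordinates in the family table are 0-based,
half-open, as everywhere in this package.
"""

from __future__ import annotations

import csv
from typing import Iterable, Sequence, TextIO

from .families import CoreAnnotation, NestedFamily
from .features import CHANNELS, FeatureTracks

FAMILY_TABLE_COLUMNS = (
    "family_id",
    "member_count",
    "carrier_id",
    "core_start",
    "core_end",
    "core_seq",
)


def write_family_table(
    rows: Iterable[tuple[NestedFamily, CoreAnnotation]], handle: TextIO
) -> None:
    handle.write("# coordinates: 0-based, half-open on the carrier\n")
    writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
    writer.writerow(FAMILY_TABLE_COLUMNS)
    for family, core in rows:
        writer.writerow(
            [
                family.family_id,
                len(family.members),
                core.carrier_id,
                core.start,
                core.end,
                core.core_residues,
            ]
        )


def write_token_file(
    items: Iterable[tuple[FeatureTracks, Sequence[str] | None]], handle: TextIO
) -> None:
    """Write featurized (optionally labeled) sequences in token format."""
    first = True
    for tracks, labels in items:
        if not first:
            handle.write("\n")
        first = False
        for i in range(tracks.length):
            cols = list(tracks.column(i))
            if labels is not None:
                cols.append(labels[i])
            handle.write("\t".join(cols) + "\n")


def read_token_file(
    handle: TextIO, labeled: bool = True
) -> list[tuple[FeatureTracks, list[str] | None]]:
    """Read a token/label file back into tracks (and labels if present)."""
    blocks: list[list[list[str]]] = [[]]
    for line in handle:
        line = line.rstrip("\n")
        if not line.strip():
            if blocks[-1]:
                blocks.append([])
            continue
        blocks[-1].append(line.split())
    if blocks and not blocks[-1]:
        blocks.pop()
    out = []
    n_cols = len(CHANNELS) + (1 if labeled else 0)
    for k, rows in enumerate(blocks):
        for row in rows:
            if len(row) != n_cols:
                raise ValueError(
                    f"sequence {k}: expected {n_cols} columns, got {len(row)}"
                )
        channels = {
            name: tuple(row[ci] for row in rows) for ci, name in enumerate(CHANNELS)
        }
        tracks = FeatureTracks(
            sequence_id=f"seq{k + 1}", length=len(rows), channels=channels
        )
        labels = [row[-1] for row in rows] if labeled else None
        out.append((tracks, labels))
    return out


def read_domain_bed(handle: TextIO) -> dict[str, list[tuple[int, int]]]:
    """BED-like 3 columns: sequence_id, start, end (0-based, half-open)."""
    out: dict[str, list[tuple[int, int]]] = {}
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        seq_id, start, end = line.split()[:3]
        out.setdefault(seq_id, []).append((int(start), int(end)))
    return out
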
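"""Concatenate per-locus alignments into a supermatrix with nexus partitions.

Taxa absent from a locus get a filler row of ``?`` (distinct from the
alignment gap ``-`` so data absence stays distinguishable; downstream
phylogenetic software treats both as missing).  Partition coordinates are
1-based inclusive, nexus style.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from orthoforge.alignment_io import LocusAlignment
from orthoforge.errors import PartitionError

__all__ = [
    "MISSING_CHAR",
    "PartitionScheme",
    "Supermatrix",
    "concatenate",
    "split_supermatrix",
    "write_partition_nexus",
    "read_partition_nexus",
    "write_supermatrix_phylip",
    "read_supermatrix_phylip",
    "write_supermatrix_fasta",
]

MISSING_CHAR = "?"

_CHARSET_SAFE = re.compile(r"[^A-Za-z0-9_]")
_CHARSET_LINE = re.compile(r"^\s*charset\s+(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*;\s*$", re.I)


@dataclass
class PartitionScheme:
    """Ordered, contiguous, non-overlapping 1-based inclusive locus ranges."""

    entries: list[tuple[str, int, int]] = field(default_factory=list)

    def validate(self) -> None:
        if not self.entries:
            raise PartitionError("partition scheme has no entries")
        names = [name for name, _, _ in self.entries]
        if len(set(names)) != len(names):
            raise PartitionError("duplicate locus names in partition scheme")
        expected_start = 1
        for name, start, end in self.entries:
            if start != expected_start:
                raise PartitionError(
                    f"{name}: starts at {start}, expected {expected_start} (contiguity)"
                )
            if end < start:
                raise PartitionError(f"{name}: end {end} < start {start}")
            expected_start = end + 1

    @property
    def total_length(self) -> int:
        return self.entries[-1][2] if self.entries else 0

    @classmethod
    def from_lengths(cls, lengths: Iterable[tuple[str, int]]) -> "PartitionScheme":
        entries, start = [], 1
        for name, width in lengths:
            entries.append((name, start, start + width - 1))
            start += width
        scheme = cls(entries)
        scheme.validate()
        return scheme


@dataclass
class Supermatrix:
    """Concatenated alignment over the union of taxa, plus its partitions."""

    matrix: dict[str, str]
    partitions: PartitionScheme

    def __post_init__(self) -> None:
        self.partitions.validate()
        total = self.partitions.total_length
        for taxon, row in self.matrix.items():
            if len(row) != total:
                raise PartitionError(
                    f"taxon {taxon}: row length {len(row)} != partition coverage {total}"
                )

    @property
    def taxa(self) -> list[str]:
        return list(self.matrix)

    @property
    def length(self) -> int:
        return self.partitions.total_length


def concatenate(
    alignments: Sequence[LocusAlignment],
    taxon_order: Sequence[str] | None = None,
    missing_char: str = MISSING_CHAR,
) -> Supermatrix:
    """Concatenate locus alignments; absent taxon/locus cells become filler.

    Taxa default to the sorted union across loci; an explicit ``taxon_order``
    must cover that union.  Partitions follow the input locus order.
    """
    if not alignments:
        raise PartitionError("nothing to concatenate: empty alignment list")
    names = [a.busco_id for a in alignments]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise PartitionError(f"duplicate locus names: {dupes}")
    union: set[str] = set()
    for aln in alignments:
        union.update(aln.sequences)
    if taxon_order is None:
        taxa = sorted(union)
    else:
        taxa = list(taxon_order)
        if set(taxa) != union:
            raise PartitionError(
                "explicit taxon_order does not match the union of aligned taxa"
            )
    rows = {taxon: [] for taxon in taxa}
    for aln in alignments:
        filler = missing_char * aln.length
        for taxon in taxa:
            rows[taxon].append(aln.sequences.get(taxon, filler))
    scheme = PartitionScheme.from_lengths((a.busco_id, a.length) for a in alignments)
    return Supermatrix(
        matrix={taxon: "".join(parts) for taxon, parts in rows.items()},
        partitions=scheme,
    )


def split_supermatrix(sm: Supermatrix) -> list[LocusAlignment]:
    """Slice a supermatrix back into per-locus alignments (filler rows kept)."""
    out = []
    for name, start, end in sm.partitions.entries:
        out.append(
            LocusAlignment(
                name, {taxon: row[start - 1:end] for taxon, row in sm.matrix.items()}
            )
        )
    return out


def sanitize_charset_name(name: str) -> str:
    """Replace nexus-unsafe characters with underscores."""
    return _CHARSET_SAFE.sub("_", name)


def write_partition_nexus(scheme: PartitionScheme, dest: str | Path) -> None:
    """Write the scheme as a nexus ``sets`` block of charsets (byte-stable)."""
    scheme.validate()
    lines = ["#nexus", "begin sets;"]
    for name, start, end in scheme.entries:
        lines.append(f"    charset {sanitize_charset_name(name)} = {start}-{end};")
    lines.append("end;")
    Path(dest).write_text("\n".join(lines) + "\n")


def read_partition_nexus(src: str | Path) -> PartitionScheme:
    """Parse a charset-only nexus sets block back into a scheme."""
    entries = []
    for line in Path(src).read_text().splitlines():
        match = _CHARSET_LINE.match(line)
        if match:
            entries.append((match.group(1), int(match.group(2)), int(match.group(3))))
    scheme = PartitionScheme(entries)
    scheme.validate()
    return scheme


def write_supermatrix_phylip(sm: Supermatrix, dest: str | Path) -> None:
    """Relaxed-phylip rendering of the whole matrix."""
    lines = [f"{len(sm.matrix)} {sm.length}"]
    lines += [f"{taxon} {row}" for taxon, row in sm.matrix.items()]
    Path(dest).write_text("\n".join(lines) + "\n")


def read_supermatrix_phylip(matrix_src: str | Path, partitions_src: str | Path) -> Supermatrix:
    """Rebuild a supermatrix from its phylip matrix + nexus partition files."""
    from orthoforge.alignment_io import read_relaxed_phylip

    aln = read_relaxed_phylip(matrix_src, busco_id="supermatrix")
    return Supermatrix(matrix=dict(aln.sequences), partitions=read_partition_nexus(partitions_src))


def write_supermatrix_fasta(sm: Supermatrix, dest: str | Path) -> None:
    with open(dest, "w") as handle:
        for taxon, row in sm.matrix.items():
            handle.write(f">{taxon}\n{row}\n")
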
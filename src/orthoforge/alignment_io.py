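"""Per-locus alignment via pluggable backends, plus relaxed-phylip I/O.

The alignment step is delegated to a backend.  The default external backend
shells out to MAFFT with ``--adjustdirection`` so all rows end up on the same
strand; MAFFT marks rows it flipped by prefixing ``_R_`` to the name, which is
stripped here before taxon labels propagate downstream.  A deterministic
right-pad backend keeps the whole pipeline testable without any binary.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

from orthoforge.errors import AlignmentError, PhylipFormatError
from orthoforge.harvest import LocusBin

__all__ = [
    "ORIENTATION_MARKER",
    "LocusAlignment",
    "Aligner",
    "PadAligner",
    "MafftAligner",
    "align_locus",
    "strip_orientation_markers",
    "write_relaxed_phylip",
    "read_relaxed_phylip",
]

ORIENTATION_MARKER = "_R_"


@dataclass
class LocusAlignment:
    """One aligned locus: equal-length rows keyed by taxon, insertion-ordered."""

    busco_id: str
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"{self.busco_id}: alignment has no rows")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.busco_id}: ragged alignment rows {sorted(lengths)}")
        if lengths == {0}:
            raise ValueError(f"{self.busco_id}: zero-length alignment")
        for taxon in self.sequences:
            if taxon.startswith(ORIENTATION_MARKER):
                raise ValueError(
                    f"{self.busco_id}: taxon {taxon!r} carries a residual orientation marker"
                )

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))


class Aligner(Protocol):
    """Alignment backend contract: bin in, name->aligned-row mapping out.

    Backends may rename flipped rows with a leading ``_R_``; callers strip it.
    """

    def __call__(self, records: dict[str, str]) -> dict[str, str]: ...


class PadAligner:
    """Deterministic test backend: uppercase and right-pad rows with gaps.

    Not a real aligner — it exists so the full pipeline runs byte-reproducibly
    with no external binary.
    """

    def __call__(self, records: dict[str, str]) -> dict[str, str]:
        width = max(len(s) for s in records.values())
        return {name: seq.upper().ljust(width, "-") for name, seq in records.items()}


class MafftAligner:
    """External MAFFT backend with same-strand orientation assurance.

    Runs ``mafft --adjustdirection --quiet <in.fasta>`` and parses the FASTA
    written to stdout.  Rows MAFFT reverse-complemented come back named
    ``_R_<taxon>``; the marker is passed through for the caller to strip.
    """

    def __init__(self, executable: str = "mafft", adjust_direction: bool = True,
                 extra_args: tuple[str, ...] = ()):
        self.executable = executable
        self.adjust_direction = adjust_direction
        self.extra_args = extra_args

    @staticmethod
    def available(executable: str = "mafft") -> bool:
        return shutil.which(executable) is not None

    def __call__(self, records: dict[str, str]) -> dict[str, str]:
        from Bio import SeqIO

        with tempfile.TemporaryDirectory(prefix="orthoforge_mafft_") as tmp:
            in_path = Path(tmp) / "in.fasta"
            with open(in_path, "w") as handle:
                for name, seq in records.items():
                    handle.write(f">{name}\n{seq}\n")
            cmd = [self.executable]
            if self.adjust_direction:
                cmd.append("--adjustdirection")
            cmd += ["--quiet", *self.extra_args, str(in_path)]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise AlignmentError(
                    f"mafft exited {proc.returncode}: {proc.stderr.strip()[-500:]}"
                )
            out: dict[str, str] = {}
            out_path = Path(tmp) / "out.fasta"
            out_path.write_text(proc.stdout)
            for record in SeqIO.parse(str(out_path), "fasta"):
                out[record.id] = str(record.seq).upper()
        if not out:
            raise AlignmentError("mafft produced no output records")
        return out


def strip_orientation_markers(labels: list[str]) -> list[str]:
    """Remove one leading ``_R_`` orientation marker from each label.

    Idempotent on already-clean labels.  Raises if stripping makes two labels
    collide (the alignment would silently lose a row).
    """
    stripped = [
        label[len(ORIENTATION_MARKER):] if label.startswith(ORIENTATION_MARKER) else label
        for label in labels
    ]
    if len(set(stripped)) != len(stripped):
        dupes = sorted({s for s in stripped if stripped.count(s) > 1})
        raise AlignmentError(f"orientation-marker stripping collides on {dupes}")
    return stripped


def align_locus(locus_bin: LocusBin, aligner: Aligner | None = None) -> LocusAlignment:
    """Align one locus bin; single-record bins pass through unaligned.

    The output carries exactly the bin's species, with any backend orientation
    markers stripped from taxon labels.  Backend failures are re-raised as
    :class:`AlignmentError` carrying the locus id.
    """
    if not locus_bin.records:
        raise AlignmentError(f"{locus_bin.busco_id}: empty bin")
    if len(locus_bin.records) == 1:
        ((taxon, seq),) = locus_bin.records.items()
        return LocusAlignment(locus_bin.busco_id, {taxon: seq.upper()})
    if aligner is None:
        aligner = PadAligner()
    try:
        raw = aligner(dict(locus_bin.records))
    except AlignmentError as exc:
        raise AlignmentError(f"locus {locus_bin.busco_id}: {exc}") from exc
    clean_names = strip_orientation_markers(list(raw))
    aligned = dict(zip(clean_names, raw.values()))
    if set(aligned) != set(locus_bin.records):
        raise AlignmentError(
            f"locus {locus_bin.busco_id}: backend returned taxa {sorted(aligned)} "
            f"but bin has {sorted(locus_bin.records)}"
        )
    # restore the bin's record order regardless of backend output order
    ordered = {taxon: aligned[taxon] for taxon in locus_bin.records}
    return LocusAlignment(locus_bin.busco_id, ordered)


def write_relaxed_phylip(aln: LocusAlignment, dest: str | Path) -> None:
    """Write a sequential relaxed-phylip file: header then ``name seq`` rows.

    Names are unrestricted in length (no 10-character truncation), separated
    from the uppercased, unwrapped sequence by a single space.
    """
    dest = Path(dest)
    lines = [f"{len(aln.sequences)} {aln.length}"]
    for taxon, seq in aln.sequences.items():
        lines.append(f"{taxon} {seq.upper()}")
    dest.write_text("\n".join(lines) + "\n")


def read_relaxed_phylip(src: str | Path, busco_id: str | None = None) -> LocusAlignment:
    """Read a sequential relaxed-phylip file written by :func:`write_relaxed_phylip`."""
    src = Path(src)
    text = src.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise PhylipFormatError(f"{src}: empty file")
    header = lines[0].split()
    if len(header) != 2:
        raise PhylipFormatError(f"{src}: malformed header {lines[0]!r}")
    try:
        ntaxa, ncols = int(header[0]), int(header[1])
    except ValueError as exc:
        raise PhylipFormatError(f"{src}: non-integer header {lines[0]!r}") from exc
    rows = lines[1:]
    if len(rows) != ntaxa:
        raise PhylipFormatError(f"{src}: header says {ntaxa} taxa, found {len(rows)} rows")
    sequences: dict[str, str] = {}
    for row in rows:
        parts = row.split(None, 1)
        if len(parts) != 2:
            raise PhylipFormatError(f"{src}: row without sequence: {row!r}")
        name, seq = parts[0], parts[1].replace(" ", "")
        if name in sequences:
            raise PhylipFormatError(f"{src}: duplicate taxon {name}")
        if len(seq) != ncols:
            raise PhylipFormatError(
                f"{src}: taxon {name} has {len(seq)} columns, header says {ncols}"
            )
        sequences[name] = seq
    if busco_id is None:
        busco_id = src.stem
    return LocusAlignment(busco_id, sequences)
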
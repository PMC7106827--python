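"""Parse BUSCO v3 full-table results and resolve best hits per locus.

A BUSCO v3 transcriptome run writes ``full_table_<species>.tsv`` with one row
per (BUSCO id, matching transcript): ``busco_id  status  sequence  score
length``.  ``Missing`` rows carry only the first two columns.  This module
parses those tables and reduces each species' hits to at most one winning
transcript per BUSCO locus: duplicates are resolved by maximum score with
earliest-row tie-break, and fragmented hits are kept or dropped according to a
user policy with an optional minimum match length.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from orthoforge.errors import FullTableParseError

__all__ = [
    "BuscoStatus",
    "BuscoHit",
    "SpeciesResult",
    "SelectionPolicy",
    "parse_full_table",
    "parse_full_table_file",
    "select_best_hits",
    "discover_full_tables",
    "run_busco",
]


class BuscoStatus(enum.Enum):
    """BUSCO classification of a locus match."""

    COMPLETE = "Complete"
    DUPLICATED = "Duplicated"
    FRAGMENTED = "Fragmented"
    MISSING = "Missing"

    @classmethod
    def from_string(cls, token: str) -> "BuscoStatus":
        """Match a status token case-insensitively after trimming."""
        normalized = token.strip().lower()
        for member in cls:
            if member.value.lower() == normalized:
                return member
        raise ValueError(f"unknown BUSCO status {token!r}")


@dataclass(frozen=True)
class BuscoHit:
    """One row of a BUSCO full table.

    ``sequence_id``, ``score`` and ``length`` are all ``None`` exactly when
    ``status`` is Missing.
    """

    busco_id: str
    status: BuscoStatus
    sequence_id: str | None = None
    score: float | None = None
    length: int | None = None

    def __post_init__(self) -> None:
        absent = (self.sequence_id is None, self.score is None, self.length is None)
        if self.status is BuscoStatus.MISSING:
            if not all(absent):
                raise ValueError(
                    f"{self.busco_id}: Missing hit must not carry sequence/score/length"
                )
        else:
            if any(absent):
                raise ValueError(
                    f"{self.busco_id}: non-Missing hit requires sequence, score and length"
                )
            if self.score < 0:
                raise ValueError(f"{self.busco_id}: negative score {self.score}")
            if self.length < 1:
                raise ValueError(f"{self.busco_id}: non-positive length {self.length}")


@dataclass
class SpeciesResult:
    """All hits for one species, preserving full-table row order.

    Row order matters: the duplicate tie-break rule awards equal-score
    duplicates to the first row encountered.
    """

    species: str
    hits: list[BuscoHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species or re.search(r"\s", self.species):
            raise ValueError(f"invalid species label {self.species!r}")


@dataclass(frozen=True)
class SelectionPolicy:
    """Controls which hits are eligible to win a locus.

    Fragmented hits are retained only when ``keep_fragmented`` is true and
    their match length is at least ``min_fragment_length`` (inclusive).  The
    length threshold is ignored when fragments are dropped wholesale.
    """

    keep_fragmented: bool = True
    min_fragment_length: int = 0

    def __post_init__(self) -> None:
        if self.min_fragment_length < 0:
            raise ValueError("min_fragment_length must be non-negative")

    def admits(self, hit: BuscoHit) -> bool:
        if hit.status is BuscoStatus.MISSING:
            return False
        if hit.status is BuscoStatus.FRAGMENTED:
            if not self.keep_fragmented:
                return False
            return hit.length >= self.min_fragment_length
        return True


def parse_full_table(table_text: str, species_label: str) -> SpeciesResult:
    """Parse BUSCO v3 full-table TSV content into a :class:`SpeciesResult`.

    Lines starting with ``#`` are comments.  Missing rows need only two
    columns; all other rows need at least five (``busco_id, status, sequence,
    score, length``); trailing extra columns are tolerated.

    Raises :class:`FullTableParseError` (with line number) on malformed rows,
    unknown statuses, or an empty table.
    """
    hits: list[BuscoHit] = []
    saw_content = False
    for lineno, raw in enumerate(table_text.splitlines(), start=1):
        line = raw.rstrip("\n\r")
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            saw_content = True
            continue
        saw_content = True
        fields = line.split("\t")
        if len(fields) < 2:
            raise FullTableParseError(
                f"expected at least 2 tab-separated columns, got {len(fields)}", lineno
            )
        busco_id = fields[0].strip()
        if not busco_id:
            raise FullTableParseError("empty BUSCO id", lineno)
        try:
            status = BuscoStatus.from_string(fields[1])
        except ValueError as exc:
            raise FullTableParseError(str(exc), lineno) from exc
        if status is BuscoStatus.MISSING:
            extras = [f for f in fields[2:] if f.strip()]
            if extras:
                raise FullTableParseError(
                    f"Missing row carries unexpected data columns {extras!r}", lineno
                )
            hits.append(BuscoHit(busco_id, status))
            continue
        if len(fields) < 5:
            raise FullTableParseError(
                f"{status.value} row needs 5 columns (id, status, sequence, score, "
                f"length), got {len(fields)}",
                lineno,
            )
        sequence_id = fields[2].strip()
        if not sequence_id:
            raise FullTableParseError("empty sequence id", lineno)
        try:
            score = float(fields[3])
        except ValueError as exc:
            raise FullTableParseError(f"non-numeric score {fields[3]!r}", lineno) from exc
        try:
            length = int(fields[4])
        except ValueError as exc:
            raise FullTableParseError(f"non-integer length {fields[4]!r}", lineno) from exc
        try:
            hits.append(BuscoHit(busco_id, status, sequence_id, score, length))
        except ValueError as exc:
            raise FullTableParseError(str(exc), lineno) from exc
    if not saw_content:
        raise FullTableParseError("empty full table")
    return SpeciesResult(species=species_label, hits=hits)


def parse_full_table_file(path: str | Path, species_label: str | None = None) -> SpeciesResult:
    """Parse a full-table file; the species label defaults to the file name.

    A ``full_table_<species>.tsv`` name yields ``<species>``.
    """
    path = Path(path)
    if species_label is None:
        stem = path.stem
        species_label = stem[len("full_table_"):] if stem.startswith("full_table_") else stem
    return parse_full_table(path.read_text(), species_label)


def select_best_hits(
    result: SpeciesResult, policy: SelectionPolicy | None = None
) -> dict[str, tuple[str, BuscoStatus]]:
    """Resolve each BUSCO locus to at most one winning transcript.

    Missing rows never win; fragmented rows are filtered by the policy before
    scores are compared; among the surviving rows of a locus the maximum score
    wins, with ties broken in favour of the earliest table row.  Returns
    ``{busco_id: (sequence_id, status)}`` in first-appearance order.
    """
    if policy is None:
        policy = SelectionPolicy()
    best: dict[str, tuple[float, int, str, BuscoStatus]] = {}
    for index, hit in enumerate(result.hits):
        if not policy.admits(hit):
            continue
        incumbent = best.get(hit.busco_id)
        if incumbent is None or hit.score > incumbent[0]:
            best[hit.busco_id] = (hit.score, index, hit.sequence_id, hit.status)
    return {locus: (seq_id, status) for locus, (_, _, seq_id, status) in best.items()}


def discover_full_tables(results_dir: str | Path) -> dict[str, Path]:
    """Find BUSCO v3 result tables laid out as ``run_<sp>/full_table_<sp>.tsv``.

    Also accepts bare ``full_table_<sp>.tsv`` files directly under
    ``results_dir``.  Returns ``{species: path}`` sorted by species.
    """
    results_dir = Path(results_dir)
    if not results_dir.is_dir():
        raise FileNotFoundError(f"BUSCO results directory not found: {results_dir}")
    found: dict[str, Path] = {}
    for run_dir in sorted(results_dir.glob("run_*")):
        if not run_dir.is_dir():
            continue
        species = run_dir.name[len("run_"):]
        table = run_dir / f"full_table_{species}.tsv"
        if table.is_file():
            found[species] = table
    for table in sorted(results_dir.glob("full_table_*.tsv")):
        species = table.stem[len("full_table_"):]
        found.setdefault(species, table)
    return dict(sorted(found.items()))


def run_busco(
    fasta_paths: Iterable[str | Path],
    lineage_db: str | Path,
    out_dir: str | Path,
    *,
    busco_executable: str = "run_BUSCO.py",
    cpus: int = 1,
    runner=None,
) -> dict[str, Path]:
    """Drive an external BUSCO v3 over each FASTA (optional integration hook).

    One ``run_BUSCO.py -i <fasta> -l <lineage> -m tran`` invocation per file;
    results land under ``out_dir``.  ``runner`` defaults to
    :func:`subprocess.run` and exists so tests can inject a stub.  Returns
    ``{species: expected full-table path}``.
    """
    import subprocess

    if runner is None:
        runner = subprocess.run
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, Path] = {}
    for fasta in fasta_paths:
        fasta = Path(fasta)
        species = fasta.stem
        cmd = [
            busco_executable,
            "-i", str(fasta),
            "-l", str(lineage_db),
            "-m", "tran",
            "-o", species,
            "-c", str(cpus),
        ]
        proc = runner(cmd, cwd=out_dir, capture_output=True, text=True)
        if getattr(proc, "returncode", 1) != 0:
            raise RuntimeError(
                f"BUSCO failed for {species}: {getattr(proc, 'stderr', '')[-500:]}"
            )
        tables[species] = out_dir / f"run_{species}" / f"full_table_{species}.tsv"
    return tables


def selections_by_species(
    tables: Mapping[str, str | Path], policy: SelectionPolicy | None = None
) -> dict[str, dict[str, tuple[str, BuscoStatus]]]:
    """Parse and resolve every species' table in one pass."""
    out: dict[str, dict[str, tuple[str, BuscoStatus]]] = {}
    for species in sorted(tables):
        result = parse_full_table_file(tables[species], species)
        out[species] = select_best_hits(result, policy)
    return out
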
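"""Extract winning transcripts from species FASTAs and bin them per locus."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from orthoforge.errors import FetchError

__all__ = [
    "SpeciesSample",
    "LocusBin",
    "extract_sequences",
    "bin_by_locus",
    "write_locus_bins",
    "read_locus_bin",
    "fetch_cdna",
]

logger = logging.getLogger(__name__)

_COORD_SUFFIX = re.compile(r":\d+-\d+$")


@dataclass(frozen=True)
class SpeciesSample:
    """One species' transcriptome FASTA; the label is the basename sans extension."""

    species: str
    fasta_path: Path

    @classmethod
    def from_path(cls, fasta_path: str | Path) -> "SpeciesSample":
        fasta_path = Path(fasta_path)
        return cls(species=fasta_path.stem, fasta_path=fasta_path)


@dataclass
class LocusBin:
    """Unaligned sequences for one BUSCO locus, keyed by species."""

    busco_id: str
    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for species, seq in self.records.items():
            if not seq:
                raise ValueError(f"{self.busco_id}/{species}: empty sequence")


def _index_fasta(fasta_path: Path) -> dict[str, str]:
    """First-token-keyed FASTA index; first record wins on duplicate ids."""
    index: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        key = record.id  # biopython id = first whitespace token
        if key in index:
            logger.warning("%s: duplicate FASTA id %s, keeping first record", fasta_path, key)
            continue
        index[key] = str(record.seq)
    return index


def extract_sequences(
    sample: SpeciesSample, selection: Mapping[str, str | tuple]
) -> dict[str, str]:
    """Pull each selected transcript's sequence from the species FASTA.

    ``selection`` maps busco_id to a sequence id (or a ``(sequence_id, status)``
    pair as produced by hit selection).  BUSCO sometimes appends a
    ``:<start>-<end>`` coordinate suffix to the sequence column; lookup first
    tries the id verbatim, then with that suffix stripped.  A transcript id
    absent from the FASTA is logged and skipped, never fatal.
    """
    if not Path(sample.fasta_path).is_file():
        raise FileNotFoundError(f"FASTA not found for {sample.species}: {sample.fasta_path}")
    index = _index_fasta(Path(sample.fasta_path))
    out: dict[str, str] = {}
    for busco_id, value in selection.items():
        sequence_id = value[0] if isinstance(value, tuple) else value
        seq = index.get(sequence_id)
        if seq is None:
            stripped = _COORD_SUFFIX.sub("", sequence_id)
            if stripped != sequence_id:
                seq = index.get(stripped)
        if seq is None:
            logger.warning(
                "species %s: transcript %s for locus %s not found in %s; skipped",
                sample.species, sequence_id, busco_id, sample.fasta_path,
            )
            continue
        out[busco_id] = seq
    return out


def bin_by_locus(per_species: Mapping[str, Mapping[str, str]]) -> list[LocusBin]:
    """Regroup species->locus->sequence into per-locus bins.

    Bins are sorted by BUSCO id and records within a bin by species label, so
    output order is deterministic.
    """
    if len(set(per_species)) != len(per_species):
        raise ValueError("species labels must be unique")
    grouped: dict[str, dict[str, str]] = {}
    for species in sorted(per_species):
        for busco_id, seq in per_species[species].items():
            grouped.setdefault(busco_id, {})[species] = seq
    return [
        LocusBin(busco_id=busco_id, records=dict(sorted(grouped[busco_id].items())))
        for busco_id in sorted(grouped)
    ]


def write_locus_bins(bins: Iterable[LocusBin], out_dir: str | Path) -> list[Path]:
    """Write one ``<busco_id>.fasta`` per bin; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for locus_bin in bins:
        records = [
            SeqRecord(Seq(seq), id=species, description="")
            for species, seq in locus_bin.records.items()
        ]
        path = out_dir / f"{locus_bin.busco_id}.fasta"
        SeqIO.write(records, str(path), "fasta")
        paths.append(path)
    return paths


def read_locus_bin(path: str | Path) -> LocusBin:
    """Read a per-locus FASTA back into a :class:`LocusBin`."""
    path = Path(path)
    records: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in records:
            raise ValueError(f"{path}: duplicate taxon {record.id}")
        records[record.id] = str(record.seq)
    return LocusBin(busco_id=path.stem, records=records)


def fetch_cdna(
    taxon_query: str,
    out_dir: str | Path,
    transport: Callable[[str], Mapping[str, list[tuple[str, str]]]],
) -> list[SpeciesSample]:
    """Fetch cDNA/TSA records for a taxon and write one FASTA per species.

    ``transport`` is any callable mapping the query to
    ``{genus_species: [(record_id, sequence), ...]}`` — a real NCBI E-utilities
    client or an injected stub.  Species with zero records produce no file.
    Transport failures raise :class:`FetchError` naming the query.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        per_species = transport(taxon_query)
    except Exception as exc:
        raise FetchError(f"fetching {taxon_query!r} failed: {exc}") from exc
    samples: list[SpeciesSample] = []
    for species in sorted(per_species):
        records = per_species[species]
        if not records:
            logger.info("query %s: species %s returned no sequences", taxon_query, species)
            continue
        path = out_dir / f"{species}.fasta"
        SeqIO.write(
            [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records],
            str(path),
            "fasta",
        )
        samples.append(SpeciesSample(species=species, fasta_path=path))
    return samples
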
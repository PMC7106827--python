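"""Taxon x locus occupancy states, hierarchical summaries, and filtering.

Every cell is ``complete``, ``fragmented``, or ``missing``.  Duplicated BUSCO
winners count as complete (a best copy was recovered).  Thresholding keeps
taxa first, then loci on the taxon-reduced matrix; reassembly re-aligns the
surviving raw sequences per locus rather than slicing columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from orthoforge.busco_results import BuscoStatus
from orthoforge.errors import OccupancyError
from orthoforge.harvest import LocusBin, read_locus_bin
from orthoforge.alignment_io import Aligner, align_locus
from orthoforge.supermatrix import Supermatrix, concatenate

__all__ = [
    "COMPLETE",
    "FRAGMENTED",
    "MISSING",
    "OccupancyMatrix",
    "ThresholdSpec",
    "build_occupancy",
    "build_occupancy_from_fasta_dir",
    "read_presence_absence",
    "summarize",
    "apply_thresholds",
    "reassemble",
]

logger = logging.getLogger(__name__)

COMPLETE = "complete"
FRAGMENTED = "fragmented"
MISSING = "missing"
STATES = (COMPLETE, FRAGMENTED, MISSING)

_GAP_CHARS = set("-?")


@dataclass
class OccupancyMatrix:
    """States for every taxon x locus cell.

    ``states`` is a pandas DataFrame indexed by taxon with loci as columns and
    values drawn from :data:`STATES`.
    """

    states: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.states.values.ravel()) - set(STATES)
        if bad:
            raise OccupancyError(f"invalid occupancy states {sorted(bad)}")
        if self.states.index.duplicated().any() or self.states.columns.duplicated().any():
            raise OccupancyError("duplicate taxon or locus labels")

    @property
    def taxa(self) -> list[str]:
        return list(self.states.index)

    @property
    def loci(self) -> list[str]:
        return list(self.states.columns)

    def present_counts(self, count_fragmented_as_present: bool = True) -> pd.Series:
        """Per-taxon count of present loci."""
        present = self.states == COMPLETE
        if count_fragmented_as_present:
            present |= self.states == FRAGMENTED
        return present.sum(axis=1)

    def missing_fraction(self) -> float:
        return float((self.states == MISSING).values.mean())

    def to_csv(self, dest: str | Path) -> None:
        self.states.to_csv(dest, index_label="taxon")

    @classmethod
    def from_csv(cls, src: str | Path) -> "OccupancyMatrix":
        return cls(pd.read_csv(src, index_col="taxon"))


@dataclass(frozen=True)
class ThresholdSpec:
    """Minimum occupancy requirements for keeping taxa and loci."""

    min_loci_per_taxon: int = 0
    min_taxa_per_locus: int = 0
    count_fragmented_as_present: bool = True

    def __post_init__(self) -> None:
        if self.min_loci_per_taxon < 0 or self.min_taxa_per_locus < 0:
            raise ValueError("thresholds must be non-negative")


def _status_of(value) -> BuscoStatus:
    status = value[1] if isinstance(value, tuple) else value
    if isinstance(status, str):
        status = BuscoStatus.from_string(status)
    return status


def build_occupancy(
    selections: Mapping[str, Mapping[str, object]],
    locus_universe: Sequence[str],
) -> OccupancyMatrix:
    """Build the matrix from per-species best-hit selections.

    ``selections`` maps species to ``{busco_id: (sequence_id, status)}`` (or to
    a bare status).  Complete and Duplicated winners are complete cells,
    Fragmented winners fragmented, everything else missing.  A selected locus
    outside ``locus_universe`` is an error.
    """
    loci = list(locus_universe)
    if len(set(loci)) != len(loci):
        raise OccupancyError("locus universe contains duplicates")
    universe = set(loci)
    rows = {}
    for species in sorted(selections):
        row = dict.fromkeys(loci, MISSING)
        for busco_id, value in selections[species].items():
            if busco_id not in universe:
                raise OccupancyError(
                    f"species {species}: selected locus {busco_id} outside the universe"
                )
            status = _status_of(value)
            if status in (BuscoStatus.COMPLETE, BuscoStatus.DUPLICATED):
                row[busco_id] = COMPLETE
            elif status is BuscoStatus.FRAGMENTED:
                row[busco_id] = FRAGMENTED
        rows[species] = row
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=loci)
    frame = frame.fillna(MISSING)
    return OccupancyMatrix(frame)


def build_occupancy_from_fasta_dir(
    fasta_dir: str | Path, taxa: Sequence[str] | None = None
) -> OccupancyMatrix:
    """Two-state occupancy from a directory of per-locus FASTA files.

    Works for any marker set (AHE, UCE, ...): each file is one locus, record
    ids are taxon labels.  A taxon is complete at a locus iff its record has
    at least one non-gap character; this mode never assigns ``fragmented``.
    """
    fasta_dir = Path(fasta_dir)
    files = sorted(
        p for p in fasta_dir.iterdir()
        if p.suffix.lower() in (".fasta", ".fa", ".fas", ".fna")
    ) if fasta_dir.is_dir() else []
    if not files:
        raise OccupancyError(f"no FASTA files found in {fasta_dir}")
    per_locus: dict[str, set[str]] = {}
    seen_taxa: set[str] = set()
    for path in files:
        locus_bin = read_locus_bin(path)  # raises on duplicate taxon
        present = {
            taxon for taxon, seq in locus_bin.records.items()
            if any(ch not in _GAP_CHARS for ch in seq)
        }
        per_locus[path.stem] = present
        seen_taxa.update(locus_bin.records)
    taxa_list = list(taxa) if taxa is not None else sorted(seen_taxa)
    frame = pd.DataFrame(
        {
            locus: [COMPLETE if t in present else MISSING for t in taxa_list]
            for locus, present in per_locus.items()
        },
        index=taxa_list,
    )
    return OccupancyMatrix(frame)


def read_presence_absence(
    delimited_text: str,
    present_tokens: Iterable[str] = ("1", "present", "TRUE", "True", "true"),
    absent_tokens: Iterable[str] = ("0", "absent", "FALSE", "False", "false"),
    delimiter: str = ",",
) -> OccupancyMatrix:
    """Two-state occupancy from any delimited presence/absence table.

    First row holds column (locus/character) labels, first column row (taxon)
    labels.  Accepts behavioural/phenotypic/expression tables alike; any token
    outside both sets is an error naming the offending cell.
    """
    present = set(present_tokens)
    absent = set(absent_tokens)
    lines = [ln for ln in delimited_text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise OccupancyError("presence/absence table needs a header and at least one row")
    header = [c.strip() for c in lines[0].split(delimiter)]
    loci = header[1:]
    ncols = len(header)
    rows = {}
    for raw in lines[1:]:
        cells = [c.strip() for c in raw.split(delimiter)]
        if len(cells) != ncols:
            raise OccupancyError(
                f"ragged row for {cells[0]!r}: {len(cells)} cells, expected {ncols}"
            )
        taxon = cells[0]
        states = []
        for locus, token in zip(loci, cells[1:]):
            if token in present:
                states.append(COMPLETE)
            elif token in absent:
                states.append(MISSING)
            else:
                raise OccupancyError(f"unmapped token {token!r} at ({taxon}, {locus})")
        rows[taxon] = states
    return OccupancyMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=loci))


def summarize(
    occ: OccupancyMatrix, grouping: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Long-format state counts/percentages per taxon, per locus, per group.

    Columns: ``level`` (taxon/locus/group), ``label``, ``state``, ``count``,
    ``percent``.  ``grouping`` (e.g. a taxonomy level) must cover every taxon.
    """
    if grouping is not None:
        missing_taxa = [t for t in occ.taxa if t not in grouping]
        if missing_taxa:
            raise OccupancyError(f"grouping does not cover taxa {missing_taxa}")
    records = []

    def emit(level: str, label: str, cells: pd.Series) -> None:
        total = len(cells)
        counts = cells.value_counts()
        for state in STATES:
            count = int(counts.get(state, 0))
            records.append(
                {
                    "level": level,
                    "label": label,
                    "state": state,
                    "count": count,
                    "percent": 100.0 * count / total,
                }
            )

    for taxon in occ.taxa:
        emit("taxon", taxon, occ.states.loc[taxon])
    for locus in occ.loci:
        emit("locus", locus, occ.states[locus])
    if grouping is not None:
        for group in sorted(set(grouping[t] for t in occ.taxa)):
            members = [t for t in occ.taxa if grouping[t] == group]
            emit("group", group, occ.states.loc[members].stack())
    return pd.DataFrame.from_records(
        records, columns=["level", "label", "state", "count", "percent"]
    )


def apply_thresholds(
    occ: OccupancyMatrix, spec: ThresholdSpec
) -> tuple[list[str], list[str]]:
    """Keep taxa with enough present loci, then loci with enough kept taxa.

    Present means complete, plus fragmented when
    ``spec.count_fragmented_as_present``.  Locus counts are evaluated on the
    taxon-filtered matrix.  Deterministic: output order follows the input.
    """
    present = occ.states == COMPLETE
    if spec.count_fragmented_as_present:
        present |= occ.states == FRAGMENTED
    taxon_counts = present.sum(axis=1)
    kept_taxa = [t for t in occ.taxa if taxon_counts[t] >= spec.min_loci_per_taxon]
    reduced = present.loc[kept_taxa]
    locus_counts = reduced.sum(axis=0)
    kept_loci = [l for l in occ.loci if locus_counts[l] >= spec.min_taxa_per_locus]
    return kept_taxa, kept_loci


def reassemble(
    kept_taxa: Sequence[str],
    kept_loci: Sequence[str],
    locus_bins: Mapping[str, LocusBin],
    aligner: Aligner | None = None,
) -> Supermatrix:
    """Re-align each surviving locus from raw sequences and re-concatenate.

    Loci reduced to zero surviving taxa are dropped with a warning; a
    single-taxon locus survives as an aligner pass-through row.  The partition
    scheme is regenerated from the new locus lengths.
    """
    kept_taxa_set = set(kept_taxa)
    alignments = []
    for locus in kept_loci:
        if locus not in locus_bins:
            raise OccupancyError(f"no sequence bin available for kept locus {locus}")
        source = locus_bins[locus]
        surviving = {
            taxon: seq for taxon, seq in source.records.items() if taxon in kept_taxa_set
        }
        if not surviving:
            logger.warning("locus %s: no surviving taxa after filtering; dropped", locus)
            continue
        alignments.append(align_locus(LocusBin(locus, surviving), aligner))
    if not alignments:
        raise OccupancyError("no loci survived filtering; nothing to reassemble")
    return concatenate(alignments)
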
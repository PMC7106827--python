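"""Synthetic transcriptome fixtures with planted ortholog ground truth.

Generates per-species FASTA transcriptomes plus emulated BUSCO v3 full tables
that are mutually consistent with a planted species x locus truth table
(Complete / Duplicated / Fragmented / Missing, with controlled score ties,
reverse-complemented transcripts, and decoy contigs).  Everything is driven by
one seed and is byte-reproducible, so the full pipeline can be tested end to
end without BUSCO, MAFFT, or network access.

Ortholog transcripts for a locus are light mutations of a shared master
sequence, so real aligners also produce sensible alignments; decoys are
independent random sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from orthoforge.errors import FixtureError
from orthoforge.busco_results import BuscoStatus
from orthoforge.occupancy import COMPLETE, FRAGMENTED, MISSING, OccupancyMatrix
from orthoforge.supermatrix import MISSING_CHAR, Supermatrix

__all__ = ["FixtureSpec", "TruthEntry", "FixtureBundle", "generate_fixture",
           "planted_truth_check"]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for one synthetic dataset; ``seed`` fixes all randomness."""

    n_species: int = 4
    n_loci: int = 20
    locus_length_range: tuple[int, int] = (300, 900)
    p_missing: float = 0.2
    p_fragment: float = 0.1
    fragment_length_fraction_range: tuple[float, float] = (0.3, 0.7)
    p_duplicate: float = 0.1
    p_reverse_complement: float = 0.1
    n_decoy_transcripts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_loci < 1:
            raise FixtureError("n_species and n_loci must be positive")
        for name in ("p_missing", "p_fragment", "p_duplicate", "p_reverse_complement"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise FixtureError(f"{name}={p} outside [0, 1]")
        lo, hi = self.locus_length_range
        if not 1 <= lo <= hi:
            raise FixtureError(f"bad locus_length_range {self.locus_length_range}")
        flo, fhi = self.fragment_length_fraction_range
        if not 0.0 < flo <= fhi <= 1.0:
            raise FixtureError(
                f"bad fragment_length_fraction_range {self.fragment_length_fraction_range}"
            )
        if self.n_decoy_transcripts < 0:
            raise FixtureError("n_decoy_transcripts must be non-negative")


@dataclass(frozen=True)
class TruthEntry:
    """Planted outcome for one (species, locus) cell."""

    state: str                      # complete | fragmented | missing
    busco_status: str | None        # Complete | Duplicated | Fragmented | None
    transcript_id: str | None       # expected winning transcript
    is_tie: bool = False            # equal-score duplicate pair planted


@dataclass
class FixtureBundle:
    """Everything a test needs: file locations plus the planted truth."""

    spec: FixtureSpec
    out_dir: Path
    species: list[str]
    loci: list[str]
    fasta_paths: dict[str, Path] = field(default_factory=dict)
    table_paths: dict[str, Path] = field(default_factory=dict)
    truth: dict[tuple[str, str], TruthEntry] = field(default_factory=dict)
    truth_path: Path | None = None

    def expected_selection(self, species: str) -> dict[str, tuple[str, BuscoStatus]]:
        out = {}
        for locus in self.loci:
            entry = self.truth[(species, locus)]
            if entry.transcript_id is not None:
                out[locus] = (entry.transcript_id, BuscoStatus.from_string(entry.busco_status))
        return out

    def expected_state(self, species: str, locus: str) -> str:
        return self.truth[(species, locus)].state


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float = 0.03) -> str:
    chars = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        chars[i] = _BASES[(np.flatnonzero(_BASES == chars[i])[0] + rng.integers(1, 4)) % 4]
    return "".join(chars)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureBundle:
    """Write the synthetic dataset under ``out_dir`` and return its truth.

    Layout: ``fasta/<genus_species>.fasta``, ``busco/run_<sp>/full_table_<sp>.tsv``
    and ``ground_truth.tsv``.  Planted guarantees: every Duplicated locus has
    at least two table rows for that species; tie rows carry equal scores and
    distinct transcripts with the planted winner first; non-tie duplicate
    winners have strictly the highest score regardless of row order.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    fasta_dir = out_dir / "fasta"
    busco_dir = out_dir / "busco"
    fasta_dir.mkdir(parents=True, exist_ok=True)
    busco_dir.mkdir(parents=True, exist_ok=True)

    species = [f"Genus{i:02d}_species{i:02d}" for i in range(spec.n_species)]
    loci = [f"EOG9TEST{i:04d}" for i in range(spec.n_loci)]
    lo, hi = spec.locus_length_range
    masters = {locus: _random_seq(rng, int(rng.integers(lo, hi + 1))) for locus in loci}

    bundle = FixtureBundle(spec=spec, out_dir=out_dir, species=species, loci=loci)

    for sp in species:
        transcript_counter = 0
        fasta_records: list[tuple[str, str]] = []    # (id, sequence as written)
        table_rows: list[str] = []

        def new_id() -> str:
            nonlocal transcript_counter
            transcript_counter += 1
            return f"{sp}_tr{transcript_counter:04d}"

        for locus in loci:
            if rng.random() < spec.p_missing:
                table_rows.append(f"{locus}\tMissing")
                bundle.truth[(sp, locus)] = TruthEntry(MISSING, None, None)
                continue

            base = _mutate(rng, masters[locus])
            fragmented = rng.random() < spec.p_fragment
            if fragmented:
                flo, fhi = spec.fragment_length_fraction_range
                frac = rng.uniform(flo, fhi)
                width = max(1, int(round(frac * len(base))))
                start = int(rng.integers(0, len(base) - width + 1))
                base = base[start:start + width]

            winner_id = new_id()
            winner_score = round(float(rng.uniform(200.0, 1500.0)), 1)
            duplicated = (not fragmented) and rng.random() < spec.p_duplicate
            status = (
                BuscoStatus.FRAGMENTED if fragmented
                else BuscoStatus.DUPLICATED if duplicated
                else BuscoStatus.COMPLETE
            )
            winner_row = (
                f"{locus}\t{status.value}\t{winner_id}\t{winner_score}\t{len(base)}"
            )

            written = reverse_complement(base) if rng.random() < spec.p_reverse_complement else base
            fasta_records.append((winner_id, written))

            if duplicated:
                extra = _mutate(rng, base, rate=0.05)
                extra_id = new_id()
                tie = bool(rng.random() < 0.5)
                if tie:
                    extra_score = winner_score
                    rows = [winner_row,
                            f"{locus}\t{status.value}\t{extra_id}\t{extra_score}\t{len(extra)}"]
                else:
                    extra_score = round(winner_score - float(rng.uniform(1.0, 50.0)), 1)
                    rows = [f"{locus}\t{status.value}\t{extra_id}\t{extra_score}\t{len(extra)}",
                            winner_row]
                    if rng.random() < 0.5:
                        rows.reverse()
                table_rows.extend(rows)
                extra_written = (
                    reverse_complement(extra)
                    if rng.random() < spec.p_reverse_complement else extra
                )
                fasta_records.append((extra_id, extra_written))
                bundle.truth[(sp, locus)] = TruthEntry(
                    COMPLETE, status.value, winner_id, is_tie=tie
                )
            else:
                table_rows.append(winner_row)
                bundle.truth[(sp, locus)] = TruthEntry(
                    FRAGMENTED if fragmented else COMPLETE, status.value, winner_id
                )

        for _ in range(spec.n_decoy_transcripts):
            fasta_records.append((new_id(), _random_seq(rng, int(rng.integers(100, 401)))))

        fasta_path = fasta_dir / f"{sp}.fasta"
        with open(fasta_path, "w") as handle:
            for rid, seq in fasta_records:
                handle.write(f">{rid}\n{seq}\n")
        bundle.fasta_paths[sp] = fasta_path

        run_dir = busco_dir / f"run_{sp}"
        run_dir.mkdir(parents=True, exist_ok=True)
        table_path = run_dir / f"full_table_{sp}.tsv"
        header = "# Busco id\tStatus\tSequence\tScore\tLength\n"
        table_path.write_text(header + "\n".join(table_rows) + "\n")
        bundle.table_paths[sp] = table_path

    truth_path = out_dir / "ground_truth.tsv"
    with open(truth_path, "w") as handle:
        handle.write("species\tbusco_id\tstate\tbusco_status\ttranscript_id\tis_tie\n")
        for sp in species:
            for locus in loci:
                entry = bundle.truth[(sp, locus)]
                handle.write(
                    f"{sp}\t{locus}\t{entry.state}\t{entry.busco_status or ''}\t"
                    f"{entry.transcript_id or ''}\t{int(entry.is_tie)}\n"
                )
    bundle.truth_path = truth_path
    return bundle


def planted_truth_check(
    bundle: FixtureBundle,
    selections: Mapping[str, Mapping[str, tuple]] | None = None,
    occupancy: OccupancyMatrix | None = None,
    supermatrix: Supermatrix | None = None,
) -> tuple[bool, list[str]]:
    """Compare pipeline outputs against the planted truth.

    Checks whichever of ``selections`` (species -> locus -> (transcript,
    status)), ``occupancy`` and ``supermatrix`` are supplied.  Supermatrix
    membership is judged by whether a taxon's slice at a locus partition is
    entirely the missing filler.  Returns ``(ok, diffs)`` where every
    mismatching (species, locus) is named.
    """
    diffs: list[str] = []

    if selections is not None:
        for sp in bundle.species:
            got = selections.get(sp, {})
            expected = bundle.expected_selection(sp)
            for locus in bundle.loci:
                exp = expected.get(locus)
                act = got.get(locus)
                if act is not None and not isinstance(act, tuple):
                    act = (act, None)
                if exp is None and act is not None:
                    diffs.append(f"selection {sp}/{locus}: expected nothing, got {act[0]}")
                elif exp is not None and act is None:
                    diffs.append(f"selection {sp}/{locus}: expected {exp[0]}, got nothing")
                elif exp is not None and act is not None:
                    if act[0] != exp[0]:
                        diffs.append(
                            f"selection {sp}/{locus}: expected {exp[0]}, got {act[0]}"
                        )
                    elif act[1] is not None and act[1] != exp[1]:
                        diffs.append(
                            f"selection {sp}/{locus}: status {act[1]} != {exp[1]}"
                        )

    if occupancy is not None:
        for sp in bundle.species:
            for locus in bundle.loci:
                expected_state = bundle.expected_state(sp, locus)
                if sp not in occupancy.taxa or locus not in occupancy.loci:
                    diffs.append(f"occupancy {sp}/{locus}: cell absent from matrix")
                    continue
                actual = occupancy.states.loc[sp, locus]
                if actual != expected_state:
                    diffs.append(
                        f"occupancy {sp}/{locus}: expected {expected_state}, got {actual}"
                    )

    if supermatrix is not None:
        ranges = {name: (start, end) for name, start, end in supermatrix.partitions.entries}
        for sp in bundle.species:
            row = supermatrix.matrix.get(sp)
            for locus in bundle.loci:
                expected_present = bundle.expected_state(sp, locus) != MISSING
                if locus not in ranges:
                    if expected_present:
                        diffs.append(f"supermatrix {sp}/{locus}: locus absent from partitions")
                    continue
                start, end = ranges[locus]
                cell = row[start - 1:end] if row is not None else ""
                actually_present = any(ch != MISSING_CHAR for ch in cell)
                if actually_present != expected_present:
                    diffs.append(
                        f"supermatrix {sp}/{locus}: expected "
                        f"{'present' if expected_present else 'filler'}, got "
                        f"{'present' if actually_present else 'filler'}"
                    )

    return (not diffs, diffs)
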
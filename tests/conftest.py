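"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import random

import pytest

from orthoforge.busco_results import BuscoHit, BuscoStatus
from orthoforge.fixtures import FixtureSpec, generate_fixture


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never share code with the package)

def brute_force_select(hits, keep_fragmented=True, min_fragment_length=0):
    """Group by busco_id; drop Missing; filter fragments; argmax score with
    lowest-index tie-break."""
    groups = {}
    for index, hit in enumerate(hits):
        if hit.status is BuscoStatus.MISSING:
            continue
        if hit.status is BuscoStatus.FRAGMENTED:
            if not keep_fragmented or hit.length < min_fragment_length:
                continue
        groups.setdefault(hit.busco_id, []).append((index, hit))
    out = {}
    for busco_id, members in groups.items():
        best_index, best = members[0]
        for index, hit in members[1:]:
            if hit.score > best.score or (hit.score == best.score and index < best_index):
                best_index, best = index, hit
        out[busco_id] = (best.sequence_id, best.status)
    return out


def brute_force_thresholds(states, min_loci_per_taxon, min_taxa_per_locus,
                           count_fragmented=True):
    """states: dict[(taxon, locus)] -> state string; returns (taxa, loci) lists
    in input label order."""
    taxa = sorted({t for t, _ in states}, key=lambda t: str(t))
    loci = sorted({l for _, l in states}, key=lambda l: str(l))
    present_values = {"complete", "fragmented"} if count_fragmented else {"complete"}

    def present(t, l):
        return states[(t, l)] in present_values

    kept_taxa = [t for t in taxa
                 if sum(present(t, l) for l in loci) >= min_loci_per_taxon]
    kept_loci = [l for l in loci
                 if sum(present(t, l) for t in kept_taxa) >= min_taxa_per_locus]
    return kept_taxa, kept_loci


def brute_force_intersections(entries):
    """entries: dict[locus] -> set of categories.  Enumerate every possible
    combination over the full category vocabulary and count exact matches."""
    from itertools import combinations

    vocabulary = sorted({c for cats in entries.values() for c in cats})
    exclusive = {}
    for degree in range(1, len(vocabulary) + 1):
        for combo in combinations(vocabulary, degree):
            count = sum(1 for cats in entries.values() if cats == set(combo))
            if count:
                exclusive[frozenset(combo)] = count
    set_sizes = {
        c: sum(1 for cats in entries.values() if c in cats) for c in vocabulary
    }
    set_sizes = {c: n for c, n in set_sizes.items() if n}
    unannotated = sum(1 for cats in entries.values() if not cats)
    return exclusive, set_sizes, unannotated


def random_hits(rng: random.Random, n_loci=8, max_rows_per_locus=4):
    """Random full-table hit list with duplicates, ties, fragments, missing."""
    hits = []
    for i in range(n_loci):
        busco_id = f"L{i:03d}"
        kind = rng.random()
        if kind < 0.2:
            hits.append(BuscoHit(busco_id, BuscoStatus.MISSING))
            continue
        n_rows = rng.randint(1, max_rows_per_locus)
        status = (
            BuscoStatus.DUPLICATED if n_rows > 1
            else rng.choice([BuscoStatus.COMPLETE, BuscoStatus.FRAGMENTED])
        )
        scores = [round(rng.choice([100.0, 250.0, 250.0, 400.0, 875.5]), 1)
                  for _ in range(n_rows)]
        for j in range(n_rows):
            row_status = BuscoStatus.FRAGMENTED if (
                status is BuscoStatus.DUPLICATED and rng.random() < 0.15
            ) else status
            hits.append(BuscoHit(busco_id, row_status, f"tr_{i}_{j}", scores[j],
                                 rng.randint(50, 1500)))
    rng.shuffle(hits)
    return hits


# ---------------------------------------------------------------------------
# shared pipeline fixture

@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    spec = FixtureSpec(n_species=5, n_loci=30, p_missing=0.3, p_fragment=0.15,
                       p_duplicate=0.2, p_reverse_complement=0.2, seed=11)
    return generate_fixture(spec, tmp_path_factory.mktemp("fixture"))


def run_pipeline(bundle, aligner=None):
    """Fixture bundle -> (selections, occupancy, supermatrix) via the package."""
    from orthoforge import (
        PadAligner, align_locus, bin_by_locus, build_occupancy, concatenate,
        extract_sequences,
    )
    from orthoforge.busco_results import selections_by_species
    from orthoforge.harvest import SpeciesSample

    selections = selections_by_species(bundle.table_paths)
    per_species = {
        sp: extract_sequences(SpeciesSample(sp, bundle.fasta_paths[sp]), sel)
        for sp, sel in selections.items()
    }
    bins = bin_by_locus(per_species)
    aligner = aligner or PadAligner()
    alignments = [align_locus(b, aligner) for b in bins]
    supermatrix = concatenate(alignments)
    occupancy = build_occupancy(selections, bundle.loci)
    return selections, occupancy, supermatrix
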
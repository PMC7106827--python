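# orthoforge

Assemble phylogenetics-ready supermatrices of BUSCO single-copy orthologs
from per-species transcriptome FASTA files.

Given per-species transcriptomes (`genus_species.fasta`) and their BUSCO v3
`full_table` results, orthoforge:

- resolves each species' hits to one winning transcript per BUSCO locus
  (duplicates by best score, equal scores by first table row; fragmented hits
  kept or dropped under a length-threshold policy),
- extracts the winning sequences and bins them into per-locus FASTA files,
- aligns each locus (external MAFFT with `--adjustdirection` for same-strand
  orientation, or a deterministic built-in test backend),
- concatenates the loci into a relaxed-phylip supermatrix with a nexus
  `charset` partition file readable by IQ-TREE,
- quantifies complete / fragmented / missing occupancy per taxon x locus,
  summarizes it at user-defined hierarchical levels, applies occupancy
  thresholds, and reassembles a filtered supermatrix by re-aligning each
  surviving locus,
- maps loci to GO categories and emits upset-style intersection counts and
  per-sample relative-percent-sampled tables.

Occupancy also works on any per-locus FASTA directory (AHE, UCE, ...) and on
arbitrary delimited presence/absence tables. A synthetic-fixture generator
plants known ortholog structure (missingness, fragmentation, duplication with
score ties, reverse-complemented transcripts, decoys) with matching emulated
BUSCO tables, so the whole pipeline is testable offline.

## CLI

Stages share one work directory and compose in order; every stage appends a
record to `<workdir>/manifest.jsonl`.

```sh
# synthetic demo data with known ground truth
orthoforge fixture --out demo --n-species 6 --n-loci 40 --seed 1

orthoforge parse    --busco-dir demo/busco --workdir work
orthoforge harvest  --fasta-dir demo/fasta --workdir work
orthoforge align    --backend mafft --workdir work     # or --backend pad
orthoforge concat   --workdir work                     # supermatrix.phy + partitions.nex

orthoforge occupancy --workdir work                    # occupancy.csv + summary
orthoforge filter    --workdir work --min-loci-per-taxon 20
orthoforge reassemble --backend mafft --workdir work   # filtered supermatrix

orthoforge goterms  --workdir work --mapping go_map.tsv
```

`orthoforge occupancy --fasta-dir <dir>` computes occupancy for any per-locus
FASTA directory; `--presence-absence <table>` reads a delimited 0/1 table.
`orthoforge fetch` writes per-species FASTAs from a pre-fetched JSON record
set (live database fetching is deliberately not bundled); `orthoforge
busco-run` drives an external BUSCO v3 installation when present.

## Library

```python
from orthoforge import (
    parse_full_table, select_best_hits, SelectionPolicy,
    extract_sequences, bin_by_locus, align_locus, MafftAligner,
    concatenate, write_partition_nexus,
    build_occupancy, apply_thresholds, ThresholdSpec, reassemble,
    load_go_mapping, intersection_counts, relative_percent_sampled,
)
```

## Conventions

- Partition coordinates are 1-based inclusive; charset names are sanitized to
  `[A-Za-z0-9_]`.
- Missing taxon/locus cells are filled with `?`, distinct from alignment gaps
  `-`.
- Relaxed phylip is sequential, unwrapped, single-space separated, with
  unrestricted name lengths.
- Fragment length thresholds are inclusive (`length >= min_fragment_length`).
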
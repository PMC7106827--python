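"""GO-category mapping for BUSCO loci: intersections and sampling percentages.

Categories come from a user-supplied two-column table (busco_id, category);
no online GO/OrthoDB lookup happens here.  The exclusive intersection counts
are the upset-plot numbers: every annotated locus contributes to exactly one
combination — its full category set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from orthoforge.errors import AnnotationError
from orthoforge.occupancy import COMPLETE, FRAGMENTED, OccupancyMatrix

__all__ = [
    "GoMapping",
    "IntersectionCounts",
    "load_go_mapping",
    "intersection_counts",
    "relative_percent_sampled",
]

logger = logging.getLogger(__name__)


@dataclass
class GoMapping:
    """busco_id -> set of GO category labels (possibly empty)."""

    entries: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for busco_id, categories in self.entries.items():
            if any(not c for c in categories):
                raise AnnotationError(f"{busco_id}: empty category label")

    @property
    def categories(self) -> list[str]:
        out: set[str] = set()
        for cats in self.entries.values():
            out.update(cats)
        return sorted(out)

    def loci_in(self, category: str) -> set[str]:
        return {b for b, cats in self.entries.items() if category in cats}


@dataclass
class IntersectionCounts:
    """Upset-style summary of a :class:`GoMapping`.

    ``exclusive`` counts loci per exact category combination (a partition of
    the annotated loci); ``set_sizes`` are the ordinary per-category totals;
    ``n_unannotated`` counts loci with no category at all.
    """

    exclusive: dict[frozenset, int]
    set_sizes: dict[str, int]
    n_unannotated: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"combination": "+".join(sorted(combo)), "degree": len(combo), "count": count}
            for combo, count in self.exclusive.items()
        ]
        frame = pd.DataFrame(rows, columns=["combination", "degree", "count"])
        return frame.sort_values(
            ["count", "combination"], ascending=[False, True], ignore_index=True
        )

    def set_sizes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.set_sizes.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["category", "n_loci"],
        )


def load_go_mapping(delimited_text: str, delimiter: str | None = None) -> GoMapping:
    """Parse a two-column (busco_id, category) table; repeated ids union.

    The delimiter is sniffed (tab, then comma) unless given.  Rows with any
    other column count raise :class:`AnnotationError` with the line number.
    """
    entries: dict[str, set[str]] = {}
    for lineno, raw in enumerate(delimited_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        sep = delimiter
        if sep is None:
            sep = "\t" if "\t" in line else ","
        fields = [f.strip() for f in line.split(sep)]
        if len(fields) != 2:
            raise AnnotationError(
                f"line {lineno}: expected 2 columns (busco_id, category), got {len(fields)}"
            )
        busco_id, category = fields
        if not busco_id or not category:
            raise AnnotationError(f"line {lineno}: empty busco_id or category")
        entries.setdefault(busco_id, set()).add(category)
    return GoMapping(entries)


def intersection_counts(mapping: GoMapping) -> IntersectionCounts:
    """Count loci per exclusive category combination and per category.

    The exclusive counts sum to the number of annotated loci (those with at
    least one category); uncategorized loci are reported separately.
    """
    exclusive: dict[frozenset, int] = {}
    set_sizes: dict[str, int] = {}
    n_unannotated = 0
    for busco_id, categories in mapping.entries.items():
        if not categories:
            n_unannotated += 1
            continue
        combo = frozenset(categories)
        exclusive[combo] = exclusive.get(combo, 0) + 1
        for category in categories:
            set_sizes[category] = set_sizes.get(category, 0) + 1
    return IntersectionCounts(exclusive, set_sizes, n_unannotated)


def relative_percent_sampled(
    mapping: GoMapping,
    occ: OccupancyMatrix,
    count_fragmented_as_present: bool = True,
) -> pd.DataFrame:
    """Per sample/taxon x category: percent of the category's loci present.

    The category total is the number of the matrix's loci carrying that
    category; the numerator counts those present for the taxon.  Categories
    with zero loci in the matrix are excluded with a warning.  Returns a long
    DataFrame (taxon, category, n_present, n_total, percent).
    """
    present_states = {COMPLETE, FRAGMENTED} if count_fragmented_as_present else {COMPLETE}
    matrix_loci = set(occ.loci)
    records = []
    for category in mapping.categories:
        members = sorted(mapping.loci_in(category) & matrix_loci)
        if not members:
            logger.warning("category %s has no loci in the occupancy matrix; excluded",
                           category)
            continue
        for taxon in occ.taxa:
            row = occ.states.loc[taxon, members]
            n_present = int(row.isin(present_states).sum())
            records.append(
                {
                    "taxon": taxon,
                    "category": category,
                    "n_present": n_present,
                    "n_total": len(members),
                    "percent": 100.0 * n_present / len(members),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["taxon", "category", "n_present", "n_total", "percent"]
    )
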
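"""Edge-list comparison arithmetic between a predicted network and a reference.

The report mirrors the published comparison table: the query's number of
unique undirected pairs, the overlap with the reference, the
unique-to-overlap ratio, and the proportion of the reference recovered.
Two overlap conventions are emitted:

* ``intersect_count`` — *record-level*: every reference record (in the
  reference's native, possibly directed, representation) whose undirected
  form is among the query's unique pairs is counted.  A reference that
  lists each pair in both orientations therefore counts double — exactly
  the arithmetic behind the published table's self-comparison row (ratio
  0.50, proportion 2.00).
* ``intersect_unique`` — both sides normalized to undirected unique pairs;
  the recommended convention (self-comparison gives ratio 1, proportion 1).
"""

from __future__ import annotations

from dataclasses import dataclass

from ppinet.io import EdgeSet


@dataclass(frozen=True)
class ComparisonReport:
    query_unique: int
    reference_unique: int
    intersect_count: int
    intersect_unique: int
    unique_intersect_ratio: float  # query_unique / intersect_count; NaN when overlap 0
    reference_proportion: float  # intersect_count / reference_unique
    unique_intersect_ratio_normalized: float
    reference_proportion_normalized: float

    @property
    def ratio_undefined(self) -> bool:
        return self.intersect_count == 0

    def row(self) -> dict:
        return {
            "query_unique": self.query_unique,
            "reference_unique": self.reference_unique,
            "intersect_count": self.intersect_count,
            "intersect_unique": self.intersect_unique,
            "unique_intersect_ratio": self.unique_intersect_ratio,
            "reference_proportion": self.reference_proportion,
            "unique_intersect_ratio_normalized": self.unique_intersect_ratio_normalized,
            "reference_proportion_normalized": self.reference_proportion_normalized,
        }


def count_intersect(query: EdgeSet, reference: EdgeSet) -> ComparisonReport:
    """Compare a query edge set against a reference edge list.

    ``query`` is reduced to its unique undirected pairs.  The record-level
    overlap counts reference *records* whose undirected form the query
    contains; the normalized overlap counts unique undirected pairs.
    """
    if not reference.records:
        raise ValueError("empty reference edge list")
    query_pairs = query.unique_undirected()
    reference_pairs = reference.unique_undirected()

    intersect_count = sum(
        1 for a, b in reference.records if a != b and _key(a, b) in query_pairs
    )
    intersect_unique = len(query_pairs & reference_pairs)

    nan = float("nan")
    return ComparisonReport(
        query_unique=len(query_pairs),
        reference_unique=len(reference_pairs),
        intersect_count=intersect_count,
        intersect_unique=intersect_unique,
        unique_intersect_ratio=(len(query_pairs) / intersect_count) if intersect_count else nan,
        reference_proportion=intersect_count / len(reference_pairs),
        unique_intersect_ratio_normalized=(
            (len(query_pairs) / intersect_unique) if intersect_unique else nan
        ),
        reference_proportion_normalized=intersect_unique / len(reference_pairs),
    )


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)
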
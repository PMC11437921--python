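"""Cell-type (or any gene-set) overrepresentation by one-sided Fisher
exact tests.

Given a query set of differential proteins, a background of all
quantified proteins and a collection of named marker sets (GMT format),
each set is tested for enrichment with the hypergeometric upper tail
``P(X >= overlap)`` --- identical to the one-sided Fisher exact p on the
2x2 table.  P-values are reported raw (no multiplicity correction
across sets), together with the overlapping identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Set

from scipy.stats import hypergeom


@dataclass
class EnrichmentResult:
    """One marker set's overrepresentation test.

    ``table`` is the 2x2 count tuple (query & set, query \\ set,
    set \\ query, neither), summing to the background size.
    """

    set_name: str
    overlap_ids: list[str]
    table: tuple[int, int, int, int]
    p_value: float

    @property
    def overlap(self) -> int:
        return self.table[0]

    @property
    def set_size(self) -> int:
        return self.table[0] + self.table[2]


def _norm(ids: Iterable[str]) -> Set[str]:
    # duplicate identifiers collapse case-insensitively
    return {str(x).strip().upper() for x in ids if str(x).strip()}


def fisher_enrichment(
    query: Iterable[str],
    background: Iterable[str],
    marker_sets: Dict[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Test each marker set for enrichment of the query within the
    background.

    Marker sets are intersected with the background before testing; the
    query must be a subset of the background.  Returns results sorted by
    p-value (ties by set name).
    """
    q = _norm(query)
    bg = _norm(background)
    if not bg:
        raise ValueError("background is empty")
    stray = q - bg
    if stray:
        raise ValueError(
            f"query contains {len(stray)} identifiers outside the background, e.g. "
            f"{sorted(stray)[:3]}"
        )
    N, n = len(bg), len(q)
    results = []
    for name, members in marker_sets.items():
        s = _norm(members) & bg
        K = len(s)
        overlap = sorted(q & s)
        k = len(overlap)
        # upper-tail hypergeometric: P(X >= k)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        table = (k, n - k, K - k, N - n - K + k)
        results.append(
            EnrichmentResult(
                set_name=name, overlap_ids=overlap, table=table, p_value=min(p, 1.0)
            )
        )
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results
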
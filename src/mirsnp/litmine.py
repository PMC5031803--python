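"""Literature-mining stage: classify disease genes from publication counts.

A gene is called a breast-cancer gene when its publication count reaches
the median count among genes with at least one publication (the Q50
cutoff): setting the cutoff to the median screens out weak literature
associations while remaining inclusive.  Counts arrive as a pre-fetched
two-column TSV; there is no live PubMed access.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "GeneRecord",
    "NoPublicationSignalError",
    "compute_publication_cutoff",
    "classify_cancer_genes",
    "read_publication_counts",
    "write_gene_list",
]


class NoPublicationSignalError(ValueError):
    """No gene has a nonzero publication count."""


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    n_publications: int
    go_terms: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.n_publications < 0:
            raise ValueError(f"{self.symbol}: negative publication count")


def compute_publication_cutoff(records: Iterable[GeneRecord]) -> int:
    """Median publication count over genes with >= 1 publication.

    Zero-count genes are excluded from the median so the cutoff reflects
    the literature-positive universe rather than a zero-dominated one.  An
    even-cardinality median is the mean of the two central values rounded
    half up to an integer, since the cutoff is applied as an integer
    threshold.
    """
    counts = sorted(r.n_publications for r in records if r.n_publications >= 1)
    if not counts:
        raise NoPublicationSignalError(
            "no publication signal: every gene has zero publications"
        )
    n = len(counts)
    if n % 2 == 1:
        return counts[n // 2]
    central = (counts[n // 2 - 1] + counts[n // 2]) / 2
    return int(math.floor(central + 0.5))


def classify_cancer_genes(records: Iterable[GeneRecord], cutoff: int) -> set[str]:
    """Symbols with n_publications >= cutoff (inclusive threshold)."""
    if cutoff < 1:
        raise ValueError(f"cutoff must be >= 1, got {cutoff}")
    return {r.symbol for r in records if r.n_publications >= cutoff}


def read_publication_counts(path) -> list[GeneRecord]:
    """Read ``symbol<TAB>n_publications`` (header required, UTF-8)."""
    records = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[0].lower() not in ("symbol", "gene"):
            raise ValueError(
                "publication-count TSV requires a 'symbol<TAB>n_publications' header"
            )
        for row in reader:
            if not row:
                continue
            symbol = row[0]
            if symbol in seen:
                raise ValueError(f"duplicate gene symbol {symbol!r}")
            seen.add(symbol)
            records.append(GeneRecord(symbol, int(row[1])))
    return records


def write_gene_list(symbols: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sorted(symbols):
            fh.write(s + "\n")
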
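"""Local gene-set over-representation analysis.

A self-contained replacement for web-service enrichment: one-sided
hypergeometric (Fisher exact, "greater") tests of a query gene list
against a GMT library over an explicit background, with BH adjustment
across sets. The background matters — use the interactome node set when
validating subnetworks and the measured protein panel when interpreting
regression hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .association import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class GeneSetLibrary:
    sets: dict[str, set[str]]
    source_tag: str = ""

    def __post_init__(self) -> None:
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentRow:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    background_size: int
    p_raw: float
    p_adj: float
    overlap_genes: list[str]


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Parse a GMT file (name, description, genes...); genes are
    upper-cased and de-duplicated per set; blank lines are skipped."""
    sets: dict[str, set[str]] = {}
    malformed: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                log.warning("%s:%d blank line skipped", path, lineno)
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                malformed.append(lineno)
                continue
            name = parts[0].strip()
            genes = {g.strip().upper() for g in parts[2:] if g.strip()}
            if name in sets:
                raise ValueError(f"duplicate set name {name!r} at line {lineno}")
            if genes:
                sets[name] = genes
    if malformed:
        log.warning("%s: malformed lines skipped: %s", path, malformed[:10])
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return GeneSetLibrary(sets=sets, source_tag=str(path))


def write_gmt(library: GeneSetLibrary | dict, path: str | Path,
              description: str = "na") -> None:
    sets = library.sets if isinstance(library, GeneSetLibrary) else library
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = sorted(set(sets[name]))
            fh.write("\t".join([name, description, *genes]) + "\n")


def enrich(
    query: set[str],
    library: GeneSetLibrary,
    background: set[str],
) -> list[EnrichmentRow]:
    """One-sided hypergeometric enrichment of `query` against every set.

    Sets are intersected with the background before testing; p = P(X >=
    overlap) with X ~ Hypergeometric(N=|background|, K=|set∩background|,
    n=|query|). Rows come back sorted by raw p, ties by set name.
    """
    query = {g.upper() for g in query}
    background = {g.upper() for g in background}
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    stray = query - background
    if stray:
        raise ValueError(f"query genes outside background: {sorted(stray)[:5]}")
    N, n = len(background), len(query)
    rows = []
    for name, genes in library.sets.items():
        inset = {g.upper() for g in genes} & background
        K = len(inset)
        hit = sorted(query & inset)
        k = len(hit)
        # survival function at k-1 gives P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(EnrichmentRow(name, k, K, n, N, min(max(p, 0.0), 1.0),
                                  1.0, hit))
    adj = bh_adjust([r.p_raw for r in rows])
    for r, a in zip(rows, adj):
        r.p_adj = float(a)
    rows.sort(key=lambda r: (r.p_raw, r.set_name))
    return rows


def rows_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.set_name, r.overlap, r.set_size, r.query_size, r.background_size,
          r.p_raw, r.p_adj, ";".join(r.overlap_genes)) for r in rows],
        columns=["set_name", "overlap", "set_size", "query_size",
                 "background_size", "p_raw", "p_adj", "overlap_genes"],
    )


def write_rows(rows: list[EnrichmentRow], path: str | Path) -> None:
    rows_to_frame(rows).to_csv(path, sep="\t", index=False,
                               float_format="%.6g")


__all__ = [
    "GeneSetLibrary",
    "EnrichmentRow",
    "read_gmt",
    "write_gmt",
    "enrich",
    "rows_to_frame",
    "write_rows",
]
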
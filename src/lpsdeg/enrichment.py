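"""Gene-set over-representation analysis against a GMT library.

The statistical core of a pathway-enrichment step: for every set in the
library, the overlap with the query list is scored with the one-sided
Fisher exact test (hypergeometric upper tail) and Benjamini-Hochberg
adjusted across the library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetLibrary:
    sets: dict[str, list[str]]
    background_size: int = 0

    def __post_init__(self) -> None:
        union = set()
        for members in self.sets.values():
            union.update(members)
        if self.background_size < len(union):
            self.background_size = len(union)


@dataclass
class EnrichmentRecord:
    set_name: str
    overlap_size: int
    overlap_genes: list[str] = field(repr=False)
    set_size: int = 0
    p: float = 1.0
    adjusted_p: float = 1.0
    odds_ratio: float = float("nan")


def read_gmt(path) -> GeneSetLibrary:
    """Parse a GMT file (set name, description, members; tab separated)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"malformed GMT line {lineno}: expected at least 3 tab-separated fields"
                )
            name = fields[0]
            members: list[str] = []
            seen = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    warnings.warn(
                        f"duplicate member {g!r} in set {name!r} (line {lineno})"
                    )
                    continue
                seen.add(g)
                members.append(g)
            sets[name] = members
    return GeneSetLibrary(sets=sets)


def write_gmt(library: GeneSetLibrary, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in library.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def enrich(
    query,
    library: GeneSetLibrary,
    background_size: int | None = None,
    background_genes=None,
    drop_unknown: bool = True,
) -> list[EnrichmentRecord]:
    """Over-representation of the query list in every library set.

    p is the hypergeometric upper tail P(X >= overlap) for a draw of
    |query| genes from a background of ``background_size`` containing the
    set.  Records come back sorted by ascending p, ties by set name, with
    BH adjustment over the whole library.
    """
    query = list(dict.fromkeys(str(g) for g in query))
    if not query:
        raise ValueError("query gene list is empty")
    if background_genes is not None:
        background_genes = set(map(str, background_genes))
        unknown = [g for g in query if g not in background_genes]
        if unknown:
            if not drop_unknown:
                raise ValueError(f"query genes absent from background: {unknown[:5]}")
            warnings.warn(
                f"dropping {len(unknown)} query genes absent from background"
            )
            query = [g for g in query if g in background_genes]
            if not query:
                raise ValueError("no query genes left after background filtering")
        m = len(background_genes)
    else:
        m = background_size if background_size is not None else library.background_size
    if m < len(query):
        raise ValueError("background smaller than query")
    qset = set(query)
    records = []
    for name in sorted(library.sets):
        members = library.sets[name]
        if background_genes is not None:
            members = [g for g in members if g in background_genes]
        overlap = sorted(qset.intersection(members))
        k, big_k, n = len(overlap), len(members), len(query)
        p = float(hypergeom.sf(k - 1, m, big_k, n)) if k > 0 else 1.0
        # odds ratio of the 2x2 overlap table
        a, b, c = k, n - k, big_k - k
        d = m - n - c
        odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
        records.append(
            EnrichmentRecord(
                set_name=name,
                overlap_size=k,
                overlap_genes=overlap,
                set_size=big_k,
                p=min(p, 1.0),
                odds_ratio=odds,
            )
        )
    if records:
        adj = multipletests([r.p for r in records], method="fdr_bh")[1]
        for r, q in zip(records, adj):
            r.adjusted_p = float(max(q, r.p))
    records.sort(key=lambda r: (r.p, r.set_name))
    return records


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in records],
            "overlap_size": [r.overlap_size for r in records],
            "set_size": [r.set_size for r in records],
            "p": [r.p for r in records],
            "adjusted_p": [r.adjusted_p for r in records],
            "odds_ratio": [r.odds_ratio for r in records],
            "overlap_genes": [";".join(r.overlap_genes) for r in records],
        }
    )
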
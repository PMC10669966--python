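"""Compendium-derived tissue-specificity exclusion list.

Given an expression compendium labeled by tissue type and healthy/cancer
category, compute per-tissue mean expression (dropping genes with fewer
than ``min_datapoints`` non-missing values in a tissue), rank the top-k
expressing genes per tissue, and collect the genes that appear in at most
``max_healthy`` healthy top lists and at most ``max_cancer`` cancer top
lists.  The result is used as an exclusion list to remove genes that are
highly expressed elsewhere and therefore not subtype specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CATEGORIES = ("healthy", "cancer")

#: compendium metadata columns; remaining columns are genes
META_COLS = ("sample", "tissue", "category")


@dataclass
class TissueSummary:
    tissue: str
    category: str
    means: pd.Series  # per-gene mean, only genes with enough datapoints
    n_datapoints: pd.Series  # per-gene non-missing count (all genes)


@dataclass
class TopList:
    tissue: str
    category: str
    genes: list[str]


@dataclass
class ExclusionList:
    """Genes top-ranked in few tissues, with their top-list membership counts."""

    genes: set[str]
    healthy_counts: dict[str, int] = field(repr=False)
    cancer_counts: dict[str, int] = field(repr=False)
    k: int = 500
    max_healthy: int = 1
    max_cancer: int = 3

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.genes)
        return pd.DataFrame(
            {
                "gene": genes,
                "n_healthy_top_lists": [self.healthy_counts.get(g, 0) for g in genes],
                "n_cancer_top_lists": [self.cancer_counts.get(g, 0) for g in genes],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, **params) -> "ExclusionList":
        df = pd.read_csv(path, sep="\t")
        return cls(
            genes=set(df["gene"].astype(str)),
            healthy_counts=dict(zip(df["gene"].astype(str), df["n_healthy_top_lists"])),
            cancer_counts=dict(zip(df["gene"].astype(str), df["n_cancer_top_lists"])),
            **params,
        )

    @classmethod
    def empty(cls) -> "ExclusionList":
        return cls(genes=set(), healthy_counts={}, cancer_counts={})


def summarize_tissues(
    compendium: pd.DataFrame, min_datapoints: int = 6
) -> list[TissueSummary]:
    """Per-tissue, per-gene mean expression over non-missing values.

    ``compendium`` holds one row per sample with columns ``sample``,
    ``tissue``, ``category`` followed by one column per gene.  Genes with
    fewer than ``min_datapoints`` non-missing values in a tissue
    contribute no mean for that tissue.
    """
    bad = set(compendium["category"].unique()) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown category labels: {sorted(bad)}")
    gene_cols = [c for c in compendium.columns if c not in META_COLS]
    summaries = []
    for (tissue, category), block in compendium.groupby(
        ["tissue", "category"], sort=True
    ):
        values = block[gene_cols]
        n = values.notna().sum(axis=0)
        means = values.mean(axis=0)[n >= min_datapoints]
        summaries.append(
            TissueSummary(
                tissue=str(tissue), category=str(category), means=means, n_datapoints=n
            )
        )
    return summaries


def top_k(summary: TissueSummary, k: int = 500) -> TopList:
    """Top-k genes of a tissue by mean expression.

    Sorted by descending mean; ties broken by ascending gene id so the
    selection is platform independent.  Shorter than k when the tissue has
    fewer eligible genes.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if summary.means.empty:
        return TopList(summary.tissue, summary.category, [])
    # mergesort is stable; pre-sort by gene id so ties land in ascending id order
    order = (
        summary.means.to_frame("mean")
        .set_axis(summary.means.index.astype(str))
        .sort_index()
        .sort_values(by="mean", ascending=False, kind="mergesort")
    )
    return TopList(summary.tissue, summary.category, list(order.index[:k]))


def build_exclusion_list(
    top_lists: list[TopList],
    max_healthy: int = 1,
    max_cancer: int = 3,
    k: int = 500,
    invert: bool = False,
) -> ExclusionList:
    """Collect genes appearing in few top lists.

    A gene in the union of all top lists enters the exclusion list iff its
    healthy-list membership count H_g <= max_healthy and its cancer-list
    membership count C_g <= max_cancer.  With ``invert=True`` the
    complementary rule is applied instead (gene excluded when it exceeds
    either bound), provided as an alternative reading of the rule's intent.
    """
    healthy_counts: dict[str, int] = {}
    cancer_counts: dict[str, int] = {}
    for tl in top_lists:
        if tl.category not in CATEGORIES:
            raise ValueError(f"unknown category: {tl.category!r}")
        target = healthy_counts if tl.category == "healthy" else cancer_counts
        for g in tl.genes:
            target[g] = target.get(g, 0) + 1
    universe = set(healthy_counts) | set(cancer_counts)
    if invert:
        genes = {
            g
            for g in universe
            if healthy_counts.get(g, 0) > max_healthy
            or cancer_counts.get(g, 0) > max_cancer
        }
    else:
        genes = {
            g
            for g in universe
            if healthy_counts.get(g, 0) <= max_healthy
            and cancer_counts.get(g, 0) <= max_cancer
        }
    return ExclusionList(
        genes=genes,
        healthy_counts={g: healthy_counts.get(g, 0) for g in genes},
        cancer_counts={g: cancer_counts.get(g, 0) for g in genes},
        k=k,
        max_healthy=max_healthy,
        max_cancer=max_cancer,
    )


def exclusion_list_from_compendium(
    compendium: pd.DataFrame,
    k: int = 500,
    min_datapoints: int = 6,
    max_healthy: int = 1,
    max_cancer: int = 3,
    invert: bool = False,
) -> ExclusionList:
    """Full pipeline: tissue summaries -> top-k lists -> exclusion list."""
    summaries = summarize_tissues(compendium, min_datapoints=min_datapoints)
    lists = [top_k(s, k=k) for s in summaries]
    return build_exclusion_list(
        lists, max_healthy=max_healthy, max_cancer=max_cancer, k=k, invert=invert
    )


def apply_exclusion(genes, exclusion: ExclusionList) -> list[str]:
    """Remove exclusion-list members, preserving input order."""
    return [g for g in genes if g not in exclusion.genes]
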
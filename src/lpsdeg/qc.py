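"""CPM normalization and pre-DE quality-control filters.

Two filters run before differential expression: samples whose median
log-CPM deviates more than 10% (relative) from the cohort median are
dropped, and weakly expressed genes are removed with the standard
smallest-group CPM rule (min_count=10, min_total_count=15).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CountMatrix


@dataclass
class GeneFilterParams:
    """Expression-filter thresholds, applied per smallest group size."""

    min_count: float = 10.0
    min_total_count: float = 15.0

    def __post_init__(self) -> None:
        if self.min_count < 0 or self.min_total_count < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class SampleQCReport:
    sample_id: str
    median_logcount: float
    deviation: float
    excluded: bool


def cpm(
    matrix: CountMatrix, log: bool = False, prior_count: float = 2.0
) -> pd.DataFrame:
    """Counts per million, optionally log2 with a library-size-adjusted prior.

    Linear mode is ``count / library_size * 1e6``.  Log mode adds a prior
    scaled to each sample's library size (prior * L_s / mean(L)) to the
    count and twice that prior to the library size before taking log2 of
    the per-million value, so that all-zero genes map to a constant within
    a sample and no log(0) occurs.
    """
    lib = matrix.library_sizes.to_numpy(dtype=float)
    zero = np.flatnonzero(lib <= 0)
    if zero.size:
        bad = matrix.sample_ids[zero[0]]
        raise ValueError(f"zero library size for sample {bad!r}")
    counts = matrix.counts.to_numpy(dtype=float)
    if not log:
        vals = counts / lib * 1e6
    else:
        adj = prior_count * lib / lib.mean()
        vals = np.log2((counts + adj) / (lib + 2.0 * adj) * 1e6)
    return pd.DataFrame(vals, index=matrix.gene_ids, columns=matrix.sample_ids)


def filter_samples_by_median_logcount(
    matrix: CountMatrix, threshold: float = 0.10
) -> tuple[CountMatrix, list[SampleQCReport]]:
    """Drop samples whose median log-CPM deviates from the cohort median.

    A sample is kept iff |median_s - M| / |M| <= threshold, where median_s
    is the median over genes of the sample's log-CPM and M is the median
    of the per-sample medians.
    """
    if matrix.counts.shape[1] < 2:
        raise ValueError("need at least 2 samples for sample QC")
    logcpm = cpm(matrix, log=True)
    medians = logcpm.median(axis=0)
    overall = float(medians.median())
    if overall == 0.0:
        raise ValueError("median of per-sample medians is 0; relative deviation undefined")
    deviations = (medians - overall).abs() / abs(overall)
    reports = [
        SampleQCReport(
            sample_id=str(s),
            median_logcount=float(medians[s]),
            deviation=float(deviations[s]),
            excluded=bool(deviations[s] > threshold),
        )
        for s in matrix.sample_ids
    ]
    kept = [r.sample_id for r in reports if not r.excluded]
    return matrix.subset_samples(kept), reports


def filter_genes_by_expression(
    matrix: CountMatrix, params: GeneFilterParams | None = None
) -> list[str]:
    """Gene ids passing the smallest-group CPM expression rule.

    A gene is kept iff at least n_min samples have CPM >= k and its total
    count is >= min_total_count, where k = min_count / median(library
    sizes) * 1e6 and n_min is the size of the smallest group.
    """
    if params is None:
        params = GeneFilterParams()
    sizes = matrix.group_sizes()
    if sizes.empty:
        raise ValueError("no groups")
    n_min = int(sizes.min())
    lib = matrix.library_sizes.to_numpy(dtype=float)
    k = params.min_count / np.median(lib) * 1e6
    cpm_vals = cpm(matrix, log=False)
    n_above = (cpm_vals.to_numpy() >= k).sum(axis=1)
    totals = matrix.counts.sum(axis=1).to_numpy()
    keep = (n_above >= n_min) & (totals >= params.min_total_count)
    return [str(g) for g in matrix.gene_ids[keep]]


def qc_report_frame(reports: list[SampleQCReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [r.sample_id for r in reports],
            "median_logcount": [r.median_logcount for r in reports],
            "deviation": [r.deviation for r in reports],
            "excluded": [r.excluded for r in reports],
        }
    )
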
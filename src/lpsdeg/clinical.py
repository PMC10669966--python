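"""Clinical scoring and association statistics.

Downstream of the transcriptomic screen: immunohistochemistry H-scores and
their quartile/low-high binning, qPCR relative quantification by the
delta-delta-Ct method, viability-plate normalization, and the association
tests used on cross-tabulated cohorts — Pearson chi-square, an exact
Fisher-Freeman-Halton r x c test (authored here; no SciPy equivalent
exists), Mann-Whitney U, Kruskal-Wallis with Bonferroni pairwise
comparisons, and rank/linear correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

# ---------------------------------------------------------------------------
# H-score


def h_score(intensity: int, percent_positive: float) -> float:
    """Staining intensity (0-3) times percent positive cells (0-100)."""
    if not 0 <= intensity <= 3 or int(intensity) != intensity:
        raise ValueError("intensity must be an integer in 0..3")
    if not 0.0 <= percent_positive <= 100.0:
        raise ValueError("percent_positive must be in [0, 100]")
    return float(intensity * percent_positive)


def h_score_bins(h: float) -> tuple[int, str]:
    """Quartile class (0-3) and low/high split of an H-score.

    Quartile boundaries 75/150/225 belong to the lower bin; the binary
    split is low for h <= 150, high above.
    """
    if not 0.0 <= h <= 300.0:
        raise ValueError("H-score must be in [0, 300]")
    if h <= 75:
        quartile = 0
    elif h <= 150:
        quartile = 1
    elif h <= 225:
        quartile = 2
    else:
        quartile = 3
    return quartile, ("low" if h <= 150 else "high")


@dataclass
class IHCRecord:
    sample_id: str
    intensity: int
    percent_positive: float
    h_score: float = field(init=False)
    quartile: int = field(init=False)
    binary: str = field(init=False)
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h_score = h_score(self.intensity, self.percent_positive)
        self.quartile, self.binary = h_score_bins(self.h_score)


def score_ihc_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add h_score / quartile / binary columns to an IHC scoring table."""
    out = table.copy()
    scored = [
        h_score(int(i), float(p))
        for i, p in zip(out["intensity"], out["percent_positive"])
    ]
    bins = [h_score_bins(h) for h in scored]
    out["h_score"] = scored
    out["quartile"] = [b[0] for b in bins]
    out["binary"] = [b[1] for b in bins]
    return out


# ---------------------------------------------------------------------------
# Contingency tables


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("table must be at least 2 x 2")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        r, c = self.counts.shape
        if self.row_labels is None:
            self.row_labels = [f"row{i}" for i in range(r)]
        if self.col_labels is None:
            self.col_labels = [f"col{j}" for j in range(c)]

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def pearson_chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction."""
    if (table.row_margins == 0).any() or (table.col_margins == 0).any():
        raise ValueError("zero row or column margin")
    stat, p, df, _ = stats.chi2_contingency(table.counts, correction=False)
    return float(stat), int(df), float(p)


def _table_logprob_const(row_margins: np.ndarray, col_margins: np.ndarray) -> float:
    n = row_margins.sum()
    return float(
        gammaln(row_margins + 1).sum()
        + gammaln(col_margins + 1).sum()
        - gammaln(n + 1)
    )


def _enumerate_rx2(row_margins: np.ndarray, c1: int) -> np.ndarray:
    """Cumulative -sum(lgamma(t_ij + 1)) over all r x 2 tables with the
    given margins, vectorized breadth-first over rows.  Returns the array
    of per-table values."""
    rem1 = np.array([c1], dtype=np.int64)
    lp = np.zeros(1)
    total_remaining = int(row_margins.sum())  # rows not yet placed
    for r_i in row_margins[:-1]:
        r_i = int(r_i)
        rem2 = total_remaining - rem1  # col-2 capacity before placing this row
        total_remaining -= r_i
        lo = np.maximum(0, r_i - rem2)
        hi = np.minimum(r_i, rem1)
        counts = hi - lo + 1
        idx = np.repeat(np.arange(rem1.size), counts)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        a = lo[idx] + (np.arange(counts.sum()) - np.repeat(starts, counts))
        lp = lp[idx] - gammaln(a + 1) - gammaln(r_i - a + 1)
        rem1 = rem1[idx] - a
    r_last = int(row_margins[-1])
    b = r_last - rem1
    lp = lp - gammaln(rem1 + 1) - gammaln(b + 1)
    return lp


def _enumerate_generic(row_margins, col_margins, budget: int):
    """Depth-first enumeration of all tables with the given margins.

    Yields cumulative -sum(lgamma(t+1)) per complete table.  Used for
    c > 2; raises if the number of visited tables exceeds the budget.
    """
    row_margins = np.asarray(row_margins, dtype=np.int64)
    r = len(row_margins)
    results: list[float] = []
    visited = 0

    def fill_row(i: int, rem_cols: np.ndarray, acc: float) -> None:
        nonlocal visited
        if i == r - 1:
            # last row is forced by the remaining column margins
            visited += 1
            if visited > budget:
                raise RuntimeError(
                    "enumeration budget exceeded; use fisher_freeman_halton_mc"
                )
            results.append(acc - gammaln(rem_cols + 1).sum())
            return
        r_i = int(row_margins[i])
        tail = int(row_margins[i + 1 :].sum())
        c = len(rem_cols)

        def fill_cell(j: int, left: int, rem: np.ndarray, a: float) -> None:
            if j == c - 1:
                if left <= rem[j]:
                    new_rem = rem.copy()
                    new_rem[j] -= left
                    if (new_rem <= tail).all():
                        fill_row(i + 1, new_rem, a - gammaln(left + 1))
                return
            # leave enough for the remaining cells of this row
            lo = max(0, left - int(rem[j + 1 :].sum()))
            hi = min(int(rem[j]), left)
            for t in range(lo, hi + 1):
                new_rem = rem.copy()
                new_rem[j] -= t
                fill_cell(j + 1, left - t, new_rem, a - gammaln(t + 1))

        fill_cell(0, r_i, rem_cols, acc)

    fill_row(0, np.asarray(col_margins, dtype=np.int64), 0.0)
    return np.array(results)


def fisher_freeman_halton(
    table: ContingencyTable,
    rel_tol: float = 1e-7,
    budget: int = 20_000_000,
) -> float:
    """Exact two-sided Fisher-Freeman-Halton p for an r x c table.

    Enumerates every table with the observed margins and sums the
    multivariate hypergeometric probabilities of those no more probable
    than the observed table (within a relative tolerance for ties).
    """
    counts = table.counts
    rows, cols = counts.shape
    if cols > rows and cols > 2:
        return fisher_freeman_halton(
            ContingencyTable(counts.T), rel_tol=rel_tol, budget=budget
        )
    if cols > 2:
        lp = _enumerate_generic(table.row_margins, table.col_margins, budget)
    else:
        n_tables = int(
            np.prod(np.minimum(table.row_margins, counts.sum()) + 1.0)
        )
        if n_tables > budget * 10:
            raise RuntimeError(
                "enumeration budget exceeded; use fisher_freeman_halton_mc"
            )
        lp = _enumerate_rx2(table.row_margins, int(table.col_margins[0]))
    const = _table_logprob_const(table.row_margins, table.col_margins)
    logps = const + lp
    obs = const - gammaln(counts + 1).sum()
    mask = logps <= obs + np.log1p(rel_tol)
    return float(min(np.exp(logps[mask]).sum(), 1.0))


def fisher_freeman_halton_mc(
    table: ContingencyTable,
    n_samples: int = 100_000,
    seed: int = 0,
    rel_tol: float = 1e-7,
) -> float:
    """Seeded Monte-Carlo estimate of the FFH p for large tables."""
    rng = np.random.default_rng(seed)
    dist = stats.random_table(table.row_margins, table.col_margins)
    samples = dist.rvs(n_samples, random_state=rng)
    const = _table_logprob_const(table.row_margins, table.col_margins)
    logps = const - gammaln(samples + 1).sum(axis=(1, 2))
    obs = const - gammaln(table.counts + 1).sum()
    hits = int((logps <= obs + np.log1p(rel_tol)).sum())
    return (hits + 1) / (n_samples + 1)


# ---------------------------------------------------------------------------
# Rank tests and correlations


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact for small tie-free samples,
    tie-corrected normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(x.size, y.size) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(
    groups: list, pairwise: bool = False
) -> tuple[float, float, pd.DataFrame | None]:
    """Tie-corrected Kruskal-Wallis H test across groups.

    With ``pairwise=True`` also returns Bonferroni-corrected Mann-Whitney
    p-values for every pair (multiplied by the number of pairs, capped at 1).
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:  # all values identical: H = 0 by definition
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    pair_frame = None
    if pairwise:
        k = len(arrays)
        n_pairs = k * (k - 1) // 2
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                _, praw = mann_whitney_u(arrays[i], arrays[j])
                rows.append(
                    {
                        "group_a": i,
                        "group_b": j,
                        "p_raw": praw,
                        "p_bonferroni": min(praw * n_pairs, 1.0),
                    }
                )
        pair_frame = pd.DataFrame(rows)
    return float(h), float(p), pair_frame


def correlations(x, y, method: str = "spearman") -> tuple[float, float]:
    """Spearman rank or Pearson linear correlation with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant vector")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# qPCR delta-delta-Ct


@dataclass
class QPCRMeasurement:
    sample_id: str
    target_ct: list[float]
    reference_ct: list[float]
    calibrator_delta_ct: float = 0.0


def delta_delta_ct(m: QPCRMeasurement) -> float:
    """Relative expression 2^-(dCt - calibrator dCt), dCt on triplicate means."""
    target = np.asarray(m.target_ct, dtype=float)
    reference = np.asarray(m.reference_ct, dtype=float)
    if np.isnan(target).all() or np.isnan(reference).all():
        raise ValueError(f"all-NaN Ct triplicate for sample {m.sample_id!r}")
    d_ct = np.nanmean(target) - np.nanmean(reference)
    return float(2.0 ** -(d_ct - m.calibrator_delta_ct))


def ddct_table(
    table: pd.DataFrame, calibrator_sample: str | None = None
) -> pd.DataFrame:
    """Relative expression for each row of a Ct triplicate table.

    Expects columns sample, target_ct_1..3, reference_ct_1..3 and
    optionally calibrator_delta_ct; if ``calibrator_sample`` is given, its
    own dCt is used as the calibrator for every sample (so it maps to 1).
    """
    t_cols = [c for c in table.columns if c.startswith("target_ct")]
    r_cols = [c for c in table.columns if c.startswith("reference_ct")]
    d_ct = table[t_cols].mean(axis=1) - table[r_cols].mean(axis=1)
    if calibrator_sample is not None:
        cal = float(d_ct[table["sample"] == calibrator_sample].iloc[0])
    elif "calibrator_delta_ct" in table.columns:
        cal = table["calibrator_delta_ct"]
    else:
        cal = 0.0
    out = table.copy()
    out["delta_ct"] = d_ct
    out["relative_expression"] = 2.0 ** -(d_ct - cal)
    return out


# ---------------------------------------------------------------------------
# Viability plates


@dataclass
class ViabilityResult:
    treatment: str
    per_well_percent: np.ndarray
    mean_percent: float
    p_vs_control: float


def relative_viability(
    plate: pd.DataFrame,
    control: str = "control",
    background: str = "background",
    welch: bool = False,
) -> dict[str, ViabilityResult]:
    """Background-subtracted viability as percent of the control mean.

    Each well's luminescence has the mean background signal subtracted and
    is divided by the mean background-subtracted control signal; the
    control mean therefore maps to 100%.  Each treatment is compared to
    the control with a two-tailed unpaired t-test (pooled variance by
    default, Welch by flag).
    """
    lum = plate["luminescence"].astype(float)
    if (lum < 0).any():
        raise ValueError("negative luminescence")
    bg_mask = plate["treatment"] == background
    bg = float(lum[bg_mask].mean()) if bg_mask.any() else 0.0
    ctrl = lum[plate["treatment"] == control] - bg
    if ctrl.size < 1 or float(ctrl.mean()) <= 0:
        raise ValueError("control mean non-positive after background subtraction")
    ctrl_mean = float(ctrl.mean())
    results: dict[str, ViabilityResult] = {}
    for treatment in pd.unique(plate["treatment"]):
        if treatment == background:
            continue
        wells = (lum[plate["treatment"] == treatment] - bg).to_numpy()
        percent = wells / ctrl_mean * 100.0
        if treatment == control:
            p = 1.0
        else:
            if wells.size < 2:
                raise ValueError(f"need >= 2 wells for treatment {treatment!r}")
            same = np.ptp(np.concatenate([wells, ctrl.to_numpy()])) == 0
            p = (
                1.0
                if same
                else float(
                    stats.ttest_ind(wells, ctrl.to_numpy(), equal_var=not welch).pvalue
                )
            )
        results[str(treatment)] = ViabilityResult(
            treatment=str(treatment),
            per_well_percent=percent,
            mean_percent=float(percent.mean()),
            p_vs_control=p,
        )
    return results
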
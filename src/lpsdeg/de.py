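"""One-subtype-vs-rest differential expression on negative-binomial counts.

The model: counts for gene g, sample s are NB with mean mu_gs and variance
mu_gs + phi * mu_gs^2 (phi = dispersion).  Library sizes are first
equalized toward their geometric mean so that the conditional exact test
(which assumes exchangeable samples) applies.  The common dispersion is
estimated by conditional maximum likelihood (CML) summed over genes; per-gene
dispersions shrink the gene-wise CML toward the common value with a prior
weight.  The exact test conditions on the two-group total S = S_A + S_B
and sums the probabilities of all splits no more likely than the observed
one, using the closed NB convolution: the sum of n iid NB(mu, phi) counts
is NB(n*mu, phi/n), i.e. size n/phi.

A gene is called subtype specific when its one-vs-rest log2 fold change
exceeds ``logfc_min`` (default 1.5), its exact-test p is below ``p_max``
(default 0.05), and it is not on the tissue-specificity exclusion list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix
from .specificity import ExclusionList

PHI_MIN = 1e-6
PHI_MAX = 10.0


@dataclass
class DispersionEstimate:
    common: float
    tagwise: pd.Series
    prior_df: float


@dataclass
class DEGRecord:
    gene_id: str
    subtype: str
    logfc: float
    p: float
    adjusted_p: float
    in_exclusion_list: bool
    is_deg: bool


def equalize_library_sizes(matrix: CountMatrix) -> tuple[CountMatrix, float]:
    """Rescale counts toward the geometric-mean library size.

    Each count is multiplied by common/observed library size and rounded
    to the nearest integer (deterministic; mean preserving up to rounding).
    Equal input sizes return the input unchanged.
    """
    lib = matrix.library_sizes.to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    common = float(np.exp(np.mean(np.log(lib))))
    if np.allclose(lib, lib[0]):
        return matrix, common
    scaled = np.rint(matrix.counts.to_numpy(dtype=float) * (common / lib))
    adjusted = pd.DataFrame(
        scaled.astype(np.int64), index=matrix.gene_ids, columns=matrix.sample_ids
    )
    return CountMatrix(adjusted, matrix.groups), common


def _group_indices(groups: pd.Series) -> dict[str, np.ndarray]:
    labels = groups.to_numpy()
    return {g: np.flatnonzero(labels == g) for g in pd.unique(labels)}


def _conditional_loglik(counts: np.ndarray, group_idx, phi: float) -> np.ndarray:
    """Per-gene NB conditional log-likelihood given per-group totals.

    For one group of n iid NB(mu, phi) counts y_i with total z, the
    probability of the counts given z is
    prod_i C(y_i + r - 1, y_i) / C(z + n*r - 1, z) with r = 1/phi; its log
    is summed over groups.  Dependence on mu cancels, which is what makes
    CML estimation of phi possible.
    """
    r = 1.0 / phi
    total = np.zeros(counts.shape[0])
    for idx in group_idx.values():
        y = counts[:, idx]
        n = y.shape[1]
        z = y.sum(axis=1)
        total += (
            gammaln(y + r).sum(axis=1)
            - n * gammaln(r)
            + gammaln(n * r)
            - gammaln(z + n * r)
        )
        # gammaln(y+1) and gammaln(z+1) terms are constant in phi but kept
        # out for speed; omit them consistently so likelihood *differences*
        # in phi are exact.
    return total


def estimate_common_dispersion(matrix: CountMatrix) -> float:
    """Common dispersion by conditional maximum likelihood over all genes."""
    group_idx = _group_indices(matrix.groups)
    if not any(len(idx) >= 2 for idx in group_idx.values()):
        raise ValueError("no group with at least 2 samples; dispersion not estimable")
    group_idx = {g: idx for g, idx in group_idx.items() if len(idx) >= 2}
    counts = matrix.counts.to_numpy(dtype=float)

    def neg_ll(log_phi: float) -> float:
        return -float(_conditional_loglik(counts, group_idx, np.exp(log_phi)).sum())

    res = minimize_scalar(
        neg_ll,
        bounds=(np.log(PHI_MIN), np.log(PHI_MAX)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))


def estimate_tagwise_dispersion(
    matrix: CountMatrix,
    phi_common: float,
    prior_df: float = 10.0,
    grid_points: int = 61,
) -> pd.Series:
    """Per-gene dispersions shrunk toward the common value.

    Maximizes, per gene, the weighted conditional likelihood
    l_g(phi) + (prior_df / 2) * l_common(phi), where l_common is the
    per-gene average CML over all genes.  Evaluated on a log-spaced grid
    spanning the search range with quadratic refinement around the grid
    optimum; prior_df -> infinity recovers the common estimate.
    """
    if phi_common <= 0:
        raise ValueError("phi_common must be positive")
    group_idx = {
        g: idx for g, idx in _group_indices(matrix.groups).items() if len(idx) >= 2
    }
    counts = matrix.counts.to_numpy(dtype=float)
    n_genes = counts.shape[0]
    grid = np.exp(np.linspace(np.log(PHI_MIN), np.log(PHI_MAX), grid_points))
    # refine around the common estimate: most genes shrink to its vicinity,
    # and the infinite-prior limit must recover it precisely
    local = phi_common * np.exp(np.array([-0.1, -0.02, -0.004, 0.0, 0.004, 0.02, 0.1]))
    grid = np.unique(np.concatenate([grid, local]))
    ll = np.empty((grid.size, n_genes))
    for i, phi in enumerate(grid):
        ll[i] = _conditional_loglik(counts, group_idx, phi)
    common_term = ll.mean(axis=1)  # average CML per gene, as function of phi
    weighted = ll + (prior_df / 2.0) * common_term[:, None]
    best = weighted.argmax(axis=0)
    # quadratic interpolation in log(phi) around the grid maximum
    log_grid = np.log(grid)
    phi_g = np.empty(n_genes)
    for j in range(n_genes):
        i = best[j]
        if i == 0 or i == grid.size - 1:
            phi_g[j] = grid[i]
            continue
        x0, x1, x2 = log_grid[i - 1 : i + 2]
        y0, y1, y2 = weighted[i - 1 : i + 2, j]
        # three-point parabola vertex, valid for non-uniform spacing
        num = (x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)
        den = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
        if den == 0:
            phi_g[j] = grid[i]
        else:
            x_star = x1 - 0.5 * num / den
            phi_g[j] = np.exp(np.clip(x_star, x0, x2))
    return pd.Series(phi_g, index=matrix.gene_ids, name="phi")


def estimate_dispersion(
    matrix: CountMatrix, prior_df: float = 10.0
) -> DispersionEstimate:
    common = estimate_common_dispersion(matrix)
    tagwise = estimate_tagwise_dispersion(matrix, common, prior_df=prior_df)
    return DispersionEstimate(common=common, tagwise=tagwise, prior_df=prior_df)


def _nb_sum_logpmf(x: np.ndarray, n: int, mu: float, phi: float) -> np.ndarray:
    """log pmf of the sum of n iid NB(mu, phi) at integer points x.

    NB is closed under summation at fixed per-observation phi: the sum has
    mean n*mu and size n/phi.
    """
    size = n / phi
    total_mean = n * mu
    logp = size * np.log(size / (size + total_mean)) + x * np.log(
        total_mean / (size + total_mean)
    ) if total_mean > 0 else np.where(x == 0, 0.0, -np.inf)
    if total_mean > 0:
        logp = logp + gammaln(x + size) - gammaln(size) - gammaln(x + 1)
    return logp


def nb_exact_test(
    counts_a: np.ndarray, counts_b: np.ndarray, phi: float, rel_tol: float = 1e-10
) -> float:
    """Conditional NB exact test for a difference between two groups.

    Conditions on S = S_A + S_B and sums the probabilities of all splits
    (a, S-a) whose probability is <= that of the observed split, within a
    relative tolerance for ties.  Returns p in (0, 1]; symmetric in the
    two groups.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if (counts_a < 0).any() or (counts_b < 0).any():
        raise ValueError("counts must be non-negative")
    if phi <= 0:
        raise ValueError("dispersion must be positive")
    n_a, n_b = counts_a.size, counts_b.size
    s_a = int(round(counts_a.sum()))
    s_b = int(round(counts_b.sum()))
    s = s_a + s_b
    if s == 0:
        return 1.0
    mu = s / (n_a + n_b)
    a = np.arange(s + 1)
    log_joint = _nb_sum_logpmf(a, n_a, mu, phi) + _nb_sum_logpmf(
        s - a, n_b, mu, phi
    )
    log_joint -= log_joint.max()  # conditional probs need only ratios
    probs = np.exp(log_joint)
    probs /= probs.sum()
    observed = probs[s_a]
    p = float(probs[probs <= observed * (1.0 + rel_tol)].sum())
    return min(p, 1.0)


def log_fold_change(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    lib_a: np.ndarray | None = None,
    lib_b: np.ndarray | None = None,
    prior_count: float = 2.0,
) -> float:
    """log2 ratio of group-mean CPM with a prior offset.

    The prior count is expressed on the CPM scale using the mean library
    size, so equal groups give exactly 0 and the swap of groups flips the
    sign.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if lib_a is None:
        lib_a = np.full(counts_a.shape[-1], 1e6)
    if lib_b is None:
        lib_b = np.full(counts_b.shape[-1], 1e6)
    lib_a = np.asarray(lib_a, dtype=float)
    lib_b = np.asarray(lib_b, dtype=float)
    mean_lib = np.concatenate([lib_a, lib_b]).mean()
    offset = prior_count / mean_lib * 1e6
    cpm_a = (counts_a / lib_a * 1e6).mean(axis=-1)
    cpm_b = (counts_b / lib_b * 1e6).mean(axis=-1)
    return float(np.log2((cpm_a + offset) / (cpm_b + offset)))


def call_subtype_degs(
    matrix: CountMatrix,
    exclusion: ExclusionList | None = None,
    logfc_min: float = 1.5,
    p_max: float = 0.05,
    prior_df: float = 10.0,
    prior_count: float = 2.0,
) -> dict[str, list[DEGRecord]]:
    """One-vs-rest DEG calling for every subtype.

    For each subtype the subtype samples are tested against the pooled
    remainder per gene with the NB exact test at the tagwise dispersion,
    the log2 fold change is computed on group-mean CPM, and genes passing
    logFC > logfc_min, p < p_max and not on the exclusion list are flagged.
    Records are ranked by descending logFC.
    """
    if exclusion is None:
        exclusion = ExclusionList.empty()
    sizes = matrix.group_sizes()
    if len(sizes) < 2:
        raise ValueError("need at least 2 subtypes")
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValueError(f"subtype with fewer than 2 samples: {small.index[0]!r}")
    lib_raw = matrix.library_sizes.to_numpy(dtype=float)
    eq, _common_size = equalize_library_sizes(matrix)
    disp = estimate_dispersion(eq, prior_df=prior_df)
    counts_eq = eq.counts.to_numpy(dtype=float)
    counts_raw = matrix.counts.to_numpy(dtype=float)
    phi = disp.tagwise.to_numpy()
    group_idx = _group_indices(matrix.groups)
    gene_ids = [str(g) for g in matrix.gene_ids]
    results: dict[str, list[DEGRecord]] = {}
    for subtype in sorted(group_idx):
        idx_a = group_idx[subtype]
        idx_b = np.flatnonzero(~np.isin(np.arange(len(matrix.sample_ids)), idx_a))
        pvals = np.array(
            [
                nb_exact_test(counts_eq[g, idx_a], counts_eq[g, idx_b], phi[g])
                for g in range(counts_eq.shape[0])
            ]
        )
        logfc = np.array(
            [
                log_fold_change(
                    counts_raw[g, idx_a],
                    counts_raw[g, idx_b],
                    lib_raw[idx_a],
                    lib_raw[idx_b],
                    prior_count=prior_count,
                )
                for g in range(counts_raw.shape[0])
            ]
        )
        adj = multipletests(pvals, method="fdr_bh")[1]
        records = []
        for g, gene in enumerate(gene_ids):
            in_excl = gene in exclusion
            records.append(
                DEGRecord(
                    gene_id=gene,
                    subtype=subtype,
                    logfc=float(logfc[g]),
                    p=float(pvals[g]),
                    adjusted_p=float(adj[g]),
                    in_exclusion_list=in_excl,
                    is_deg=bool(
                        logfc[g] > logfc_min and pvals[g] < p_max and not in_excl
                    ),
                )
            )
        records.sort(key=lambda r: (-r.logfc, r.gene_id))
        results[subtype] = records
    return results


def deg_frame(records: list[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "symbol": [r.gene_id for r in records],
            "logFC": [r.logfc for r in records],
            "p": [r.p for r in records],
            "adjusted_p": [r.adjusted_p for r in records],
            "in_exclusion_list": [r.in_exclusion_list for r in records],
            "is_deg": [r.is_deg for r in records],
        }
    )
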
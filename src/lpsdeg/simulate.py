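"""Synthetic-data generators for every pipeline input.

Everything the pipeline consumes can be generated here with known ground
truth: NB count matrices with planted subtype-specific genes (emulating a
three-subtype liposarcoma cohort), a healthy/cancer expression compendium
with housekeeping and tissue-specific genes, IHC scoring tables, qPCR Ct
triplicates, and 96-well viability plates.  Every generator is a pure
function of its spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CountMatrix

#: default group sizes mirroring a 53/54/24 three-subtype cohort
DEFAULT_GROUP_SIZES = {"DDLPS": 53, "MLPS": 54, "PLPS": 24}


@dataclass
class SimulationSpec:
    """Generative model for a subtype count matrix.

    Counts for gene g in sample s are NB with mean q_g * L_s / mean(L)
    and variance mu + dispersion * mu^2, where q_g = 2**b_g with b_g drawn
    uniformly from ``baseline_log_mean_range`` and L_s is the sample's
    library size drawn log-uniformly from ``library_size_range``.  Planted
    genes have their mean multiplied by 2**effect in their subtype only.
    """

    n_genes: int = 2000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    baseline_log_mean_range: tuple[float, float] = (3.0, 8.0)
    dispersion: float = 0.1
    planted_degs: list[tuple[str, str, float]] = field(default_factory=list)
    library_size_range: tuple[int, int] = (500_000, 2_000_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not self.group_sizes:
            raise ValueError("group_sizes must be non-empty")
        for label, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(
                    f"group {label!r} needs >= 2 samples for dispersion estimation"
                )
        seen = set()
        for gene, subtype, effect in self.planted_degs:
            if effect < 0:
                raise ValueError("planted effect sizes must be >= 0")
            if subtype not in self.group_sizes:
                raise ValueError(f"planted subtype {subtype!r} not in group_sizes")
            if (gene, subtype) in seen:
                raise ValueError(f"duplicate planted gene {gene!r} for {subtype!r}")
            seen.add((gene, subtype))


def gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_subtype_counts(spec: SimulationSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """NB count matrix with planted subtype-specific genes.

    Returns the matrix and a ground-truth table (gene, subtype, log2
    effect) holding only genes with a strictly positive planted effect.
    """
    rng = np.random.default_rng(spec.seed)
    genes = gene_names(spec.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    lo, hi = spec.baseline_log_mean_range
    base_log = rng.uniform(lo, hi, size=spec.n_genes)
    q = 2.0 ** base_log  # relative expression at the mean library size

    sample_ids, labels = [], []
    for label in spec.group_sizes:  # insertion order: deterministic
        for i in range(spec.group_sizes[label]):
            sample_ids.append(f"{label}_{i:03d}")
            labels.append(label)
    n_samples = len(sample_ids)
    l_lo, l_hi = spec.library_size_range
    lib = np.exp(rng.uniform(np.log(l_lo), np.log(l_hi), size=n_samples))

    # per-gene, per-sample mean
    mu = np.outer(q, lib / lib.mean())
    for gene, subtype, effect in spec.planted_degs:
        if gene not in gene_index:
            raise ValueError(f"planted gene {gene!r} not in gene universe")
        cols = [j for j, lab in enumerate(labels) if lab == subtype]
        mu[gene_index[gene], cols] *= 2.0 ** effect

    phi = spec.dispersion
    # numpy's NB(n, p): mean n(1-p)/p -> n = 1/phi, p = 1/(1 + phi*mu)
    counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
    matrix = CountMatrix(
        pd.DataFrame(counts.astype(np.int64), index=genes, columns=sample_ids),
        pd.Series(labels, index=sample_ids),
    )
    truth = pd.DataFrame(
        [
            {"gene": g, "subtype": s, "log2_effect": e}
            for g, s, e in spec.planted_degs
            if e > 0
        ],
        columns=["gene", "subtype", "log2_effect"],
    )
    return matrix, truth


@dataclass
class CompendiumSpec:
    """Generative model for a healthy/cancer expression compendium.

    Continuous expression scores (log-like scale), one row per sample with
    tissue and category labels.  Housekeeping genes are high in every
    tissue; tissue-specific genes are high only in their designated
    tissues; tissues may have fewer than the datapoint threshold of
    samples to exercise that filter.
    """

    n_genes: int = 1000
    n_healthy_tissues: int = 95
    n_cancer_tissues: int = 106
    samples_per_tissue: int | tuple[int, int] = 10
    housekeeping_genes: list[str] = field(default_factory=list)
    tissue_specific_genes: dict[str, list[tuple[str, str]]] = field(
        default_factory=dict
    )
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    high_offset: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy_tissues < 0 or self.n_cancer_tissues < 0:
            raise ValueError("tissue counts must be non-negative")
        for gene, assignments in self.tissue_specific_genes.items():
            for _, category in assignments:
                if category not in ("healthy", "cancer"):
                    raise ValueError(f"unknown category {category!r} for {gene!r}")

    def tissue_labels(self) -> list[tuple[str, str]]:
        healthy = [(f"healthy_{i:03d}", "healthy") for i in range(self.n_healthy_tissues)]
        cancer = [(f"cancer_{i:03d}", "cancer") for i in range(self.n_cancer_tissues)]
        return healthy + cancer


def simulate_compendium(spec: CompendiumSpec) -> pd.DataFrame:
    """Sample x gene expression table with tissue and category labels.

    Housekeeping genes receive a large positive offset everywhere;
    tissue-specific genes receive it only in their designated tissues, so
    both rank in the top expression stratum exactly where intended.
    """
    rng = np.random.default_rng(spec.seed)
    genes = gene_names(spec.n_genes)
    universe = set(genes)
    for g in spec.housekeeping_genes:
        if g not in universe:
            raise ValueError(f"housekeeping gene {g!r} not in gene universe")
    for g in spec.tissue_specific_genes:
        if g not in universe:
            raise ValueError(f"tissue-specific gene {g!r} not in gene universe")
    tissues = spec.tissue_labels()
    tissue_names = {t for t, _ in tissues}
    for g, assignments in spec.tissue_specific_genes.items():
        for tissue, category in assignments:
            if tissue not in tissue_names:
                raise ValueError(f"unknown tissue {tissue!r} for gene {g!r}")

    # per-gene baseline, shared across tissues so tissue means are stable
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    hk_idx = [gene_index[g] for g in spec.housekeeping_genes]
    # pin tissue-specific genes well below the baseline band outside their
    # designated tissues so "top only where designated" holds by construction
    for g in spec.tissue_specific_genes:
        baseline[gene_index[g]] = spec.baseline_mean - 6.0 * spec.baseline_sd

    rows = []
    sample_counter = 0
    for tissue, category in tissues:
        if isinstance(spec.samples_per_tissue, tuple):
            lo, hi = spec.samples_per_tissue
            n = int(rng.integers(lo, hi + 1))
        else:
            n = int(spec.samples_per_tissue)
        offsets = np.zeros(spec.n_genes)
        offsets[hk_idx] = spec.high_offset
        for g, assignments in spec.tissue_specific_genes.items():
            if (tissue, category) in assignments:
                offsets[gene_index[g]] = spec.high_offset
        means = baseline + offsets
        values = means + rng.normal(0.0, 0.25, size=(n, spec.n_genes))
        for i in range(n):
            rows.append(
                {
                    "sample": f"S{sample_counter:05d}",
                    "tissue": tissue,
                    "category": category,
                    **dict(zip(genes, values[i])),
                }
            )
            sample_counter += 1
    return pd.DataFrame(rows)


def simulate_ihc_table(
    n_samples: int,
    subtype_mix: dict[str, float],
    hscore_dists: dict[str, tuple[float, float]],
    seed: int = 0,
) -> pd.DataFrame:
    """IHC scoring table with class-conditional H-score distributions.

    For each sample a subtype is drawn from ``subtype_mix``, a target
    H-score from the subtype's truncated-normal (mean, sd) distribution on
    [0, 300], and decomposed into an intensity in 0..3 and a percent
    positive in [0, 100] whose product is the H-score.
    """
    for subtype, (mean, _) in hscore_dists.items():
        if not 0.0 <= mean <= 300.0:
            raise ValueError(f"H-score mean for {subtype!r} outside [0, 300]")
    rng = np.random.default_rng(seed)
    subtypes = list(subtype_mix)
    probs = np.array([subtype_mix[s] for s in subtypes], dtype=float)
    probs /= probs.sum()
    rows = []
    for i in range(n_samples):
        subtype = subtypes[rng.choice(len(subtypes), p=probs)]
        mean, sd = hscore_dists[subtype]
        h = float(np.clip(rng.normal(mean, sd), 0.0, 300.0)) if sd > 0 else float(mean)
        if h == 0:
            intensity, percent = 0, 0.0
        else:
            intensity = int(np.clip(np.ceil(h / 100.0), 1, 3))
            percent = h / intensity
        rows.append(
            {
                "sample": f"IHC{i:04d}",
                "subtype": subtype,
                "intensity": intensity,
                "percent_positive": percent,
            }
        )
    return pd.DataFrame(rows)


def simulate_qpcr(
    n_samples: int,
    true_relative_expression: dict[str, float] | float = 1.0,
    ct_noise_sd: float = 0.1,
    seed: int = 0,
    reference_ct_mean: float = 20.0,
    calibrator_delta_ct: float = 5.0,
) -> pd.DataFrame:
    """Ct triplicate table whose delta-delta-Ct recovers a known truth.

    Target Ct is set to reference Ct + calibrator dCt - log2(relative
    expression), so with zero noise the recovered relative expression
    equals the truth exactly.
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        sample = f"Q{i:04d}"
        if isinstance(true_relative_expression, dict):
            rel = true_relative_expression.get(sample, 1.0)
        else:
            rel = float(true_relative_expression)
        if rel <= 0:
            raise ValueError("relative expression must be positive")
        ref_ct = reference_ct_mean
        target_ct = ref_ct + calibrator_delta_ct - np.log2(rel)
        row = {"sample": sample, "true_relative_expression": rel,
               "calibrator_delta_ct": calibrator_delta_ct}
        for k in range(3):
            row[f"target_ct_{k + 1}"] = target_ct + rng.normal(0, ct_noise_sd)
            row[f"reference_ct_{k + 1}"] = ref_ct + rng.normal(0, ct_noise_sd)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_viability_plate(
    treatments: list[str],
    true_effects: dict[str, float],
    background: float = 500.0,
    control_signal: float = 50_000.0,
    noise_sd: float = 0.0,
    n_replicates: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Luminescence plate with replicate wells per treatment.

    ``true_effects`` maps each treatment to its viability fraction of the
    control (control itself is 1.0); eight replicate wells per treatment
    by default, plus control and media-background wells.
    """
    for t, e in true_effects.items():
        if e <= 0:
            raise ValueError(f"effect for {t!r} must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    well = 0

    def add_wells(label: str, signal: float) -> None:
        nonlocal well
        for _ in range(n_replicates):
            lum = background + signal + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            rows.append(
                {"well": f"W{well:03d}", "treatment": label, "luminescence": max(lum, 0.0)}
            )
            well += 1

    add_wells("background", 0.0)
    add_wells("control", control_signal)
    for t in treatments:
        add_wells(t, control_signal * true_effects.get(t, 1.0))
    return pd.DataFrame(rows)
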
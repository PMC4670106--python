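"""Synthetic cohort generator with ground truth.

Emulates the statistical structure of a post-mortem case/control brain
RNA-seq study so every downstream stage is testable without any download:

* negative-binomial counts (variance mu + alpha*mu^2) with sample-specific
  sequencing-depth multipliers and heavy-tailed log-normal base means;
* a configurable fraction of genes truly differentially expressed, skewed
  toward up-regulation in cases;
* a small class of "case-exclusive" genes whose control-side mean is a
  near-zero floor (0.05 normalized counts) — the analogue of homeobox-like
  genes detected almost only in disease tissue;
* clinical covariates: cases die younger than controls on average, cases
  carry an expanded CAG repeat whose length correlates negatively with age
  at onset, plus RIN and neuropathological involvement scores;
* geneset collections with sets planted to concentrate at chosen depths of
  a ranked gene list, for recovery tests of the enrichment sweep.

Defaults model a scaled-down cohort: 2,000 genes, 20 cases vs 49 controls,
19% of genes DE with 54.8% of those up-regulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .preprocess import CASE_LABEL, CONTROL_LABEL

EXCLUSIVE_FLOOR = 0.05  # control-side mean for case-exclusive genes


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    nb_dispersion is the NB overdispersion alpha in var = mu + alpha*mu^2;
    depth_range is the uniform range of per-sample depth multipliers;
    lfc_scale scales the spread of true |log2 fold changes|.
    """

    n_genes: int = 2000
    n_cases: int = 20
    n_controls: int = 49
    de_fraction: float = 0.19
    up_fraction: float = 0.548
    exclusive_fraction: float = 0.02
    lfc_scale: float = 1.0
    nb_dispersion: float = 0.1
    depth_range: tuple[float, float] = (0.5, 1.5)
    base_mean_log_mu: float = 4.0
    base_mean_log_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("simulation dimensions must be positive")
        for name in ("de_fraction", "up_fraction", "exclusive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.lfc_scale <= 0:
            raise ConfigurationError("lfc_scale must be positive")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be non-negative")
        lo, hi = self.depth_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError(f"invalid depth_range {self.depth_range}")
        n_de = int(round(self.de_fraction * self.n_genes))
        if self.de_fraction > 0 and n_de < 1:
            raise ConfigurationError(
                "de_fraction * n_genes must be >= 1 when de_fraction > 0")
        if int(round(self.exclusive_fraction * n_de)) > n_de:
            raise ConfigurationError("exclusive genes must be a subset of DE genes")


@dataclass(frozen=True)
class GeneSetTruth:
    """A geneset planted to concentrate in the top `planted_depth` ranks."""

    set_name: str
    planted_depth: int
    planted_overlap: int
    set_size: int

    def __post_init__(self):
        if self.planted_overlap > self.set_size:
            raise ConfigurationError(
                f"{self.set_name}: planted_overlap {self.planted_overlap} "
                f"exceeds set size {self.set_size}")
        if self.planted_depth < 1 or self.planted_overlap < 0:
            raise ConfigurationError(f"{self.set_name}: invalid planting")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson NB sampler; degenerates to Poisson as alpha -> 0."""
    if alpha < 1e-12:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def simulate_counts(config: SimulationConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (counts, sample table, truth table) under `config`.

    Counts are drawn gene-wise from NB with mean
    depth_j * base_mean_i * 2^(lfc_i * [case_j]); case-exclusive genes have
    their control-side mean replaced by the floor 0.05 so sampling remains
    defined while control counts are almost surely zero. The same seed
    reproduces identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_de = int(round(config.de_fraction * n))
    n_excl = int(round(config.exclusive_fraction * n_de))

    gene_ids = [f"G{i:05d}" for i in range(n)]
    base_mean = rng.lognormal(config.base_mean_log_mu,
                              config.base_mean_log_sigma, size=n)

    is_de = np.zeros(n, dtype=bool)
    de_idx = rng.choice(n, size=n_de, replace=False)
    is_de[de_idx] = True
    is_excl = np.zeros(n, dtype=bool)
    excl_idx = de_idx[:n_excl]
    is_excl[excl_idx] = True

    # effect sizes: |lfc| = 0.25 + Gamma(2, lfc_scale/2): modest floor keeps
    # effects detectable; heavy right tail mimics the wide printed range.
    magnitude = 0.25 + rng.gamma(2.0, config.lfc_scale / 2.0, size=n)
    sign = np.where(rng.random(n) < config.up_fraction, 1.0, -1.0)
    true_lfc = np.where(is_de, sign * magnitude, 0.0)

    control_mean = base_mean.copy()
    case_mean = base_mean * 2.0 ** true_lfc
    # exclusive genes: expressed in cases, floor in controls (always up)
    if n_excl:
        excl_case = np.maximum(base_mean[excl_idx], 2.0)
        case_mean[excl_idx] = excl_case
        control_mean[excl_idx] = EXCLUSIVE_FLOOR
        true_lfc[excl_idx] = np.log2(excl_case / EXCLUSIVE_FLOOR)

    n_samp = config.n_cases + config.n_controls
    is_case = np.zeros(n_samp, dtype=bool)
    is_case[: config.n_cases] = True
    depths = rng.uniform(*config.depth_range, size=n_samp)

    mu = np.where(is_case[None, :], case_mean[:, None], control_mean[:, None])
    mu = mu * depths[None, :]
    counts = _nb_draw(rng, mu, config.nb_dispersion)

    sample_ids = [f"HD_{i:03d}" for i in range(config.n_cases)] + \
                 [f"C_{i:03d}" for i in range(config.n_controls)]
    age = np.where(is_case,
                   rng.normal(58.0, 10.0, n_samp),
                   rng.normal(69.0, 15.0, n_samp))
    age = np.clip(np.round(age), 30, 106).astype(int)
    rin = np.where(is_case,
                   rng.normal(7.2, 0.8, n_samp),
                   rng.normal(7.8, 0.7, n_samp))
    rin = np.clip(np.round(rin, 1), 5.5, 9.5)

    cag = rng.integers(40, 54, size=config.n_cases)
    onset = 136.5 - 2.1 * cag + rng.normal(0.0, 5.0, config.n_cases)
    onset = np.minimum(np.round(onset), age[: config.n_cases] - 2)
    onset = np.maximum(onset, 18).astype(int)
    duration = age[: config.n_cases] - onset
    grade = rng.choice([3, 4], p=[0.7, 0.3], size=config.n_cases)
    hv_striatal = np.clip(rng.normal(2.9, 0.5, config.n_cases), 1.5, 4.0)
    hv_cortical = np.clip(rng.normal(1.35, 0.5, config.n_cases), 0.2, 2.6)

    samples = pd.DataFrame({
        "condition": np.where(is_case, CASE_LABEL, CONTROL_LABEL),
        "age_of_death": age,
        "rin": rin,
        "depth_factor": depths,
    }, index=pd.Index(sample_ids, name="sample_id"))
    for col, vals in [("cag", cag), ("age_of_onset", onset),
                      ("duration", duration), ("vonsattel_grade", grade),
                      ("hv_striatal", np.round(hv_striatal, 3)),
                      ("hv_cortical", np.round(hv_cortical, 3))]:
        samples[col] = np.nan
        samples.iloc[: config.n_cases, samples.columns.get_loc(col)] = vals

    truth = pd.DataFrame({
        "is_de": is_de,
        "true_lfc": true_lfc,
        "is_exclusive": is_excl,
        "base_mean": base_mean,
    }, index=pd.Index(gene_ids, name="gene_id"))

    counts_df = pd.DataFrame(counts, index=truth.index, columns=samples.index)
    return counts_df, samples, truth


def simulate_biotypes(gene_ids, seed: int = 0,
                      proportions: dict[str, float] | None = None) -> dict[str, str]:
    """Assign biotypes at the approximate genome-wide mix of a bulk study."""
    proportions = proportions or {
        "protein_coding": 0.70, "lincRNA": 0.12, "pseudogene": 0.10,
        "antisense": 0.06, "other": 0.02,
    }
    rng = np.random.default_rng(seed)
    labels = list(proportions)
    draws = rng.choice(labels, p=list(proportions.values()), size=len(gene_ids))
    return dict(zip(gene_ids, draws))


def simulate_genesets(gene_ids: list[str], n_sets: int,
                      set_size: int | tuple[int, int],
                      planted: list[GeneSetTruth] | None = None,
                      seed: int = 0, prefix: str = "SET"
                      ) -> dict[str, list[str]]:
    """Build a geneset collection over `gene_ids` (ranked by planted effect).

    Planted sets draw `planted_overlap` members uniformly from ranks
    <= planted_depth and the remainder from the rest of the universe;
    non-planted sets are uniform draws from the whole universe.
    """
    rng = np.random.default_rng(seed)
    planted = planted or []
    universe = list(gene_ids)
    n_univ = len(universe)
    for p in planted:
        if p.planted_depth > n_univ:
            raise ConfigurationError(
                f"{p.set_name}: planted_depth {p.planted_depth} exceeds "
                f"universe size {n_univ}")

    def draw_size() -> int:
        if isinstance(set_size, tuple):
            return int(rng.integers(set_size[0], set_size[1] + 1))
        return int(set_size)

    sets: dict[str, list[str]] = {}
    for p in planted:
        top = rng.choice(p.planted_depth, size=p.planted_overlap, replace=False)
        members = {universe[i] for i in top}
        rest_pool = [g for g in universe if g not in members]
        n_rest = p.set_size - p.planted_overlap
        if n_rest:
            rest = rng.choice(len(rest_pool), size=n_rest, replace=False)
            members |= {rest_pool[i] for i in rest}
        sets[p.set_name] = sorted(members)
    for i in range(n_sets - len(planted)):
        size = min(draw_size(), n_univ)
        idx = rng.choice(n_univ, size=size, replace=False)
        sets[f"{prefix}_{i:03d}"] = sorted(universe[j] for j in idx)
    return sets
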
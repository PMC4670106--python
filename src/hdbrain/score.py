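"""Differential Expression Score (DES) and ranked-list descriptive statistics.

A significance-only ranking of a DE table is dominated by low-abundance
genes that are absent in one group: they reach astronomical p-values at
trivial expression levels. The DES re-prioritizes genes that are abundant,
strongly changed, *and* significant:

    DES = overall_mean * |log2 FC| * (-log10 padj)

where overall_mean is the mean normalized count over all samples and padj
the FDR-adjusted p-value (floored at 1e-300 so an underflowed p cannot
produce an infinite score). DES is strictly increasing in each factor,
so e.g. a myelin gene at 180,000 mean counts with a modest fold change
outranks a near-silent homeobox gene with a 10^-34 adjusted p.

Also here: the up/down sliding-window profile over a significance-ranked
gene list, biotype composition of a gene list, and row-max normalization
for expression heatmaps.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

PADJ_FLOOR = 1e-300


def des(overall_mean, lfc, padj, padj_floor: float = PADJ_FLOOR):
    """DES = overall_mean * |lfc| * (-log10 max(padj, padj_floor)).

    Scalar or array arguments (broadcast). padj must lie in (0, 1] after
    flooring; overall_mean must be non-negative.
    """
    overall_mean = np.asarray(overall_mean, dtype=float)
    lfc = np.asarray(lfc, dtype=float)
    padj = np.asarray(padj, dtype=float)
    if (overall_mean < 0).any():
        raise InputError("des: overall_mean must be non-negative")
    clamped = np.maximum(padj, padj_floor)
    if ((clamped <= 0) | (clamped > 1)).any():
        bad = padj[(clamped <= 0) | (clamped > 1)]
        raise InputError(f"des: padj outside (0, 1]: {bad[:5]}")
    result = overall_mean * np.abs(lfc) * (-np.log10(clamped))
    return float(result) if result.ndim == 0 else result


def add_des(table: pd.DataFrame, padj_floor: float = PADJ_FLOOR,
            use_nominal_p: bool = False) -> pd.DataFrame:
    """Return a copy of a DE table with a `des` column appended.

    ``use_nominal_p`` switches the significance factor to the nominal p,
    for sensitivity analysis only; the score is defined on adjusted p.
    """
    out = table.copy()
    pcol = "p" if use_nominal_p else "padj"
    out["des"] = des(out["overall_mean"].to_numpy(),
                     out["lfc"].to_numpy(),
                     out[pcol].to_numpy(), padj_floor=padj_floor)
    return out


def rank_by_des(table: pd.DataFrame) -> pd.DataFrame:
    """Full table sorted descending by DES (ties by gene_id), with `des_rank`."""
    scored = table if "des" in table.columns else add_des(table)
    scored = scored.reset_index() if scored.index.name else scored.copy()
    idcol = "gene_id" if "gene_id" in scored.columns else scored.columns[0]
    scored = scored.sort_values(["des", idcol], ascending=[False, True],
                                kind="stable")
    scored["des_rank"] = np.arange(1, len(scored) + 1)
    return scored.set_index(idcol)


def updown_profile(lfc_ranked, window: int = 100, step: int = 1) -> pd.DataFrame:
    """Fraction of up-regulated genes in a sliding window down a ranked list.

    At position x the window covers ranks (x, x + window] (1-based); the
    final windows truncate to the genes available. Returns a table of
    (position, fraction_up, window_size).
    """
    if window < 1:
        raise ConfigurationError(f"updown_profile: window must be >= 1, got {window}")
    if step < 1:
        raise ConfigurationError(f"updown_profile: step must be >= 1, got {step}")
    lfc = np.asarray(lfc_ranked, dtype=float)
    n = lfc.size
    if window > n:
        raise ConfigurationError(
            f"updown_profile: window {window} exceeds list length {n}")
    up = (lfc > 0).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(up)])
    positions = np.arange(0, n, step)
    ends = np.minimum(positions + window, n)
    sizes = ends - positions
    valid = sizes > 0
    positions, ends, sizes = positions[valid], ends[valid], sizes[valid]
    frac = (csum[ends] - csum[positions]) / sizes
    return pd.DataFrame({"position": positions, "fraction_up": frac,
                         "window_size": sizes})


def biotype_composition(genes, biotypes: dict[str, str]) -> pd.Series:
    """Proportion of each biotype among `genes`; unmapped genes -> 'unknown'."""
    labels = []
    n_missing = 0
    for g in genes:
        b = biotypes.get(g)
        if b is None:
            n_missing += 1
            b = "unknown"
        labels.append(b)
    if n_missing:
        logger.warning("biotype_composition: %d of %d genes missing from the "
                       "biotype map, bucketed as 'unknown'", n_missing, len(labels))
    counts = pd.Series(labels).value_counts()
    return (counts / counts.sum()).sort_values(ascending=False)


def lfc_histogram(lfc, bins: int = 50) -> pd.DataFrame:
    """Histogram of log2 fold changes (bin edges and counts) for DE genes."""
    lfc = np.asarray(lfc, dtype=float)
    counts, edges = np.histogram(lfc, bins=bins)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})


def rowmax_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its maximum; all-zero rows pass through as zeros."""
    mat = matrix.to_numpy(dtype=float)
    rowmax = mat.max(axis=1)
    zero = rowmax <= 0
    if zero.any():
        logger.warning("rowmax_normalize: %d all-zero rows left unscaled",
                       int(zero.sum()))
    scale = np.where(zero, 1.0, rowmax)
    return pd.DataFrame(mat / scale[:, None], index=matrix.index,
                        columns=matrix.columns)
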
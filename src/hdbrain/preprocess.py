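"""Count preprocessing: low-signal filter, outlier trimming, normalization, VST.

The preprocessing contract mirrors a standard bulk RNA-seq workflow on a
case/control cohort:

1. Drop genes detected (nonzero) in fewer than half the samples of *both*
   groups. Retention on either group's evidence alone is deliberate: genes
   expressed almost exclusively in cases — which include the strongest
   disease signals in this setting — survive even though every control
   count is zero.
2. Winsorize extreme counts per gene per group at the Tukey fence
   Q3 + k*IQR (k = 3 by default, quartiles by linear interpolation), so a
   single aberrant library cannot drive a gene's fold change.
3. Median-of-ratios size factors and normalized counts.
4. A closed-form variance-stabilizing transform for NB(mu, mu + alpha*mu^2)
   counts, g(x) = (2/sqrt(alpha)) * asinh(sqrt(alpha*x)), which makes
   per-gene variances approximately constant in the mean so downstream
   per-gene linear regressions are well behaved.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LabelingError, NormalizationError

logger = logging.getLogger(__name__)

CASE_LABEL = "HD"
CONTROL_LABEL = "control"


def _group_masks(counts: pd.DataFrame, groups: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    groups = groups.reindex(counts.columns)
    known = groups.isin([CASE_LABEL, CONTROL_LABEL])
    if not known.all():
        bad = groups.index[~known].tolist()
        raise LabelingError(
            f"samples with unknown group label: {bad} "
            f"(expected {CASE_LABEL!r} or {CONTROL_LABEL!r})"
        )
    case = (groups == CASE_LABEL).to_numpy()
    control = (groups == CONTROL_LABEL).to_numpy()
    if case.sum() == 0 or control.sum() == 0:
        raise LabelingError("both groups must be non-empty")
    return case, control


def filter_low_signal(counts: pd.DataFrame, groups: pd.Series
                      ) -> tuple[pd.DataFrame, list[str]]:
    """Remove genes with nonzero counts in less than half of both groups.

    A gene is retained iff it is nonzero in at least ceil(n_case/2) case
    samples OR at least ceil(n_control/2) control samples. Returns the
    filtered matrix and the list of removed gene identifiers.
    """
    case, control = _group_masks(counts, groups)
    nz = counts.to_numpy() > 0
    case_ok = nz[:, case].sum(axis=1) >= int(np.ceil(case.sum() / 2))
    ctrl_ok = nz[:, control].sum(axis=1) >= int(np.ceil(control.sum() / 2))
    keep = case_ok | ctrl_ok
    removed = counts.index[~keep].tolist()
    logger.info("filter_low_signal: removed %d of %d genes",
                len(removed), counts.shape[0])
    return counts.loc[keep], removed


def trim_outlier_counts(counts: pd.DataFrame, groups: pd.Series,
                        k: float = 3.0) -> pd.DataFrame:
    """Winsorize per-gene per-group counts above the Tukey fence Q3 + k*IQR.

    Quartiles use linear interpolation. Values above the fence are replaced
    by ceil(Q3 + k*IQR), so counts stay integral and never increase. The
    within-group median is never altered (the fence is always >= Q3).
    """
    if k <= 0:
        raise ConfigurationError(f"trim_outlier_counts: k must be > 0, got {k}")
    case, control = _group_masks(counts, groups)
    out = counts.to_numpy().copy()
    n_trimmed = 0
    for mask in (case, control):
        block = out[:, mask].astype(float)
        q1 = np.percentile(block, 25, axis=1)
        q3 = np.percentile(block, 75, axis=1)
        bound = np.ceil(q3 + k * (q3 - q1))
        over = block > bound[:, None]
        n_trimmed += int(over.sum())
        block = np.where(over, bound[:, None], block)
        out[:, mask] = block.astype(out.dtype)
    logger.info("trim_outlier_counts: adjusted %d cells (k=%g)", n_trimmed, k)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each gene a geometric mean across samples is computed; genes with a
    positive geometric mean (nonzero in every sample) form the reference
    set, and each sample's factor is the median of its counts over the
    reference genes divided by their geometric means.
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        loggeo = np.log(mat).mean(axis=1)
    ref = np.isfinite(loggeo)
    if not ref.any():
        raise NormalizationError(
            "size_factors: no gene has nonzero counts in every sample; "
            "cannot form a median-of-ratios reference set. Filter your "
            "matrix less aggressively or provide size factors directly."
        )
    ratios = np.log(mat[ref]) - loggeo[ref][:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if factors is None:
        factors = size_factors(counts)
    return counts / factors.reindex(counts.columns)


def estimate_dispersion(normalized: pd.DataFrame, groups: pd.Series,
                        per_gene: bool = False, floor: float = 1e-8
                        ) -> float | np.ndarray:
    """Method-of-moments NB dispersion from within-group mean/variance pairs.

    For each gene, alpha = (s^2 - mean) / mean^2 pooled within groups
    (unbiased variance), floored at `floor`. With ``per_gene=False`` the
    median across genes with positive means is returned as a shared alpha.
    """
    case, control = _group_masks(normalized, groups)
    mat = normalized.to_numpy(dtype=float)
    num = np.zeros(mat.shape[0])
    df = 0
    means = mat.mean(axis=1)
    for mask in (case, control):
        block = mat[:, mask]
        mu = block.mean(axis=1, keepdims=True)
        num += ((block - mu) ** 2).sum(axis=1)
        df += mask.sum() - 1
    s2 = num / max(df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - means) / means**2
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    alpha = np.maximum(alpha, floor)
    if per_gene:
        return alpha
    positive = means > 0
    return float(np.median(alpha[positive])) if positive.any() else floor


def vst(normalized: pd.DataFrame | np.ndarray, alpha: float):
    """Closed-form variance-stabilizing transform for NB counts.

    g(x) = (2 / sqrt(alpha)) * asinh(sqrt(alpha * x)); monotone, g(0) = 0,
    and g(x) -> 2*sqrt(x) as alpha -> 0 (the Poisson limit).
    """
    if alpha <= 0:
        raise ConfigurationError(f"vst: alpha must be > 0, got {alpha}")
    values = np.asarray(normalized, dtype=float) if not isinstance(
        normalized, pd.DataFrame) else normalized
    if np.any(np.asarray(values) < 0):
        raise ConfigurationError("vst: normalized values must be non-negative")
    result = (2.0 / np.sqrt(alpha)) * np.arcsinh(np.sqrt(alpha * values))
    return result
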
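"""Pre-inference transformations.

The expression layers go through log2 → background filtering → quantile
normalization → empirical-Bayes batch adjustment; the microbial layer goes
through log2 of normalized counts and, before correlation analysis, per-feature
Z-scoring.  All operations preserve feature and sample ID order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import OmicsMatrix, SampleMetadata, Scale

__all__ = [
    "BackgroundModel",
    "log2_transform",
    "filter_above_background",
    "quantile_normalize",
    "batch_adjust",
    "zscore_rows",
]

log = logging.getLogger(__name__)


@dataclass
class BackgroundModel:
    """Per-sample background intensity thresholds (same scale as the matrix).

    Built either from explicit thresholds or from designated negative-control
    features summarized as mean + ``n_sd``·SD per sample.
    """

    thresholds: pd.Series  # indexed by sample_id

    def __post_init__(self) -> None:
        if not np.isfinite(self.thresholds.to_numpy(dtype=float)).all():
            raise ValueError("background thresholds must be finite")

    @classmethod
    def from_negative_controls(cls, m: OmicsMatrix, control_ids,
                               n_sd: float = 2.0) -> "BackgroundModel":
        ctrl = m.subset_features(list(control_ids)).values
        thr = ctrl.mean(axis=0) + n_sd * ctrl.std(axis=0, ddof=1)
        return cls(pd.Series(thr, index=m.sample_ids))


def log2_transform(m: OmicsMatrix, pseudocount: float = 0.0) -> OmicsMatrix:
    """log2(x + pseudocount); requires non-negative input and a finite result."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    x = m.values
    if (x < 0).any():
        raise ValueError("log2_transform requires non-negative values")
    if pseudocount == 0 and (x == 0).any():
        raise ValueError("zeros present with pseudocount=0 (log2 would be -inf)")
    return m.with_values(np.log2(x + pseudocount), scale=Scale.LOG2)


def filter_above_background(m: OmicsMatrix, bg: BackgroundModel,
                            min_fraction: float = 0.5) -> OmicsMatrix:
    """Keep features above background in at least ``min_fraction`` of samples.

    A feature is retained iff the count of samples where its value strictly
    exceeds that sample's threshold is ≥ ``min_fraction · n_samples``
    (inclusive — "at least half").
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    thr = bg.thresholds.reindex(m.sample_ids)
    if thr.isna().any():
        missing = thr.index[thr.isna()].tolist()
        raise KeyError(f"background thresholds missing for samples: {missing[:5]}")
    above = (m.values > thr.to_numpy(dtype=float)[None, :]).sum(axis=1)
    keep = above >= min_fraction * m.n_samples
    if not keep.any():
        warnings.warn("all features fell below background; result is empty")
    return OmicsMatrix(m.data.loc[keep], m.layer, m.scale)


def quantile_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Force every sample onto the common mean distribution by rank.

    After normalization each sample's sorted values equal the across-sample
    mean of sorted values; ties within a sample receive the mean of the
    reference quantiles they span, so the result is order-independent.
    """
    if m.n_samples == 1:
        warnings.warn("quantile_normalize on a single sample is a no-op")
        return m.with_values(m.values)
    x = m.values
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # ties: average the reference quantiles the tie group spans
        sorted_vals = col[order]
        start = 0
        while start < len(sorted_vals):
            stop = start
            while stop + 1 < len(sorted_vals) and sorted_vals[stop + 1] == sorted_vals[start]:
                stop += 1
            if stop > start:
                assigned[order[start:stop + 1]] = ref[start:stop + 1].mean()
            start = stop + 1
        out[:, j] = assigned
    return m.with_values(out)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    from scipy.special import polygamma
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def batch_adjust(m: OmicsMatrix, meta: SampleMetadata, factor: str,
                 preserve: str | None = "group",
                 tol: float = 1e-8, max_iter: int = 200) -> OmicsMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    The classic ComBat scheme: per feature, estimate grand and group effects by
    least squares; standardize residuals; estimate per-batch location (γ) and
    scale (δ²) and shrink them toward normal / inverse-gamma priors with
    moment-matched hyperparameters; adjust by (x − γ*)/δ* and restore the
    preserved design. Group structure named by ``preserve`` is kept intact.
    """
    meta = meta.aligned_to(m)
    batches = meta.table[factor].astype(str).to_numpy()
    levels = list(dict.fromkeys(batches))
    n = m.n_samples
    if len(levels) == 1:
        return m.with_values(m.values)

    # design: batch indicators + (non-reference) group indicator
    design_cols: list[np.ndarray] = [
        (batches == lev).astype(float) for lev in levels]
    n_batch = len(levels)
    if preserve is not None:
        groups = meta.table[meta.group_col if preserve == "group" else preserve]
        groups = groups.astype(str).to_numpy()
        glevels = list(dict.fromkeys(groups))
        for lev in glevels[1:]:
            design_cols.append((groups == lev).astype(float))
    design = np.column_stack(design_cols)  # n × p
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"batch factor {factor!r} design is rank-deficient "
            "(batch confounded 1:1 with the preserved covariate)")

    x = m.values  # G × n
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)  # p × G
    batch_sizes = np.array([(batches == lev).sum() for lev in levels], dtype=float)
    grand = (batch_sizes / n) @ beta[:n_batch, :]  # G
    resid = x.T - design @ beta
    var_pooled = (resid ** 2).sum(axis=0) / n  # G
    if (var_pooled <= 0).any():
        raise ValueError("zero pooled variance for some features; cannot standardize")

    stand_mean = np.tile(grand, (n, 1))
    if design.shape[1] > n_batch:
        stand_mean = stand_mean + design[:, n_batch:] @ beta[n_batch:, :]
    z = (x.T - stand_mean) / np.sqrt(var_pooled)  # n × G standardized

    # per-batch location/scale estimates
    gamma_hat = np.vstack([z[batches == lev].mean(axis=0) for lev in levels])
    delta_hat = np.vstack([z[batches == lev].var(axis=0, ddof=1) for lev in levels])

    # moment-matched hyperpriors per batch
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    d_mean = delta_hat.mean(axis=1)
    d_var = delta_hat.var(axis=1, ddof=1)
    a_prior = (2 * d_var + d_mean ** 2) / d_var
    b_prior = (d_mean * d_var + d_mean ** 3) / d_var

    z_adj = z.copy()
    for bi, lev in enumerate(levels):
        mask = batches == lev
        nb = mask.sum()
        zb = z[mask]
        g_old = gamma_hat[bi].copy()
        d_old = delta_hat[bi].copy()
        for _ in range(max_iter):
            g_new = (nb * tau2[bi] * gamma_hat[bi] + d_old * gamma_bar[bi]) / (
                nb * tau2[bi] + d_old)
            sum2 = ((zb - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + b_prior[bi]) / (nb / 2.0 + a_prior[bi] - 1.0)
            change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        z_adj[mask] = (zb - g_old[None, :]) / np.sqrt(d_old)[None, :]

    out = z_adj * np.sqrt(var_pooled) + stand_mean
    return m.with_values(out.T)


def zscore_rows(m: OmicsMatrix) -> OmicsMatrix:
    """Standardize each feature across samples (mean 0, SD 1; n−1 denominator)."""
    x = m.values
    sd = x.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        ids = [m.feature_ids[i] for i in bad[:10]]
        raise ValueError(f"zero-variance features cannot be Z-scored: {ids}")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return m.with_values(z, scale=Scale.ZSCORE)
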
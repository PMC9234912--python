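"""Two-group differential expression/abundance with FDR control.

Expression layers use an empirical-Bayes moderated t-test: per-feature residual
variances s²_g (d_g = n_A + n_B − 2 df each) are shrunk toward a prior (d₀, s₀²)
estimated by moment-matching the distribution of log s²_g, giving posterior
variances s̃²_g = (d₀·s₀² + d_g·s²_g)/(d₀ + d_g) and t-statistics on d₀ + d_g
degrees of freedom.  Setting d₀ = 0 recovers the ordinary pooled two-sample t
exactly; d₀ → ∞ pools every feature to the common prior variance.  The
microbial layer uses a plain two-sample t.  Multiplicity is controlled with
Benjamini-Hochberg step-up adjustment.

Effect sizes are reported as ``log2_fc`` = mean(group A) − mean(group B) in
log2 units, where group A is the first group level in the metadata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .preprocess import _trigamma_inverse
from .types import Layer, OmicsMatrix, SampleMetadata

__all__ = [
    "moderated_t_test",
    "two_sample_t",
    "bh_adjust",
    "apply_de_filters",
    "split_layers",
    "infer_layer_from_prefix",
]

RESULT_COLUMNS = ["layer", "log2_fc", "statistic", "df",
                  "p_raw", "p_adj", "significant", "passes_fc"]


def _group_arrays(m: OmicsMatrix, meta: SampleMetadata):
    meta = meta.aligned_to(m)
    groups = meta.table[meta.group_col].astype(str).to_numpy()
    lev_a, lev_b = meta.group_levels
    xa = m.values[:, groups == lev_a]
    xb = m.values[:, groups == lev_b]
    if xa.shape[1] < 2 or xb.shape[1] < 2:
        raise ValueError("both groups need at least two samples")
    return xa, xb


def _finalize(m: OmicsMatrix, beta, tstat, df, p_raw,
              alpha: float = 0.05) -> pd.DataFrame:
    res = pd.DataFrame({
        "layer": m.layer.value,
        "log2_fc": beta,
        "statistic": tstat,
        "df": df,
        "p_raw": p_raw,
    }, index=pd.Index(m.feature_ids, name="feature_id"))
    res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())
    res["significant"] = res["p_adj"] <= alpha
    res["passes_fc"] = True
    return res


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d₀, s₀²) to the empirical distribution of log s²_g.

    Features with s² = 0 are excluded from the fit.  Returns
    ``(inf, exp(mean))`` when the excess spread of log s² is non-positive
    (no feature-to-feature variance heterogeneity beyond chi-square noise).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need ≥2 positive residual variances to fit the prior")
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0)


def moderated_t_test(m: OmicsMatrix, meta: SampleMetadata,
                     alpha: float = 0.05, d0: float | None = None,
                     s0_sq: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated t per feature (limma-style variance shrinkage).

    Parameters
    ----------
    d0, s0_sq:
        Override the prior df / prior variance; ``d0=0`` recovers the ordinary
        pooled two-sample t exactly.  By default both are estimated from the
        data by moment matching.
    """
    xa, xb = _group_arrays(m, meta)
    na, nb = xa.shape[1], xb.shape[1]
    beta = xa.mean(axis=1) - xb.mean(axis=1)
    df_resid = na + nb - 2
    ss = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((xb - xb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df_resid
    if (s2 == 0).mean() > 0.5:
        raise ValueError("zero residual variance on >50% of features")

    if d0 is None:
        d0_fit, s0_fit = fit_variance_prior(s2, df_resid)
    else:
        d0_fit = float(d0)
        s0_fit = float(s0_sq) if s0_sq is not None else (
            fit_variance_prior(s2, df_resid)[1] if d0_fit > 0 else 0.0)

    if np.isinf(d0_fit):
        s2_post = np.full_like(s2, s0_fit)
        df_total = np.inf
    elif d0_fit == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (d0_fit * s0_fit + df_resid * s2) / (d0_fit + df_resid)
        df_total = d0_fit + df_resid

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    p = np.where(se > 0, p, 1.0)
    res = _finalize(m, beta, tstat,
                    np.full(len(beta), df_total), p, alpha)
    res.attrs["d0"] = d0_fit
    res.attrs["s0_sq"] = s0_fit
    res.attrs["s2_post"] = s2_post
    return res


def two_sample_t(m: OmicsMatrix, meta: SampleMetadata, alpha: float = 0.05,
                 equal_var: bool = True) -> pd.DataFrame:
    """Classic two-sample t per feature (pooled variance; Welch optional)."""
    xa, xb = _group_arrays(m, meta)
    stat = stats.ttest_ind(xa, xb, axis=1, equal_var=equal_var)
    beta = xa.mean(axis=1) - xb.mean(axis=1)
    df = getattr(stat, "df", None)
    if df is None:  # older scipy
        df = np.full(len(beta), xa.shape[1] + xb.shape[1] - 2, dtype=float)
    tstat = np.nan_to_num(stat.statistic, nan=0.0)
    p = np.where(np.isnan(stat.pvalue), 1.0, stat.pvalue)
    return _finalize(m, beta, tstat, np.asarray(df, dtype=float), p, alpha)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def apply_de_filters(res: pd.DataFrame, alpha: float = 0.05,
                     fc_log2: float = 0.58, use_fc: bool = False) -> pd.DataFrame:
    """Flag significance (p_adj ≤ α, inclusive) and the fold-change gate.

    The fold-change gate is strict: |log2_fc| > ``fc_log2``.  Per the study
    design it applies to the mRNA layer only; lncRNAs and OTUs are gated on
    FDR alone, so callers pass ``use_fc`` per layer.
    """
    out = res.copy()
    out["significant"] = out["p_adj"] <= alpha
    if use_fc:
        out["passes_fc"] = out["log2_fc"].abs() > fc_log2
    else:
        out["passes_fc"] = True
    return out


_LNC_PREFIXES = ("NR_", "XR_", "ENS", "XLOC", "LINC")


def infer_layer_from_prefix(feature_id: str) -> Layer | None:
    """RefSeq/Ensembl convention: NR_/XR_/ENS* are non-coding, NM_/XM_ coding."""
    fid = str(feature_id)
    if fid.startswith(("NM_", "XM_")):
        return Layer.MRNA
    if fid.startswith(_LNC_PREFIXES):
        return Layer.LNCRNA
    return None


def split_layers(res: pd.DataFrame,
                 annotation: dict[str, Layer | str] | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition transcript-level results into (mRNA, lncRNA) layers.

    An explicit ``annotation`` map wins over ID-prefix inference; features
    that are neither annotated nor prefix-inferable raise an error.
    """
    annotation = {k: Layer(v) for k, v in (annotation or {}).items()}
    layers = []
    unknown = []
    for fid in res.index:
        lay = annotation.get(fid) or infer_layer_from_prefix(fid)
        if lay is None:
            unknown.append(fid)
        layers.append(lay)
    if unknown:
        raise ValueError(f"features with no layer annotation: {unknown[:10]}")
    mask = np.array([lay == Layer.MRNA for lay in layers], dtype=bool)
    mrna = res.loc[mask].copy()
    lnc = res.loc[~mask].copy()
    mrna["layer"] = Layer.MRNA.value
    lnc["layer"] = Layer.LNCRNA.value
    return mrna, lnc
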
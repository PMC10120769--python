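"""Count normalization: size factors, variance-stabilizing transform, and
co-normalization of test samples against a packaged reference cohort.

The VST here follows the standard negative-binomial recipe: per-gene
dispersions are estimated by method of moments on size-factor-normalized
counts, a parametric mean-dispersion trend alpha(mu) = a0 + a1/mu is fitted
by iteratively trimmed least squares, and the closed-form transform of that
trend is applied.  For large counts the transform is asymptotically log2.
Downstream classification consumes ranks and margins, so exact equivalence
with any particular reference implementation is not required; a plain
log2(normalized + 1) fallback is available and is selected automatically
when the trend fit is degenerate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CountMatrix, GEPMatrix

log = logging.getLogger(__name__)


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over genes g of count_gj / geomean_g, restricted to
    genes whose geometric mean across samples is positive.

    Raises
    ------
    ValueError
        If no gene is expressed in every sample (use the log fallback with
        total-count factors instead).
    """
    v = counts.values.to_numpy(dtype=float)
    if v.shape[1] < 2:
        raise ValueError("size factors require at least 2 samples")
    with np.errstate(divide="ignore"):
        loggeo = np.log(v).mean(axis=1)
    usable = np.isfinite(loggeo)
    if not usable.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "use log-fallback normalization (total-count size factors)"
        )
    ratios = np.log(v[usable]) - loggeo[usable, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def total_count_factors(counts: CountMatrix) -> pd.Series:
    """Library-size factors scaled to geometric mean 1 (fallback path)."""
    totals = counts.values.sum(axis=0).astype(float)
    factors = totals / np.exp(np.log(totals).mean())
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def _fit_dispersion_trend(mu: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu by robust (Huber) regression."""
    import statsmodels.api as sm

    keep = (disp > 1e-8) & (mu > 1.0) & np.isfinite(disp)
    if keep.sum() < 10:
        raise ValueError("too few genes with usable dispersion estimates")
    X = sm.add_constant(1.0 / mu[keep])
    res = sm.RLM(disp[keep], X).fit()
    return float(res.params[0]), float(res.params[1])


def _closed_form_vst(x: np.ndarray, a0: float, a1: float) -> np.ndarray:
    """Closed-form VST for the NB dispersion trend a0 + a1/mu.

    Integrating 1/sqrt(v(mu)) with v(mu) = mu + (a0 + a1/mu) mu^2 gives,
    up to affine scaling chosen so large counts land on the log2 scale:

        log2( (1 + a1 + 2 a0 x + 2 sqrt(a0 x (1 + a1 + a0 x))) / (4 a0) )
    """
    x = np.maximum(x, 0.0)
    inner = 1.0 + a1 + 2.0 * a0 * x + 2.0 * np.sqrt(
        a0 * x * (1.0 + a1 + a0 * x)
    )
    return np.log2(inner / (4.0 * a0))


def vst_transform(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    *,
    fallback: bool = False,
) -> GEPMatrix:
    """Variance-stabilize raw counts.

    Parameters
    ----------
    counts :
        Raw counts.
    factors :
        Size factors from :func:`size_factors`; computed if omitted.
    fallback :
        Force log2(normalized + 1) instead of the closed-form VST.
    """
    if factors is None:
        try:
            factors = size_factors(counts)
        except ValueError:
            log.warning("size-factor estimation failed; using total counts")
            factors = total_count_factors(counts)
            fallback = True
    norm = counts.values.to_numpy(dtype=float) / factors.to_numpy()[None, :]

    if not fallback:
        mu = norm.mean(axis=1)
        var = norm.var(axis=1, ddof=1) if norm.shape[1] > 1 else np.zeros_like(mu)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = (var - mu) / np.square(mu)
        disp = np.where(np.isfinite(disp), disp, 0.0)
        try:
            a0, a1 = _fit_dispersion_trend(mu, disp)
        except ValueError:
            a0, a1 = -1.0, 0.0
        if a0 <= 0 or a1 <= 0:
            log.warning(
                "dispersion trend fit degenerate (a0=%.3g, a1=%.3g); "
                "falling back to log2(normalized + 1)",
                a0,
                a1,
            )
            fallback = True
        else:
            values = _closed_form_vst(norm, a0, a1)
            return GEPMatrix(
                pd.DataFrame(
                    values, index=counts.gene_ids, columns=counts.sample_ids
                ),
                provenance="vst",
            )

    values = np.log2(norm + 1.0)
    return GEPMatrix(
        pd.DataFrame(values, index=counts.gene_ids, columns=counts.sample_ids),
        provenance="log-fallback",
    )


def conorm_to_reference(
    test: GEPMatrix,
    reference: GEPMatrix,
    *,
    min_overlap: float = 0.5,
    enabled: bool = True,
) -> GEPMatrix:
    """Quantile-map each test sample onto the pooled reference distribution.

    The test matrix is restricted to genes shared with the reference; genes
    present in the reference but missing from the test are imputed at the
    reference per-gene median (and logged).  Each test sample's values are
    then replaced by the pooled-reference quantiles at the sample's own
    plotting positions, which removes monotone global shifts while exactly
    preserving within-sample ranks.  Prediction models accept data without
    batch correction, so ``enabled=False`` skips the mapping and only
    aligns the gene space.

    Raises
    ------
    ValueError
        If fewer than ``min_overlap`` of reference genes are present.
    """
    shared = reference.genes.intersection(test.genes)
    frac = len(shared) / len(reference.genes)
    if frac < min_overlap:
        raise ValueError(
            f"insufficient gene overlap: {frac:.1%} of reference genes "
            f"present in test (need >= {min_overlap:.0%})"
        )
    missing = reference.genes.difference(test.genes)
    aligned = test.values.reindex(reference.genes)
    if len(missing):
        log.warning(
            "%d reference genes missing from test; imputed at reference "
            "per-gene median",
            len(missing),
        )
        med = reference.values.median(axis=1)
        for g in missing:
            aligned.loc[g] = med.loc[g]

    if not enabled:
        return GEPMatrix(aligned, provenance=test.provenance)

    pooled = np.sort(reference.values.to_numpy().ravel())
    out = np.empty_like(aligned.to_numpy(dtype=float))
    for j in range(aligned.shape[1]):
        col = aligned.iloc[:, j].to_numpy(dtype=float)
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(col))
        probs = (ranks + 0.5) / len(col)
        out[:, j] = np.quantile(pooled, probs)
    return GEPMatrix(
        pd.DataFrame(out, index=aligned.index, columns=aligned.columns),
        provenance=test.provenance,
    )
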
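"""Classical scaling normalizers, reimplemented for head-to-head comparison.

Every scaling normalization method estimates, per sample, the compositional
correction factor Λ⁻¹ from some summary of the ratio of the sample's
proportions to a reference: total-sum (Λ⁻¹ ≡ 1), TMM (trimmed weighted mean
of log ratios over shared positive features), the median-of-ratios size
factor, plain median and upper-quartile proportions, the CLR divisor
(geometric mean of pseudocounted proportions), and cumulative-sum scaling
(CSS).  On sparse 16S-like data several of these degenerate — zero medians,
empty reference support, pseudocount dominance — so failures are surfaced as
explicit per-sample or dataset-level markers, never silent NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import CountMatrix
from .wrench import NormalizationResult, normalization_factors

__all__ = [
    "BaselineFactors",
    "total_sum_factors",
    "tmm_factors",
    "median_of_ratios_factors",
    "quantile_factors",
    "clr_factors",
    "css_factors",
    "baseline_factors",
    "ScalingNormalizer",
    "BASELINE_METHODS",
]

BASELINE_METHODS = (
    "total_sum",
    "tmm",
    "median_of_ratios",
    "median",
    "upper_quartile",
    "clr",
    "css",
)


@dataclass(frozen=True)
class BaselineFactors:
    """Per-sample compositional factors from one baseline method.

    ``ccf`` carries NaN where the method failed for a sample; the matching
    entry of ``failure_reasons`` carries a machine-readable reason string.
    """

    method: str
    ccf: np.ndarray
    failure_reasons: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ccf = np.asarray(self.ccf, dtype=float)
        object.__setattr__(self, "ccf", ccf)
        reasons = list(self.failure_reasons) or [None] * ccf.shape[0]
        if len(reasons) != ccf.shape[0]:
            raise ValueError("failure_reasons must align with ccf")
        defined = ~np.isnan(ccf)
        if np.any(ccf[defined] <= 0):
            raise ValueError("defined ccf entries must be positive")
        for j in np.flatnonzero(~defined):
            if reasons[j] is None:
                raise ValueError(f"failed sample {j} lacks a failure reason")
        object.__setattr__(self, "failure_reasons", reasons)

    @property
    def n_failed(self) -> int:
        return int(np.isnan(self.ccf).sum())


def total_sum_factors(counts: CountMatrix) -> BaselineFactors:
    """Library-size-only normalization: Λ⁻¹ ≡ 1 (no compositional correction)."""
    return BaselineFactors("total_sum", np.ones(counts.n_samples))


def _trim_keep(values: np.ndarray, frac: float) -> np.ndarray:
    """Boolean mask keeping the central (1 − 2·frac) mass by rank."""
    m = values.shape[0]
    lo = int(np.floor(m * frac))
    keep = np.zeros(m, dtype=bool)
    order = np.argsort(values, kind="stable")
    keep[order[lo : m - lo]] = True
    return keep


def tmm_factors(
    counts: CountMatrix,
    ref_sample: int | str = "auto",
    trim_logfc: float = 0.30,
    trim_abs: float = 0.05,
) -> BaselineFactors:
    """Trimmed mean of M-values over features positive in sample and reference.

    M_i = log2(q_ji / q_ref,i) and A_i = ½·log2(q_ji · q_ref,i) are computed
    over the shared positive support; both are double-sided rank-trimmed
    (defaults 30% on M, 5% on A) and the surviving M are averaged with
    inverse delta-method binomial variance weights.  Samples sharing no
    positive features with the reference get a failure marker.
    """
    q = counts.proportions
    tau = counts.depths.astype(float)
    n = counts.n_samples
    if ref_sample == "auto":
        uq = np.quantile(q, 0.75, axis=0)
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref = int(ref_sample)
    Y = counts.counts
    ccf = np.full(n, np.nan)
    reasons: list = [None] * n
    for j in range(n):
        if j == ref:
            ccf[j] = 1.0
            continue
        both = (Y[:, j] > 0) & (Y[:, ref] > 0)
        if not np.any(both):
            reasons[j] = "no-common-features"
            continue
        qj, qr = q[both, j], q[both, ref]
        M = np.log2(qj / qr)
        A = 0.5 * np.log2(qj * qr)
        keep = _trim_keep(M, trim_logfc) & _trim_keep(A, trim_abs)
        if not np.any(keep):
            reasons[j] = "all-features-trimmed"
            continue
        var = (
            1.0 / Y[both, j][keep]
            - 1.0 / tau[j]
            + 1.0 / Y[both, ref][keep]
            - 1.0 / tau[ref]
        )
        var = np.maximum(var, 1e-12)
        w = 1.0 / var
        ccf[j] = float(2.0 ** (w @ M[keep] / w.sum()))
    return BaselineFactors(
        "tmm",
        ccf,
        reasons,
        {"ref_sample": ref, "trim_logfc": trim_logfc, "trim_abs": trim_abs},
    )


def median_of_ratios_factors(counts: CountMatrix) -> BaselineFactors:
    """Size factors as the median ratio to a geometric-mean pseudo-reference.

    The reference is the across-sample geometric mean of proportions (zero
    when any sample lacks the feature); with no feature positive in every
    sample the whole dataset fails, mirroring the behavior on sparse data.
    """
    q = counts.proportions
    everywhere = np.all(counts.counts > 0, axis=1)
    n = counts.n_samples
    if not np.any(everywhere):
        return BaselineFactors(
            "median_of_ratios", np.full(n, np.nan), ["no-feature-positive-in-all-samples"] * n
        )
    ref = np.exp(np.mean(np.log(q[everywhere]), axis=1))
    ratios = q[everywhere] / ref[:, None]
    ccf = np.median(ratios, axis=0)
    return BaselineFactors("median_of_ratios", ccf)


def quantile_factors(counts: CountMatrix, which: str = "median") -> BaselineFactors:
    """Median or upper-quartile of the sample's proportion vector, zeros included.

    With ≥ 50% (resp. 25%) zero features the statistic itself is zero and the
    sample is marked failed rather than silently reported as 0.
    """
    if which not in ("median", "upper_quartile"):
        raise ValueError("which must be 'median' or 'upper_quartile'")
    qlevel = 0.5 if which == "median" else 0.75
    stat = np.quantile(counts.proportions, qlevel, axis=0)
    reasons: list = [None] * counts.n_samples
    ccf = stat.astype(float)
    for j in np.flatnonzero(stat <= 0):
        ccf[j] = np.nan
        reasons[j] = "zero-quantile"
    return BaselineFactors(which, ccf, reasons, {"quantile": qlevel})


def clr_factors(counts: CountMatrix, pseudocount: float = 1.0) -> BaselineFactors:
    """CLR divisor: geometric mean of pseudocounted proportions.

    On sparse data the factor is dominated by the pseudocount — the bias this
    module exists to exhibit — but it is always defined.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    y = counts.counts + pseudocount
    q = y / y.sum(axis=0)[None, :]
    ccf = np.exp(np.mean(np.log(q), axis=0))
    return BaselineFactors("clr", ccf, params={"pseudocount": pseudocount})


def css_factors(counts: CountMatrix, quantile: float = 0.5) -> BaselineFactors:
    """Cumulative-sum scaling: proportion of counts at or below a positive-count quantile.

    t_j is the given quantile of the sample's *positive* counts; the factor is
    the summed counts ≤ t_j divided by the sample depth.  The original
    adaptive quantile selection is deliberately replaced by a fixed,
    configurable quantile.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    Y = counts.counts
    tau = counts.depths.astype(float)
    ccf = np.empty(counts.n_samples)
    for j in range(counts.n_samples):
        pos = Y[Y[:, j] > 0, j]
        t = np.quantile(pos, quantile)
        ccf[j] = Y[Y[:, j] <= t, j].sum() / tau[j]
    return BaselineFactors("css", ccf, params={"quantile": quantile})


def baseline_factors(counts: CountMatrix, method: str, **params) -> BaselineFactors:
    """Dispatch a baseline by name (see :data:`BASELINE_METHODS`)."""
    if method == "total_sum":
        return total_sum_factors(counts)
    if method == "tmm":
        return tmm_factors(counts, **params)
    if method == "median_of_ratios":
        return median_of_ratios_factors(counts)
    if method in ("median", "upper_quartile"):
        return quantile_factors(counts, which=method)
    if method == "clr":
        return clr_factors(counts, **params)
    if method == "css":
        return css_factors(counts, **params)
    raise ValueError(f"unknown baseline method {method!r}; choose from {BASELINE_METHODS}")


def baseline_normalization_result(
    counts: CountMatrix, factors: BaselineFactors, centering: str = "geometric_mean_one"
) -> NormalizationResult:
    """Compose nf = ccf·τ for a baseline, skipping failed samples (NaN propagates)."""
    ccf = factors.ccf.copy()
    ok = ~np.isnan(ccf)
    if not np.any(ok):
        nf = np.full_like(ccf, np.nan)
        return NormalizationResult(factors.method, ccf, nf, "none", list(counts.sample_ids))
    sub = normalization_factors(
        ccf[ok], counts.depths.astype(float)[ok], centering=centering, estimator=factors.method
    )
    out_ccf = np.full_like(ccf, np.nan)
    out_nf = np.full_like(ccf, np.nan)
    out_ccf[ok] = sub.ccf
    out_nf[ok] = sub.nf
    return NormalizationResult(
        factors.method, out_ccf, out_nf, centering, list(counts.sample_ids),
        {"failure_reasons": factors.failure_reasons},
    )


class ScalingNormalizer(TransformerMixin, BaseEstimator):
    """Scikit-learn wrapper over the baseline scaling normalizers.

    ``X`` is ``(n_samples, n_features)`` counts.  After ``fit``, ``ccf_``
    holds the per-sample compositional factors (NaN = failure, with
    ``failure_reasons_``) and ``nf_`` the centered normalization factors.
    """

    def __init__(self, method: str = "tmm", centering: str = "geometric_mean_one", **params):
        self.method = method
        self.centering = centering
        self.params = params

    def get_params(self, deep: bool = True) -> dict:
        return {"method": self.method, "centering": self.centering, "params": self.params}

    def fit(self, X, y=None):
        X = check_array(X, dtype="numeric", ensure_min_samples=1)
        counts = CountMatrix(np.asarray(X).T)
        factors = baseline_factors(counts, self.method, **self.params)
        result = baseline_normalization_result(counts, factors, self.centering)
        self.n_features_in_ = X.shape[1]
        self.factors_ = factors
        self.ccf_ = result.ccf
        self.nf_ = result.nf
        self.failure_reasons_ = factors.failure_reasons
        self._fit_shape = X.shape
        return self

    def transform(self, X):
        check_is_fitted(self, "nf_")
        X = check_array(X, dtype="numeric")
        if X.shape != self._fit_shape:
            raise ValueError(f"expected the fitted shape {self._fit_shape}, got {X.shape}")
        return X / self.nf_[:, None]
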
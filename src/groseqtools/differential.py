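"""Negative-binomial differential-transcription calling (DESeq-v1 style).

The model: read count K_ij for gene i in library j is negative-binomial
with mean s_j * q_i and variance mu + alpha * mu^2, where s_j is a
per-library size factor (median-of-ratios) and alpha the overdispersion.
Dispersion is estimated "blind" (all libraries pooled as one group) and
used "fit-only": every gene gets the value of a fitted mean-dispersion
trend alpha(q) = a0 + a1/q, never its own noisy per-gene estimate.  Two
conditions are compared with the conditional exact test: given the total
K_A + K_B, the probability of every split (a, b) is computed from the two
negative-binomial laws, and the two-sided p-value is the summed probability
of all splits at most as probable as the observed one.  Benjamini-Hochberg
adjusted p-values at padj <= 0.1 call a gene differentially transcribed.

With several annotated isoforms per gene the isoform with the largest
magnitude of fold change represents the gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8

__all__ = [
    "DispersionModel",
    "size_factors",
    "fit_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "call_differential",
]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes in rows, samples in columns).

    s_j = median_i of K_ij / g_i with g_i the geometric mean of gene i
    across samples; genes whose geometric mean is zero are excluded.
    """
    k = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        loggm = np.log(k).mean(axis=1)
    finite = np.isfinite(loggm)
    if not finite.any():
        raise ValueError(
            "size_factors: no gene has positive counts in every sample"
        )
    with np.errstate(divide="ignore"):
        ratios = np.log(k[finite]) - loggm[finite, None]
    s = np.exp(np.median(ratios, axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


@dataclass
class DispersionModel:
    """Fitted mean-dispersion trend alpha(q) = a0 + a1 / q."""

    a0: float
    a1: float
    base_mean: pd.Series            # per-gene mean of normalised counts
    dispersion: pd.Series           # per-gene fitted (fit-only) dispersion
    n_fit: int = 0                  # genes entering the trend fit
    constant_fallback: bool = False

    def __call__(self, q: float | np.ndarray) -> float | np.ndarray:
        return np.maximum(self.a0 + self.a1 / np.maximum(q, 1e-300), DISPERSION_FLOOR)


def _fit_gamma_trend(q: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Gamma-family regression of raw dispersions on (1, 1/q), identity link."""
    import statsmodels.api as sm

    x = np.column_stack([np.ones_like(q), 1.0 / q])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(disp, x, family=sm.families.Gamma(sm.families.links.Identity()))
        res = model.fit(maxiter=100)
    a0, a1 = float(res.params[0]), float(res.params[1])
    if not (np.isfinite(a0) and np.isfinite(a1)):
        raise RuntimeError("gamma trend fit returned non-finite coefficients")
    return a0, a1


def fit_dispersion(counts: pd.DataFrame, s: pd.Series) -> DispersionModel:
    """Blind, fit-only dispersion estimation.

    All samples are pooled as a single group.  Per gene the raw
    method-of-moments dispersion is (w - xi*q) / q^2 with q the mean and w
    the sample variance of the normalised counts and xi = q * mean(1/s_j)
    the expected shot-noise contribution.  Genes with non-positive raw
    dispersion (variance at or below the Poisson level) carry no
    overdispersion information and are excluded from the trend fit.  The
    trend alpha(q) = a0 + a1/q is fitted by gamma-family regression; when
    fewer than two positive raw dispersions exist the model degrades to a
    constant fit with a warning.
    """
    if counts.shape[1] < 2:
        raise ValueError("fit_dispersion needs >= 2 samples")
    k = counts.to_numpy(dtype=float)
    sv = s.to_numpy(dtype=float)
    norm = k / sv[None, :]
    q = norm.mean(axis=1)
    w = norm.var(axis=1, ddof=1)
    xi = float(np.mean(1.0 / sv))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (w - xi * q) / q**2
    usable = (q > 0) & np.isfinite(raw) & (raw > 0)
    if usable.sum() < 2:
        warnings.warn(
            "fewer than 2 positive raw dispersions; using constant dispersion",
            RuntimeWarning,
        )
        const = float(raw[usable].mean()) if usable.any() else DISPERSION_FLOOR
        const = max(const, DISPERSION_FLOOR)
        disp = np.full(len(q), const)
        return DispersionModel(
            a0=const,
            a1=0.0,
            base_mean=pd.Series(q, index=counts.index, name="base_mean"),
            dispersion=pd.Series(disp, index=counts.index, name="dispersion"),
            n_fit=int(usable.sum()),
            constant_fallback=True,
        )
    try:
        a0, a1 = _fit_gamma_trend(q[usable], raw[usable])
    except Exception:
        # robust fallback: constant at the median of the raw estimates
        warnings.warn(
            "gamma trend fit failed; falling back to constant dispersion",
            RuntimeWarning,
        )
        a0, a1 = float(np.median(raw[usable])), 0.0
        model = DispersionModel(
            a0=a0,
            a1=a1,
            base_mean=pd.Series(q, index=counts.index, name="base_mean"),
            dispersion=pd.Series(
                np.maximum(a0, DISPERSION_FLOOR), index=counts.index, name="dispersion"
            ),
            n_fit=int(usable.sum()),
            constant_fallback=True,
        )
        return model
    fitted = np.maximum(a0 + np.divide(a1, q, out=np.full_like(q, np.inf), where=q > 0),
                        DISPERSION_FLOOR)
    return DispersionModel(
        a0=a0,
        a1=a1,
        base_mean=pd.Series(q, index=counts.index, name="base_mean"),
        dispersion=pd.Series(fitted, index=counts.index, name="dispersion"),
        n_fit=int(usable.sum()),
    )


def _cond_logpmf(
    total: int, s_a: float, s_b: float, q: float, alpha: float, support: np.ndarray
) -> np.ndarray:
    """log P(a, total-a) for a in ``support`` under the two NB laws."""
    mu_a, mu_b = s_a * q, s_b * q
    a = support
    b = total - support
    if alpha <= DISPERSION_FLOOR:  # Poisson limit; also avoids 1/alpha overflow
        return stats.poisson.logpmf(a, mu_a) + stats.poisson.logpmf(b, mu_b)
    # variance mu + alpha * s^2 * q^2  =>  size r = 1/alpha for both conditions
    r = 1.0 / alpha
    pa = r / (r + mu_a)
    pb = r / (r + mu_b)
    return stats.nbinom.logpmf(a, r, pa) + stats.nbinom.logpmf(b, r, pb)


def nb_exact_test(
    k_a: int,
    k_b: int,
    s_a: float,
    s_b: float,
    alpha_disp: float,
    max_exact: int = 10_000,
) -> float:
    """Two-sided conditional exact test of condition totals K_A vs K_B.

    The pooled mean is q = (K_A+K_B)/(s_A+s_B); each condition total is
    negative-binomial with mean s_c*q and variance mu + alpha*s_c^2*q^2.
    p sums, over all splits of the observed total, the probabilities no
    larger than that of the observed split, normalised by the total.

    For totals above ``max_exact`` the conditional support is enumerated on
    a window around the mode covering all but < 1e-12 of the conditional
    mass (terms outside are negligible in numerator and denominator alike).
    """
    if k_a < 0 or k_b < 0:
        raise ValueError("counts must be non-negative")
    if s_a <= 0 or s_b <= 0:
        raise ValueError("size factors must be positive")
    total = k_a + k_b
    if total == 0:
        return 1.0
    q = total / (s_a + s_b)
    if total <= max_exact:
        support = np.arange(total + 1)
    else:
        # normal-scale window around the conditional mode
        mean_a = total * s_a / (s_a + s_b)
        var_a = mean_a * (1 + alpha_disp * s_a * q)  # crude NB-width guess
        half = 10.0 * np.sqrt(max(var_a, 1.0))
        lo = int(min(mean_a - half, k_a - half))
        hi = int(max(mean_a + half, k_a + half))
        support = np.arange(max(0, lo), min(total, hi) + 1)
    lp = _cond_logpmf(total, s_a, s_b, q, alpha_disp, support)
    lp_obs = _cond_logpmf(total, s_a, s_b, q, alpha_disp, np.array([k_a]))[0]
    den = logsumexp(lp)
    qualifies = lp <= lp_obs + 1e-10
    if not qualifies.any():
        return float(np.exp(lp_obs - den))
    num = logsumexp(lp[qualifies])
    return float(min(1.0, np.exp(num - den)))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    counts: pd.DataFrame,
    conditions: Mapping[str, str],
    condition_pair: tuple[str, str],
    threshold: float = 0.1,
    gene_of: Mapping[str, str] | None = None,
    max_exact: int = 10_000,
) -> pd.DataFrame:
    """Full differential pipeline: size factors -> blind dispersion ->
    exact test -> BH -> isoform collapse -> call at padj <= threshold.

    ``counts``: isoform/gene x sample integer matrix; ``conditions`` maps
    sample name to condition label; ``condition_pair`` = (A, B) compares B
    against A (fold change = normalised mean B / normalised mean A, no
    pseudocount).  ``gene_of`` maps isoform id to gene id; identity when
    omitted.  Returns one row per gene sorted by the input order of its
    representative isoform.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    cond_a, cond_b = condition_pair
    samples_a = [c for c in counts.columns if conditions.get(c) == cond_a]
    samples_b = [c for c in counts.columns if conditions.get(c) == cond_b]
    if not samples_a or not samples_b:
        raise ValueError(
            f"conditions {condition_pair} not both present in the count matrix"
        )
    s = size_factors(counts)
    disp = fit_dispersion(counts, s)
    norm = counts.div(s, axis=1)

    k_a = counts[samples_a].sum(axis=1).to_numpy()
    k_b = counts[samples_b].sum(axis=1).to_numpy()
    s_a = float(s[samples_a].sum())
    s_b = float(s[samples_b].sum())
    mean_a = norm[samples_a].mean(axis=1).to_numpy()
    mean_b = norm[samples_b].mean(axis=1).to_numpy()

    # dispersion evaluated at the pooled mean of the two tested conditions
    pooled_q = (k_a + k_b) / (s_a + s_b)
    alpha = np.asarray(disp(np.maximum(pooled_q, 1e-300)), dtype=float)

    pvals = np.ones(len(counts))
    for i in range(len(counts)):
        pvals[i] = nb_exact_test(
            int(k_a[i]), int(k_b[i]), s_a, s_b, float(alpha[i]), max_exact=max_exact
        )
    padj = bh_adjust(pvals)

    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_b / mean_a
    res = pd.DataFrame(
        {
            "isoform": counts.index,
            "gene": [gene_of.get(i, i) for i in counts.index]
            if gene_of
            else counts.index,
            "mean_norm_A": mean_a,
            "mean_norm_B": mean_b,
            "fold_change": fold,
            "pval": pvals,
            "padj": padj,
        }
    )

    # isoform collapse: keep the isoform with the largest |log fold change|;
    # infinite or zero folds rank above any finite fold, NaN (0/0) lowest.
    with np.errstate(divide="ignore", invalid="ignore"):
        mag = np.abs(np.log(res["fold_change"].to_numpy()))
    mag = np.where(np.isnan(mag), -1.0, mag)
    res["_mag"] = mag
    res = (
        res.sort_values("_mag", ascending=False, kind="stable")
        .drop_duplicates("gene", keep="first")
        .drop(columns="_mag")
    )
    res = res.set_index("gene")
    res["called"] = res["padj"] <= threshold
    return res
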
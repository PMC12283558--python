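"""Bimodal insertion-index classifier for gene essentiality.

The per-gene insertion index (unique insertions / gene length) of a
saturated transposon library is bimodal: a near-zero mode of essential
genes and a broad mode of non-essential genes.  The low mode is fitted
with an exponential distribution and the high mode with a gamma, the two
fitting sections being separated by manually chosen insertion-index
cut-offs (defaults 0.006 and 0.03) that minimise overlap in the
transition region.  Each gene is then scored by the log2 likelihood
ratio of the two fitted densities and called essential when the
essential mode is at least a given fold (default 12x) more likely,
non-essential when the non-essential mode is, and unclear in between.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .insertions import GeneInsertionStats
from .io_formats import GenomeAnnotation

__all__ = [
    "DENSITY_FLOOR",
    "LLR_CAP",
    "CUTOFF_LOW",
    "CUTOFF_HIGH",
    "THRESHOLD_FOLD",
    "EssentialityFit",
    "GeneCall",
    "CallResult",
    "fit_modes",
    "loglik_ratio",
    "classify",
    "call_genome",
    "summarize_calls",
]

log = logging.getLogger(__name__)

#: Densities are floored here before taking the ratio, so a zero density
#: (e.g. the gamma at insertion index 0 with shape > 1) stays finite.
DENSITY_FLOOR = 1e-300
#: The log2 likelihood ratio is clamped to +/- this value.
LLR_CAP = 1000.0

CUTOFF_LOW = 0.006
CUTOFF_HIGH = 0.03
THRESHOLD_FOLD = 12.0

_LN2 = math.log(2.0)
_LOG2_FLOOR = math.log(DENSITY_FLOOR) / _LN2

CALLS = ("essential", "non_essential", "unclear")


@dataclass(frozen=True)
class EssentialityFit:
    """Fitted mode parameters and section occupancy."""

    cutoff_low: float
    cutoff_high: float
    exp_rate: float
    gamma_shape: float
    gamma_scale: float
    n_low: int
    n_high: int
    n_between: int

    @property
    def n_genes(self) -> int:
        return self.n_low + self.n_high + self.n_between


@dataclass
class GeneCall:
    gene_id: str
    insertion_index: float
    llr: float
    call: str
    domain_flag: bool = False


@dataclass
class CallResult:
    calls: list[GeneCall]
    fit: EssentialityFit
    summary: dict


class ModeFitError(ValueError):
    """A mode section is too small or degenerate to fit."""


def fit_modes(
    stats: Sequence[GeneInsertionStats],
    cutoff_low: float = CUTOFF_LOW,
    cutoff_high: float = CUTOFF_HIGH,
) -> EssentialityFit:
    """Fit the exponential (essential) and gamma (non-essential) modes.

    The exponential rate is the closed-form maximum-likelihood estimate
    (reciprocal mean) on the section with insertion index <= cutoff_low.
    The gamma parameters are a numerical maximum-likelihood fit on the
    section with index >= cutoff_high; because that section is a
    left-truncated sample of the non-essential mode, the likelihood is
    the conditional one given index >= cutoff_high (method-of-moments
    start, bounded optimisation, tolerance 1e-9) — an unconditional fit
    would overestimate the shape whenever the mode leaks below the
    cut-off.  Genes strictly between the cut-offs take no part in
    fitting but are still classified.

    When the low section is all zeros (a fully insertion-free essential
    mode) its mean is replaced by one pseudo-insertion spread over the
    section's combined gene length, which keeps the rate finite while
    preserving the mode's scale.
    """
    if cutoff_low >= cutoff_high:
        raise ValueError("cutoff_low must be below cutoff_high")
    low = [s for s in stats if s.insertion_index <= cutoff_low]
    high = [s for s in stats if s.insertion_index >= cutoff_high]
    n_between = len(stats) - len(low) - len(high)
    if len(low) < 2:
        raise ModeFitError(
            f"cannot fit essential (exponential) mode: only {len(low)} gene(s) "
            f"with insertion index <= {cutoff_low}"
        )
    if len(high) < 2:
        raise ModeFitError(
            f"cannot fit non-essential (gamma) mode: only {len(high)} gene(s) "
            f"with insertion index >= {cutoff_high}"
        )
    mean_low = float(np.mean([s.insertion_index for s in low]))
    if mean_low == 0.0:
        total_len = sum(s.length_bp for s in low)
        log.warning(
            "essential-mode section is entirely insertion-free; using one "
            "pseudo-insertion over its combined %d bp to set the rate",
            total_len,
        )
        exp_rate = float(total_len)  # 1 / (1 insertion / total_len bp)
    else:
        exp_rate = 1.0 / mean_low

    high_ii = np.array([s.insertion_index for s in high], dtype=float)
    shape, scale = _fit_truncated_gamma(high_ii, cutoff_high)
    return EssentialityFit(
        cutoff_low=cutoff_low,
        cutoff_high=cutoff_high,
        exp_rate=exp_rate,
        gamma_shape=float(shape),
        gamma_scale=float(scale),
        n_low=len(low),
        n_high=len(high),
        n_between=n_between,
    )


def _fit_truncated_gamma(
    data: np.ndarray, lower: float, tol: float = 1e-9
) -> tuple[float, float]:
    """MLE of gamma (shape, scale) given observations >= ``lower``.

    Maximises the conditional likelihood pdf(x) / sf(lower); with the
    truncation point far below the data this reduces to the ordinary
    gamma MLE.  Optimised in log-parameter space from a method-of-
    moments start.
    """
    from scipy import optimize

    mean = float(np.mean(data))
    var = float(np.var(data))
    k0 = mean * mean / var if var > 0 else 1.0
    theta0 = var / mean if var > 0 else mean

    def nll(logp: np.ndarray) -> float:
        k, theta = np.exp(logp)
        return float(
            -np.sum(sps.gamma.logpdf(data, k, scale=theta))
            + len(data) * sps.gamma.logsf(lower, k, scale=theta)
        )

    res = optimize.minimize(
        nll,
        x0=np.log([max(k0, 1e-3), max(theta0, 1e-12)]),
        method="Nelder-Mead",
        options={"xatol": tol, "fatol": tol, "maxiter": 10_000},
    )
    shape, scale = np.exp(res.x)
    return float(shape), float(scale)


def _log2_exp_pdf(ii: float, rate: float) -> float:
    return (math.log(rate) - rate * ii) / _LN2


def _log2_gamma_pdf(ii: float, shape: float, scale: float) -> float:
    if ii <= 0.0:
        return -math.inf
    return (
        (shape - 1.0) * math.log(ii)
        - ii / scale
        - math.lgamma(shape)
        - shape * math.log(scale)
    ) / _LN2


def loglik_ratio(ii: float, fit: EssentialityFit) -> float:
    """log2 of essential-mode density over non-essential-mode density.

    Positive values favour the essential (exponential) mode.  Both
    densities are floored at DENSITY_FLOOR before the ratio, and the
    result is clamped to [-LLR_CAP, +LLR_CAP]: an insertion-free gene
    under a shape>1 gamma therefore scores +LLR_CAP rather than +inf.
    """
    l2e = max(_log2_exp_pdf(ii, fit.exp_rate), _LOG2_FLOOR)
    l2g = max(_log2_gamma_pdf(ii, fit.gamma_shape, fit.gamma_scale), _LOG2_FLOOR)
    return max(-LLR_CAP, min(LLR_CAP, l2e - l2g))


def classify(llr: float, threshold: float | None = None) -> str:
    """Trichotomous call from a log2 likelihood ratio.

    essential iff llr > threshold, non_essential iff llr < -threshold,
    unclear otherwise.  The default threshold is log2(12): essential
    means the gene is at least 12 times more likely under the essential
    mode than under the non-essential one.
    """
    if threshold is None:
        threshold = math.log2(THRESHOLD_FOLD)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if llr > threshold:
        return "essential"
    if llr < -threshold:
        return "non_essential"
    return "unclear"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize_calls(
    counts: Mapping[str, int], n_genes: int | None = None
) -> dict:
    """Counts and rounded percentages per call.

    ``percent_of_classified`` divides by the total number of classified
    features (genes plus pseudogenes).  When ``n_genes`` — the genome's
    gene inventory excluding pseudogenes — is given, ``percent_of_genes``
    is reported as well; published essentiality percentages conventionally
    use that denominator even though pseudogenes are classified too.
    """
    total = sum(counts.values())
    summary: dict = {
        "counts": {c: int(counts.get(c, 0)) for c in CALLS},
        "total_classified": total,
        "percent_of_classified": {
            c: _round_half_up(counts.get(c, 0) / total * 100) if total else 0
            for c in CALLS
        },
    }
    if n_genes is not None:
        summary["n_genes"] = int(n_genes)
        summary["percent_of_genes"] = {
            c: _round_half_up(counts.get(c, 0) / n_genes * 100) for c in CALLS
        }
    return summary


def call_genome(
    stats: Sequence[GeneInsertionStats],
    cutoff_low: float = CUTOFF_LOW,
    cutoff_high: float = CUTOFF_HIGH,
    threshold_fold: float = THRESHOLD_FOLD,
    annotation: GenomeAnnotation | None = None,
) -> CallResult:
    """Fit both modes and classify every gene (pseudogenes included)."""
    fit = fit_modes(stats, cutoff_low=cutoff_low, cutoff_high=cutoff_high)
    threshold = math.log2(threshold_fold)
    calls = []
    for s in stats:
        llr = loglik_ratio(s.insertion_index, fit)
        calls.append(
            GeneCall(
                gene_id=s.gene_id,
                insertion_index=s.insertion_index,
                llr=llr,
                call=classify(llr, threshold),
            )
        )
    counts = {c: sum(1 for gc in calls if gc.call == c) for c in CALLS}
    summary = summarize_calls(
        counts, n_genes=annotation.n_genes if annotation is not None else None
    )
    summary["fit"] = {
        "exp_rate": fit.exp_rate,
        "gamma_shape": fit.gamma_shape,
        "gamma_scale": fit.gamma_scale,
        "n_low": fit.n_low,
        "n_high": fit.n_high,
        "n_between": fit.n_between,
        "cutoff_low": fit.cutoff_low,
        "cutoff_high": fit.cutoff_high,
        "threshold_fold": threshold_fold,
    }
    return CallResult(calls=calls, fit=fit, summary=summary)
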
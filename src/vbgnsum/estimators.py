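"""Scale-up estimators of hidden population size.

The network scale-up family estimates the size of a hidden (key) population
K inside a frame population F from aggregate relational data — respondents'
counts of acquaintances in various groups. The estimators implemented here,
in increasing order of realism about the sampling design:

``basic_nsum``
    The traditional scale-up estimator,
    N̂_K = N · Σy_i / Σd_i, scaling the share of respondents' ties that land
    in the key population up to a known total population size N.

``ht_total``
    The Horvitz–Thompson total Σ y_i/π_i, usable only when absolute
    inclusion probabilities π_i are known — the benchmark case that
    venue-based sampling cannot deliver.

``relprob_mean``
    The modified Hansen–Hurwitz / generalized Horvitz–Thompson estimator of
    a population mean from a *relative probability sample*:
    ( Σ x_i/c_i ) / ( Σ 1/c_i ), where the c_i are inclusion probabilities
    known only up to a common constant. Invariant to rescaling all c_i.

``relprob_outreport_total``
    N_{F∖K} × relprob_mean(y, c): the estimated total out-reports from
    non-key frame members to the key population, using an externally
    supplied count of non-key frame members. Exactly linear in that count.

``vb_gnsum``
    The venue-based generalized scale-up estimator: the ratio of the
    relative-probability out-report total (numerator, non-key respondents)
    to the relative-probability mean in-report, i.e. mean visibility, of key
    respondents (denominator):

        N̂_K = [ N_{F∖K} · ȳ̂_{F∖K} ] / v̄̂_K .

``gnsum_known_probs``
    The same ratio with a Horvitz–Thompson numerator — the
    known-probability oracle the venue-based estimator is benchmarked
    against in simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, InestimableVisibilityError
from .population import SeedLike, _rng
from .sampling import VenueSample


@dataclass(frozen=True)
class EstimateResult:
    """A size estimate with its numerator/denominator decomposition."""

    n_hat: float
    numerator_total: float      # estimated total out-reports Ŷ_{F∖K→K}
    denominator_mean: float     # estimated mean in-report (visibility) v̄̂
    estimator_name: str
    n_frame_minus_key_used: float

    def rescale_frame(self, n_frame_minus_key: float) -> "EstimateResult":
        """Exact re-estimate under a different supplied N_{F∖K}.

        The numerator is linear in N_{F∖K}, so no data pass is needed:
        supplying a count off by a factor (1+ε) changes the estimate by
        exactly (1+ε).
        """
        factor = n_frame_minus_key / self.n_frame_minus_key_used
        return EstimateResult(
            n_hat=self.n_hat * factor,
            numerator_total=self.numerator_total * factor,
            denominator_mean=self.denominator_mean,
            estimator_name=self.estimator_name,
            n_frame_minus_key_used=n_frame_minus_key,
        )


def _as_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if np.any(np.isnan(arr)):
        raise ConfigurationError(f"{name} contains missing values")
    return arr


def basic_nsum(out_ties_to_key, total_degrees, n_total: float) -> float:
    """Traditional network scale-up estimate N · Σy / Σd."""
    y = _as_float(out_ties_to_key, "out_ties_to_key")
    d = _as_float(total_degrees, "total_degrees")
    if y.size != d.size:
        raise ConfigurationError("out-tie and degree lists must have equal length")
    total_degree = d.sum()
    if total_degree <= 0:
        raise DegenerateInputError("total reported degree is zero; scale-up ratio undefined")
    return float(n_total * y.sum() / total_degree)


def ht_total(values, inclusion_probs) -> float:
    """Horvitz–Thompson estimate of a population total, Σ x_i / π_i.

    Requires absolute inclusion probabilities in (0, 1]; used only as the
    known-probability oracle in tests and benchmarks.
    """
    x = _as_float(values, "values")
    pi = _as_float(inclusion_probs, "inclusion_probs")
    if x.size != pi.size:
        raise ConfigurationError("values and inclusion_probs must have equal length")
    if np.any(pi <= 0) or np.any(pi > 1):
        raise ConfigurationError("inclusion probabilities must lie in (0, 1]")
    return float(np.sum(x / pi))


def relprob_mean(values, relative_probs) -> float:
    """Population-mean estimate from a relative probability sample.

    ( Σ x_i/c_i ) / ( Σ 1/c_i ). Multiplying every c_i by one positive
    constant leaves the value unchanged, which is what makes the estimator
    usable when inclusion probabilities are known only up to scale.
    """
    x = _as_float(values, "values")
    c = _as_float(relative_probs, "relative_probs")
    if x.size == 0:
        raise ConfigurationError("relprob_mean requires a nonempty sample")
    if x.size != c.size:
        raise ConfigurationError("values and relative_probs must have equal length")
    if np.any(c <= 0):
        raise ConfigurationError("relative probabilities must be positive")
    w = 1.0 / c
    return float(np.sum(x * w) / np.sum(w))


def relprob_outreport_total(y_nonkey, c_nonkey, n_frame_minus_key: float) -> float:
    """Estimated total out-reports from non-key frame members to K.

    The relative-probability mean out-report among non-key respondents,
    scaled by the externally supplied count of non-key frame members.
    Exactly linear in ``n_frame_minus_key``.
    """
    if n_frame_minus_key <= 0:
        raise ConfigurationError("n_frame_minus_key must be positive")
    return float(n_frame_minus_key) * relprob_mean(y_nonkey, c_nonkey)


def vb_gnsum(sample: VenueSample, n_frame_minus_key: float) -> EstimateResult:
    """Venue-based generalized network scale-up estimate of N_K.

    Non-key respondents contribute only their out-reports (numerator); key
    respondents contribute only their in-report proxies (denominator). Key
    respondents' out-reports and non-key respondents' in-reports are
    ignored by design.

    Raises
    ------
    InestimableVisibilityError
        If every sampled key member reports zero in-ties; mean visibility
        zero makes the ratio undefined (this is not an estimate of zero).
    """
    if sample.n_key_respondents < 1 or sample.n_nonkey_respondents < 1:
        raise ConfigurationError("sample must contain at least one key and one non-key respondent")
    denominator = relprob_mean(sample.v_key, sample.c_key)
    if denominator <= 0:
        raise InestimableVisibilityError(
            "all sampled key members reported zero in-ties; visibility inestimable"
        )
    numerator = relprob_outreport_total(sample.y_nonkey, sample.c_nonkey, n_frame_minus_key)
    return EstimateResult(
        n_hat=numerator / denominator,
        numerator_total=numerator,
        denominator_mean=denominator,
        estimator_name="vb_gnsum",
        n_frame_minus_key_used=float(n_frame_minus_key),
    )


def gnsum_known_probs(sample: VenueSample, inclusion_probs_nonkey) -> EstimateResult:
    """Generalized scale-up with a known-probability numerator (oracle).

    Horvitz–Thompson total of non-key out-reports over the denominator of
    :func:`vb_gnsum`. Only usable in simulation or benchmark settings where
    the non-key respondents' absolute inclusion probabilities are known.
    """
    if sample.n_key_respondents < 1 or sample.n_nonkey_respondents < 1:
        raise ConfigurationError("sample must contain at least one key and one non-key respondent")
    denominator = relprob_mean(sample.v_key, sample.c_key)
    if denominator <= 0:
        raise InestimableVisibilityError(
            "all sampled key members reported zero in-ties; visibility inestimable"
        )
    numerator = ht_total(sample.y_nonkey, inclusion_probs_nonkey)
    return EstimateResult(
        n_hat=numerator / denominator,
        numerator_total=numerator,
        denominator_mean=denominator,
        estimator_name="gnsum_known_probs",
        n_frame_minus_key_used=float("nan"),
    )


def bootstrap_estimates(
    sample: VenueSample,
    n_frame_minus_key: float,
    n_boot: int = 1000,
    *,
    seed: SeedLike,
) -> np.ndarray:
    """Heuristic respondent-level bootstrap of the venue-based estimate.

    Resamples respondents with replacement within each stratum and
    recomputes the estimator. No design-consistent variance estimator is
    established for scale-up methods, so this is an exploratory uncertainty
    summary, not a formal one; replicates whose key-stratum resample has
    zero mean visibility are recorded as NaN.
    """
    if n_boot < 0:
        raise ConfigurationError("n_boot must be nonnegative")
    rng = _rng(seed)
    y, cy = sample.y_nonkey.astype(float), sample.c_nonkey
    v, cv = sample.v_key.astype(float), sample.c_key
    out = np.empty(n_boot)
    for b in range(n_boot):
        ik = rng.integers(0, v.size, size=v.size)
        inn = rng.integers(0, y.size, size=y.size)
        den = relprob_mean(v[ik], cv[ik])
        if den <= 0:
            out[b] = np.nan
            continue
        out[b] = relprob_outreport_total(y[inn], cy[inn], n_frame_minus_key) / den
    return out
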
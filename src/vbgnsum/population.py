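"""Synthetic frame populations for venue-based scale-up simulation.

The objects here emulate the setting the venue-based generalized network
scale-up method (VB-GNSUM) is designed for: a *frame population* F of people
who attend the venues on a sampling frame, containing a small *key
population* K (the hidden group whose size is to be estimated, e.g. men who
have sex with men in a bars-and-clubs frame). Frame members are connected to
key members by acquaintance ties. Each tie from a non-key frame member i to
a key member j contributes one unit to i's *out-report* y_i ("how many
venue-attending key-population members do you know?") and one unit to j's
*in-report* v_j (how many venue-attending non-key acquaintances know j). By
construction the tie set is shared, so

    sum_i y_i  ==  sum_j v_j

holds exactly for every generated population — the accounting identity the
scale-up estimator rests on — and consequently

    sum_i y_i / (sum_j v_j / N_K)  ==  N_K

exactly in an error-free census.

A separate attendance layer assigns each person a positive venue-attendance
rate (expected visits per reference period) that later drives sample
inclusion, and a reporting-error layer perturbs the *reported* tie counts
while leaving the true network untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence, Union

import numpy as np
from scipy.special import ndtri

from .errors import ConfigurationError

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]

#: Recognised venue-attendance scenario families (see :func:`assign_attendance`).
ATTENDANCE_SCENARIOS = ("S1", "S2", "S3", "S4")

# Family parameters. Defaults are documented stand-ins chosen to span
# homogeneous, right-skewed, clumped, and degree-confounded attendance.
_LOGNORMAL_SIGMA = 1.0
_S3_HIGH_RATE = 10.0
_S3_HIGH_SHARE = 0.2
_S4_RANK_CORRELATION = 0.5


def _rng(seed: SeedLike) -> np.random.Generator:
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ReportingModel:
    """One-directional reporting error applied to acquaintance ties.

    Parameters
    ----------
    false_positive_rate:
        Rate in [0, 1) governing phantom out-ties: reported acquaintances
        who are not actually key-population members. Phantom ties arise from
        respondents misattributing key-population membership to non-key
        venue-attending acquaintances, so the expected phantom count per
        respondent is ``false_positive_rate * misattribution_pool * N_K/N_F``
        — proportional to how prevalent the key population is on the frame.
        Phantom ties inflate out-reports only; no in-report matches them.
    false_negative_rate:
        Probability in [0, 1) that a true tie to a key member is invisible:
        it is dropped from the out-report *and* from the matched in-report
        (a visibility failure affects both sides symmetrically).
    misattribution_pool:
        Mean number of non-key venue-attending acquaintances per respondent
        that are eligible for misattribution. Default 6, a typical count of
        venue-going acquaintances spoken to in the past month in
        venue-intercept surveys.
    """

    false_positive_rate: float = 0.0
    false_negative_rate: float = 0.0
    misattribution_pool: float = 6.0

    def __post_init__(self):
        for name in ("false_positive_rate", "false_negative_rate"):
            r = getattr(self, name)
            if not (0.0 <= r < 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1); got {r!r}")
        if self.misattribution_pool < 0:
            raise ConfigurationError("misattribution_pool must be nonnegative")


@dataclass(frozen=True, eq=False)
class SyntheticPopulation:
    """A frame population with acquaintance ties into its key subgroup.

    Ties are stored as a flat edge list (``tie_from[k]`` knows ``tie_to[k]``),
    which is all the estimators ever consume; per-person counts are
    materialised in ``y_*``/``v_*`` arrays of length ``n_frame``.

    ``y_true``/``v_true`` describe the actual network; ``y_reported``/
    ``v_reported`` are what survey respondents would say, and coincide with
    the true counts until :func:`apply_reporting_error` is used.
    """

    n_frame: int
    is_key: np.ndarray          # bool, length n_frame
    tie_from: np.ndarray        # int person ids (non-key), one per tie
    tie_to: np.ndarray          # int person ids (key), one per tie
    y_true: np.ndarray          # int, length n_frame; zero for key members
    v_true: np.ndarray          # int, length n_frame; zero for non-members
    y_reported: np.ndarray
    v_reported: np.ndarray
    attendance_rate: np.ndarray  # positive float, length n_frame

    def __post_init__(self):
        if self.n_key == 0 or self.n_key == self.n_frame:
            raise ConfigurationError("population must contain both key and non-key members")
        if np.any(self.attendance_rate <= 0):
            raise ConfigurationError("attendance rates must be strictly positive")
        if np.any(self.v_true[~self.is_key] != 0) or np.any(self.v_reported[~self.is_key] != 0):
            raise ConfigurationError("non-members must have zero in-reports")

    # -- derived views ----------------------------------------------------
    @property
    def n_key(self) -> int:
        return int(self.is_key.sum())

    @property
    def n_nonkey(self) -> int:
        return self.n_frame - self.n_key

    @property
    def key_ids(self) -> np.ndarray:
        return np.flatnonzero(self.is_key)

    @property
    def nonkey_ids(self) -> np.ndarray:
        return np.flatnonzero(~self.is_key)

    @property
    def total_out_ties(self) -> int:
        return int(self.y_true.sum())

    @property
    def total_in_ties(self) -> int:
        return int(self.v_true.sum())

    @classmethod
    def from_ties(
        cls,
        n_frame: int,
        key_ids: Iterable[int],
        ties: Sequence[tuple],
        attendance_rate: np.ndarray | float = 1.0,
    ) -> "SyntheticPopulation":
        """Build a population from an explicit (from, to) tie list.

        Every tie must run from a non-key person to a key person; each tie
        increments exactly one out-count and one in-count, so the
        out/in identity holds by construction.
        """
        is_key = np.zeros(n_frame, dtype=bool)
        key_ids = np.asarray(list(key_ids), dtype=np.int64)
        is_key[key_ids] = True
        tie_from = np.asarray([t[0] for t in ties], dtype=np.int64)
        tie_to = np.asarray([t[1] for t in ties], dtype=np.int64)
        if tie_from.size and (np.any(is_key[tie_from]) or not np.all(is_key[tie_to])):
            raise ConfigurationError("ties must run from non-key to key persons")
        y = np.bincount(tie_from, minlength=n_frame).astype(np.int64)
        v = np.bincount(tie_to, minlength=n_frame).astype(np.int64)
        rates = np.broadcast_to(np.asarray(attendance_rate, dtype=float), (n_frame,)).copy()
        return cls(
            n_frame=n_frame, is_key=is_key, tie_from=tie_from, tie_to=tie_to,
            y_true=y, v_true=v, y_reported=y.copy(), v_reported=v.copy(),
            attendance_rate=rates,
        )


def generate_population(
    n_frame: int,
    n_key: int,
    mean_degree_to_key: float = 3.0,
    degree_dispersion: float = 1.0,
    *,
    seed: SeedLike,
) -> SyntheticPopulation:
    """Generate a synthetic frame population with ties into the key group.

    Each non-key frame member's number of key acquaintances is drawn from a
    count distribution with mean ``mean_degree_to_key``: Binomial(n_key,
    mean/n_key) when ``degree_dispersion == 1`` (the marginal of independent
    per-pair Bernoulli ties), or a negative binomial with
    variance = dispersion × mean when ``degree_dispersion > 1`` (gamma-mixed
    tie propensities). Tie partners are assigned uniformly at random among
    key members, so in-tie counts are multinomial over K and the out/in
    identity is exact for every realisation.

    All persons start with attendance rate 1 (the homogeneous S1 scenario);
    use :func:`assign_attendance` to overlay a different scenario.
    """
    if not (0 < n_key < n_frame):
        raise ConfigurationError(f"need 0 < n_key < n_frame; got {n_key}, {n_frame}")
    if mean_degree_to_key <= 0:
        raise ConfigurationError("mean_degree_to_key must be positive")
    if degree_dispersion < 1.0:
        raise ConfigurationError("degree_dispersion must be >= 1")
    if mean_degree_to_key > n_key:
        raise ConfigurationError("mean_degree_to_key cannot exceed n_key")

    rng = _rng(seed)
    n_nonkey = n_frame - n_key
    m = float(mean_degree_to_key)
    if degree_dispersion == 1.0:
        counts = rng.binomial(n_key, m / n_key, size=n_nonkey)
    else:
        r = m / (degree_dispersion - 1.0)
        counts = rng.negative_binomial(r, r / (r + m), size=n_nonkey)

    is_key = np.zeros(n_frame, dtype=bool)
    is_key[:n_key] = True  # key members occupy ids 0..n_key-1 by convention
    nonkey_ids = np.arange(n_key, n_frame, dtype=np.int64)
    tie_from = np.repeat(nonkey_ids, counts)
    tie_to = rng.integers(0, n_key, size=tie_from.size, dtype=np.int64)

    y = np.bincount(tie_from, minlength=n_frame).astype(np.int64)
    v = np.bincount(tie_to, minlength=n_frame).astype(np.int64)
    return SyntheticPopulation(
        n_frame=n_frame, is_key=is_key, tie_from=tie_from, tie_to=tie_to,
        y_true=y, v_true=v, y_reported=y.copy(), v_reported=v.copy(),
        attendance_rate=np.ones(n_frame),
    )


def _scenario_rates(
    scenario: str, n: int, tie_counts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw attendance rates for one stratum under scenario S1..S4."""
    if scenario == "S1":
        # Homogeneous: everyone attends equally often.
        return np.ones(n)
    if scenario == "S2":
        # Right-skewed: lognormal visit rates, a heavy tail of frequent attenders.
        return rng.lognormal(mean=0.0, sigma=_LOGNORMAL_SIGMA, size=n)
    if scenario == "S3":
        # Clumped two-point mixture: 80% occasional (rate 1), 20% regulars (rate 10).
        return np.where(rng.random(n) < _S3_HIGH_SHARE, _S3_HIGH_RATE, 1.0)
    if scenario == "S4":
        # Degree-confounded: lognormal rates rank-correlated (~0.5) with the
        # person's tie count, via a Gaussian copula on jittered ranks.
        rho = 2.0 * np.sin(np.pi * _S4_RANK_CORRELATION / 6.0)  # Spearman -> Pearson
        order = np.lexsort((rng.random(n), tie_counts))
        ranks = np.empty(n)
        ranks[order] = np.arange(n)
        z_tie = ndtri((ranks + 0.5) / n)
        z = rho * z_tie + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        return np.exp(_LOGNORMAL_SIGMA * z)
    raise ConfigurationError(f"unknown attendance scenario {scenario!r}; expected one of {ATTENDANCE_SCENARIOS}")


def assign_attendance(
    pop: SyntheticPopulation,
    scenario_nonkey: str = "S1",
    scenario_key: str = "S1",
    *,
    seed: SeedLike,
) -> SyntheticPopulation:
    """Assign venue-attendance rates, separately for key and non-key strata.

    The acquaintance network is untouched, so the same population can be
    re-dressed under different attendance scenarios. For the
    degree-confounded family S4, key members' rates track their in-tie
    counts (their visibility) and non-key members' rates track their
    out-tie counts.
    """
    rng = _rng(seed)
    rates = np.empty(pop.n_frame)
    key, nonkey = pop.key_ids, pop.nonkey_ids
    # Key stratum first, then non-key: fixed order keeps the draw reproducible.
    rates[key] = _scenario_rates(scenario_key, key.size, pop.v_true[key], rng)
    rates[nonkey] = _scenario_rates(scenario_nonkey, nonkey.size, pop.y_true[nonkey], rng)
    return replace(pop, attendance_rate=rates)


def apply_reporting_error(
    pop: SyntheticPopulation, model: ReportingModel, *, seed: SeedLike
) -> SyntheticPopulation:
    """Perturb reported tie counts under a :class:`ReportingModel`.

    The model is always applied to the *true* network (repeated calls do not
    compound). False negatives delete ties from both the out-report and the
    matched in-report; false positives add unmatched phantom out-ties only,
    so a positive false-positive rate breaks the out/in identity in exactly
    one direction — reported out-totals exceed in-totals in expectation.
    Non-members' in-reports remain identically zero.
    """
    rng = _rng(seed)
    if model.false_negative_rate > 0:
        keep = rng.random(pop.tie_from.size) >= model.false_negative_rate
        y = np.bincount(pop.tie_from[keep], minlength=pop.n_frame).astype(np.int64)
        v = np.bincount(pop.tie_to[keep], minlength=pop.n_frame).astype(np.int64)
    else:
        y, v = pop.y_true.copy(), pop.v_true.copy()
    if model.false_positive_rate > 0:
        lam = model.false_positive_rate * model.misattribution_pool * pop.n_key / pop.n_frame
        y = y + rng.poisson(lam, size=pop.n_frame)
    return replace(pop, y_reported=y, v_reported=v)
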
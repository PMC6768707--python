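"""Venue-intercept sampling from a synthetic frame population.

Venue-based (time-location) sampling intercepts people at the venues they
attend, so a person's chance of ending up in the sample grows with how often
they attend. The sampler here models that as sequential draws proportional
to each person's attendance rate, without replacement, continuing until
fixed quotas of key and non-key respondents are met (draws from an
already-filled stratum are discarded, as intercept studies keep recruiting
until quotas close).

Crucially, the sample records carry only the *relative* inclusion
probability c_i — the attendance rate itself, meaningful only up to a common
constant. Absolute inclusion probabilities are never exposed to the
estimators; :func:`true_inclusion_probs` estimates them by brute-force
replication purely as an oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SamplingError
from .population import SeedLike, SyntheticPopulation, _rng


@dataclass(frozen=True, eq=False)
class VenueSample:
    """Respondent records from one venue-intercept sample.

    ``v`` is the in-report proxy and is only defined for key respondents
    (NaN for non-key); ``y`` is the out-report and is only *used* for
    non-key respondents, mirroring how the estimator consumes the survey
    questions. ``is_key`` is the self-reported status, taken as accurate in
    the non-key direction (non-members do not claim membership).
    """

    person_id: np.ndarray
    is_key: np.ndarray   # bool
    c: np.ndarray        # relative inclusion probability, > 0
    y: np.ndarray        # out-reports (int)
    v: np.ndarray        # in-report proxy (float, NaN for non-key)

    def __post_init__(self):
        if np.any(self.c <= 0):
            raise ConfigurationError("relative inclusion probabilities must be positive")

    def __len__(self) -> int:
        return self.person_id.size

    # Stratum views consumed by the estimators ---------------------------
    @property
    def n_key_respondents(self) -> int:
        return int(self.is_key.sum())

    @property
    def n_nonkey_respondents(self) -> int:
        return len(self) - self.n_key_respondents

    @property
    def y_nonkey(self) -> np.ndarray:
        return self.y[~self.is_key]

    @property
    def c_nonkey(self) -> np.ndarray:
        return self.c[~self.is_key]

    @property
    def v_key(self) -> np.ndarray:
        return self.v[self.is_key]

    @property
    def c_key(self) -> np.ndarray:
        return self.c[self.is_key]

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: person_id, stratum, c, y, v (v empty for non-key)."""
        return pd.DataFrame(
            {
                "person_id": self.person_id,
                "stratum": np.where(self.is_key, "key", "nonkey"),
                "c": self.c,
                "y": self.y,
                "v": self.v,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VenueSample":
        is_key = df["stratum"].astype(str).str.lower().eq("key").to_numpy()
        return cls(
            person_id=df["person_id"].to_numpy(),
            is_key=is_key,
            c=df["c"].to_numpy(dtype=float),
            y=df["y"].to_numpy(dtype=np.int64),
            v=df["v"].to_numpy(dtype=float),
        )


def _successive_pick(
    rng: np.random.Generator, ids: np.ndarray, rates: np.ndarray, k: int
) -> np.ndarray:
    """First k ids in successive-sampling (PPS without replacement) order.

    Sequential draws proportional to rate without replacement produce a
    size-biased permutation, realisable as the ascending order of
    u_i = Exp(1)/rate_i; the first k entries are the sampled set. Selected
    ids are returned in ascending id order (the set, not the draw order, is
    what the estimators use).
    """
    if k == ids.size:
        return ids.copy()
    u = rng.exponential(size=ids.size) / rates
    sel = np.argpartition(u, k - 1)[:k]
    return np.sort(ids[sel])


def draw_sample(
    pop: SyntheticPopulation,
    n_key_target: int,
    n_nonkey_target: int,
    *,
    seed: SeedLike,
) -> VenueSample:
    """Draw one venue-intercept sample with fixed stratum quotas.

    Inclusion is probability-proportional-to-attendance without replacement;
    recruiting continues until exactly ``n_key_target`` key members and
    ``n_nonkey_target`` non-members are obtained. Because a size-biased
    permutation restricted to a stratum is that stratum's own size-biased
    permutation, the two quotas are filled by independent per-stratum
    successive sampling — an exact reformulation of walking the joint draw
    order and discarding draws from filled strata.

    Reported tie counts (``y_reported``/``v_reported``) populate the sample,
    and each record's ``c`` is the attendance rate: a relative inclusion
    probability only.
    """
    if n_key_target < 1 or n_nonkey_target < 1:
        raise ConfigurationError("stratum targets must be at least 1")
    if n_key_target > pop.n_key or n_nonkey_target > pop.n_nonkey:
        raise SamplingError(
            f"targets ({n_key_target} key, {n_nonkey_target} non-key) exceed "
            f"stratum sizes ({pop.n_key}, {pop.n_nonkey})"
        )
    rng = _rng(seed)
    key_ids = pop.key_ids
    nonkey_ids = pop.nonkey_ids
    # Key stratum drawn first, then non-key: fixed stream order for determinism.
    sel_key = _successive_pick(rng, key_ids, pop.attendance_rate[key_ids], n_key_target)
    sel_non = _successive_pick(rng, nonkey_ids, pop.attendance_rate[nonkey_ids], n_nonkey_target)

    ids = np.concatenate([sel_key, sel_non])
    is_key = np.zeros(ids.size, dtype=bool)
    is_key[: sel_key.size] = True
    v = np.full(ids.size, np.nan)
    v[: sel_key.size] = pop.v_reported[sel_key]
    return VenueSample(
        person_id=ids,
        is_key=is_key,
        c=pop.attendance_rate[ids].copy(),
        y=pop.y_reported[ids].copy(),
        v=v,
    )


def true_inclusion_probs(
    pop: SyntheticPopulation,
    n_key_target: int,
    n_nonkey_target: int,
    n_replicates: int = 1000,
    *,
    seed: SeedLike,
) -> np.ndarray:
    """Monte-Carlo per-person inclusion frequencies under :func:`draw_sample`.

    Test/oracle support only: the design's absolute inclusion probabilities
    are exactly what venue-based sampling does *not* observe, but knowing
    them lets tests benchmark the relative-probability estimators against
    known-probability ones. Returns an array of length ``n_frame``.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be at least 1")
    rng = _rng(seed)
    counts = np.zeros(pop.n_frame)
    strata = (
        (pop.key_ids, n_key_target),
        (pop.nonkey_ids, n_nonkey_target),
    )
    for ids, k in strata:
        if k > ids.size:
            raise SamplingError("target exceeds stratum size")
        rates = pop.attendance_rate[ids]
        if k == ids.size:
            counts[ids] += n_replicates
            continue
        # Vectorise in modest chunks to bound memory.
        chunk = max(1, int(2e7 // ids.size))
        done = 0
        while done < n_replicates:
            b = min(chunk, n_replicates - done)
            u = rng.exponential(size=(b, ids.size)) / rates
            part = np.argpartition(u, k - 1, axis=1)[:, :k]
            counts += np.bincount(ids[part.ravel()], minlength=pop.n_frame)
            done += b
    return counts / n_replicates
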
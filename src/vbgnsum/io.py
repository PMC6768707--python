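"""Readers, writers, and configuration for vbgnsum.

Survey mode consumes a delimited file of venue-intercept interview records
with the two acquaintance-count questions the method needs:

* ``q1_total_venue_acquaintances`` — "of the people you know (and who know
  you), how many go out to the venues on the frame?"
* ``q2_key_venue_acquaintances`` — the same count restricted to key
  population members.

plus ``is_key`` (self-reported status, 0/1), ``attendance_freq`` (venue
visits per reference period, the relative inclusion probability proxy), and
``respondent_id``. Column matching is case-insensitive. The mapping to the
estimator's inputs follows the survey protocol's operational rule: key
respondents contribute ``v = q1 − q2`` (their venue-attending non-key
acquaintances, the in-report proxy) and non-key respondents contribute
``y = q2`` (their out-report of key acquaintances).

All files are comma-separated UTF-8 with a mandatory header and "." decimal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, MissingColumnError, SurveyValidationError
from .estimators import EstimateResult
from .population import SyntheticPopulation
from .sampling import VenueSample
from .simulate import ScenarioConfig

SURVEY_COLUMNS = (
    "respondent_id",
    "is_key",
    "attendance_freq",
    "q1_total_venue_acquaintances",
    "q2_key_venue_acquaintances",
)


def read_survey(path: str | Path) -> VenueSample:
    """Read and validate a venue-intercept survey file into a VenueSample.

    Rows failing validation are reported together in a single
    :class:`SurveyValidationError`, each with its file line number (the
    header is line 1). Distinct failure modes: nonpositive attendance
    frequency, negative counts, ``is_key`` outside {0, 1}, and a key
    respondent reporting more key acquaintances than total acquaintances
    (q2 > q1).
    """
    df = pd.read_csv(path)
    rename = {c: c.strip().lower() for c in df.columns}
    df = df.rename(columns=rename)
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise MissingColumnError(missing)

    problems: list[tuple[int, str]] = []
    lines = df.index.to_numpy() + 2  # header occupies line 1

    def numeric(col):
        out = pd.to_numeric(df[col], errors="coerce")
        for row in lines[out.isna().to_numpy()]:
            problems.append((int(row), f"{col} is not numeric"))
        return out.to_numpy(dtype=float)

    is_key = numeric("is_key")
    att = numeric("attendance_freq")
    q1 = numeric("q1_total_venue_acquaintances")
    q2 = numeric("q2_key_venue_acquaintances")
    with np.errstate(invalid="ignore"):
        for row in lines[~np.isin(is_key, (0.0, 1.0)) & ~np.isnan(is_key)]:
            problems.append((int(row), "is_key must be 0 or 1"))
        for row in lines[(att <= 0) & ~np.isnan(att)]:
            problems.append((int(row), "attendance_freq must be positive"))
        for col, arr in (("q1_total_venue_acquaintances", q1),
                         ("q2_key_venue_acquaintances", q2)):
            for row in lines[(arr < 0) & ~np.isnan(arr)]:
                problems.append((int(row), f"{col} must be nonnegative"))
        bad_q = (is_key == 1.0) & (q2 > q1)
        for row in lines[bad_q & ~np.isnan(q1) & ~np.isnan(q2)]:
            problems.append((int(row), "key respondent reports q2 > q1"))
    if problems:
        raise SurveyValidationError(sorted(problems))

    key_mask = is_key == 1.0
    v = np.where(key_mask, q1 - q2, np.nan)
    return VenueSample(
        person_id=df["respondent_id"].to_numpy(),
        is_key=key_mask,
        c=att,
        y=q2.astype(np.int64),
        v=v,
    )


def write_survey(sample: VenueSample, path: str | Path, *,
                 q1_filler: np.ndarray | None = None) -> None:
    """Write a VenueSample as a survey-format file (inverse of read_survey).

    Key respondents' q1 is reconstructed as v + q2 so the operational rule
    round-trips exactly; non-key respondents' q1 is their q2 plus optional
    filler acquaintances (q1 is never used by the estimator for them).
    """
    q2 = sample.y.astype(np.int64)
    extra = np.zeros(len(sample), dtype=np.int64) if q1_filler is None else q1_filler
    q1 = np.where(sample.is_key, q2 + np.nan_to_num(sample.v).astype(np.int64), q2 + extra)
    pd.DataFrame(
        {
            "respondent_id": sample.person_id,
            "is_key": sample.is_key.astype(int),
            "attendance_freq": sample.c,
            "q1_total_venue_acquaintances": q1,
            "q2_key_venue_acquaintances": q2,
        }
    ).to_csv(path, index=False)


def write_sample(sample: VenueSample, path: str | Path) -> None:
    """Serialise a sample: person_id, stratum, c, y, v (v empty for non-key)."""
    sample.to_frame().to_csv(path, index=False)


def read_sample(path: str | Path) -> VenueSample:
    return VenueSample.from_frame(pd.read_csv(path))


def write_population(pop: SyntheticPopulation, path: str | Path) -> None:
    """Serialise a population, one row per person.

    The flat tie list is not serialised — reporting error must be applied
    before writing if reported counts are to differ from true counts.
    """
    pd.DataFrame(
        {
            "id": np.arange(pop.n_frame),
            "is_key": pop.is_key.astype(int),
            "y_true": pop.y_true,
            "y_reported": pop.y_reported,
            "v_true": pop.v_true,
            "v_reported": pop.v_reported,
            "attendance_rate": pop.attendance_rate,
        }
    ).to_csv(path, index=False)


def write_report(
    result: EstimateResult,
    path_prefix: str | Path,
    *,
    bootstrap: np.ndarray | None = None,
    ci: tuple[float, float] = (2.5, 97.5),
    seed: int | None = None,
    provenance: dict | None = None,
) -> dict:
    """Write a JSON + CSV estimate report; returns the report dict.

    The bootstrap percentile interval is included only when replicate draws
    are supplied (NaN replicates — inestimable resamples — are dropped and
    counted).
    """
    from . import __version__

    report: dict = {
        "estimator": result.estimator_name,
        "n_hat": result.n_hat,
        "numerator_total": result.numerator_total,
        "denominator_mean": result.denominator_mean,
        "n_frame_minus_key_used": result.n_frame_minus_key_used,
    }
    if bootstrap is not None and len(bootstrap) > 0:
        draws = np.asarray(bootstrap, dtype=float)
        ok = draws[~np.isnan(draws)]
        lo, hi = np.percentile(ok, ci) if ok.size else (float("nan"),) * 2
        report["bootstrap"] = {
            "n_replicates": int(draws.size),
            "n_inestimable": int(draws.size - ok.size),
            "percentiles": list(ci),
            "ci_lower": float(lo),
            "ci_upper": float(hi),
        }
    report["provenance"] = {
        "package": "vbgnsum",
        "version": __version__,
        "seed": seed,
        **(provenance or {}),
    }

    path_prefix = Path(path_prefix)
    path_prefix.parent.mkdir(parents=True, exist_ok=True)
    path_prefix.with_suffix(".json").write_text(
        json.dumps(report, indent=2) + "\n", encoding="utf-8"
    )
    flat = {k: v for k, v in report.items() if not isinstance(v, dict)}
    if "bootstrap" in report:
        flat.update({f"bootstrap_{k}": v for k, v in report["bootstrap"].items()
                     if not isinstance(v, list)})
    pd.DataFrame([flat]).to_csv(path_prefix.with_suffix(".csv"), index=False)
    return report


def read_report(path_prefix: str | Path) -> dict:
    return json.loads(Path(path_prefix).with_suffix(".json").read_text(encoding="utf-8"))


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    """Load a ScenarioConfig from a flat-key YAML file.

    Unknown keys are rejected rather than ignored so that a typo in a
    scenario file cannot silently run the default instead.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("scenario config must be a mapping")
    valid = set(ScenarioConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ConfigurationError(f"unknown config keys: {', '.join(sorted(unknown))}")
    return ScenarioConfig(**raw)
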
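"""Deterministic trauma-severity scoring: RTS, ISS, and the TRISS survival probability.

The TRISS (Trauma and Injury Severity Score) methodology estimates a patient's
probability of survival ``Ps`` from physiology and anatomy via a fixed logistic
model::

    Ps = 1 / (1 + exp(-b)),      b = b0 + b1*RTS + b2*ISS + b3*AgeIndex

where

* ``RTS`` is the Revised Trauma Score, a weighted sum of *coded* (0-4) values of
  the Glasgow Coma Scale total, systolic blood pressure, and respiratory rate:
  ``RTS = 0.9368*GCSc + 0.7326*sBPc + 0.2908*RRc`` (maximum 7.8408);
* ``ISS`` is the Injury Severity Score, the sum of squared AIS severities of the
  three most severely injured of six body regions (75 if any region has AIS 6);
* ``AgeIndex`` dichotomises age at a threshold (conventionally 55 years).

Coefficient sets are pluggable; the default is the Major Trauma Outcome Study
(MTOS) blunt-trauma set. All functions are pure; vectorised variants operating
on numpy arrays / pandas DataFrames back the registry-scale paths.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ISS_REGIONS",
    "RTS_WEIGHTS",
    "RTS_MAX",
    "MTOS_BLUNT",
    "ScoringError",
    "TrissCoefficients",
    "CodedPhysiology",
    "AISProfile",
    "ScoreResult",
    "round_half_up",
    "code_gcs",
    "code_sbp",
    "code_rr",
    "compute_rts",
    "compute_iss",
    "compute_age_index",
    "compute_triss_ps",
    "score_patient",
    "score_table",
]

#: The six ISS body regions (AIS severities are stored per region, 0 = uninjured).
ISS_REGIONS = ("head_neck", "face", "chest", "abdomen", "extremities", "external")

#: Default RTS component weights for (coded GCS, coded sBP, coded RR).
RTS_WEIGHTS = (0.9368, 0.7326, 0.2908)

#: Maximum attainable RTS with the default weights: all three coded values at 4.
RTS_MAX = 7.8408


class ScoringError(ValueError):
    """Raised for out-of-range or degenerate scoring inputs."""


def round_half_up(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Display rounding throughout the package uses this convention (the tables'
    convention), not banker's rounding.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrissCoefficients:
    """Logistic coefficients for the TRISS model plus RTS weights.

    ``b1`` multiplies RTS, ``b2`` ISS, ``b3`` the age index.  Sets for other
    cohorts (penetrating, locally recalibrated) can be injected anywhere a
    coefficient argument is accepted, or loaded from YAML/JSON via :meth:`load`.
    """

    b0: float
    b1: float
    b2: float
    b3: float
    rts_weights: tuple[float, float, float] = RTS_WEIGHTS
    age_threshold_years: int = 55

    def __post_init__(self) -> None:
        for name in ("b0", "b1", "b2", "b3"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ScoringError(f"coefficient {name} must be finite, got {v!r}")
        w = tuple(float(x) for x in self.rts_weights)
        if len(w) != 3 or any(x <= 0 for x in w):
            raise ScoringError(f"rts_weights must be 3 strictly positive reals, got {self.rts_weights!r}")
        object.__setattr__(self, "rts_weights", w)
        if self.age_threshold_years < 0:
            raise ScoringError("age_threshold_years must be non-negative")

    @classmethod
    def from_mapping(cls, d: Mapping) -> "TrissCoefficients":
        kwargs = dict(
            b0=float(d["b0"]),
            b1=float(d["b1"]),
            b2=float(d["b2"]),
            b3=float(d["b3"]),
        )
        if "rts_weights" in d:
            kwargs["rts_weights"] = tuple(float(x) for x in d["rts_weights"])
        if "age_threshold" in d:
            kwargs["age_threshold_years"] = int(d["age_threshold"])
        elif "age_threshold_years" in d:
            kwargs["age_threshold_years"] = int(d["age_threshold_years"])
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "TrissCoefficients":
        """Load a coefficient set from a YAML or JSON file."""
        text = open(path).read()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_mapping(d)

    def to_mapping(self) -> dict:
        return {
            "b0": self.b0,
            "b1": self.b1,
            "b2": self.b2,
            "b3": self.b3,
            "rts_weights": list(self.rts_weights),
            "age_threshold": self.age_threshold_years,
        }


#: MTOS blunt-trauma coefficient set (the conventional default).
MTOS_BLUNT = TrissCoefficients(-0.4499, 0.8085, -0.0835, -1.7430)


@dataclass(frozen=True)
class CodedPhysiology:
    """RTS coded values, each in 0-4, for (GCS, systolic BP, respiratory rate)."""

    gcs_coded: int
    sbp_coded: int
    rr_coded: int

    def __post_init__(self) -> None:
        for name in ("gcs_coded", "sbp_coded", "rr_coded"):
            v = getattr(self, name)
            if v not in (0, 1, 2, 3, 4):
                raise ScoringError(f"{name} must be an integer in 0..4, got {v!r}")

    @property
    def as_tuple(self) -> tuple[int, int, int]:
        return (self.gcs_coded, self.sbp_coded, self.rr_coded)


@dataclass(frozen=True)
class AISProfile:
    """AIS severity (0-6, 0 = uninjured) for each of the six ISS body regions."""

    head_neck: int = 0
    face: int = 0
    chest: int = 0
    abdomen: int = 0
    extremities: int = 0
    external: int = 0

    def __post_init__(self) -> None:
        for name in ISS_REGIONS:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or not (0 <= v <= 6):
                raise ScoringError(f"AIS severity {name} must be an integer in 0..6, got {v!r}")

    @classmethod
    def from_mapping(cls, d: Mapping) -> "AISProfile":
        return cls(**{r: int(d.get(r, 0)) for r in ISS_REGIONS})

    @property
    def severities(self) -> tuple[int, ...]:
        return tuple(getattr(self, r) for r in ISS_REGIONS)


@dataclass(frozen=True)
class ScoreResult:
    """Scores for one patient: RTS, ISS, age index, and the TRISS Ps."""

    rts: float
    iss: int
    age_index: int
    ps: float


# ---------------------------------------------------------------------------
# Coded-value bands (standard RTS revision)
# ---------------------------------------------------------------------------


def code_gcs(gcs_total: int) -> int:
    """Code a GCS total (3-15) to the RTS 0-4 band: 13-15→4, 9-12→3, 6-8→2, 4-5→1, 3→0."""
    if not (3 <= gcs_total <= 15):
        raise ScoringError(f"gcs_total must be in 3..15, got {gcs_total!r}")
    if gcs_total >= 13:
        return 4
    if gcs_total >= 9:
        return 3
    if gcs_total >= 6:
        return 2
    if gcs_total >= 4:
        return 1
    return 0


def code_sbp(sbp_mmhg: float) -> int:
    """Code systolic BP (mmHg) to the RTS 0-4 band: >89→4, 76-89→3, 50-75→2, 1-49→1, 0→0."""
    if not (sbp_mmhg >= 0) or not math.isfinite(sbp_mmhg):
        raise ScoringError(f"sbp_mmhg must be a finite value >= 0, got {sbp_mmhg!r}")
    if sbp_mmhg > 89:
        return 4
    if sbp_mmhg >= 76:
        return 3
    if sbp_mmhg >= 50:
        return 2
    if sbp_mmhg > 0:
        return 1
    return 0


def code_rr(rr_per_min: float) -> int:
    """Code respiratory rate (/min) to the RTS 0-4 band: 10-29→4, >29→3, 6-9→2, 1-5→1, 0→0."""
    if not (rr_per_min >= 0) or not math.isfinite(rr_per_min):
        raise ScoringError(f"rr_per_min must be a finite value >= 0, got {rr_per_min!r}")
    if rr_per_min > 29:
        return 3
    if rr_per_min >= 10:
        return 4
    if rr_per_min >= 6:
        return 2
    if rr_per_min > 0:
        return 1
    return 0


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def compute_rts(coded: CodedPhysiology, weights: Iterable[float] = RTS_WEIGHTS) -> float:
    """Revised Trauma Score: weighted sum of the coded GCS/sBP/RR values.

    With the default weights the range is [0, 7.8408].
    """
    wg, ws, wr = (float(w) for w in weights)
    return wg * coded.gcs_coded + ws * coded.sbp_coded + wr * coded.rr_coded


def compute_iss(profile: AISProfile) -> int:
    """Injury Severity Score from a per-region AIS profile.

    Sum of squares of the three highest region severities (one term per
    region); any region at AIS 6 forces the maximum, 75.
    """
    sev = profile.severities
    if all(s == 0 for s in sev):
        raise ScoringError("uninjured patient: all region severities are 0")
    if any(s == 6 for s in sev):
        return 75
    top3 = sorted(sev, reverse=True)[:3]
    return int(sum(s * s for s in top3))


def compute_age_index(age_years: int, threshold: int = 55) -> int:
    """Age index for the TRISS linear predictor: 1 if age >= threshold else 0."""
    if age_years < 0:
        raise ScoringError(f"age_years must be non-negative, got {age_years!r}")
    return int(age_years >= threshold)


def compute_triss_ps(
    rts: float,
    iss: int,
    age_index: int,
    coef: TrissCoefficients = MTOS_BLUNT,
) -> float:
    """TRISS survival probability: logistic of b0 + b1*RTS + b2*ISS + b3*AgeIndex.

    Strictly inside (0, 1); increasing in RTS and decreasing in ISS for the
    conventional coefficient signs (b1 > 0, b2 < 0).
    """
    b = coef.b0 + coef.b1 * rts + coef.b2 * iss + coef.b3 * age_index
    if not math.isfinite(b):
        raise ScoringError(f"non-finite linear predictor b={b!r}")
    ps = 1.0 / (1.0 + math.exp(-b))
    # keep the open-interval contract under float saturation
    return min(max(ps, np.nextafter(0.0, 1.0)), np.nextafter(1.0, 0.0))


def score_patient(
    age_years: int,
    gcs_total: int,
    sbp_mmhg: float,
    rr_per_min: float,
    ais: AISProfile,
    coef: TrissCoefficients = MTOS_BLUNT,
) -> ScoreResult:
    """Score one patient from raw physiology and anatomy: RTS, ISS, Ps."""
    coded = CodedPhysiology(code_gcs(gcs_total), code_sbp(sbp_mmhg), code_rr(rr_per_min))
    rts = compute_rts(coded, coef.rts_weights)
    iss = compute_iss(ais)
    age_index = compute_age_index(age_years, coef.age_threshold_years)
    ps = compute_triss_ps(rts, iss, age_index, coef)
    return ScoreResult(rts=rts, iss=iss, age_index=age_index, ps=ps)


# ---------------------------------------------------------------------------
# Vectorised table scoring
# ---------------------------------------------------------------------------


def _code_gcs_vec(g: np.ndarray) -> np.ndarray:
    return np.select([g >= 13, g >= 9, g >= 6, g >= 4], [4, 3, 2, 1], default=0)


def _code_sbp_vec(s: np.ndarray) -> np.ndarray:
    return np.select([s > 89, s >= 76, s >= 50, s > 0], [4, 3, 2, 1], default=0)


def _code_rr_vec(r: np.ndarray) -> np.ndarray:
    return np.select([r > 29, r >= 10, r >= 6, r > 0], [3, 4, 2, 1], default=0)


def _iss_vec(sev: np.ndarray) -> np.ndarray:
    """ISS for an (n, 6) severity matrix; rows must have at least one injury."""
    top3 = np.sort(sev, axis=1)[:, -3:]
    iss = (top3 * top3).sum(axis=1)
    iss[(sev == 6).any(axis=1)] = 75
    return iss.astype(int)


def score_table(df: pd.DataFrame, coef: TrissCoefficients = MTOS_BLUNT) -> pd.DataFrame:
    """Vectorised :func:`score_patient` over a complete-case registry frame.

    Requires columns ``age_years``, ``gcs_total``, ``sbp_mmhg``, ``rr_per_min``
    and ``ais_<region>`` for the six ISS regions, with no missing values.
    Returns a copy with ``rts``, ``iss`` and ``ps`` columns appended.
    """
    out = df.copy()
    g = _code_gcs_vec(df["gcs_total"].to_numpy(dtype=float))
    s = _code_sbp_vec(df["sbp_mmhg"].to_numpy(dtype=float))
    r = _code_rr_vec(df["rr_per_min"].to_numpy(dtype=float))
    wg, ws, wr = coef.rts_weights
    rts = wg * g + ws * s + wr * r
    sev = df[[f"ais_{reg}" for reg in ISS_REGIONS]].to_numpy(dtype=int)
    if (sev == 0).all(axis=1).any():
        raise ScoringError("uninjured patient: all region severities are 0")
    iss = _iss_vec(sev)
    age_idx = (df["age_years"].to_numpy(dtype=float) >= coef.age_threshold_years).astype(int)
    b = coef.b0 + coef.b1 * rts + coef.b2 * iss + coef.b3 * age_idx
    ps = 1.0 / (1.0 + np.exp(-b))
    eps = np.finfo(float).tiny
    out["rts"] = rts
    out["iss"] = iss
    out["ps"] = np.clip(ps, eps, 1.0 - 1e-16)
    return out
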
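"""Seeded synthetic pediatric blunt-trauma registry generator.

Emulates the structure of a national trauma registry cohort so the whole
scoring/validation pipeline can run without restricted data.  The generative
chain, per patient:

1. age group (four pediatric bands; default sizes proportional to the
   reference cohort: 330 / 2183 / 5950 / 9282) and uniform age within band;
2. per-region injuries: each of the six ISS body regions is severely injured
   (AIS 3-5) with an age-group-specific probability (e.g. severe head injury
   in 81% of neonates/infants vs 31% of adolescents), otherwise carries a
   minor injury (AIS 1-2) with a region-specific probability; patients with no
   injury at all get a minor external injury;
3. physiology on the raw scale (GCS 3-15, systolic BP in mmHg, respiratory
   rate per minute), degraded stochastically with head-injury severity (GCS)
   and worst-region severity (sBP, RR), so the coded-band arithmetic is
   exercised end to end;
4. survival ~ Bernoulli(logistic(gamma*b + delta)) where ``b`` is the TRISS
   linear predictor under the truth coefficients — with ``gamma=1, delta=0``
   the registry is perfectly calibrated *by construction*, which is the truth
   the validation module must recover; a nonzero logit offset ``delta``
   injects miscalibration;
5. optional ineligible records (overage, penetrating, burn, arrest on
   arrival) and per-field, per-age-group MCAR missingness, so the inclusion
   filter and missing-data accounting have work to do.

Identical config (including seed) gives byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .scoring import ISS_REGIONS, MTOS_BLUNT, TrissCoefficients, score_table
from .registry import PatientRecord, dataframe_to_records
from .validation import AGE_GROUPS

__all__ = ["SynthConfig", "generate_registry", "generate_records", "truth_table"]

_GROUP_LABELS = tuple(g.label for g in AGE_GROUPS)

#: P(region has AIS >= 3) per age group (neonates/infants, preschool,
#: schoolchildren, adolescents), patterned on the reference cohort's
#: injured-region table (head-heavy infants, chest/extremity-heavy teens).
_DEFAULT_SEVERE_REGION_PROBS = {
    "head_neck": (0.81, 0.39, 0.33, 0.31),
    "face": (0.005, 0.006, 0.007, 0.013),
    "chest": (0.03, 0.16, 0.145, 0.23),
    "abdomen": (0.009, 0.04, 0.08, 0.085),
    "extremities": (0.04, 0.21, 0.28, 0.25),
    "external": (0.01, 0.01, 0.01, 0.01),
}

#: P(region has a minor injury, AIS 1-2 | not severely injured).
_DEFAULT_MINOR_REGION_PROBS = {
    "head_neck": 0.25,
    "face": 0.15,
    "chest": 0.10,
    "abdomen": 0.08,
    "extremities": 0.35,
    "external": 0.40,
}

#: MCAR missingness per field, per age group; marginals patterned on the
#: reference registry (outcome 9.4%, ISS 2.6%, GCS 7.4%, sBP 6.1%, RR 14.5%
#: overall) with markedly higher rates for neonates/infants.
_DEFAULT_MISSING_RATES = {
    "survived": (0.30, 0.11, 0.08, 0.09),
    "ais": (0.08, 0.03, 0.02, 0.025),
    "gcs_total": (0.22, 0.09, 0.06, 0.07),
    "sbp_mmhg": (0.20, 0.08, 0.05, 0.055),
    "rr_per_min": (0.35, 0.17, 0.12, 0.14),
}

_DEFAULT_INELIGIBLE_RATES = {
    "age_over_18": 0.01,
    "penetrating": 0.02,
    "burn": 0.01,
    "arrest": 0.01,
}


@dataclass
class SynthConfig:
    """Generative parameters for a synthetic registry; identical config ⇒ identical output."""

    group_sizes: tuple[int, int, int, int] = (330, 2183, 5950, 9282)
    male_fraction: tuple[float, float, float, float] = (0.66, 0.64, 0.72, 0.76)
    severe_region_probs: dict = field(default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_SEVERE_REGION_PROBS.items()})
    minor_region_probs: dict = field(default_factory=lambda: dict(_DEFAULT_MINOR_REGION_PROBS))
    severe_level_probs: tuple[float, float, float] = (0.68, 0.22, 0.10)  # AIS 3,4,5
    minor_level_probs: tuple[float, float] = (0.55, 0.45)  # AIS 1,2
    coefficients: TrissCoefficients = MTOS_BLUNT
    logit_slope: float = 1.0  # gamma
    logit_offset: float = 0.0  # delta
    missing_rates: dict = field(default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_MISSING_RATES.items()})
    ineligible_rates: dict = field(default_factory=lambda: dict(_DEFAULT_INELIGIBLE_RATES))
    seed: int = 7

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(_GROUP_LABELS):
            raise ValueError("group_sizes must have one entry per age group")
        if any(n < 0 for n in self.group_sizes):
            raise ValueError("group sizes must be >= 0")
        if sum(self.group_sizes) == 0:
            raise ValueError("total n must be > 0")
        for name, probs in [
            ("male_fraction", self.male_fraction),
            ("severe_level_probs", self.severe_level_probs),
            ("minor_level_probs", self.minor_level_probs),
        ]:
            if any(not (0 <= p <= 1) for p in probs):
                raise ValueError(f"{name} entries must be probabilities in [0,1]")
        for region, probs in self.severe_region_probs.items():
            if any(not (0 <= p <= 1) for p in probs):
                raise ValueError(f"severe_region_probs[{region}] must be in [0,1]")

    @classmethod
    def calibration(cls, total_n: int = 200_000, seed: int = 7, **overrides) -> "SynthConfig":
        """A clean, perfectly calibrated config at scale ``total_n``.

        Group sizes are scaled proportionally from the defaults; missingness
        and ineligibility are zeroed so every generated record enters the
        cohort (the config used for calibration-recovery checks, where
        filtering is not under test).
        """
        base = np.array(cls().group_sizes, dtype=float)
        sizes = np.floor(base / base.sum() * total_n).astype(int)
        sizes[-1] += total_n - sizes.sum()
        return cls(
            group_sizes=tuple(int(s) for s in sizes),
            missing_rates={k: (0.0,) * 4 for k in _DEFAULT_MISSING_RATES},
            ineligible_rates={k: 0.0 for k in _DEFAULT_INELIGIBLE_RATES},
            seed=seed,
            **overrides,
        )

    # -- serialisation -----------------------------------------------------
    def to_mapping(self) -> dict:
        d = asdict(self)
        d["coefficients"] = self.coefficients.to_mapping()
        d["group_sizes"] = list(self.group_sizes)
        return d

    @classmethod
    def from_mapping(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "coefficients" in d and not isinstance(d["coefficients"], TrissCoefficients):
            d["coefficients"] = TrissCoefficients.from_mapping(d["coefficients"])
        for key in ("group_sizes", "male_fraction", "severe_level_probs", "minor_level_probs"):
            if key in d:
                d[key] = tuple(d[key])
        if "severe_region_probs" in d:
            d["severe_region_probs"] = {k: tuple(v) for k, v in d["severe_region_probs"].items()}
        if "missing_rates" in d:
            d["missing_rates"] = {k: tuple(v) for k, v in d["missing_rates"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=False)

    def digest(self) -> str:
        """Stable hash of the full config, for provenance blocks."""
        return hashlib.sha256(json.dumps(self.to_mapping(), sort_keys=True).encode()).hexdigest()[:16]


# GCS mean/sd conditional on head/neck AIS severity 0..5; sBP drop and
# RR dispersion growth conditional on worst-region excess severity
# max(AIS-2, 0) in 0..3.  Chosen so the scored cohort reproduces the
# reference registry's marginal structure (median Ps 0.99, Ps-interval
# shares ~1/2/3/5/6/82%, ISS median 10) — see docs/methods.md.
_GCS_MU = np.array([15.0, 14.9, 14.6, 13.2, 7.0, 4.0])
_GCS_SD = np.array([0.5, 0.6, 0.9, 2.0, 3.5, 1.6])
_SBP_DROP = np.array([0.0, 5.0, 24.0, 50.0])
_SBP_SD0 = 11.0
_RR_SD0 = 3.0
_RR_SDX = 2.8


def _simulate_group(rng: np.random.Generator, cfg: SynthConfig, gidx: int) -> pd.DataFrame:
    group = AGE_GROUPS[gidx]
    n = cfg.group_sizes[gidx]
    age = rng.integers(group.lo, group.hi + 1, size=n)
    sex = np.where(rng.random(n) < cfg.male_fraction[gidx], "male", "female")

    sev = np.zeros((n, len(ISS_REGIONS)), dtype=int)
    severe_levels = np.array([3, 4, 5])
    minor_levels = np.array([1, 2])
    for j, region in enumerate(ISS_REGIONS):
        p_severe = cfg.severe_region_probs[region][gidx]
        p_minor = cfg.minor_region_probs.get(region, 0.0)
        u = rng.random(n)
        is_severe = u < p_severe
        is_minor = (~is_severe) & (rng.random(n) < p_minor)
        sev[is_severe, j] = rng.choice(severe_levels, size=int(is_severe.sum()), p=cfg.severe_level_probs)
        sev[is_minor, j] = rng.choice(minor_levels, size=int(is_minor.sum()), p=np.asarray(cfg.minor_level_probs) / sum(cfg.minor_level_probs))
    uninjured = (sev == 0).all(axis=1)
    sev[uninjured, ISS_REGIONS.index("external")] = 1

    head = sev[:, ISS_REGIONS.index("head_neck")]
    worst = sev.max(axis=1)
    excess = np.maximum(worst - 2, 0)

    gcs = np.clip(np.round(rng.normal(_GCS_MU[head], _GCS_SD[head])), 3, 15).astype(int)
    sbp = np.clip(rng.normal(115.0 - _SBP_DROP[excess], _SBP_SD0 + 3.0 * excess), 0.0, 260.0)
    rr = np.clip(np.round(rng.normal(21.0 + 1.0 * excess, _RR_SD0 + _RR_SDX * excess)), 0.0, 80.0)

    df = pd.DataFrame(
        {
            "age_years": age,
            "sex": sex,
            "mechanism": "blunt",
            "arrest_on_arrival": False,
            "gcs_total": gcs,
            "sbp_mmhg": np.round(sbp, 0),
            "rr_per_min": rr,
        }
    )
    for j, region in enumerate(ISS_REGIONS):
        df[f"ais_{region}"] = sev[:, j]
    df["_group"] = gidx
    return df


def _true_death_probability(df: pd.DataFrame, cfg: SynthConfig) -> np.ndarray:
    """P(death) per record under the (possibly distorted) truth model."""
    scored = score_table(df, cfg.coefficients)
    c = cfg.coefficients
    b = c.b0 + c.b1 * scored["rts"].to_numpy() + c.b2 * scored["iss"].to_numpy()
    b = b + c.b3 * (df["age_years"].to_numpy() >= c.age_threshold_years).astype(int)
    p_survive = 1.0 / (1.0 + np.exp(-(cfg.logit_slope * b + cfg.logit_offset)))
    return 1.0 - p_survive


def generate_registry(config: Optional[SynthConfig] = None) -> pd.DataFrame:
    """Generate a synthetic registry as a canonical-schema DataFrame.

    Deterministic under a fixed config; see the module docstring for the
    generative chain.  Missing values are NaN/None in the returned frame.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    parts = [_simulate_group(rng, cfg, g) for g in range(len(_GROUP_LABELS)) if cfg.group_sizes[g] > 0]
    df = pd.concat(parts, ignore_index=True)
    n = len(df)

    p_death = _true_death_probability(df, cfg)
    df["survived"] = rng.random(n) >= p_death

    # ineligible-record injection (for filter testing); flags flipped in place
    rates = cfg.ineligible_rates
    u = rng.random(n)
    over = u < rates.get("age_over_18", 0.0)
    df.loc[over, "age_years"] = rng.integers(19, 90, size=int(over.sum()))
    u = rng.random(n)
    pen = (~over) & (u < rates.get("penetrating", 0.0))
    burn = (~over) & (~pen) & (u < rates.get("penetrating", 0.0) + rates.get("burn", 0.0))
    df.loc[pen, "mechanism"] = "penetrating"
    df.loc[burn, "mechanism"] = "burn"
    arrest = rng.random(n) < rates.get("arrest", 0.0)
    df.loc[arrest, "arrest_on_arrival"] = True

    # MCAR missingness per field per age group
    gidx = df["_group"].to_numpy()
    for fld, per_group in cfg.missing_rates.items():
        rate = np.asarray(per_group, dtype=float)[gidx]
        mask = rng.random(n) < rate
        if fld == "ais":
            for region in ISS_REGIONS:
                df.loc[mask, f"ais_{region}"] = np.nan
        elif fld == "survived":
            df["survived"] = df["survived"].astype(object)
            df.loc[mask, "survived"] = None
        else:
            df.loc[mask, fld] = np.nan

    df = df.drop(columns=["_group"])
    df.insert(0, "patient_id", [f"P{i:07d}" for i in range(n)])
    return df


def generate_records(config: Optional[SynthConfig] = None) -> list[PatientRecord]:
    """:func:`generate_registry` materialised as :class:`PatientRecord` objects."""
    return dataframe_to_records(generate_registry(config))


def truth_table(config: Optional[SynthConfig] = None) -> pd.DataFrame:
    """Expected marginal summaries implied by the config, for generator self-tests.

    Per age group: n, the analytic expected count of severe (AIS >= 3) injury
    per region (probability x n), and the expected mortality — the mean true
    death probability over a seeded latent draw (exact conditional expectation
    given that draw; there is no closed form through the physiology chain),
    with the binomial standard deviation of the observed death count.
    """
    cfg = config or SynthConfig()
    clean = replace(
        cfg,
        missing_rates={k: (0.0,) * 4 for k in cfg.missing_rates},
        ineligible_rates={k: 0.0 for k in cfg.ineligible_rates},
    )
    rng = np.random.default_rng(clean.seed)
    rows = []
    for gidx, label in enumerate(_GROUP_LABELS):
        n = clean.group_sizes[gidx]
        if n == 0:
            continue
        df = _simulate_group(rng, clean, gidx)
        p_death = _true_death_probability(df, clean)
        row = {"age_group": label, "n": n}
        for region in ISS_REGIONS:
            row[f"expected_severe_{region}"] = clean.severe_region_probs[region][gidx] * n
        row["expected_deaths"] = float(p_death.sum())
        row["expected_mortality"] = float(p_death.mean())
        row["death_count_sd"] = float(np.sqrt((p_death * (1 - p_death)).sum()))
        rows.append(row)
    return pd.DataFrame(rows)
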
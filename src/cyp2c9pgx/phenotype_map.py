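"""Diplotype → activity score → phenotype → EHR risk → CPIC NSAID bucket.

The activity score (AS) of a diplotype is the sum of its two alleles'
activity values (normal 1, decreased 0.5, no function 0).  AS determines
the predicted metabolizer phenotype (NM at 2, IM at 1–1.5, PM at 0–0.5),
the EHR Priority Result Notation risk dichotomy (NM → Low, IM/PM → High),
and the CPIC NSAID recommendation bucket: usual starting dose with Strong
(AS 2) or Moderate (AS 1.5) strength, versus adjusting the initial dose or
drug choice (AS ≤ 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

from .star_model import ConfigurationError, StarConfig, load_star_config

__all__ = [
    "AS_GRID",
    "PhenotypeProfile",
    "CohortSummary",
    "activity_score",
    "phenotype_from_as",
    "ehr_risk",
    "cpic_nsaid_recommendation",
    "phenytoin_flag",
    "profile_for",
    "summarize_cohort",
]

AS_GRID = (0.0, 0.5, 1.0, 1.5, 2.0)

BUCKET_STRONG = "Strong-usual"
BUCKET_MODERATE = "Moderate-usual"
BUCKET_ADJUST = "Adjust"
_BUCKETS = (BUCKET_STRONG, BUCKET_MODERATE, BUCKET_ADJUST)
_PHENOTYPES = ("NM", "IM", "PM")


def _split_diplotype(diplotype) -> tuple:
    if isinstance(diplotype, str):
        parts = diplotype.split("/")
        if len(parts) != 2:
            raise ConfigurationError(f"cannot parse diplotype {diplotype!r}")
        return tuple(parts)
    a, b = diplotype
    return a, b


def activity_score(diplotype, config: StarConfig) -> float:
    """Sum of the two alleles' activity values.

    Accepts a '*1/*3'-style string or a pair; the pooled 'var' label
    (any of *5/*8/*11 on a *1 background) carries the decreased-function
    activity 0.5.
    """
    a, b = _split_diplotype(diplotype)
    return config.activity(a) + config.activity(b)


def phenotype_from_as(as_value: float) -> str:
    """Metabolizer phenotype from the activity score grid value."""
    if as_value not in AS_GRID:
        raise ValueError(f"activity score {as_value} outside grid {AS_GRID}")
    if as_value == 2.0:
        return "NM"
    if as_value >= 1.0:
        return "IM"
    return "PM"


def ehr_risk(phenotype: str) -> str:
    """EHR Priority Result Notation: Normal/Routine/Low vs Abnormal/Priority/High."""
    if phenotype == "NM":
        return "Low"
    if phenotype in ("IM", "PM"):
        return "High"
    raise ValueError(f"unknown phenotype {phenotype!r}")


def nsaid_bucket(as_value: float) -> str:
    """CPIC NSAID recommendation bucket for an activity score."""
    if as_value not in AS_GRID:
        raise ValueError(f"activity score {as_value} outside grid {AS_GRID}")
    if as_value == 2.0:
        return BUCKET_STRONG
    if as_value == 1.5:
        return BUCKET_MODERATE
    return BUCKET_ADJUST


def cpic_nsaid_recommendation(as_value: float, drug: str = "other"):
    """CPIC therapeutic recommendation (action, strength) for one NSAID.

    Drug groups: meloxicam, piroxicam, tenoxicam, or 'other' CYP2C9-substrate
    NSAIDs.  Recommendations diverge between drugs only below AS 1.5.
    """
    if as_value not in AS_GRID:
        raise ValueError(f"activity score {as_value} outside grid {AS_GRID}")
    drug = drug.lower()
    if drug not in ("meloxicam", "piroxicam", "tenoxicam", "other"):
        raise ValueError(f"unknown drug group {drug!r}")
    if as_value == 2.0:
        return ("usual starting dose", "Strong")
    if as_value == 1.5:
        return ("usual starting dose", "Moderate")
    if as_value == 1.0:
        return {
            "meloxicam": ("reduce initial dose", "Moderate"),
            "piroxicam": ("alternative drug", "Moderate"),
            "tenoxicam": ("alternative drug", "Optional"),
            "other": ("lowest recommended starting dose", "Moderate"),
        }[drug]
    # PM range (AS 0 or 0.5)
    return {
        "meloxicam": ("alternative drug", "Moderate"),
        "piroxicam": ("alternative drug", "Moderate"),
        "tenoxicam": ("alternative drug", "Optional"),
        "other": ("reduced dose", "Moderate"),
    }[drug]


def phenytoin_flag(phenotype: str) -> str | None:
    """Informational note for the phenytoin guideline (PMs only).

    HLA-B*15:02, on which the phenytoin recommendation also depends, is not
    modelled here; the note says so.
    """
    if phenotype == "PM":
        return (
            "phenytoin: Strong recommendation for dose adjustment in CYP2C9 PMs; "
            "HLA-B*15:02 status (not modelled here) must also be considered"
        )
    return None


@dataclass(frozen=True)
class PhenotypeProfile:
    """Full annotation chain for one diplotype."""

    diplotype: str
    activity_score: float
    phenotype: str
    ehr_risk: str
    nsaid_bucket: str


def profile_for(diplotype, config: StarConfig) -> PhenotypeProfile:
    a, b = _split_diplotype(diplotype)
    name = config.canonical_diplotype(a, b) if "var" not in (a, b) else f"{a}/{b}"
    as_value = activity_score((a, b), config)
    phen = phenotype_from_as(as_value)
    return PhenotypeProfile(
        diplotype=name,
        activity_score=as_value,
        phenotype=phen,
        ehr_risk=ehr_risk(phen),
        nsaid_bucket=nsaid_bucket(as_value),
    )


@dataclass
class CohortSummary:
    """Cohort-level distributions over diplotypes, AS, phenotype, risk, bucket."""

    n: int
    diplotype_counts: dict
    as_distribution: dict
    phenotype_distribution: dict
    risk_distribution: dict
    bucket_distribution: dict

    @property
    def high_risk_fraction(self) -> float:
        """Proportion of IM+PM phenotypes (1 − proportion of NM, AS = 2)."""
        return self.risk_distribution.get("High", 0.0)

    def as_json_dict(self) -> dict:
        return {
            "n": self.n,
            "diplotype_counts": self.diplotype_counts,
            "as_distribution": {str(k): v for k, v in self.as_distribution.items()},
            "phenotype_distribution": self.phenotype_distribution,
            "risk_distribution": self.risk_distribution,
            "bucket_distribution": self.bucket_distribution,
            "high_risk_fraction": self.high_risk_fraction,
        }


def summarize_cohort(diplotypes, config: StarConfig | None = None) -> CohortSummary:
    """Aggregate diplotypes into AS / phenotype / risk / CPIC distributions.

    ``diplotypes`` is either a mapping from diplotype name to count (as in
    a published frequency table turned into integers) or an iterable of
    DiplotypeCall objects, of which only included calls are used.
    """
    if config is None:
        config = load_star_config()
    if isinstance(diplotypes, Mapping):
        counts = {str(k): int(v) for k, v in diplotypes.items()}
    else:
        counts = {}
        for call in diplotypes:
            if not call.included:
                continue
            name = config.canonical_diplotype(*call.diplotype)
            counts[name] = counts.get(name, 0) + 1
    if any(v < 0 for v in counts.values()):
        raise ValueError("diplotype counts must be non-negative")
    n = sum(counts.values())
    if n == 0:
        raise ValueError("empty cohort: no (included) diplotypes to summarise")

    as_dist = {a: 0.0 for a in AS_GRID}
    phen_dist = {p: 0.0 for p in _PHENOTYPES}
    risk_dist = {"Low": 0.0, "High": 0.0}
    bucket_dist = {b: 0.0 for b in _BUCKETS}
    for name, count in counts.items():
        if count == 0:
            continue
        prof = profile_for(name, config)
        w = count / n
        as_dist[prof.activity_score] += w
        phen_dist[prof.phenotype] += w
        risk_dist[prof.ehr_risk] += w
        bucket_dist[prof.nsaid_bucket] += w
    return CohortSummary(
        n=n,
        diplotype_counts=counts,
        as_distribution=as_dist,
        phenotype_distribution=phen_dist,
        risk_distribution=risk_dist,
        bucket_distribution=bucket_dist,
    )
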
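"""End-to-end orchestration: phase → phenotype → statistics → impact.

`run_full_analysis` drives one cohort from a genotype file to diplotype
calls, phenotype summaries, population statistics and (optionally) NNG
estimates, writing plain TSV/JSON reports plus a machine-readable run
manifest.  `reproduce_published` recomputes the published-table quantities
from the packaged frequency fixtures and reports computed vs expected.
"""

from __future__ import annotations

import json
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .clinical_impact import MODE_RISK_RATIO, RiskModelParams, calibrate, nng
from .phasing_em import (
    DEFAULT_POSTERIOR_THRESHOLD,
    HaplotypeSpace,
    call_diplotypes,
    em_fit,
)
from .phenotype_map import CohortSummary, summarize_cohort
from .popstats import (
    DEFAULT_ALPHA,
    allele_freqs_from_diplotypes,
    hwe_chisq,
)
from .star_model import StarConfig, load_genotype_table, load_star_config, load_vcf
from .synthetic_data import table1_fixtures

__all__ = [
    "RunConfig",
    "run_full_analysis",
    "reproduce_published",
    "PUBLISHED",
    "NNG_ANCHORS",
]

#: Published anchor points (high-risk phenotype fraction, NNG) used to
#: calibrate the two-parameter risk model: the cohorts with the highest
#: and lowest high-risk fractions.
NNG_ANCHORS = ((0.365, 230.0), (0.071, 989.0))

#: Published values the reproduction report compares against.
PUBLISHED = {
    "allele_freq_PUR_*2": 0.139,
    "allele_freq_CLM_*3": 0.064,
    "allele_freq_PEL_*2": 0.024,
    "allele_freq_PEL_*3": 0.012,
    "high_risk_pct_PUR": 36.5,
    "high_risk_pct_PEL": 7.1,
    "bucket_moderate_PUR": 0.260,
    "bucket_adjust_PUR": 0.106,
    "bucket_moderate_Black": 0.137,
    "bucket_adjust_Black": 0.051,
    "bucket_moderate_White": 0.212,
    "bucket_adjust_White": 0.117,
    "nng_White": 250,
    "nng_Black": 402,
}


@dataclass
class RunConfig:
    """Configuration of one full-analysis run."""

    genotypes: str
    out_dir: str
    input_format: str = "auto"  # auto | tsv | vcf
    space_mode: str = "star-restricted"  # star-restricted | full-enumeration
    posterior_threshold: float = DEFAULT_POSTERIOR_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    risk_q: Optional[float] = None
    risk_effect: Optional[float] = None
    risk_mode: str = MODE_RISK_RATIO
    cost_per_sample: Optional[float] = None
    seed: Optional[int] = None
    star_config_path: Optional[str] = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _load_genotypes(cfg: RunConfig, star_config: StarConfig):
    fmt = cfg.input_format
    if fmt == "auto":
        fmt = "vcf" if str(cfg.genotypes).endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        return load_vcf(cfg.genotypes, star_config.loci)
    return load_genotype_table(cfg.genotypes, star_config.loci)


def _hwe_per_locus(genotypes, star_config: StarConfig):
    results = {}
    for i, locus in enumerate(star_config.loci):
        dosages = [g.dosage[i] for g in genotypes if not g.missing[i]]
        counts = (
            sum(d == 0 for d in dosages),
            sum(d == 1 for d in dosages),
            sum(d == 2 for d in dosages),
        )
        if sum(counts) == 0:
            continue
        res = hwe_chisq(counts)
        results[locus.rsid] = {
            "genotype_counts": list(counts),
            "chi2": res.chi2,
            "p_value": res.p_value,
        }
    return results


def run_full_analysis(cfg: RunConfig) -> dict:
    """Phase, phenotype, summarise and (optionally) score clinical impact.

    Writes calls.tsv, haplotype_frequencies.json, cohort_summary.json,
    statistics.json, nng.json (when risk parameters are configured) and
    run_manifest.json under cfg.out_dir; returns the bundle as a dict.
    Deterministic for fixed inputs and configuration.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    star_config = load_star_config(cfg.star_config_path)
    genotypes = _load_genotypes(cfg, star_config)
    if cfg.space_mode == "full-enumeration":
        space = HaplotypeSpace.full_enumeration(star_config)
    else:
        space = HaplotypeSpace.star_restricted(star_config)

    em = em_fit(genotypes, space)
    calls = call_diplotypes(
        genotypes, em, space, threshold=cfg.posterior_threshold, config=star_config
    )
    summary = summarize_cohort(calls, star_config)
    allele_freqs = allele_freqs_from_diplotypes(summary.diplotype_counts)
    hwe = _hwe_per_locus(genotypes, star_config)

    calls_lines = ["sample_id\tdiplotype\tposterior\tincluded"]
    for c in calls:
        calls_lines.append(
            f"{c.sample_id}\t{'/'.join(c.diplotype)}\t{c.posterior:.6f}\t{int(c.included)}"
        )
    (out / "calls.tsv").write_text("\n".join(calls_lines) + "\n")
    (out / "haplotype_frequencies.json").write_text(
        json.dumps(
            {
                "frequencies": em.as_dict(),
                "converged": em.converged,
                "n_iter": em.n_iter,
                "loglik": em.loglik_trace[-1],
            },
            indent=2,
        )
    )
    (out / "cohort_summary.json").write_text(json.dumps(summary.as_json_dict(), indent=2))
    (out / "statistics.json").write_text(
        json.dumps(
            {"allele_frequencies": allele_freqs, "hwe": hwe, "alpha": cfg.alpha},
            indent=2,
        )
    )

    bundle = {
        "em": em,
        "calls": calls,
        "summary": summary,
        "allele_frequencies": allele_freqs,
        "hwe": hwe,
    }

    if cfg.risk_q is not None and cfg.risk_effect is not None:
        params = RiskModelParams(q=cfg.risk_q, effect=cfg.risk_effect, mode=cfg.risk_mode)
        result = nng(summary.high_risk_fraction, params)
        nng_report = {
            "f": result.f,
            "q0": result.q0,
            "q1": result.q1,
            "risk_difference": result.risk_difference,
            "nnt": result.nnt,
            "nng": result.nng,
            "nng_rounded": result.nng_rounded,
        }
        if cfg.cost_per_sample:
            nng_report["total_cost"] = result.nng * cfg.cost_per_sample
        (out / "nng.json").write_text(json.dumps(nng_report, indent=2))
        bundle["nng"] = result

    manifest = {
        "package": "cyp2c9pgx",
        "version": __version__,
        "config": cfg.as_dict(),
        "n_samples": len(genotypes),
        "n_included": sum(c.included for c in calls),
        "posterior_threshold": cfg.posterior_threshold,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    print(
        f"[cyp2c9pgx] phased {len(genotypes)} samples, "
        f"{manifest['n_included']} included at posterior >= {cfg.posterior_threshold}",
        file=sys.stderr,
    )
    bundle["manifest"] = manifest
    return bundle


def published_quantities(star_config: StarConfig | None = None) -> dict:
    """Recompute every published-table quantity from the packaged fixtures.

    Allele frequencies and high-risk / CPIC-bucket proportions come from
    the reconstructed integer counts; the NNG predictions come from the
    risk model calibrated on the published anchor cohorts.
    """
    if star_config is None:
        star_config = load_star_config()
    fixtures = table1_fixtures()
    values = {}

    freqs = {
        g: allele_freqs_from_diplotypes(fixtures[g]["counts"]) for g in fixtures
    }
    values["allele_freq_PUR_*2"] = round(freqs["PUR"]["*2"], 3)
    values["allele_freq_CLM_*3"] = round(freqs["CLM"]["*3"], 3)
    values["allele_freq_PEL_*2"] = round(freqs["PEL"]["*2"], 3)
    values["allele_freq_PEL_*3"] = round(freqs["PEL"]["*3"], 3)

    summaries = {
        g: summarize_cohort(fixtures[g]["counts"], star_config) for g in fixtures
    }
    values["high_risk_pct_PUR"] = round(100 * summaries["PUR"].high_risk_fraction, 1)
    values["high_risk_pct_PEL"] = round(100 * summaries["PEL"].high_risk_fraction, 1)
    for group in ("PUR", "Black", "White"):
        b = summaries[group].bucket_distribution
        values[f"bucket_moderate_{group}"] = round(b["Moderate-usual"], 3)
        values[f"bucket_adjust_{group}"] = round(b["Adjust"], 3)

    params = calibrate(NNG_ANCHORS, mode=MODE_RISK_RATIO)
    for group in ("White", "Black"):
        f = summaries[group].high_risk_fraction
        values[f"nng_{group}"] = nng(f, params).nng_rounded
    values["_risk_params"] = {"q": params.q, "effect": params.effect, "mode": params.mode}
    values["_n"] = {g: fixtures[g]["n"] for g in fixtures}
    return values


def reproduce_published(stream=None) -> bool:
    """Print computed vs published values; True when everything agrees.

    NNG predictions are allowed one individual of slack (root-finding and
    rounding); every other comparison is exact at the printed precision.
    """
    stream = stream or sys.stdout
    computed = published_quantities()
    all_ok = True
    print(f"{'quantity':<28}{'computed':>12}{'published':>12}  status", file=stream)
    for key, expected in PUBLISHED.items():
        got = computed[key]
        if key.startswith("nng_"):
            ok = abs(got - expected) <= 1
        else:
            ok = got == expected
        all_ok &= ok
        print(
            f"{key:<28}{got:>12}{expected:>12}  {'ok' if ok else 'MISMATCH'}",
            file=stream,
        )
    return all_ok
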
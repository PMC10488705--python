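"""Synthetic cohort generator with the structure the analysis assumes.

Cohorts are drawn under Hardy-Weinberg equilibrium: each individual
receives two independent haplotype draws from a star-allele frequency
vector, and unphased dosages are derived from the star-defining loci.
An admixed mode draws per-individual ancestry proportions from a
Dirichlet distribution and mixes population-specific frequency vectors,
reproducing the ancestry-correlated allele-frequency gradients seen in
admixed Latin American cohorts (e.g. *2 tracking European, *8 tracking
African ancestry).

Truth records retain the simulated diplotype (and ancestry proportions,
in admixed mode) so phasing recovery can be scored exactly.  The module
also ships integer-count fixtures reconstructed from the published
per-cohort diplotype frequency tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .star_model import (
    ConfigurationError,
    FrequencyTable,
    GenotypeRecord,
    StarConfig,
    load_star_config,
    reconstruct_counts,
)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_cohort",
    "simulate_admixed",
    "table1_fixtures",
    "frequency_presets",
    "write_genotype_tsv",
    "write_truth_tsv",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Frequencies, cohort size and seed for one simulated cohort.

    ``haplotype_frequencies`` maps star-allele name to frequency for a
    single-population cohort, or population label to such a map in admixed
    mode (together with ``ancestry_concentration`` Dirichlet parameters).
    """

    haplotype_frequencies: Mapping
    n: int
    seed: int
    ancestry_concentration: Optional[Mapping] = None

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError("cohort size n must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    """Simulated ground truth for one individual."""

    sample_id: str
    diplotype: tuple
    ancestry_proportions: Optional[dict] = None


def _check_simplex(freqs: Mapping, context: str) -> None:
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-9 or any(v < 0 for v in freqs.values()):
        raise ConfigurationError(
            f"{context}: haplotype frequencies must be a probability vector "
            f"(sum={total:.6g})"
        )


def _records_from_hap_draws(names, hap_a, hap_b, config: StarConfig):
    """Build genotype and truth records from per-individual allele-name draws."""
    vec = {name: config.defining_vector(name) for name in names}
    genotypes, truths = [], []
    for i, (a, b) in enumerate(zip(hap_a, hap_b)):
        sid = f"S{i + 1:05d}"
        dosage = tuple(x + y for x, y in zip(vec[a], vec[b]))
        genotypes.append(
            GenotypeRecord(sid, dosage, (False,) * config.n_loci)
        )
        pair = tuple(sorted((a, b), key=config.allele_order))
        truths.append(TruthRecord(sample_id=sid, diplotype=pair))
    return genotypes, truths


def simulate_cohort(cfg: SimulationConfig, config: StarConfig | None = None):
    """HWE cohort: two independent haplotype draws per individual.

    Returns (list of GenotypeRecord, list of TruthRecord); byte-identical
    for a fixed seed.
    """
    if config is None:
        config = load_star_config()
    freqs = dict(cfg.haplotype_frequencies)
    _check_simplex(freqs, "simulate_cohort")
    names = list(freqs)
    probs = np.array([freqs[k] for k in names], dtype=float)
    rng = np.random.default_rng(cfg.seed)
    draws = rng.choice(len(names), size=(cfg.n, 2), p=probs)
    hap_a = [names[i] for i in draws[:, 0]]
    hap_b = [names[i] for i in draws[:, 1]]
    return _records_from_hap_draws(names, hap_a, hap_b, config)


def simulate_admixed(cfg: SimulationConfig, config: StarConfig | None = None):
    """Admixed cohort: Dirichlet ancestry per individual, mixed frequencies.

    Each individual's two haplotypes are drawn from the convex combination
    of the ancestral population frequency vectors weighted by that
    individual's ancestry proportions; truth records carry the proportions.
    """
    if config is None:
        config = load_star_config()
    if cfg.ancestry_concentration is None:
        raise ConfigurationError("admixed mode requires ancestry_concentration")
    pops = list(cfg.haplotype_frequencies)
    if len(pops) < 2:
        raise ConfigurationError("admixed mode requires >= 2 ancestral populations")
    if list(cfg.ancestry_concentration) != pops:
        raise ConfigurationError(
            "ancestry_concentration labels must match the population labels"
        )
    allele_names: list = []
    for pop in pops:
        _check_simplex(cfg.haplotype_frequencies[pop], f"population {pop}")
        for name in cfg.haplotype_frequencies[pop]:
            if name not in allele_names:
                allele_names.append(name)
    F = np.array(
        [
            [cfg.haplotype_frequencies[pop].get(name, 0.0) for name in allele_names]
            for pop in pops
        ]
    )
    alpha = np.array([cfg.ancestry_concentration[p] for p in pops], dtype=float)
    rng = np.random.default_rng(cfg.seed)
    ancestries = rng.dirichlet(alpha, size=cfg.n)
    mixed = ancestries @ F  # per-individual haplotype frequency vectors
    hap_a, hap_b = [], []
    for i in range(cfg.n):
        idx = rng.choice(len(allele_names), size=2, p=mixed[i])
        hap_a.append(allele_names[idx[0]])
        hap_b.append(allele_names[idx[1]])
    genotypes, truths = _records_from_hap_draws(allele_names, hap_a, hap_b, config)
    truths = [
        TruthRecord(
            sample_id=t.sample_id,
            diplotype=t.diplotype,
            ancestry_proportions={p: float(a) for p, a in zip(pops, ancestries[i])},
        )
        for i, t in enumerate(truths)
    ]
    return genotypes, truths


def _table1_raw() -> dict:
    raw = resources.files("cyp2c9pgx.data").joinpath("table1.json").read_text()
    return json.loads(raw)


def table1_fixtures() -> dict:
    """Integer diplotype counts reconstructed from the published frequency table.

    Returns {group: {"n": int, "counts": {category: int}, "kind": ...}} for
    the five cohorts (CLM, MXL, PEL, PUR and the census-weighted Brazilian
    total) and the three Brazilian subcohorts (White, Brown, Black).
    """
    data = _table1_raw()
    categories = data["categories"]
    out = {}
    for group, row in data["cohorts"].items():
        ft = FrequencyTable(
            labels=tuple(categories),
            frequencies=tuple(row["frequencies"]),
            n=int(row["n"]),
        )
        counts = reconstruct_counts(ft)
        out[group] = {
            "n": ft.n,
            "counts": dict(zip(categories, (int(c) for c in counts))),
            "kind": row.get("kind", "cohort"),
            "census_weighted": bool(row.get("census_weighted", False)),
        }
    return out


def frequency_presets() -> dict:
    """Star-haplotype frequency presets derived from the published tables.

    Allele frequencies are computed from the reconstructed diplotype counts
    of selected groups, giving realistic low/intermediate/high-variant
    regimes for simulations (PEL-like, PUR-like, White/Black-Brazilian-like).
    The pooled 'var' category is attributed to *5/*8/*11 evenly.
    """
    from .popstats import allele_freqs_from_diplotypes

    fixtures = table1_fixtures()
    presets = {}
    for group in ("PEL", "PUR", "White", "Black"):
        counts = fixtures[group]["counts"]
        freqs = allele_freqs_from_diplotypes(counts)
        var = freqs.pop("var", 0.0)
        for name in ("*5", "*8", "*11"):
            freqs[name] = freqs.get(name, 0.0) + var / 3.0
        total = sum(freqs.values())
        presets[f"{group}-like"] = {k: v / total for k, v in freqs.items()}
    return presets


def write_genotype_tsv(path, genotypes: Sequence[GenotypeRecord], config: StarConfig) -> None:
    """Write genotypes in the TSV dialect the readers consume."""
    lines = ["sample_id\t" + "\t".join(config.rsids)]
    for g in genotypes:
        cells = []
        for locus, d, m in zip(config.loci, g.dosage, g.missing):
            if m:
                cells.append("./.")
            else:
                a = [locus.ref_allele] * (2 - d) + [locus.alt_allele] * d
                cells.append("/".join(a))
        lines.append(g.sample_id + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_tsv(path, truths: Sequence[TruthRecord]) -> None:
    """Write truth records (diplotype and, if present, ancestry proportions)."""
    pops = []
    if truths and truths[0].ancestry_proportions:
        pops = list(truths[0].ancestry_proportions)
    header = ["sample_id", "diplotype"] + [f"ancestry_{p}" for p in pops]
    lines = ["\t".join(header)]
    for t in truths:
        row = [t.sample_id, "/".join(t.diplotype)]
        if pops:
            row += [f"{t.ancestry_proportions[p]:.6f}" for p in pops]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
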
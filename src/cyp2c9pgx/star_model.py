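"""CYP2C9 locus and star-allele model, genotype input, and count reconstruction.

The package works with a five-variant CYP2C9 panel: the no-function allele
*3 (rs1057910) and the decreased-function alleles *2 (rs1799853),
*5 (rs28371686), *8 (rs7900194) and *11 (rs28371685), all on NC_000010.11.
The reference allele *1 is assigned by default, i.e. by the absence of any
of the panel variants on a haplotype.

This module defines the domain types (:class:`VariantLocus`,
:class:`StarAllele`, :class:`GenotypeRecord`, :class:`FrequencyTable`),
reads genotypes from TSV or VCF, translates haplotype bit-vectors to star
alleles, and reconstructs integer diplotype counts from published
frequency tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "GenotypeParseError",
    "DataError",
    "VariantLocus",
    "StarAllele",
    "StarConfig",
    "GenotypeRecord",
    "FrequencyTable",
    "load_star_config",
    "load_genotype_table",
    "load_vcf",
    "assign_star",
    "reconstruct_counts",
]


class ConfigurationError(ValueError):
    """A required configuration element is missing or inconsistent."""


class GenotypeParseError(ValueError):
    """A genotype cell could not be interpreted against the locus alleles."""


class DataError(ValueError):
    """Input data violate a structural contract (duplicates, bad margins...)."""


@dataclass(frozen=True)
class VariantLocus:
    """One biallelic SNP of the panel, 1-based on NC_000010.11."""

    rsid: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    tags_star: str


@dataclass(frozen=True)
class StarAllele:
    """A named CYP2C9 haplotype with its CPIC-style activity value.

    ``activity_value`` is 1.0 for normal function, 0.5 for decreased and
    0.0 for no function.  ``defining_loci`` is empty for the reference *1.
    """

    name: str
    activity_value: float
    function_class: str
    defining_loci: frozenset

    def __post_init__(self):
        if self.activity_value not in (0.0, 0.5, 1.0):
            raise ConfigurationError(
                f"activity value of {self.name} must be 0, 0.5 or 1, "
                f"got {self.activity_value}"
            )


@dataclass(frozen=True)
class StarConfig:
    """The locus panel plus the star-allele table it defines.

    Loci are stored sorted by genomic position; star-allele haplotype
    vectors are per-locus alt indicators in that order.
    """

    loci: tuple
    alleles: tuple
    pooled_label: str = "var"
    pooled_members: tuple = ("*5", "*8", "*11")
    pooled_activity: float = 0.5

    def __post_init__(self):
        positions = [l.position for l in self.loci]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ConfigurationError("locus positions must be strictly increasing")
        tagged = [l.tags_star for l in self.loci]
        if len(set(tagged)) != len(tagged):
            raise ConfigurationError("each locus must tag exactly one star allele")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def rsids(self) -> tuple:
        return tuple(l.rsid for l in self.loci)

    @property
    def allele_names(self) -> tuple:
        return tuple(a.name for a in self.alleles)

    def allele(self, name: str) -> StarAllele:
        for a in self.alleles:
            if a.name == name:
                return a
        raise ConfigurationError(f"unknown star allele {name!r}")

    def activity(self, name: str) -> float:
        """Activity value for a star allele name, including the pooled label."""
        if name == self.pooled_label:
            return self.pooled_activity
        return self.allele(name).activity_value

    def allele_order(self, name: str) -> int:
        """Deterministic sort key: configured order, pooled label last."""
        if name == self.pooled_label:
            return len(self.alleles)
        return self.allele_names.index(name)

    def defining_vector(self, name: str) -> tuple:
        """Per-locus alt-indicator vector of a star allele (all-zero for *1)."""
        allele = self.allele(name)
        return tuple(int(l.rsid in allele.defining_loci) for l in self.loci)

    def canonical_diplotype(self, a: str, b: str) -> str:
        """Unordered star pair rendered in configured allele order, e.g. '*1/*3'."""
        first, second = sorted((a, b), key=self.allele_order)
        return f"{first}/{second}"


def load_star_config(path=None) -> StarConfig:
    """Load the locus/star definitions from JSON (packaged default config)."""
    if path is None:
        raw = resources.files("cyp2c9pgx.data").joinpath("star_config.json").read_text()
    else:
        raw = Path(path).read_text()
    cfg = json.loads(raw)
    chrom = cfg.get("chromosome", "10")
    loci = tuple(
        sorted(
            (
                VariantLocus(
                    rsid=l["rsid"],
                    chromosome=chrom,
                    position=int(l["position"]),
                    ref_allele=l["ref"],
                    alt_allele=l["alt"],
                    tags_star=l["tags_star"],
                )
                for l in cfg["loci"]
            ),
            key=lambda l: l.position,
        )
    )
    tag_of = {l.tags_star: l.rsid for l in loci}
    alleles = []
    for a in cfg["star_alleles"]:
        defining = frozenset([tag_of[a["name"]]]) if a["name"] in tag_of else frozenset()
        alleles.append(
            StarAllele(
                name=a["name"],
                activity_value=float(a["activity"]),
                function_class=a["function"],
                defining_loci=defining,
            )
        )
    pooled = cfg.get("pooled_allele", {})
    return StarConfig(
        loci=loci,
        alleles=tuple(alleles),
        pooled_label=pooled.get("name", "var"),
        pooled_members=tuple(pooled.get("members", ("*5", "*8", "*11"))),
        pooled_activity=float(pooled.get("activity", 0.5)),
    )


@dataclass(frozen=True)
class GenotypeRecord:
    """One individual's unphased alt-allele dosages at the panel loci.

    ``dosage[i]`` counts alt alleles in {0,1,2} at locus i and is only
    meaningful where ``missing[i]`` is False.
    """

    sample_id: str
    dosage: tuple
    missing: tuple

    def __post_init__(self):
        if len(self.dosage) != len(self.missing):
            raise DataError("dosage and missing masks differ in length")
        for d, m in zip(self.dosage, self.missing):
            if not m and d not in (0, 1, 2):
                raise DataError(f"dosage {d} outside {{0,1,2}} for {self.sample_id}")

    @property
    def has_missing(self) -> bool:
        return any(self.missing)

    @property
    def n_het(self) -> int:
        return sum(1 for d, m in zip(self.dosage, self.missing) if not m and d == 1)


def _parse_cell(cell: str, locus: VariantLocus, sample_id: str):
    """Parse an 'X/Y' genotype cell into (dosage, missing)."""
    cell = cell.strip()
    parts = cell.replace("|", "/").split("/")
    if len(parts) != 2:
        raise GenotypeParseError(
            f"sample {sample_id}, locus {locus.rsid}: malformed genotype {cell!r}"
        )
    if "." in parts:
        return 0, True
    dosage = 0
    for allele in parts:
        if allele == locus.alt_allele:
            dosage += 1
        elif allele != locus.ref_allele:
            raise GenotypeParseError(
                f"sample {sample_id}, locus {locus.rsid}: allele {allele!r} "
                f"not in {{{locus.ref_allele}, {locus.alt_allele}, .}}"
            )
    return dosage, False


def load_genotype_table(path, loci: Sequence[VariantLocus], sample_column: str = "sample_id"):
    """Read genotypes from a tab-separated table.

    The header must name ``sample_column`` and one column per locus rsid;
    cells are 'X/Y' allele pairs or './.' for missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [sample_column] + [l.rsid for l in loci]
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise ConfigurationError(f"genotype table lacks required column(s): {absent}")
    records = []
    for _, row in df.iterrows():
        sid = str(row[sample_column])
        dosage, missing = [], []
        for locus in loci:
            d, m = _parse_cell(str(row[locus.rsid]), locus, sid)
            dosage.append(d)
            missing.append(m)
        records.append(GenotypeRecord(sid, tuple(dosage), tuple(missing)))
    return records


_CHROM_ALIASES = {"NC_000010.11": "10"}


def _norm_chrom(c: str) -> str:
    c = c.removeprefix("chr")
    return _CHROM_ALIASES.get(c, c)


def load_vcf(path, loci: Sequence[VariantLocus]):
    """Read genotypes from a VCF; loci matched by position+alleles, then rsid.

    Only GT is consumed; phased genotypes are accepted and treated as
    unphased dosages.  Loci absent from the file are set missing for every
    sample, with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise DataError(f"VCF {path} has no sample columns")

    per_locus = {}  # rsid -> list of (dosage, missing) per sample
    for var in vcf:
        for locus in loci:
            by_coord = (
                _norm_chrom(var.CHROM) == _norm_chrom(locus.chromosome)
                and var.POS == locus.position
                and var.REF == locus.ref_allele
                and locus.alt_allele in var.ALT
            )
            by_id = var.ID == locus.rsid
            if not (by_coord or by_id):
                continue
            if by_id and not by_coord and var.ALT and locus.alt_allele not in var.ALT:
                raise DataError(
                    f"VCF record with ID {locus.rsid} does not carry alt "
                    f"{locus.alt_allele} (found {var.ALT})"
                )
            alt_idx = var.ALT.index(locus.alt_allele) + 1 if locus.alt_allele in var.ALT else None
            calls = []
            for gt in var.genotypes:
                a, b = gt[0], gt[1]
                if a < 0 or b < 0:
                    calls.append((0, True))
                else:
                    d = int(a == alt_idx) + int(b == alt_idx) if alt_idx else 0
                    calls.append((d, False))
            if locus.rsid in per_locus and per_locus[locus.rsid] != calls:
                raise DataError(f"contradictory duplicate VCF records for {locus.rsid}")
            per_locus[locus.rsid] = calls

    for locus in loci:
        if locus.rsid not in per_locus:
            warnings.warn(
                f"locus {locus.rsid} not found in VCF; set missing for all samples",
                stacklevel=2,
            )
            per_locus[locus.rsid] = [(0, True)] * len(samples)

    records = []
    for i, sid in enumerate(samples):
        dosage = tuple(per_locus[l.rsid][i][0] for l in loci)
        missing = tuple(per_locus[l.rsid][i][1] for l in loci)
        records.append(GenotypeRecord(sid, dosage, missing))
    return records


def assign_star(haplotype: Sequence[int], config: StarConfig) -> str:
    """Translate a per-locus alt-indicator vector to a star-allele name.

    All-reference maps to *1 (assigned by default); a single alt maps to
    the star allele tagged by that locus; two or more alts lie outside the
    six-allele space and return "undefined".
    """
    hap = tuple(int(x) for x in haplotype)
    if len(hap) != config.n_loci:
        raise ConfigurationError(
            f"haplotype length {len(hap)} != number of loci {config.n_loci}"
        )
    n_alt = sum(hap)
    if n_alt == 0:
        return "*1"
    if n_alt == 1:
        idx = hap.index(1)
        return config.loci[idx].tags_star
    return "undefined"


@dataclass(frozen=True)
class FrequencyTable:
    """Published category frequencies with the cohort size they came from."""

    labels: tuple
    frequencies: tuple
    n: int

    def __post_init__(self):
        if self.n <= 0:
            raise DataError("cohort size must be a positive integer")
        if len(self.labels) != len(self.frequencies):
            raise DataError("labels and frequencies differ in length")
        freqs = np.asarray(self.frequencies, dtype=float)
        if (freqs < 0).any() or (freqs > 1).any():
            raise DataError("frequencies must lie in [0, 1]")
        k = len(freqs)
        # printed frequencies are rounded; allow up to half a rounding unit per category
        if abs(freqs.sum() - 1.0) > 0.5 * k / self.n + 1e-12:
            raise DataError(
                f"frequencies sum to {freqs.sum():.4f}, outside rounding "
                f"tolerance of 1 for n={self.n}, k={k}"
            )


def reconstruct_counts(ft: FrequencyTable) -> np.ndarray:
    """Recover integer category counts from rounded published frequencies.

    Uses the largest-remainder rule: start from floor(f*n), then hand the
    remaining units to the categories with the largest fractional parts,
    ties broken by category order.  The result sums exactly to n and every
    count is within one unit of f*n.
    """
    raw = np.asarray(ft.frequencies, dtype=float) * ft.n
    counts = np.floor(raw + 1e-9).astype(int)
    deficit = ft.n - int(counts.sum())
    k = len(raw)
    if deficit < 0 or deficit > k:
        raise DataError(
            f"cannot reconcile frequencies with n={ft.n}: residual of {deficit} counts"
        )
    remainders = raw - counts
    order = sorted(range(k), key=lambda i: (-remainders[i], i))
    for i in order[:deficit]:
        counts[i] += 1
    if np.abs(counts - raw).max() > 1 + 1e-9:
        raise DataError("reconstructed counts drift more than one unit from f*n")
    return counts
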
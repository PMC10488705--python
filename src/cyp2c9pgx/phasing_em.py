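"""Haplotype-frequency EM and star-allele diplotype calling.

Unphased multi-locus genotypes are phased statistically: haplotype
frequencies are estimated by the classic multinomial EM (the
Excoffier–Slatkin gene-counting algorithm) and each individual is then
assigned the maximum-posterior diplotype, with a posterior-probability
threshold (default 0.95) deciding inclusion in downstream analyses.

Two haplotype spaces are supported: the star-restricted space containing
exactly the six star-defining haplotypes (the default — observed diplotype
tables contain only star pairs), and full enumeration of all 2^L vectors
for sensitivity analysis.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .star_model import DataError, GenotypeRecord, StarConfig, assign_star

__all__ = [
    "EstimationError",
    "HaplotypeSpace",
    "EMResult",
    "DiplotypeCall",
    "enumerate_diplotypes",
    "em_fit",
    "diplotype_posterior",
    "call_diplotypes",
]

DEFAULT_POSTERIOR_THRESHOLD = 0.95
_FREQ_CLAMP = 1e-12  # frequencies below this are numerical dust


class EstimationError(RuntimeError):
    """No usable individuals, or the likelihood cannot be evaluated."""


@dataclass(frozen=True)
class HaplotypeSpace:
    """The set of candidate haplotypes the EM distributes mass over."""

    haplotypes: tuple  # tuple of per-locus alt-indicator tuples
    labels: tuple  # star names, or bit-strings for undefined haplotypes
    mode: str  # "star-restricted" | "full-enumeration"

    def __post_init__(self):
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise DataError("duplicate haplotype vectors in space")

    def __len__(self) -> int:
        return len(self.haplotypes)

    @classmethod
    def star_restricted(cls, config: StarConfig) -> "HaplotypeSpace":
        haps = tuple(config.defining_vector(name) for name in config.allele_names)
        return cls(haplotypes=haps, labels=config.allele_names, mode="star-restricted")

    @classmethod
    def full_enumeration(cls, config: StarConfig) -> "HaplotypeSpace":
        haps, labels = [], []
        for bits in product((0, 1), repeat=config.n_loci):
            haps.append(bits)
            star = assign_star(bits, config)
            if star == "undefined":
                carried = "+".join(
                    l.tags_star for l, b in zip(config.loci, bits) if b
                )
                star = f"[{carried}]"
            labels.append(star)
        return cls(haplotypes=tuple(haps), labels=tuple(labels), mode="full-enumeration")


@dataclass
class EMResult:
    """Fitted haplotype frequencies with the log-likelihood trace."""

    frequencies: np.ndarray
    labels: tuple
    loglik_trace: list
    converged: bool
    n_iter: int

    def as_dict(self) -> dict:
        return {lab: float(f) for lab, f in zip(self.labels, self.frequencies)}


@dataclass(frozen=True)
class DiplotypeCall:
    """Maximum-posterior diplotype for one individual."""

    sample_id: str
    diplotype: tuple  # unordered star pair, stored in configured order
    posterior: float
    included: bool


def enumerate_diplotypes(g: GenotypeRecord, space: HaplotypeSpace):
    """Index pairs (i <= j) of space haplotypes whose sum matches g's dosages.

    Requires a fully typed record (no missing loci).
    """
    if g.has_missing:
        raise DataError(f"sample {g.sample_id} has missing loci; cannot enumerate phases")
    pairs = []
    H = space.haplotypes
    for i in range(len(H)):
        for j in range(i, len(H)):
            if all(a + b == d for a, b, d in zip(H[i], H[j], g.dosage)):
                pairs.append((i, j))
    return pairs


def _compatible_patterns(genotypes, space):
    """Group usable records by dosage pattern; returns (patterns, weights, skipped).

    patterns: list of (pair list, multiplicity); skipped: sample ids dropped
    because of missing loci or incompatibility with the space.
    """
    by_dosage = {}
    skipped_missing, skipped_incompatible = [], []
    for g in genotypes:
        if g.has_missing:
            skipped_missing.append(g.sample_id)
            continue
        by_dosage.setdefault(g.dosage, []).append(g.sample_id)
    patterns = []
    for dosage, sids in by_dosage.items():
        probe = GenotypeRecord(sids[0], dosage, (False,) * len(dosage))
        pairs = enumerate_diplotypes(probe, space)
        if not pairs:
            skipped_incompatible.extend(sids)
            continue
        patterns.append((pairs, len(sids)))
    if skipped_missing:
        warnings.warn(
            f"{len(skipped_missing)} individual(s) with missing loci excluded from phasing",
            stacklevel=3,
        )
    if skipped_incompatible:
        warnings.warn(
            f"{len(skipped_incompatible)} individual(s) incompatible with the haplotype "
            "space excluded from the likelihood",
            stacklevel=3,
        )
    return patterns, skipped_missing, skipped_incompatible


def _init_frequencies(genotypes, space: HaplotypeSpace, init: str) -> np.ndarray:
    """Starting point: per-locus allele-frequency product projected on the space."""
    K = len(space)
    if init == "uniform":
        return np.full(K, 1.0 / K)
    if init != "allele-freq":
        raise ValueError(f"unknown init {init!r}")
    usable = [g for g in genotypes if not g.has_missing]
    if not usable:
        return np.full(K, 1.0 / K)
    L = len(space.haplotypes[0])
    p_alt = np.array(
        [sum(g.dosage[l] for g in usable) / (2.0 * len(usable)) for l in range(L)]
    )
    f = np.array(
        [
            np.prod([p_alt[l] if h[l] else 1.0 - p_alt[l] for l in range(L)])
            for h in space.haplotypes
        ]
    )
    total = f.sum()
    if total <= 0:
        return np.full(K, 1.0 / K)
    return f / total


def _loglik_and_expected(freqs, patterns, K):
    """One E-step: observed-data log-likelihood and expected haplotype counts."""
    loglik = 0.0
    counts = np.zeros(K)
    for pairs, mult in patterns:
        w = np.array(
            [(2.0 if i != j else 1.0) * freqs[i] * freqs[j] for i, j in pairs]
        )
        total = w.sum()
        if total <= 0:
            raise EstimationError("zero likelihood mass for a compatible genotype")
        loglik += mult * np.log(total)
        w /= total
        for (i, j), wij in zip(pairs, w):
            counts[i] += mult * wij
            counts[j] += mult * wij
    return loglik, counts


def em_fit(
    genotypes: Sequence[GenotypeRecord],
    space: HaplotypeSpace,
    init: str = "allele-freq",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> EMResult:
    """Estimate haplotype frequencies by EM on unphased genotypes.

    E-step: each compatible haplotype pair (h_i, h_j) of an individual gets
    weight 2^[i!=j] * f_i * f_j, normalised within the individual.  M-step:
    frequencies become expected haplotype counts over 2N.  Convergence is
    declared when the log-likelihood changes by less than ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    patterns, _, _ = _compatible_patterns(genotypes, space)
    if not patterns:
        raise EstimationError("no phasable individuals compatible with the haplotype space")
    n_used = sum(mult for _, mult in patterns)
    K = len(space)
    freqs = _init_frequencies(genotypes, space, init)

    trace = []
    converged = False
    n_iter = 0
    prev = -np.inf
    for n_iter in range(1, max_iter + 1):
        loglik, counts = _loglik_and_expected(freqs, patterns, K)
        trace.append(loglik)
        new = counts / (2.0 * n_used)
        new[new < _FREQ_CLAMP] = 0.0
        new /= new.sum()
        freqs = new
        if abs(loglik - prev) < tol:
            converged = True
            break
        prev = loglik
    return EMResult(
        frequencies=freqs,
        labels=space.labels,
        loglik_trace=trace,
        converged=converged,
        n_iter=n_iter,
    )


def _label_key(label: str):
    """Deterministic ordering of haplotype labels: *1 < *2 < ... < *11 < rest."""
    m = re.fullmatch(r"\*(\d+)", label)
    if m:
        return (0, int(m.group(1)), label)
    return (1, 0, label)


def diplotype_posterior(g: GenotypeRecord, freqs, space: HaplotypeSpace) -> dict:
    """Posterior over the compatible diplotypes of one individual.

    P(h_i, h_j | g) is proportional to (2 if i != j else 1) * f_i * f_j,
    normalised over the compatible set; the returned map is keyed by
    (label_i, label_j) pairs and sums to 1.
    """
    freqs = np.asarray(freqs, dtype=float)
    pairs = enumerate_diplotypes(g, space)
    if not pairs:
        raise DataError(f"sample {g.sample_id}: genotype incompatible with haplotype space")
    w = np.array([(2.0 if i != j else 1.0) * freqs[i] * freqs[j] for i, j in pairs])
    total = w.sum()
    if total <= 0:
        raise EstimationError(
            f"sample {g.sample_id}: all compatible haplotypes have zero frequency"
        )
    w /= total
    return {
        tuple(sorted((space.labels[i], space.labels[j]), key=_label_key)): float(p)
        for (i, j), p in zip(pairs, w)
    }


def call_diplotypes(
    genotypes: Sequence[GenotypeRecord],
    em: EMResult,
    space: HaplotypeSpace,
    threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
    config: StarConfig | None = None,
):
    """Maximum-posterior diplotype per individual, thresholded for inclusion.

    ``included`` is True when the posterior is at or above ``threshold``
    (inclusive at the boundary).  Individuals with missing loci are skipped
    with a warning; ties are broken by configured star-allele order.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0.5, 1]")

    calls = []
    skipped = []
    for g in genotypes:
        if g.has_missing:
            skipped.append(g.sample_id)
            continue
        post = diplotype_posterior(g, em.frequencies, space)
        p = max(post.values())
        tied = [k for k, v in post.items() if v >= p - 1e-15]
        pair = min(tied, key=lambda pr: tuple(_label_key(x) for x in pr))
        calls.append(
            DiplotypeCall(
                sample_id=g.sample_id,
                diplotype=pair,
                posterior=p,
                included=bool(p >= threshold - 1e-12),
            )
        )
    if skipped:
        warnings.warn(
            f"{len(skipped)} individual(s) with missing loci skipped in diplotype calling",
            stacklevel=2,
        )
    return calls
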
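"""EM haplotype-frequency estimation and diplotype calling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from cyp2c9pgx.phasing_em import (
    EMResult,
    HaplotypeSpace,
    call_diplotypes,
    diplotype_posterior,
    em_fit,
    enumerate_diplotypes,
)
from cyp2c9pgx.star_model import GenotypeRecord
from cyp2c9pgx.synthetic_data import SimulationConfig, simulate_cohort


def record(dosage, sid="S1"):
    return GenotypeRecord(sid, tuple(dosage), (False,) * len(dosage))


def two_locus_full_space():
    haps = ((0, 0), (1, 0), (0, 1), (1, 1))
    return HaplotypeSpace(haplotypes=haps, labels=("*1", "*2", "*3", "[*2+*3]"),
                          mode="full-enumeration")


class TestEnumerate:
    def test_reference_genotype_unique_pair(self, star_space):
        pairs = enumerate_diplotypes(record((0, 0, 0, 0, 0)), star_space)
        assert pairs == [(0, 0)]  # (*1, *1)

    def test_single_het_has_unique_phase(self, star_space, star_config):
        i3 = star_config.rsids.index("rs1057910")
        dosage = tuple(int(k == i3) for k in range(5))
        pairs = enumerate_diplotypes(record(dosage), star_space)
        labels = {tuple(sorted((star_space.labels[i], star_space.labels[j])))
                  for i, j in pairs}
        assert labels == {("*1", "*3")}

    def test_double_het_star_vs_full(self, star_space, full_space, star_config):
        """Exhaustive phase enumeration: star space is unambiguous, full is not."""
        dosage = tuple(
            int(r in ("rs1799853", "rs1057910")) for r in star_config.rsids
        )
        star_pairs = enumerate_diplotypes(record(dosage), star_space)
        star_labels = {frozenset((star_space.labels[i], star_space.labels[j]))
                       for i, j in star_pairs}
        assert star_labels == {frozenset(("*2", "*3"))}

        full_pairs = enumerate_diplotypes(record(dosage), full_space)
        full_labels = {frozenset((full_space.labels[i], full_space.labels[j]))
                       for i, j in full_pairs}
        assert full_labels == {frozenset(("*2", "*3")), frozenset(("*1", "[*2+*3]"))}
        # oracle: brute force over all ordered haplotype pairs
        brute = set()
        for h1 in full_space.haplotypes:
            for h2 in full_space.haplotypes:
                if tuple(a + b for a, b in zip(h1, h2)) == dosage:
                    i, j = full_space.haplotypes.index(h1), full_space.haplotypes.index(h2)
                    brute.add((min(i, j), max(i, j)))
        assert set(full_pairs) == brute


class TestEmFit:
    def test_monomorphic_cohort(self, star_space):
        genotypes = [record((0, 0, 0, 0, 0), f"S{i}") for i in range(100)]
        res = em_fit(genotypes, star_space)
        assert res.converged
        assert res.frequencies[0] == pytest.approx(1.0)
        assert res.n_iter <= 2

    def test_single_locus_closed_form(self, star_space, star_config):
        """With one segregating locus the MLE is the allele frequency."""
        i2 = star_config.rsids.index("rs1799853")
        genotypes = []
        for k, d in enumerate([0] * 60 + [1] * 30 + [2] * 10):
            dosage = tuple(d if i == i2 else 0 for i in range(5))
            genotypes.append(record(dosage, f"S{k}"))
        res = em_fit(genotypes, star_space)
        f = res.as_dict()
        assert f["*2"] == pytest.approx(50 / 200, abs=1e-9)
        assert f["*1"] == pytest.approx(150 / 200, abs=1e-9)

    def test_matches_brute_force_maximizer(self):
        """EM equals an independent likelihood maximizer on a small instance."""
        space = two_locus_full_space()
        genotypes = [record(d, f"S{i}") for i, d in enumerate(
            [(1, 1), (1, 1), (1, 0), (0, 1), (0, 0), (1, 1)]
        )]
        res = em_fit(genotypes, space, tol=1e-12, max_iter=5000)

        patterns = [(enumerate_diplotypes(g, space), 1) for g in genotypes]

        def negloglik(f):
            ll = 0.0
            for pairs, mult in patterns:
                mass = sum((2.0 if i != j else 1.0) * f[i] * f[j] for i, j in pairs)
                ll += mult * np.log(max(mass, 1e-300))
            return -ll

        # coarse exhaustive simplex grid, then a constrained polish
        step = 0.02
        best, best_ll = None, np.inf
        grid = np.arange(0, 1 + step / 2, step)
        for f1, f2, f3 in itertools.product(grid, grid, grid):
            f0 = 1.0 - f1 - f2 - f3
            if f0 < -1e-12:
                continue
            v = negloglik(np.array([max(f0, 0), f1, f2, f3]))
            if v < best_ll:
                best, best_ll = np.array([max(f0, 0), f1, f2, f3]), v
        polish = minimize(
            negloglik,
            best,
            method="SLSQP",
            bounds=[(0, 1)] * 4,
            constraints=[{"type": "eq", "fun": lambda f: f.sum() - 1}],
            options={"ftol": 1e-14, "maxiter": 500},
        )
        assert np.abs(res.frequencies - polish.x).max() < 1e-3
        assert res.loglik_trace[-1] >= -polish.fun - 1e-6

    def test_loglik_trace_non_decreasing_on_fixed_cohort(self, star_space, star_config):
        cfg = SimulationConfig(
            haplotype_frequencies={"*1": 0.6, "*2": 0.2, "*3": 0.1, "*5": 0.1},
            n=200, seed=11,
        )
        genotypes, _ = simulate_cohort(cfg, star_config)
        res = em_fit(genotypes, star_space)
        diffs = np.diff(res.loglik_trace)
        assert (diffs >= -1e-10).all()
        assert res.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    @given(
        st.lists(
            st.tuples(*[st.integers(0, 2)] * 3),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=40)
    def test_em_monotone_and_normalized_on_random_inputs(self, dosages):
        """EM ascent property on arbitrary 3-locus cohorts in the full space."""
        haps = tuple(itertools.product((0, 1), repeat=3))
        space = HaplotypeSpace(
            haplotypes=haps,
            labels=tuple("h" + "".join(map(str, h)) for h in haps),
            mode="full-enumeration",
        )
        genotypes = [record(d, f"S{i}") for i, d in enumerate(dosages)]
        res = em_fit(genotypes, space)
        assert (np.diff(res.loglik_trace) >= -1e-10).all()
        assert res.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
        assert (res.frequencies >= 0).all()


class TestPosteriorAndCalls:
    def test_unambiguous_genotype_posterior_one(self, star_space):
        freqs = np.array([0.9, 0.05, 0.05, 0.0, 0.0, 0.0])
        post = diplotype_posterior(record((0, 0, 0, 0, 0)), freqs, star_space)
        assert post == {("*1", "*1"): 1.0}

    def test_double_het_hand_computed_posterior(self, full_space, star_config):
        """2*f2*f3 / (2*f2*f3 + 2*f1*f23) with the stated frequencies."""
        labels = list(full_space.labels)
        freqs = np.zeros(len(labels))
        freqs[labels.index("*1")] = 0.84
        freqs[labels.index("*2")] = 0.1
        freqs[labels.index("*3")] = 0.05
        freqs[labels.index("[*2+*3]")] = 0.01
        dosage = tuple(int(r in ("rs1799853", "rs1057910")) for r in star_config.rsids)
        post = diplotype_posterior(record(dosage), freqs, full_space)
        assert sum(post.values()) == pytest.approx(1.0)
        p23 = post[("*2", "*3")]
        assert p23 == pytest.approx(0.01 / (0.01 + 0.0168), abs=1e-4)
        assert p23 == pytest.approx(0.3731, abs=1e-4)

    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    def test_posterior_normalizes_for_any_frequencies(self, raw):
        space = two_locus_full_space()
        freqs = np.array(raw) / np.sum(raw)
        post = diplotype_posterior(record((1, 1)), freqs, space)
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)

    def test_inclusion_threshold_boundary(self, star_config):
        """0.95 posterior is included (inclusive rule), 0.90 is not."""
        space = two_locus_full_space()

        def freqs_for(target):
            # symmetric frequencies (x, y, y, x): posterior of (*2,*3) is
            # y^2 / (y^2 + x^2) = target when y = x * sqrt(target/(1-target))
            r = np.sqrt(target / (1 - target))
            x = 1.0 / (2 * (1 + r))
            return np.array([x, r * x, r * x, x])

        for target, expect_included in ((0.95, True), (0.90, False)):
            f = freqs_for(target)
            em = EMResult(frequencies=f / f.sum(), labels=space.labels,
                          loglik_trace=[0.0], converged=True, n_iter=1)
            calls = call_diplotypes([record((1, 1))], em, space, threshold=0.95)
            assert len(calls) == 1
            assert calls[0].posterior == pytest.approx(target, abs=1e-9)
            assert calls[0].included is expect_included
            assert calls[0].diplotype == ("*2", "*3")

    def test_missing_records_skipped_with_warning(self, star_space):
        g_ok = record((0, 0, 0, 0, 0), "A")
        g_miss = GenotypeRecord("B", (0, 0, 0, 0, 0), (False, False, True, False, False))
        em = em_fit([g_ok], star_space)
        with pytest.warns(UserWarning, match="missing"):
            calls = call_diplotypes([g_ok, g_miss], em, star_space)
        assert [c.sample_id for c in calls] == ["A"]


class TestRecovery:
    def test_phasing_recovery_on_synthetic_cohort(self, star_space, star_config):
        """>=99% of included calls match simulated truth at realistic frequencies."""
        cfg = SimulationConfig(
            haplotype_frequencies={"*1": 0.80, "*2": 0.12, "*3": 0.05,
                                   "*5": 0.01, "*8": 0.01, "*11": 0.01},
            n=500, seed=42,
        )
        genotypes, truths = simulate_cohort(cfg, star_config)
        res = em_fit(genotypes, star_space)
        calls = call_diplotypes(genotypes, res, star_space, config=star_config)
        truth_by_id = {t.sample_id: t.diplotype for t in truths}
        included = [c for c in calls if c.included]
        assert len(included) >= 0.95 * len(calls)
        agree = sum(c.diplotype == truth_by_id[c.sample_id] for c in included)
        assert agree / len(included) >= 0.99
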
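"""Correlation integral and coarse-grained correlation dimension."""

import dataclasses

import numpy as np
import pytest

from egmfrac import (
    EmbeddingConfig,
    cgcd_record,
    cgcd_segment,
    compute_rcg,
    correlation_integral,
    reconstruct,
    select_reference_vectors,
    sweep_m,
)
from egmfrac.errors import DegenerateSignalError, LengthError, ParameterError
from egmfrac.synthgen import SynthParams, gen_dataset, gen_type1, gen_type3


def brute_force_correlation_integral(refs, r):
    """Independent O(n^2) double-loop pair count with strict inequality."""
    n = len(refs)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.sqrt(np.sum((refs[i] - refs[j]) ** 2)) < r:
                count += 1
    return 2.0 * count / (n * (n - 1))


class TestCorrelationIntegral:
    def test_identical_vectors(self):
        refs = np.zeros((5, 3))
        assert correlation_integral(refs, 1e-9) == 1.0

    def test_distant_collinear_points(self):
        refs = np.array([[0.0], [10.0], [20.0]])
        assert correlation_integral(refs, 1.0) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(5, 60)
            dim = rng.integers(1, 5)
            refs = rng.random((n, dim))
            r = rng.uniform(0.05, 1.5)
            assert correlation_integral(refs, r) == brute_force_correlation_integral(
                refs, r
            )

    def test_strict_inequality_at_tie(self):
        refs = np.array([[0.0], [1.0]])
        assert correlation_integral(refs, 1.0) == 0.0  # Theta(0) = 0
        assert correlation_integral(refs, 1.0 + 1e-12) == 1.0

    def test_monotone_in_r(self, rng):
        refs = rng.standard_normal((40, 3))
        rs = np.linspace(0.05, 6.0, 30)
        cs = [correlation_integral(refs, r) for r in rs]
        assert all(b >= a for a, b in zip(cs, cs[1:]))
        assert cs[-1] == 1.0  # r beyond the max pairwise distance

    def test_invalid_r(self, rng):
        with pytest.raises(ParameterError):
            correlation_integral(rng.random((5, 2)), 0.0)


class TestSelectReferenceVectors:
    def test_first_mode_takes_prefix(self, rng):
        p = reconstruct(rng.standard_normal(1000), 4, 8)
        refs = select_reference_vectors(p, 334)
        np.testing.assert_array_equal(refs, p.vectors[:334])

    def test_identity_when_nref_equals_count(self, rng):
        p = reconstruct(rng.standard_normal(100), 2, 1)
        np.testing.assert_array_equal(
            select_reference_vectors(p, p.n_vectors), p.vectors
        )

    def test_too_many_requested(self, rng):
        p = reconstruct(rng.standard_normal(1000), 4, 8)  # 976 vectors
        with pytest.raises(LengthError):
            select_reference_vectors(p, 977)

    def test_random_mode_seeded(self, rng):
        p = reconstruct(rng.standard_normal(500), 2, 2)
        a = select_reference_vectors(p, 100, mode="random", seed=3)
        b = select_reference_vectors(p, 100, mode="random", seed=3)
        np.testing.assert_array_equal(a, b)


class TestComputeRcg:
    def test_sine_closed_form_and_amplitude_invariance(self):
        t = np.arange(1000)
        x = np.sin(2 * np.pi * t / 40.0)  # 25 whole periods, peaks sampled
        expected = 0.5 / (2 * np.sqrt(2))  # (A/sqrt 2) / (2A) / 2
        assert abs(compute_rcg(x) - expected) < 1e-3
        assert abs(compute_rcg(123.4 * x) - compute_rcg(x)) < 1e-12

    def test_uniform_noise_closed_form(self, rng):
        x = rng.uniform(0.0, 1.0, 200_000)
        # sd -> 1/sqrt(12), ptp -> 1:  r_cg -> 0.5/sqrt(12)
        assert abs(compute_rcg(x) - 0.5 / np.sqrt(12)) < 2e-3

    def test_constant_segment(self):
        with pytest.raises(DegenerateSignalError):
            compute_rcg(np.ones(100))


class TestCgcdSegment:
    def test_uniform_line_has_dimension_near_one(self):
        """334 equally spaced points embedded at m=1: the local log-log
        slope of C(r) at r_cg for a uniform 1-D set is d ln(2r - r^2)/d ln r
        evaluated near r_cg ~ 0.14, i.e. ~0.92 — within 0.15 of 1."""
        cfg = EmbeddingConfig(m=1, tau_samples=1, nref=334)
        res = cgcd_segment(np.linspace(0.0, 1.0, 334), cfg)
        assert res.cgcd is not None
        assert abs(res.cgcd - 1.0) <= 0.15

    def test_plateau_gives_zero(self):
        """Two tight clusters: C(r) is flat between the within-cluster and
        between-cluster distance scales, so the slope at r_cg is zero."""
        cfg = EmbeddingConfig(m=1, tau_samples=1, nref=334)
        x = np.r_[np.zeros(167), np.ones(167)]
        res = cgcd_segment(x, cfg)
        assert res.cgcd == 0.0

    def test_constant_segment_degenerate(self):
        cfg = EmbeddingConfig(m=1, tau_samples=1, nref=334)
        with pytest.raises(DegenerateSignalError):
            cgcd_segment(np.ones(400), cfg)

    def test_too_short_segment(self):
        with pytest.raises(LengthError):
            cgcd_segment(np.random.default_rng(0).standard_normal(300))

    def test_amplitude_invariance(self, rng):
        x = rng.standard_normal(1000)
        a = cgcd_segment(x)
        b = cgcd_segment(1000.0 * x)
        assert a.cgcd == pytest.approx(b.cgcd, rel=1e-9)
        assert a.r_cg == pytest.approx(b.r_cg, rel=1e-9)

    def test_repeated_vector_degenerate_limit(self):
        """A two-valued segment whose portrait collapses to near-identical
        vectors: C = 1 at both slope points, CGCD = 0."""
        cfg = EmbeddingConfig(m=2, tau_samples=1, nref=300)
        x = np.r_[1.0, np.zeros(400)]
        x[0] = 1.0  # single spike fixes ptp; baseline identical
        res = cgcd_segment(x, cfg)
        assert res.cgcd == 0.0


class TestCgcdRecord:
    def test_median_over_ten_epochs(self, default_params):
        out = cgcd_record(gen_type1(default_params))
        assert len(out.per_segment) == 10
        vals = sorted(out.defined_values)
        expected = np.median(vals)
        assert out.median_cgcd == pytest.approx(expected)
        assert out.n_undefined == 0

    def test_fractionation_ordering_type3_above_type1(self, default_params):
        m1 = cgcd_record(gen_type1(default_params)).median_cgcd
        m3 = cgcd_record(gen_type3(default_params)).median_cgcd
        assert m3 > m1

    def test_record_shorter_than_one_window(self):
        from egmfrac import EGMRecord

        with pytest.raises(LengthError):
            cgcd_record(EGMRecord(np.random.default_rng(0).standard_normal(500), 1000.0))


class TestSweepM:
    def test_single_m_table(self):
        recs = gen_dataset([("I", 2), ("III", 2)], seed=2)
        table = sweep_m(recs, [r.label for r in recs], m_range=[4])
        assert len(table) == 1
        assert table.iloc[0]["m"] == 4
        assert table.iloc[0]["recommended"]
        assert table.iloc[0]["n_undefined"] == 0
        assert table.iloc[0]["median_I"] < table.iloc[0]["median_III"]

    def test_requires_two_classes(self):
        recs = gen_dataset([("I", 3)], seed=2)
        with pytest.raises(ParameterError):
            sweep_m(recs, [r.label for r in recs], m_range=[4])

    def test_separation_scored_across_m(self):
        recs = gen_dataset([("I", 3), ("II", 3), ("III", 3)], seed=5)
        table = sweep_m(recs, [r.label for r in recs], m_range=[2, 4, 6])
        assert table["recommended"].sum() == 1
        assert (table["separation_score"] > 0).all()
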
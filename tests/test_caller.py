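import math
from decimal import Decimal, getcontext
from fractions import Fraction

import numpy as np
import pytest

from editcall import (
    CallerConfig,
    bh_adjust,
    build_spectrum,
    call_candidates,
    editing_fraction,
    fisher_site_test,
    fisher_site_test_log10,
    make_reference,
    pileup_alignments,
    plant_sites,
    simulate_reads,
)
from editcall.io import SnpTable

from conftest import make_site

getcontext().prec = 60


# --- independent oracle: exact-rational hypergeometric enumeration ---------


def fisher_enumeration(site_ref, site_alt, bg_ref, bg_alt):
    """Two-sided exact p as a Fraction, enumerating all tables with the
    observed margins and summing probabilities not exceeding the observed
    one (with the conventional 1+1e-7 relative tie tolerance)."""
    n = site_ref + site_alt
    M = n + bg_ref + bg_alt
    K = site_alt + bg_alt
    denom = math.comb(M, n)
    pmf = {
        k: Fraction(math.comb(K, k) * math.comb(M - K, n - k), denom)
        for k in range(max(0, n - (M - K)), min(n, K) + 1)
    }
    obs = pmf[site_alt]
    cutoff = obs * Fraction(10_000_001, 10_000_000)
    return sum(p for p in pmf.values() if p <= cutoff)


def log10_fraction(f: Fraction) -> float:
    return float(
        (Decimal(f.numerator).ln() - Decimal(f.denominator).ln()) / Decimal(10).ln()
    )


class TestEditingFraction:
    @pytest.mark.parametrize(
        "ref, alt, counts, expected",
        [
            ("T", "C", [0, 79, 0, 117], 79 / 196),  # 40.31%
            ("A", "G", [0, 0, 15, 0], 1.0),  # fully edited
            ("A", "G", [10, 0, 0, 0], 0.0),  # no alternate bases
            ("A", "G", [0, 0, 0, 0], 0.0),  # empty denominator
        ],
    )
    def test_alt_over_ref_plus_alt(self, ref, alt, counts, expected):
        assert editing_fraction(make_site(ref, counts), ref, alt) == pytest.approx(
            expected
        )

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            editing_fraction(make_site("A", [1, 0, 0, 0]), "A", "A")


class TestFisher:
    def test_modal_table_gives_one(self):
        assert fisher_site_test(1, 1, 1, 1) == 1.0

    def test_degenerate_column_gives_one(self):
        assert fisher_site_test(10, 0, 1000, 0) == 1.0

    def test_extreme_table_matches_enumeration_in_log_space(self):
        """A strongly edited site against a large clean background: the
        p-value is far below double precision, so compare log10 values
        against the exact-rational oracle."""
        exact = fisher_enumeration(96, 167, 100000, 30)
        expected_log10 = log10_fraction(exact)
        got = fisher_site_test_log10(96, 167, 100000, 30)
        assert got == pytest.approx(expected_log10, rel=1e-12)
        assert got < -50  # p < 1e-50
        assert 0 < fisher_site_test(96, 167, 100000, 30) < 1e-50

    def test_matches_enumeration_on_sampled_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            total = int(rng.integers(4, 201))
            cuts = np.sort(rng.integers(0, total + 1, size=3))
            a, b, c, d = (
                int(cuts[0]),
                int(cuts[1] - cuts[0]),
                int(cuts[2] - cuts[1]),
                int(total - cuts[2]),
            )
            if a + b == 0:
                a += 1
            expected = float(fisher_enumeration(a, b, c, d))
            assert fisher_site_test(a, b, c, d) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_scipy_reference(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(7)
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(0, 60, size=4))
            if a + b == 0:
                a = 1
            expected = fisher_exact([[a, b], [c, d]]).pvalue
            assert fisher_site_test(a, b, c, d) == pytest.approx(expected, rel=1e-9)

    def test_one_sided_enrichment_monotone_in_alt_count(self):
        # fixed margins: moving a count from ref to alt only sharpens the tail
        previous = 1.1
        for alt in range(0, 21, 4):
            p = fisher_site_test(20 - alt, alt, 1000, 10, alternative="greater")
            assert p <= previous + 1e-15
            previous = p

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_site_test(0, 0, 10, 10)
        with pytest.raises(ValueError):
            fisher_site_test(-1, 2, 3, 4)


class TestBhAdjust:
    @staticmethod
    def naive_bh(pvals):
        """Direct O(m^2) step-up definition: q_(i) = min_{j>=i} m p_(j)/j."""
        m = len(pvals)
        order = sorted(range(m), key=lambda i: pvals[i])
        out = [0.0] * m
        for rank, i in enumerate(order):
            out[i] = min(
                min(1.0, m * pvals[order[j]] / (j + 1)) for j in range(rank, m)
            )
        return out

    def test_single_p_unchanged(self):
        assert bh_adjust([0.05]).tolist() == [0.05]

    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.1], [0.01, 0.1]),
        ],
    )
    def test_step_up_examples(self, pvals, expected):
        assert bh_adjust(pvals).tolist() == pytest.approx(expected)

    def test_matches_naive_definition_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            m = int(rng.integers(1, 51))
            p = rng.uniform(1e-6, 1.0, size=m)
            got = bh_adjust(p)
            expected = self.naive_bh(list(p))
            assert got.tolist() == pytest.approx(expected, rel=1e-12)
            assert np.all(got >= p)  # adjusted never below raw

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        p = rng.uniform(1e-8, 1.0, size=40)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p).tolist() == pytest.approx(expected.tolist(), rel=1e-12)

    def test_order_preserving_on_sorted_input(self):
        p = np.sort(np.random.default_rng(1).uniform(0.001, 1, size=25))
        q = bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-15)

    def test_out_of_range_p_rejected(self):
        for bad in ([0.0], [1.2], [-0.1]):
            with pytest.raises(ValueError):
                bh_adjust(bad)


class TestCallCandidates:
    def _simulated(self, level, seed=21, coverage=100):
        genome, models = make_reference(seed=seed)
        truth = plant_sites(
            genome, models, n_editing=4, levels=level, n_het_snps=1, n_hom_snps=1,
            seed=seed,
        )
        reads = simulate_reads(truth, mean_coverage=coverage, read_len=50, seed=seed + 1)
        sites = pileup_alignments(reads, genome, min_quality=25)
        self._last_sites = sites
        snps = truth.snp_table()
        spectrum = build_spectrum(sites, snps)
        config = CallerConfig()
        cands = call_candidates(
            sites, spectrum, snps, models, config, genome=genome
        )
        return truth, cands, config

    def test_planted_site_recovered_with_close_editing_fraction(self):
        """Planted 40% sites come back with a close editing fraction.  A
        planted site can legitimately be excluded when a stray sequencing
        error deposits a third base type there (the single-substitution
        filter), so the per-site assertion applies to clean pileups."""
        from editcall import pileup_alignments

        truth, cands, _ = self._simulated(level=0.4)
        called = {(c.chrom, c.position): c for c in cands}
        clean = 0
        for site in truth.editing_sites:
            ref, alt = ("A", "G") if site.strand == "+" else ("T", "C")
            sc = next(
                s for s in self._last_sites
                if (s.chrom, s.position) == (site.chrom, site.position)
            )
            others = [i for i in range(4) if "ACGT"[i] not in (ref, alt)]
            if sc.counts_filtered[others].sum() > 0:
                continue  # excluded by the single-substitution rule
            clean += 1
            c = called[(site.chrom, site.position)]
            assert abs(c.editing_fraction - 0.4) <= 0.10
            assert c.substitution_type == ref + alt
        assert clean >= 3  # the filter only rarely removes a planted site

    def test_low_level_sites_fall_below_editing_threshold(self):
        truth, cands, _ = self._simulated(level=0.05)
        called = {(c.chrom, c.position) for c in cands}
        assert called.isdisjoint(truth.editing_positions())

    def test_snp_positions_are_masked(self):
        truth, cands, _ = self._simulated(level=0.4)
        called = {(c.chrom, c.position) for c in cands}
        assert called.isdisjoint({(s.chrom, s.position) for s in truth.snps})

    def test_empty_site_stream_gives_empty_output(self):
        genome, models = make_reference(seed=1)
        spectrum = build_spectrum([])
        assert call_candidates([], spectrum, None, models, CallerConfig()) == []

    def test_reported_candidates_satisfy_all_filters(self):
        truth, cands, config = self._simulated(level=0.4)
        snp_positions = {(s.chrom, s.position) for s in truth.snps}
        assert cands, "expected at least one candidate"
        for c in cands:
            assert (c.chrom, c.position) not in snp_positions
            assert c.region == "CDS" and c.gene is not None
            ref_i = "ACGT".index(c.ref_base)
            alt_i = "ACGT".index(c.substitution_type[1])
            others = [i for i in range(4) if i not in (ref_i, alt_i)]
            assert c.counts_filtered[others].sum() == 0
            assert c.coverage >= config.min_coverage
            assert c.editing_fraction >= config.min_editing_fraction
            assert c.fdr <= config.fdr_threshold
            assert c.fdr >= c.p_value
        # ranked by ascending p-value
        assert all(
            a.log10_p <= b.log10_p for a, b in zip(cands, cands[1:])
        )

    def test_spectrum_quality_mismatch_rejected(self):
        genome, models = make_reference(seed=1)
        spectrum = build_spectrum([], min_quality=30)
        with pytest.raises(ValueError, match="Q30"):
            call_candidates([], spectrum, None, models, CallerConfig(min_base_quality=25))

    def test_sites_with_wrong_reference_base_never_tested(self):
        genome, models = make_reference(seed=1)
        plus = next(m for m in models if m.strand == "+")
        # a G-reference site inside a plus-strand gene CDS
        site = make_site(
            "G", [0, 0, 50, 20], chrom=plus.chrom, pos=plus.cds_start + 1
        )
        spectrum = build_spectrum([site])
        cands = call_candidates([site], spectrum, None, models, CallerConfig())
        assert cands == []
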
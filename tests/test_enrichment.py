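"""Enrichment statistic: log2FC, continuity-corrected normal tail, exact oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seedreg.enrichment import (
    enrich_all,
    enrichment_stat,
    exact_binomial_tail,
    read_enrichment_report,
    write_enrichment_report,
)
from seedreg.motifs import BackgroundModel, Motif, build_background
from seedreg.promoters import PromoterRecord, PromoterSet
from seedreg.simulate import PromoterSimSpec, simulate_promoters


class TestEnrichmentStat:
    def test_worked_example(self):
        log2fc, z, p = enrichment_stat(8, 1994, 0.001)
        assert log2fc == pytest.approx(math.log2(8.5 / 2.494), abs=1e-9)
        assert log2fc == pytest.approx(1.769, abs=1e-3)
        # the normal tail and the exact binomial tail agree on the call
        assert p <= 0.1 and exact_binomial_tail(8, 1994, 0.001) <= 0.1

    def test_degenerate_null_no_signal_no_background(self):
        log2fc, z, p = enrichment_stat(0, 1000, 0.0)
        assert (log2fc, p) == (0.0, 1.0)
        assert z == -math.inf

    def test_observed_at_expectation_has_mass_above_corrected_mean(self):
        _, _, p = enrichment_stat(10, 1000, 0.01)
        assert p == pytest.approx(0.5631, abs=1e-3)

    def test_zero_rate_with_excess_count_is_infinitely_surprising(self):
        log2fc, z, p = enrichment_stat(3, 1000, 0.0)
        assert z == math.inf and p == 0.0 and log2fc > 0

    @pytest.mark.parametrize(
        "x,w,rate", [(-1, 10, 0.1), (11, 10, 0.1), (5, 10, 1.5), (5, 0, 0.1)]
    )
    def test_invalid_arguments_rejected(self, x, w, rate):
        with pytest.raises(ValueError):
            enrichment_stat(x, w, rate)

    def test_p_nonincreasing_and_log2fc_increasing_in_observed(self):
        w, rate = 1994, 5e-4
        stats = [enrichment_stat(x, w, rate) for x in range(0, 15)]
        log2fcs = [s[0] for s in stats]
        ps = [s[2] for s in stats]
        assert all(a < b for a, b in zip(log2fcs, log2fcs[1:]))
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @settings(derandomize=True, max_examples=60)
    @given(
        w=st.integers(20, 5000),
        rate=st.floats(1e-5, 0.5),
        frac=st.floats(0, 1),
    )
    def test_exact_tail_bounds_and_monotonicity(self, w, rate, frac):
        x = int(round(frac * w))
        p = exact_binomial_tail(x, w, rate)
        assert 0.0 <= p <= 1.0
        if x > 0:
            assert p <= exact_binomial_tail(x - 1, w, rate) + 1e-12


class TestExactBinomialTail:
    def test_zero_observed_is_certain(self):
        assert exact_binomial_tail(0, 100, 0.3) == 1.0

    def test_enumerated_two_trials(self):
        # four equally likely outcomes at rate 1/2
        assert exact_binomial_tail(2, 2, 0.5) == pytest.approx(0.25)
        assert exact_binomial_tail(1, 2, 0.5) == pytest.approx(0.75)


class TestNormalVsExact:
    def test_approximation_error_decays_with_expected_count(self):
        """Characterisation of the continuity-corrected normal tail against
        the exact binomial: worst gap ~0.02 at mu = 10 (skewed small-rate
        regime), under 0.01 by mu = 60."""
        def max_gap(mu):
            worst = 0.0
            for w in (500, 2000, 20000):
                rate = mu / w
                if rate > 0.5:
                    continue
                sd = math.sqrt(w * rate * (1 - rate))
                for x in range(max(0, int(mu - 4 * sd)),
                               min(w, int(mu + 5 * sd)) + 1):
                    gap = abs(
                        enrichment_stat(x, w, rate)[2]
                        - exact_binomial_tail(x, w, rate)
                    )
                    worst = max(worst, gap)
            return worst

        assert max_gap(10) <= 0.022
        assert max_gap(30) <= 0.015
        assert max_gap(60) <= 0.01
        assert max_gap(10) > max_gap(30) > max_gap(60)


def one_motif_background(rate, motif_name="RY"):
    # synthetic background model with a chosen per-window rate
    total_windows = 10_000_000
    return {
        motif_name: BackgroundModel(
            motif_name, int(rate * total_windows), total_windows
        )
    }


class TestEnrichAll:
    @pytest.fixture()
    def motif(self):
        return Motif("RY", "CATGCAT")

    def test_planted_tenfold_enrichment_is_flagged(self, motif):
        """Candidates planted at 10x a 5e-4 background are flagged at
        alpha = 0.1 in >= 95% of cases (small-n version of the power check)."""
        spec = PromoterSimSpec(
            n_promoters=60, length=2000, background_rate={"RY": 5e-3},
            seed=31,
        )
        candidates, _ = simulate_promoters(spec, [motif])
        chance = 0.25 ** 7
        table = enrich_all(
            candidates, [motif], one_motif_background(5e-4 + chance)
        )
        assert table["significant"].mean() >= 0.95

    def test_null_candidates_flagged_at_most_conservatively(self, motif):
        spec = PromoterSimSpec(
            n_promoters=300, length=2000, background_rate={"RY": 5e-4},
            seed=32,
        )
        candidates, _ = simulate_promoters(spec, [motif])
        chance = 0.25 ** 7
        table = enrich_all(
            candidates, [motif], one_motif_background(5e-4 + chance)
        )
        assert table["significant"].mean() <= 0.15

    def test_rows_sorted_by_p_and_flag_matches_alpha(self, motif):
        spec = PromoterSimSpec(
            n_promoters=40, length=500, background_rate={"RY": 2e-3}, seed=33
        )
        candidates, _ = simulate_promoters(spec, [motif])
        table = enrich_all(candidates, [motif], one_motif_background(1e-3),
                           alpha=0.1)
        assert list(table["p"]) == sorted(table["p"])
        assert (table["significant"] == (table["p"] <= 0.1)).all()

    def test_empty_candidate_set_gives_empty_table(self, motif):
        table = enrich_all(
            PromoterSet(records=[], requested_length=100),
            [motif],
            one_motif_background(1e-3),
        )
        assert len(table) == 0
        assert "significant" in table.columns

    def test_missing_background_model_errors(self, motif):
        candidates = PromoterSet(
            records=[PromoterRecord("g", "ACGTACGTACGT", "c", 1, 12, "+", False)],
            requested_length=12,
        )
        with pytest.raises(KeyError, match="RY"):
            enrich_all(candidates, [motif], {})


class TestReport:
    def test_report_and_significant_subset_round_trip(self, tmp_path):
        motif = Motif("RY", "CATGCAT")
        spec = PromoterSimSpec(
            n_promoters=5, length=300, background_rate={"RY": 3e-3}, seed=34
        )
        candidates, _ = simulate_promoters(spec, [motif])
        table = enrich_all(candidates, [motif], one_motif_background(5e-4))
        path = tmp_path / "enrichment.tsv"
        write_enrichment_report(table, path)
        full = read_enrichment_report(path)
        sig = read_enrichment_report(tmp_path / "enrichment.significant.tsv")
        assert len(full) == len(table)
        assert len(sig) == int(table["significant"].sum())
        for col in ("log2fc", "z", "p"):
            assert np.allclose(full[col], table[col], atol=1e-6)

    def test_empty_table_writes_headers_only(self, tmp_path):
        table = enrich_all(
            PromoterSet(records=[], requested_length=10),
            [Motif("RY", "CATGCAT")],
            one_motif_background(1e-3),
        )
        path = tmp_path / "empty.tsv"
        write_enrichment_report(table, path)
        assert len(read_enrichment_report(path)) == 0
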
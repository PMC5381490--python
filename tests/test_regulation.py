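from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tsmirnet.io_formats import ExpressionMatrix, TISSUES
from tsmirnet.regulation import (
    RegulatoryEdge,
    find_consistent_pairs,
    select_targets,
    target_tissue_enrichment,
    tissue_occurrence,
)
from tsmirnet.specificity import SpecificityProfile, TSCall


def _tf_matrix(rows):
    return ExpressionMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=list(TISSUES)))


def edge(tf, mirna):
    return RegulatoryEdge("tf_mirna", tf, mirna)


class TestTissueOccurrence:
    def test_edge_count_follows_tf_presence(self):
        expr = _tf_matrix({"TFA": [1.0] * 6 + [0.0] * 6, "TFB": [2.0] * 12})
        result = tissue_occurrence([edge("TFA", "m1"), edge("TFA", "m2"), edge("TFB", "m1")], expr)
        counts = dict(zip(result.per_edge["tf"], result.per_edge["n_tissues"]))
        assert counts == {"TFA": 6, "TFB": 12}
        assert result.histogram[6] == 2 and result.histogram[12] == 1

    def test_histogram_conserves_edges(self):
        expr = _tf_matrix({"TFA": [1.0] * 12})
        result = tissue_occurrence([edge("TFA", f"m{i}") for i in range(5)], expr)
        assert result.histogram.sum() == 5

    def test_absent_tf_is_excluded_and_reported(self, caplog):
        expr = _tf_matrix({"TFA": [1.0] * 12})
        with caplog.at_level("WARNING"):
            result = tissue_occurrence([edge("TFA", "m1"), edge("GHOST", "m1")], expr)
        assert result.skipped_tfs == ["GHOST"]
        assert result.histogram.sum() == 1

    def test_presence_threshold_is_strict(self):
        expr = _tf_matrix({"TFA": [5.0] * 3 + [1.0] * 9})
        result = tissue_occurrence([edge("TFA", "m1")], expr, presence_threshold=1.0)
        assert result.per_edge.loc[0, "n_tissues"] == 3

    def test_per_tissue_fractions_sum_to_one(self):
        expr = _tf_matrix({"TFA": [1.0] * 12, "TFB": [1.0] * 4 + [0.0] * 8})
        result = tissue_occurrence([edge("TFA", "m1"), edge("TFB", "m2")], expr)
        sums = result.per_tissue.sum(axis=1)
        assert np.allclose(sums[sums > 0], 1.0)


class TestConsistentPairs:
    def _profile(self, name, specific_in):
        tsvt = {t: (-1.0 if t in specific_in else -5.0) for t in TISSUES}
        return SpecificityProfile(name, sum(tsvt.values()), tsvt)

    def test_shared_tissue_pair_emitted(self):
        profiles = {"SRF": self._profile("SRF", {"skeletal muscle"})}
        calls = {"miR-1": TSCall("miR-1", ("skeletal muscle",), {"skeletal muscle": 500.0})}
        result = find_consistent_pairs([edge("SRF", "miR-1")], profiles, calls)
        assert result.to_dict("records") == [
            {"tissue": "skeletal muscle", "tf": "SRF", "mirna": "miR-1"}
        ]

    def test_disjoint_tissues_yield_nothing(self):
        profiles = {"TF1": self._profile("TF1", {"liver"})}
        calls = {"m1": TSCall("m1", ("brain",), {"brain": 100.0})}
        assert find_consistent_pairs([edge("TF1", "m1")], profiles, calls).empty

    def test_dual_tissue_mirna_matches_on_either_tissue(self):
        profiles = {"SPI1": self._profile("SPI1", {"spleen"})}
        calls = {"miR-146a": TSCall("miR-146a", ("kidney", "spleen"),
                                    {"kidney": 90.0, "spleen": 120.0})}
        result = find_consistent_pairs([edge("SPI1", "miR-146a")], profiles, calls)
        assert list(result["tissue"]) == ["spleen"]

    def test_output_is_subset_of_edges(self):
        profiles = {"TF1": self._profile("TF1", set(TISSUES))}
        calls = {"m1": TSCall("m1", ("heart",), {"heart": 100.0})}
        result = find_consistent_pairs([edge("TF1", "m1")], profiles, calls)
        assert set(zip(result["tf"], result["mirna"])) <= {("TF1", "m1")}


class TestSelectTargets:
    verified = pd.DataFrame(
        {"mirna": ["miR-1"] * 3, "gene": ["TPM1", "TPM2", "HDAC4"],
         "evidence": "verified", "context_score": np.nan}
    )
    predicted = pd.DataFrame(
        {"mirna": ["miR-1"] * 3 + ["miR-2"] * 3,
         "gene": ["P1", "P2", "P3", "Q1", "Q2", "Q3"],
         "evidence": "predicted",
         "context_score": [-0.5, -0.4, -0.31, -0.31, -0.30, -0.29]}
    )

    def test_verified_first(self):
        out = select_targets("miR-1", self.verified, self.predicted)
        assert list(out["gene"]) == ["TPM1", "TPM2", "HDAC4"]
        assert (out["evidence"] == "verified").all()

    def test_strict_score_cutoff(self):
        out = select_targets("miR-2", self.verified, self.predicted)
        assert list(out["gene"]) == ["Q1"]  # -0.31 kept, -0.30 boundary excluded

    def test_no_rows_gives_empty(self):
        out = select_targets("miR-404", self.verified, self.predicted)
        assert out.empty

    def test_idempotent_and_cutoff_ignored_for_verified(self):
        once = select_targets("miR-1", self.verified, self.predicted, score_cutoff=-0.9)
        again = select_targets("miR-1", once, self.predicted, score_cutoff=-0.9)
        pd.testing.assert_frame_equal(once, again)


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration with exact rational arithmetic."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    pmf = {k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom) for k in range(lo, hi + 1)}
    pa = pmf[a]
    return float(sum(p for p in pmf.values() if p <= pa))


class TestFisherEnrichment:
    def test_worked_table_matches_enumeration(self):
        a, b, c, d = 3, 7, 10, 80
        _, p = stats.fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-10)

    def test_exhaustive_small_tables_match_oracle(self):
        """Every 2x2 table with total <= 14 agrees with the exact enumeration."""
        for n in range(15):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        _, p = stats.fisher_exact([[a, b], [c, d]])
                        assert p == pytest.approx(
                            fisher_two_sided_oracle(a, b, c, d), abs=1e-10
                        ), (a, b, c, d)

    def test_random_tables_with_margins_up_to_50(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 26, size=4)  # margins <= 50
            _, p = stats.fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-10)

    def test_enrichment_pipeline_on_known_table(self):
        # 5 specific of 20 targets; background 100 genes, 15 more specific
        targets = {f"g{i}" for i in range(20)}
        labels = {f"g{i}": "kidney" for i in range(5)} | {
            f"h{i}": "kidney" for i in range(15)
        }
        background = targets | {f"h{i}" for i in range(80)}
        (result,) = target_tissue_enrichment({"kidney": targets}, labels, background)
        assert result.table == ((5, 15), (15, 65))
        assert result.proportion == pytest.approx(0.25)
        assert result.p_value == pytest.approx(fisher_two_sided_oracle(5, 15, 15, 65), abs=1e-12)

    def test_null_direction_not_significant(self):
        # labelled fraction identical in targets (1/10) and background rest (9/90)
        targets = {f"g{i}" for i in range(10)}
        labels = {"g0": "liver"} | {f"h{i}": "liver" for i in range(9)}
        background = targets | {f"h{i}" for i in range(90)}
        (result,) = target_tissue_enrichment({"liver": targets}, labels, background)
        assert result.odds_ratio <= 1.0 + 1e-9
        assert result.p_value >= 0.05

    def test_empty_target_set_flagged_untested(self):
        results = target_tissue_enrichment({"liver": set()}, {}, {"g1"})
        assert results[0].p_value is None and results[0].proportion is None

    def test_targets_outside_background_rejected(self):
        with pytest.raises(ValueError, match="outside background"):
            target_tissue_enrichment({"liver": {"gX"}}, {}, {"g1"})

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(3)
        targets_by_tissue = {}
        labels = {}
        background = {f"g{i}" for i in range(200)}
        for t_idx, tissue in enumerate(TISSUES):
            genes = rng.choice(sorted(background), size=30, replace=False)
            targets_by_tissue[tissue] = set(genes)
            for g in genes[: 3 + t_idx]:
                labels[g] = tissue
        results = target_tissue_enrichment(targets_by_tissue, labels, background)
        tested = [r for r in results if r.tested]
        assert all(r.adjusted_p >= r.p_value - 1e-12 for r in tested)
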
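"""Screen scoring: filters, differentials, corrections and the hit rule set."""

import numpy as np
import pandas as pd
import pytest

from mitosense import screen_scoring as ss
from mitosense import synthetic_data as sd
from mitosense.errors import InputError

from conftest import score_six_screens, toy_count_pair


class TestZeroCountFilter:
    def test_guide_with_zero_in_one_replicate_removed(self):
        high, low = toy_count_pair(
            [(10, 12), (5, 8), (100, 90)], [(3, 4), (10, 0), (50, 60)]
        )
        hf, lf = ss.filter_zero_count_guides(high, low)
        assert list(hf["guide_id"]) == ["g00", "g02"]
        assert hf["guide_id"].equals(lf["guide_id"])

    def test_all_positive_is_identity_and_order_preserved(self):
        high, low = toy_count_pair([(1, 2), (3, 4)], [(5, 6), (7, 8)])
        hf, lf = ss.filter_zero_count_guides(high, low)
        pd.testing.assert_frame_equal(hf, high)
        pd.testing.assert_frame_equal(lf, low)

    def test_six_guides_two_zeros_four_survive(self):
        high, low = toy_count_pair(
            [(9, 9), (0, 9), (9, 9), (9, 9), (9, 9), (9, 9)],
            [(9, 9), (9, 9), (9, 0), (9, 9), (9, 9), (9, 9)],
        )
        hf, _ = ss.filter_zero_count_guides(high, low)
        assert len(hf) == 4

    def test_empty_input_empty_output(self):
        high, low = toy_count_pair([(1, 1)], [(1, 1)])
        hf, lf = ss.filter_zero_count_guides(high.iloc[:0], low.iloc[:0])
        assert len(hf) == 0 and len(lf) == 0

    def test_universe_mismatch_rejected(self):
        high, low = toy_count_pair([(1, 1), (2, 2)], [(1, 1), (2, 2)])
        with pytest.raises(InputError):
            ss.filter_zero_count_guides(high, low.iloc[::-1].reset_index(drop=True))


class TestGuideDifferential:
    def test_identical_tables_zero_log2fc(self):
        high, low = toy_count_pair(
            [(10, 20), (300, 310), (47, 53)], [(10, 20), (300, 310), (47, 53)]
        )
        stats = ss.guide_differential(high, low)
        assert np.allclose(stats["log2fc"], 0.0)

    def test_exact_doubling_gives_log2fc_one(self):
        """high = 2x low with equal library sizes -> log2fc ~ 1 up to the
        pseudocount perturbation (< 0.1 at counts >= 100)."""
        rng = np.random.default_rng(0)
        base = rng.integers(100, 1000, size=30)
        # alternate sign of the doubling so joint median-of-ratios size
        # factors stay at 1 and the construction is exact
        low_counts = [(int(b), int(b)) for b in base]
        high_counts = [(int(2 * b), int(2 * b)) for b in base]
        # append mirrored guides to balance library size
        low_all = low_counts + [(int(2 * b), int(2 * b)) for b in base]
        high_all = high_counts + [(int(b), int(b)) for b in base]
        high, low = toy_count_pair(high_all, low_all)
        stats = ss.guide_differential(high, low)
        doubled = stats.iloc[:30]
        assert np.all(np.abs(doubled["log2fc"] - 1.0) < 0.1)

    def test_log2fc_matches_brute_force_oracle(self):
        """Median-of-ratios + pseudocount recomputed from first principles."""
        rng = np.random.default_rng(42)
        # odd guide count: the median is an order statistic, so the linear-
        # space oracle median equals the implementation's log-space median
        counts_h = rng.integers(1, 2000, size=(21, 2))
        counts_l = rng.integers(1, 2000, size=(21, 2))
        high, low = toy_count_pair(
            [tuple(r) for r in counts_h], [tuple(r) for r in counts_l]
        )
        stats = ss.guide_differential(high, low)
        # brute force: geometric-mean reference, per-column median ratio
        all_counts = np.concatenate([counts_h, counts_l], axis=1).astype(float)
        ref = np.exp(np.mean(np.log(all_counts), axis=1))
        factors = np.median(all_counts / ref[:, None], axis=0)
        norm = all_counts / factors
        expected = np.log2(norm[:, :2].mean(axis=1) + 0.5) - np.log2(
            norm[:, 2:].mean(axis=1) + 0.5
        )
        assert np.allclose(stats["log2fc"], expected, atol=1e-9)

    def test_single_replicate_uses_permutation_null(self):
        rng = np.random.default_rng(1)
        n = 200
        high, low = toy_count_pair(
            [(int(c),) for c in rng.integers(200, 800, n)],
            [(int(c),) for c in rng.integers(200, 800, n)],
        )
        stats = ss.guide_differential(high, low)
        assert stats["p_raw"].between(0, 1).all()
        # the most extreme guide gets the smallest p
        extreme = (stats["log2fc"] - stats["log2fc"].median()).abs().idxmax()
        assert stats.loc[extreme, "p_raw"] == stats["p_raw"].min()

    def test_null_type_one_error_calibrated(self):
        """Null screen: fraction of guides with p_raw < 0.05 in [0.03, 0.07]."""
        cfg = sd.ScreenSimConfig(n_genes=1000, seed=17)
        high, low, _ = sd.simulate_screen(cfg)
        hf, lf = ss.filter_zero_count_guides(high, low)
        stats = ss.guide_differential(hf, lf)
        frac = (stats["p_raw"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestCorrectionsAndScore:
    @pytest.mark.parametrize(
        "p, m, mode, expected",
        [
            (0.5, 1, "standard", 0.5),
            (1e-6, 10_000, "standard", 0.01),
            (0.1, 100, "standard", 1.0),
            (0.1, 100, "as_printed", 0.001),
        ],
    )
    def test_bonferroni_arithmetic(self, p, m, mode, expected):
        assert ss.bonferroni_correct([p], m=m, mode=mode)[0] == pytest.approx(expected)

    def test_bonferroni_rejects_bad_inputs(self):
        with pytest.raises(InputError):
            ss.bonferroni_correct([0.5], m=0)
        with pytest.raises(InputError):
            ss.bonferroni_correct([1.5], m=10)

    @pytest.mark.parametrize(
        "p_adj, lfc, expected",
        [(1.0, 5.0, 0.0), (0.5, 0.0, 0.0), (0.01, -2.0, -4.0), (0.1, 3.0, 3.0)],
    )
    def test_gene_score_arithmetic(self, p_adj, lfc, expected):
        assert ss.gene_score(p_adj, lfc) == pytest.approx(expected, abs=1e-12)

    def test_gene_score_zero_p_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            value = ss.gene_score(0.0, 1.0)
        assert np.isfinite(value) and value > 0


class TestAggregation:
    def make_stats(self, rows):
        df = pd.DataFrame(rows, columns=["guide_id", "gene", "log2fc", "p_adj"])
        df["score"] = ss.gene_score(df["p_adj"], df["log2fc"])
        return df

    def test_single_guide_passes_through(self):
        stats = self.make_stats([("g1", "A", -2.0, 0.01)])
        gene = ss.aggregate_guides_to_gene(stats)
        assert gene.loc[0, "log2fc"] == pytest.approx(-2.0)
        assert gene.loc[0, "p_adj"] == pytest.approx(0.01)
        assert bool(gene.loc[0, "significant"])

    def test_best_pair_uses_two_largest_agreeing_scores(self):
        """Scores {-4, -3, +0.1, 0, 0} -> gene from the -4 and -3 guides."""
        stats = self.make_stats(
            [
                ("g1", "A", -2.0, 0.01),   # score -4
                ("g2", "A", -3.0, 0.1),    # score -3
                ("g3", "A", 0.1, 0.1),     # score +0.1
                ("g4", "A", 0.0, 0.5),     # score 0
                ("g5", "A", 5.0, 1.0),     # score 0
            ]
        )
        gene = ss.aggregate_guides_to_gene(stats, method="best_guide_pair")
        assert gene.loc[0, "log2fc"] == pytest.approx((-2.0 - 3.0) / 2)
        assert gene.loc[0, "p_adj"] == pytest.approx(0.1)

    def test_mean_method(self):
        stats = self.make_stats([("g1", "A", -2.0, 0.2), ("g2", "A", -1.0, 0.4)])
        gene = ss.aggregate_guides_to_gene(stats, method="mean")
        assert gene.loc[0, "log2fc"] == pytest.approx(-1.5)
        assert gene.loc[0, "p_adj"] == pytest.approx(0.3)

    def test_recovery_of_planted_genes(self):
        """>= 90% of 50 planted shift -3 genes significant with lfc < -1."""
        genes = [f"GENE{i:04d}" for i in range(1, 51)]
        cfg = sd.ScreenSimConfig(
            n_genes=1000, effect_table={g: -3.0 for g in genes}, seed=23
        )
        high, low, _ = sd.simulate_screen(cfg)
        _, gene_scores = ss.score_screen(high, low)
        planted = gene_scores[gene_scores["gene"].isin(genes)]
        recovered = (planted["significant"] & (planted["log2fc"] < -1)).mean()
        assert recovered >= 0.9


class TestClassifyHits:
    def six_tables(self, lfc, sig):
        """Single-gene gene-score tables for the six screens."""
        out = {}
        for key in sd.SCREEN_KEYS:
            out[key] = pd.DataFrame(
                {
                    "gene": ["A"],
                    "log2fc": [lfc.get(key, 0.0)],
                    "p_adj": [0.01 if sig.get(key, True) else 0.5],
                    "score": [0.0],
                    "significant": [sig.get(key, True)],
                }
            )
        return out

    def test_activator_rule(self):
        scores = self.six_tables({"HeLa_Parkin_NT": -1.5, "HeLa_noParkin_NT": 0.0}, {})
        assert ss.classify_hits(scores).loc[0, "category"] == "parkin_activator"

    def test_activator_difference_threshold(self):
        scores = self.six_tables({"HeLa_Parkin_NT": -1.5, "HeLa_noParkin_NT": -1.0}, {})
        assert ss.classify_hits(scores).loc[0, "category"] == "none"

    def test_facilitator_rule(self):
        scores = self.six_tables(
            {"HeLa_Parkin_AO": 2.0, "HeLa_Parkin_NT": 0.5, "HeLa_noParkin_AO": 0.3}, {}
        )
        assert ss.classify_hits(scores).loc[0, "category"] == "parkin_facilitator"

    def test_downregulator_requires_both_screens_and_excludes_activator(self):
        scores = self.six_tables({"HEK293_NT": -2.0, "HeLa_noParkin_NT": -1.5}, {})
        assert ss.classify_hits(scores).loc[0, "category"] == "mfn2_downregulator"
        # also an activator -> activator wins
        scores = self.six_tables(
            {"HEK293_NT": -2.0, "HeLa_noParkin_NT": -1.5, "HeLa_Parkin_NT": -3.0}, {}
        )
        assert ss.classify_hits(scores).loc[0, "category"] == "parkin_activator"

    def test_not_significant_never_called(self):
        scores = self.six_tables(
            {"HeLa_Parkin_NT": -5.0}, {"HeLa_Parkin_NT": False}
        )
        assert ss.classify_hits(scores).loc[0, "category"] == "none"

    def test_missing_screen_key_named_in_error(self):
        scores = self.six_tables({}, {})
        del scores["HEK293_AO"]
        with pytest.raises(InputError, match="HEK293_AO"):
            ss.classify_hits(scores)


class TestAnnotation:
    def test_renames_applied_before_lookup(self):
        calls = pd.DataFrame({"gene": ["TIMM23B", "PARK2", "HSPE1-MOB4"], "category": ["none"] * 3})
        mitocarta = pd.DataFrame(
            {"gene": ["TIMM23", "PRKN", "HSPE1"], "is_mitochondrial": [True, False, True]}
        )
        out = ss.harmonize_and_annotate(calls, mitocarta)
        assert list(out["gene"]) == ["TIMM23", "PRKN", "HSPE1"]
        assert list(out["is_mitochondrial"]) == [True, False, True]

    def test_unknown_genes_flagged_false(self):
        calls = pd.DataFrame({"gene": ["NOVEL1"], "category": ["none"]})
        mitocarta = pd.DataFrame({"gene": ["TIMM23"], "is_mitochondrial": [True]})
        out = ss.harmonize_and_annotate(calls, mitocarta)
        assert not out.loc[0, "is_mitochondrial"]

    def test_malformed_annotation_rejected(self):
        calls = pd.DataFrame({"gene": ["A"], "category": ["none"]})
        with pytest.raises(InputError):
            ss.harmonize_and_annotate(calls, pd.DataFrame({"symbol": ["A"]}))


def test_type_one_control_on_null_six_screens():
    """Null six-screen simulation yields <= 1% activator + facilitator calls."""
    tables, _ = sd.simulate_six_screens(300, {}, seed=31)
    calls = ss.classify_hits(score_six_screens(tables))
    rate = calls["category"].isin(["parkin_activator", "parkin_facilitator"]).mean()
    assert rate <= 0.01
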
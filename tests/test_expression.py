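"""Normalization, NB testing, pattern algebra, representatives, ΔΔCt."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import methylcross as mc
from methylcross import expression as ex


def _design(samples):
    return pd.DataFrame({"sample": samples,
                         "genotype": [s.split("_")[0] for s in samples],
                         "replicate": [int(s.split("_")[1]) for s in samples]})


class TestNormalization:
    def test_doubled_sample_doubles_factor(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]},
                              index=["f1", "f2", "f3"])
        sf, norm = mc.normalize_counts(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)
        assert np.allclose(norm["s1"], norm["s2"])

    def test_identical_samples_equal_factors(self):
        counts = pd.DataFrame({"s1": [5, 7, 9], "s2": [5, 7, 9]}, index=list("abc"))
        sf, _ = mc.normalize_counts(counts)
        assert sf["s1"] == pytest.approx(sf["s2"])

    def test_matches_hand_computed_median_of_ratios(self):
        counts = pd.DataFrame({"s1": [100, 50, 20], "s2": [200, 150, 20]},
                              index=["f1", "f2", "f3"])
        # geometric-mean reference: f1 sqrt(2e4), f2 sqrt(7500), f3 20
        ref = np.sqrt(counts["s1"] * counts["s2"])
        expected = (counts.div(ref, axis=0)).median()
        sf, _ = mc.normalize_counts(counts)
        assert np.allclose(sf, expected)

    def test_fallback_to_total_count_scaling(self):
        counts = pd.DataFrame({"s1": [10, 0], "s2": [0, 10]}, index=["f1", "f2"])
        sf, _ = mc.normalize_counts(counts)
        assert sf["s1"] == pytest.approx(sf["s2"])


class TestNbPairwise:
    def _null_counts(self, n=2000, mu=100.0, alpha=0.05, seed=7):
        rng = np.random.default_rng(seed)
        r = 1 / alpha
        samples = [f"A_{i}" for i in range(1, 4)] + [f"P_{i}" for i in range(1, 4)]
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu), size=(n, 6)),
            index=[f"g{i}" for i in range(n)], columns=samples,
        )
        return counts, _design(samples)

    def test_null_type_one_error_near_nominal(self):
        """With identical NB groups the raw p<0.05 fraction stays near 0.05
        and p-values are roughly uniform (sup-norm bound on the ECDF)."""
        counts, design = self._null_counts()
        res = mc.nb_pairwise_test(counts, design, "A", "P")
        frac = (res["p"] < 0.05).mean()
        assert 0.01 <= frac <= 0.08
        ks = sps.kstest(res["p"].dropna(), "uniform").statistic
        assert ks < 0.08
        assert res["significant"].mean() < 0.01

    def test_power_at_fourfold_change(self):
        """A 4-fold shift (|log2fc| = 2) at mean 100 and n=3 is detected with
        power >= 0.9; most features are null so normalization stays anchored."""
        rng = np.random.default_rng(21)
        n, n_eff, mu, alpha = 400, 80, 100.0, 0.05
        r = 1 / alpha
        samples = [f"A_{i}" for i in range(1, 4)] + [f"H_{i}" for i in range(1, 4)]
        fold = np.ones(n)
        fold[:n_eff] = 4.0
        a = rng.negative_binomial(r, r / (r + mu), size=(n, 3))
        b = rng.negative_binomial(r, r / (r + mu * fold[:, None]), size=(n, 3))
        counts = pd.DataFrame(np.hstack([a, b]), columns=samples,
                              index=[f"g{i}" for i in range(n)])
        res = mc.nb_pairwise_test(counts, _design(samples), "A", "H")
        effect = res.iloc[:n_eff]
        assert effect["significant"].mean() >= 0.9
        assert effect["log2fc"].median() == pytest.approx(2.0, abs=0.25)

    def test_small_fold_change_never_significant(self):
        """q can be tiny but |log2fc| < 1 fails the effect-size rule."""
        samples = [f"A_{i}" for i in range(1, 4)] + [f"P_{i}" for i in range(1, 4)]
        base = np.array([1000, 1001, 999])
        up = np.round(base * 2 ** 0.8).astype(int)
        rows = {f"g{i}": np.concatenate([base + i, up + i]) for i in range(10)}
        rows.update({f"null{i}": np.concatenate([base + i, base + i])
                     for i in range(30)})
        counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
        res = mc.nb_pairwise_test(counts, _design(samples), "A", "P")
        tight = res[(res["q"] < 0.05) & (res["log2fc"].abs() < 1.0)]
        assert len(tight) > 0
        assert not tight["significant"].any()

    def test_all_zero_feature_reported_untested(self):
        counts, design = self._null_counts(n=10)
        counts.iloc[0] = 0
        res = mc.nb_pairwise_test(counts, design, "A", "P")
        assert not res.iloc[0]["tested"]
        assert np.isnan(res.iloc[0]["p"])

    def test_single_replicate_rejected(self):
        counts, _ = self._null_counts(n=5)
        design = _design(list(counts.columns))
        with pytest.raises(mc.DataError, match="replicates"):
            mc.nb_pairwise_test(counts.drop(columns=["P_2", "P_3"]),
                                design[~design["sample"].isin(["P_2", "P_3"])],
                                "A", "P")

    def test_agrees_with_deseq2_on_strong_effects(self):
        """Independent engine check: same data, same contrast, pydeseq2."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(4)
        n, mu = 200, 120.0
        r = 1 / 0.05
        fc = np.ones(n)
        fc[:10] = 4.0
        fc[10:16] = 0.25
        a = rng.negative_binomial(r, r / (r + mu), size=(n, 3))
        b = rng.negative_binomial(r, r / (r + mu * fc[:, None]), size=(n, 3))
        samples = [f"A_{i}" for i in range(1, 4)] + [f"P_{i}" for i in range(1, 4)]
        counts = pd.DataFrame(np.hstack([a, b]), columns=samples,
                              index=[f"g{i}" for i in range(n)])
        ours = mc.nb_pairwise_test(counts, _design(samples), "A", "P")

        meta = pd.DataFrame({"condition": ["A"] * 3 + ["P"] * 3},
                            index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition",
                           quiet=True)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "P", "A"], quiet=True)
        stats.summary()
        ref = stats.results_df

        strong = np.abs(ref["log2FoldChange"]) >= 1.5
        assert strong.sum() >= 10
        assert np.allclose(ours.loc[strong.index[strong], "log2fc"],
                           ref.loc[strong, "log2FoldChange"], atol=0.5)
        # significance agreement on the engineered strong effects
        ours_sig = set(ours.index[ours["significant"]])
        ref_sig = set(ref.index[(ref["padj"] < 0.05)
                                & (ref["log2FoldChange"].abs() >= 1)])
        engineered = {f"g{i}" for i in range(16)}
        assert len(engineered - ours_sig) <= 2
        assert len((ours_sig ^ ref_sig) & engineered) <= 2
        # neither engine should flag more than a couple of the null features
        assert len(ours_sig - engineered) <= 2
        assert len(ref_sig - engineered) <= 2


def _de_row(contrast, rel):
    """Build a DE row encoding first<second (-1), tie (0) or first>second (+1)."""
    sig = rel != 0
    return pd.Series({"contrast": contrast, "tested": True, "base_mean": 100.0,
                      "log2fc": {-1: 2.0, 0: 0.1, 1: -2.0}[rel],
                      "p": 1e-6 if sig else 0.5, "q": 1e-5 if sig else 0.6,
                      "significant": sig})


class TestPatternAlgebra:
    def _oracle_consistent(self, triad):
        """A triad is consistent iff some rank assignment matches all relations."""
        for ranks in itertools.product(range(3), repeat=3):
            ra, rh, rp = ranks  # higher rank = higher expression
            ok = (np.sign(ra - rp) == triad[0]
                  and np.sign(ra - rh) == triad[1]
                  and np.sign(rp - rh) == triad[2])
            if ok:
                return True
        return False

    def test_total_deterministic_and_13_consistent(self):
        """All 27 sign triads classify; exactly 13 are order-consistent."""
        seen = {}
        consistent_patterns = set()
        for triad in itertools.product((-1, 0, 1), repeat=3):
            rel_ap, rel_ah, rel_ph = triad
            call = mc.classify_pattern(
                _de_row("A-vs-P", rel_ap), _de_row("A-vs-H", rel_ah),
                _de_row("P-vs-H", rel_ph),
            )
            again = mc.classify_pattern(
                _de_row("A-vs-P", rel_ap), _de_row("A-vs-H", rel_ah),
                _de_row("P-vs-H", rel_ph),
            )
            assert call == again
            assert call["coarse_class"] in mc.PATTERN_CLASSES
            assert call["consistent"] == self._oracle_consistent(triad)
            if call["consistent"]:
                consistent_patterns.add(call["fine_pattern"])
            seen[triad] = call
        assert len(seen) == 27
        assert len(consistent_patterns) == 13
        assert sum(c["consistent"] for c in seen.values()) == 13

    def test_coarse_class_invariants(self):
        """hybrid_up iff H above both parents; hybrid_down symmetric."""
        for triad in itertools.product((-1, 0, 1), repeat=3):
            rel_ap, rel_ah, rel_ph = triad
            call = mc.classify_pattern(
                _de_row("A-vs-P", rel_ap), _de_row("A-vs-H", rel_ah),
                _de_row("P-vs-H", rel_ph),
            )
            if not call["consistent"]:
                continue
            h_above_both = rel_ah == -1 and rel_ph == -1
            h_below_both = rel_ah == 1 and rel_ph == 1
            assert (call["coarse_class"] == "hybrid_up") == h_above_both
            assert (call["coarse_class"] == "hybrid_down") == h_below_both
            if call["coarse_class"] == "equal":
                assert triad == (0, 0, 0)

    @pytest.mark.parametrize(
        "rels,fine,coarse",
        [
            ((0, 0, 0), "A=H=P", "equal"),
            # A<H, H<P, A<P: ascending strict order
            ((-1, -1, 1), "A<H<P", "peach_up"),
            # H above both, parents tie
            ((0, -1, -1), "(A=P)<H", "hybrid_up"),
            ((1, 1, -1), "A>H>P", "almond_up"),
            ((-1, 0, 1), "(A=H)<P", "peach_up"),
            ((1, 0, -1), "(A=H)>P", "almond_up"),
            ((-1, -1, 0), "A<(H=P)", "peach_up"),
        ],
    )
    def test_named_patterns(self, rels, fine, coarse):
        rel_ap, rel_ah, rel_ph = rels  # -1 means first < second
        call = mc.classify_pattern(
            _de_row("A-vs-P", rel_ap), _de_row("A-vs-H", rel_ah),
            _de_row("P-vs-H", rel_ph),
        )
        assert call["fine_pattern"] == fine
        assert call["coarse_class"] == coarse
        assert call["consistent"]

    def test_missing_contrast_raises(self):
        with pytest.raises(mc.DataError, match="A-vs-H"):
            mc.classify_pattern(_de_row("A-vs-P", 0), None, _de_row("P-vs-H", 0))


class TestSummaries:
    def test_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(2)
        calls = pd.DataFrame({"coarse_class": rng.choice(mc.PATTERN_CLASSES, 500)})
        table = mc.summarize_patterns(calls)
        assert table["n"].sum() == 500
        assert abs(table["percent"].sum() - 100.0) < 0.3

    def test_single_feature(self):
        table = mc.summarize_patterns({"equal": 1})
        assert table.iloc[0]["percent"] == 100.0

    def test_empty_input(self):
        assert mc.summarize_patterns({}).empty


class TestRepresentatives:
    def _table(self, coverages):
        return pd.DataFrame({"family": "LTR_9", "contig": "ctg1",
                             "copy_id": [f"c{i}" for i in range(len(coverages))],
                             "coverage": coverages})

    def test_highest_coverage_wins(self):
        choice = mc.select_family_representative(self._table([0.85, 0.79]),
                                                 "retrotransposon")
        assert choice["copy_id"] == "c0"
        assert choice["alignment_coverage"] == 0.85

    def test_dna_transposon_cutoff_is_40_percent(self):
        choice = mc.select_family_representative(self._table([0.45]), "DNA transposon")
        assert choice is not None

    def test_below_cutoff_gives_none(self):
        assert mc.select_family_representative(self._table([0.79]),
                                               "retrotransposon") is None

    def test_empty_table(self):
        empty = self._table([]).iloc[0:0]
        assert mc.select_family_representative(empty, "retrotransposon") is None


class TestOrthologCorrelation:
    def test_identity_pairing(self):
        expr = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        pairs = pd.DataFrame({"id_a": list("abcd"), "id_p": list("abcd")})
        assert mc.ortholog_correlation(expr, expr, pairs) == pytest.approx(1.0)

    def test_anticorrelated(self):
        x = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        y = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        pairs = pd.DataFrame({"id_a": list("abc"), "id_p": list("abc")})
        assert mc.ortholog_correlation(x, y, pairs) == pytest.approx(-1.0)

    def test_too_few_pairs(self):
        x = pd.Series([1.0, 2.0], index=list("ab"))
        pairs = pd.DataFrame({"id_a": list("ab"), "id_p": list("ab")})
        with pytest.raises(mc.DataError, match="3 ortholog pairs"):
            mc.ortholog_correlation(x, x, pairs)

    def test_small_noise_keeps_r_above_99(self):
        """Shared signal sd 2 with independent measurement noise sd 0.1."""
        rng = np.random.default_rng(12)
        n = 500
        signal = rng.normal(6, 2, n)
        ids = [f"g{i}" for i in range(n)]
        xa = pd.Series(signal + rng.normal(0, 0.1, n), index=ids)
        xp = pd.Series(signal + rng.normal(0, 0.1, n), index=ids)
        pairs = pd.DataFrame({"id_a": ids, "id_p": ids})
        assert mc.ortholog_correlation(xa, xp, pairs) >= 0.99


class TestDdct:
    def _ct(self, rows):
        return pd.DataFrame(rows, columns=["sample", "genotype", "gene", "ct"])

    def _noise_free(self, fold_h=4.0):
        rows = []
        for genotype, fold in (("P", 1.0), ("A", 1.0), ("H", fold_h)):
            for rep in (1, 2, 3):
                rows.append([f"{genotype}_{rep}", genotype, "TEF2", 20.0])
                rows.append([f"{genotype}_{rep}", genotype, "RPII", 22.0])
                rows.append([f"{genotype}_{rep}", genotype, "tgt",
                             25.0 - np.log2(fold)])
        return self._ct(rows)

    def test_calibrator_self_comparison_is_one(self):
        rel = mc.ddct_quantify(self._noise_free(), calibrator="P")
        p = rel[(rel["target"] == "tgt") & (rel["genotype"] == "P")]
        assert p.iloc[0]["relative_expression"] == pytest.approx(1.0)

    def test_minus_two_ddct_gives_fourfold(self):
        rel = mc.ddct_quantify(self._noise_free(4.0), calibrator="P")
        h = rel[(rel["target"] == "tgt") & (rel["genotype"] == "H")]
        assert h.iloc[0]["ddct"] == pytest.approx(-2.0)
        assert h.iloc[0]["relative_expression"] == pytest.approx(4.0)

    def test_plate_offset_invariance(self):
        ct = self._noise_free(8.0)
        shifted = ct.copy()
        shifted["ct"] += 5.3
        a = mc.ddct_quantify(ct, calibrator="P")
        b = mc.ddct_quantify(shifted, calibrator="P")
        assert np.allclose(a["relative_expression"], b["relative_expression"])

    def test_missing_reference_names_sample(self):
        ct = self._noise_free()
        ct = ct[~((ct["sample"] == "A_2") & (ct["gene"] == "RPII"))]
        with pytest.raises(mc.DataError, match="A_2"):
            mc.ddct_quantify(ct, calibrator="P")

    def test_noisy_simulation_recovers_fold_changes(self, small_cfg):
        """50 targets at known folds, Ct noise sd 0.2: mean |log2 error| stays
        well under the replicate-noise bound (~3 x 0.2)."""
        rng = np.random.default_rng(30)
        folds = 2.0 ** rng.uniform(-3, 3, 50)
        expr = pd.DataFrame(
            {"A": 100.0 * folds, "P": np.full(50, 100.0), "H": np.full(50, 100.0)},
            index=[f"t{i}" for i in range(50)],
        )
        expr.loc["TEF2"] = 100.0
        expr.loc["RPII"] = 100.0
        ct = mc.simulate_qpcr(expr, small_cfg, noise_sd=0.2)
        rel = mc.ddct_quantify(ct, calibrator="P")
        a = rel[rel["genotype"] == "A"].set_index("target")
        err = np.abs(np.log2(a["relative_expression"].loc[[f"t{i}" for i in range(50)]])
                     - np.log2(folds))
        assert err.mean() < 0.3
        assert err.max() < 0.6 * 3  # 3 sd of the propagated replicate noise
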
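"""TE class fractions, insertion-eligibility filter, fold classification,
and the resampling DE probability."""
import numpy as np
import pandas as pd
import pytest

from oopromscan.te_quant import (CountsTable, TEInsertion, annotate_genic,
                                 class_read_fraction, classify_insertions,
                                 de_probability, eligible_subfamilies)
from oopromscan.io_formats import GeneModel


def make_table(a, b, lib_a=None, lib_b=None):
    df = pd.DataFrame({"condA": a, "condB": b},
                      index=[f"f{i}" for i in range(len(a))])
    lib = {"condA": lib_a if lib_a is not None else int(df["condA"].sum()),
           "condB": lib_b if lib_b is not None else int(df["condB"].sum())}
    return CountsTable(df, lib)


def ins(iid, subfamily="SF0", genic=False, te_class="LINE", start=0):
    return TEInsertion(insertion_id=iid, subfamily=subfamily, te_class=te_class,
                       chrom="chr1", start=start, end=start + 100, genic=genic)


class TestClassFraction:
    def test_even_split(self):
        df = pd.DataFrame({"condA": [50, 50], "condB": [20, 80]}, index=["LINE", "LTR"])
        t = CountsTable(df, {"condA": 100, "condB": 100})
        frac = class_read_fraction(t)
        assert frac.loc["LINE", "condA"] == pytest.approx(50.0)
        assert frac.loc["LTR", "condB"] == pytest.approx(80.0)

    def test_single_class_is_100(self):
        df = pd.DataFrame({"condA": [7], "condB": [3]}, index=["SINE"])
        frac = class_read_fraction(CountsTable(df, {"condA": 7, "condB": 3}))
        assert (frac.values == 100.0).all()

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"condA": rng.integers(1, 100, 4),
                           "condB": rng.integers(1, 100, 4)},
                          index=["LINE", "SINE", "LTR", "other"])
        frac = class_read_fraction(CountsTable(df, {"condA": 10**6, "condB": 10**6}))
        assert np.allclose(frac.sum(axis=0), 100.0, atol=1e-9)


class TestEligibility:
    def _build(self, n_qualifying):
        insertions = [ins(f"i{k}", genic=False) for k in range(n_qualifying)]
        counts_a = [6] * n_qualifying
        counts_b = [0] * n_qualifying
        df = pd.DataFrame({"condA": counts_a, "condB": counts_b},
                          index=[f"i{k}" for k in range(n_qualifying)])
        t = CountsTable(df, {"condA": int(df.condA.sum()), "condB": 1})
        return insertions, t

    def test_boundary_51_kept_50_dropped(self):
        ins51, t51 = self._build(51)
        assert eligible_subfamilies(ins51, t51) == {"SF0"}
        ins50, t50 = self._build(50)
        assert eligible_subfamilies(ins50, t50) == set()

    def test_strict_read_threshold(self):
        insertions = [ins(f"i{k}") for k in range(60)]
        df = pd.DataFrame({"condA": [5] * 60, "condB": [5] * 60},
                          index=[f"i{k}" for k in range(60)])
        t = CountsTable(df, {"condA": 300, "condB": 300})
        assert eligible_subfamilies(insertions, t) == set()  # 5 is not > 5

    def test_either_condition_rule(self):
        insertions = [ins(f"i{k}") for k in range(60)]
        df = pd.DataFrame({"condA": [0] * 60, "condB": [6] * 60},
                          index=[f"i{k}" for k in range(60)])
        t = CountsTable(df, {"condA": 1, "condB": 360})
        assert eligible_subfamilies(insertions, t) == {"SF0"}

    def test_genic_insertions_excluded(self):
        insertions = [ins(f"i{k}", genic=True) for k in range(60)]
        df = pd.DataFrame({"condA": [9] * 60, "condB": [9] * 60},
                          index=[f"i{k}" for k in range(60)])
        t = CountsTable(df, {"condA": 540, "condB": 540})
        assert eligible_subfamilies(insertions, t) == set()

    def test_monotone_in_thresholds(self):
        insertions = [ins(f"i{k}") for k in range(80)]
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"condA": rng.integers(0, 12, 80),
                           "condB": rng.integers(0, 12, 80)},
                          index=[f"i{k}" for k in range(80)])
        t = CountsTable(df, {"condA": 10**4, "condB": 10**4})
        strict = eligible_subfamilies(insertions, t, min_insertions=50, min_reads=5)
        lax = eligible_subfamilies(insertions, t, min_insertions=40, min_reads=3)
        assert strict <= lax


class TestAnnotateGenic:
    def test_gene_body_overlap(self):
        gene = GeneModel(gene_id="g", chrom="chr1", strand="+",
                         exons=[(1000, 1100), (1900, 2000)])
        # insertion entirely within the intron still counts as genic
        inside_intron = ins("a", start=1500)
        outside = ins("b", start=5000)
        out = annotate_genic([inside_intron, outside], [gene])
        assert out[0].genic and not out[1].genic


class TestClassify:
    def test_pseudocount_fold(self):
        t = make_table([10], [30], lib_a=1000, lib_b=1000)
        calls = classify_insertions(t)
        assert calls["fold"].iloc[0] == pytest.approx(30.5 / 10.5)
        assert calls["cls"].iloc[0] == "up"

    def test_down_symmetry(self):
        t = make_table([30], [10], lib_a=1000, lib_b=1000)
        assert classify_insertions(t)["cls"].iloc[0] == "down"

    def test_same(self):
        t = make_table([10], [10], lib_a=1000, lib_b=1000)
        assert classify_insertions(t)["cls"].iloc[0] == "same"

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 200, 50)
        b = rng.integers(0, 200, 50)
        fwd = classify_insertions(make_table(a, b, 10**4, 10**4))["cls"]
        rev = classify_insertions(make_table(b, a, 10**4, 10**4))["cls"]
        swap = {"up": "down", "down": "up", "same": "same"}
        assert list(rev) == [swap[c] for c in fwd]


class TestDeProbability:
    def test_seed_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            de_probability([1, 2], [1, 2], (10, 10), seed=None)

    def test_equal_counts_low_probability(self):
        counts = np.full(200, 50)
        probs = de_probability(counts, counts, (10_000, 10_000), seed=1)
        assert probs.max() <= 0.5

    def test_reproducible_and_order_invariant(self):
        rng = np.random.default_rng(9)
        a = rng.poisson(100, 300)
        b = rng.poisson(100, 300)
        lib = (int(a.sum()), int(b.sum()))
        p1 = de_probability(a, b, lib, seed=7)
        p2 = de_probability(a, b, lib, seed=7)
        assert np.array_equal(p1, p2)

    def test_strong_fold_scores_high(self):
        rng = np.random.default_rng(10)
        n = 500
        means = np.exp(rng.uniform(np.log(20), np.log(2000), n))
        means_a, means_b = means.copy(), means.copy()
        de = np.arange(50)
        means_a[de], means_b[de] = 200.0, 1600.0
        a = rng.poisson(means_a)
        b = rng.poisson(means_b)
        probs = de_probability(a, b, (int(a.sum()), int(b.sum())), seed=2)
        assert (probs[de] >= 0.95).mean() >= 0.9
        assert (probs[50:] >= 0.95).mean() <= 0.1

    def test_invalid_fraction(self):
        with pytest.raises(ValueError, match="replicate_fraction"):
            de_probability([1], [1], (10, 10), replicate_fraction=0.0, seed=1)
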
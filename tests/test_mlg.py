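"""MLG construction, distances, UPGMA, encoding, stepwise LDA, LD."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pelopop import mlg
from pelopop.genotyping import ALLELES_BY_IUPAC


def calls_frame(records):
    """records: (individual, marker, pos, alleles)"""
    from pelopop.genotyping import IUPAC_BY_ALLELES

    rows = [
        (ind, m, p, "called" if a else "no_call", a,
         IUPAC_BY_ALLELES.get(frozenset(a), "N") if a else "N", 50)
        for ind, m, p, a in records
    ]
    return pd.DataFrame(
        rows, columns=["individual", "marker", "pos", "status", "alleles",
                       "iupac", "cov_tot"],
    )


def meta_frame(records):
    """records: (individual, taxon, popsys)"""
    return pd.DataFrame(
        [(ind, tx, "P", ps, "w", 50.0, 10.0, "F", 2) for ind, tx, ps in records],
        columns=["individual", "taxon", "population", "popsys", "region",
                 "lat", "lon", "sex", "ploidy"],
    )


PANEL = [("m1", 1), ("m2", 1)]


class TestBuildMlgs:
    def test_identical_strings_collapse(self):
        calls = calls_frame(
            [("i1", "m1", 1, "A"), ("i1", "m2", 1, "AG"),
             ("i2", "m1", 1, "A"), ("i2", "m2", 1, "AG")]
        )
        meta = meta_frame([("i1", "LR", "L-E"), ("i2", "LR", "L-E")])
        out = mlg.build_mlgs(calls, PANEL, meta)
        assert len(out) == 1
        assert out[0].sequence == "AR"
        assert out[0].multiplicity == 2

    def test_shared_between_systems(self):
        calls = calls_frame(
            [("i1", "m1", 1, "A"), ("i1", "m2", 1, "AG"),
             ("i2", "m1", 1, "A"), ("i2", "m2", 1, "AG")]
        )
        meta = meta_frame([("i1", "LR", "L-E"), ("i2", "LR", "R-E")])
        out = mlg.build_mlgs(calls, PANEL, meta)
        assert len(out) == 1
        assert out[0].popsys_labels == ("L-E", "R-E")

    def test_missing_site_distinct(self):
        calls = calls_frame(
            [("i1", "m1", 1, "A"), ("i1", "m2", 1, ""),
             ("i2", "m1", 1, "A"), ("i2", "m2", 1, "A")]
        )
        meta = meta_frame([("i1", "LR", "L-E"), ("i2", "LR", "L-E")])
        out = mlg.build_mlgs(calls, PANEL, meta)
        assert sorted(m.sequence for m in out) == ["AA", "AN"]

    def test_empty_panel_raises(self):
        with pytest.raises(ValueError, match="empty"):
            mlg.build_mlgs(calls_frame([]), [], meta_frame([]))


def brute_force_pdistance(a, b):
    """Average mismatch over all resolution pairs; independent oracle."""
    total, scored = 0.0, 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            continue
        scored += 1
        if x == y:
            continue
        pairs = list(itertools.product(ALLELES_BY_IUPAC[x], ALLELES_BY_IUPAC[y]))
        total += sum(px != py for px, py in pairs) / len(pairs)
    return total / scored if scored else 0.0


class TestAmbiguityPDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("AR", "AR", 0.0),       # identical ambiguity codes score zero
            ("A", "R", 0.5),         # resolutions A,G -> mismatches 0 and 1
            ("AA", "AG", 0.5),
            ("AN", "AG", 0.0),       # N excluded pairwise
            ("R", "Y", 1.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert mlg.ambiguity_pdistance(a, b) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            mlg.ambiguity_pdistance("AA", "A")

    @given(
        st.lists(
            st.tuples(
                st.sampled_from("ACGTRYMKWSN"), st.sampled_from("ACGTRYMKWSN")
            ),
            min_size=1, max_size=10,
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_resolution_average(self, site_pairs):
        a = "".join(x for x, _ in site_pairs)
        b = "".join(y for _, y in site_pairs)
        assert mlg.ambiguity_pdistance(a, b) == pytest.approx(
            brute_force_pdistance(a, b), abs=1e-12
        )
        # symmetry
        assert mlg.ambiguity_pdistance(b, a) == pytest.approx(
            mlg.ambiguity_pdistance(a, b), abs=1e-12
        )


class TestUpgma:
    def test_three_taxon_hand_computation(self):
        d = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        tree = mlg.upgma(d, ["A", "B", "C"])
        tips = {t.name: t for t in tree.tips()}
        assert tips["A"].length == pytest.approx(0.1)
        assert tips["B"].length == pytest.approx(0.1)
        assert tips["C"].length == pytest.approx(0.3)
        ab_parent = tips["A"].parent
        assert ab_parent is tips["B"].parent
        assert ab_parent.length == pytest.approx(0.2)

    def test_all_zero_matrix_star_at_zero(self):
        d = np.zeros((4, 4))
        tree = mlg.upgma(d, list("ABCD"))
        for tip in tree.tips():
            assert tip.accumulate_to_ancestor(tree) == pytest.approx(0.0)

    def test_random_matrix_ultrametric_and_leaves_preserved(self):
        rng = np.random.default_rng(3)
        x = rng.random((8, 5))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(8)]
        tree = mlg.upgma(d, labels)
        assert sorted(t.name for t in tree.tips()) == labels
        assert mlg.is_ultrametric(tree)

    def test_nan_rejected(self):
        d = np.zeros((2, 2))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            mlg.upgma(d, ["a", "b"])


class TestAtomicEncoding:
    def test_base_values(self):
        assert mlg.atomic_encode("ACGT").tolist() == [70.0, 58.0, 78.0, 66.0]

    def test_ambiguity_mean(self):
        assert mlg.atomic_encode("R").tolist() == [74.0]

    def test_missing_is_nan(self):
        assert np.isnan(mlg.atomic_encode("N")[0])

    def test_unknown_character(self):
        with pytest.raises(ValueError, match="unknown character"):
            mlg.atomic_encode("AZ")


def planted_clusters(rng, n_per_class=20, n_noise=4, sep=2.0, noise_sd=1.0):
    """Three classes separated on 2 informative variables + noise columns."""
    centers = {"L-E": (0.0, 0.0), "E": (sep, 0.0), "R-E": (0.0, sep)}
    X, y = [], []
    for label, (cx, cy) in centers.items():
        pts = rng.normal([cx, cy], noise_sd, size=(n_per_class, 2))
        noise = rng.normal(0, 1, size=(n_per_class, n_noise))
        X.append(np.hstack([pts, noise]))
        y += [label] * n_per_class
    return np.vstack(X), np.array(y)


class TestStepwiseLda:
    def test_separable_single_variable(self):
        rng = np.random.default_rng(5)
        n = 30
        informative = np.r_[np.zeros(n), np.ones(n) * 10]
        X = np.column_stack([informative + rng.normal(0, 0.1, 2 * n),
                             rng.normal(0, 1, 2 * n),
                             rng.normal(0, 1, 2 * n)])
        y = ["a"] * n + ["b"] * n
        res = mlg.stepwise_lda(X, y)
        assert res.selected == [0]
        assert res.accuracy == 100.0

    def test_permuted_labels_rarely_enter(self):
        # n=40, 5 uninformative variables, two classes: at step one the
        # partial F of each variable is a null F(1, 38), so the chance that
        # no variable reaches F=4.0 is (1 - sf(4; 1, 38))^5 ~ 0.76
        from scipy import stats

        rng = np.random.default_rng(15)
        X = rng.normal(size=(40, 5))
        y = np.array(["a"] * 20 + ["b"] * 20)
        nothing = 0
        reps = 200
        for _ in range(reps):
            perm = rng.permutation(y)
            try:
                mlg.stepwise_lda(X, perm)
            except ValueError:
                nothing += 1
        expected = (1.0 - stats.f.sf(4.0, 1, 38)) ** 5
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(nothing / reps - expected) <= 3 * se

    def test_three_cluster_accuracy_matches_direct_lda(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(25)
        X, y = planted_clusters(rng, n_per_class=40)
        res = mlg.stepwise_lda(X, y)
        assert {0, 1} <= set(res.selected)
        oracle = LinearDiscriminantAnalysis().fit(X[:, :2], y)
        oracle_acc = 100.0 * float(np.mean(oracle.predict(X[:, :2]) == y))
        assert abs(res.accuracy - oracle_acc) <= 10.0

    def test_max_steps_and_determinism(self):
        rng = np.random.default_rng(35)
        X, y = planted_clusters(rng, n_per_class=15, n_noise=8)
        res1 = mlg.stepwise_lda(X, y, f_enter=0.5, max_steps=3)
        res2 = mlg.stepwise_lda(X, y, f_enter=0.5, max_steps=3)
        assert len(res1.selected) <= 3
        assert res1.selected == res2.selected
        assert res1.accuracy == res2.accuracy

    def test_encode_mlgs_imputes_missing(self):
        mlgs = [
            mlg.MultilocusGenotype("a", "AN", "LR", 1, ("L-E",), "L-E"),
            mlg.MultilocusGenotype("b", "GG", "LR", 1, ("R-E",), "R-E"),
            mlg.MultilocusGenotype("c", "GG", "LR", 1, ("R-E",), "R-E"),
        ]
        X, y = mlg.encode_mlgs(mlgs)
        assert not np.isnan(X).any()
        assert X[0, 1] == pytest.approx(78.0)  # imputed from the two G columns


class TestPairwiseLd:
    def meta(self, n):
        return meta_frame([(f"i{k}", "RR", "all-R") for k in range(n)])

    def dosage_calls(self, genotype_lists):
        """genotype_lists: marker -> list of allele strings per individual."""
        records = []
        for marker, genos in genotype_lists.items():
            for k, g in enumerate(genos):
                records.append((f"i{k}", marker, 1, g))
        return calls_frame(records)

    def test_self_pair_perfect(self):
        genos = ["A", "AG", "G", "A", "AG"]
        calls = self.dosage_calls({"m1": genos})
        out = mlg.pairwise_ld(
            calls, self.meta(5), "RR", {("m1", 1): "A"},
            pairs=[(("m1", 1), ("m1", 1))],
        )
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_independent_snps_uncorrelated(self):
        rng = np.random.default_rng(45)
        n = 500
        genos = {}
        for m in ("m1", "m2", "m3", "m4"):
            dosages = rng.binomial(2, 0.5, n)
            genos[m] = ["GG A AG".split()[d] if False else ["G", "AG", "A"][d]
                        for d in dosages]
        calls = self.dosage_calls(genos)
        des = {(m, 1): "A" for m in genos}
        out = mlg.pairwise_ld(calls, self.meta(n), "RR", des)
        assert (out["r"].abs() < 0.15).mean() >= 0.95

    def test_co_inherited_pair(self):
        rng = np.random.default_rng(55)
        n = 200
        dosages = rng.binomial(2, 0.4, n)
        genos = {m: [["G", "AG", "A"][d] for d in dosages] for m in ("m1", "m2")}
        calls = self.dosage_calls(genos)
        out = mlg.pairwise_ld(
            calls, self.meta(n), "RR", {("m1", 1): "A", ("m2", 1): "A"}
        )
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_monomorphic_missing(self):
        genos = {"m1": ["A"] * 4, "m2": ["A", "AG", "G", "A"]}
        calls = self.dosage_calls(genos)
        out = mlg.pairwise_ld(
            calls, self.meta(4), "RR", {("m1", 1): "A", ("m2", 1): "A"}
        )
        assert np.isnan(out.iloc[0]["r"])
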
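import numpy as np
import pytest

from coexkit import (
    AnnotationCatalog,
    CoexpressionMatrix,
    OrthoGroups,
    PairLabeling,
    ValidationError,
    average_linkage_cluster,
    confusion_metrics,
    consistency_score,
    label_pairs,
    one_to_one_pairs,
    platform_similarity,
    propagate_annotations,
    select_informative_terms,
)
from coexkit.synthetic import generate_null_coexpression


def auroc_oracle(scores_pos, scores_neg):
    """Pair-counting AUROC: P(pos > neg) + 0.5 P(tie)."""
    wins = ties = 0
    for p in scores_pos:
        for n in scores_neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(scores_pos) * len(scores_neg))


def coex_of(pair_values: dict, genes) -> CoexpressionMatrix:
    idx = {g: i for i, g in enumerate(genes)}
    vals = np.full((len(genes), len(genes)), np.nan)
    for (a, b), v in pair_values.items():
        vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = v
    return CoexpressionMatrix(list(genes), vals, scale="zscore")


class TestPropagation:
    def test_chain_transitive_closure(self):
        cat = AnnotationCatalog(
            {"C": {"g"}},
            term_to_parents={"C": {"B"}, "B": {"A"}},
        )
        out = propagate_annotations(cat)
        assert out.term_to_genes["A"] == {"g"}
        assert out.term_to_genes["B"] == {"g"}
        assert out.term_to_genes["C"] == {"g"}

    def test_flat_catalog_identity(self):
        cat = AnnotationCatalog({"T": {"g1", "g2"}})
        assert propagate_annotations(cat) is cat

    def test_diamond_counts_once(self):
        cat = AnnotationCatalog(
            {"D": {"g"}},
            term_to_parents={"D": {"B", "C"}, "B": {"A"}, "C": {"A"}},
        )
        out = propagate_annotations(cat)
        assert out.term_to_genes["A"] == {"g"}

    def test_idempotent(self):
        cat = AnnotationCatalog(
            {"C": {"g1"}, "B": {"g2"}},
            term_to_parents={"C": {"B"}, "B": {"A"}},
        )
        once = propagate_annotations(cat)
        twice = propagate_annotations(once)
        assert once.term_to_genes == twice.term_to_genes

    def test_cycle_rejected_at_construction(self):
        with pytest.raises(ValidationError, match="cycle"):
            AnnotationCatalog({"A": {"g"}},
                              term_to_parents={"A": {"B"}, "B": {"A"}})


class TestInformativeTerms:
    def test_strict_size_threshold(self):
        cat = AnnotationCatalog({
            "small": {f"g{i}" for i in range(49)},
            "big": {f"g{i}" for i in range(50)},
        })
        out = select_informative_terms(cat)
        assert set(out.term_to_genes) == {"small"}

    def test_all_generic_gives_empty_with_warning(self, caplog):
        cat = AnnotationCatalog({"big": {f"g{i}" for i in range(60)}})
        with caplog.at_level("WARNING"):
            out = select_informative_terms(cat)
        assert out.n_terms == 0
        assert any("informative" in r.message for r in caplog.records)

    def test_singleton_term_kept(self):
        out = select_informative_terms(AnnotationCatalog({"t": {"g"}}))
        assert out.term_to_genes == {"t": {"g"}}


class TestLabelPairs:
    def og(self, groups):
        return OrthoGroups(["S"], {f"OG{i}": {"S": list(g)}
                                   for i, g in enumerate(groups)})

    def test_shared_term_different_groups_positive(self):
        cat = AnnotationCatalog({"T": {"a", "b"}})
        labels = label_pairs(cat, self.og([["a"], ["b"]]), species="S")
        assert ("a", "b") in labels.positives
        assert ("a", "b") not in labels.excluded

    def test_same_orthogroup_excluded(self):
        cat = AnnotationCatalog({"T": {"a", "b"}})
        labels = label_pairs(cat, self.og([["a", "b"]]), species="S")
        assert ("a", "b") in labels.excluded
        assert list(labels.iter_pairs()) == []

    def test_disjoint_terms_negative(self):
        cat = AnnotationCatalog({"T1": {"a"}, "T2": {"b"}})
        labels = label_pairs(cat)
        pairs = list(labels.iter_pairs())
        assert pairs == [("a", "b", False)]

    def test_species_without_ortho_rejected(self):
        with pytest.raises(ValidationError):
            label_pairs(AnnotationCatalog({"T": {"a", "b"}}), species="S")


class TestConsistencyScore:
    def separated_instance(self, n_pos=10, n_neg=400):
        """All positive pairs score above all negative pairs."""
        genes = [f"p{i}" for i in range(5)] + [f"q{i}" for i in range(29)]
        cat = AnnotationCatalog({"T": set(genes[:5])})
        labels = label_pairs(cat)
        labels = PairLabeling(universe=genes, positives=labels.positives)
        rng = np.random.default_rng(0)
        pair_values = {}
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                key = (a, b) if a < b else (b, a)
                if key in labels.positives:
                    pair_values[key] = 10 + rng.random()
                else:
                    pair_values[key] = rng.random()
        return coex_of(pair_values, genes), labels

    def test_perfect_separation_scores_100(self):
        coex, labels = self.separated_instance()
        s = consistency_score(coex, labels)
        assert s.value == pytest.approx(100.0, abs=1e-9)

    def test_inverted_scores_near_zero(self):
        coex, labels = self.separated_instance()
        inverted = CoexpressionMatrix(coex.gene_ids, -coex.values, scale="zscore")
        s = consistency_score(inverted, labels)
        assert s.value < 1.0

    def test_invariant_under_monotone_transform(self):
        coex, labels = self.separated_instance()
        transformed = CoexpressionMatrix(
            coex.gene_ids, np.arctan(coex.values / 5) * 3 + 7, scale="zscore")
        a = consistency_score(coex, labels, fpr_ceiling=0.5)
        b = consistency_score(transformed, labels, fpr_ceiling=0.5)
        assert a.value == pytest.approx(b.value, abs=1e-9)

    def test_full_auc_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i:02d}" for i in range(15)]
        cat = AnnotationCatalog({"T1": set(genes[:5]), "T2": set(genes[4:8])})
        labels = label_pairs(cat)
        # integer-quantized scores force ties through the tied-block trapezoid
        pair_values = {}
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                pair_values[(a, b)] = float(rng.integers(0, 6))
        coex = coex_of(pair_values, genes)
        s = consistency_score(coex, labels, fpr_ceiling=1.0, scale=1.0)
        universe = set(labels.universe)  # only annotated genes are evaluated
        pos = [v for (a, b), v in pair_values.items()
               if a in universe and b in universe and (a, b) in labels.positives]
        neg = [v for (a, b), v in pair_values.items()
               if a in universe and b in universe
               and (a, b) not in labels.positives]
        assert s.value == pytest.approx(auroc_oracle(pos, neg), abs=1e-12)

    def test_missing_pairs_dropped(self):
        genes = ["a", "b", "c", "d"]
        cat = AnnotationCatalog({"T": {"a", "b"}, "U": {"c", "d"}})
        labels = label_pairs(cat)
        pair_values = {("a", "b"): 3.0, ("a", "c"): 0.1, ("a", "d"): 0.2,
                       ("b", "c"): 0.3, ("b", "d"): 0.4}  # (c,d) missing
        s = consistency_score(coex_of(pair_values, genes), labels,
                              fpr_ceiling=1.0, scale=1.0)
        assert s.n_pos == 1 and s.n_neg == 4

    def test_no_negatives_rejected(self):
        genes = ["a", "b"]
        cat = AnnotationCatalog({"T": {"a", "b"}})
        labels = label_pairs(cat)
        with pytest.raises(ValidationError):
            consistency_score(coex_of({("a", "b"): 1.0}, genes), labels)

    def test_null_calibration_quick(self):
        """Random scores vs labels average near 0.5 over seeds."""
        truth = {f"g{i:04d}": i // 20 for i in range(100)}
        scores = []
        from coexkit.synthetic import generate_annotations

        for seed in range(30):
            cat = generate_annotations(truth, seed=seed)
            labels = label_pairs(cat)
            coex = generate_null_coexpression(100, seed=1000 + seed)
            scores.append(consistency_score(coex, labels).value)
        assert np.mean(scores) == pytest.approx(0.5, abs=0.25)


class TestPlatformSimilarity:
    def test_self_similarity_and_display(self):
        v = np.array([0.3, -1.2, 0.7, 2.2])
        sim = platform_similarity([v, v.copy()])
        assert sim[0, 1] == pytest.approx(1.0)
        disp = platform_similarity([v, v.copy()], display_rounding=True)
        assert disp[0, 1] == 10

    def test_negated_vector(self):
        v = np.array([0.3, -1.2, 0.7, 2.2])
        sim = platform_similarity([v, -v])
        assert sim[0, 1] == pytest.approx(-1.0)

    def test_matches_pcc_oracle(self):
        rng = np.random.default_rng(21)
        vs = [rng.standard_normal(50) for _ in range(3)]
        sim = platform_similarity(vs)
        for i in range(3):
            for j in range(3):
                xm = vs[i] - vs[i].mean()
                ym = vs[j] - vs[j].mean()
                expect = np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2))
                assert sim[i, j] == pytest.approx(expect, abs=1e-12)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            platform_similarity([np.zeros(3), np.zeros(4)])


class TestOneToOnePairs:
    def make_og(self, n_groups, species, extras=()):
        groups = {}
        for i in range(n_groups):
            groups[f"OG{i:04d}"] = {sp: [f"{sp}_g{i}"] for sp in species}
        for j, grp in enumerate(extras):
            groups[f"EX{j:03d}"] = grp
        return OrthoGroups(list(species), groups)

    def test_two_groups_one_pair(self):
        og = self.make_og(2, ["A", "B"])
        _, n_pairs = one_to_one_pairs(og, ["A", "B"])
        assert n_pairs == 1

    def test_multi_copy_group_excluded(self):
        og = self.make_og(3, ["A", "B"],
                          extras=[{"A": ["A_x1", "A_x2"], "B": ["B_x"]}])
        aligned, n_pairs = one_to_one_pairs(og, ["A", "B"])
        assert len(aligned["A"]) == 3
        assert n_pairs == 3

    def test_count_matches_brute_force(self):
        og = self.make_og(9, ["A", "B", "C"])
        aligned, n_pairs = one_to_one_pairs(og, ["A", "B", "C"])
        n = len(aligned["A"])
        brute = sum(1 for i in range(n) for j in range(i + 1, n))
        assert n_pairs == brute == 36


class TestAverageLinkage:
    def test_two_items(self):
        sim = np.array([[1.0, 0.4], [0.4, 1.0]])
        link = average_linkage_cluster(sim)
        assert link.shape == (1, 4)
        assert link[0, 2] == pytest.approx(0.6)

    def test_three_item_upgma_by_hand(self):
        # distances: d(AB)=0.1, d(AC)=d(BC)=0.5 -> AB first, C at 0.5
        sim = 1 - np.array([
            [0.0, 0.1, 0.5],
            [0.1, 0.0, 0.5],
            [0.5, 0.5, 0.0],
        ])
        link = average_linkage_cluster(sim)
        assert link[0, 2] == pytest.approx(0.1)
        assert sorted(link[0, :2]) == [0, 1]
        assert link[1, 2] == pytest.approx(0.5)

    def test_identical_items_merge_at_zero(self):
        sim = np.ones((4, 4))
        link = average_linkage_cluster(sim)
        np.testing.assert_allclose(link[:, 2], 0.0, atol=1e-12)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError):
            average_linkage_cluster(np.array([[1.0, 0.2], [0.5, 1.0]]))


class TestConfusionMetrics:
    def test_worked_example(self):
        # counts sum to 99; the plain formula gives 85/99 (~0.859, i.e. the
        # often-quoted 0.85 at one-count precision)
        out = confusion_metrics(46, 10, 4, 39)
        assert out["accuracy"] == pytest.approx(85 / 99, abs=1e-12)
        assert out["sensitivity"] == pytest.approx(46 / 50)
        assert out["specificity"] == pytest.approx(39 / 49)
        assert out["precision"] == pytest.approx(46 / 56)

    def test_perfect_tiny(self):
        assert confusion_metrics(1, 0, 0, 1)["accuracy"] == 1.0

    def test_zero_denominators_reported_missing(self):
        out = confusion_metrics(0, 0, 0, 5)
        assert out["accuracy"] == 1.0
        assert out["precision"] is None
        assert out["sensitivity"] is None

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            confusion_metrics(0, 0, 0, 0)
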
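"""Domain-pair support, randomization nulls, GO sharing, gold-standard metrics."""

import numpy as np
import pytest

from interolink import (
    DomainAnnotation,
    DomainPairSet,
    GOAnnotation,
    InteractionNetwork,
    InteractionTable,
    count_ipfam_supported,
    evaluate_against_gold,
    generate_gsn,
    go_sharing_fraction,
    random_pair_null,
    validate_network,
)
from interolink.validation import count_pairs_ipfam_supported


def _net(pairs):
    return InteractionNetwork.from_pairs(pairs, label="t")


class TestIpfamSupport:
    IPFAM = DomainPairSet([("D1", "D2")])

    def test_supported_edge_counted(self):
        anns = [DomainAnnotation("A", "D1", 1e-4), DomainAnnotation("B", "D2", 1e-4)]
        assert count_ipfam_supported(_net([("A", "B")]), anns, self.IPFAM) == 1

    def test_weak_evalue_not_counted(self):
        anns = [DomainAnnotation("A", "D1", 0.5), DomainAnnotation("B", "D2", 1e-4)]
        assert count_ipfam_supported(_net([("A", "B")]), anns, self.IPFAM) == 0

    def test_monotone_in_e_cutoff(self):
        anns = [
            DomainAnnotation("A", "D1", 0.005),
            DomainAnnotation("B", "D2", 0.05),
            DomainAnnotation("C", "D1", 0.5),
            DomainAnnotation("D", "D2", 1e-6),
        ]
        net = _net([("A", "B"), ("C", "D")])
        counts = [count_ipfam_supported(net, anns, self.IPFAM, e) for e in (0.001, 0.01, 0.1, 1.0)]
        assert counts == sorted(counts)

    def test_matches_double_loop_enumeration(self, rng):
        ids = [f"P{i}" for i in range(12)]
        anns = [
            DomainAnnotation(pid, f"D{rng.integers(4)}", float(rng.random()))
            for pid in ids
            for _ in range(rng.integers(0, 3))
        ]
        ipfam = DomainPairSet([("D0", "D1"), ("D2", "D2")])
        edges = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :] if rng.random() < 0.3]
        expected = 0
        for a, b in edges:
            da = {x.domain_id for x in anns if x.protein_id == a and x.e_value <= 0.05}
            db = {x.domain_id for x in anns if x.protein_id == b and x.e_value <= 0.05}
            if any((p, q) in ipfam for p in da for q in db):
                expected += 1
        assert count_pairs_ipfam_supported(edges, anns, ipfam, 0.05) == expected


class TestRandomPairNull:
    IDS = [f"P{i}" for i in range(30)]

    def test_never_exceeded_prints_zero(self):
        result = random_pair_null(self.IDS, 10, 100, lambda pairs: 0.0, observed=70.0, seed=1)
        assert result.empirical_p == 0.0
        assert result.formatted_p() == "0.000"

    def test_always_equalled_gives_one(self):
        result = random_pair_null(self.IDS, 5, 50, lambda pairs: 3.0, observed=3.0, seed=1)
        assert result.empirical_p == 1.0

    def test_deterministic_per_seed_and_no_self_pairs(self):
        seen = []

        def stat(pairs):
            assert all(a != b for a, b in pairs)
            seen.append(tuple(pairs))
            return float(len(set(pairs)))

        r1 = random_pair_null(self.IDS, 20, 10, stat, observed=5.0, seed=7)
        r2 = random_pair_null(self.IDS, 20, 10, stat, observed=5.0, seed=7)
        assert r1.null_samples == r2.null_samples
        assert len(r1.null_samples) == 10

    def test_p_on_discrete_grid(self):
        result = random_pair_null(self.IDS, 5, 20, lambda p: float(len(p)), observed=2.0, seed=0)
        assert result.empirical_p in {i / 20 for i in range(21)}

    def test_add_one_variant_never_zero(self):
        result = random_pair_null(
            self.IDS, 5, 99, lambda p: 0.0, observed=1.0, seed=0, add_one=True
        )
        assert result.empirical_p == pytest.approx(1 / 100)

    def test_tiny_proteome_rejected(self):
        with pytest.raises(ValueError):
            random_pair_null(["P1"], 5, 10, lambda p: 0.0, observed=0.0, seed=0)


class TestGoSharing:
    GO = [
        GOAnnotation("A", "GO:1", "biological_process"),
        GOAnnotation("B", "GO:1", "molecular_function"),
        GOAnnotation("C", "GO:2", "cellular_component"),
        GOAnnotation("D", "GO:3", "cellular_component"),
    ]

    def test_half_sharing(self):
        assert go_sharing_fraction(_net([("A", "B"), ("C", "D")]), self.GO) == pytest.approx(0.5)

    def test_full_sharing(self):
        assert go_sharing_fraction(_net([("A", "B")]), self.GO) == pytest.approx(1.0)

    def test_unannotated_endpoints_in_denominator_by_default(self):
        net = _net([("A", "B"), ("A", "ZZZ")])
        assert go_sharing_fraction(net, self.GO) == pytest.approx(0.5)
        assert go_sharing_fraction(net, self.GO, include_unannotated=False) == pytest.approx(1.0)

    def test_empty_network_undefined(self):
        with pytest.raises(ValueError):
            go_sharing_fraction(InteractionNetwork(), self.GO)

    def test_planted_sharing_probability_recovered(self, rng):
        go, edges = [], []
        for i in range(2000):
            a, b = f"L{i}", f"R{i}"
            edges.append((a, b))
            if rng.random() < 0.3:
                go.append(GOAnnotation(a, f"GO:{i}", "biological_process"))
                go.append(GOAnnotation(b, f"GO:{i}", "biological_process"))
        frac = go_sharing_fraction(_net(edges), go)
        assert frac == pytest.approx(0.3, abs=0.03)


class TestGoldStandard:
    def test_hand_computed_confusion(self):
        gsp = InteractionTable.from_pairs([(f"a{i}", f"b{i}") for i in range(10)])
        gsn = InteractionTable.from_pairs([(f"c{i}", f"d{i}") for i in range(10)])
        predicted = _net(
            [(f"a{i}", f"b{i}") for i in range(9)] + [("c0", "d0")]
        )  # TP=9 FN=1 FP=1 TN=9
        result = evaluate_against_gold(predicted, gsp, gsn)
        assert (result.confusion.tp, result.confusion.fn) == (9, 1)
        assert (result.confusion.fp, result.confusion.tn) == (1, 9)
        assert result.accuracy == pytest.approx(0.9)
        assert result.precision == pytest.approx(0.9)

    def test_perfect_oracle_predictor(self):
        gsp = InteractionTable.from_pairs([("a", "b"), ("c", "d")])
        gsn = InteractionTable.from_pairs([("e", "f")])
        result = evaluate_against_gold(_net(gsp.pairs), gsp, gsn)
        assert result.accuracy == 1.0 and result.precision == 1.0

    def test_all_positive_predictor_flags_undefined_component(self):
        gsp = InteractionTable.from_pairs([("a", "b"), ("c", "d")])
        gsn = InteractionTable.from_pairs([("e", "f")])
        result = evaluate_against_gold(_net(gsp.pairs + gsn.pairs), gsp, gsn)
        assert result.confusion.tn == 0 and result.confusion.fn == 0
        assert result.accuracy == pytest.approx(2 / 3)
        assert "non_ppi_precision_undefined" in result.flags
        assert result.precision == pytest.approx(result.precision_ppi)

    def test_label_swap_relations(self):
        """Swapping the gold sets turns positives counted among predictions
        into negatives: TP<->FP and FN<->TN, with total count conserved."""
        ids = [f"P{i}" for i in range(20)]
        gsp = InteractionTable.from_pairs([(ids[i], ids[i + 1]) for i in range(0, 10, 2)])
        gsn = InteractionTable.from_pairs([(ids[i], ids[i + 1]) for i in range(10, 20, 2)])
        predicted = _net(gsp.pairs[:2] + gsn.pairs[:1])
        fwd = evaluate_against_gold(predicted, gsp, gsn)
        rev = evaluate_against_gold(predicted, gsn, gsp)
        assert (rev.confusion.tp, rev.confusion.fn) == (fwd.confusion.fp, fwd.confusion.tn)
        assert (rev.confusion.fp, rev.confusion.tn) == (fwd.confusion.tp, fwd.confusion.fn)

    def test_overlapping_gold_sets_rejected(self):
        gsp = InteractionTable.from_pairs([("a", "b")])
        with pytest.raises(ValueError):
            evaluate_against_gold(_net([]), gsp, gsp)

    def test_gsn_generation_avoids_gsp(self):
        ids = [f"P{i}" for i in range(15)]
        gsp = InteractionTable.from_pairs([("P0", "P1"), ("P2", "P3")])
        gsn = generate_gsn(ids, 10, gsp, seed=3)
        assert len(gsn) == 10
        assert not (gsn.pair_set() & gsp.pair_set())


class TestFullBattery:
    def test_report_fields_present_and_consistent(self, bundle):
        net = _net(sorted(bundle.expected["merged"]))
        report = validate_network(
            net,
            "merged",
            bundle.target_ids,
            annotations=bundle.domain_annotations,
            ipfam=bundle.domain_pairs,
            go=bundle.go_annotations,
            gsp=bundle.gsp,
            gsn=bundle.gsn,
            reps_ipfam=20,
            reps_go=20,
            seed=5,
        )
        block = report.to_dict()
        assert block["ipfam_supported_count"] >= 1
        assert 0.0 <= report.go_sharing_fraction <= 1.0
        assert report.gold.confusion.fp == 0  # GSN drawn disjoint from predictions
        assert report.gold.confusion.fn == bundle.spec.n_gsp_extra
        assert report.ipfam_null.reps == 20
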
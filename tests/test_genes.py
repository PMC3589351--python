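"""Candidate-gene event counting and direction-bias tests."""

import numpy as np
import pandas as pd
import pytest

from concordia.genes import (
    average_frequency,
    background_frequency,
    classify_stability,
    count_direction_events,
    direction_bias_test,
    explode_catalog,
    validate_catalog,
)
from concordia.synthetic import CatalogSpec, CohortSpec, generate_catalog_and_mutations, generate_expression_pair
from conftest import calls_frame


def _catalog(rows):
    return pd.DataFrame(
        rows, columns=["gene", "role", "stability", "cancer_types"]
    )


def _cna_calls(rows, dataset="A"):
    return calls_frame(rows, dataset=dataset, modality="cna")


def build_cna_fixture():
    """Five cancers of candidate CNA events.

    Oncogenes: 14 amplification events over 12 genes (two genes amplified in
    two cancers each) and 13 deletion events over 11 genes (two genes
    deleted in two cancers). TSGs: 23 deletion events over 16 genes, no
    amplifications.
    """
    cancers = [f"c{i}" for i in range(1, 6)]
    onco_amp = [f"OA{i}" for i in range(12)]
    onco_del = [f"OD{i}" for i in range(11)]
    tsg = [f"TS{i}" for i in range(16)]

    cat_rows = []
    events: dict[tuple, list] = {(c, "cna"): [] for c in cancers}

    def place(genes, extra_events, direction, role, prefix_cancers):
        # each gene gets one event in its home cancer; the first
        # `extra_events` genes get a second event in the next cancer
        for i, g in enumerate(genes):
            home = cancers[i % len(cancers)]
            cts = [home]
            events[(home, "cna")].append((g, direction))
            if i < extra_events:
                second = cancers[(i + 1) % len(cancers)]
                cts.append(second)
                events[(second, "cna")].append((g, direction))
            cat_rows.append(
                {
                    "gene": g,
                    "role": role,
                    "stability": False,
                    "cancer_types": tuple(cts),
                }
            )

    place(onco_amp, 2, 1, "oncogene", cancers)  # 12 + 2 = 14 amp events
    place(onco_del, 2, -1, "oncogene", cancers)  # 11 + 2 = 13 del events
    place(tsg, 7, -1, "TSG", cancers)  # 16 + 7 = 23 del events

    catalog = _catalog(cat_rows)
    merged = {
        key: _cna_calls(rows, dataset=key[0]) for key, rows in events.items() if rows
    }
    return catalog, merged


class TestCatalog:
    def test_classify_stability_from_annotation(self):
        cat = _catalog(
            [
                {"gene": "g1", "role": "TSG", "stability": False, "cancer_types": ("c1",)},
                {"gene": "g2", "role": "TSG", "stability": True, "cancer_types": ("c1",)},
            ]
        )
        out = classify_stability(cat, ["g1"])
        assert out.set_index("gene")["stability"].to_dict() == {"g1": True, "g2": False}
        empty = classify_stability(cat, [])
        assert not empty["stability"].any()

    def test_dual_role_gene_rejected(self):
        cat = _catalog(
            [
                {"gene": "g1", "role": "oncogene", "stability": False, "cancer_types": ("c1",)},
                {"gene": "g1", "role": "TSG", "stability": False, "cancer_types": ("c1",)},
            ]
        )
        with pytest.raises(ValueError, match="both oncogene and TSG"):
            validate_catalog(cat)

    def test_explode_one_row_per_gene_cancer(self):
        cat = _catalog(
            [{"gene": "g1", "role": "oncogene", "stability": False, "cancer_types": ("c1", "c2")}]
        )
        long = explode_catalog(cat)
        assert len(long) == 2
        assert set(long["cancer_type"]) == {"c1", "c2"}


class TestEvents:
    def test_candidate_event_counts_and_distinct_genes(self):
        catalog, merged = build_cna_fixture()
        events = count_direction_events(merged, catalog)
        onco = events[events["role"] == "oncogene"]
        amp = onco[onco["direction"] == "amp"]
        dele = onco[onco["direction"] == "del"]
        assert len(amp) == 14 and amp["gene"].nunique() == 12
        assert len(dele) == 13 and dele["gene"].nunique() == 11
        tsg = events[events["role"] == "TSG"]
        assert len(tsg) == 23 and tsg["gene"].nunique() == 16
        assert (tsg["direction"] == "del").all()

    def test_non_candidate_calls_produce_no_events(self):
        catalog = _catalog(
            [{"gene": "g1", "role": "oncogene", "stability": False, "cancer_types": ("c1",)}]
        )
        merged = {("c1", "cna"): _cna_calls([("other", 1)])}
        assert len(count_direction_events(merged, catalog)) == 0

    def test_event_in_wrong_cancer_type_not_counted(self):
        catalog = _catalog(
            [{"gene": "g1", "role": "oncogene", "stability": False, "cancer_types": ("c1",)}]
        )
        merged = {("c2", "cna"): _cna_calls([("g1", 1)])}
        assert len(count_direction_events(merged, catalog)) == 0

    def test_row_order_invariance(self):
        catalog, merged = build_cna_fixture()
        shuffled = {
            k: v.sample(frac=1.0, random_state=3).reset_index(drop=True)
            for k, v in merged.items()
        }
        e1 = count_direction_events(merged, catalog)
        e2 = count_direction_events(shuffled, catalog)
        key = ["gene", "cancer_type", "modality"]
        pd.testing.assert_frame_equal(
            e1.sort_values(key).reset_index(drop=True),
            e2.sort_values(key).reset_index(drop=True),
        )


class TestBias:
    def test_all_deletion_tsg_class(self):
        catalog, merged = build_cna_fixture()
        events = count_direction_events(merged, catalog)
        res = direction_bias_test(events, "del", role="TSG", modality="cna")
        assert (res.n_total, res.n_favored, res.frequency) == (23, 23, 1.0)
        assert res.p_value == pytest.approx(1.19e-7, rel=0.005)

    def test_balanced_oncogene_cna_events(self):
        catalog, merged = build_cna_fixture()
        events = count_direction_events(merged, catalog)
        res = direction_bias_test(events, "amp", role="oncogene", modality="cna")
        assert (res.n_total, res.n_favored) == (27, 14)
        assert res.p_value == pytest.approx(0.5)

    def test_zero_events_flagged_undefined(self):
        res = direction_bias_test(
            pd.DataFrame(columns=["gene", "cancer_type", "modality", "direction", "role", "stability"]),
            "amp",
        )
        assert res.empty and res.frequency is None and res.p_value is None

    def test_one_direction_only(self):
        catalog, merged = build_cna_fixture()
        events = count_direction_events(merged, catalog)
        tsg_amp = direction_bias_test(events, "amp", role="TSG", modality="cna")
        assert tsg_amp.n_favored == 0 and tsg_amp.frequency == 0.0

    def test_recovers_planted_class_bias(self):
        # plant a class whose events favor one direction at rate ~0.8
        rng = np.random.default_rng(0)
        n = 200
        dirs = np.where(rng.random(n) < 0.8, "del", "amp")
        events = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n)],
                "cancer_type": "c1",
                "modality": "cna",
                "direction": dirs,
                "role": "TSG",
                "stability": False,
            }
        )
        res = direction_bias_test(events, "del", role="TSG")
        from scipy.stats import binom

        lo, hi = binom.interval(0.999, n, 0.8)
        assert lo <= res.n_favored <= hi


class TestFrequencies:
    def test_background_fraction_of_all_retained_genes(self):
        merged = calls_frame([("a", 1), ("b", 1), ("c", -1), ("d", 1)])
        assert background_frequency(merged, 1) == pytest.approx(0.75)
        assert background_frequency(merged, -1) == pytest.approx(0.25)
        assert background_frequency(calls_frame([]), 1) is None

    def test_pooled_and_per_cancer_mean_reported_side_by_side(self):
        per_cancer = {"c1": (9, 10), "c2": (1, 2)}
        out = average_frequency(per_cancer)
        assert out["pooled"] == pytest.approx(10 / 12)
        assert out["per_cancer_mean"] == pytest.approx((0.9 + 0.5) / 2)
        assert out["n_events"] == 12

    def test_zero_event_cancers_excluded_from_mean(self):
        out = average_frequency({"c1": (2, 4), "c2": (0, 0)})
        assert out["per_cancer_mean"] == pytest.approx(0.5)
        assert out["n_cancers"] == 1


def test_synthetic_catalog_round_trip_through_events(planted_pair):
    spec, _ = planted_pair
    pair = generate_expression_pair(
        CohortSpec(n_genes=300, n_cancer=10, n_normal=10, frac_de=0.5, seed=21)
    )
    catalog, _ = generate_catalog_and_mutations(
        CatalogSpec(n_oncogenes=10, n_tsgs=10, mutation_rate=0.0), pair, "c1", seed=22
    )
    truth = pair.truth.set_index("gene")
    rows = [
        (g, int(truth.at[g, "direction_a"]))
        for g in catalog["gene"]
        if truth.at[g, "planted"]
    ]
    merged = {("c1", "expression"): calls_frame(rows)}
    events = count_direction_events(merged, catalog)
    assert len(events) == len(rows)
    assert set(events["gene"]) <= set(catalog["gene"])
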
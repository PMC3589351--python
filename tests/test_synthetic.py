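"""Generator contracts: determinism, planted truth, null behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, ttest_ind

from concordia.cna import gscores
from concordia.methylation import compute_beta
from concordia.synthetic import (
    CatalogSpec,
    CohortSpec,
    generate_catalog_and_mutations,
    generate_cna_profiles,
    generate_expression_pair,
    generate_methylation_pair,
)


class TestSpecs:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_cancer=1)
        with pytest.raises(ValueError):
            CohortSpec(frac_de=1.5)
        with pytest.raises(ValueError):
            CohortSpec(noise_sd=0.0)
        with pytest.raises(ValueError):
            CohortSpec(n_genes=100, frac_de=0.001)  # < 1 gene would be planted
        with pytest.raises(ValueError):
            CatalogSpec(mutation_rate=-0.1)


class TestExpression:
    def test_same_seed_identical_output(self):
        spec = CohortSpec(n_genes=300, seed=42)
        p1 = generate_expression_pair(spec)
        p2 = generate_expression_pair(spec)
        pd.testing.assert_frame_equal(p1.cohort_a.values, p2.cohort_a.values)
        pd.testing.assert_frame_equal(p1.cohort_b.values, p2.cohort_b.values)
        pd.testing.assert_frame_equal(p1.truth, p2.truth)

    def test_full_consistency_forces_agreement(self):
        spec = CohortSpec(n_genes=500, frac_de=0.2, consistency=1.0, seed=1)
        truth = generate_expression_pair(spec).truth
        planted = truth[truth["planted"]]
        assert (planted["direction_a"] == planted["direction_b"]).all()

    def test_null_generator_plants_nothing(self):
        spec = CohortSpec(n_genes=400, frac_de=0.0, seed=2)
        pair = generate_expression_pair(spec)
        assert not pair.truth["planted"].any()
        # group means coincide up to noise for every gene
        diff = (
            pair.cohort_a.group("cancer").mean(axis=1)
            - pair.cohort_a.group("normal").mean(axis=1)
        )
        se = spec.noise_sd * np.sqrt(1 / spec.n_cancer + 1 / spec.n_normal)
        assert (diff.abs() < 5 * se).all()

    def test_planted_count_and_shift_magnitude(self, planted_pair):
        spec, pair = planted_pair
        truth = pair.truth
        assert truth["planted"].sum() == round(spec.frac_de * spec.n_genes)
        planted = truth[truth["planted"]].set_index("gene")
        diff = (
            pair.cohort_a.group("cancer").mean(axis=1)
            - pair.cohort_a.group("normal").mean(axis=1)
        )
        observed = diff[planted.index] * planted["direction_a"]
        se = 3 * spec.noise_sd * np.sqrt(1 / spec.n_cancer + 1 / spec.n_normal)
        assert (np.abs(observed - spec.effect_size) < 3 * se).mean() > 0.98

    def test_planted_agreement_within_binomial_interval(self, planted_pair):
        spec, pair = planted_pair
        planted = pair.truth[pair.truth["planted"]]
        agree = int((planted["direction_a"] == planted["direction_b"]).sum())
        lo, hi = binom.interval(0.95, len(planted), spec.consistency)
        assert lo <= agree <= hi


class TestMethylation:
    def test_null_betas_balanced(self):
        spec = CohortSpec(
            n_genes=300, frac_de=0.0, effect_size=0.2, noise_sd=0.05, seed=3
        )
        pair = generate_methylation_pair(spec)
        diff = (
            pair.cohort_a.group("cancer").mean(axis=1)
            - pair.cohort_a.group("normal").mean(axis=1)
        )
        assert diff.abs().max() < 0.1

    def test_um_tables_reproduce_beta_matrix(self):
        spec = CohortSpec(
            n_genes=50, n_cancer=5, n_normal=5, frac_de=0.1, effect_size=0.2,
            noise_sd=0.05, seed=4,
        )
        pair = generate_methylation_pair(spec)
        um = pair.extra["um_tables"]["A"]
        assert (um[["U", "M"]] >= 0).all().all()
        beta = compute_beta(um["U"].values, um["M"].values)
        um = um.assign(beta=beta)
        pivot = um.pivot(index="probe", columns="sample", values="beta")
        pmap = pair.extra["probe_map"]
        pivot.index = pmap.reindex(pivot.index).values
        recon = pivot.loc[pair.cohort_a.features, pair.cohort_a.samples]
        np.testing.assert_allclose(recon.values, pair.cohort_a.values.values, atol=1e-9)

    def test_planted_shift_recovered_within_three_se(self):
        spec = CohortSpec(
            n_genes=500, n_cancer=30, n_normal=30, frac_de=0.1, effect_size=0.2,
            noise_sd=0.05, consistency=1.0, seed=6,
        )
        pair = generate_methylation_pair(spec)
        truth = pair.truth[pair.truth["planted"] & (pair.truth["direction_a"] == 1)]
        baseline = pair.cohort_a.group("normal").mean(axis=1)
        diff = (pair.cohort_a.group("cancer").mean(axis=1) - baseline)[truth["gene"]]
        # probes whose shifted beta hits the clip boundary are attenuated by design
        unclipped = baseline[truth["gene"]] + spec.effect_size < 0.9
        se = spec.noise_sd * np.sqrt(1 / spec.n_cancer + 1 / spec.n_normal)
        assert ((diff[unclipped] - 0.2).abs() < 3 * se).mean() > 0.95


class TestCna:
    def test_saturated_segment_is_gscore_maximum(self):
        spec = CohortSpec(
            n_genes=300, n_cancer=20, frac_de=0.05, effect_size=1.0, noise_sd=0.05, seed=8
        )
        pair = generate_cna_profiles(spec, segment_length=15, carrier_frac=1.0)
        seg = pair.truth.iloc[0]
        kind = "amplification" if seg["direction_a"] > 0 else "deletion"
        g = gscores(pair.cohort_a.values.to_numpy(), kind)
        inside = np.zeros(len(g), dtype=bool)
        inside[seg["segment_start"] : seg["segment_end"]] = True
        assert g[inside].min() > g[~inside].max()

    def test_partial_carriers_give_freq_times_amplitude(self):
        spec = CohortSpec(
            n_genes=500, n_cancer=100, frac_de=0.05, effect_size=0.8, noise_sd=0.05,
            consistency=1.0, seed=5,
        )
        pair = generate_cna_profiles(spec, segment_length=25, carrier_frac=0.4)
        amp_segs = pair.truth[pair.truth["direction_a"] > 0]
        g = gscores(pair.cohort_a.values.to_numpy(), "amplification")
        for seg in amp_segs.itertuples():
            mean_g = g[seg.segment_start : seg.segment_end].mean()
            assert mean_g == pytest.approx(0.4 * 0.8, rel=0.1)

    def test_marker_gene_map_covers_all_markers(self):
        spec = CohortSpec(n_genes=200, n_cancer=10, frac_de=0.1, seed=9)
        pair = generate_cna_profiles(spec, segment_length=10)
        assert list(pair.gene_map.index) == list(pair.cohort_a.features)


class TestCatalogAndMutations:
    def test_zero_mutation_rate_all_wild_type(self):
        spec = CohortSpec(n_genes=100, n_cancer=10, n_normal=10, frac_de=0.1, seed=1)
        pair = generate_expression_pair(spec)
        _, ann = generate_catalog_and_mutations(
            CatalogSpec(n_oncogenes=5, n_tsgs=5, mutation_rate=0.0), pair, seed=2
        )
        assert (ann["mclass"] == "wild_type").all()

    def test_stability_fraction_exact(self):
        spec = CohortSpec(n_genes=200, n_cancer=10, n_normal=10, frac_de=0.1, seed=1)
        pair = generate_expression_pair(spec)
        catalog, _ = generate_catalog_and_mutations(
            CatalogSpec(n_oncogenes=5, n_tsgs=10, frac_stability=0.3), pair, seed=3
        )
        tsgs = catalog[catalog["role"] == "TSG"]
        assert tsgs["stability"].sum() == 3
        assert not catalog.loc[catalog["role"] == "oncogene", "stability"].any()

    def test_all_tsgs_flagged_when_fraction_one(self):
        spec = CohortSpec(n_genes=100, n_cancer=10, n_normal=10, frac_de=0.1, seed=1)
        pair = generate_expression_pair(spec)
        catalog, _ = generate_catalog_and_mutations(
            CatalogSpec(n_oncogenes=3, n_tsgs=7, frac_stability=1.0), pair, seed=4
        )
        assert catalog.loc[catalog["role"] == "TSG", "stability"].all()

    def test_activating_shift_detectable_in_stratum(self):
        spec = CohortSpec(
            n_genes=100, n_cancer=60, n_normal=20, frac_de=0.0, noise_sd=0.5, seed=11
        )
        pair = generate_expression_pair(spec)
        cspec = CatalogSpec(
            n_oncogenes=3, n_tsgs=0, mutation_rate=0.5, activating_shift=2.0
        )
        catalog, ann = generate_catalog_and_mutations(cspec, pair, seed=12)
        gene = catalog["gene"].iloc[0]
        act = ann[(ann["gene"] == gene) & (ann["mclass"] == "activating")]["sample"]
        normals = pair.cohort_a.group("normal").loc[gene]
        stratum = pair.cohort_a.values.loc[gene, act]
        assert len(stratum) >= 2
        res = ttest_ind(stratum, normals)
        assert stratum.mean() > normals.mean()
        assert res.pvalue < 0.05
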
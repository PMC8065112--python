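"""Cancer fractions, dominance calls, polyclonality, hotspot variation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctclone import (
    PatientProfile,
    annotate_clonality,
    compute_mvaf,
    dual_mutation_linkage,
    gene_dominance_table,
    gene_dominance_test,
    hotspot_cf_variation,
    polyclonality_summary,
    polyclonality_table,
)
from ctclone.io import Cohort

from conftest import fisher_oracle, make_cohort, make_variant


class TestMvaf:
    def test_maximum_over_variants(self):
        p = PatientProfile("P1", variants=[make_variant(vaf=v) for v in (4.0, 12.5, 0.3)])
        assert compute_mvaf(p) == 12.5

    def test_single_variant(self):
        p = PatientProfile("P1", variants=[make_variant(vaf=7.0)])
        assert compute_mvaf(p) == 7.0

    def test_no_variants_is_absent(self):
        assert compute_mvaf(PatientProfile("P1")) is None

    def test_pathogenic_only_switch(self):
        p = PatientProfile(
            "P1",
            variants=[
                make_variant(vaf=20.0, pathogenic="non-pathogenic"),
                make_variant(vaf=5.0, pathogenic="pathogenic"),
            ],
        )
        assert compute_mvaf(p) == 20.0
        assert compute_mvaf(p, pathogenic_only=True) == 5.0


class TestAnnotateClonality:
    def test_ratio_and_dominance(self):
        p = PatientProfile("P1", variants=[make_variant(vaf=20.0), make_variant(vaf=5.0)])
        ann = annotate_clonality(p)
        assert ann[0].cancer_fraction == pytest.approx(1.0)
        assert ann[0].dominance == "dominant"
        assert ann[1].cancer_fraction == pytest.approx(0.25)
        assert ann[1].dominance == "subclonal"

    def test_cf_exactly_half_is_dominant(self):
        p = PatientProfile("P1", variants=[make_variant(vaf=20.0), make_variant(vaf=10.0)])
        assert annotate_clonality(p)[1].dominance == "dominant"

    def test_single_variant_not_assessable(self):
        p = PatientProfile("P1", variants=[make_variant(vaf=7.0)])
        ann = annotate_clonality(p)
        assert ann[0].dominance == "not_assessable"
        assert ann[0].cancer_fraction is None

    def test_zero_mvaf_with_variants_is_error(self):
        p = PatientProfile("P1", variants=[make_variant(vaf=0.0), make_variant(vaf=0.0)])
        with pytest.raises(ValueError, match="mVAF is 0"):
            annotate_clonality(p)

    def test_all_maximal_variants_have_cf_one(self):
        p = PatientProfile("P1", variants=[make_variant(vaf=8.0) for _ in range(3)])
        assert all(a.cancer_fraction == pytest.approx(1.0) for a in annotate_clonality(p))

    @given(
        st.lists(st.floats(min_value=0.01, max_value=50, allow_nan=False), min_size=2, max_size=8),
        st.floats(min_value=0.1, max_value=2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, vafs, factor):
        """Multiplying all VAFs by a constant leaves CFs and dominance unchanged."""
        p1 = PatientProfile("P1", variants=[make_variant(vaf=v) for v in vafs])
        p2 = PatientProfile("P2", variants=[make_variant(vaf=v * factor) for v in vafs])
        a1, a2 = annotate_clonality(p1), annotate_clonality(p2)
        for x, y in zip(a1, a2):
            assert x.cancer_fraction == pytest.approx(y.cancer_fraction, rel=1e-9)
            assert x.dominance == y.dominance


class TestGeneDominance:
    def _cohort(self, gene_a_cf=1.0, n=6):
        """n patients each with a gene-A mutation at gene_a_cf and background at 0.2."""
        patients = {}
        for i in range(n):
            pid = f"P{i}"
            patients[pid] = [
                make_variant(pid, gene="TRUNK", vaf=10.0),
                make_variant(pid, gene="GENEA", vaf=10.0 * gene_a_cf),
                make_variant(pid, gene="OTHER", vaf=2.0),
            ]
        return make_cohort(patients)

    def test_constructed_dominant_gene_flagged(self):
        summary = gene_dominance_test(self._cohort(), "GENEA")
        assert summary.direction == "more dominant"
        assert summary.p_value < 0.05
        assert summary.n_dominant == 6 and summary.n_subclonal == 0

    def test_absent_gene_is_error(self):
        with pytest.raises(ValueError, match="NOSUCH"):
            gene_dominance_test(self._cohort(), "NOSUCH")

    def test_single_observation_runs_with_wide_p(self):
        cohort = self._cohort()
        cohort.add(
            PatientProfile(
                "PX",
                variants=[
                    make_variant("PX", gene="TRUNK", vaf=10.0),
                    make_variant("PX", gene="RARE", vaf=5.0),
                ],
            )
        )
        summary = gene_dominance_test(cohort, "RARE")
        assert 0.0 < summary.p_value <= 1.0

    def test_null_gene_rarely_significant(self):
        """A gene whose CFs are drawn like the background keeps p >= 0.05 in
        at least 90% of seeded replicates (genes assigned independently of
        VAF, so every gene shares one CF distribution)."""
        rng = np.random.default_rng(42)
        genes = ["GENEA", "OTHER1", "OTHER2", "OTHER3"]
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            patients = {}
            for i in range(40):
                pid = f"P{i}"
                vafs = rng.uniform(0.5, 20.0, size=3)
                labels = rng.choice(genes, size=3)
                patients[pid] = [
                    make_variant(pid, gene=g, vaf=v) for g, v in zip(labels, vafs)
                ]
            cohort = make_cohort(patients)
            try:
                summary = gene_dominance_test(cohort, "GENEA")
            except ValueError:  # GENEA happened to be absent this replicate
                continue
            hits += summary.p_value < 0.05
        assert hits <= 0.10 * n_rep

    def test_q_values_dominate_p_values(self, default_cohort):
        cohort, _ = default_cohort
        table = gene_dominance_table(cohort)
        assert (table["q"] >= table["p"] - 1e-12).all()
        assert (table["n_dominant"] + table["n_subclonal"] == table["n"]).all()


class TestPolyclonality:
    def _cohort(self):
        patients = {
            # multiple ESR1 mutations in one patient
            "P1": [
                make_variant("P1", gene="ESR1", vaf=10.0, protein_change="D538G",
                             pathogenic="pathogenic"),
                make_variant("P1", gene="ESR1", vaf=3.0, protein_change="Y537S",
                             pathogenic="pathogenic"),
            ],
            "P2": [
                make_variant("P2", gene="ESR1", vaf=8.0, protein_change="D538G",
                             pathogenic="pathogenic"),
            ],
            "P3": [
                make_variant("P3", gene="AKT1", vaf=9.0, protein_change="E17K",
                             pathogenic="pathogenic"),
            ],
        }
        return make_cohort(patients)

    def test_single_vs_multiple_counts(self):
        row = polyclonality_summary(self._cohort(), "ESR1")
        assert (row["n_single"], row["n_multiple"]) == (1, 1)

    def test_gene_mutated_once_per_carrier(self):
        row = polyclonality_summary(self._cohort(), "AKT1")
        assert row["fraction_multiple"] == 0.0

    def test_fisher_matches_enumeration_oracle(self):
        """The constructed 2x2 [[10,10],[90,10]] must give the exact
        hypergeometric enumeration p-value."""
        patients = {}
        k = 0
        # gene G: 10 multiple, 10 single carriers; gene H: 10 multiple, 90 single
        for n_multi, n_single, gene in ((10, 10, "G"), (10, 90, "H")):
            for _ in range(n_multi):
                pid = f"P{k}"; k += 1
                patients[pid] = [
                    make_variant(pid, gene=gene, vaf=10.0, protein_change="A1B",
                                 pathogenic="pathogenic"),
                    make_variant(pid, gene=gene, vaf=5.0, protein_change="C2D",
                                 pathogenic="pathogenic"),
                ]
            for _ in range(n_single):
                pid = f"P{k}"; k += 1
                patients[pid] = [
                    make_variant(pid, gene=gene, vaf=10.0, protein_change="A1B",
                                 pathogenic="pathogenic"),
                ]
        row = polyclonality_summary(make_cohort(patients), "G")
        assert row["p"] == pytest.approx(fisher_oracle(10, 10, 10, 90), abs=1e-12)

    def test_unclassified_cohort_raises_with_guidance(self):
        cohort = make_cohort({"P1": [make_variant()]})
        with pytest.raises(ValueError, match="classify_cohort"):
            polyclonality_table(cohort)


class TestHotspotVariation:
    def _cohort(self, counts):
        """counts: list of (protein_change, variant_class, cf values)."""
        patients = {}
        k = 0
        for change, vclass, cfs in counts:
            for cf in cfs:
                pid = f"P{k}"; k += 1
                patients[pid] = [
                    make_variant(pid, gene="TRUNK", vaf=10.0, protein_change="TRUNCAL",
                                 pathogenic="pathogenic"),
                    make_variant(
                        pid, gene="PIK3CA", vaf=10.0 * cf, protein_change=change,
                        variant_class=vclass, pathogenic="pathogenic",
                        ref="C" if vclass == "missense" else "A",
                        alt="T" if vclass == "missense" else "AT",
                        context3="ACA" if vclass == "missense" else None,
                    ),
                ]
        return make_cohort(patients)

    def test_separated_hotspots_detected(self):
        res = hotspot_cf_variation(
            self._cohort(
                [("H1047R", "missense", [0.9, 0.9, 0.9]), ("E545K", "missense", [0.1, 0.1, 0.1])]
            ),
            "PIK3CA",
        )
        assert res.p_value < 0.05

    def test_rare_snv_hotspot_excluded_but_indel_included(self):
        res = hotspot_cf_variation(
            self._cohort(
                [
                    ("H1047R", "missense", [0.9, 0.8, 0.7]),
                    ("E545K", "missense", [0.3, 0.2]),      # SNV below min_count
                    ("E109del", "in-frame indel", [0.4]),     # any indel included
                ]
            ),
            "PIK3CA",
        )
        assert set(res.cf_by_hotspot) == {"H1047R", "E109del"}

    def test_fewer_than_two_hotspots_is_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            hotspot_cf_variation(
                self._cohort([("H1047R", "missense", [0.9, 0.8, 0.7])]), "PIK3CA"
            )


class TestDualMutationLinkage:
    def _cohort(self, anchor_cfs, partner_cfs):
        patients = {}
        for i, (a_cf, p_cf) in enumerate(zip(anchor_cfs, partner_cfs)):
            pid = f"P{i}"
            patients[pid] = [
                make_variant(pid, gene="PIK3CA", vaf=20.0 * a_cf, protein_change="H1047R",
                             pathogenic="pathogenic"),
                make_variant(pid, gene="PIK3CA", vaf=20.0 * p_cf, protein_change="E726K",
                             pathogenic="pathogenic"),
                make_variant(pid, gene="TRUNK", vaf=20.0, protein_change="X1X",
                             pathogenic="pathogenic"),
            ]
        return make_cohort(patients)

    def test_dominant_anchor_detected(self):
        res = dual_mutation_linkage(
            self._cohort([0.9, 0.8, 0.95], [0.1, 0.2, 0.15]), "PIK3CA", "H1047R"
        )
        assert len(res.pairs) == 3
        assert res.p_value < 0.05
        assert (res.pairs["anchor_cf"] > res.pairs["partner_cf"]).all()

    def test_symmetric_pairs_give_p_one(self):
        res = dual_mutation_linkage(
            self._cohort([0.3, 0.5, 0.7], [0.3, 0.5, 0.7]), "PIK3CA", "H1047R"
        )
        assert res.p_value == pytest.approx(1.0)

    def test_anchor_only_patients_excluded(self):
        cohort = self._cohort([0.9], [0.1])
        cohort.add(
            PatientProfile(
                "PX",
                variants=[
                    make_variant("PX", gene="PIK3CA", vaf=10.0, protein_change="H1047R",
                                 pathogenic="pathogenic"),
                    make_variant("PX", gene="TRUNK", vaf=12.0, protein_change="X1X",
                                 pathogenic="pathogenic"),
                ],
            )
        )
        res = dual_mutation_linkage(cohort, "PIK3CA", "H1047R")
        assert set(res.pairs["patient_id"]) == {"P0"}

    def test_no_qualifying_patients_gives_empty_result(self):
        cohort = make_cohort(
            {"P1": [make_variant("P1", gene="PIK3CA", vaf=5.0, protein_change="E545K",
                                 pathogenic="pathogenic"),
                    make_variant("P1", gene="TRUNK", vaf=9.0, pathogenic="pathogenic")]}
        )
        res = dual_mutation_linkage(cohort, "PIK3CA", "H1047R")
        assert res.pairs.empty and res.p_value is None
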
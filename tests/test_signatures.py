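"""Catalogues, exposure refitting, bootstrap, condition comparison, APOBEC."""

import numpy as np
import pandas as pd
import pytest

from ctclone import (
    MutationCatalogue,
    PatientProfile,
    SignatureDeconvolution,
    aggregate_clonal_subclonal,
    apobec_dominance_analysis,
    bootstrap_exposures,
    compare_conditions,
    fit_exposures,
    generate_signature_mixture,
    read_signature_matrix,
    snv_channel,
)
from ctclone.channels import CHANNELS, revcomp
from ctclone.io import Cohort

from conftest import fisher_oracle, make_cohort, make_variant


def _variant_from_channel(pid, channel, vaf, gene="SYN", pos=None, flip=False, **kw):
    label = CHANNELS[channel]
    ref, alt = label[2], label[4]
    ctx = label[0] + label[2] + label[6]
    if flip:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        ref, alt, ctx = comp[ref], comp[alt], revcomp(ctx)
    return make_variant(pid, gene=gene, vaf=vaf, ref=ref, alt=alt, context3=ctx,
                        pos=pos, **kw)


class TestCatalogue:
    def test_counts_conserved(self):
        channels = [0, 0, 5, 95, 33]
        cat = MutationCatalogue.from_channels(channels)
        assert cat.total == len(channels)
        assert cat.counts[0] == 2

    def test_strand_flip_leaves_catalogue_unchanged(self):
        rng = np.random.default_rng(0)
        channels = rng.integers(0, 96, 50)
        plus = [_variant_from_channel(f"P{i}", ch, 5.0) for i, ch in enumerate(channels)]
        minus = [_variant_from_channel(f"P{i}", ch, 5.0, flip=True) for i, ch in enumerate(channels)]
        a = MutationCatalogue.from_variants(plus)
        b = MutationCatalogue.from_variants(minus)
        assert (a.counts == b.counts).all()

    def test_non_snvs_and_missing_contexts_skipped(self):
        variants = [
            _variant_from_channel("P1", 10, 5.0),
            make_variant("P1", ref="A", alt="AT", context3=None, variant_class="frameshift"),
            make_variant("P1", context3=None),
        ]
        assert MutationCatalogue.from_variants(variants).total == 1

    def test_tsv_roundtrip(self, tmp_path):
        cat = MutationCatalogue.from_channels([1, 1, 2, 90])
        cat.write_tsv(tmp_path / "cat.tsv")
        again = MutationCatalogue.read_tsv(tmp_path / "cat.tsv")
        assert (again.counts == cat.counts).all()


def test_cosmic_layout_signature_matrix_roundtrip(tmp_path, signatures):
    frame = signatures.to_frame().reset_index(names="label")
    frame.insert(0, "Substitution Type", [lab[2:5] for lab in frame["label"]])
    frame.insert(1, "Trinucleotide", [lab[0] + lab[2] + lab[6] for lab in frame["label"]])
    frame = frame.drop(columns=["label"]).sample(frac=1.0, random_state=0)  # shuffle rows
    frame.to_csv(tmp_path / "sigs.tsv", sep="\t", index=False)
    again = read_signature_matrix(tmp_path / "sigs.tsv")
    assert again.names == signatures.names
    assert np.allclose(again.probs, signatures.probs)


class TestAggregation:
    def _profile(self, pid, site_specs):
        """site_specs: list of (pos, cf) sharing a truncal anchor at vaf 10."""
        variants = [_variant_from_channel(pid, 3, 10.0, pos=999_999)]
        variants += [
            _variant_from_channel(pid, 7, 10.0 * cf, pos=pos) for pos, cf in site_specs
        ]
        return PatientProfile(pid, variants=variants)

    def test_shared_dominant_site_counted_once(self):
        cohort = Cohort([self._profile("P1", [(5, 0.9)]), self._profile("P2", [(5, 0.8)])])
        sets = aggregate_clonal_subclonal(cohort)
        assert sum(1 for s in sets.clonal.sites if s[1] == 5) == 1

    def test_split_site_counted_in_both_sets(self):
        cohort = Cohort([self._profile("P1", [(5, 0.9)]), self._profile("P2", [(5, 0.2)])])
        sets = aggregate_clonal_subclonal(cohort)
        assert any(s[1] == 5 for s in sets.clonal.sites)
        assert any(s[1] == 5 for s in sets.subclonal.sites)

    def test_not_assessable_contributes_to_neither(self):
        single = PatientProfile("P1", variants=[_variant_from_channel("P1", 4, 9.0, pos=5)])
        sets = aggregate_clonal_subclonal(Cohort([single]))
        assert len(sets.clonal) == 0 and len(sets.subclonal) == 0

    def test_unclassified_variants_still_enter(self):
        """Signature aggregation ignores pathogenicity entirely."""
        p = self._profile("P1", [(5, 0.4)])
        for v in p.variants:
            v.pathogenic = "non-pathogenic"
        sets = aggregate_clonal_subclonal(Cohort([p]))
        assert len(sets.clonal) + len(sets.subclonal) == 2


class TestExposureFitting:
    def test_exact_member_recovery(self, signatures):
        cat = MutationCatalogue(np.round(signatures.probs[:, 0] * 1e5).astype(int))
        res = fit_exposures(cat, signatures)
        assert res.weights["Signature 1"] >= 0.99
        assert (res.weights.drop("Signature 1") == 0).all()

    @pytest.mark.parametrize("seed", [7, 19])
    def test_two_signature_mixture_recovery(self, signatures, seed):
        truth = np.array([0.7, 0.0, 0.0, 0.0, 0.3])
        _, cat = generate_signature_mixture(signatures, truth, 1000, seed=seed)
        res = fit_exposures(cat, signatures)
        assert np.abs(res.weights.to_numpy() - truth).max() < 0.05

    def test_minor_component_below_threshold_discarded(self, signatures):
        truth = np.array([0.97, 0.0, 0.0, 0.0, 0.03])
        _, cat = generate_signature_mixture(signatures, truth, 5000, seed=2)
        res = fit_exposures(cat, signatures)
        assert res.weights["Signature 13"] == 0.0
        assert res.weights["Signature 1"] > 0.9

    def test_absent_signature_converges_to_zero(self, signatures):
        truth = np.array([0.6, 0.0, 0.0, 0.4, 0.0])
        for n in (200, 2000):
            _, cat = generate_signature_mixture(signatures, truth, n, seed=5)
            res = fit_exposures(cat, signatures)
            assert res.weights["Signature 13"] == 0.0

    def test_empty_catalogue_is_error(self, signatures):
        with pytest.raises(ValueError, match="empty"):
            fit_exposures(MutationCatalogue(np.zeros(96, dtype=int)), signatures)

    def test_error_never_increases_as_tol_decreases(self, signatures):
        _, cat = generate_signature_mixture(
            signatures, np.array([0.5, 0.2, 0.0, 0.0, 0.3]), 800, seed=9
        )
        errors = [
            SignatureDeconvolution(cat, signatures, discard_threshold=0.0, tol=tol).fit().reconstruction_error
            for tol in (1e-1, 1e-2, 1e-3, 1e-4)
        ]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errors, errors[1:]))

    def test_nnls_cross_check(self, signatures):
        """Independent route: unconstrained-sum NNLS on the same catalogue
        should land within a few percent of the greedy refit."""
        from scipy.optimize import nnls

        truth = np.array([0.65, 0.0, 0.0, 0.0, 0.35])
        _, cat = generate_signature_mixture(signatures, truth, 4000, seed=13)
        greedy = fit_exposures(cat, signatures).weights.to_numpy()
        reference, _ = nnls(signatures.probs, cat.normalised())
        assert np.abs(greedy - reference).max() < 0.05

    def test_summary_reports_fit(self, signatures):
        _, cat = generate_signature_mixture(signatures, np.array([1, 0, 0, 0, 0.0]), 500, seed=1)
        text = fit_exposures(cat, signatures).summary()
        assert "Signature 1" in text and "reconstruction SSE" in text


class TestBootstrap:
    def test_same_seed_bit_identical(self, signatures):
        channels = np.random.default_rng(1).integers(0, 96, 80)
        a = bootstrap_exposures(channels, signatures, n_iter=25, seed=42)
        b = bootstrap_exposures(channels, signatures, n_iter=25, seed=42)
        pd.testing.assert_frame_equal(a.exposures, b.exposures)

    def test_single_iteration_has_zero_iqr_width(self, signatures):
        channels = np.random.default_rng(2).integers(0, 96, 40)
        res = bootstrap_exposures(channels, signatures, n_iter=1, seed=0)
        iqr = res.iqr
        assert len(res.exposures) == 1
        assert (iqr.loc[0.75] - iqr.loc[0.25]).abs().max() == 0.0

    def test_small_mutation_set_is_error(self, signatures):
        with pytest.raises(ValueError, match="too small"):
            bootstrap_exposures(np.arange(9), signatures)

    def test_single_signature_clones_concentrate(self, signatures):
        """Clones of a pure-signature sample: the generating signature tops
        every iteration and its IQR width stays below 0.1."""
        _, cat = generate_signature_mixture(signatures, np.array([1, 0, 0, 0, 0.0]), 300, seed=3)
        channels = np.repeat(np.arange(96), cat.counts)
        res = bootstrap_exposures(channels, signatures, n_iter=50, seed=8)
        assert (res.exposures.idxmax(axis=1) == "Signature 1").all()
        width = res.iqr.loc[0.75, "Signature 1"] - res.iqr.loc[0.25, "Signature 1"]
        assert width < 0.1

    def test_median_approaches_full_fit_as_frac_grows(self, signatures):
        _, cat = generate_signature_mixture(
            signatures, np.array([0.6, 0.0, 0.0, 0.0, 0.4]), 600, seed=6
        )
        channels = np.repeat(np.arange(96), cat.counts)
        full = fit_exposures(cat, signatures).weights
        near = bootstrap_exposures(channels, signatures, n_iter=50, sample_frac=0.99, seed=1)
        far = bootstrap_exposures(channels, signatures, n_iter=50, sample_frac=0.5, seed=1)
        assert (near.median - full).abs().max() <= (far.median - full).abs().max() + 1e-6


class TestCompareConditions:
    def test_identical_distributions_not_flagged(self, signatures):
        channels = np.random.default_rng(4).integers(0, 96, 60)
        a = bootstrap_exposures(channels, signatures, n_iter=30, seed=5)
        comp = compare_conditions(a, a)
        assert comp["p"].tolist() == pytest.approx([1.0] * len(comp))
        assert not comp["iqr_disjoint"].any()
        assert not comp["highlighted"].any()

    def test_extreme_separation_flagged(self, signatures):
        names = signatures.names
        lo = pd.DataFrame(np.full((30, 5), 0.1), columns=names)
        hi = pd.DataFrame(np.full((30, 5), 0.8) + np.linspace(0, 0.01, 30)[:, None], columns=names)
        from ctclone.signatures import BootstrapResult

        comp = compare_conditions(BootstrapResult(lo), BootstrapResult(hi))
        assert comp["highlighted"].all()
        assert (comp["direction"] == "higher-in-B").all()

    def test_mismatched_signature_sets_error(self, signatures):
        from ctclone.signatures import BootstrapResult

        a = BootstrapResult(pd.DataFrame(np.zeros((5, 2)), columns=["X", "Y"]))
        b = BootstrapResult(pd.DataFrame(np.zeros((5, 2)), columns=["X", "Z"]))
        with pytest.raises(ValueError, match="mismatched"):
            compare_conditions(a, b)


APOBEC_CHANNEL = CHANNELS.index("T[C>G]T")
OTHER_CHANNEL = CHANNELS.index("A[C>T]G")


def _apobec_cohort(rng, n_dominant, n_subclonal, frac_dom, frac_sub):
    """One patient carrying the full constructed mutation set."""
    variants = [_variant_from_channel("P1", OTHER_CHANNEL, 10.0, gene="ANCHOR",
                                      pathogenic="pathogenic")]
    for i in range(n_dominant):
        ch = APOBEC_CHANNEL if rng.random() < frac_dom else OTHER_CHANNEL
        variants.append(_variant_from_channel("P1", ch, 9.0, gene="PIK3CA",
                                              pathogenic="pathogenic"))
    for i in range(n_subclonal):
        ch = APOBEC_CHANNEL if rng.random() < frac_sub else OTHER_CHANNEL
        variants.append(_variant_from_channel("P1", ch, 2.0, gene="PIK3CA",
                                              pathogenic="pathogenic"))
    return Cohort([PatientProfile("P1", variants=variants)])


class TestApobecDominance:
    def test_oracle_on_complete_separation(self):
        rng = np.random.default_rng(0)
        cohort = _apobec_cohort(rng, 10, 10, frac_dom=0.0, frac_sub=1.0)
        res = apobec_dominance_analysis(cohort, "PIK3CA")
        assert res.table.tolist() == [[0, 10], [10, 0]]
        assert res.p_value == pytest.approx(fisher_oracle(0, 10, 10, 0), abs=1e-12)

    def test_all_apobec_gives_flat_proportions(self):
        rng = np.random.default_rng(0)
        cohort = _apobec_cohort(rng, 5, 5, frac_dom=1.0, frac_sub=1.0)
        res = apobec_dominance_analysis(cohort, "PIK3CA")
        assert res.prop_dominant == 1.0 and res.prop_subclonal == 1.0
        assert res.p_value == pytest.approx(1.0)

    def test_no_assessable_mutations_gives_empty_result(self):
        cohort = make_cohort({"P1": [make_variant("P1", gene="PIK3CA", vaf=5.0,
                                                  pathogenic="pathogenic")]})
        res = apobec_dominance_analysis(cohort, "PIK3CA")
        assert res.empty and res.p_value is None

    def test_power_at_generator_rates(self):
        """Subclonal APOBEC fraction 0.4 vs dominant 0.1, 100 mutations each:
        the subclonal excess is significant in at least 90% of 100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cohort = _apobec_cohort(rng, 100, 100, frac_dom=0.1, frac_sub=0.4)
            res = apobec_dominance_analysis(cohort, "PIK3CA")
            higher = (res.prop_subclonal or 0) > (res.prop_dominant or 0)
            hits += higher and res.p_value < 0.05
        assert hits >= 90
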
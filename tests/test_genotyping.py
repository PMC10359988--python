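"""Mixture-based copy-number genotyping: recovery, labelling, confirmation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from cnvscatter.datatypes import CNVGenotype, RegionSummary
from cnvscatter.genotyping import (
    CANONICAL_SHIFTS,
    DeltaMixtureGenotyper,
    NoReferenceClusterError,
    assign_genotype,
    confirm_with_baf,
    delta_vs_het_table,
    fit_clusters,
    genotype_cohort,
)


def deltas_for(rng, shifts, counts, sd=0.05):
    """Simulated delta values with known cluster membership."""
    values, truth = [], []
    for shift, n in zip(shifts, counts):
        values.append(rng.normal(shift, sd, size=n))
        truth.extend([shift] * n)
    return np.concatenate(values), np.array(truth)


def make_summary(delta5, delta3=None, n_hom=50, n_di=0, n_tri=0,
                 sample_id="s", region_id="R"):
    delta3 = delta5 if delta3 is None else delta3
    return RegionSummary(sample_id=sample_id, region_id=region_id,
                         median_target=delta5, median_flank5=0.0,
                         median_flank3=delta5 - delta3 if delta3 is not None else 0.0,
                         delta5=delta5, delta3=delta3,
                         n_hom=n_hom, n_di_het=n_di, n_tri_het=n_tri,
                         n_probes_used=100)


class TestDeltaMixtureGenotyper:
    def test_three_state_recovery(self):
        rng = np.random.default_rng(0)
        x, truth = deltas_for(rng, [-0.5, 0.0, 0.25], [60, 380, 60], sd=0.05)
        est = DeltaMixtureGenotyper(random_state=0).fit(x[:, None])
        assert est.n_components_ == 3
        assert est.cn_labels_ == [1, 2, 3]
        np.testing.assert_allclose(est.means_, [-0.5, 0.0, 0.25], atol=0.02)
        cn = est.predict(x[:, None])
        truth_cn = np.select([truth == -0.5, truth == 0.0], [1, 2], 3)
        assert (cn == truth_cn).mean() >= 0.99

    def test_all_diploid_single_cluster(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 0.05, size=400)
        est = DeltaMixtureGenotyper(random_state=0).fit(x[:, None])
        assert est.n_components_ == 1
        assert est.cn_labels_ == [2]

    def test_homozygous_deletion_cluster_below_cn1(self):
        rng = np.random.default_rng(2)
        x, _ = deltas_for(rng, [-2.0, -0.5, 0.0], [8, 50, 400], sd=0.05)
        est = DeltaMixtureGenotyper(random_state=0).fit(x[:, None])
        assert est.cn_labels_ == [0, 1, 2]

    def test_no_reference_cluster_error(self):
        rng = np.random.default_rng(3)
        x = rng.normal(-0.5, 0.03, size=200)
        with pytest.raises(NoReferenceClusterError):
            DeltaMixtureGenotyper(random_state=0).fit(x[:, None])

    def test_determinism(self):
        rng = np.random.default_rng(4)
        x, _ = deltas_for(rng, [-0.5, 0.0, 0.25], [40, 300, 40])
        a = DeltaMixtureGenotyper(random_state=7).fit(x[:, None])
        b = DeltaMixtureGenotyper(random_state=7).fit(x[:, None])
        np.testing.assert_array_equal(a.means_, b.means_)
        np.testing.assert_array_equal(a.weights_, b.weights_)
        assert a.cn_labels_ == b.cn_labels_

    def test_well_separated_equals_nearest_center(self):
        """With clusters >= 6 noise SDs apart, mixture assignment equals the
        brute-force nearest-center rule."""
        rng = np.random.default_rng(5)
        sd = 0.02  # separations 0.25/0.5 >> 6 * 0.02
        x, _ = deltas_for(rng, [-0.5, 0.0, 0.25], [50, 300, 50], sd=sd)
        est = DeltaMixtureGenotyper(random_state=0).fit(x[:, None])
        comps = est.predict_components(x[:, None])
        nearest = np.argmin(np.abs(x[:, None] - est.means_[None, :]), axis=1)
        np.testing.assert_array_equal(comps, nearest)

    def test_sorted_centers_have_nondecreasing_cn(self):
        rng = np.random.default_rng(6)
        x, _ = deltas_for(rng, [-2.0, -0.5, 0.0, 0.25, 0.45], [10, 40, 300, 40, 10])
        est = DeltaMixtureGenotyper(random_state=0).fit(x[:, None])
        labelled = [l for l in est.cn_labels_ if l is not None]
        assert labelled == sorted(labelled)
        assert all(np.diff(est.means_) > 0)

    def test_sklearn_params_and_clone(self):
        est = DeltaMixtureGenotyper(random_state=3, membership_threshold=0.9)
        cloned = clone(est)
        assert cloned.get_params()["membership_threshold"] == 0.9
        est.set_params(max_components=4)
        assert est.get_params()["max_components"] == 4

    def test_needs_twenty_samples(self):
        with pytest.raises(ValueError, match="20"):
            DeltaMixtureGenotyper(random_state=0).fit(np.zeros((5, 1)))


class TestAssignGenotype:
    @pytest.fixture
    def models(self):
        rng = np.random.default_rng(8)
        x, _ = deltas_for(rng, [-0.5, 0.0, 0.25], [60, 300, 60], sd=0.04)
        summaries = [make_summary(v, v, sample_id=f"s{i}")
                     for i, v in enumerate(x)]
        m5 = fit_clusters(summaries, "5prime", random_state=0)
        m3 = fit_clusters(summaries, "3prime", random_state=0)
        return m5, m3

    def test_concordant_deletion(self, models):
        g = assign_genotype(make_summary(-0.49, -0.51), *models)
        assert g.cn == 1 and g.flank_agreement is True

    def test_reference_cluster(self, models):
        g = assign_genotype(make_summary(0.0, 0.0), *models)
        assert g.cn == 2 and g.flank_agreement is True

    def test_flank_conflict_resolved_by_membership(self, models):
        g = assign_genotype(make_summary(-0.5, 0.0), *models)
        assert g.flank_agreement is False
        assert g.cn in (1, 2)
        # the winning flank is the one with higher membership probability
        m5, m3 = models
        p5 = m5.estimator.predict_proba([[-0.5]]).max()
        p3 = m3.estimator.predict_proba([[0.0]]).max()
        assert g.cn == (1 if p5 >= p3 else 2)

    def test_both_deltas_missing_is_no_call(self, models):
        g = assign_genotype(make_summary(float("nan"), float("nan")), *models)
        assert g.cn is None

    def test_single_flank_available(self, models):
        g = assign_genotype(make_summary(-0.5, float("nan")), *models)
        assert g.cn == 1 and g.flank_agreement is None


class TestBAFConfirmation:
    @pytest.mark.parametrize("cn,n_di,n_tri,expected", [
        (1, 0, 0, "confirmed"),       # deletions carry no heterozygotes
        (1, 5, 0, "contradicted"),
        (3, 0, 7, "confirmed"),       # duplication: 1:2 allelic ratio hets
        (3, 0, 0, "contradicted"),
        (3, 8, 7, "contradicted"),    # tri-het must dominate di-het
        (0, 0, 0, "uninformative"),   # homozygous deletion: nothing to type
        (0, 0, 3, "uninformative"),
        (2, 4, 0, "confirmed"),
        (2, 0, 0, "contradicted"),
        (4, 9, 9, "uninformative"),   # balanced duplication: BAF cannot decide
    ])
    def test_rule_table(self, cn, n_di, n_tri, expected):
        g = CNVGenotype("s", "R", cn=cn, delta_used=0.0)
        s = make_summary(0.0, n_di=n_di, n_tri=n_tri)
        assert confirm_with_baf(g, s).baf_confirmed == expected

    def test_no_call_rejected(self):
        g = CNVGenotype("s", "R", cn=None, delta_used=float("nan"))
        with pytest.raises(ValueError):
            confirm_with_baf(g, make_summary(0.0))


class TestDeltaHetTable:
    def test_cardinality_and_noise_free_counts(self):
        rng = np.random.default_rng(10)
        x, truth = deltas_for(rng, [-0.5, 0.0], [10, 40], sd=0.02)
        summaries = [make_summary(v, v, sample_id=f"s{i}",
                                  n_di=0 if t == -0.5 else 30,
                                  n_tri=0)
                     for i, (v, t) in enumerate(zip(x, truth))]
        model = fit_clusters(summaries, "5prime", random_state=0)
        table = delta_vs_het_table(summaries, model)
        assert len(table) == 50
        assert (table.loc[table["cn"] == 1, "n_di_het"] == 0).all()
        assert (table.loc[table["cn"] == 2, "n_tri_het"] == 0).all()


class TestCohortRecovery:
    def test_parameter_recovery_on_clean_cohort(self, clean_cohort):
        """Calibration conditions: recovered centers within +/-0.05 of the
        simulated shifts and >= 99% genotype accuracy against truth."""
        cfg, _, _, truth, summaries = clean_cohort
        genotypes, models = genotype_cohort(summaries, random_state=1)
        for (region_id, flank), model in models.items():
            for comp, cn in model.cn_labels.items():
                if cn is not None:
                    assert abs(model.cluster_centers[comp]
                               - cfg.cn_shifts[cn]) <= 0.05
        merged = genotypes.merge(truth.cn, on=["sample_id", "region_id"])
        accuracy = (merged["cn"] == merged["true_cn"]).mean()
        assert accuracy >= 0.99

    def test_deletion_carriers_lack_di_hets(self, clean_cohort):
        cfg, _, _, truth, summaries = clean_cohort
        merged = summaries.merge(truth.cn, on=["sample_id", "region_id"])
        cn1 = merged[merged["true_cn"] == 1]
        cn3 = merged[merged["true_cn"] == 3]
        assert (cn1["n_di_het"] == 0).all()
        assert (cn3["n_tri_het"] >= 1).all()
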
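"""QC path: filters, size factors, stabilization, PCA, outlier split."""
import numpy as np
import pandas as pd
import pytest

import seedcourse as sc
from seedcourse import qc

from conftest import random_count_matrix


def _cm_from_counts(arr, seed=0):
    arr = np.asarray(arr)
    counts = pd.DataFrame(arr, index=[f"T{i}" for i in range(arr.shape[0])],
                          columns=[f"S{j}" for j in range(arr.shape[1])])
    md = pd.DataFrame({"line": "L1", "location": "S1", "replicate": 1,
                       "daa": 8}, index=counts.columns)
    return sc.CountMatrix(counts, md)


class TestFilterSamples:
    def test_identity_when_all_deep_enough(self):
        cm = random_count_matrix(seed=1)
        out = qc.filter_samples(cm, min_mapped=0)
        assert list(out.sample_ids) == list(cm.sample_ids)

    def test_threshold_is_inclusive_on_column_sums(self):
        cm = _cm_from_counts([[400_000, 600_000]])
        out = qc.filter_samples(cm, min_mapped=500_000)
        assert list(out.sample_ids) == ["S1"]

    def test_mirrors_study_sample_attrition_419_to_397(self):
        # 419 samples, 22 of them shallow -> 397 retained
        rng = np.random.default_rng(0)
        depth = np.full(419, 700_000)
        shallow = rng.choice(419, size=22, replace=False)
        depth[shallow] = 400_000
        counts = np.round(depth[None, :] * rng.dirichlet(
            np.ones(50), size=1).T).astype(int)
        out = qc.filter_samples(_cm_from_counts(counts), 500_000)
        assert out.n_samples == 397

    def test_everything_removed_names_threshold(self):
        cm = _cm_from_counts([[1, 2]])
        with pytest.raises(ValueError, match="500000"):
            qc.filter_samples(cm, min_mapped=500_000)

    def test_idempotent(self):
        cm = random_count_matrix(seed=2)
        once = qc.filter_samples(cm, 100)
        twice = qc.filter_samples(once, 100)
        assert list(once.sample_ids) == list(twice.sample_ids)


class TestFilterTranscripts:
    def test_all_zero_transcript_removed(self):
        cm = _cm_from_counts(np.vstack([np.zeros(12), np.full(12, 5)]))
        out = qc.filter_transcripts(cm, 2, 10)
        assert list(out.transcript_ids) == ["T1"]

    def test_boundary_exactly_two_in_exactly_ten_retained(self):
        row = np.zeros(397)
        row[:10] = 2
        cm = _cm_from_counts(np.vstack([row, np.full(397, 5)]))
        out = qc.filter_transcripts(cm, 2, 10)
        assert "T0" in out.transcript_ids

    def test_matches_brute_force_rule(self):
        rng = np.random.default_rng(3)
        arr = rng.poisson(1.0, size=(200, 30))
        cm = _cm_from_counts(arr)
        out = qc.filter_transcripts(cm, 2, 10)
        expect = [f"T{i}" for i in range(200)
                  if sum(1 for v in arr[i] if v >= 2) >= 10]
        assert list(out.transcript_ids) == expect

    def test_literal_removal_reading_is_the_complement_rule(self):
        rng = np.random.default_rng(4)
        arr = rng.poisson(1.0, size=(100, 30))
        cm = _cm_from_counts(arr)
        out = qc.filter_transcripts(cm, 2, 10, literal_removal=True)
        expect = [f"T{i}" for i in range(100)
                  if sum(1 for v in arr[i] if v < 2) < 10]
        assert list(out.transcript_ids) == expect

    def test_min_samples_larger_than_sample_count_errors(self):
        cm = random_count_matrix(n_s=4)
        with pytest.raises(ValueError, match="min_samples"):
            qc.filter_transcripts(cm, 2, 10)


class TestSizeFactors:
    def test_identical_columns_get_equal_factors(self):
        col = np.arange(1, 21)
        cm = _cm_from_counts(np.column_stack([col, col, col]))
        sf = qc.size_factors(cm)
        assert np.allclose(sf, sf.iloc[0])

    def test_doubled_column_doubles_its_factor(self):
        rng = np.random.default_rng(5)
        a = rng.poisson(30, size=50) + 1
        cm = _cm_from_counts(np.column_stack([a, 2 * a]))
        sf = qc.size_factors(cm)
        assert sf["S1"] / sf["S0"] == pytest.approx(2.0, rel=1e-12)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(6)
        arr = rng.poisson(25, size=(50, 6)) + 1
        cm = _cm_from_counts(arr)
        sf = qc.size_factors(cm).to_numpy()
        # independent brute force
        geo = np.exp(np.mean(np.log(arr), axis=1))
        raw = np.array([np.median(arr[:, j] / geo) for j in range(6)])
        raw = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(sf, raw, rtol=1e-10)

    def test_known_column_scalings_recovered_up_to_common_factor(self):
        rng = np.random.default_rng(7)
        base = rng.poisson(40, size=80) + 1
        scales = np.array([0.5, 1.0, 2.0, 4.0])
        arr = np.column_stack([np.round(base * s) for s in scales])
        sf = qc.size_factors(_cm_from_counts(arr)).to_numpy()
        ratio = sf / scales
        assert np.allclose(ratio, ratio[0], rtol=0.05)

    def test_no_universal_reference_transcript_errors(self):
        cm = _cm_from_counts([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            qc.size_factors(cm)


class TestVarianceStabilize:
    def test_closed_form_values(self):
        cm = _cm_from_counts([[0, 7]])
        nm = qc.variance_stabilize(cm, pd.Series([1.0, 1.0],
                                                 index=cm.sample_ids))
        assert nm.values.iloc[0, 0] == 0.0
        assert nm.values.iloc[0, 1] == pytest.approx(3.0)

    def test_invariant_to_joint_count_and_sf_doubling(self):
        cm = random_count_matrix(seed=8)
        sf = pd.Series(1.0, index=cm.sample_ids)
        a = qc.variance_stabilize(cm, sf)
        cm2 = sc.CountMatrix(cm.counts * 2, cm.metadata)
        b = qc.variance_stabilize(cm2, 2 * sf)
        assert np.allclose(a.values, b.values)


class TestSamplePCA:
    def _nm(self, values, md=None):
        values = pd.DataFrame(values,
                              index=[f"T{i}" for i in range(len(values))],
                              columns=[f"S{j}"
                                       for j in range(len(values[0]))])
        if md is None:
            md = pd.DataFrame({"line": "L1", "location": "S1",
                               "replicate": 1, "daa": 8},
                              index=values.columns)
        return sc.NormalizedMatrix(values,
                                   pd.Series(1.0, index=values.columns), md)

    def test_duplicated_samples_get_duplicated_scores(self):
        rng = np.random.default_rng(9)
        v = rng.standard_normal((30, 5))
        v = np.column_stack([v, v[:, 0]])
        scores, _ = qc.sample_pca(self._nm(v.tolist()), top_n=30)
        assert np.allclose(scores.iloc[0], scores.iloc[-1])

    def test_dominant_gradient_loads_on_pc1(self):
        rng = np.random.default_rng(10)
        grad = np.linspace(-3, 3, 24)
        v = np.outer(rng.standard_normal(40), grad) \
            + 0.05 * rng.standard_normal((40, 24))
        scores, varexp = qc.sample_pca(self._nm(v.tolist()), top_n=40)
        assert varexp[0] >= varexp[1:].max()
        assert abs(np.corrcoef(scores["PC1"], grad)[0, 1]) > 0.99

    def test_scores_match_eigendecomposition_oracle_up_to_sign(self):
        rng = np.random.default_rng(11)
        v = rng.standard_normal((60, 12))
        nm = self._nm(v.tolist())
        scores, varexp = qc.sample_pca(nm, top_n=25)
        # oracle: eigendecomposition of the sample covariance of the
        # same top-25-variance, transcript-centered submatrix
        var = v.var(axis=1, ddof=1)
        top = np.sort(np.argsort(var)[::-1][:25])
        sub = v[top] - v[top].mean(axis=1, keepdims=True)
        C = sub.T @ sub
        w, vec = np.linalg.eigh(C)
        w, vec = w[::-1], vec[:, ::-1]
        for j in range(3):
            oracle = vec[:, j] * np.sqrt(w[j])
            got = scores.iloc[:, j].to_numpy()
            assert min(np.abs(got - oracle).max(),
                       np.abs(got + oracle).max()) < 1e-8

    def test_fewer_than_two_samples_errors(self):
        with pytest.raises(ValueError, match="two samples"):
            qc.sample_pca(self._nm([[1.0]]), top_n=1)


class TestOutlierSplit:
    def test_two_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(12)
        pts = np.vstack([rng.standard_normal((326, 2)),
                         rng.standard_normal((71, 2)) + [8.0, 0.0]])
        scores = pd.DataFrame(pts, columns=["PC1", "PC2"],
                              index=[f"S{i:03d}" for i in range(397)])
        major, minor = qc.split_outlier_cluster(scores)
        assert len(major) == 326 and len(minor) == 71
        assert set(minor) == {f"S{i:03d}" for i in range(326, 397)}

    def test_unimodal_cloud_is_not_split(self):
        rng = np.random.default_rng(13)
        scores = pd.DataFrame(rng.standard_normal((200, 2)),
                              columns=["PC1", "PC2"],
                              index=[f"S{i}" for i in range(200)])
        major, minor = qc.split_outlier_cluster(scores)
        assert len(minor) == 0 and len(major) == 200

    def test_continuous_gradient_is_not_split(self):
        rng = np.random.default_rng(14)
        x = np.linspace(-5, 5, 300)
        scores = pd.DataFrame(
            np.column_stack([x, 0.3 * rng.standard_normal(300)]),
            columns=["PC1", "PC2"], index=[f"S{i}" for i in range(300)])
        major, minor = qc.split_outlier_cluster(scores)
        assert len(minor) == 0

    def test_deterministic_given_state(self):
        rng = np.random.default_rng(15)
        pts = np.vstack([rng.standard_normal((60, 2)),
                         rng.standard_normal((20, 2)) + [7.0, 0.0]])
        scores = pd.DataFrame(pts, columns=["PC1", "PC2"],
                              index=[f"S{i}" for i in range(80)])
        a = qc.split_outlier_cluster(scores, random_state=3)
        b = qc.split_outlier_cluster(scores, random_state=3)
        assert list(a[0]) == list(b[0]) and list(a[1]) == list(b[1])


class TestTimeCorrelation:
    def test_gradient_course_correlation_decays_with_interval_distance(
            self, design6):
        truth = sc.simulate.make_truth(design6, 400,
                                       pattern_codes=["uuuuu", "ddddd",
                                                      "00000", "00000"],
                                       seed=16, latent_fraction=0.0)
        cm, _ = sc.simulate.simulate_counts(design6, truth, seed=17,
                                            line_sd=0.1, latent_sd=0.0)
        nm = qc.variance_stabilize(cm, qc.size_factors(cm))
        corr = qc.time_correlation(nm)
        c = corr.to_numpy()
        # averaged over rows: correlation non-increasing with distance
        for lag in range(1, 5):
            a = np.mean([c[i, i + lag] for i in range(6 - lag)])
            b = np.mean([c[i, i + lag + 1] for i in range(5 - lag)])
            assert a >= b - 1e-6
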
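"""LOD/left-censoring assessment and batch-effect summaries/adjustments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from promiss import (
    QuantMatrix,
    SampleMetadata,
    SimulationConfig,
    ValidationError,
    apply_batch_adjustment,
    apply_threshold,
    batch_sensitivity,
    batch_summary,
    lod_assessment,
    profile,
    simulate,
)
from promiss.assessments import BATCH_SCHEMES


class TestLodAssessment:
    def test_no_lod_term_means_no_abundance_link(self):
        cfg = SimulationConfig(
            n_proteins=250, n_detectable=220, n_informative=0, lod_strength=0.0, seed=6
        )
        matrix, meta, _ = simulate(cfg)
        filtered, _ = apply_threshold(matrix)
        res = lod_assessment(filtered)
        assert res.defined
        assert abs(res.r) < 0.15
        assert res.ci_low < res.r < res.ci_high

    def test_complete_matrix_reports_undefined(self):
        rng = np.random.default_rng(0)
        matrix = QuantMatrix(
            pd.DataFrame(
                np.exp(rng.normal(10, 1, (20, 6))),
                index=[f"P{i}" for i in range(20)],
                columns=[f"s{j}" for j in range(6)],
            )
        )
        res = lod_assessment(matrix)
        assert not res.defined and res.n_proteins == 20

    def test_all_missing_protein_excluded_and_reported(self):
        rng = np.random.default_rng(1)
        values = np.exp(rng.normal(10, 1, (12, 8)))
        values[0] = np.nan
        values[1:4, :3] = np.nan
        matrix = QuantMatrix(
            pd.DataFrame(
                values, index=[f"P{i}" for i in range(12)], columns=[f"s{j}" for j in range(8)]
            )
        )
        res = lod_assessment(matrix)
        assert res.excluded_proteins == ("P0",)
        assert res.n_proteins == 11

    def test_stratum_scope_equals_overall_on_single_stratum(self, toy_meta):
        rng = np.random.default_rng(2)
        values = np.exp(rng.normal(8, 1, (15, 4)))
        values[rng.random((15, 4)) < 0.3] = np.nan
        matrix = QuantMatrix(
            pd.DataFrame(values, index=[f"P{i}" for i in range(15)],
                         columns=["s1", "s2", "s3", "s4"])
        )
        single = SampleMetadata(
            toy_meta.table.assign(timepoint="baseline", participant_id=["a", "b", "c", "d"])
        )
        overall = lod_assessment(matrix)
        scoped = lod_assessment(matrix, single, ("timepoint", "baseline"))
        assert scoped.r == pytest.approx(overall.r)

    def test_nonpositive_values_rejected(self):
        matrix = QuantMatrix(
            pd.DataFrame([[1.0, -2.0]] * 5, index=[f"P{i}" for i in range(5)],
                         columns=["s1", "s2"])
        )
        with pytest.raises(ValidationError, match="positive"):
            lod_assessment(matrix)


class TestBatchSummary:
    def test_default_cohort_group_spans(self, default_cohort):
        _, meta, _ = default_cohort
        summary = batch_summary(meta)
        spans = summary["batches_per_group"]
        assert spans.to_dict() == {"2HD": 8, "HD": 2, "LD": 10}
        assert summary["by_group"].to_numpy().sum() == meta.n_samples
        assert summary["by_timepoint"].to_numpy().sum() == meta.n_samples

    def test_single_batch_metadata(self, toy_meta):
        single = SampleMetadata(toy_meta.table.assign(batch=1))
        summary = batch_summary(single)
        assert (summary["batches_per_group"] == 1).all()
        assert summary["n_batches"] == 1


def _one_stratum_profiles(alpha, missing_count, n_samples):
    return pd.DataFrame(
        [
            {
                "protein_id": "P0",
                "axis": "group",
                "level": "HD",
                "missing_count": missing_count,
                "n_samples": n_samples,
                "alpha": alpha,
            }
        ]
    )


class TestBatchAdjustment:
    def _meta_single_batch(self):
        # one stratum (HD) of 10 samples in a single batch
        return SampleMetadata(
            pd.DataFrame(
                {
                    "participant_id": [f"p{i}" for i in range(10)],
                    "timepoint": ["baseline"] * 10,
                    "group": ["HD"] * 10,
                    "batch": [1] * 10,
                },
                index=pd.Index([f"s{i}" for i in range(10)], name="sample_id"),
            )
        )

    def test_scheme_arithmetic_single_batch(self):
        prof = _one_stratum_profiles(alpha=0.5, missing_count=5, n_samples=10)
        meta = self._meta_single_batch()
        got = {
            s: apply_batch_adjustment(prof, meta, s)["adjusted"].iloc[0]
            for s in BATCH_SCHEMES
        }
        assert got["alpha_over_batchcount"] == pytest.approx(0.5)  # reduces to alpha
        assert got["alpha_over_batch_sample_sum"] == pytest.approx(0.05)
        assert got["alpha_over_freq_times_batchcount"] == pytest.approx(0.05)
        assert got["rawcount_over_freq_times_batchcount"] == pytest.approx(0.5)

    def test_zero_alpha_gives_zero_under_every_scheme(self):
        prof = _one_stratum_profiles(alpha=0.0, missing_count=0, n_samples=10)
        meta = self._meta_single_batch()
        for s in BATCH_SCHEMES:
            assert apply_batch_adjustment(prof, meta, s)["adjusted"].iloc[0] == 0.0

    def test_adjusted_values_finite_and_nonnegative(self, default_cohort):
        matrix, meta, _ = default_cohort
        filtered, _ = apply_threshold(matrix)
        prof = profile(filtered, meta, "group")
        for s in BATCH_SCHEMES:
            adj = apply_batch_adjustment(prof, meta, s)["adjusted"]
            assert np.isfinite(adj).all() and (adj >= 0).all()
            assert ((adj == 0) == (prof["alpha"] == 0)).all() or s == "rawcount_over_freq_times_batchcount"

    def test_unknown_scheme_rejected(self, default_cohort):
        _, meta, _ = default_cohort
        with pytest.raises(ValidationError, match="scheme"):
            apply_batch_adjustment(_one_stratum_profiles(0.5, 5, 10), meta, "nope")


class TestBatchSensitivity:
    def test_outlier_flags_invariant_under_all_schemes(self, default_cohort):
        """Stratum-constant rescalings leave residual-band flags unchanged,
        mirroring the observation that batch adjustments do not move results."""
        matrix, meta, _ = default_cohort
        filtered, _ = apply_threshold(matrix)
        prof = profile(filtered, meta, "group")
        report = batch_sensitivity(prof, meta)
        assert (report["jaccard_vs_unadjusted"] == 1.0).all()
        assert report["min_batches_per_group"].iloc[0] == 2

    def test_residual_ranks_preserved_by_adjustment(self, default_cohort):
        from promiss import detect_outliers

        matrix, meta, _ = default_cohort
        filtered, _ = apply_threshold(matrix)
        prof = profile(filtered, meta, "group")
        base = detect_outliers(prof, ("HD", "LD"))
        adj = apply_batch_adjustment(prof, meta, "alpha_over_batchcount")
        adj = adj.drop(columns="alpha").rename(columns={"adjusted": "alpha"})
        after = detect_outliers(adj, ("HD", "LD"))
        rho = stats.spearmanr(base["residual"], after["residual"]).statistic
        assert rho >= 0.9

    def test_empty_outlier_sets_overlap_one(self):
        x = np.linspace(0.05, 0.6, 30)
        rows = []
        for level in ("HD", "2HD", "LD"):
            for i, a in enumerate(x):
                rows.append(
                    {"protein_id": f"P{i:03d}", "axis": "group", "level": level,
                     "missing_count": int(a * 100), "n_samples": 100, "alpha": a}
                )
        prof = pd.DataFrame(rows)
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "participant_id": [f"p{i}" for i in range(9)],
                    "timepoint": ["baseline"] * 9,
                    "group": ["HD", "2HD", "LD"] * 3,
                    "batch": [1, 2, 3] * 3,
                },
                index=pd.Index([f"s{i}" for i in range(9)], name="sample_id"),
            )
        )
        report = batch_sensitivity(prof, meta)
        assert (report["jaccard_vs_unadjusted"] == 1.0).all()
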
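"""Fisher-z intervals, cross-stratum correlations and residual-band outliers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promiss import (
    BandSpec,
    UndefinedCorrelationError,
    ValidationError,
    correlate_axis,
    cross_axis_screen,
    detect_outliers,
    fisher_ci,
    pearson_with_ci,
    profile,
    simulate,
    SimulationConfig,
    apply_threshold,
)
from promiss.correlation import all_outlier_reports


class TestFisherCi:
    @pytest.mark.parametrize(
        "r,n,lo,hi",
        [
            (0.95, 565, 0.94, 0.96),
            (0.97, 565, 0.96, 0.97),
            (0.94, 565, 0.93, 0.95),
            (0.48, 10, -0.21, 0.85),
            (-0.18, 64, -0.41, 0.07),
            (-0.37, 565, -0.44, -0.30),
        ],
    )
    def test_interval_to_two_decimals(self, r, n, lo, hi):
        got_lo, got_hi = fisher_ci(r, n)
        assert round(got_lo, 2) == lo
        assert round(got_hi, 2) == hi

    def test_perfect_correlation_degenerates_to_unit_interval(self):
        lo, hi = fisher_ci(1.0, 50)
        assert lo == pytest.approx(1.0, abs=1e-12)
        assert hi == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_scipy_reference(self):
        # independent oracle: scipy's pearsonr CI uses the same transform
        from scipy import stats

        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40)
        res = pearson_with_ci(x, y)
        ref = stats.pearsonr(x, y)
        ci = ref.confidence_interval()
        assert res.r == pytest.approx(ref.statistic)
        assert res.ci_low == pytest.approx(ci.low, abs=1e-9)
        assert res.ci_high == pytest.approx(ci.high, abs=1e-9)


class TestPearsonWithCi:
    def test_identity_vectors_give_r_one(self):
        x = np.array([0.1, 0.4, 0.2, 0.9, 0.5])
        res = pearson_with_ci(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(20), rng.random(20)
        a = pearson_with_ci(x, y)
        b = pearson_with_ci(y, x)
        assert a.r == pytest.approx(b.r)
        assert a.ci_low == pytest.approx(b.ci_low)

    def test_zero_variance_is_undefined_not_zero(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_ci([1.0, 1.0, 1.0, 1.0], [0.1, 0.2, 0.3, 0.4])

    def test_too_few_points_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_ci([1, 2, 3], [1, 2, 3])

    def test_ci_brackets_r_within_unit_range(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x, y = rng.random(12), rng.random(12)
            res = pearson_with_ci(x, y)
            assert -1 <= res.ci_low <= res.r <= res.ci_high <= 1


def _profiles_from_alphas(alpha_by_level: dict[str, np.ndarray], axis: str) -> pd.DataFrame:
    rows = []
    n_prot = len(next(iter(alpha_by_level.values())))
    for level, alphas in alpha_by_level.items():
        for i, a in enumerate(alphas):
            rows.append(
                {
                    "protein_id": f"P{i:03d}",
                    "axis": axis,
                    "level": level,
                    "missing_count": int(round(a * 100)),
                    "n_samples": 100,
                    "alpha": a,
                }
            )
    return pd.DataFrame(rows)


class TestCorrelateAxis:
    def test_three_pairs_per_axis(self, default_cohort):
        matrix, meta, _ = default_cohort
        filtered, _ = apply_threshold(matrix)
        res = correlate_axis(profile(filtered, meta, "timepoint"), "timepoint")
        assert [(c.stratum_a, c.stratum_b) for c in res] == [
            ("baseline", "3m"),
            ("baseline", "6m"),
            ("3m", "6m"),
        ]

    def test_self_comparison_gives_unit_correlation(self):
        rng = np.random.default_rng(3)
        alphas = rng.random(30)
        prof = _profiles_from_alphas({"HD": alphas, "2HD": alphas, "LD": rng.random(30)}, "group")
        res = {(c.stratum_a, c.stratum_b): c.r for c in correlate_axis(prof, "group")}
        assert res[("HD", "2HD")] == pytest.approx(1.0)

    def test_group_labels_uninformative_when_nothing_planted(self):
        """Without planted proteins the group-axis correlation is statistically
        indistinguishable from correlations computed under permuted group labels."""
        cfg = SimulationConfig(
            n_proteins=200, n_detectable=170, n_informative=0, seed=9
        )
        matrix, meta, _ = simulate(cfg)
        filtered, _ = apply_threshold(matrix)
        observed = min(
            c.r for c in correlate_axis(profile(filtered, meta, "group"), "group")
        )
        rng = np.random.default_rng(0)
        null = []
        table = meta.table.copy()
        part = table.groupby("participant_id")["group"].first()
        for _ in range(30):
            perm = pd.Series(
                rng.permutation(part.to_numpy()), index=part.index
            )
            shuffled = table.copy()
            shuffled["group"] = shuffled["participant_id"].map(perm).to_numpy()
            from promiss import SampleMetadata

            null.append(
                min(
                    c.r
                    for c in correlate_axis(
                        profile(filtered, SampleMetadata(shuffled), "group"), "group"
                    )
                )
            )
        lo, hi = np.quantile(null, [0.02, 0.98])
        assert lo - 0.02 <= observed <= hi + 0.02


class TestDetectOutliers:
    def test_single_off_line_protein_flagged_with_direction(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(0, 0.6, 50)
        alphas_a = np.append(base, 0.30)
        alphas_b = np.append(base + rng.normal(0, 0.01, 50), 0.76)
        prof = _profiles_from_alphas(
            {"HD": alphas_a, "2HD": alphas_a, "LD": alphas_b}, "group"
        )
        rep = detect_outliers(prof, ("HD", "LD"))
        flagged = rep[rep.flagged]
        assert list(flagged.protein_id) == ["P050"]
        assert flagged.iloc[0].direction == "LD"  # excess missingness in stratum b

    def test_collinear_points_produce_no_outliers(self):
        x = np.linspace(0, 1, 20)
        prof = _profiles_from_alphas({"HD": x, "2HD": x, "LD": 0.5 * x + 0.1}, "group")
        rep = detect_outliers(prof, ("HD", "LD"))
        assert not rep.flagged.any()

    def test_constant_alphas_warn_and_flag_nothing(self):
        ones = np.full(15, 0.3)
        prof = _profiles_from_alphas({"HD": ones, "2HD": ones, "LD": ones}, "group")
        with pytest.warns(UserWarning, match="degenerate"):
            rep = detect_outliers(prof, ("HD", "LD"))
        assert not rep.flagged.any()

    def test_too_few_proteins_rejected(self):
        x = np.linspace(0, 1, 5)
        prof = _profiles_from_alphas({"HD": x, "2HD": x, "LD": x}, "group")
        with pytest.raises(ValidationError, match="10 proteins"):
            detect_outliers(prof, ("HD", "LD"))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_to_protein_ordering(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(25)
        b = a + rng.normal(0, 0.05, 25)
        prof = _profiles_from_alphas({"HD": a, "2HD": a, "LD": b}, "group")
        rep = detect_outliers(prof, ("HD", "LD"))
        prof2 = prof.sample(frac=1, random_state=seed).reset_index(drop=True)
        rep2 = detect_outliers(prof2, ("HD", "LD"))
        merged = rep.merge(rep2, on="protein_id", suffixes=("_1", "_2"))
        assert (merged.flagged_1 == merged.flagged_2).all()
        assert np.allclose(merged.residual_1, merged.residual_2)

    def test_null_flag_rate_near_band_tail_mass(self):
        """With nothing planted, ~<=2% of protein-comparisons exceed the 2.5 SD band."""
        rates = []
        for seed in range(6):
            cfg = SimulationConfig(
                n_proteins=300, n_detectable=260, n_informative=0, seed=seed
            )
            matrix, meta, _ = simulate(cfg)
            filtered, _ = apply_threshold(matrix)
            rep = all_outlier_reports(profile(filtered, meta, "group"), "group")
            rates.append(rep.flagged.mean())
        assert np.mean(rates) <= 0.02


class TestCrossAxisScreen:
    def test_group_outlier_with_stable_time_profile_retained(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0, 0.6, 40)
        g = {
            "HD": np.append(base, 0.32),
            "2HD": np.append(base + rng.normal(0, 0.01, 40), 0.30),
            "LD": np.append(base + rng.normal(0, 0.01, 40), 0.76),
        }
        stable = np.append(base, 0.50)
        t = {
            "baseline": stable,
            "3m": stable + rng.normal(0, 0.01, 41),
            "6m": stable + rng.normal(0, 0.01, 41),
        }
        cand = cross_axis_screen(
            all_outlier_reports(_profiles_from_alphas(g, "group"), "group"),
            all_outlier_reports(_profiles_from_alphas(t, "timepoint"), "timepoint"),
        )
        assert "P040" in set(cand.protein_id)

    def test_time_localized_artefact_excluded(self):
        """A batch-style dropout confined to one timepoint is a time-axis outlier
        and must not survive the screen even if it also separates groups."""
        rng = np.random.default_rng(8)
        base = rng.uniform(0, 0.5, 40)
        g = {
            "HD": np.append(base, 0.2),
            "2HD": np.append(base + rng.normal(0, 0.01, 40), 0.2),
            "LD": np.append(base + rng.normal(0, 0.01, 40), 0.6),
        }
        t = {
            "baseline": np.append(base, 0.9),  # dropout concentrated at baseline
            "3m": np.append(base + rng.normal(0, 0.01, 40), 0.1),
            "6m": np.append(base + rng.normal(0, 0.01, 40), 0.1),
        }
        cand = cross_axis_screen(
            all_outlier_reports(_profiles_from_alphas(g, "group"), "group"),
            all_outlier_reports(_profiles_from_alphas(t, "timepoint"), "timepoint"),
        )
        assert "P040" not in set(cand.protein_id)

    def test_no_outliers_anywhere_gives_empty_table(self):
        x = np.linspace(0.05, 0.6, 30)
        g = {"HD": x, "2HD": x, "LD": x}
        t = {"baseline": x, "3m": x, "6m": x}
        cand = cross_axis_screen(
            all_outlier_reports(_profiles_from_alphas(g, "group"), "group"),
            all_outlier_reports(_profiles_from_alphas(t, "timepoint"), "timepoint"),
        )
        assert cand.empty
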
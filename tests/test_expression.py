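"""Correlation screens, relative quantification, circadian profiles, clustering."""

import numpy as np
import pandas as pd
import pytest

from cryptarget.expression import (
    CircadianProfile,
    CtTable,
    ExpressionError,
    cluster_profiles,
    ddct_fold_change,
    peak_summary,
    pearson_r,
    relative_profile,
    trans_candidates,
    validate_expression,
)


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # r = cov / (sd_x sd_y) for x=(1,2,3,4), y=(1,2,3,5)
        x, y = np.array([1, 2, 3, 4.0]), np.array([1, 2, 3, 5.0])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert pearson_r(x, y) == pytest.approx(num / den)

    def test_affine_invariance_and_sign_flip(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        r = pearson_r(x, y)
        assert pearson_r(3 * x + 7, y) == pytest.approx(r)
        assert pearson_r(-2 * x + 1, y) == pytest.approx(-r)

    def test_zero_variance_rejected(self):
        with pytest.raises(ExpressionError, match="zero variance"):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(ExpressionError, match="at least 3"):
            pearson_r([1, 2], [3, 4])


class TestTransScreen:
    def test_planted_pair_retained_decoy_excluded(self, rng):
        t = np.linspace(0, 70, 18)
        focal = 5 + 4 * np.cos(2 * np.pi * t / 24)
        cols = [f"ZT{int(h)}" for h in t]
        genes = pd.DataFrame([focal], index=["focal"], columns=cols)
        lncs = pd.DataFrame(
            [2 * focal + 1, rng.normal(5, 1, size=18)], index=["good", "noise"], columns=cols
        )
        out = trans_candidates(lncs, genes, r_min=0.9)
        assert [(a, b) for a, b, _ in out] == [("good", "focal")]

    def test_published_style_fixture_vectors(self, published_trans, rng):
        """Construct one vector per published correlation so that its sample r
        reproduces the printed value, then screen at the stricter 0.99 cut."""
        n = 18
        t = np.linspace(0, 70, n)
        focal = 5 + 4 * np.cos(2 * np.pi * t / 24)
        x = (focal - focal.mean()) / focal.std()
        z = rng.normal(size=n)
        z -= (z @ x) / (x @ x) * x
        z -= z.mean()
        z /= z.std()
        cols = [f"ZT{int(h)}" for h in t]
        rows, ids = [], []
        for _, row in published_trans.iterrows():
            rho = row.correlation
            y = rho * x + np.sqrt(1 - rho**2) * z
            rows.append(10 + 2 * y)
            ids.append(row.lncrna_id)
        lncs = pd.DataFrame(rows, index=ids, columns=cols)
        genes = pd.DataFrame([focal], index=["sjCRY-DASH"], columns=cols)
        out = trans_candidates(lncs, genes, r_min=0.99)
        assert len(out) == 9
        got = {a: r for a, _, r in out}
        for _, row in published_trans.iterrows():
            assert got[row.lncrna_id] == pytest.approx(row.correlation, abs=1e-6)

    def test_shared_condition_requirement(self):
        a = pd.DataFrame([[1, 2]], index=["x"], columns=["c1", "c2"])
        with pytest.raises(ExpressionError, match="shared conditions"):
            trans_candidates(a, a)

    def test_strict_boundary_flag(self):
        cols = list("abcd")
        x = pd.DataFrame([[1, 2, 3, 4.0]], index=["u"], columns=cols)
        y = pd.DataFrame([[2, 4, 6, 8.0]], index=["v"], columns=cols)
        assert trans_candidates(x, y, r_min=1.0) != []
        assert trans_candidates(x, y, r_min=1.0, strict=True) == []


def make_ct(rows):
    return CtTable(
        data=pd.DataFrame(rows, columns=["sample", "gene", "ct"]),
        reference_gene="ref",
        calibrator_sample="cal",
    )


class TestDdct:
    def test_hand_worked_example(self):
        ct = make_ct(
            [("s", "tgt", 24.0), ("s", "ref", 20.0), ("cal", "tgt", 26.0), ("cal", "ref", 21.0)]
        )
        # ΔCt_s = 4, ΔCt_cal = 5, ΔΔCt = -1 -> 2.0
        assert ddct_fold_change(ct, "tgt", "s") == pytest.approx(2.0)

    def test_calibrator_is_exactly_one(self):
        ct = make_ct([("cal", "tgt", 27.3), ("cal", "ref", 19.1)])
        assert ddct_fold_change(ct, "tgt", "cal") == 1.0

    def test_missing_ct_named(self):
        ct = make_ct([("cal", "tgt", 27.3), ("cal", "ref", 19.1)])
        with pytest.raises(ExpressionError, match="s1.*tgt|tgt.*s1"):
            ddct_fold_change(ct, "tgt", "s1")

    def test_replicates_averaged(self):
        rows = pd.DataFrame(
            [
                ("s", "tgt", 1, 24.0), ("s", "ref", 1, 20.0),
                ("s", "tgt", 2, 23.0), ("s", "ref", 2, 20.0),
                ("cal", "tgt", 1, 25.0), ("cal", "ref", 1, 20.0),
                ("cal", "tgt", 2, 25.0), ("cal", "ref", 2, 20.0),
            ],
            columns=["sample", "gene", "replicate", "ct"],
        )
        ct = CtTable(rows, reference_gene="ref", calibrator_sample="cal")
        mean, sd = ddct_fold_change(ct, "tgt", "s", with_sd=True)
        assert mean == pytest.approx((2.0 + 4.0) / 2)
        assert sd == pytest.approx(np.std([2.0, 4.0], ddof=1))


class TestProfiles:
    def test_relative_profile_baseline_one(self):
        row = pd.Series([2.0, 4.0, 6.0], index=["ZT2", "ZT6", "ZT10"])
        prof = relative_profile(row)
        assert prof.fold_changes[0] == 1.0
        assert prof.fold_changes == (1.0, 2.0, 3.0)
        assert prof.timepoints == (2.0, 6.0, 10.0)

    def test_zero_baseline_rejected(self):
        row = pd.Series([0.0, 4.0, 6.0, 1.0], index=["ZT2", "ZT6", "ZT10", "ZT14"])
        with pytest.raises(ExpressionError, match="zero"):
            relative_profile(row)

    def test_24h_cosine_has_24h_periodicity(self):
        t = np.arange(0, 73, 4.0)
        prof = CircadianProfile(tuple(t), tuple(np.cos(2 * np.pi * t / 24) + 1.5))
        s = peak_summary(prof)
        assert s.has_24h_periodicity
        assert all(d == pytest.approx(24.0) for d in s.intervals)

    def test_12h_cosine_rejected(self):
        t = np.arange(0, 73, 4.0)
        prof = CircadianProfile(tuple(t), tuple(np.cos(2 * np.pi * t / 12) + 1.5))
        assert not peak_summary(prof).has_24h_periodicity

    def test_monotone_profile_no_peaks(self):
        t = np.arange(0, 48, 4.0)
        prof = CircadianProfile(tuple(t), tuple(np.linspace(1, 3, t.size)))
        s = peak_summary(prof)
        assert s.peak_times == () and not s.has_24h_periodicity

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ExpressionError):
            peak_summary(CircadianProfile((0.0, 4.0, 8.0), (1.0, 2.0, 1.0)))


class TestClustering:
    def _two_phase_matrix(self, rng, n_per=5):
        t = np.arange(0, 72, 4.0)
        cols = [f"ZT{int(h)}" for h in t]
        rows, idx = [], []
        for i in range(n_per):
            rows.append(5 + 3 * np.cos(2 * np.pi * t / 24) + rng.normal(0, 0.1, t.size))
            idx.append(f"day_{i}")
        for i in range(n_per):
            rows.append(5 - 3 * np.cos(2 * np.pi * t / 24) + rng.normal(0, 0.1, t.size))
            idx.append(f"night_{i}")
        return pd.DataFrame(rows, index=idx, columns=cols)

    def test_opposite_phase_groups_recovered(self, rng):
        expr = self._two_phase_matrix(rng)
        labels = cluster_profiles(expr, k=2)
        day = set(labels[labels.index.str.startswith("day")])
        night = set(labels[labels.index.str.startswith("night")])
        assert len(day) == 1 and len(night) == 1 and day != night

    def test_k_equals_n(self, rng):
        expr = self._two_phase_matrix(rng, n_per=3)
        labels = cluster_profiles(expr, k=6)
        assert labels.nunique() == 6

    def test_row_permutation_invariance_up_to_relabeling(self, rng):
        expr = self._two_phase_matrix(rng)
        perm = expr.sample(frac=1, random_state=1)
        l1 = cluster_profiles(expr, k=2)
        l2 = cluster_profiles(perm, k=2).reindex(expr.index)
        # same partition regardless of labels
        for a in expr.index:
            for b in expr.index:
                assert (l1[a] == l1[b]) == (l2[a] == l2[b])

    def test_constant_rows_reported(self, rng):
        expr = self._two_phase_matrix(rng, n_per=2)
        expr.loc["flat"] = 1.0
        with pytest.raises(ExpressionError, match="flat"):
            cluster_profiles(expr, k=2)

    def test_exactly_one_of_k_or_height(self, rng):
        expr = self._two_phase_matrix(rng, n_per=2)
        with pytest.raises(ExpressionError):
            cluster_profiles(expr)
        with pytest.raises(ExpressionError):
            cluster_profiles(expr, k=2, cut_height=0.5)


class TestValidation:
    def test_missing_values_rejected(self):
        df = pd.DataFrame([[1.0, np.nan]], index=["a"], columns=["c1", "c2"])
        with pytest.raises(ExpressionError, match="missing"):
            validate_expression(df)

    def test_negative_values_rejected(self):
        df = pd.DataFrame([[1.0, -2.0]], index=["a"], columns=["c1", "c2"])
        with pytest.raises(ExpressionError, match="non-negative"):
            validate_expression(df)
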
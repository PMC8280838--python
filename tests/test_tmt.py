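import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phosphotriage import tmt
from phosphotriage.io import TMT_CONDITIONS, tmt_col
from phosphotriage.tmt import TmtThresholds


def profiles_frame(rows, ids=None):
    """rows: list of 10-value intensity vectors in the fixed condition order."""
    ids = ids or [f"s{i}" for i in range(len(rows))]
    data = {"site_id": ids}
    for j, cond in enumerate(TMT_CONDITIONS):
        data[tmt_col(cond)] = [row[j] for row in rows]
    return pd.DataFrame(data)


def as_series(values):
    return pd.Series(dict(zip(TMT_CONDITIONS, values)))


REFERENCE = [1e5, 1.26e5, 1.78e5, 2.5e5, 1.26e5, 5e4, 5e4, 5e4, 5e4, 5e4]


class TestCompleteProfiles:
    def test_missing_condition_removed(self):
        incomplete = [1e5] * 9 + [np.nan]
        df = profiles_frame([[1e5] * 10, incomplete])
        assert list(tmt.complete_profiles_only(df)["site_id"]) == ["s0"]

    def test_zero_intensity_counts_as_missing(self):
        df = profiles_frame([[1e5] * 5 + [0.0] + [1e5] * 4])
        assert len(tmt.complete_profiles_only(df)) == 0

    def test_count_matches_direct_enumeration(self, small_screen):
        sites = small_screen.sites
        cols = [tmt_col(c) for c in TMT_CONDITIONS]
        direct = int((sites[cols].notna().all(axis=1) & (sites[cols] > 0).all(axis=1)).sum())
        assert len(tmt.complete_profiles_only(sites)) == direct


class TestNormalize:
    def test_constant_profile_relative_log2_is_zero(self):
        df = profiles_frame([[7e4] * 10])
        norm = tmt.normalize(df, "relative_log2")
        assert np.allclose(norm[[tmt_col(c) for c in TMT_CONDITIONS]], 0.0)

    def test_double_the_mean_gives_one(self):
        # nine conditions at x, one at 2x scaled so it sits at twice the mean
        vals = [100.0] * 10
        vals[3] = 1800.0 / 8  # solves v = 2 * mean
        df = profiles_frame([vals])
        norm = tmt.normalize(df, "relative_log2")
        assert norm[tmt_col("WT_60")].iloc[0] == pytest.approx(1.0)

    def test_anchored_zero_at_dko0(self):
        rng = np.random.default_rng(0)
        df = profiles_frame([10 ** rng.uniform(3, 6, 10) for _ in range(20)])
        norm = tmt.normalize(df, "anchored_to_DKO0")
        assert (norm[tmt_col("DKO_0")] == 0.0).all()

    def test_nonpositive_intensity_names_condition(self):
        vals = [1e5] * 10
        vals[TMT_CONDITIONS.index("DKO_30")] = -1.0
        with pytest.raises(ValueError, match="DKO_30"):
            tmt.normalize(profiles_frame([vals]), "log10_raw")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            tmt.normalize(profiles_frame([[1.0] * 10]), "zscore")

    @given(
        st.lists(
            st.floats(min_value=1.0, max_value=1e9), min_size=10, max_size=10
        )
    )
    def test_relative_log2_mean_identity(self, values):
        """Sum over conditions of 2^value is exactly 10 (to tolerance)."""
        norm = tmt.normalize(profiles_frame([values]), "relative_log2")
        v = norm[[tmt_col(c) for c in TMT_CONDITIONS]].to_numpy()[0]
        assert np.sum(2.0**v) == pytest.approx(10.0, abs=1e-9)


class TestTriageVariables:
    def test_identical_to_reference_has_unit_correlation(self):
        norm = tmt.normalize(profiles_frame([REFERENCE]), "log10_raw")
        ref = as_series(np.log10(REFERENCE))
        vars_df = tmt.triage_variables(norm, ref)
        assert vars_df["V4"].iloc[0] == pytest.approx(1.0)

    def test_negated_reference_has_minus_one(self):
        ref_log = np.log10(REFERENCE)
        anchored = ref_log - ref_log[TMT_CONDITIONS.index("DKO_0")]
        df = profiles_frame([10 ** (-anchored + 5)])
        norm = tmt.normalize(df, "anchored_to_DKO0")
        vars_df = tmt.triage_variables(norm, as_series(anchored))
        assert vars_df["V4"].iloc[0] == pytest.approx(-1.0)

    def test_contrasts_are_direct_subtractions(self):
        log10 = {c: 1.0 for c in TMT_CONDITIONS}
        log10.update({"WT_60": 1.6, "WT_RF": 1.1, "DKO_60": 1.2, "WT_0": 1.0})
        df = profiles_frame([[10 ** log10[c] for c in TMT_CONDITIONS]])
        vars_df = tmt.triage_variables(
            tmt.normalize(df, "log10_raw"), as_series(np.log10(REFERENCE))
        )
        row = vars_df.iloc[0]
        assert row["V1"] == pytest.approx(0.6)
        assert row["V2"] == pytest.approx(0.4)
        assert row["V3"] == pytest.approx(0.5)

    def test_constant_reference_is_an_error(self):
        norm = tmt.normalize(profiles_frame([REFERENCE]), "log10_raw")
        with pytest.raises(ValueError, match="constant"):
            tmt.triage_variables(norm, as_series([1.0] * 10))

    def test_v4_invariant_under_positive_affine_transform(self):
        rng = np.random.default_rng(2)
        rows = [10 ** rng.uniform(4, 6, 10) for _ in range(10)]
        norm = tmt.normalize(profiles_frame(rows), "log10_raw")
        ref = as_series(np.log10(REFERENCE))
        v4 = tmt.triage_variables(norm, ref)["V4"]
        v4_scaled = tmt.triage_variables(norm, 3.0 * ref + 2.0)["V4"]
        assert np.allclose(v4, v4_scaled)

    def test_v1_to_v3_identical_in_anchored_and_raw_modes(self):
        rng = np.random.default_rng(5)
        rows = [10 ** rng.uniform(4, 6, 10) for _ in range(15)]
        ref = as_series(np.log10(REFERENCE))
        raw = tmt.triage_variables(tmt.normalize(profiles_frame(rows), "log10_raw"), ref)
        anc = tmt.triage_variables(
            tmt.normalize(profiles_frame(rows), "anchored_to_DKO0"), ref
        )
        assert np.allclose(raw[["V1", "V2", "V3"]], anc[["V1", "V2", "V3"]])


class TestAssignTier:
    def vars_row(self, v1, v2, v3, v4):
        return pd.DataFrame(
            {"site_id": ["s"], "V1": [v1], "V2": [v2], "V3": [v3], "V4": [v4]}
        )

    def test_primary_takes_precedence_over_similarity(self):
        tiers = tmt.assign_tier(self.vars_row(0.2, 0.3, 0.15, 0.2))
        assert tiers["tier"].iloc[0] == "primary"

    def test_similarity_rescues_primary_failure(self):
        tiers = tmt.assign_tier(self.vars_row(0.05, 0.3, 0.15, 0.9))
        assert tiers["tier"].iloc[0] == "similarity_only"

    def test_correlation_boundary_is_strict(self):
        tiers = tmt.assign_tier(self.vars_row(0.05, 0.3, 0.15, 0.7))
        assert tiers["tier"].iloc[0] == "none"

    def test_undefined_v4_is_tier_none(self):
        tiers = tmt.assign_tier(self.vars_row(0.05, 0.05, 0.05, np.nan))
        assert tiers["tier"].iloc[0] == "none"

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(8)
        vars_df = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(200)],
                "V1": rng.normal(0.1, 0.2, 200),
                "V2": rng.normal(0.1, 0.2, 200),
                "V3": rng.normal(0.1, 0.2, 200),
                "V4": rng.uniform(-1, 1, 200),
            }
        )
        strict = tmt.assign_tier(vars_df, TmtThresholds(0.2, 0.2, 0.2, 0.9))
        loose = tmt.assign_tier(vars_df, TmtThresholds(0.05, 0.05, 0.05, 0.5))
        in_strict = set(strict.loc[strict["tier"] != "none", "site_id"])
        in_loose = set(loose.loc[loose["tier"] != "none", "site_id"])
        assert in_strict <= in_loose


class TestSelectMostVariable:
    def test_identity_when_n_equals_total(self):
        rng = np.random.default_rng(1)
        df = tmt.normalize(
            profiles_frame([10 ** rng.uniform(4, 6, 10) for _ in range(8)]), "log10_raw"
        )
        assert len(tmt.select_most_variable(df, 8)) == 8

    def test_planted_high_variance_profile_wins(self):
        quiet = [1e5 * (1 + 0.01 * i) for i in range(10)]
        loud = [10 ** (5 + 0.5 * (i % 2)) for i in range(10)]
        df = tmt.normalize(profiles_frame([quiet, loud], ids=["q", "l"]), "log10_raw")
        assert list(tmt.select_most_variable(df, 1)["site_id"]) == ["l"]

    def test_matches_brute_force_sort(self, small_screen):
        norm = tmt.normalize(
            tmt.complete_profiles_only(small_screen.sites), "log10_raw"
        )
        n = 50
        chosen = set(tmt.select_most_variable(norm, n)["site_id"])
        var = norm[[tmt_col(c) for c in TMT_CONDITIONS]].to_numpy().var(axis=1)
        order = sorted(zip(-var, norm["site_id"]))[:n]
        assert chosen == {sid for _, sid in order}


class TestCorrelationCluster:
    def two_family_frame(self, n_per=20, noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        shape_a = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0], dtype=float)
        shape_b = np.array([1, 1, 1, 1, 1, -1, -1, -1, -1, -1], dtype=float)
        rows, ids, families = [], [], []
        for i in range(n_per):
            for name, shape in (("a", shape_a), ("b", shape_b)):
                rows.append(10 ** (5 + shape + rng.normal(0, noise, 10)))
                ids.append(f"{name}{i:02d}")
                families.append(name)
        df = tmt.normalize(profiles_frame(rows, ids=ids), "log10_raw")
        return df, dict(zip(ids, families))

    def test_k1_single_cluster(self):
        df, _ = self.two_family_frame(n_per=3)
        labels, _ = tmt.correlation_cluster(df, k=1)
        assert set(labels["cluster"]) == {1}

    def test_planted_partition_recovered(self):
        df, families = self.two_family_frame()
        labels, means = tmt.correlation_cluster(df, k=2)
        by_family = labels.assign(fam=[families[s] for s in labels["site_id"]])
        groups = by_family.groupby("fam")["cluster"].nunique()
        assert (groups == 1).all()
        assert by_family.groupby("cluster")["fam"].nunique().eq(1).all()
        assert set(means.index) == {1, 2}

    def test_labels_invariant_under_row_permutation(self):
        df, _ = self.two_family_frame()
        labels1, _ = tmt.correlation_cluster(df, k=2)
        shuffled = df.sample(frac=1.0, random_state=42).reset_index(drop=True)
        labels2, _ = tmt.correlation_cluster(shuffled, k=2)
        merged = labels1.merge(labels2, on="site_id")
        assert (merged["cluster_x"] == merged["cluster_y"]).all()

    def test_flat_profiles_get_dedicated_cluster(self):
        df, _ = self.two_family_frame(n_per=5)
        flat = tmt.normalize(profiles_frame([[1e5] * 10], ids=["flat0"]), "log10_raw")
        combined = pd.concat([df, flat], ignore_index=True)
        labels, means = tmt.correlation_cluster(combined, k=2)
        assert labels.set_index("site_id").loc["flat0", "cluster"] == tmt.FLAT_CLUSTER
        assert tmt.FLAT_CLUSTER in means.index

    def test_too_few_profiles_for_k(self):
        df, _ = self.two_family_frame(n_per=1)
        with pytest.raises(ValueError):
            tmt.correlation_cluster(df, k=5)
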
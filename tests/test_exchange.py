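import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aerodx import (
    AbundanceTable,
    SampleMetadata,
    SitePair,
    SyntheticCohortSpec,
    cooccurrence_prevalence,
    detect_exchanged,
    differential_prevalence,
    generate_cohort,
    null_calibration,
    permutation_p,
    spearman_partial,
    to_relative_abundance,
)


def partial_oracle(x, y, z):
    """Independent evaluation: scipy Spearman correlations + the
    first-order partial-correlation formula."""
    r_xy = stats.spearmanr(x, y).statistic
    r_xz = stats.spearmanr(x, z).statistic
    r_zy = stats.spearmanr(z, y).statistic
    return (r_xy - r_xz * r_zy) / np.sqrt((1 - r_xz**2) * (1 - r_zy**2))


class TestSpearmanPartial:
    def test_matches_oracle_on_random_triples(self):
        rng = np.random.default_rng(0)
        for i in range(300):
            n = int(rng.integers(4, 40))
            if i % 2:  # integer data forces ties
                x, y, z = (rng.integers(0, 5, n).astype(float) for _ in range(3))
                if len(set(x)) < 2 or len(set(y)) < 2 or len(set(z)) < 2:
                    continue
            else:
                x, y, z = (rng.normal(size=n) for _ in range(3))
            r_xz = stats.spearmanr(x, z).statistic
            r_zy = stats.spearmanr(z, y).statistic
            if min(1 - r_xz**2, 1 - r_zy**2) < 1e-3:
                continue  # near-degenerate denominator: not-computable regime
            expected = partial_oracle(x, y, z)
            if not np.isfinite(expected):
                continue
            assert spearman_partial(x, y, z) == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        for _ in range(20):
            x, y, z = (rng.normal(size=25) for _ in range(3))
            df = pd.DataFrame({"x": x, "y": y, "z": z})
            expected = float(
                pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")["r"].iloc[0]
            )
            assert spearman_partial(x, y, z) == pytest.approx(expected, abs=1e-9)

    def test_perfect_concordance(self):
        x = np.array([1.0, 2, 3, 4, 5])
        z = np.array([3.0, 1, 4, 5, 2])
        assert spearman_partial(x, x, z) == pytest.approx(1.0)

    def test_constant_z_reduces_to_plain_spearman(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=15), rng.normal(size=15)
        z = np.full(15, 3.0)
        assert spearman_partial(x, y, z) == pytest.approx(
            stats.spearmanr(x, y).statistic, abs=1e-12
        )

    def test_constant_x_not_computable(self):
        assert np.isnan(spearman_partial([1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1]))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman_partial([1, 2], [1, 2], [1, 2])


class TestPermutationP:
    def test_perfect_correlation_gives_zero(self):
        x = np.arange(8, dtype=float)
        z = np.array([3.0, 7, 1, 0, 5, 2, 6, 4])
        # strict ">" means no null statistic can exceed the observed 1.0
        assert permutation_p(x, x, z, n_permutations=500, seed=0) == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        x, y, z = (rng.normal(size=20) for _ in range(3))
        p1 = permutation_p(x, y, z, n_permutations=500, seed=11)
        p2 = permutation_p(x, y, z, n_permutations=500, seed=11)
        assert p1 == p2

    def test_invariant_to_joint_reordering(self):
        rng = np.random.default_rng(3)
        x, y, z = (rng.normal(size=30) for _ in range(3))
        order = rng.permutation(30)
        assert spearman_partial(x, y, z) == pytest.approx(
            spearman_partial(x[order], y[order], z[order]), abs=1e-12
        )
        p1 = permutation_p(x, y, z, n_permutations=2000, seed=4)
        p2 = permutation_p(x[order], y[order], z[order], n_permutations=2000, seed=4)
        assert abs(p1 - p2) <= 0.03  # Monte-Carlo wobble only

    def test_not_computable_observed_rejected(self):
        with pytest.raises(ValueError, match="not computable"):
            permutation_p([1, 1, 1, 1], [1, 2, 3, 4], [1, 2, 3, 4])


def _small_cohort(seed=0, **kwargs):
    defaults = dict(
        n_patients=45,
        n_otus=60,
        n_exchanged={("lung", "oropharynx"): 8},
        sequencing_depth=10_000,
        seed=seed,
        aspiration_mixing=0.0,
    )
    defaults.update(kwargs)
    spec = SyntheticCohortSpec(**defaults)
    table, meta, truth = generate_cohort(spec)
    return to_relative_abundance(table), meta, truth


class TestDetectExchanged:
    def test_recovers_planted_otus_small(self):
        rel, meta, truth = _small_cohort(seed=8)
        pair = SitePair("lung", "oropharynx")
        results = detect_exchanged(rel, meta, pair, n_permutations=500, seed=8)
        detected = {r.otu_id for r in results if r.exchanged}
        planted = set(truth.exchanged_otu_ids[("lung", "oropharynx")])
        assert len(detected & planted) >= 6  # of 8 planted

    def test_results_respect_invariants(self):
        rel, meta, _ = _small_cohort(seed=9)
        results = detect_exchanged(
            rel, meta, SitePair("lung", "oropharynx"), n_permutations=300, seed=9
        )
        assert results
        for r in results:
            assert -1.0 <= r.partial_rho <= 1.0
            assert 0.0 <= r.perm_p <= 1.0
            assert r.n_patients >= 10
            assert r.q_value >= r.perm_p - 1e-12
            assert r.exchanged == (r.q_value < 0.1)

    def test_deterministic_given_seed(self):
        rel, meta, _ = _small_cohort(seed=10)
        pair = SitePair("lung", "oropharynx")
        r1 = detect_exchanged(rel, meta, pair, n_permutations=300, seed=5)
        r2 = detect_exchanged(rel, meta, pair, n_permutations=300, seed=5)
        assert r1 == r2

    def test_prevalence_filter_empty_result(self):
        # every OTU private to a single patient: nothing passes min_patients
        rng = np.random.default_rng(0)
        n_pat, n_otus = 12, 24
        cols, rows = {}, []
        for i in range(n_pat):
            for site in ("lung", "oropharynx", "gastric"):
                v = np.zeros(n_otus)
                v[2 * i : 2 * i + 2] = rng.integers(50, 100, 2)
                sid = f"P{i}-{site}"
                cols[sid] = v
                rows.append((sid, f"P{i}", site, "B1", "untested"))
        table = AbundanceTable(
            pd.DataFrame(cols, index=[f"o{j}" for j in range(n_otus)]), mode="counts"
        )
        meta = SampleMetadata(
            pd.DataFrame(
                rows,
                columns=["sample_id", "patient_id", "site", "batch", "aspiration_status"],
            ).set_index("sample_id")
        )
        rel = to_relative_abundance(table)
        assert detect_exchanged(rel, meta, SitePair("lung", "oropharynx"), seed=0) == []

    def test_too_few_triple_site_patients(self):
        rel, meta, _ = _small_cohort(seed=11)
        pruned = meta.data[meta.data["site"] != "gastric"]
        with pytest.raises(ValueError, match="all three"):
            detect_exchanged(rel, SampleMetadata(pruned), SitePair("lung", "oropharynx"))

    def test_counts_mode_rejected(self):
        rel, meta, _ = _small_cohort(seed=12)
        counts = AbundanceTable(rel.data * 100, list(rel.taxonomy), mode="counts")
        with pytest.raises(ValueError, match="relative"):
            detect_exchanged(counts, meta, SitePair("lung", "oropharynx"))


class TestNullCalibration:
    def test_shuffling_destroys_planted_signal(self):
        rel, meta, _ = _small_cohort(seed=13)
        cal = null_calibration(
            rel, meta, SitePair("lung", "oropharynx"),
            n_rounds=3, n_permutations=300, seed=13,
        )
        assert cal.n_rounds == 3
        assert cal.median_count <= 2
        assert cal.max_count == max(cal.counts)

    def test_deterministic_given_seed(self):
        rel, meta, _ = _small_cohort(seed=14)
        pair = SitePair("lung", "oropharynx")
        c1 = null_calibration(rel, meta, pair, n_rounds=2, n_permutations=200, seed=3)
        c2 = null_calibration(rel, meta, pair, n_rounds=2, n_permutations=200, seed=3)
        assert c1.counts == c2.counts

    def test_zero_rounds_rejected(self):
        rel, meta, _ = _small_cohort(seed=15)
        with pytest.raises(ValueError, match="n_rounds"):
            null_calibration(rel, meta, SitePair("lung", "oropharynx"), n_rounds=0)


def _prevalence_fixture():
    """4 patients per group; OTU presence patterns chosen by hand."""
    otus = ["oA", "oB", "oC"]
    cols, rows = {}, []
    presence = {
        # (patient, site) -> set of present OTUs
        ("N1", "lung"): {"oA", "oB"}, ("N1", "oropharynx"): {"oA"},
        ("N2", "lung"): {"oA"}, ("N2", "oropharynx"): {"oA", "oB"},
        ("N3", "lung"): {"oA", "oB"}, ("N3", "oropharynx"): {"oA", "oB"},
        ("N4", "lung"): set(), ("N4", "oropharynx"): {"oA"},
        ("A1", "lung"): {"oA", "oB"}, ("A1", "oropharynx"): {"oA", "oB"},
        ("A2", "lung"): {"oA", "oB"}, ("A2", "oropharynx"): {"oA", "oB"},
        ("A3", "lung"): {"oA"}, ("A3", "oropharynx"): {"oA", "oB"},
        ("A4", "lung"): {"oA", "oB"}, ("A4", "oropharynx"): {"oA", "oB"},
    }
    otus = otus + ["oFiller"]  # keeps every sample's total positive
    for (patient, site), present in presence.items():
        sid = f"{patient}-{site}"
        cols[sid] = [10.0 if o in present else 0.0 for o in otus[:-1]] + [5.0]
        status = "aspirator" if patient.startswith("A") else "non_aspirator"
        rows.append((sid, patient, site, "B1", status))
    table = AbundanceTable(pd.DataFrame(cols, index=otus), mode="counts")
    meta = SampleMetadata(
        pd.DataFrame(
            rows,
            columns=["sample_id", "patient_id", "site", "batch", "aspiration_status"],
        ).set_index("sample_id")
    )
    return to_relative_abundance(table), meta


class TestPrevalence:
    def test_hand_counted_prevalences(self):
        rel, meta = _prevalence_fixture()
        pair = SitePair("lung", "oropharynx")
        non = cooccurrence_prevalence(rel, meta, ["oA", "oB", "oC"], pair, "non_aspirator")
        asp = cooccurrence_prevalence(rel, meta, ["oA", "oB", "oC"], pair, "aspirator")
        # oA co-occurs in N1,N2,N3 of 4 non-aspirators; all 4 aspirators
        assert non.prevalence["oA"] == pytest.approx(75.0)
        assert asp.prevalence["oA"] == pytest.approx(100.0)
        assert non.prevalence["oB"] == pytest.approx(25.0)
        assert asp.prevalence["oB"] == pytest.approx(75.0)
        assert non.prevalence["oC"] == 0.0

    def test_fractional_prevalence_rounding(self):
        # 7 of 23 co-occurring patients -> 30.4% at one decimal place
        assert round(100 * 7 / 23, 1) == 30.4

    def test_monotone_in_added_patient(self):
        rel, meta = _prevalence_fixture()
        pair = SitePair("lung", "oropharynx")
        before = cooccurrence_prevalence(rel, meta, ["oA", "oB"], pair, "non_aspirator")
        # add a non-aspirator patient carrying every OTU in both sites
        data = rel.data.copy()
        data["N5-lung"] = [0.4, 0.4, 0.0, 0.2]
        data["N5-oropharynx"] = [0.4, 0.4, 0.0, 0.2]
        meta2 = meta.data.copy()
        meta2.loc["N5-lung"] = ["N5", "lung", "B1", "non_aspirator"]
        meta2.loc["N5-oropharynx"] = ["N5", "oropharynx", "B1", "non_aspirator"]
        after = cooccurrence_prevalence(
            AbundanceTable(data, list(rel.taxonomy), "relative"),
            SampleMetadata(meta2), ["oA", "oB"], pair, "non_aspirator",
        )
        assert (after.prevalence >= before.prevalence - 1e-12).all()

    def test_empty_group_rejected(self):
        rel, meta = _prevalence_fixture()
        with pytest.raises(ValueError, match="untested"):
            cooccurrence_prevalence(
                rel, meta, ["oA"], SitePair("lung", "oropharynx"), "untested"
            )


class TestDifferentialPrevalence:
    def test_differences_from_printed_prevalences(self):
        # published per-OTU co-occurrence percentages as inputs
        non = pd.Series({"Flavobacteriaceae": 8.7, "Neisseria": 17.4})
        asp = pd.Series({"Flavobacteriaceae": 48.0, "Neisseria": 20.0})
        from aerodx.exchange import PrevalenceResult

        pair = SitePair("lung", "oropharynx")
        res = differential_prevalence(
            PrevalenceResult(non, 23, "non_aspirator", pair),
            PrevalenceResult(asp, 25, "aspirator", pair),
        )
        assert res.per_otu.loc["Flavobacteriaceae", "difference"] == pytest.approx(39.3)
        assert res.per_otu.loc["Neisseria", "difference"] == pytest.approx(2.6)

    def test_identical_vectors_degenerate(self):
        from aerodx.exchange import PrevalenceResult

        pair = SitePair("lung", "oropharynx")
        prev = pd.Series({"a": 30.0, "b": 60.0})
        res = differential_prevalence(
            PrevalenceResult(prev, 10, "g1", pair),
            PrevalenceResult(prev.copy(), 10, "g2", pair),
        )
        assert (res.per_otu["difference"] == 0).all()
        assert res.p_value == 1.0

    def test_mismatched_otu_sets_rejected(self):
        from aerodx.exchange import PrevalenceResult

        pair = SitePair("lung", "oropharynx")
        with pytest.raises(ValueError, match="different OTU sets"):
            differential_prevalence(
                PrevalenceResult(pd.Series({"a": 1.0}), 5, "g1", pair),
                PrevalenceResult(pd.Series({"b": 1.0}), 5, "g2", pair),
            )
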
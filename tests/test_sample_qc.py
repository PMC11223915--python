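import random
import statistics

import pytest

from varshare.errors import CohortTooSmallError
from varshare.fixtures import CohortRecipe, simulate_cohort
from varshare.regions import PanelRegions
from varshare.sample_qc import (
    SampleProfile,
    detect_noisy_empty,
    duplicate_score,
    kinship,
    profile_from_vcf,
    relatedness_clusters,
    run_cohort_qc,
    tukey_bounds,
    write_cohort_report,
)

PANEL = PanelRegions.from_intervals([("1", 0, 100000)])


def profile(sid, keys=(), genotypes=None, panel=PANEL, family=None, order=0):
    return SampleProfile(
        sample_id=sid,
        variant_keys=frozenset(keys),
        panel=panel,
        genotypes=genotypes or {},
        positions={k: ("1", int(k.split(":")[1])) for k in keys},
        family_id=family,
        submission_index=order,
    )


def brute_quantile(values, q):
    """Independent linear-interpolation quantile (oracle)."""
    ordered = sorted(values)
    h = (len(ordered) - 1) * q
    lo = int(h)
    hi = min(lo + 1, len(ordered) - 1)
    return ordered[lo] + (h - lo) * (ordered[hi] - ordered[lo])


class TestTukeyBounds:
    def test_degenerate_distribution(self):
        fences = tukey_bounds([7, 7, 7, 7, 7])
        assert fences.lower == fences.upper == 7

    def test_against_quantile_oracle(self):
        counts = [10, 12, 14, 16, 100]
        fences = tukey_bounds(counts)
        q1 = brute_quantile(counts, 0.25)
        q3 = brute_quantile(counts, 0.75)
        iqr = q3 - q1
        assert fences.lower == pytest.approx(q1 - 4 * iqr)
        assert fences.upper == pytest.approx(q3 + 5 * iqr)

    def test_random_cohorts_match_oracle(self):
        rng = random.Random(4)
        for _ in range(50):
            counts = [rng.randrange(0, 500) for _ in range(rng.randrange(4, 40))]
            fences = tukey_bounds(counts)
            q1, q3 = brute_quantile(counts, 0.25), brute_quantile(counts, 0.75)
            assert fences.lower == pytest.approx(q1 - 4 * (q3 - q1))
            assert fences.upper == pytest.approx(q3 + 5 * (q3 - q1))

    def test_too_small_cohort(self):
        with pytest.raises(CohortTooSmallError):
            tukey_bounds([1, 2, 3])


class TestDetectNoisyEmpty:
    def _cohort(self, counts):
        return [
            profile(f"S{i}", [f"1:{100 + j}:A:G" for j in range(c)])
            for i, c in enumerate(counts)
        ]

    def test_noisy_flagged(self):
        verdicts = detect_noisy_empty(self._cohort([10, 11, 12, 11, 10, 500]))
        assert verdicts["S5"] == "noisy"
        assert verdicts["S0"] == "ok"

    def test_empty_flagged(self):
        verdicts = detect_noisy_empty(self._cohort([100, 101, 102, 101, 100, 0]))
        assert verdicts["S5"] == "empty"

    def test_iqr_zero_one_extra_variant_flagged(self):
        verdicts = detect_noisy_empty(self._cohort([50, 50, 50, 50, 51]))
        assert verdicts["S4"] == "noisy"

    def test_on_fence_retained(self):
        # IQR 0 cohort: bound == count -> strict inequality keeps the sample
        verdicts = detect_noisy_empty(self._cohort([50, 50, 50, 50, 50]))
        assert set(verdicts.values()) == {"ok"}

    def test_inside_fences_never_flagged(self):
        counts = [40, 45, 50, 55, 60]
        fences = tukey_bounds(counts)
        newcomer = int((fences.lower + fences.upper) / 2)
        verdicts = detect_noisy_empty(self._cohort(counts + [newcomer]))
        assert verdicts["S5"] == "ok"


class TestDuplicateScore:
    def test_identical_profiles(self):
        keys = [f"1:{i}:A:G" for i in range(100, 120)]
        score = duplicate_score(profile("A", keys), profile("B", keys))
        assert score.p1 == score.p2 == 1.0
        assert score.score == 1.0
        assert score.is_duplicate

    def test_disjoint_sets(self):
        a = profile("A", ["1:100:A:G"])
        b = profile("B", ["1:200:C:T"])
        score = duplicate_score(a, b)
        assert score.score == 0.0
        assert not score.is_duplicate

    def test_partial_overlap_arithmetic(self):
        shared = [f"1:{i}:A:G" for i in range(100, 108)]  # 8 shared
        a = profile("A", shared + [f"1:{i}:C:T" for i in range(200, 202)])  # 10
        b = profile("B", shared + [f"1:{i}:C:T" for i in range(300, 308)])  # 16
        score = duplicate_score(a, b)
        assert score.p1 == pytest.approx(0.8)
        assert score.p2 == pytest.approx(0.5)
        assert score.score == pytest.approx(0.65)
        assert not score.is_duplicate

    def test_symmetry(self):
        a = profile("A", [f"1:{i}:A:G" for i in range(100, 110)])
        b = profile("B", [f"1:{i}:A:G" for i in range(105, 125)])
        ab, ba = duplicate_score(a, b), duplicate_score(b, a)
        assert ab.score == pytest.approx(ba.score)

    def test_empty_panel_intersection_skipped(self):
        a = profile("A", ["1:100:A:G"], panel=PanelRegions.from_intervals([("1", 0, 500)]))
        b = profile("B", ["2:100:A:G"], panel=PanelRegions.from_intervals([("2", 0, 500)]))
        assert duplicate_score(a, b) is None

    def test_restricted_to_panel_intersection(self):
        left = PanelRegions.from_intervals([("1", 0, 500)])
        wide = PanelRegions.from_intervals([("1", 0, 100000)])
        shared = [f"1:{i}:A:G" for i in range(100, 110)]
        extra_outside = [f"1:{i}:C:T" for i in range(1000, 1050)]  # outside `left`
        a = profile("A", shared, panel=left)
        b = profile("B", shared + extra_outside, panel=wide)
        score = duplicate_score(a, b)
        assert score.score == 1.0  # outside calls are invisible to the test


class TestKinship:
    def _geno_profile(self, sid, dosages, panel=PANEL):
        genotypes = {("1", 100 + i): d for i, d in enumerate(dosages) if d}
        keys = [f"1:{100 + i}:A:G" for i, d in enumerate(dosages) if d]
        return SampleProfile(
            sample_id=sid,
            variant_keys=frozenset(keys),
            panel=panel,
            genotypes=genotypes,
            positions={k: ("1", int(k.split(":")[1])) for k in keys},
        )

    def test_self_phi_half(self):
        p = self._geno_profile("A", [1, 1, 0, 2, 1])
        est = kinship(p, p)
        assert est.phi == pytest.approx(0.5)

    def test_self_phi_independent_of_site_count(self):
        for n in (10, 100, 1000):
            p = self._geno_profile("A", [1] * n)
            assert kinship(p, p).phi == pytest.approx(0.5)

    def test_no_het_sites_undefined(self):
        a = self._geno_profile("A", [2, 0, 2])
        b = self._geno_profile("B", [0, 2, 2])
        assert kinship(a, b) is None

    def test_opposite_homozygotes_push_negative(self):
        a = self._geno_profile("A", [2, 2, 2, 1])
        b = self._geno_profile("B", [0, 0, 0, 1])
        est = kinship(a, b)
        assert est.phi < 0

    def test_unrelated_simulation_oracle(self):
        cohort = simulate_cohort(CohortRecipe(seed=21, n_unrelated=20, n_sites=2000))
        profiles = cohort.profiles()
        phis = []
        for i in range(0, 18, 2):
            est = kinship(profiles[i], profiles[i + 1])
            phis.append(est.phi)
        assert abs(statistics.mean(phis)) < 0.03

    def test_parent_offspring_simulation_oracle(self):
        phis = []
        for seed in range(3):
            cohort = simulate_cohort(
                CohortRecipe(seed=seed, n_unrelated=0, n_parent_offspring=4, n_sites=2000)
            )
            profiles = {p.sample_id: p for p in cohort.profiles()}
            by_family: dict[str, list[str]] = {}
            for sample in cohort.samples:
                by_family.setdefault(sample.family_id, []).append(sample.sample_id)
            for pair in by_family.values():
                phis.append(kinship(profiles[pair[0]], profiles[pair[1]]).phi)
        assert abs(statistics.mean(phis) - 0.25) < 0.03


class TestRelatednessClusters:
    def test_kin_and_family_edges_merge(self):
        clusters = relatedness_clusters(
            ["A", "B", "C"], [("A", "B")], {"A": None, "B": "F1", "C": "F1"}
        )
        assert clusters == [frozenset({"A", "B", "C"})]

    def test_no_edges_singletons(self):
        clusters = relatedness_clusters(["A", "B"], [], {})
        assert sorted(len(c) for c in clusters) == [1, 1]

    def test_duplicate_edges_no_double_count(self):
        clusters = relatedness_clusters(["A", "B"], [("A", "B"), ("A", "B")], {})
        assert clusters == [frozenset({"A", "B"})]


class TestCohortDriver:
    def test_injected_pathologies_recovered(self, qc_cohort):
        result = run_cohort_qc(qc_cohort.profiles())
        roles = {s.sample_id: s.role for s in qc_cohort.samples}
        for sid, verdict in result.verdicts.items():
            if roles[sid] in ("noisy", "empty", "duplicate"):
                assert verdict == roles[sid], sid
            else:
                assert verdict == "ok", sid

    def test_family_pairs_share_cluster(self, qc_cohort):
        result = run_cohort_qc(qc_cohort.profiles())
        by_family: dict[str, list[str]] = {}
        for sample in qc_cohort.samples:
            if sample.family_id:
                by_family.setdefault(sample.family_id, []).append(sample.sample_id)
        for members in by_family.values():
            containing = [c for c in result.clusters if set(members) <= c]
            assert containing, members

    def test_report_written(self, qc_cohort, tmp_path):
        result = run_cohort_qc(qc_cohort.profiles())
        out = tmp_path / "report.tsv"
        write_cohort_report(result, out)
        assert out.read_text().startswith("subject\ttest\tstatistic\tverdict")

    def test_small_cohort_skips_fences(self):
        profiles = [profile("A", ["1:100:A:G"]), profile("B", ["1:100:A:G"])]
        result = run_cohort_qc(profiles)
        assert any("skipped" in w for w in result.warnings)


def test_profile_from_vcf_round_trip(tmp_path, qc_cohort):
    qc_cohort.write(tmp_path)
    sample = qc_cohort.samples[0]
    panel = PanelRegions.from_bed(tmp_path / "panel.bed")
    prof = profile_from_vcf(
        tmp_path / f"{sample.sample_id}.vcf", sample.sample_id, panel, min_depth=10
    )
    expected = {qc_cohort.site_key(i) for i in sample.genotypes}
    assert prof.variant_keys == frozenset(expected)
    dosages = {qc_cohort.sites[i]: d for i, d in sample.genotypes.items()}
    assert {pos: d for (_c, pos), d in prof.genotypes.items()} == dosages
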
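"""Landscape statistics: burden, age association, KDE ratio, exclusivity,
CNV tracks, co-occurrence."""

import math

import numpy as np
import pandas as pd
import pytest

from clonetraj import landscape
from clonetraj.datatypes import ClinicalRecord, CnvSegment, VariantCall


def clin(pid, subgroup="pediatric T-ALL", age=10.0):
    age_group, entity = subgroup.split(" ", 1)
    return ClinicalRecord(pid, entity, age_group, age, False, 1000.0, False, [0])


def var(pid, gene, tp=0):
    return VariantCall(pid, f"{pid}:T{tp}", tp, "1", 1000, "A", "T", gene,
                       vaf=0.4, depth=500)


class TestBurden:
    def test_mean_and_sd(self):
        clinical = [clin("P1"), clin("P2")]
        variants = [var("P1", "G1"), var("P1", "G2"),
                    var("P2", "G1"), var("P2", "G2"), var("P2", "G3"), var("P2", "G4")]
        df = landscape.mutation_burden_summary(variants, clinical)
        row = df.loc["pediatric T-ALL"]
        assert row["variant_mean"] == pytest.approx(3.0)
        assert row["variant_sd"] == pytest.approx(math.sqrt(2))

    def test_single_patient_degenerate_sd(self):
        df = landscape.mutation_burden_summary([var("P1", "G1")], [clin("P1")])
        assert df.loc["pediatric T-ALL", "variant_sd"] == 0.0
        assert bool(df.loc["pediatric T-ALL", "degenerate_sd"])

    def test_poisson_burden_sampling(self, rng):
        clinical = [clin(f"P{i}") for i in range(500)]
        variants = []
        for i in range(500):
            for j in range(rng.poisson(3)):
                variants.append(var(f"P{i}", f"G{j}"))
        df = landscape.mutation_burden_summary(variants, clinical)
        se = math.sqrt(3 / 500)
        assert abs(df.loc["pediatric T-ALL", "variant_mean"] - 3) < 3 * se

    def test_relapse_samples_excluded(self):
        clinical = [clin("P1")]
        variants = [var("P1", "G1", tp=0), var("P1", "G2", tp=300)]
        df = landscape.mutation_burden_summary(variants, clinical)
        assert df.loc["pediatric T-ALL", "variant_mean"] == 1.0


class TestAgeAssociation:
    def _matrix(self, mutated, all_patients):
        genes = ["G"]
        data = [[p in mutated for p in all_patients]]
        return pd.DataFrame(data, index=genes, columns=all_patients)

    def test_exact_ranksum_example(self):
        """Fully separated ages {30,35,40} vs {5,6,7}: exact two-sided
        rank-sum p = 2/C(6,3) = 0.1."""
        patients = [f"P{i}" for i in range(6)]
        mat = self._matrix({"P0", "P1", "P2"}, patients)
        ages = pd.Series([30, 35, 40, 5, 6, 7.0], index=patients)
        df = landscape.gene_age_association(mat, ages, min_freq=0.05)
        assert df.loc["G", "p_value"] == pytest.approx(0.1)

    def test_low_frequency_gene_excluded(self):
        patients = [f"P{i}" for i in range(25)]
        mat = self._matrix({"P0"}, patients)  # 4% < 5%
        ages = pd.Series(np.arange(25.0), index=patients)
        df = landscape.gene_age_association(mat, ages, min_freq=0.05)
        assert math.isnan(df.loc["G", "p_value"])
        assert "frequency" in df.loc["G", "note"]

    def test_all_mutated_skipped(self):
        patients = ["P0", "P1", "P2"]
        mat = self._matrix(set(patients), patients)
        ages = pd.Series([1.0, 2.0, 3.0], index=patients)
        df = landscape.gene_age_association(mat, ages)
        assert math.isnan(df.loc["G", "p_value"])

    def test_null_pvalues_roughly_uniform(self, rng):
        """Permuting mutation labels against age: p-values not enriched at
        the tail beyond binomial noise."""
        patients = [f"P{i}" for i in range(40)]
        ages = pd.Series(rng.uniform(1, 60, 40), index=patients)
        ps = []
        for rep in range(300):
            mutated = set(rng.choice(patients, size=10, replace=False))
            mat = self._matrix(mutated, patients)
            df = landscape.gene_age_association(mat, ages)
            ps.append(df.loc["G", "p_value"])
        frac = np.mean(np.array(ps) <= 0.05)
        assert frac < 0.05 + 3 * math.sqrt(0.05 * 0.95 / 300)


class TestAgeDensity:
    def test_self_normalization_is_flat(self, rng):
        ages = rng.uniform(1, 60, 200)
        curve = landscape.age_density_curve(ages, ages)
        d = curve.density[curve.supported]
        assert d.max() / d.min() <= 1.05

    def test_upper_age_shift_raises_upper_density(self, rng):
        ages = rng.uniform(0, 60, 400)
        mutated = ages[ages > np.median(ages)]
        curve = landscape.age_density_curve(mutated, ages)
        half = len(curve.grid) // 2
        assert curve.density[half:].sum() > curve.density[:half].sum()

    def test_doubling_bandwidth_smooths(self, rng):
        ages = rng.uniform(0, 60, 300)
        mutated = rng.choice(ages, 80, replace=False)
        c1 = landscape.age_density_curve(mutated, ages)
        c2 = landscape.age_density_curve(mutated, ages,
                                         bandwidth=2 * c1.bandwidth)
        tv1 = np.abs(np.diff(c1.density)).sum()
        tv2 = np.abs(np.diff(c2.density)).sum()
        assert tv2 < tv1

    def test_needs_two_mutated(self):
        with pytest.raises(ValueError):
            landscape.age_density_curve([5.0], np.arange(20.0))


class TestExclusivity:
    def _matrix(self, a_set, b_set, patients):
        return pd.DataFrame(
            [[p in a_set for p in patients], [p in b_set for p in patients]],
            index=["A", "B"], columns=patients)

    def test_direct_or_formula(self):
        patients = [f"P{i}" for i in range(20)]
        a = set(patients[:10])
        b = {patients[0]} | set(patients[10:19])
        mat = self._matrix(a, b, patients)
        res = landscape.mutual_exclusivity(mat, "A", "B")
        assert (res.n11, res.n10, res.n01, res.n00) == (1, 9, 9, 1)
        assert res.odds_ratio == pytest.approx(1 / 81)

    def test_never_cooccurring_gives_zero(self):
        patients = [f"P{i}" for i in range(12)]
        mat = self._matrix(set(patients[:5]), set(patients[5:10]), patients)
        res = landscape.mutual_exclusivity(mat, "A", "B")
        assert res.odds_ratio == 0.0 and not res.or_infinite

    def test_symmetry(self):
        patients = [f"P{i}" for i in range(15)]
        mat = self._matrix(set(patients[:6]), set(patients[4:9]), patients)
        r1 = landscape.mutual_exclusivity(mat, "A", "B")
        r2 = landscape.mutual_exclusivity(mat, "B", "A")
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_independent_genes_calibrated(self, rng):
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            patients = [f"P{i}" for i in range(30)]
            a = set(np.array(patients)[rng.uniform(size=30) < 0.4])
            b = set(np.array(patients)[rng.uniform(size=30) < 0.4])
            res = landscape.mutual_exclusivity(self._matrix(a, b, patients), "A", "B")
            hits += res.p_value <= 0.05
        # Fisher exact is conservative: at or below nominal + noise
        assert hits / n_rep < 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_rep)


def seg(pid, chrom, start, end, cn=1, loh=False, tp=0):
    return CnvSegment(pid, f"{pid}:T{tp}", tp, chrom, start, end, cn, loh)


class TestCnvTrack:
    def test_full_arm_deletion_quarter_of_patients(self):
        patients = ["P1", "P2", "P3", "P4"]
        segs = [seg("P1", "9", 1, 43_000_000)]  # whole p arm
        track = landscape.cnv_frequency_track(segs, patients)
        f = landscape.arm_weighted_frequency(track, "9", "p", "del")
        assert f == pytest.approx(0.25)

    def test_half_arm_halves_the_weight(self):
        patients = ["P1", "P2", "P3", "P4"]
        segs = [seg("P1", "9", 1, 21_500_000)]  # half the p arm
        track = landscape.cnv_frequency_track(segs, patients)
        f = landscape.arm_weighted_frequency(track, "9", "p", "del")
        assert f == pytest.approx(0.125, abs=0.005)

    def test_invariant_to_segment_splitting(self):
        patients = ["P1", "P2"]
        whole = [seg("P1", "9", 1, 30_000_000)]
        split = [seg("P1", "9", 1, 15_000_000),
                 seg("P1", "9", 15_000_001, 30_000_000)]
        t1 = landscape.cnv_frequency_track(whole, patients)
        t2 = landscape.cnv_frequency_track(split, patients)
        np.testing.assert_allclose(t1.frequencies[("9", "del")],
                                   t2.frequencies[("9", "del")])

    def test_frequencies_never_exceed_one(self):
        patients = ["P1"]
        segs = [seg("P1", "9", 1, 10_000_000), seg("P1", "9", 1, 10_000_000, tp=0)]
        track = landscape.cnv_frequency_track(segs, patients)
        assert track.frequencies[("9", "del")].max() <= 1.0

    def test_unknown_chromosome_errors(self):
        with pytest.raises(KeyError):
            landscape.cnv_frequency_track([seg("P1", "chrZ", 1, 100)], ["P1"])


class TestCooccurrence:
    def test_examples(self):
        events = {"P1": {"A", "B"}, "P2": {"A", "B"}, "P3": {"A"},
                  "P4": set(), "P5": {"B"}}
        patients = list(events)
        assert landscape.cooccurrence_rate(events, "A", "B", patients) == 0.4
        assert landscape.cooccurrence_rate(events, "A", "C", patients) == 0.0

    def test_identical_events_rate_equals_frequency(self):
        events = {f"P{i}": ({"A", "B"} if i < 3 else set()) for i in range(10)}
        patients = list(events)
        rate = landscape.cooccurrence_rate(events, "A", "B", patients)
        freq_a = np.mean([("A" in events[p]) for p in patients])
        assert rate == pytest.approx(freq_a)
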
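"""Enterprise scoring, percentile interpolation, banding and summaries."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ehi import (
    ChemicalAgent,
    ControlProfile,
    ExposureEntry,
    ManagementProfile,
    ValidationError,
    assign_priorities,
    band_index_profiles,
    distribution_stats,
    percentile,
    score_enterprise,
    summarize_industries,
)
from ehi.scoring import EnterpriseRecord, IndustrySummary


def make_record(eid="e1", code="22", n_chem=1, oel=10.0, minutes=225.0,
                n_measures=2, ee="EEp", ppe="PPEe"):
    agent = ChemicalAgent("chem", oel_twa=oel)
    return EnterpriseRecord(
        enterprise_id=eid,
        industry_code=code,
        industry_name=f"Industry {code}",
        exposures=tuple(ExposureEntry(agent, minutes) for _ in range(n_chem)),
        management=ManagementProfile(n_measures=n_measures),
        controls=ControlProfile(ee, ppe),
    )


class TestScoreEnterprise:
    def test_single_chemical_product(self, params):
        # TI_cor(10 ppm)=8.94, MI(2)=0.60, PI(EEp+PPEe)=0.61 -> PDI=0.395
        rec = make_record(minutes=225)
        score = score_enterprise(rec, params)
        b = score.per_chemical[0].indices
        assert b.ehi == pytest.approx(b.ti * b.ei * b.pdi, rel=1e-12)
        assert b.pdi == pytest.approx(1 - (0.60 + 0.61) / 2)
        assert score.ehi_total == pytest.approx(b.ehi)

    def test_published_style_product(self, params):
        # index values as printed: 8.94 * 0.52 * PDI(0.60, 0.42) = 2.278
        assert 8.94 * 0.52 * (1 - (0.60 + 0.42) / 2) == pytest.approx(2.278, abs=1e-3)
        rec = make_record(n_measures=2, ee="EEp", ppe="PPEn", minutes=225)
        b = score_enterprise(rec, params).per_chemical[0].indices
        assert b.pdi == pytest.approx(1 - (0.60 + 0.42) / 2)

    def test_zero_exposures_scores_zero(self, params):
        rec = make_record()
        rec = EnterpriseRecord(rec.enterprise_id, rec.industry_code, rec.industry_name,
                               (), rec.management, rec.controls)
        assert score_enterprise(rec, params).ehi_total == 0.0

    def test_duplicate_chemical_doubles_contribution(self, params):
        one = score_enterprise(make_record(n_chem=1), params).ehi_total
        two = score_enterprise(make_record(n_chem=2), params).ehi_total
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_full_protection_zeroes_ehi(self, params):
        rec = make_record(n_measures=4, ee="EEe", ppe="PPEe", oel=0.005, minutes=480)
        assert score_enterprise(rec, params).ehi_total == 0.0

    def test_error_names_enterprise(self, params):
        rec = make_record(eid="plantX")
        bad = EnterpriseRecord(rec.enterprise_id, rec.industry_code, rec.industry_name,
                               rec.exposures, rec.management, rec.controls)
        object.__setattr__(bad.exposures[0], "exposure_minutes", -5)
        with pytest.raises(ValidationError, match="plantX"):
            score_enterprise(bad, params)


def _percentile_oracle(values, p):
    vals = sorted(values)
    h = (len(vals) - 1) * p + 1  # 1-based rank
    lo = math.floor(h)
    frac = h - lo
    if lo >= len(vals):
        return vals[-1]
    return vals[lo - 1] + frac * (vals[lo] - vals[lo - 1])


class TestPercentile:
    def test_published_cutoffs_on_national_values(self, national_ehi):
        assert percentile(national_ehi, 0.90) == pytest.approx(32.43, abs=0.005)
        assert percentile(national_ehi, 0.70) == pytest.approx(20.61, abs=0.005)
        assert percentile(national_ehi, 0.50) == pytest.approx(10.41, abs=0.005)

    def test_hand_interpolation(self):
        assert percentile([1, 2, 3, 4, 5], 0.95) == pytest.approx(4.8)

    def test_extremes_are_min_and_max(self):
        vals = [3.2, -1.0, 7.7, 0.0]
        assert percentile(vals, 0.0) == min(vals)
        assert percentile(vals, 1.0) == max(vals)

    def test_brute_force_oracle_and_numpy_agreement(self):
        rng = random.Random(7)
        for _ in range(1000):
            n = rng.randint(2, 50)
            vals = [rng.uniform(-100, 100) for _ in range(n)]
            p = rng.random()
            got = percentile(vals, p)
            assert got == pytest.approx(_percentile_oracle(vals, p), rel=1e-9, abs=1e-9)
            assert got == pytest.approx(float(np.percentile(vals, 100 * p)), rel=1e-9, abs=1e-9)

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            percentile([], 0.5)
        with pytest.raises(ValidationError):
            percentile([1.0], 1.5)


class TestSummarizeIndustries:
    def _scores(self, params, ehis, code="22"):
        records, scores = [], []
        for i, _ in enumerate(ehis):
            rec = make_record(eid=f"e{i}", code=code)
            records.append(rec)
            scores.append(score_enterprise(rec, params))
        # replace totals with the requested values
        from dataclasses import replace

        scores = [replace(s, ehi_total=v) for s, v in zip(scores, ehis)]
        return scores, records

    def test_default_statistic_is_p95(self, params):
        scores, records = self._scores(params, [1, 2, 3, 4, 5])
        (summary,) = summarize_industries(scores, records)
        assert summary.statistic == pytest.approx(4.8)
        assert summary.n_enterprises == 5

    def test_single_enterprise_statistic_is_its_ehi(self, params):
        scores, records = self._scores(params, [7.25])
        (summary,) = summarize_industries(scores, records)
        assert summary.statistic == pytest.approx(7.25)

    def test_grouping_by_industry(self, params):
        s1, r1 = self._scores(params, [1, 2], code="22")
        s2, r2 = self._scores(params, [9], code="17")
        s2 = [type(s2[0])(enterprise_id="x17", industry_code="17",
                          per_chemical=s2[0].per_chemical, ehi_total=9.0)]
        r2 = [make_record(eid="x17", code="17")]
        out = summarize_industries(s1 + s2, r1 + r2)
        assert {(s.industry_code, s.n_enterprises) for s in out} == {("22", 2), ("17", 1)}

    def test_mean_statistic_option(self, params):
        scores, records = self._scores(params, [1, 2, 3, 4, 5])
        (summary,) = summarize_industries(scores, records, statistic_kind="mean")
        assert summary.statistic == pytest.approx(3.0)

    def test_orphan_score_rejected(self, params):
        scores, records = self._scores(params, [1.0])
        with pytest.raises(ValidationError):
            summarize_industries(scores, [])


def _summaries(values):
    return [IndustrySummary(industry_code=f"{i:02d}", industry_name=f"I{i}",
                            n_enterprises=3, statistic=v)
            for i, v in enumerate(values)]


class TestAssignPriorities:
    def test_national_band_sizes(self, national_ehi):
        pa = assign_priorities(_summaries(national_ehi))
        assert pa.band_sizes() == (3, 5, 5, 12)
        p90, p70, p50 = pa.cutoffs
        assert (round(p90, 2), round(p70, 2), round(p50, 2)) == (32.43, 20.61, 10.41)

    def test_all_equal_values_all_band_one(self):
        pa = assign_priorities(_summaries([5.0] * 10))
        assert set(pa.bands.values()) == {1}

    def test_value_exactly_at_cutoff_takes_higher_band(self, national_ehi):
        pa = assign_priorities(_summaries(national_ehi))
        # 10.41 is exactly the p50 cutoff -> band 3, not 4
        idx = national_ehi.index(10.41)
        assert pa.bands[f"{idx:02d}"] == 3

    def test_partition_covers_every_industry(self, national_ehi):
        pa = assign_priorities(_summaries(national_ehi))
        assert sum(pa.band_sizes()) == len(national_ehi)
        assert set(pa.bands.values()) <= {1, 2, 3, 4}

    def test_scaling_invariance(self, national_ehi):
        base = assign_priorities(_summaries(national_ehi))
        scaled = assign_priorities(_summaries([3.7 * v for v in national_ehi]))
        assert scaled.bands == base.bands
        assert scaled.cutoffs == pytest.approx(tuple(3.7 * c for c in base.cutoffs))

    def test_permutation_invariance(self, national_ehi):
        base = assign_priorities(_summaries(national_ehi))
        rng = random.Random(3)
        summaries = _summaries(national_ehi)
        rng.shuffle(summaries)
        assert assign_priorities(summaries).bands == base.bands

    def test_fewer_than_four_industries_warns(self):
        with pytest.warns(UserWarning):
            assign_priorities(_summaries([1.0, 2.0]))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            assign_priorities([])


class TestDistributionStats:
    def test_national_values_round_to_published(self, national_ehi):
        mean, sd = distribution_stats(national_ehi)
        assert round(mean, 1) == 14.7
        assert round(sd, 1) == 12.0

    def test_hand_computation(self):
        mean, sd = distribution_stats([0, 2])
        assert (mean, sd) == (1.0, pytest.approx(math.sqrt(2)))

    def test_constant_vector_sd_zero(self):
        assert distribution_stats([3, 3, 3])[1] == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValidationError):
            distribution_stats([1.0])


class TestBandIndexProfiles:
    def test_single_enterprise_mean_equals_value_se_zero(self, params):
        rec = make_record()
        scores = [score_enterprise(rec, params)]
        pa = assign_priorities(
            [IndustrySummary("22", "I", 1, scores[0].ehi_total)] +
            _summaries([0.1, 0.2, 0.3]))
        with pytest.warns(UserWarning):  # synthetic filler bands are empty
            prof = band_index_profiles(scores, [rec], pa)
        row = prof[(prof["index"] == "ti")].iloc[0]
        assert row["se"] == 0.0
        assert row["mean"] == pytest.approx(scores[0].per_chemical[0].indices.ti)

    def test_two_identical_enterprises_se_zero(self, params):
        recs = [make_record(eid="a"), make_record(eid="b")]
        scores = [score_enterprise(r, params) for r in recs]
        pa = assign_priorities(
            [IndustrySummary("22", "I", 2, scores[0].ehi_total)] + _summaries([0.1, 0.2, 0.3]))
        with pytest.warns(UserWarning):
            prof = band_index_profiles(scores, recs, pa)
        assert (prof["se"] == 0.0).all()
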
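import numpy as np
import pytest

from trawlkit.errors import ConfigError, InvalidInputError, MissingParameterError
from trawlkit.species import Category, Individual, Sample
from trawlkit.standardize import (
    abundance_table,
    aggregate_abundance,
    aggregate_biomass,
    bin_lengths,
    biomass_table,
    standardized_abundance,
    standardized_biomass,
)

from conftest import make_random_dataset


def make_sample(sp=1.0, dp=1.0, cat=Category.LANDED, sid="s1", hid="h1"):
    return Sample(sample_id=sid, haul_id=hid, category=cat,
                  subsample_weight=1.0, fraction_weight=sp, sp=sp, dp=dp)


class TestBinLengths:
    def test_enumerated_assignment(self):
        inds = [Individual("X", L, "s1") for L in (2.1, 2.9, 3.0)]
        out = {(c.length_class): c.count for c in bin_lengths(inds, 1.0)}
        assert out == {2.0: 2, 3.0: 1}

    def test_empty_input(self):
        assert bin_lengths([], 1.0) == []

    def test_boundary_falls_in_upper_bin(self):
        (c,) = bin_lengths([Individual("X", 3.0, "s1")], 1.0)
        assert c.length_class == 3.0

    def test_half_cm_bins(self):
        (c,) = bin_lengths([Individual("X", 2.3, "s1")], 0.5)
        assert c.length_class == 2.0

    def test_total_count_preserved(self):
        rng = np.random.default_rng(3)
        inds = [Individual("X", float(L), "s1") for L in rng.uniform(1, 30, 200)]
        assert sum(c.count for c in bin_lengths(inds, 1.0)) == 200

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ConfigError):
            bin_lengths([], 0.0)


class TestAbundance:
    @pytest.mark.parametrize(
        "F,sp,dp,sd,gw,expected",
        [(10, 2.0, 1.0, 2.0, 0.05, 200.0), (0, 1.0, 1.0, 1.0, 0.1, 0.0),
         (5, 1.0, 1.0, 1.0, 1.0, 5.0)],
    )
    def test_values(self, F, sp, dp, sd, gw, expected):
        assert standardized_abundance(F, sp, dp, sd, gw) == pytest.approx(expected)

    def test_degenerate_haul_rejected(self):
        with pytest.raises(InvalidInputError):
            standardized_abundance(10, 1.0, 1.0, 0.0, 0.05)

    def test_linearity_in_sp(self):
        base = standardized_abundance(7, 1.5, 1.2, 3.0, 0.04)
        assert standardized_abundance(7, 3.0, 1.2, 3.0, 0.04) == pytest.approx(2 * base)

    def test_conservation_over_length_classes(self, registry):
        """Sum of binned abundances x swept area equals the raised count."""
        rng = np.random.default_rng(11)
        inds = [Individual("HKE", float(L), "s1") for L in rng.uniform(5, 80, 137)]
        sp, dp, sd, gw = 2.5, 1.0, 3.2, 0.05
        total = sum(
            standardized_abundance(c.count, sp, dp, sd, gw)
            for c in bin_lengths(inds, 1.0)
        )
        assert total * sd * gw == pytest.approx(137 * sp * dp, rel=1e-12)


class TestBiomass:
    def test_laboratory_weight_used_directly(self, registry):
        inds = [Individual("HKE", 40.0, "s1", weight=1000.0, measured_in="laboratory")]
        v = standardized_biomass(inds, registry["HKE"], make_sample(), sd_km=1.0, gw_km=0.5)
        assert v == pytest.approx(2.0)

    def test_no_individuals_is_zero(self, registry):
        assert standardized_biomass([], registry["HKE"], make_sample(), 1.0, 0.5) == 0.0

    def test_field_individual_converted(self, registry):
        inds = [Individual("TOY", 10.0, "s1")]  # 0.01 * 10^3 = 10 g
        v = standardized_biomass(inds, registry["TOY"], make_sample(sp=2.0), 1.0, 0.02)
        assert v == pytest.approx(1.0)

    def test_missing_parameters_rejected(self, registry):
        inds = [Individual("ZZZ", 10.0, "s1")]
        with pytest.raises(MissingParameterError):
            standardized_biomass(inds, None, make_sample(), 1.0, 0.02)

    def test_measured_weights_independent_of_ab(self, registry):
        inds = [Individual("HKE", 40.0, "s1", weight=500.0, measured_in="laboratory"),
                Individual("HKE", 30.0, "s1", weight=250.0, measured_in="laboratory")]
        v1 = standardized_biomass(inds, registry["HKE"], make_sample(), 1.0, 0.5)
        v2 = standardized_biomass(inds, registry["DPS"], make_sample(), 1.0, 0.5)
        assert v1 == v2

    def test_linearity_in_sp(self, registry):
        inds = [Individual("TOY", 10.0, "s1")]
        v1 = standardized_biomass(inds, registry["TOY"], make_sample(sp=1.0), 1.0, 0.02)
        v2 = standardized_biomass(inds, registry["TOY"], make_sample(sp=3.0), 1.0, 0.02)
        assert v2 == pytest.approx(3 * v1)


def brute_force_aggregate(per_sample, dataset, group_hauls, value_cols):
    """Independent oracle: materialize every row, loop in pure Python."""
    acc: dict[tuple, float] = {}
    for row in per_sample.itertuples(index=False):
        if row.haul_id not in group_hauls:
            continue
        key = tuple(getattr(row, c) for c in value_cols)
        acc[key] = acc.get(key, 0.0) + row.value
    n = len(group_hauls)
    return {k: v / n for k, v in acc.items()}


class TestAggregation:
    def make_two_haul_dataset(self, registry, values):
        """Hand dataset: unit swept areas so per-sample value == raw count."""
        from datetime import date
        from trawlkit.survey import Haul, SurveyDataset

        ds = SurveyDataset(registry=registry)
        for i, _ in enumerate(values):
            ds.add_haul(Haul(
                haul_id=f"h{i}", vessel_id="v", date=date(2021, 6, 1), port="Roses",
                area="north", season="summer", depth_stratum_m=100.0,
                gear_width_m=1000.0, swept_distance_km=1.0, swept_area_km2=1.0,
            ))
        for i, sample_values in enumerate(values):
            for j, v in enumerate(sample_values):
                sid = f"s{i}{j}"
                cat = Category.LANDED if j == 0 else Category.DISCARDED
                ds.add_sample(Sample(sample_id=sid, haul_id=f"h{i}", category=cat,
                                     subsample_weight=1.0, fraction_weight=1.0))
                ds.add_individuals(
                    Individual("TOY", 10.0, sid) for _ in range(v)
                )
        return ds

    def test_mean_over_two_hauls(self, registry):
        ds = self.make_two_haul_dataset(registry, [[10], [20]])
        res = aggregate_abundance(abundance_table(ds), ds, by="all")[0]
        assert res.n_hauls == 2 and res.n_samples == 2
        assert res.values["value"].sum() == pytest.approx(15.0)

    def test_single_haul_identity(self, registry):
        ds = self.make_two_haul_dataset(registry, [[7]])
        res = aggregate_abundance(abundance_table(ds), ds, by="all")[0]
        assert res.values["value"].sum() == pytest.approx(7.0)

    def test_two_samples_one_haul_summed(self, registry):
        # landed 10 + discarded 5 in one haul: sum over NS samples, divide by N=1
        ds = self.make_two_haul_dataset(registry, [[10, 5]])
        res = aggregate_abundance(abundance_table(ds), ds, by="all")[0]
        assert res.n_hauls == 1 and res.n_samples == 2
        assert res.values["value"].sum() == pytest.approx(15.0)

    def test_absent_species_dilutes_through_n(self, registry):
        # species present in 1 of 3 hauls at 30 -> group aggregate 10
        ds = self.make_two_haul_dataset(registry, [[30], [0], [0]])
        res = aggregate_biomass(biomass_table(ds), ds, by="all")[0]
        assert res.n_hauls == 3
        assert res.values["value"].sum() == pytest.approx(
            30 * 0.01 * 10.0**3 / 1000.0 / 3.0
        )

    def test_empty_group_is_empty_result(self, registry):
        from trawlkit.survey import SurveyDataset

        ds = SurveyDataset(registry=registry)
        assert aggregate_abundance(abundance_table(ds), ds, by="all") == []

    def test_unknown_grouping_rejected(self, registry):
        ds = self.make_two_haul_dataset(registry, [[1]])
        with pytest.raises(ConfigError):
            aggregate_abundance(abundance_table(ds), ds, by="bogus")

    @pytest.mark.parametrize("by", ["all", "port", "area", "season"])
    def test_matches_brute_force_oracle(self, registry, by):
        rng = np.random.default_rng(5)
        ds = make_random_dataset(registry, rng, n_hauls=15)
        per_sample = abundance_table(ds)
        hauls = ds.hauls_table()
        for res in aggregate_abundance(per_sample, ds, by=by):
            if by == "all":
                group_hauls = set(hauls["haul_id"])
            else:
                group_hauls = set(hauls[hauls[by] == res.key[0]]["haul_id"])
            oracle = brute_force_aggregate(
                per_sample, ds, group_hauls, ["species_code", "length_class"]
            )
            got = {
                (r.species_code, r.length_class): r.value
                for r in res.values.itertuples(index=False)
            }
            assert set(got) == set(oracle)
            for k in oracle:
                assert got[k] == pytest.approx(oracle[k], rel=1e-9)

    def test_biomass_matches_brute_force_oracle(self, registry):
        rng = np.random.default_rng(6)
        ds = make_random_dataset(registry, rng, n_hauls=12)
        per_sample = biomass_table(ds)
        for res in aggregate_biomass(per_sample, ds, by="port"):
            hauls = ds.hauls_table()
            group_hauls = set(hauls[hauls["port"] == res.key[0]]["haul_id"])
            oracle = brute_force_aggregate(
                per_sample, ds, group_hauls, ["species_code", "category"]
            )
            got = {
                (r.species_code, r.category): r.value
                for r in res.values.itertuples(index=False)
            }
            assert set(got) == set(oracle)
            for k in oracle:
                assert got[k] == pytest.approx(oracle[k], rel=1e-9)
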
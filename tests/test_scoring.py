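"""Moult scoring: tract-weighted areas, relative extent, annual index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import moultclim as mc
from moultclim.scoring import ScoringError, tract_fraction
from moultclim.simulate import BASE_TRACT_AREAS

TOTAL_A = sum(BASE_TRACT_AREAS.values())


class TestLayout:
    def test_discrete_feathers_sum_to_48(self, layout):
        assert len(layout.discrete_labels) == 48
        assert len(set(layout.discrete_labels)) == 48

    def test_tract_names_and_priorities(self, layout):
        names = [t.name for t in layout.tracts]
        assert sorted(names) == sorted(["LC", "MC", "GC", "CC", "AL", "PC", "P", "S", "T", "R"])
        assert sorted(t.priority for t in layout.tracts) == list(range(1, 11))

    def test_proportion_tracts(self, layout):
        assert layout.tract("LC").is_proportion
        assert layout.tract("MC").is_proportion
        assert layout.tract("P").n_feathers == 10
        assert layout.tract("T").labels == ("T7", "T8", "T9")

    def test_bad_priority_order_rejected(self):
        with pytest.raises(ScoringError):
            mc.default_layout(priority_order=("LC", "MC"))


class TestMoultedArea:
    def test_nothing_moulted_is_zero(self, make_record, areas_one, layout):
        assert mc.compute_moulted_area(make_record(), areas_one, layout) == 0.0

    def test_complete_moult_is_total_area(self, make_record, areas_one, layout):
        rec = make_record(
            scores={l: 1 for l in layout.discrete_labels}, lc=1.0, mc_prop=1.0
        )
        assert mc.compute_moulted_area(rec, areas_one, layout) == pytest.approx(TOTAL_A)

    def test_single_tract_weighted_sum(self, make_record, layout):
        # all ten greater coverts moulted against a 120 mm² GC tract
        areas = mc.TractAreaTable(
            {("spA", t.name): (120.0 if t.name == "GC" else 1.0) for t in layout.tracts}
        )
        rec = make_record(scores={f"GC{i}": 1 for i in range(1, 11)})
        assert mc.compute_moulted_area(rec, areas, layout) == pytest.approx(120.0)

    def test_missing_feathers_rescale_denominator(self, make_record, areas_one, layout):
        # 5 moulted + 5 missing greater coverts: fraction is 5/5, not 5/10
        scores = {f"GC{i}": 1 for i in range(1, 6)}
        scores.update({f"GC{i}": None for i in range(6, 11)})
        rec = make_record(scores=scores)
        assert mc.compute_moulted_area(rec, areas_one, layout) == pytest.approx(
            BASE_TRACT_AREAS["GC"]
        )

    def test_unknown_species_errors(self, make_record, areas_one, layout):
        with pytest.raises(ScoringError, match="spB"):
            mc.compute_moulted_area(make_record(species="spB"), areas_one, layout)

    def test_fully_missing_tract_names_tract(self, make_record, areas_one, layout):
        rec = make_record(scores={f"R{i}": None for i in range(1, 7)})
        with pytest.raises(ScoringError, match="R"):
            mc.compute_moulted_area(rec, areas_one, layout)

    def test_relative_extent_endpoints_and_half(self, make_record, areas_one, layout):
        none = make_record()
        full = make_record(scores={l: 1 for l in layout.discrete_labels}, lc=1.0, mc_prop=1.0)
        assert mc.compute_relative_extent(none, areas_one, layout) == 0.0
        assert mc.compute_relative_extent(full, areas_one, layout) == pytest.approx(1.0)
        # every discrete tract exactly half moulted is impossible for odd
        # counts, so check the weighted definition directly on LC/MC = 0.5
        half = make_record(lc=0.5, mc_prop=0.5)
        expected = 0.5 * (BASE_TRACT_AREAS["LC"] + BASE_TRACT_AREAS["MC"]) / TOTAL_A
        assert mc.compute_relative_extent(half, areas_one, layout) == pytest.approx(expected)

    def test_half_fractions_in_every_tract_give_half_extent(self, make_record, areas_one, layout):
        # halve each even-count tract by scores and use 0.5 proportions; odd
        # multi-feather tracts (AL, PC, T) are halved via one missing feather;
        # the single-feather carpal covert cannot be halved and stays at 0
        scores = {}
        for tract in layout.tracts:
            if tract.labels is None or tract.name == "CC":
                continue
            n = tract.n_feathers
            for j, label in enumerate(tract.labels):
                if n % 2 == 0:
                    scores[label] = 1 if j < n // 2 else 0
                else:  # drop one feather so observed count is even
                    scores[label] = None if j == n - 1 else (1 if j < (n - 1) // 2 else 0)
        rec = make_record(scores=scores, lc=0.5, mc_prop=0.5)
        expected = 0.5 * (TOTAL_A - BASE_TRACT_AREAS["CC"]) / TOTAL_A
        assert mc.compute_relative_extent(rec, areas_one, layout) == pytest.approx(expected)


class TestScoringOracle:
    def test_area_matches_per_feather_brute_force(self, random_records, areas_one, layout):
        """Tract-weighted scoring equals a per-feather sum with feather area =
        tract area / feather count, rescaled for missing feathers."""
        for rec in random_records:
            brute = (
                rec.lc_proportion * areas_one.area("spA", "LC")
                + rec.mc_proportion * areas_one.area("spA", "MC")
            )
            for tract in layout.tracts:
                if tract.labels is None:
                    continue
                observed = [l for l in tract.labels if rec.feather_scores[l] is not None]
                per = areas_one.area("spA", tract.name) / len(observed)
                brute += per * sum(rec.feather_scores[l] for l in observed)
            assert mc.compute_moulted_area(rec, areas_one, layout) == pytest.approx(
                brute, abs=1e-9
            )

    def test_bounds(self, random_records, areas_one, layout):
        for rec in random_records:
            a = mc.compute_moulted_area(rec, areas_one, layout)
            assert 0.0 <= a <= TOTAL_A + 1e-9


@settings(derandomize=True, deadline=None, max_examples=60)
@given(data=st.data())
def test_flipping_a_feather_never_decreases_area(data, make_record, areas_one, layout):
    scores = {
        label: data.draw(st.sampled_from([0, 1, None]), label=label)
        for label in layout.discrete_labels
    }
    for tract in layout.tracts:
        if tract.labels and all(scores[l] is None for l in tract.labels):
            scores[tract.labels[0]] = 0
    rec = make_record(scores=scores)
    zeros = [l for l, s in scores.items() if s == 0]
    if not zeros:
        return
    flip = data.draw(st.sampled_from(zeros))
    before = mc.compute_moulted_area(rec, areas_one, layout)
    rec.feather_scores[flip] = 1
    after = mc.compute_moulted_area(rec, areas_one, layout)
    assert after >= before - 1e-12


class TestAnnualIndex:
    @staticmethod
    def _year_records(make_record, layout, year, n_full, n_total):
        """n_full complete-moult and n_total-n_full no-moult specimens, so the
        yearly mean relative extent is exactly n_full / n_total."""
        recs = []
        for i in range(n_total):
            full = i < n_full
            recs.append(
                make_record(
                    year=year,
                    scores={l: int(full) for l in layout.discrete_labels},
                    lc=float(full),
                    mc_prop=float(full),
                    specimen_id=f"y{year}-{i}",
                )
            )
        return recs

    def test_two_years_map_to_endpoints(self, make_record, areas_one, layout):
        recs = self._year_records(make_record, layout, 1900, 1, 5)
        recs += self._year_records(make_record, layout, 1950, 3, 5)
        idx = mc.annual_moult_index(recs, areas_one, layout)
        assert idx.values.loc[1900] == 0.0
        assert idx.values.loc[1950] == 1.0

    def test_three_years_linear_normalisation(self, make_record, areas_one, layout):
        recs = []
        for year, k in [(1900, 1), (1950, 2), (2000, 3)]:  # means 0.2, 0.4, 0.6
            recs += self._year_records(make_record, layout, year, k, 5)
        idx = mc.annual_moult_index(recs, areas_one, layout)
        assert idx.values.loc[1900] == pytest.approx(0.0)
        assert idx.values.loc[1950] == pytest.approx(0.5)
        assert idx.values.loc[2000] == pytest.approx(1.0)
        assert idx.raw_min == pytest.approx(0.2) and idx.raw_max == pytest.approx(0.6)

    def test_identical_yearly_means_error(self, make_record, areas_one, layout):
        recs = self._year_records(make_record, layout, 1900, 2, 4)
        recs += self._year_records(make_record, layout, 1950, 2, 4)
        with pytest.raises(ScoringError, match="identical"):
            mc.annual_moult_index(recs, areas_one, layout)

    def test_single_year_error(self, make_record, areas_one, layout):
        recs = self._year_records(make_record, layout, 1900, 1, 4)
        with pytest.raises(ScoringError, match="two years"):
            mc.annual_moult_index(recs, areas_one, layout)

    def test_species_equal_weighting(self, make_record, areas_one, layout, small_dataset):
        """Yearly average weights species equally, not by specimen count."""
        ds = small_dataset
        idx = mc.annual_moult_index(ds.records, ds.areas, ds.layout)
        table = mc.score_records(ds.records, ds.areas, ds.layout)
        per_sp = table.groupby(["year", "species_id"])["relative_extent"].mean()
        manual = per_sp.groupby("year").mean()
        lo, hi = manual.min(), manual.max()
        expected = (manual - lo) / (hi - lo)
        got = idx.values
        assert np.allclose(got.loc[expected.index], expected, atol=1e-12)


class TestSpecimenCsv:
    def test_round_trip(self, small_dataset, tmp_path):
        ds = small_dataset
        path = tmp_path / "specimens.csv"
        mc.write_specimen_csv(ds.records, path, ds.layout)
        back = mc.read_specimen_csv(path, ds.layout)
        assert len(back) == len(ds.records)
        for a, b in zip(ds.records, back):
            assert a.feather_scores == b.feather_scores
            assert a.sex == b.sex and a.collection_year == b.collection_year
            assert a.lc_proportion == pytest.approx(b.lc_proportion, abs=1e-9)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("specimen_id,species_id\nx,y\n")
        with pytest.raises(ScoringError, match="missing columns"):
            mc.read_specimen_csv(p)

    def test_record_validation_rejects_bad_proportion(self, make_record, layout):
        rec = make_record(lc=1.5)
        with pytest.raises(ScoringError, match="lc_proportion"):
            rec.validate(layout)
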
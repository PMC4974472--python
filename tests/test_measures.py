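"""The four site-level biodiversity measures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import rarefaction_enumerate, rarefaction_monte_carlo
from paeffect.measures import (
    compute_site_measures,
    endemicity,
    rarefied_richness,
    site_richness_abundance,
    study_rarefaction,
)


class TestRichnessAbundance:
    @pytest.mark.parametrize(
        "meas, s, n",
        [
            ([2, 1, 0], 2, 3.0),
            ([], 0, 0.0),
            ([0.5, 1.2], 2, 1.7),  # density-valued abundances sum as-is
        ],
    )
    def test_examples(self, meas, s, n):
        got_s, got_n = site_richness_abundance(meas)
        assert got_s == s
        assert got_n == pytest.approx(n)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            site_richness_abundance([1, -2])

    @given(st.lists(st.floats(0, 100, allow_nan=False), max_size=20))
    @settings(deadline=None)
    def test_permutation_invariant(self, meas):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(meas))
        s1, n1 = site_richness_abundance(meas)
        s2, n2 = site_richness_abundance(np.asarray(meas)[perm])
        assert s1 == s2 and n1 == pytest.approx(n2)


class TestRarefaction:
    def test_two_equal_species(self):
        # E[S_2] for counts {5,5}: 2 * (1 - C(5,2)/C(10,2)) = 14/9
        assert rarefied_richness([5, 5], 2) == pytest.approx(14 / 9, abs=1e-12)

    def test_single_draw(self):
        assert rarefied_richness([2, 1], 1) == pytest.approx(1.0, abs=1e-12)

    def test_full_sample_returns_observed_richness(self):
        counts = [3, 1, 0, 7]
        assert rarefied_richness(counts, 11) == pytest.approx(3.0, abs=1e-12)

    def test_zero_draw(self):
        assert rarefied_richness([3, 2], 0) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError, match="integer"):
            rarefied_richness([1.5, 2.0], 1)
        with pytest.raises(ValueError, match="0 <= n"):
            rarefied_richness([1, 2], 10)
        with pytest.raises(ValueError, match="nonnegative"):
            rarefied_richness([-1, 2], 1)

    @given(
        st.lists(st.integers(0, 4), min_size=1, max_size=5).filter(
            lambda c: 0 < sum(c) <= 8
        ),
        st.data(),
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_exhaustive_enumeration(self, counts, data):
        n = data.draw(st.integers(0, sum(counts)))
        assert rarefied_richness(counts, n) == pytest.approx(
            rarefaction_enumerate(counts, n), abs=1e-10
        )

    @given(st.lists(st.integers(0, 30), min_size=2, max_size=8).filter(lambda c: sum(c) > 2))
    @settings(deadline=None, max_examples=40)
    def test_monotone_in_subsample_size(self, counts):
        total = sum(counts)
        vals = [rarefied_richness(counts, n) for n in range(total + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[0] == 0.0
        assert vals[-1] == pytest.approx(sum(1 for c in counts if c > 0))

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 25, size=6)
        counts[0] = max(counts[0], 1)
        n = int(max(2, counts.sum() // 3))
        mc, se = rarefaction_monte_carlo(counts, n, 10_000, rng)
        assert rarefied_richness(counts, n) == pytest.approx(mc, abs=3 * se)

    def test_large_counts_stable(self):
        # log-space evaluation must survive totals far beyond factorial range
        val = rarefied_richness([10_000, 20_000, 5], 5_000)
        assert 2.0 < val <= 3.0


class TestStudyRarefaction:
    def test_common_subsample_size(self):
        vals, n_min = study_rarefaction({"a": [2, 1], "b": [5, 5]})
        assert n_min == 3
        assert vals["a"] == pytest.approx(2.0)
        assert vals["b"] == pytest.approx(rarefied_richness([5, 5], 3))

    def test_empty_site_undefines_study(self):
        vals, n_min = study_rarefaction({"a": [3, 2], "b": []})
        assert n_min == 0
        assert all(np.isnan(v) for v in vals.values())


class TestEndemicity:
    def test_worked_example(self):
        cwm, end = endemicity([10, 30], [1e4, 1e6])
        assert cwm == pytest.approx(5.5, abs=1e-12)
        assert end == pytest.approx(0.18182, abs=1e-5)

    def test_single_taxon(self):
        cwm, end = endemicity([7], [1e5])
        assert cwm == pytest.approx(5.0, abs=1e-12)

    def test_occurrence_unweighted(self):
        cwm, _ = endemicity([1, 1], [1e2, 1e4], occurrence=True)
        assert cwm == pytest.approx(3.0, abs=1e-12)

    def test_zero_abundance_taxa_excluded(self):
        cwm, _ = endemicity([10, 0], [1e4, 1e8])
        assert cwm == pytest.approx(4.0, abs=1e-12)

    @given(st.floats(0.01, 100.0))
    @settings(deadline=None)
    def test_invariant_to_abundance_rescaling(self, k):
        a = np.array([3.0, 9.0, 1.0])
        r = np.array([1e3, 1e5, 1e7])
        assert endemicity(a, r)[1] == pytest.approx(endemicity(k * a, r)[1], rel=1e-9)

    def test_subunit_cwm_rejected(self):
        with pytest.raises(ValueError, match="rescaling"):
            endemicity([10], [0.5])


class TestComputeSiteMeasures:
    def test_occurrence_study_has_no_abundance(self):
        sites = pd.DataFrame({"site_id": ["s1"], "study_id": ["st1"]})
        comm = pd.DataFrame(
            {
                "site_id": ["s1", "s1"],
                "taxon_id": ["t1", "t2"],
                "measurement": [1.0, 1.0],
                "measurement_type": ["occurrence"] * 2,
            }
        )
        ranges = pd.DataFrame({"taxon_id": ["t1", "t2"], "range_km2": [1e2, 1e4]})
        out = compute_site_measures(comm, sites, ranges)
        assert out.loc[0, "richness"] == 2
        assert np.isnan(out.loc[0, "abundance"])
        assert out.loc[0, "cwm_log10_range"] == pytest.approx(3.0)

    def test_density_study_skips_rarefaction(self):
        sites = pd.DataFrame({"site_id": ["s1", "s2"], "study_id": ["st1", "st1"]})
        comm = pd.DataFrame(
            {
                "site_id": ["s1", "s2"],
                "taxon_id": ["t1", "t1"],
                "measurement": [0.5, 1.25],
                "measurement_type": ["abundance"] * 2,
            }
        )
        ranges = pd.DataFrame({"taxon_id": ["t1"], "range_km2": [1e5]})
        out = compute_site_measures(comm, sites, ranges)
        assert np.isnan(out["rarefied_richness"]).all()
        assert out["abundance"].tolist() == [0.5, 1.25]

    def test_unknown_site_rejected(self):
        sites = pd.DataFrame({"site_id": ["s1"], "study_id": ["st1"]})
        comm = pd.DataFrame(
            {
                "site_id": ["sX"],
                "taxon_id": ["t1"],
                "measurement": [1.0],
                "measurement_type": ["abundance"],
            }
        )
        with pytest.raises(ValueError, match="unknown sites"):
            compute_site_measures(comm, sites, pd.DataFrame({"taxon_id": ["t1"], "range_km2": [1.0]}))

    def test_world_measures_consistent(self, small_world):
        out = compute_site_measures(
            small_world.community, small_world.sites, small_world.ranges
        )
        assert len(out) == len(small_world.sites)
        ok = out["rarefied_richness"].notna()
        assert (out.loc[ok, "rarefied_richness"] <= out.loc[ok, "richness"] + 1e-9).all()
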
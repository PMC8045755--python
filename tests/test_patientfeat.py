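"""Bin-scheme fitting and 150-feature patient aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histomorph.patientfeat import (
    CELL_FEATURES,
    BinScheme,
    aggregate_patient,
    feature_names,
    fit_bin_scheme,
)


def _cells(values: dict[str, np.ndarray]) -> pd.DataFrame:
    n = len(next(iter(values.values())))
    data = {f: values.get(f, np.linspace(1, 2, n)) for f in CELL_FEATURES}
    return pd.DataFrame(data)


def _uniform_scheme(lo=0.0, hi=10.0) -> BinScheme:
    return BinScheme(edges={f: np.linspace(lo, hi, 11) for f in CELL_FEATURES})


class TestFeatureNames:
    def test_count_and_block_structure(self):
        names = feature_names()
        assert len(names) == 150
        area_block = [n for n in names if n.startswith("area_")]
        assert len(area_block) == 15
        assert names[10] == "area_mean"
        assert area_block[:3] == ["area_bin1", "area_bin2", "area_bin3"]
        assert area_block[-5:] == [
            "area_mean",
            "area_std",
            "area_skewness",
            "area_kurtosis",
            "area_entropy",
        ]


class TestFitBinScheme:
    def test_percentile_clamped_equal_width(self):
        pooled = {f: np.arange(1.0, 101.0) for f in CELL_FEATURES}
        scheme = fit_bin_scheme(pooled)
        e = scheme.edges["area"]
        assert np.allclose(e, np.linspace(1, 99, 11))
        assert np.allclose(np.diff(e), 9.8)

    def test_round_trip(self, tmp_path):
        pooled = {f: np.random.default_rng(1).uniform(0, 5, 500) for f in CELL_FEATURES}
        scheme = fit_bin_scheme(pooled)
        path = tmp_path / "bins.json"
        scheme.to_json(path)
        reloaded = BinScheme.from_json(path)
        for f in CELL_FEATURES:
            assert (scheme.edges[f] == reloaded.edges[f]).all()

    def test_constant_values_rejected(self):
        pooled = {f: np.full(200, 3.0) for f in CELL_FEATURES}
        with pytest.raises(ValueError, match="degenerate feature range"):
            fit_bin_scheme(pooled)


class TestAggregatePatient:
    def test_uniform_histogram_max_entropy(self):
        # one nucleus per bin: all bins 0.1, entropy = ln 10
        vals = np.linspace(0.5, 9.5, 10)
        vec = aggregate_patient(_cells({f: vals for f in CELL_FEATURES}), _uniform_scheme())
        bins = vec[[f"area_bin{i}" for i in range(1, 11)]]
        assert np.allclose(bins, 0.1)
        assert vec["area_entropy"] == pytest.approx(np.log(10), abs=1e-12)

    def test_single_bin_zero_entropy(self):
        vals = np.full(20, 4.2)
        vec = aggregate_patient(_cells({f: vals for f in CELL_FEATURES}), _uniform_scheme())
        assert vec["ratio_bin5"] == 1.0
        assert vec["ratio_entropy"] == 0.0

    def test_length_is_150_with_canonical_names(self):
        rng = np.random.default_rng(0)
        vec = aggregate_patient(
            _cells({f: rng.uniform(0, 10, 30) for f in CELL_FEATURES}), _uniform_scheme()
        )
        assert len(vec) == 150
        assert list(vec.index) == feature_names()

    def test_out_of_range_values_clamp_to_edge_bins(self):
        vals = np.array([-50.0, -50.0, 50.0])
        vec = aggregate_patient(_cells({"area": vals}), _uniform_scheme())
        assert vec["area_bin1"] == pytest.approx(2 / 3)
        assert vec["area_bin10"] == pytest.approx(1 / 3)

    def test_statistics_on_raw_values(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        vec = aggregate_patient(_cells({"area": vals}), _uniform_scheme())
        assert vec["area_mean"] == 2.5
        assert vec["area_std"] == pytest.approx(np.sqrt(1.25))  # population SD
        assert vec["area_skewness"] == 0.0

    def test_empty_patient_rejected(self):
        with pytest.raises(ValueError, match="empty patient"):
            aggregate_patient(pd.DataFrame(columns=list(CELL_FEATURES)), _uniform_scheme())

    def test_isolated_nuclei_excluded_from_distance_block_only(self):
        cells = _cells({f: np.linspace(1, 9, 5) for f in CELL_FEATURES})
        cells.loc[0, "distMean"] = np.nan
        cells.loc[0, "distMax"] = np.nan
        cells.loc[0, "distMin"] = np.nan
        vec = aggregate_patient(cells, _uniform_scheme())
        # distance stats use 4 cells, area stats all 5
        assert vec["distMean_mean"] == pytest.approx(np.mean(np.linspace(1, 9, 5)[1:]))
        assert vec["area_mean"] == pytest.approx(5.0)

    def test_pooling_invariance_across_slides(self):
        rng = np.random.default_rng(3)
        cells = _cells({f: rng.uniform(0, 10, 40) for f in CELL_FEATURES})
        scheme = _uniform_scheme()
        whole = aggregate_patient(cells, scheme)
        split = aggregate_patient([cells.iloc[:13], cells.iloc[13:]], scheme)
        pd.testing.assert_series_equal(whole, split)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_histogram_proportions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        vec = aggregate_patient(
            _cells({f: rng.normal(5, 3, 25) for f in CELL_FEATURES}), _uniform_scheme()
        )
        for f in CELL_FEATURES:
            bins = vec[[f"{f}_bin{i}" for i in range(1, 11)]]
            assert bins.sum() == pytest.approx(1.0, abs=1e-12)
            assert 0.0 <= vec[f"{f}_entropy"] <= np.log(10) + 1e-12

    def test_monotone_shift_moves_mass_upward(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(2, 6, 50)
        scheme = _uniform_scheme()
        low = aggregate_patient(_cells({"area": vals}), scheme)
        high = aggregate_patient(_cells({"area": vals + 2.0}), scheme)
        cum_low = np.cumsum([low[f"area_bin{i}"] for i in range(1, 11)])
        cum_high = np.cumsum([high[f"area_bin{i}"] for i in range(1, 11)])
        assert (cum_high <= cum_low + 1e-12).all()  # stochastic dominance
        assert high["ratio_bin1":"ratio_entropy"].equals(low["ratio_bin1":"ratio_entropy"])
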
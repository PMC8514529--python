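import warnings

import numpy as np
import pandas as pd
import pytest

from crinosize.series import (
    EmptySeriesError,
    GenusRecord,
    bin_series,
    load_genus_table,
    records_to_frame,
    stage_cohorts,
)
from crinosize.timescale import GeologicTimescale


# ---------------------------------------------------------------------------
# timescale

def test_timescale_structure(ts):
    assert len(ts) == 38
    assert ts.stages[0] == "Tremadocian" and ts.stages[-1] == "Changhsingian"
    assert ts.base_ma("Katian") > ts.top_ma("Katian")
    assert ts.midpoint_ma("Katian") == pytest.approx((453.0 + 445.2) / 2)
    assert ts.successor("Katian") == "Hirnantian"
    assert ts.span("Givetian", "Famennian") == ("Givetian", "Frasnian", "Famennian")


def test_timescale_rejects_gaps():
    frame = pd.DataFrame(
        {"stage": ["A", "B"], "base_ma": [100.0, 80.0], "top_ma": [90.0, 70.0]}
    )
    with pytest.raises(ValueError, match="contiguous"):
        GeologicTimescale(frame)


def test_unknown_stage_lists_valid_names(ts):
    with pytest.raises(KeyError, match="Tremadocian"):
        ts.index("Jurassic1")


def test_youngest_stage_has_no_successor(ts):
    with pytest.raises(ValueError, match="youngest"):
        ts.successor("Changhsingian")


# ---------------------------------------------------------------------------
# loading

def _write(tmp_path, text, name="genus.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


def test_load_valid_rows_and_stage_trimming(ts, tmp_path):
    path = _write(
        tmp_path,
        "genus,subclass,parvclass,first_stage,last_stage,log_biovolume\n"
        "Abra,Camerata,other,Katian ,Hirnantian,1.5\n"
        "Cadra,Pentacrinoidea,Cladida,Sandbian,Katian,0.2\n"
        "Dira,Pentacrinoidea,Disparida,katian,Katian,-0.4\n",
    )
    records = load_genus_table(path, ts)
    assert len(records) == 3
    assert records[0].first_stage == "Katian"  # trailing space trimmed
    assert records[2].first_stage == "Katian"  # case-insensitive match


def test_load_rejects_reversed_range_with_row_number(ts, tmp_path):
    path = _write(
        tmp_path,
        "genus,subclass,parvclass,first_stage,last_stage,log_biovolume\n"
        "Abra,Camerata,other,Katian,Hirnantian,1.5\n"
        "Bad,Camerata,other,Hirnantian,Katian,0.1\n",
    )
    with pytest.raises(ValueError, match="row 2"):
        load_genus_table(path, ts)


def test_load_rejects_duplicate_genus(ts, tmp_path):
    path = _write(
        tmp_path,
        "genus,subclass,parvclass,first_stage,last_stage,log_biovolume\n"
        "Abra,Camerata,other,Katian,Hirnantian,1.5\n"
        "Abra,Camerata,other,Katian,Katian,0.3\n",
    )
    with pytest.raises(ValueError, match="duplicate genus"):
        load_genus_table(path, ts)


def test_load_computes_log_size_from_volume_or_dims(ts, tmp_path):
    path = _write(
        tmp_path,
        "genus,subclass,parvclass,first_stage,last_stage,biovolume_mm3,shape,dim_r,dim_h\n"
        "Vola,Camerata,other,Katian,Katian,1000,,,\n"
        "Shapa,Camerata,other,Katian,Katian,,cylinder,1,1\n",
    )
    records = load_genus_table(path, ts)
    assert records[0].log_size == pytest.approx(3.0)
    assert records[1].log_size == pytest.approx(np.log10(np.pi))


def test_round_trip_through_frame(ts, ten_genus_table, tmp_path):
    path = tmp_path / "table.csv"
    records_to_frame(ten_genus_table).to_csv(path, index=False)
    assert load_genus_table(path, ts) == ten_genus_table


# ---------------------------------------------------------------------------
# binning

def test_single_genus_spans_all_its_stages(ts):
    rec = GenusRecord("Solo", "Camerata", "other", "Katian", "Rhuddanian", 1.7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series = bin_series([rec], ts)
    assert series.stages == ("Katian", "Hirnantian", "Rhuddanian")
    assert np.allclose(series.mean, 1.7)
    assert np.all(series.n == 1)
    assert series.elapsed_time[0] == 0
    assert np.all(np.diff(series.elapsed_time) > 0)


def test_cooccurring_pair_mean_and_variance(ts):
    recs = [
        GenusRecord("A", "Camerata", "other", "Katian", "Katian", 1.0),
        GenusRecord("B", "Camerata", "other", "Katian", "Katian", 3.0),
    ]
    series = bin_series(recs, ts, interval=("Katian", "Katian"))
    assert series.mean[0] == pytest.approx(2.0)
    assert series.variance[0] == pytest.approx(2.0)  # unbiased
    assert series.n[0] == 2


def test_bin_counts_match_bruteforce_overlap(ts, ten_genus_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series = bin_series(ten_genus_table, ts)
    for stage, n in zip(series.stages, series.n):
        expected = sum(
            1
            for r in ten_genus_table
            if ts.index(r.first_stage) <= ts.index(stage) <= ts.index(r.last_stage)
        )
        assert n == expected
    # total contributions = sum of range lengths
    total = sum(
        ts.index(r.last_stage) - ts.index(r.first_stage) + 1 for r in ten_genus_table
    )
    assert series.n.sum() == total


def test_clade_filter_and_interval(ts, ten_genus_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series = bin_series(
            ten_genus_table, ts, {"subclass": "Camerata"}, ("Tremadocian", "Sandbian")
        )
    camerates = [r for r in ten_genus_table if r.subclass == "Camerata"]
    for stage, mean in zip(series.stages, series.mean):
        vals = [
            r.log_size
            for r in camerates
            if ts.index(r.first_stage) <= ts.index(stage) <= ts.index(r.last_stage)
        ]
        assert mean == pytest.approx(np.mean(vals))


def test_empty_selection_raises(ts, ten_genus_table):
    with pytest.raises(EmptySeriesError):
        bin_series(ten_genus_table, ts, {"subclass": "Camerata"}, ("Asselian", "Changhsingian"))


def test_singleton_bins_get_pooled_variance(ts):
    recs = [
        GenusRecord("A", "Camerata", "other", "Katian", "Hirnantian", 1.0),
        GenusRecord("B", "Camerata", "other", "Katian", "Katian", 3.0),
    ]
    series = bin_series(recs, ts, interval=("Katian", "Hirnantian"))
    # Hirnantian holds only genus A: variance pooled from the Katian bin
    assert series.pooled_variance_bins == (1,)
    assert series.variance[1] == pytest.approx(series.variance[0])
    assert np.all(np.isfinite(series.eps))


# ---------------------------------------------------------------------------
# cohorts

def test_single_stage_range_is_victim(ts):
    rec = GenusRecord("One", "Camerata", "other", "Katian", "Katian", 0.0)
    cohorts = stage_cohorts([rec], "Katian", ts)
    assert cohorts.victims == (rec,)
    assert cohorts.survivors == ()


def test_originator_not_extant_in_previous_stage(ts):
    rec = GenusRecord("New", "Camerata", "other", "Hirnantian", "Rhuddanian", 0.0)
    cohorts = stage_cohorts([rec], "Katian", ts)
    assert cohorts.extant == ()
    assert cohorts.originators_next == (rec,)


def test_cohorts_match_bruteforce_classification(ts, ten_genus_table):
    for stage in ts.stages[:12]:
        cohorts = stage_cohorts(ten_genus_table, stage, ts)
        k = ts.index(stage)
        extant = {
            r.genus
            for r in ten_genus_table
            if ts.index(r.first_stage) <= k <= ts.index(r.last_stage)
        }
        victims = {r.genus for r in ten_genus_table if ts.index(r.last_stage) == k}
        assert {r.genus for r in cohorts.extant} == extant
        assert {r.genus for r in cohorts.victims} == victims & extant
        assert {r.genus for r in cohorts.survivors} == extant - victims
        # partition is disjoint and exhaustive
        assert len(cohorts.victims) + len(cohorts.survivors) == len(cohorts.extant)


def test_survivors_equal_next_extant_minus_originators(ts, ten_genus_table):
    for stage in ts.stages[:12]:
        succ = ts.successor(stage)
        cohorts = stage_cohorts(ten_genus_table, stage, ts)
        next_extant = {
            r.genus
            for r in ten_genus_table
            if ts.index(r.first_stage) <= ts.index(succ) <= ts.index(r.last_stage)
        }
        originators = {r.genus for r in cohorts.originators_next}
        assert {r.genus for r in cohorts.survivors} == next_extant - originators
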
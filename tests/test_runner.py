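import numpy as np
import pytest

from conftest import flatten_output
from omexsim.engine import SimulationResult
from omexsim.errors import ValidationError
from omexsim.fixtures import generate_fixture
from omexsim.inline_omex import (archive_to_document, document_to_archive,
                                 parse_document)
from omexsim.runner import (PlotData, compare_expected,
                            evaluate_data_generator, run_experiment,
                            write_outputs)
from omexsim.sim_lang import DataGen


def _result(columns, rows):
    return SimulationResult(columns, np.array(rows, dtype=float))


# -- data generators --------------------------------------------------------

def test_identity_datagen_passes_column_through():
    res = {"t1": _result(["time", "S"], [[0, 1], [1, 2], [2, 3]])}
    out = evaluate_data_generator(DataGen("g", ("sym", "t1.S")), res)
    np.testing.assert_array_equal(out, [1, 2, 3])


def test_log10_datagen():
    res = {"t1": _result(["time", "S"], [[0, 1], [1, 10], [2, 100]])}
    gen = DataGen("g", ("call", "log10", (("sym", "t1.S"),)))
    np.testing.assert_allclose(evaluate_data_generator(gen, res), [0, 1, 2])


def test_sum_datagen_matches_row_loop():
    rows = [[0, 1.5, 2.5], [1, -1.0, 4.0], [2, 0.25, 0.75]]
    res = {"t1": _result(["time", "A", "B"], rows)}
    gen = DataGen("g", ("+", ("sym", "t1.A"), ("sym", "t1.B")))
    out = evaluate_data_generator(gen, res)
    brute = np.array([row[1] + row[2] for row in rows])
    np.testing.assert_array_equal(out, brute)


def test_mixed_row_counts_rejected():
    res = {"t1": _result(["time", "A"], [[0, 1]]),
           "t2": _result(["time", "B"], [[0, 1], [1, 2]])}
    gen = DataGen("g", ("+", ("sym", "t1.A"), ("sym", "t2.B")))
    with pytest.raises(ValidationError, match="row counts"):
        evaluate_data_generator(gen, res)


# -- whole-experiment execution ---------------------------------------------

def test_two_param_sets_gives_two_curves():
    doc = parse_document(generate_fixture("two_param_sets"))
    out = run_experiment(doc)["two parameter sets"]
    assert isinstance(out, PlotData)
    assert len(out.curves) == 2
    # faster decay (k1=1.5, second task) ends lower
    s_end = [c.y[-1] for c in out.curves]
    assert s_end[1] < s_end[0]


def test_parameter_scan_endpoint_monotonic():
    doc = parse_document(generate_fixture("scan"))
    out = run_experiment(doc)["decay scan"]
    assert len(out.curves) == 5
    endpoints = [c.y[-1] for c in out.curves]
    # S(t_end) = 10*exp(-k1*t_end) decreases as k1 increases
    assert all(a > b for a, b in zip(endpoints, endpoints[1:]))


def test_stochastic_repeats_have_distinct_traces():
    doc = parse_document(generate_fixture("stochastic_traces"))
    out = run_experiment(doc)["three traces"]
    assert len(out.curves) == 3
    ys = [c.y for c in out.curves]
    assert not np.array_equal(ys[0], ys[1])
    assert not np.array_equal(ys[1], ys[2])


def test_end_to_end_determinism():
    doc = parse_document(generate_fixture("birth_death"))
    r1 = flatten_output(run_experiment(doc)["report1"])
    r2 = flatten_output(run_experiment(doc)["report1"])
    np.testing.assert_array_equal(r1.rows, r2.rows)


def test_exchangeability_through_archive():
    """Running a document and its archive round-trip twin must agree."""
    for name in ("decay", "two_param_sets", "case2_edit_pattern"):
        doc = parse_document(generate_fixture(name))
        twin = archive_to_document(document_to_archive(doc))
        a = run_experiment(doc, seed_override=5)
        b = run_experiment(twin, seed_override=5)
        for key in a:
            ta, tb = flatten_output(a[key]), flatten_output(b[key])
            np.testing.assert_allclose(ta.rows, tb.rows, atol=1e-12)


# -- comparison --------------------------------------------------------------

def test_identical_tables_pass():
    r = _result(["time", "S"], [[0, 1], [1, 2]])
    cmp = compare_expected(r, r)
    assert cmp.max_mse == 0.0 and cmp.passed


def test_constant_offset_mse_thresholds():
    base = _result(["time", "S"], [[float(i), 1.0] for i in range(10)])
    off_big = _result(["time", "S"], [[float(i), 1.1] for i in range(10)])
    off_small = _result(["time", "S"], [[float(i), 1.01] for i in range(10)])
    big = compare_expected(base, off_big)
    small = compare_expected(base, off_small)
    assert big.per_column_mse["S"] == pytest.approx(0.01)
    assert not big.passed           # 0.01 >= 1e-3
    assert small.per_column_mse["S"] == pytest.approx(1e-4)
    assert small.passed             # 1e-4 < 1e-3


def test_coarser_expected_grid_aligned_by_time():
    res = _result(["time", "S"], [[i * 0.5, i * 1.0] for i in range(9)])
    exp = _result(["time", "S"], [[0.0, 0.0], [2.0, 4.0], [4.0, 8.0]])
    cmp = compare_expected(res, exp)
    assert cmp.max_mse == 0.0


def test_column_mismatch_rejected():
    r = _result(["time", "S"], [[0, 1]])
    e = _result(["time", "Q"], [[0, 1]])
    with pytest.raises(ValidationError, match="Q"):
        compare_expected(r, e)


# -- output writing ----------------------------------------------------------

def test_report_csv_header_and_determinism(tmp_path):
    doc = parse_document(generate_fixture("decay"))
    result = run_experiment(doc)
    files1 = write_outputs(result, str(tmp_path / "a"))
    files2 = write_outputs(run_experiment(doc), str(tmp_path / "b"))
    (f1,), (f2,) = files1, files2
    data1 = open(f1, "rb").read()
    assert data1 == open(f2, "rb").read()
    header = data1.decode().splitlines()[0]
    assert header.split(",") == ["t1_time", "t1_S"]


def test_plot_csv_has_xy_pairs_per_curve(tmp_path):
    doc = parse_document(generate_fixture("two_param_sets"))
    (path,) = write_outputs(run_experiment(doc), str(tmp_path))
    header = open(path).readline().strip().split(",")
    assert len(header) == 4
    assert sum(h.endswith("_x") for h in header) == 2
    assert sum(h.endswith("_y") for h in header) == 2
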
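import os

import numpy as np
import pytest

from omexsim.engine import SimulationResult
from omexsim.runner import PlotData, ReportData

DATA_DIR = os.path.join(os.path.dirname(__file__), "data")


def flatten_output(data) -> SimulationResult:
    """Flatten a PlotData/ReportData into a labeled table for comparison.

    The first column doubles as the alignment axis (it is the time column
    for reports and the first curve's x for plots).
    """
    if isinstance(data, ReportData):
        labels = [label for label, _ in data.columns]
        cols = [np.asarray(v, dtype=float) for _, v in data.columns]
    else:
        labels, cols = [], []
        for s in data.curves:
            labels += [f"{s.label}:x", f"{s.label}:y"]
            cols += [np.asarray(s.x, dtype=float), np.asarray(s.y, dtype=float)]
    return SimulationResult(labels, np.column_stack(cols))


def write_table_csv(path: str, table: SimulationResult, stride: int = 1) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(",".join(table.column_ids) + "\n")
        for row in table.rows[::stride]:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_table_csv(path: str) -> SimulationResult:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        rows = [[float(v) for v in line.strip().split(",")]
                for line in fh if line.strip()]
    return SimulationResult(header, np.array(rows, dtype=float))


@pytest.fixture
def tmp_out(tmp_path):
    return str(tmp_path)
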
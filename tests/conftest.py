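import numpy as np
import pandas as pd
import pytest

from mbdcapdm.counts import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20160818)


def write_fastqc(path, counts_by_gc):
    """Write a minimal fastqc_data.txt with a GC-content module."""
    lines = [
        "##FastQC\t0.11.2",
        ">>Per base sequence quality\tpass",
        ">>END_MODULE",
        ">>Per sequence GC content\tpass",
        "#GC Content\tCount",
    ]
    for gc in range(101):
        lines.append(f"{gc}\t{counts_by_gc.get(gc, 0.0)}")
    lines.append(">>END_MODULE")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def fastqc_writer():
    return write_fastqc


def make_count_matrix(arr, conditions=("A", "A", "B", "B"), prefix="p"):
    arr = np.asarray(arr)
    samples = [f"s{i}" for i in range(arr.shape[1])]
    data = pd.DataFrame(
        arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])], columns=samples
    )
    cond = pd.Series(list(conditions), index=samples)
    return CountMatrix(data, cond)


@pytest.fixture
def count_matrix_factory():
    return make_count_matrix
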
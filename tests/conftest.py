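import numpy as np
import pandas as pd
import pytest

from polyratio import SimulationConfig
from polyratio.tables import LIBRARIES, CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def small_config():
    """Small, fast experiment with the planted default effects."""
    return SimulationConfig(n_genes=2000, seed=42)


@pytest.fixture
def sinusoid():
    """40-point deterministic sinusoid fixture for LOESS oracle checks."""
    x = np.linspace(0.0, 4.0 * np.pi, 40)
    y = np.sin(x) + 0.25 * np.cos(3.0 * x)
    return x, y


def write_htseq(path, pairs, specials=()):
    """Write an HTSeq-count-dialect two-column file."""
    with open(path, "w") as fh:
        for gene, count in pairs:
            fh.write(f"{gene}\t{count}\n")
        for gene, count in specials:
            fh.write(f"{gene}\t{count}\n")
    return path


@pytest.fixture
def htseq_dir(tmp_path):
    """Four consistent HTSeq files over genes g1..g3."""
    base = {"g1": (10, 20, 30, 40), "g2": (5, 5, 5, 5), "g3": (100, 1, 7, 9)}
    paths = []
    for j, lib in enumerate(LIBRARIES):
        pairs = [(g, counts[j]) for g, counts in base.items()]
        paths.append(write_htseq(tmp_path / f"{lib}.tsv", pairs,
                                 specials=[("__no_feature", 999)]))
    return paths, base


def toy_count_matrix(rows: dict[str, tuple], lib_sizes=None) -> CountMatrix:
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(LIBRARIES)).astype(np.int64)
    frame.index.name = "gene_id"
    return CountMatrix(frame, None if lib_sizes is None
                       else pd.Series(lib_sizes, index=list(LIBRARIES)))


def toy_gene_table(n=None, ids=None, orf=None, sites=None) -> pd.DataFrame:
    if ids is None:
        ids = [f"g{i+1}" for i in range(n)]
    n = len(ids)
    return pd.DataFrame({
        "gene_id": ids,
        "orf_length": orf if orf is not None else [1000] * n,
        "site_count": sites if sites is not None else [0] * n,
    })
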
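"""Shared fixtures: tiny hand-built networks, count tables, annotations."""

import numpy as np
import pandas as pd
import pytest

from methylflux.methylome.io import CytosineCountTable
from methylflux.network import load_network

CHAIN_TSV = """\
metabolite\tS\t\t0
metabolite\tA\t\t1
metabolite\tB\t\t1
metabolite\tP\t\t0
reaction\tupt\tS -> A\t0
reaction\tr1\tA -> B\t0
reaction\texp\tB -> P\t0
"""

BRANCH_TSV = """\
metabolite\tS\t\t0
metabolite\tA\t\t1
metabolite\tP1\t\t0
metabolite\tP2\t\t0
reaction\tupt\tS -> A\t0
reaction\tout1\tA -> P1\t0
reaction\tout2\tA -> P2\t0
"""


@pytest.fixture
def chain_network():
    """S -> A -> B -> P with one internal chain; conservation forces all
    three fluxes equal."""
    return load_network(CHAIN_TSV)


@pytest.fixture
def branch_network():
    """A single branch point: uptake splits over two irreversible exports."""
    return load_network(BRANCH_TSV)


def make_count_table(
    loci: pd.DataFrame,
    counts: dict[str, tuple[np.ndarray, np.ndarray]],
    groups: dict[str, str],
) -> CytosineCountTable:
    """Assemble a CytosineCountTable from per-sample (meth, total) arrays."""
    df = loci.copy().reset_index(drop=True)
    for sample, (meth, total) in counts.items():
        df[f"meth_{sample}"] = np.asarray(meth, dtype=np.int64)
        df[f"total_{sample}"] = np.asarray(total, dtype=np.int64)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return CytosineCountTable(df, groups)


@pytest.fixture
def uniform_table():
    """Two groups x 2 replicates, every CG locus at proportion 0.5,
    coverage 20, loci every 50 bp."""
    n = 40
    loci = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n + 1) * 50,
            "strand": "+",
            "context": "CG",
        }
    )
    counts = {}
    for s in ("G+_1", "G+_2", "G-_1", "G-_2"):
        counts[s] = (np.full(n, 10), np.full(n, 20))
    groups = {s: s.rsplit("_", 1)[0] for s in counts}
    return make_count_table(loci, counts, groups)
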
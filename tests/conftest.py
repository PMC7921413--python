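"""Shared fixtures: synthetic cohorts and small hand-built tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import clonetrace as ct
from clonetrace.counts import COLUMNS


def make_table(rows, individual_id="I1"):
    """Rows of (cell, contig, pos, ref, A, C, G, T, DEL)."""
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    return ct.AlleleCountTable(df, individual_id=individual_id)


@pytest.fixture(scope="session")
def threeclones():
    """The standard well-separated fixture pushed through matrix construction."""
    config = ct.standard_fixtures()["threeclones"]
    tables, truth = ct.simulate_cohort(config)
    table = tables["I1"]
    candidates, _ = ct.discover_cohort_variants({"I1": table})
    selected = ct.select_covered_variants(table, candidates["I1"])
    matrix = ct.build_call_matrix(table, selected)
    return {
        "config": config,
        "table": table,
        "truth": truth,
        "candidates": candidates["I1"],
        "matrix": matrix,
    }


@pytest.fixture(scope="session")
def threeclones_variant_names(threeclones):
    """Map planted variant name (v1..v4) -> call-matrix label."""
    truth = threeclones["truth"]
    vdf = truth.variants
    out = {}
    for r in vdf.itertuples():
        label = f"{r.contig}:{r.position}{r.ref}>{r.alt}"
        out[r.label] = label
    return out


@pytest.fixture()
def tiny_matrix():
    """3 variants x 6 cells with known calls, including missing entries."""
    N = np.array(
        [
            [1, 1, 1],
            [1, 1, 0],
            [1, 0, 0],
            [0, 0, 0],
            [1, -1, 1],
            [-1, -1, -1],
        ],
        dtype=np.int8,
    )
    cov = np.where(N == -1, 0, 10).astype(np.int64)
    alt = np.where(N == 1, 9, 0).astype(np.int64)
    ref = cov - alt
    cells = [f"c{i}" for i in range(6)]
    return ct.CallMatrix(N, alt, ref, cov, cells, ["vA", "vB", "vC"], [])
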
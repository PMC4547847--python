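"""Shared fixtures: tiny hand-written proteinGroups files and small synthetic tables."""

import numpy as np
import pandas as pd
import pytest

from qdsp_profiler import GeneratorConfig, generate_qdsp_dataset

PG_HEADER = [
    "Majority protein IDs",
    "Gene names",
    "Intensity S1",
    "Intensity S2",
    "Reverse",
    "Potential contaminant",
]


@pytest.fixture
def tiny_pg_file(tmp_path):
    """3-row proteinGroups file: one reverse hit, one zero intensity."""
    rows = [
        ["P1", "GeneA", "1000", "2000", "", ""],
        ["P2", "GeneB", "0", "500", "", ""],
        ["REV__P3", "GeneC", "300", "400", "+", ""],
    ]
    path = tmp_path / "proteinGroups.txt"
    path.write_text(
        "\t".join(PG_HEADER) + "\n" + "\n".join("\t".join(r) for r in rows) + "\n"
    )
    sheet = tmp_path / "samples.tsv"
    sheet.write_text(
        "column\tsample_id\tcondition\tfraction\treplicate\tmouse_id\tcompartment\n"
        "Intensity S1\tS1\tPBS\tFR1\t1\tm1\tTISSUE\n"
        "Intensity S2\tS2\tBLEO\tFR1\t1\tm2\tTISSUE\n"
    )
    return path, sheet


@pytest.fixture(scope="session")
def small_qdsp():
    """A 400-protein QDSP dataset with defaults (shared, read-only)."""
    return generate_qdsp_dataset(GeneratorConfig(n_proteins=400, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_annotations_frame(terms):
    """Helper: AnnotationCollection from {term: iterable of ids}."""
    from qdsp_profiler import AnnotationCollection

    return AnnotationCollection({t: {"members": set(m)} for t, m in terms.items()})
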
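import numpy as np
import pandas as pd
import pytest

from microeuk.io import RANKS, CommunityTable, SampleMetadata, TaxonomyTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """3 samples x 4 ASVs with distinct compositions."""
    df = pd.DataFrame(
        [[10, 5, 0, 1], [0, 8, 4, 2], [3, 3, 3, 3]],
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        columns=["a1", "a2", "a3", "a4"],
    )
    return CommunityTable(df)


def make_taxonomy(lineages: dict) -> TaxonomyTable:
    """Build a TaxonomyTable from {asv: partial-lineage-tuple}."""
    rows = {
        asv: list(lin) + [""] * (len(RANKS) - len(lin)) for asv, lin in lineages.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    df.index.name = "asv_id"
    return TaxonomyTable(df)


def make_metadata(n_sites=4, depths=(0.5, 5.0, 10.0), seed=0) -> SampleMetadata:
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sites):
        for d in depths:
            rows.append(
                {
                    "sample_id": f"site{i}_d{d:g}",
                    "site": f"site{i}",
                    "season": "spring" if i % 2 == 0 else "autumn",
                    "depth_m": d,
                    "latitude": 28.0 + 0.01 * i,
                    "longitude": 119.65 + 0.02 * i,
                    "temperature": float(rng.uniform(10, 28)),
                    "pH": float(rng.uniform(7, 8.5)),
                    "DO": float(rng.uniform(5, 12)),
                    "chla": float(rng.uniform(0.5, 11)),
                    "NO3_N": float(rng.uniform(0.1, 1.0)),
                    "NO2_N": float(rng.uniform(0.001, 0.05)),
                    "NH4_N": float(rng.uniform(0.02, 0.5)),
                    "TN": float(rng.uniform(0.5, 2.0)),
                    "TP": float(rng.uniform(0.01, 0.1)),
                    "PO4_P": float(rng.uniform(0.005, 0.05)),
                    "CODMn": float(rng.uniform(1, 5)),
                    "TOC": float(rng.uniform(1, 6)),
                }
            )
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))
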
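import numpy as np
import pandas as pd
import pytest

from ibdkit import GenomeMap, build_reference_cloud
from ibdkit.io import SEGMENT_COLUMNS


@pytest.fixture(scope="session")
def gmap() -> GenomeMap:
    return GenomeMap.default()


@pytest.fixture(scope="session")
def one_chrom() -> GenomeMap:
    """Single 1-Morgan chromosome, for closed-form spot checks."""
    return GenomeMap.from_lengths([100.0])


def make_segments(rows) -> pd.DataFrame:
    """rows: (iid1, iid2, chrom, start_cM, length_cM) tuples."""
    frame = pd.DataFrame(
        [
            (a, b, c, s, s + ln, ln, round(ln * 250))
            for (a, b, c, s, ln) in rows
        ],
        columns=SEGMENT_COLUMNS,
    )
    return frame


@pytest.fixture()
def toy_segments() -> pd.DataFrame:
    """Hand-traceable four-individual table: A-B one 25 cM tract, B-C three
    medium tracts (9, 9, 10 cM), A-D a single 9 cM tract."""
    return make_segments(
        [
            ("A", "B", 1, 10.0, 25.0),
            ("B", "C", 2, 5.0, 9.0),
            ("B", "C", 3, 15.0, 9.0),
            ("B", "C", 4, 30.0, 10.0),
            ("A", "D", 5, 50.0, 9.0),
        ]
    )


@pytest.fixture()
def toy_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "iid": ["A", "B", "C", "D"],
            "group": ["g1", "g1", "g2", "g2"],
            "region": ["C.Basin", "C.Basin", "E.E.Steppe", "C.Asia"],
            "date_CE": [500, 510, 25, 30],
            "n_snps_covered": [600_000, 700_000, 800_000, 500_000],
        }
    )


@pytest.fixture(scope="session")
def reference_cloud(gmap) -> pd.DataFrame:
    """Shared simulated pedigree cloud at the 8 cM analysis floor."""
    return build_reference_cloud(n_per_degree=500, gmap=gmap, min_len_cM=8.0, seed=11)
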
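import numpy as np
import pandas as pd
import pytest

from egakit.config import ReplicateGroup, SimConfig
from egakit.containers import SampleSheet, SpikeTagMatrix
from egakit.motif import PromoterWindow
from egakit.simulate import synthetic_ega_motif
from egakit.tfe import GeneModel


@pytest.fixture(scope="session")
def ega_pwm():
    return synthetic_ega_motif()


@pytest.fixture
def three_v_three_design():
    return [
        ReplicateGroup("A", "positive", 3, 75),
        ReplicateGroup("A", "negative", 3, 75),
    ]


@pytest.fixture
def small_null_config(three_v_three_design):
    """A tiny 3v3 experiment with no planted effects."""
    return SimConfig(
        n_tfes=50,
        n_spikes=10,
        library_size_mean=5000,
        replicate_design=three_v_three_design,
        effect_constructs=("A",),
        frac_up=0.0,
        frac_down=0.0,
        capture_efficiency_cv=0.0,
        seed=7,
    )


@pytest.fixture
def toy_matrix():
    """3 TFEs + 1 spike row over 4 samples, equal spike totals."""
    df = pd.DataFrame(
        {
            "s1": [10, 0, 5, 100],
            "s2": [12, 0, 7, 100],
            "s3": [50, 0, 5, 100],
            "s4": [55, 0, 8, 100],
        },
        index=["TFE000001", "TFE000002", "TFE000003", "SPIKE_001"],
    )
    return SpikeTagMatrix(df)


@pytest.fixture
def toy_gene_plus():
    """Coding gene on +: exon1 [1000,1300) with 5'UTR [1000,1250),
    intron [1300,1800), exon2 [1800,2100) coding, exon3 [2600,3000) with CDS
    end 2800 and 3'UTR [2800,3000)."""
    return GeneModel(
        "GENEP", "chr1", "+", 1000, 3000,
        [(1000, 1300), (1800, 2100), (2600, 3000)],
        cds_start=1250, cds_end=2800,
    )


@pytest.fixture
def toy_gene_minus():
    """Coding gene on -: 5'UTR is the exonic stretch at the high-coordinate
    end, [6750, 7000)."""
    return GeneModel(
        "GENEM", "chr1", "-", 5000, 7000,
        [(5000, 5400), (5900, 6200), (6700, 7000)],
        cds_start=5200, cds_end=6750,
    )


@pytest.fixture
def random_windows():
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def make(rng, n, length=600, tag="w"):
        return [
            PromoterWindow(
                f"{tag}{i}", "chrS", 0, length, "+",
                bases[rng.integers(0, 4, length)].tobytes().decode(),
            )
            for i in range(n)
        ]

    return make


@pytest.fixture
def default_library_sheet():
    """Default 48-well sample sheet."""
    from egakit.simulate import _sample_sheet_rows

    return SampleSheet(pd.DataFrame(_sample_sheet_rows(SimConfig())))
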
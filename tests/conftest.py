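import numpy as np
import pandas as pd
import pytest

from lncarray.simulate import SimulationConfig, simulate_study
from lncarray.study_io import ExpressionMatrix, Sample, StudyDesign, TranscriptRecord


@pytest.fixture(scope="session")
def small_study():
    """A compact seeded synthetic study shared across tests."""
    return simulate_study(SimulationConfig(seed=11, n_lnc=60, n_mrna=140,
                                           coexpressed_pair_count=12,
                                           cis_pair_count=6, trans_pair_count=4))


@pytest.fixture
def design_3x3():
    """Complete 2-condition x 3-time-point x 3-replicate design (18 samples)."""
    samples = [
        Sample(f"{prefix}_{tp}_{rep}", condition, tp, rep)
        for tp in ("T0", "T2", "T48")
        for condition, prefix in (("case", "RS"), ("control", "P"))
        for rep in (1, 2, 3)
    ]
    return StudyDesign(samples)


@pytest.fixture
def linear_matrix_factory():
    def make(values, probes=None, samples=None, normalized=False):
        values = np.asarray(values, dtype=float)
        probes = probes or [f"p{i}" for i in range(values.shape[0])]
        samples = samples or [f"s{j}" for j in range(values.shape[1])]
        frame = pd.DataFrame(values, index=probes, columns=samples)
        return ExpressionMatrix(frame, scale="linear", normalized=normalized)

    return make


def make_transcript(probe_id="t1", rna_type="lncRNA", chrom="chr1", strand="+",
                    start=0, end=1000, exons=None, utr3=None, gene_id=None):
    return TranscriptRecord(
        probe_id=probe_id, rna_type=rna_type, transcript_id=f"TX_{probe_id}",
        gene_id=gene_id or f"G_{probe_id}", chrom=chrom, strand=strand,
        start=start, end=end, exons=exons or [(start, end)], utr3=utr3,
    )
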
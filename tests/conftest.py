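import numpy as np
import pytest

from upstreamkit.formats_io import ExpressionMatrix, PromoterRecord
from upstreamkit.motif_scan import MotifModel
from upstreamkit.synthetic_data import gen_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_matrix():
    """4 genes x 4 samples; gene G1 has an exact +1 shift in YES."""
    genes = ["G1", "G2", "G3", "G4"]
    samples = ["y1", "y2", "n1", "n2"]
    values = np.array([
        [2.0, 2.0, 1.0, 1.0],
        [5.0, 5.5, 5.2, 5.3],
        [3.0, 3.1, 3.0, 3.1],
        [7.0, 6.9, 7.1, 7.0],
    ])
    groups = {"y1": "YES", "y2": "YES", "n1": "NO", "n2": "NO"}
    return ExpressionMatrix(genes, samples, values, groups)


@pytest.fixture
def toy_motif():
    """6-position motif with a sharp consensus ACATAC."""
    counts = np.array([[12, 0, 0, 0], [0, 10, 2, 0], [5, 0, 5, 2],
                       [0, 0, 0, 12], [12, 0, 0, 0], [0, 12, 0, 0]],
                      dtype=float)
    return MotifModel.from_counts("M1", "TF1", counts)


def make_promoter(seq: str, gene: str = "g", end: int | None = None
                  ) -> PromoterRecord:
    """Promoter wrapper with the TSS at ``end`` bases before the 3' end."""
    end = 0 if end is None else end
    return PromoterRecord(gene, seq, end - len(seq), end)


@pytest.fixture(scope="session")
def small_bundle():
    """A down-scaled planted study shared by read-only pipeline tests."""
    return gen_study(seed=7, n_genes=400, n_up=40, n_down=20,
                     n_yes_promoters=25, n_no_promoters=60,
                     n_motifs=8, n_nodes=80, n_distractors=2)
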
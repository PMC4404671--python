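import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tomatopop.genotypes import GenotypeMatrix
from tomatopop.simulate import worked_toy


def make_matrix(calls, positions=None, chromosomes=None, alleles=None,
                accessions=None, ids=None) -> GenotypeMatrix:
    """Build a small GenotypeMatrix from literals."""
    calls = np.asarray(calls, dtype=np.int8)
    n_acc, n_mark = calls.shape
    markers = pd.DataFrame({
        "id": ids or [f"m{j}" for j in range(n_mark)],
        "chromosome": chromosomes or ["chr1"] * n_mark,
        "position_cm": positions if positions is not None
        else np.arange(n_mark, dtype=float),
        "allele_a": [a[0] for a in alleles] if alleles else ["A"] * n_mark,
        "allele_b": [a[1] for a in alleles] if alleles else ["G"] * n_mark,
    })
    return GenotypeMatrix(calls, accessions or [f"a{i}" for i in range(n_acc)],
                          markers)


@pytest.fixture(scope="session")
def toy():
    return worked_toy()


@pytest.fixture(scope="session")
def toy_expected():
    with open(Path(__file__).parent / "data" / "worked_toy_expected.json") as fh:
        return json.load(fh)
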
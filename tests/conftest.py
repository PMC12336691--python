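import numpy as np
import pandas as pd
import pytest

from garep.io import Repertoire


def make_repertoire(rows, sample_id="s1", subject_id="p1", timepoint="single"):
    """Build a Repertoire from (nt, junction, v, j, templates, productive) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["nucleotide_seq", "junction_aa", "v_gene", "j_gene", "templates", "productive"],
    )
    return Repertoire(sample_id, subject_id, timepoint, df)


def random_repertoire(rng, n=50, sample_id="s1"):
    """Random repertoire with unique nucleotide sequences."""
    nts = set()
    while len(nts) < n:
        nts.add("".join(rng.choice(list("ACGT"), size=30)))
    rows = []
    for i, nt in enumerate(sorted(nts)):
        productive = rng.random() > 0.15
        junc = "C" + "".join(rng.choice(list("ARNDCEQGHILKMFPSTWYV"), size=10)) + "F"
        rows.append(
            (
                nt,
                junc if productive else "",
                f"TRBV{rng.integers(2, 30):02d}" if productive else "",
                f"TRBJ{rng.integers(1, 2):02d}-{rng.integers(1, 7):02d}" if productive else "",
                int(rng.zipf(2.0)),
                productive,
            )
        )
    return make_repertoire(rows, sample_id=sample_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
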
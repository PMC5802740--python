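import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def study_table_file(tmp_path):
    """Psychiatric-consortium style study table: six rows of group sizes
    and observed one-sided P-values for a single SNP."""
    text = (
        "# one-sided P-values for rs2535629-style association rows\n"
        "label\tcases\tcontrols\tp_one_sided\n"
        "ADHD\t2787\t2635\t0.1005\n"
        "ASD\t4949\t5314\t0.098\n"
        "BP\t6990\t4820\t3.305e-06\n"
        "MDD\t9227\t7383\t0.000108\n"
        "Schizophrenia\t9379\t7736\t3.355e-05\n"
        "All\t33332\t27888\t1.27e-12\n"
    )
    path = tmp_path / "studies.tsv"
    path.write_text(text)
    return path
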
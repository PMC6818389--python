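import io

import pytest

from drivercall import build_weighted_reference, read_maf

MICRO_MAF = """\
# synthetic micro-MAF fixture
Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification
TP53\tS1\tMissense_Mutation
TP53\tS2\tNonsense_Mutation
KRAS\tS1\tSilent
"""

FULL_MAF = """\
Hugo_Symbol\tChromosome\tStart_Position\tEnd_Position\tReference_Allele\tTumor_Seq_Allele2\tVariant_Classification\tTumor_Sample_Barcode
TP53\t17\t7577120\t7577120\tC\tT\tMissense_Mutation\tS1
KRAS\t12\t25398284\t25398284\tC\tA\tMissense_Mutation\tS2
"""


@pytest.fixture
def micro_records():
    return read_maf(io.StringIO(MICRO_MAF), dialect="micro")


@pytest.fixture
def tiny_weighted_ref():
    """Three-gene weighted reference with hand-computable weights 1.0/0.3/0."""
    return build_weighted_reference({"A": 100, "B": 60, "C": 40})
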
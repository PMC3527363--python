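from __future__ import annotations

import pytest

from helpers import HUMAN, MOUSE, RAT, build_kb, gene, record, ref
from interactograph.model import InteractionType


@pytest.fixture
def ipsc_kb():
    """Handmade reprogramming-factor knowledgebase: human and mouse
    orthologs of the six stem-cell factors plus a couple of bystanders.
    'Oct4' is a synonym of the official symbol POU5F1/Pou5f1."""
    genes = [
        gene(5460, "POU5F1", HUMAN, synonyms=("Oct4", "OCT3")),
        gene(6657, "SOX2", HUMAN),
        gene(9314, "KLF4", HUMAN),
        gene(4609, "MYC", HUMAN, synonyms=("c-Myc",)),
        gene(79923, "NANOG", HUMAN),
        gene(79727, "LIN28A", HUMAN),
        gene(18999, "Pou5f1", MOUSE, synonyms=("Oct4",)),
        gene(20674, "Sox2", MOUSE),
        gene(1482, "NKX2-5", HUMAN),
        gene(4208, "MEF2C", HUMAN),
    ]
    interactions = [
        record(1, ref(5460), ref(6657)),                                  # POU5F1-SOX2 PP
        record(2, ref(6657), ref(79923), InteractionType.protein_dna),    # SOX2->NANOG PD
        record(3, ref(4609), ref(9314), InteractionType.genetic),
        record(4, ref(18999, MOUSE), ref(20674, MOUSE)),                  # mouse Pou5f1-Sox2
        record(5, ref(1482), ref(4208)),
    ]
    groups = {
        10: [ref(5460), ref(18999, MOUSE)],   # POU5F1 orthologs
        11: [ref(6657), ref(20674, MOUSE)],   # SOX2 orthologs
    }
    return build_kb(genes, interactions, groups)
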
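"""Shared fixtures: toy references and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from hacseq.reference import TRNARecord, assign_canonical_positions
from hacseq.simulate import (
    CdsSimConfig,
    paper_pattern_references,
    simulate_cds_set,
)


def make_toy_trna(
    name: str = "tRNA-Ser-GCT-1-1",
    anticodon: str = "GCT",
    length: int = 76,
    anticodon_index: int = 33,
    seed: int = 0,
) -> TRNARecord:
    """Deterministic toy tRNA with the anticodon planted at a known index."""
    rng = np.random.default_rng(seed)
    for _ in range(100):
        seq = rng.choice(list("ACGT"), size=length)
        seq[anticodon_index - 2] = "C"
        seq[anticodon_index : anticodon_index + 3] = list(anticodon)
        seq[-3:] = list("CCA")
        s = "".join(seq)
        occ = [i for i in range(length - 2) if s[i : i + 3] == anticodon]
        if occ == [anticodon_index]:
            parts = name.split("-")
            rec = TRNARecord(
                id=name, amino_acid=parts[1], anticodon=anticodon, sequence=s
            )
            return assign_canonical_positions(rec)
    raise RuntimeError("could not build toy tRNA")


@pytest.fixture(scope="session")
def toy_trna() -> TRNARecord:
    return make_toy_trna()


@pytest.fixture(scope="session")
def preset_references():
    return paper_pattern_references()


@pytest.fixture(scope="session")
def small_cds_models():
    models, truth = simulate_cds_set(
        CdsSimConfig(genes_per_group={"base": 60}, mean_codons=80, sd_codons=10, seed=42)
    )
    return models, truth
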
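import numpy as np
import pandas as pd
import pytest

import combiscreen as cs


@pytest.fixture
def hand_block():
    """6x6 single-replicate block with vehicle signal 1000 and a smooth
    dose-dependent decline on both axes."""
    doses = cs.SIX_BY_SIX.doses("A")
    vA = 1.0 / (1.0 + (doses / 4e-7))
    vB = 1.0 / (1.0 + (doses / 2e-6))
    v = np.outer(vA, vB)
    return cs.DoseMatrixBlock(
        block_id="hand",
        drugA=cs.CompoundRecord("drugA"),
        drugB=cs.CompoundRecord("drugB"),
        dosesA=doses,
        dosesB=doses,
        signal=1000.0 * v[:, :, None],
    )


def block_from_surface(v, dosesA=None, dosesB=None, replicates=1, scale=1000.0):
    """Wrap a viability surface into a DoseMatrixBlock with clean signal."""
    nA, nB = v.shape
    if dosesA is None:
        dosesA = np.concatenate([[0.0], np.geomspace(1e-9, 1e-6, nA - 1)])
    if dosesB is None:
        dosesB = np.concatenate([[0.0], np.geomspace(1e-9, 1e-6, nB - 1)])
    signal = scale * np.repeat(v[:, :, None], replicates, axis=2)
    return cs.DoseMatrixBlock(
        block_id="surface",
        drugA=cs.CompoundRecord("A"),
        drugB=cs.CompoundRecord("B"),
        dosesA=dosesA,
        dosesB=dosesB,
        signal=signal,
    )


def dataset_to_long_frame(dataset):
    rows = []
    for blk in dataset.blocks:
        nA, nB, nR = blk.signal.shape
        for i in range(nA):
            for j in range(nB):
                for r in range(nR):
                    rows.append(
                        {
                            "block_id": blk.block_id,
                            "drugA_id": blk.drugA.compound_id,
                            "doseA": blk.dosesA[i],
                            "drugB_id": blk.drugB.compound_id,
                            "doseB": blk.dosesB[j],
                            "replicate": r + 1,
                            "signal": blk.signal[i, j, r],
                            "assay": blk.assay,
                        }
                    )
    return pd.DataFrame(rows)
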
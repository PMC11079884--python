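import numpy as np
import pytest

from lipidiff.io_preprocess import IntensityTable, SampleMeta
from lipidiff.nomenclature import ClassCategory

# A curated set of real-world shorthand lipid names, as printed by
# LipidSearch-style identification software, with their expected class
# categories. Exercises every grammar feature: sphingoid "d" bases,
# ether "e" and plasmalogen "p" linkages, 1-3 chains, "(rep)" twins.
CURATED_LIPID_NAMES: dict[str, ClassCategory] = {
    "DG(18:2/18:2)": ClassCategory.DIGLYCERIDE,
    "LPC(14:0)": ClassCategory.LYSO_PHOSPHOLIPID,
    "LPC(20:1)": ClassCategory.LYSO_PHOSPHOLIPID,
    "LPE(18:0)": ClassCategory.LYSO_PHOSPHOLIPID,
    "PI(18:0/18:2)": ClassCategory.PHOSPHOLIPID,
    "Cer(d18:2/24:1)": ClassCategory.CERAMIDE,
    "CerG2(d18:1/24:1)": ClassCategory.GLYCOSYLCERAMIDE,
    "PC(16:0/16:0)": ClassCategory.PHOSPHOLIPID,
    "PC(16:0p/16:0)": ClassCategory.PHOSPHOLIPID,
    "PI(18:1/20:4)": ClassCategory.PHOSPHOLIPID,
    "PS(18:0/18:1)": ClassCategory.PHOSPHOLIPID,
    "PS(18:1/22:1)": ClassCategory.PHOSPHOLIPID,
    "DG(16:0/18:1)": ClassCategory.DIGLYCERIDE,
    "DG(16:0/18:2)": ClassCategory.DIGLYCERIDE,
    "DG(18:0/18:1)": ClassCategory.DIGLYCERIDE,
    "DG(18:0/20:3)": ClassCategory.DIGLYCERIDE,
    "DG(18:1/18:1)": ClassCategory.DIGLYCERIDE,
    "DG(18:1/18:2)": ClassCategory.DIGLYCERIDE,
    "PC(16:0/14:0)": ClassCategory.PHOSPHOLIPID,
    "Cer(d18:1/16:0)": ClassCategory.CERAMIDE,
    "LPC(18:0)(rep)": ClassCategory.LYSO_PHOSPHOLIPID,
    "PI(18:0/18:1)": ClassCategory.PHOSPHOLIPID,
    "TG(18:0e/18:1/18:1)": ClassCategory.TRIGLYCERIDE,
    "LPC(16:0)": ClassCategory.LYSO_PHOSPHOLIPID,
    "LPC(16:0)(rep)": ClassCategory.LYSO_PHOSPHOLIPID,
    "LPC(18:0e)": ClassCategory.LYSO_PHOSPHOLIPID,
    "LPI(18:0)": ClassCategory.LYSO_PHOSPHOLIPID,
}


@pytest.fixture
def toy_samples():
    return [
        SampleMeta("s1", "tumor", "p1"),
        SampleMeta("s2", "tumor", "p2"),
        SampleMeta("s3", "tumor", "p3"),
        SampleMeta("s4", "ctrl", "p4"),
        SampleMeta("s5", "ctrl", "p5"),
    ]


@pytest.fixture
def toy_table(toy_samples):
    """Five samples, four lipids, one missing cell, mixed grades."""
    intensities = np.array(
        [
            [10.0, 12.0, 14.0, 20.0, 22.0],
            [5.0, 6.0, 7.0, 5.5, 6.5],
            [100.0, np.nan, 300.0, 50.0, 60.0],
            [1.0, 2.0, 3.0, 1.0, 2.0],
        ]
    )
    return IntensityTable(
        lipids=["DG(18:2/18:2)", "LPC(16:0)", "LPC(16:0)(rep)", "TG(18:0e/18:1/18:1)"],
        grades=["A", "B", "C", "D"],
        intensities=intensities,
        missing_mask=np.isnan(intensities),
        samples=toy_samples,
    )
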
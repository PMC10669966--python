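"""Published PDE3A immunohistochemistry cross-tabulations.

Small printed tables from a clinical liposarcoma / soft-tissue-sarcoma
PDE3A IHC study, bundled as inputs for the association statistics: the
per-sarcoma-type staining-intensity table of a 543-sample TMA series and
the H-score (low/high) cross-tabulations of a 181-sample liposarcoma
series against clinicopathological factors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clinical import ContingencyTable

#: PDE3A staining intensity (0-3) by sarcoma type, N per cell.
STS_INTENSITY_COUNTS = pd.DataFrame(
    {
        0: [7, 0, 46, 19, 133, 11, 27, 14, 29],
        1: [2, 0, 24, 17, 67, 4, 14, 12, 4],
        2: [1, 8, 14, 17, 19, 3, 7, 5, 3],
        3: [0, 19, 3, 6, 3, 2, 0, 2, 1],
    },
    index=[
        "fibrosarcoma",
        "gastrointestinal_stromal_tumor",
        "liposarcoma",
        "leiomyosarcoma",
        "malignant_fibrohistiocytoma",
        "malignant_peripheral_nerve_sheath_tumor",
        "myxofibrosarcoma",
        "sarcoma_nos",
        "synovial_sarcoma",
    ],
)


def intensity_percent(sarcoma_type: str, intensity: int) -> float:
    """Percent of a sarcoma type's samples at exactly this intensity."""
    row = STS_INTENSITY_COUNTS.loc[sarcoma_type]
    return float(row[intensity] / row.sum() * 100.0)


def intensity_at_least_percent(sarcoma_type: str, min_intensity: int) -> float:
    """Percent of a sarcoma type's samples at or above an intensity."""
    row = STS_INTENSITY_COUNTS.loc[sarcoma_type]
    return float(row[row.index >= min_intensity].sum() / row.sum() * 100.0)


def sex_table() -> ContingencyTable:
    """Sex x PDE3A H-score class (low/high) in the liposarcoma series."""
    return ContingencyTable(
        np.array([[57, 38], [66, 20]]),
        row_labels=["male", "female"],
        col_labels=["low", "high"],
    )


def subtype_table() -> ContingencyTable:
    """Histological subtype x PDE3A H-score class (low/high)."""
    return ContingencyTable(
        np.array([[10, 0], [57, 15], [26, 39], [30, 4]]),
        row_labels=["well_differentiated", "dedifferentiated", "myxoid", "pleomorphic"],
        col_labels=["low", "high"],
    )


def tumor_site_table() -> ContingencyTable:
    """Tumor site x PDE3A H-score class (low/high)."""
    return ContingencyTable(
        np.array([[50, 33], [39, 9], [25, 11], [8, 3], [1, 2]]),
        row_labels=["limb", "retroperitoneal", "trunk", "abdomen", "head"],
        col_labels=["low", "high"],
    )


def metastasis_table() -> ContingencyTable:
    """Metastasis at diagnosis x PDE3A H-score class (low/high)."""
    return ContingencyTable(
        np.array([[4, 4], [119, 54]]),
        row_labels=["present", "not_present"],
        col_labels=["low", "high"],
    )


def high_hscore_percent(subtype: str) -> float:
    """Percent of a liposarcoma subtype with a high (>150) H-score."""
    t = subtype_table()
    i = t.row_labels.index(subtype)
    row = t.counts[i]
    return float(row[1] / row.sum() * 100.0)
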
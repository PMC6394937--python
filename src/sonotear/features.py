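"""Per-case feature extraction: moments + directional GLCM statistics.

The feature table (one row per case, 4 intensity + 14 texture columns plus
case metadata) is the single hand-off artifact between extraction and
modelling, so the modelling layer is testable on hand-written tables.
"""

from __future__ import annotations

import pandas as pd

from .intensity import compute_moments
from .io import CaseRecord, masked_pixels
from .screening import ALL_FEATURE_NAMES, META_COLUMNS
from .texture import texture_features


def extract_case_features(
    record: CaseRecord, n_levels: int = 8, distance: int = 1
) -> dict[str, float]:
    """All 18 features of one case, keyed by their canonical names."""
    pixels = masked_pixels(record.image, record.mask)
    row = compute_moments(pixels).as_dict()
    row.update(
        texture_features(record.image, record.mask, n_levels=n_levels, distance=distance)
    )
    return row


def extract_features(
    records, n_levels: int = 8, distance: int = 1
) -> pd.DataFrame:
    """Feature table for a list of case records."""
    rows = []
    for rec in records:
        row = {
            "case_id": rec.case_id,
            "patient_id": rec.patient_id,
            "label": rec.label,
        }
        row.update(extract_case_features(rec, n_levels=n_levels, distance=distance))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(ALL_FEATURE_NAMES))
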
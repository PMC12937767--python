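"""Clinical-metadata encoding (12 dimensions).

Each lesion carries the PAD-UFES-20-style clinical record: patient age,
gender, two lesion diameters in millimetres, two lifestyle flags
(smoke, drink) and six symptom flags (itch, grew, hurt, changed, bleed,
elevation). Continuous fields are z-scored with statistics fitted on
the training partition only — x_hat = (x - mu) / (sigma + eps) with
population sigma — so no information leaks from the test side. Gender
encodes Male = 1, Female = 0; boolean flags encode true = 1, false = 0.

Missing values: continuous fields are imputed with the train median
(then z-scored); missing booleans encode as 0. Imputations are counted
and logged. A strict mode rejects records with missing fields instead.

Fixed output order:
[age_z, gender, d1_z, d2_z, smoke, drink, itch, grew, hurt, changed,
 bleed, elevation].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTINUOUS_FIELDS = ["age", "diameter_1", "diameter_2"]
BINARY_FIELDS = ["smoke", "drink", "itch", "grew", "hurt", "changed", "bleed", "elevation"]

#: Canonical schema columns and the fixed encoding order.
METADATA_COLUMNS = ["age", "gender", "diameter_1", "diameter_2"] + BINARY_FIELDS

_TRUE_TOKENS = {True, 1, "1", "true", "True", "TRUE", "yes", "YES"}
_FALSE_TOKENS = {False, 0, "0", "false", "False", "FALSE", "no", "NO"}


@dataclass
class MetadataStats:
    """Train-fitted standardization parameters for continuous fields."""

    mean: dict[str, float]
    std: dict[str, float]          # population standard deviation
    median: dict[str, float]       # imputation values
    n_train: int
    eps: float = 1e-8
    n_imputed: int = field(default=0, compare=False)


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    if isinstance(v, str) and v.strip().lower() in ("", "nan", "unk", "unknown", "na"):
        return True
    return False


def fit_stats(train_records: pd.DataFrame | list[dict], eps: float = 1e-8) -> MetadataStats:
    """Fit per-field mean / population std / median on the train split.

    A continuous field with no observed values raises, naming the field.
    """
    df = pd.DataFrame(train_records)
    mean, std, median = {}, {}, {}
    for f in CONTINUOUS_FIELDS:
        vals = pd.to_numeric(df.get(f), errors="coerce").dropna()
        if len(vals) == 0:
            raise ValueError(f"continuous field {f!r} entirely missing in train data")
        mean[f] = float(vals.mean())
        std[f] = float(vals.std(ddof=0))
        median[f] = float(vals.median())
    return MetadataStats(mean=mean, std=std, median=median, n_train=len(df), eps=eps)


def _encode_binary(value, fieldname: str, strict: bool, stats: MetadataStats) -> float:
    if _is_missing(value):
        if strict:
            raise ValueError(f"missing value for field {fieldname!r} in strict mode")
        stats.n_imputed += 1
        return 0.0
    if value in _TRUE_TOKENS:
        return 1.0
    if value in _FALSE_TOKENS:
        return 0.0
    raise ValueError(f"unrecognized boolean token {value!r} for field {fieldname!r}")


def encode(record: dict | pd.Series, stats: MetadataStats, strict: bool = False) -> np.ndarray:
    """Encode one clinical record into the fixed 12-d vector."""
    rec = dict(record)
    out = []
    # age
    out.append(_z(rec.get("age"), "age", stats, strict))
    # gender
    g = rec.get("gender")
    if _is_missing(g):
        if strict:
            raise ValueError("missing gender in strict mode")
        stats.n_imputed += 1
        out.append(0.0)
    elif str(g).strip().lower() in ("male", "m", "1"):
        out.append(1.0)
    elif str(g).strip().lower() in ("female", "f", "0"):
        out.append(0.0)
    else:
        raise ValueError(
            f"unknown gender token {g!r}; accepted: Male/M/1, Female/F/0"
        )
    out.append(_z(rec.get("diameter_1"), "diameter_1", stats, strict))
    out.append(_z(rec.get("diameter_2"), "diameter_2", stats, strict))
    for f in BINARY_FIELDS:
        out.append(_encode_binary(rec.get(f), f, strict, stats))
    vec = np.asarray(out, dtype=float)
    if stats.n_imputed:
        logger.debug("metadata imputations so far: %d", stats.n_imputed)
    return vec


def _z(value, fieldname: str, stats: MetadataStats, strict: bool) -> float:
    if _is_missing(value):
        if strict:
            raise ValueError(f"missing value for field {fieldname!r} in strict mode")
        stats.n_imputed += 1
        value = stats.median[fieldname]
    x = float(value)
    return (x - stats.mean[fieldname]) / (stats.std[fieldname] + stats.eps)


def encode_frame(records: pd.DataFrame, stats: MetadataStats, strict: bool = False) -> np.ndarray:
    """Encode a metadata table row-by-row into an (n, 12) matrix."""
    return np.vstack([encode(row, stats, strict=strict) for _, row in records.iterrows()])


#: Maps PAD-UFES-20 CSV headers onto the canonical schema.
PAD_UFES_COLUMN_MAP = {
    "age": "age",
    "gender": "gender",
    "diameter_1": "diameter_1",
    "diameter_2": "diameter_2",
    "smoke": "smoke",
    "drink": "drink",
    "itch": "itch",
    "grew": "grew",
    "hurt": "hurt",
    "changed": "changed",
    "bleed": "bleed",
    "elevation": "elevation",
    "img_id": "image_id",
    "patient_id": "patient_id",
    "diagnostic": "label",
}


def read_metadata_csv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a metadata CSV, renaming columns onto the canonical schema."""
    df = pd.read_csv(path)
    cmap = dict(PAD_UFES_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    return df.rename(columns={k: v for k, v in cmap.items() if k in df.columns})
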
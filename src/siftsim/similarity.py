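"""Confusion-count computation and reference-vs-query similarity matrices.

The similarity matrix is the input of the SRD comparison: one row per query
ligand, one column per similarity measure, every value the scaled
similarity of that ligand's fingerprint to a single reference fingerprint.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .fingerprints import FingerprintDataset, InteractionFingerprint
from .measures import (
    ConfusionCounts,
    SimilarityMeasure,
    get_measure,
    list_measures,
    raw_similarity,
    scale_similarity,
)

#: Non-measure columns of a similarity matrix frame.
ID_COLUMNS = ("ligand_id", "active")


def confusion_counts(fp1, fp2) -> ConfusionCounts:
    """Confusion table (a, b, c, d) of two equal-length binary vectors.

    Accepts raw 0/1 vectors or :class:`InteractionFingerprint` objects.
    Counting is done on packed bit words with popcount, so fingerprints of
    thousands of bits stay cheap.
    """
    x = _as_bits(fp1)
    y = _as_bits(fp2)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size == 0:
        raise ValueError("cannot build a confusion table for empty vectors")
    px, py = np.packbits(x), np.packbits(y)
    a = int(np.bitwise_count(px & py).sum())
    b = int(np.bitwise_count(px & ~py).sum())
    c = int(np.bitwise_count(~px & py).sum())
    # ~ operates on the padded words too; derive d from the true length
    d = int(x.size) - a - b - c
    return ConfusionCounts(a, b, c, d)


def _as_bits(fp) -> np.ndarray:
    if isinstance(fp, InteractionFingerprint):
        return fp.bits
    arr = np.asarray(fp)
    if arr.ndim != 1:
        raise ValueError("fingerprint must be a 1-D vector")
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("fingerprint bits must be 0 or 1")
    return arr.astype(np.uint8)


def resolve_measures(measures=None) -> list[SimilarityMeasure]:
    """Normalize a measure spec (None/'all', names, or objects) to a list."""
    if measures is None or measures == "all":
        return list_measures()
    out = []
    for m in measures:
        out.append(m if isinstance(m, SimilarityMeasure) else get_measure(m))
    return out


def similarity_matrix(
    dataset: FingerprintDataset,
    reference: InteractionFingerprint,
    measures: Iterable | None = None,
) -> pd.DataFrame:
    """Scaled similarity of every dataset ligand to the reference.

    Returns a frame with columns ``ligand_id``, ``active`` and one column
    per measure abbreviation, values in [0, 1]. The query fingerprint plays
    the role of "Complex 1" (counts b) and the reference of "Complex 2"
    (counts c), which matters for the directional coefficients.
    """
    measures = resolve_measures(measures)
    n_bits = len(dataset.layout)
    if len(reference) != n_bits:
        raise ValueError(
            f"reference has {len(reference)} bits, dataset layout {n_bits}"
        )
    if n_bits == 0:
        raise ValueError("dataset has no columns")
    bits = dataset.bit_matrix.astype(np.int64)
    ref = reference.bits.astype(np.int64)
    a = bits @ ref
    b = bits.sum(axis=1) - a
    c = int(ref.sum()) - a
    data: dict[str, object] = {
        "ligand_id": dataset.ligand_ids,
        "active": dataset.activities.astype(int),
    }
    tables = [
        ConfusionCounts(int(ai), int(bi), int(ci), n_bits - int(ai + bi + ci))
        for ai, bi, ci in zip(a, b, c)
    ]
    for m in measures:
        data[m.abbrev] = [
            scale_similarity(raw_similarity(m, t), m, t.p) for t in tables
        ]
    return pd.DataFrame(data)


def measure_columns(frame: pd.DataFrame) -> list[str]:
    """Measure columns of a similarity-matrix frame."""
    return [c for c in frame.columns if c not in ID_COLUMNS]


def write_similarity_matrix(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format="%.6f")


def read_similarity_matrix(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ID_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"similarity matrix lacks columns {missing}")
    return frame
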
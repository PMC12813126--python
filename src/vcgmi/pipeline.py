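"""End-to-end helpers tying the stages together.

One record flows through: baseline removal -> R-peak detection on the
spatial magnitude -> QRS/T loop segmentation -> per-beat features ->
record-level aggregation. Cohort-level helpers map this over record lists
and produce the canonical feature table.
"""

from __future__ import annotations

import logging

import pandas as pd

from .delineate import (DEFAULT_DELINEATION, DelineationConfig,
                        detect_r_peaks, segment_beats, spatial_magnitude)
from .features import DegenerateLoopError, beat_features, record_features
from .io import FEATURE_NAMES, VCGRecord
from .preprocess import FilterSpec, remove_baseline

__all__ = ["extract_record_features", "extract_cohort"]

log = logging.getLogger(__name__)


def extract_record_features(
    record: VCGRecord,
    filter_spec: FilterSpec | None = None,
    delineation: DelineationConfig = DEFAULT_DELINEATION,
    aggregate: str = "median",
    detrend: bool = True,
) -> dict[str, float] | None:
    """The 12-feature vector of one record, or None if no beat survives."""
    if detrend:
        spec = filter_spec or FilterSpec(fs=record.fs)
        record, _ = remove_baseline(record, spec)
    magnitude = spatial_magnitude(record)
    r_peaks = detect_r_peaks(magnitude, record.fs, delineation)
    beats = segment_beats(record, r_peaks, delineation)
    vectors = []
    for beat in beats:
        try:
            vectors.append(beat_features(beat, record.fs))
        except DegenerateLoopError:
            log.info("record %s: skipped degenerate beat at %d",
                     record.record_id, beat.r_index)
    if not vectors:
        log.warning("record %s: no usable beats", record.record_id)
        return None
    return record_features(vectors, aggregate=aggregate)


def extract_cohort(records: list[VCGRecord], **kwargs) -> pd.DataFrame:
    """Feature table (record_id, label, 12 features) for a record list."""
    rows = []
    for rec in records:
        feats = extract_record_features(rec, **kwargs)
        if feats is None:
            continue
        rows.append({"record_id": rec.record_id, "label": rec.label, **feats})
    return pd.DataFrame(rows, columns=["record_id", "label", *FEATURE_NAMES])
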
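"""Shared containers for annotated micro-expression sequence collections."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .descriptors import FrameSequence
from .geometry import LandmarkSet

ANNOTATION_COLUMNS = ["subject_id", "sequence_id", "onset", "apex", "offset", "label"]


@dataclass
class SequenceRecord:
    """One sequence: identity, frames, landmarks and its ground-truth rows."""

    subject_id: str
    sequence_id: str
    frames: FrameSequence
    landmarks: LandmarkSet
    annotations: pd.DataFrame


@dataclass
class Dataset:
    """A collection of sequences with a pooled annotation table."""

    sequences: list[SequenceRecord]

    @property
    def annotations(self) -> pd.DataFrame:
        frames = [s.annotations for s in self.sequences if len(s.annotations)]
        if not frames:
            return pd.DataFrame(columns=ANNOTATION_COLUMNS)
        return pd.concat(frames, ignore_index=True)

    @property
    def subjects(self) -> list[str]:
        return sorted({s.subject_id for s in self.sequences})

    def by_subject(self, subject_id: str) -> list[SequenceRecord]:
        return [s for s in self.sequences if s.subject_id == subject_id]

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)
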
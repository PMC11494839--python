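"""Core data containers shared across the pipeline stages."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

SDH = "SDH"
EDH = "EDH"
LABELS = (SDH, EDH)


@dataclass
class SampleRecord:
    """One head-CT-like slice: grayscale image, binary lesion mask, class label.

    ``synthetic`` distinguishes SMOTE-generated (or phantom) samples from
    real ones; ``split`` tags train/test membership once assigned.
    """

    image: np.ndarray
    mask: np.ndarray | None
    label: str
    id: str = ""
    synthetic: bool = False
    split: str = ""

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown class label {self.label!r}; expected one of {LABELS}")
        if self.mask is not None and self.mask.shape != self.image.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} differs from image shape {self.image.shape}")


@dataclass
class DatasetManifest:
    """An ordered collection of records with class counts and a split tag."""

    records: list[SampleRecord] = field(default_factory=list)
    split_tag: str = "unsplit"

    @property
    def counts_by_class(self) -> dict:
        return dict(Counter(r.label for r in self.records))

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, indices, split_tag=None):
        return DatasetManifest([self.records[i] for i in indices],
                               split_tag=split_tag or self.split_tag)

    def validate(self):
        for r in self.records:
            if r.mask is not None and r.mask.shape != r.image.shape:
                raise ValueError(f"record {r.id}: image/mask dimension mismatch")
        assert sum(self.counts_by_class.values()) == len(self.records)
        return self
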
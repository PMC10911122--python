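"""Subject-level containers: pixel samples and cohorts.

A :class:`PixelSample` is the multiset of ROI pixel intensities for one
subject — the atom every statistic in this package is computed from. A
:class:`SubjectCohort` pairs each subject's sample with a group label
(e.g. ``sham`` / ``surgery``) and a table of per-subject output variables
("markers", e.g. densitometric protein expression), which is the input to
echointensity banding and to the intensity-range correlation search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EchorangeError

__all__ = ["PixelSample", "Subject", "SubjectCohort"]


@dataclass(frozen=True)
class PixelSample:
    """Intensities of all ROI pixels for one subject.

    Parameters
    ----------
    subject_id:
        Unique identifier of the subject.
    values:
        1-D integer array of pixel intensities, each in ``[0, L]``.
    L:
        Intensity ceiling (255 for 8-bit images).
    """

    subject_id: str
    values: np.ndarray
    L: int = 255

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 1 or vals.size == 0:
            raise EchorangeError(
                f"pixel sample for {self.subject_id!r} must be a nonempty 1-D array"
            )
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(vals == np.round(vals)):
                raise EchorangeError("pixel intensities must be integers")
            vals = vals.astype(np.int64)
        if vals.min() < 0 or vals.max() > self.L:
            raise EchorangeError(
                f"pixel intensities must lie in [0, {self.L}]"
            )
        object.__setattr__(self, "values", np.asarray(vals, dtype=np.int64))

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class Subject:
    """One cohort member: pixel sample, group label and marker values."""

    subject_id: str
    group: str
    sample: PixelSample
    outputs: dict[str, float] = field(default_factory=dict)


class SubjectCohort:
    """Ordered collection of subjects with unique ids.

    Parameters
    ----------
    subjects:
        Iterable of :class:`Subject`. At least one; ids must be unique and
        every subject must carry a nonempty pixel sample.
    """

    def __init__(self, subjects) -> None:
        self.subjects: list[Subject] = list(subjects)
        if not self.subjects:
            raise EchorangeError("cohort must contain at least one subject")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise EchorangeError("subject ids must be unique")
        Ls = {s.sample.L for s in self.subjects}
        if len(Ls) != 1:
            raise EchorangeError("all pixel samples must share one intensity ceiling")
        self.L: int = Ls.pop()

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.subjects]

    @property
    def marker_names(self) -> list[str]:
        names: list[str] = []
        for s in self.subjects:
            for k in s.outputs:
                if k not in names:
                    names.append(k)
        return names

    def marker_values(self, marker: str) -> np.ndarray:
        """Per-subject values of one output variable, NaN where missing."""
        return np.array(
            [float(s.outputs.get(marker, np.nan)) for s in self.subjects]
        )

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.subjects) if s.group == group])

    def outputs_frame(self) -> pd.DataFrame:
        """Markers as a subjects x markers DataFrame (index = subject_id)."""
        rows = {s.subject_id: dict(s.outputs) for s in self.subjects}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.insert(0, "group", [s.group for s in self.subjects])
        df.index.name = "subject_id"
        return df

    @classmethod
    def from_samples(cls, samples, groups, outputs) -> "SubjectCohort":
        """Assemble a cohort from parallel per-subject pieces.

        ``samples`` is a list of PixelSample, ``groups`` a list of labels,
        ``outputs`` a list of marker dicts, all in subject order.
        """
        return cls(
            Subject(s.subject_id, g, s, dict(o))
            for s, g, o in zip(samples, groups, outputs, strict=True)
        )
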
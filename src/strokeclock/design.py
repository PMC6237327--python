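"""Study design: animals x timepoints sampling layout.

The default layout mirrors a repeated-measures rodent stroke time course:
8 animals bled at 0, 1, 2, 3, 6 and 24 hours after vessel occlusion, with
a single missing draw (animal 3 at 6 h), i.e. 47 samples in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import UserInputError

DEFAULT_TIMEPOINTS_H: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 6.0, 24.0)
DEFAULT_MISSING: tuple[tuple[int, float], ...] = ((3, 6.0),)


def format_time(t: float) -> str:
    """Render an hour value compactly ('6' not '6.0', '0.5' kept)."""
    return f"{t:g}"


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout of the time-course experiment.

    Parameters
    ----------
    n_animals
        Number of animals, each sampled at every timepoint unless listed
        in ``missing``.
    timepoints_h
        Strictly increasing sampling times in hours since occlusion.
    missing
        (animal, time_h) pairs that were not collected.
    batches
        Optional mapping sample_id -> batch label. Unlisted samples get
        batch "1".
    """

    n_animals: int = 8
    timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS_H
    missing: tuple[tuple[int, float], ...] = DEFAULT_MISSING
    batches: Mapping[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise UserInputError("n_animals must be >= 1")
        tps = tuple(float(t) for t in self.timepoints_h)
        if len(tps) < 1 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise UserInputError("timepoints_h must be strictly increasing")
        object.__setattr__(self, "timepoints_h", tps)
        miss = tuple((int(a), float(t)) for a, t in self.missing)
        for animal, t in miss:
            if not (1 <= animal <= self.n_animals):
                raise UserInputError(f"missing pair references unknown animal {animal}")
            if t not in tps:
                raise UserInputError(f"missing pair references unknown timepoint {t}")
        if len(set(miss)) != len(miss):
            raise UserInputError("duplicate entries in missing list")
        object.__setattr__(self, "missing", miss)

    @property
    def n_samples(self) -> int:
        return self.n_animals * len(self.timepoints_h) - len(self.missing)

    def sample_id(self, animal: int, time_h: float) -> str:
        return f"r{animal}_t{format_time(time_h)}"

    def sample_sheet(self) -> pd.DataFrame:
        """Per-sample manifest: sample_id, animal, time_h, batch."""
        missing = set(self.missing)
        rows = []
        for animal in range(1, self.n_animals + 1):
            for t in self.timepoints_h:
                if (animal, t) in missing:
                    continue
                sid = self.sample_id(animal, t)
                batch = "1"
                if self.batches is not None:
                    batch = str(self.batches.get(sid, "1"))
                rows.append((sid, animal, t, batch))
        return pd.DataFrame(rows, columns=["sample_id", "animal", "time_h", "batch"])


DEFAULT_DESIGN = StudyDesign()
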
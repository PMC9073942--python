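"""Collective-variable trajectories: the common currency of all stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class CVTrajectory:
    """Time-ordered samples of the collective variables for one replica.

    ``points`` has shape (n_frames, n_cv); times are strictly increasing.
    ``extras`` holds any additional named per-frame columns (preserved on
    COLVAR round-trips).
    """

    times: np.ndarray
    points: np.ndarray
    replica_id: str = "0"
    cv_names: tuple = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
        self.points = pts
        if self.times.ndim != 1 or len(self.times) != len(self.points):
            raise ValidationError("CVTrajectory: times and points lengths differ")
        if len(self.times) == 0:
            raise ValidationError("CVTrajectory: empty trajectory")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("CVTrajectory: times must be strictly increasing")
        if self.cv_names is None:
            self.cv_names = tuple(f"cv{i + 1}" for i in range(self.ndim))
        self.cv_names = tuple(self.cv_names)
        if len(self.cv_names) != self.ndim:
            raise ValidationError("CVTrajectory: cv_names length mismatch")
        for key, col in self.extras.items():
            col = np.asarray(col)
            if len(col) != len(self.times):
                raise ValidationError(f"CVTrajectory: extra column {key!r} length mismatch")
            self.extras[key] = col

    @property
    def ndim(self) -> int:
        return self.points.shape[1]

    def __len__(self) -> int:
        return len(self.times)

    def subsample(self, step: int) -> "CVTrajectory":
        return CVTrajectory(
            self.times[::step],
            self.points[::step],
            replica_id=self.replica_id,
            cv_names=self.cv_names,
            extras={k: v[::step] for k, v in self.extras.items()},
        )
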
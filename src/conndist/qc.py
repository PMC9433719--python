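"""Head-motion quality control: framewise displacement, exclusion, scrubbing.

Framewise displacement (FD) follows Power's convention: the sum of absolute
backward differences of the six rigid-body realignment parameters, with the
three rotations converted to arc length on a 50 mm sphere.  Subjects whose
mean FD exceeds 0.25 mm are excluded; in retained subjects, volumes with
FD > 0.50 mm are flagged for scrubbing (only the flagged volume itself, no
neighbor augmentation, unless configured otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEAD_RADIUS_MM = 50.0
MEAN_FD_EXCLUDE_MM = 0.25
SCRUB_FD_MM = 0.50


@dataclass(frozen=True)
class MotionTrace:
    """Rigid-body motion parameters for one subject.

    ``params`` is timepoints x 6: three translations (mm) then three
    rotations (radians unless ``rotations_in_degrees``).
    """

    subject_id: str
    params: np.ndarray = field(repr=False)
    rotations_in_degrees: bool = False

    def __post_init__(self):
        p = np.asarray(self.params, dtype=float)
        if p.ndim != 2 or p.shape[1] != 6:
            raise ValueError("motion parameters must be timepoints x 6")
        if p.shape[0] < 2:
            raise ValueError("need at least 2 timepoints to difference")
        if not np.all(np.isfinite(p)):
            raise ValueError(f"subject {self.subject_id}: non-finite motion parameters")
        object.__setattr__(self, "params", p)


@dataclass(frozen=True)
class QCReport:
    """Per-subject motion QC outcome."""

    subject_id: str
    mean_fd: float
    excluded: bool
    scrub_mask: np.ndarray = field(repr=False)  # True = volume flagged for removal

    @property
    def n_scrubbed(self) -> int:
        return int(np.sum(self.scrub_mask))

    @property
    def keep_mask(self) -> np.ndarray:
        """Retention mask usable directly by connectome construction."""
        return ~np.asarray(self.scrub_mask)


def framewise_displacement(trace: MotionTrace) -> np.ndarray:
    """Power's framewise displacement series in mm; ``fd[0] = 0``.

    ``fd[t] = sum |d translation| + 50 mm * sum |d rotation|``; depends only
    on parameter differences, so constant offsets do not contribute.
    """
    p = trace.params.copy()
    if trace.rotations_in_degrees:
        p[:, 3:] = np.deg2rad(p[:, 3:])
    d = np.abs(np.diff(p, axis=0))
    fd = d[:, :3].sum(axis=1) + HEAD_RADIUS_MM * d[:, 3:].sum(axis=1)
    return np.concatenate(([0.0], fd))


def apply_qc(
    traces,
    mean_fd_exclude: float = MEAN_FD_EXCLUDE_MM,
    scrub_fd: float = SCRUB_FD_MM,
    scrub_neighbors: int = 0,
) -> list:
    """QC a cohort of motion traces.

    A subject is excluded when mean FD > ``mean_fd_exclude`` (0.25 mm).  In
    retained subjects, volumes with FD > ``scrub_fd`` (0.50 mm) are flagged;
    ``scrub_neighbors`` optionally extends each flag to that many volumes on
    either side (default 0: only the flagged volume).
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no motion traces supplied")
    reports = []
    for trace in traces:
        fd = framewise_displacement(trace)
        mean_fd = float(fd.mean())
        excluded = mean_fd > mean_fd_exclude
        mask = np.zeros(fd.size, dtype=bool)
        if not excluded:
            mask = fd > scrub_fd
            if scrub_neighbors > 0 and mask.any():
                hits = np.flatnonzero(mask)
                for h in hits:
                    lo = max(0, h - scrub_neighbors)
                    mask[lo : h + scrub_neighbors + 1] = True
        reports.append(
            QCReport(
                subject_id=trace.subject_id,
                mean_fd=mean_fd,
                excluded=excluded,
                scrub_mask=mask,
            )
        )
    return reports


def retained_sample_size(n_responders: int, n_bogus_failures: int, n_motion_excluded: int) -> int:
    """Sample accounting: responders minus attention-check failures minus
    motion exclusions."""
    if min(n_responders, n_bogus_failures, n_motion_excluded) < 0:
        raise ValueError("counts must be nonnegative")
    retained = n_responders - n_bogus_failures - n_motion_excluded
    if retained < 0:
        raise ValueError("exclusions exceed responders")
    return retained


def read_motion_file(path, subject_id: str = "", rotations_in_degrees: bool = False) -> MotionTrace:
    """Read a 6-column realignment-parameter text file (whitespace or comma
    delimited, one row per volume)."""
    arr = pd.read_csv(path, sep=None, engine="python", header=None).to_numpy(dtype=float)
    return MotionTrace(
        subject_id=subject_id or str(path),
        params=arr,
        rotations_in_degrees=rotations_in_degrees,
    )


def qc_frame(reports) -> pd.DataFrame:
    """Tabulate QC reports (one row per subject)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in reports],
            "mean_fd": [r.mean_fd for r in reports],
            "excluded": [r.excluded for r in reports],
            "n_scrubbed": [r.n_scrubbed for r in reports],
        }
    )
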
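"""Psychometric instrument scoring and composite distress measures.

Instruments: the 21-item Depression Anxiety Stress Scale (DASS-21, items
0-3), the 22-item Impact of Event Scale-Revised (IES-R, items 0-4) and the
20-item PTSD Checklist for DSM-5 (PCL-5, items 0-4).  Totals are raw item
sums; the DASS-21 total is NOT doubled to the DASS-42 scale, since only
differences and correlations of totals are analyzed and those are invariant
to rescaling.

Composites: general distress at each wave is the DASS-21 total;
``delta_distress = distress_t1 - distress_t3`` (pre minus during, so a
*negative* delta means distress increased); the pandemic posttraumatic
stress composite (CPTS) is the IES-R total plus the PCL-5 total.  A
one-factor check (Kaiser rule on the subscale correlation matrix) verifies
that a single component dominates before totals are used as composites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: instrument -> (item count, max item score)
INSTRUMENTS = {
    "DASS21": (21, 3),
    "IESR": (22, 4),
    "PCL5": (20, 4),
}


@dataclass(frozen=True)
class ScaleResponse:
    """One subject's item-level responses to one instrument."""

    subject_id: str
    instrument: str
    item_scores: tuple

    def __post_init__(self):
        object.__setattr__(self, "item_scores", tuple(int(v) for v in self.item_scores))
        if self.instrument not in INSTRUMENTS:
            raise ValueError(
                f"unknown instrument {self.instrument!r}; "
                f"expected one of {sorted(INSTRUMENTS)}"
            )
        n_items, max_score = INSTRUMENTS[self.instrument]
        if len(self.item_scores) != n_items:
            raise ValueError(
                f"{self.instrument} requires {n_items} items, "
                f"got {len(self.item_scores)} (missing items are an error)"
            )
        bad = [v for v in self.item_scores if not 0 <= v <= max_score]
        if bad:
            raise ValueError(
                f"{self.instrument} item scores must be in 0..{max_score}, got {bad}"
            )


@dataclass(frozen=True)
class CompositeScores:
    """Per-subject composite scores used by the downstream analysis."""

    subject_id: str
    distress_t1: float
    distress_t3: float
    delta_distress: float
    cpts: float

    def __post_init__(self):
        if self.delta_distress != self.distress_t1 - self.distress_t3:
            raise ValueError("delta_distress must equal distress_t1 - distress_t3")
        if self.cpts < 0:
            raise ValueError("cpts must be nonnegative")


def score_instrument(resp: ScaleResponse) -> int:
    """Total score of an instrument: the raw sum of its item scores."""
    return sum(resp.item_scores)


def one_factor_check(subscale_matrix: np.ndarray) -> tuple:
    """Check the one-factor structure of a subjects x subscales score matrix.

    Eigen-decomposes the subscale *correlation* matrix.  Returns
    ``(eigenvalues, pc1_variance_fraction, is_one_factor)`` where
    eigenvalues are sorted descending (they sum to the subscale count) and
    ``is_one_factor`` applies the Kaiser rule: only the first eigenvalue
    exceeds 1.
    """
    X = np.asarray(subscale_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a subjects x subscales matrix with >= 2 subscales")
    if X.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    sd = X.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            f"constant subscale column(s) {constant.tolist()}: correlation undefined"
        )
    corr = np.corrcoef(X, rowvar=False)
    eigenvalues = np.linalg.eigvalsh(corr)[::-1]
    eigenvalues = np.clip(eigenvalues, 0.0, None)  # guard tiny negatives
    pc1_fraction = float(eigenvalues[0] / eigenvalues.sum())
    is_one_factor = bool(eigenvalues[0] > 1.0 and np.all(eigenvalues[1:] <= 1.0))
    return eigenvalues, pc1_fraction, is_one_factor


def composite_scores(responses) -> CompositeScores:
    """Composite scores for one subject from their four instrument responses.

    Parameters
    ----------
    responses : mapping
        Keys ``"dass21_t1"``, ``"dass21_t3"``, ``"iesr"``, ``"pcl5"``, each a
        :class:`ScaleResponse`.  All four are required; a missing instrument
        is an error naming the subject and the instrument.
    """
    required = {"dass21_t1": "DASS21", "dass21_t3": "DASS21", "iesr": "IESR", "pcl5": "PCL5"}
    subject_ids = {r.subject_id for r in responses.values()}
    for key, instrument in required.items():
        if key not in responses:
            sid = next(iter(subject_ids), "?")
            raise ValueError(f"subject {sid}: missing instrument {key} ({instrument})")
        if responses[key].instrument != instrument:
            raise ValueError(
                f"response under key {key!r} is {responses[key].instrument}, "
                f"expected {instrument}"
            )
    if len(subject_ids) != 1:
        raise ValueError(f"responses mix subjects: {sorted(subject_ids)}")
    sid = subject_ids.pop()
    t1 = score_instrument(responses["dass21_t1"])
    t3 = score_instrument(responses["dass21_t3"])
    cpts = score_instrument(responses["iesr"]) + score_instrument(responses["pcl5"])
    return CompositeScores(
        subject_id=sid,
        distress_t1=t1,
        distress_t3=t3,
        delta_distress=t1 - t3,
        cpts=cpts,
    )
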
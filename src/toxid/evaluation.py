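"""Ground-truth validation of identity assignments.

The protocol counts *error propagation*: the first-starting fragment of each
identity label defines that label's reference animal, and every later
fragment given the same label is correct only if it truly belongs to the
reference animal.  An identity swap therefore poisons every subsequent
fragment of the two identities involved, which is the strict way to score a
tracker whose whole purpose is to keep identities over time.

Metrics:

* ``CFR`` — correct fragment rate, ``CF / (CF + IF + NF)`` over fragment
  counts;
* ``CSR`` — correct sample rate, same ratio over sample counts;
* ``IER`` — identity errors per animal per minute,
  ``IF / (minutes x animals)``, where IF here excludes fragments shorter
  than one second.

Fragments with fewer than ``min_samples`` samples (default 25) are discarded
from all counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fragment_tracking import Fragment
from .fragment_assignment import IdentityAssignment, UNASSIGNED


@dataclass
class GroundTruth:
    """True per-frame animal centres.

    ``centers[frame]`` is an ``(m, 2)`` array of (x, y) positions and
    ``ids[frame]`` the matching animal identities in ``1..n_animals``.
    Detections are matched to the nearest centre within ``match_radius``.
    """

    centers: dict[int, np.ndarray]
    ids: dict[int, np.ndarray]
    n_animals: int
    fps: float
    duration_minutes: float

    def label_for(self, frame: int, cm: tuple[float, float], radius: float) -> int | None:
        if frame not in self.centers:
            return None
        pts = self.centers[frame]
        d = np.hypot(pts[:, 0] - cm[0], pts[:, 1] - cm[1])
        k = int(d.argmin())
        return int(self.ids[frame][k]) if d[k] <= radius else None


def true_animal(fragment: Fragment, truth: GroundTruth, match_radius: float) -> int:
    """Majority ground-truth animal over a fragment's samples.

    Raises if any detection cannot be matched to a true centre.
    """
    votes: dict[int, int] = {}
    for det in fragment.detections:
        lab = truth.label_for(det.frame, det.cm, match_radius)
        if lab is None:
            raise ValueError(
                f"fragment {fragment.id}: unlabeled detection at frame {det.frame}"
            )
        votes[lab] = votes.get(lab, 0) + 1
    return max(sorted(votes), key=lambda k: votes[k])


@dataclass
class FragmentClassification:
    """CF/IF/NF partition of the retained fragments."""

    cf: list[Fragment] = field(default_factory=list)
    if_: list[Fragment] = field(default_factory=list)
    nf: list[Fragment] = field(default_factory=list)
    if_for_ier: list[Fragment] = field(default_factory=list)


def classify_fragments(
    assignment: IdentityAssignment,
    fragments: Sequence[Fragment],
    truth: GroundTruth,
    min_samples: int = 25,
    min_ier_seconds: float = 1.0,
    match_radius: float = 30.0,
) -> FragmentClassification:
    """Partition fragments into correct / incorrect / not assigned.

    For each identity label, the reference animal is the true animal of the
    first-starting fragment carrying that label.  A later fragment with the
    same label is CF iff its own true animal equals the reference (so one
    early swap propagates as IF through the rest of the video).  Unassigned
    fragments are NF.  Fragments below ``min_samples`` vanish from every
    count; IF fragments spanning less than ``min_ier_seconds`` are kept out
    of the IF count used for the identity error rate.
    """
    retained = [f for f in fragments if f.n_samples >= min_samples]
    truths = {f.id: true_animal(f, truth, match_radius) for f in retained}

    reference: dict[int, int] = {}
    for f in sorted(retained, key=lambda f: (f.start_frame, f.id)):
        lab = assignment.labels.get(f.id, UNASSIGNED)
        if lab != UNASSIGNED and lab not in reference:
            reference[lab] = truths[f.id]

    out = FragmentClassification()
    for f in retained:
        lab = assignment.labels.get(f.id, UNASSIGNED)
        if lab == UNASSIGNED:
            out.nf.append(f)
        elif truths[f.id] == reference[lab]:
            out.cf.append(f)
        else:
            out.if_.append(f)
            duration_s = (f.end_frame - f.start_frame + 1) / truth.fps
            if duration_s >= min_ier_seconds:
                out.if_for_ier.append(f)
    return out


@dataclass
class MetricsReport:
    CF: int
    IF: int
    NF: int
    samples_CF: int
    samples_IF: int
    samples_NF: int
    CSR: float
    CFR: float
    IER: float

    def to_dict(self) -> dict:
        return {
            "CF": self.CF, "IF": self.IF, "NF": self.NF,
            "samples_CF": self.samples_CF, "samples_IF": self.samples_IF,
            "samples_NF": self.samples_NF,
            "CSR": self.CSR, "CFR": self.CFR, "IER": self.IER,
        }


def _counts(group) -> tuple[int, int]:
    """(n_fragments, n_samples) from a fragment list or a (count, samples) pair."""
    if isinstance(group, tuple):
        return int(group[0]), int(group[1])
    return len(group), sum(f.n_samples for f in group)


def compute_metrics(
    cf,
    if_,
    nf,
    duration_minutes: float,
    n_animals: int,
    if_for_ier=None,
) -> MetricsReport:
    """Assemble CSR / CFR / IER from a CF/IF/NF partition.

    ``cf``/``if_``/``nf`` are fragment lists or ``(n_fragments, n_samples)``
    pairs.  ``if_for_ier`` (same forms; a bare count is also accepted)
    defaults to ``if_``.
    """
    if duration_minutes <= 0:
        raise ValueError("duration_minutes must be positive")
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    n_cf, s_cf = _counts(cf)
    n_if, s_if = _counts(if_)
    n_nf, s_nf = _counts(nf)
    if if_for_ier is None:
        n_if_ier = n_if
    elif isinstance(if_for_ier, int):
        n_if_ier = if_for_ier
    else:
        n_if_ier = _counts(if_for_ier)[0]
    total_frag = n_cf + n_if + n_nf
    total_samp = s_cf + s_if + s_nf
    if total_frag == 0 or total_samp == 0:
        raise ValueError("no retained fragments: CFR/CSR denominators are empty")
    return MetricsReport(
        CF=n_cf, IF=n_if, NF=n_nf,
        samples_CF=s_cf, samples_IF=s_if, samples_NF=s_nf,
        CSR=s_cf / total_samp,
        CFR=n_cf / total_frag,
        IER=n_if_ier / (duration_minutes * n_animals),
    )


def evaluate(
    assignment: IdentityAssignment,
    fragments: Sequence[Fragment],
    truth: GroundTruth,
    min_samples: int = 25,
    min_ier_seconds: float = 1.0,
    match_radius: float = 30.0,
) -> MetricsReport:
    """Classify fragments against ground truth and compute all metrics."""
    cls = classify_fragments(
        assignment, fragments, truth, min_samples, min_ier_seconds, match_radius
    )
    return compute_metrics(
        cls.cf, cls.if_, cls.nf,
        duration_minutes=truth.duration_minutes,
        n_animals=truth.n_animals,
        if_for_ier=cls.if_for_ier,
    )
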
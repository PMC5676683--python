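"""Fusing trajectory fragments into per-animal identities.

The assignment works on the identity-likelihood matrix in three stages:

1. fragments are split into *long* and *short* by a sample-count limit
   (default 50; fragments below a minimum of 25 samples are discarded);
2. *complete groups* — sets of exactly ``n_animals`` long fragments that are
   all simultaneously alive at some frame — are labelled first.  The first
   group anchors the identity labels (1..n by start frame); each later group
   is matched to the already-labelled set with the Hungarian algorithm,
   maximising the summed identity likelihoods;
3. remaining fragments are attached greedily, best likelihood first (long
   pool before short pool), until the best remaining value drops below
   ``min_correlation``.  Every new label propagates: entries that would now
   violate the one-animal-one-place constraint, or tie the fragment to a
   different identity, are zeroed.

Fragments never receive a label that would make two coexisting fragments
share an identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fragment_tracking import Fragment, solve_assignment
from .identity_similarity import IdMatrix, SimilarityConfig, build_id_matrix, coexist

logger = logging.getLogger(__name__)

#: label used for fragments that could not be assigned to any animal
UNASSIGNED = 0


@dataclass
class AssignmentConfig:
    """Thresholds of the fragment-fusion stage (all user-selectable)."""

    long_limit: int = 50
    min_correlation: float = 0.5
    min_fragment_samples: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.min_fragment_samples < self.long_limit:
            raise ValueError("need long_limit > min_fragment_samples > 0")
        if not 0 <= self.min_correlation <= 1:
            raise ValueError("min_correlation must lie in [0, 1]")


@dataclass
class IdentityAssignment:
    """Mapping fragment id -> animal identity (1..n_animals, or UNASSIGNED)."""

    labels: dict[int, int] = field(default_factory=dict)
    n_animals: int = 1

    @property
    def assigned(self) -> dict[int, int]:
        return {k: v for k, v in self.labels.items() if v != UNASSIGNED}

    @property
    def unassigned_ids(self) -> list[int]:
        return sorted(k for k, v in self.labels.items() if v == UNASSIGNED)

    def check_consistency(self, fragments: list[Fragment]) -> None:
        """Raise if two coexisting fragments share an identity label."""
        by_id = {f.id: f for f in fragments}
        per_label: dict[int, list[Fragment]] = {}
        for fid, lab in self.assigned.items():
            per_label.setdefault(lab, []).append(by_id[fid])
        for lab, frags in per_label.items():
            for i in range(len(frags)):
                for j in range(i + 1, len(frags)):
                    if coexist(frags[i], frags[j]):
                        raise AssertionError(
                            f"identity {lab} assigned to coexisting fragments "
                            f"{frags[i].id} and {frags[j].id}"
                        )


def split_long_short(
    fragments: list[Fragment],
    long_limit: int,
    min_fragment_samples: int = 25,
) -> tuple[list[Fragment], list[Fragment], list[Fragment]]:
    """Partition fragments into (long, short, discarded) by sample count."""
    if long_limit <= 0:
        raise ValueError("long_limit must be positive")
    long_f = [f for f in fragments if f.n_samples >= long_limit]
    short_f = [
        f for f in fragments if min_fragment_samples <= f.n_samples < long_limit
    ]
    discarded = [f for f in fragments if f.n_samples < min_fragment_samples]
    return long_f, short_f, discarded


def find_complete_groups(
    long_fragments: list[Fragment], n_animals: int
) -> list[list[int]]:
    """Sets of exactly ``n_animals`` long fragments simultaneously alive.

    A sweep over the frames where the alive set can change (fragment starts
    and the frames just after fragment ends) collects every distinct alive
    set of size ``n_animals``.  Groups are ordered by the first frame at
    which they are complete; each group lists fragment ids sorted by start
    frame.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if not long_fragments:
        return []
    events = sorted(
        {f.start_frame for f in long_fragments}
        | {f.end_frame + 1 for f in long_fragments}
    )
    seen: set[frozenset[int]] = set()
    groups: list[list[int]] = []
    by_start = {f.id: f.start_frame for f in long_fragments}
    for frame in events:
        alive = [f for f in long_fragments if f.start_frame <= frame <= f.end_frame]
        if len(alive) != n_animals:
            continue
        key = frozenset(f.id for f in alive)
        if key in seen:
            continue
        seen.add(key)
        groups.append(sorted(key, key=lambda fid: (by_start[fid], fid)))
    return groups


def assign_groups(
    groups: list[list[int]],
    id_matrix: IdMatrix,
    n_animals: int,
    fragments: list[Fragment],
) -> IdentityAssignment:
    """Label the complete groups; the first group anchors identities 1..n.

    Each later group is matched against the set already labelled by
    maximising the summed identity likelihood (Hungarian on ``1 - score``);
    cells that would violate coexistence are forbidden, and fragments whose
    every admissible score is zero stay unassigned.
    """
    if not groups:
        raise ValueError("need at least one complete group")
    by_id = {f.id: f for f in fragments}
    assignment = IdentityAssignment(n_animals=n_animals)
    for identity, fid in enumerate(groups[0], start=1):
        assignment.labels[fid] = identity

    for group in groups[1:]:
        pending = [fid for fid in group if fid not in assignment.labels]
        if not pending:
            continue
        used = {assignment.labels[fid] for fid in group if fid in assignment.labels}
        identities = [k for k in range(1, n_animals + 1) if k not in used]
        score = np.zeros((len(pending), len(identities)))
        for r, fid in enumerate(pending):
            row = id_matrix.values[id_matrix.index_of(fid)]
            for c, k in enumerate(identities):
                members = [g for g, lab in assignment.assigned.items() if lab == k]
                if any(coexist(by_id[fid], by_id[m]) for m in members):
                    continue  # forbidden, score stays 0
                if members:
                    score[r, c] = max(row[id_matrix.index_of(m)] for m in members)
        for r, c in solve_assignment(1.0 - score):
            if score[r, c] > 0.0:
                assignment.labels[pending[r]] = identities[c]
    return assignment


def greedy_assign(
    id_matrix: IdMatrix,
    partial: IdentityAssignment,
    long: list[Fragment],
    short: list[Fragment],
    min_correlation: float,
) -> IdentityAssignment:
    """Attach remaining fragments one by one, best identity likelihood first.

    The long pool is exhausted before the short pool is considered.  Ties on
    the likelihood break by earlier start frame, then lower fragment id.
    After each new label the matrix is updated so that entries now
    incompatible with the label (coexistence with the labelled identity, or
    links to other identities) are zeroed — the knowledge-propagation step.
    """
    by_id = {f.id: f for f in long + short}
    W = id_matrix.values.copy()
    np.fill_diagonal(W, 0.0)
    assignment = IdentityAssignment(labels=dict(partial.labels), n_animals=partial.n_animals)
    labeled = set(assignment.assigned)

    def members_of(k: int) -> list[int]:
        return [g for g, lab in assignment.assigned.items() if lab == k]

    for pool_frags in (long, short):
        pool = {f.id for f in pool_frags} - labeled
        while pool and labeled:
            best_val, best = -1.0, None
            for u in pool:
                iu = id_matrix.index_of(u)
                for f in labeled:
                    v = W[iu, id_matrix.index_of(f)]
                    if v > best_val + 1e-12:
                        best_val, best = v, (u, f)
                    elif best is not None and abs(v - best_val) <= 1e-12:
                        cand, cur = by_id[u], by_id[best[0]]
                        if (cand.start_frame, cand.id) < (cur.start_frame, cur.id):
                            best = (u, f)
            if best is None or best_val < min_correlation or best_val <= 0.0:
                break
            u, f = best
            k = assignment.labels[f]
            iu = id_matrix.index_of(u)
            if any(coexist(by_id[u], by_id[m]) for m in members_of(k)):
                # stale entry: the label is no longer admissible for u
                for m in members_of(k):
                    im = id_matrix.index_of(m)
                    W[iu, im] = W[im, iu] = 0.0
                continue
            assignment.labels[u] = k
            labeled.add(u)
            pool.discard(u)
            # propagation (a): u cannot link fragments that coexist with identity k
            for x in by_id.values():
                if x.id == u:
                    continue
                if any(coexist(x, by_id[m]) for m in members_of(k)):
                    ix = id_matrix.index_of(x.id)
                    W[iu, ix] = W[ix, iu] = 0.0
            # propagation (b): u is no longer linkable to other identities
            for g, lab in assignment.assigned.items():
                if lab != k:
                    ig = id_matrix.index_of(g)
                    W[iu, ig] = W[ig, iu] = 0.0
    for f in by_id.values():
        assignment.labels.setdefault(f.id, UNASSIGNED)
    return assignment


def _fallback_anchor(
    long: list[Fragment], short: list[Fragment], n_animals: int
) -> IdentityAssignment:
    """Anchor labels when no complete group exists: the longest pairwise
    non-coexisting fragments, labelled 1..n by start frame."""
    logger.warning("no complete fragment group found; falling back to longest "
                   "pairwise non-coexisting fragments as identity anchors")
    pool = sorted(long or short, key=lambda f: (-f.n_samples, f.start_frame, f.id))
    chosen: list[Fragment] = []
    for f in pool:
        if len(chosen) == n_animals:
            break
        if all(not coexist(f, c) for c in chosen):
            chosen.append(f)
    chosen.sort(key=lambda f: (f.start_frame, f.id))
    assignment = IdentityAssignment(n_animals=n_animals)
    for identity, f in enumerate(chosen, start=1):
        assignment.labels[f.id] = identity
    return assignment


def solve_identities(
    fragments: list[Fragment],
    n_animals: int,
    sim_cfg: SimilarityConfig | None = None,
    asg_cfg: AssignmentConfig | None = None,
    id_matrix: IdMatrix | None = None,
) -> IdentityAssignment:
    """Full fragment-fusion pipeline.

    Builds the identity-likelihood matrix, splits fragments by length,
    anchors identities on complete groups (Hungarian), then greedily attaches
    the rest.  The returned assignment never gives one identity to two
    coexisting fragments.
    """
    sim_cfg = sim_cfg or SimilarityConfig()
    asg_cfg = asg_cfg or AssignmentConfig()
    long, short, discarded = split_long_short(
        fragments, asg_cfg.long_limit, asg_cfg.min_fragment_samples
    )
    usable = long + short
    if not usable:
        return IdentityAssignment(
            labels={f.id: UNASSIGNED for f in fragments}, n_animals=n_animals
        )
    if len(usable) == 1:
        assignment = IdentityAssignment(labels={usable[0].id: 1}, n_animals=n_animals)
    else:
        if id_matrix is None:
            id_matrix = build_id_matrix(usable, sim_cfg)
        groups = find_complete_groups(long, n_animals)
        if groups:
            partial = assign_groups(groups, id_matrix, n_animals, usable)
        else:
            partial = _fallback_anchor(long, short, n_animals)
        assignment = greedy_assign(
            id_matrix, partial, long, short, asg_cfg.min_correlation
        )
    for f in discarded:
        assignment.labels.setdefault(f.id, UNASSIGNED)
    assignment.check_consistency(fragments)
    return assignment
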
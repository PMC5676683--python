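"""Fragment-to-fragment identity likelihoods.

Two trajectory fragments of the same animal should not only look alike, they
should also relate to every *other* fragment in the same way.  That idea is
implemented in two layers:

1. a raw appearance similarity ``Sim(f_R, f_C)`` built from Pearson
   correlations between the ROI intensity histograms of sample pairs drawn
   from the two fragments: the maximum correlation (amplitude ``A``) times a
   Gaussian-weighted distribution of all pair correlations over ``Ln``
   levels, and
2. the identity likelihood ``Id(R, C)``: the Pearson correlation of the two
   fragments' *Sim profiles* against all other fragments, clamped to
   ``[0, 1]``, with hard zeros for fragment pairs that coexist in time (one
   animal cannot be in two places at once) and ones on the diagonal.

Sample pairs may be pre-filtered by a shape criterion (sum of absolute
differences of reciprocal Hu invariants) and a size criterion (symmetric
relative size change), and are capped by deterministic seeded subsampling
when the cross product of two long fragments is large.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .blob_detection import Detection
from .fragment_tracking import Fragment, size_change


@dataclass
class SimilarityConfig:
    """Parameters of the similarity and identity-likelihood computation.

    ``mu`` and ``sigma`` are the Gaussian weight parameters (defaults 1 and
    0.05): correlation levels near 1 carry nearly all the weight.  ``Ln`` is
    the number of correlation levels.  ``shape_diff_limit`` /
    ``size_change_limit_id`` pre-filter sample pairs; the shape filter is off
    by default because reciprocals of the small high-order Hu invariants are
    numerically ill-conditioned (see the methods note).  ``max_pairs`` caps
    the per-fragment-pair cross product by seeded subsampling.
    """

    Ln: int = 10
    mu: float = 1.0
    sigma: float = 0.05
    shape_diff_limit: float = math.inf
    size_change_limit_id: float = 0.5
    max_pairs: int = 10_000
    hu_epsilon: float = 1e-8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.Ln < 2:
            raise ValueError("Ln must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.max_pairs < 1:
            raise ValueError("max_pairs must be >= 1")
        if self.hu_epsilon <= 0:
            raise ValueError("hu_epsilon must be positive")


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with the degenerate-input convention.

    Either vector constant -> 0 (uncorrelatable, not NaN).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("pearson needs two equal-length 1-D vectors of length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(stats.pearsonr(a, b).statistic)


def _safe_reciprocal(hu: np.ndarray, eps: float) -> np.ndarray:
    hu = np.asarray(hu, dtype=np.float64)
    sign = np.where(hu < 0, -1.0, 1.0)
    return 1.0 / (sign * np.maximum(np.abs(hu), eps))


def shape_diff(d1: Detection, d2: Detection, hu_epsilon: float = 1e-8) -> float:
    """Shape distance: sum of absolute differences of reciprocal Hu invariants.

    Reciprocals are guarded as ``1 / (sign(h) * max(|h|, eps))`` so that
    near-zero invariants cannot blow up to infinity.
    """
    r1 = _safe_reciprocal(d1.hu, hu_epsilon)
    r2 = _safe_reciprocal(d2.hu, hu_epsilon)
    return float(np.abs(r1 - r2).sum())


class _FragmentFeatures:
    """Pre-standardised per-sample features of one fragment (internal)."""

    def __init__(self, frag: Fragment, eps: float) -> None:
        H = np.array([d.hist for d in frag.detections], dtype=np.float64)
        mean = H.mean(axis=1, keepdims=True)
        sd = H.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        Z = np.zeros_like(H)
        Z[ok] = (H[ok] - mean[ok]) / sd[ok]
        self.z = Z                              # rows with zero variance stay 0 -> r = 0
        self.recip_hu = np.array([_safe_reciprocal(d.hu, eps) for d in frag.detections])
        self.sizes = np.array([d.size for d in frag.detections], dtype=np.float64)
        self.n = len(frag.detections)


def _pair_correlations(
    fa: _FragmentFeatures,
    fb: _FragmentFeatures,
    cfg: SimilarityConfig,
    pair_key: tuple[int, int],
) -> tuple[np.ndarray, int]:
    total = fa.n * fb.n
    if total > cfg.max_pairs:
        rng = np.random.default_rng([cfg.rng_seed, pair_key[0], pair_key[1]])
        flat = rng.choice(total, size=cfg.max_pairs, replace=False)
        n_pairs = cfg.max_pairs
    else:
        flat = np.arange(total)
        n_pairs = total
    ii, jj = np.divmod(flat, fb.n)

    keep = np.ones(flat.size, dtype=bool)
    if np.isfinite(cfg.shape_diff_limit):
        sdiff = np.abs(fa.recip_hu[ii] - fb.recip_hu[jj]).sum(axis=1)
        keep &= sdiff <= cfg.shape_diff_limit
    sa, sb = fa.sizes[ii], fb.sizes[jj]
    keep &= np.maximum(sa, sb) / np.minimum(sa, sb) - 1.0 <= cfg.size_change_limit_id
    ii, jj = ii[keep], jj[keep]
    if ii.size == 0:
        return np.empty(0), n_pairs
    kn = fa.z.shape[1]
    corr = (fa.z[ii] * fb.z[jj]).sum(axis=1) / kn
    return corr, n_pairs


def pair_correlations(
    fR: Fragment, fC: Fragment, cfg: SimilarityConfig
) -> tuple[np.ndarray, int]:
    """Histogram correlations of sample pairs from two fragments.

    Pairs failing the shape/size filters are skipped but still count in the
    returned denominator ``n_pairs`` (the number of pairs considered, i.e.
    the full cross product, or ``max_pairs`` after subsampling).  The result
    is symmetric in the two fragments: pairs are enumerated in a canonical
    order keyed by the sorted fragment ids.
    """
    if not fR.detections or not fC.detections:
        raise ValueError("fragments must be non-empty")
    a, b = sorted((fR, fC), key=lambda f: f.id)
    corr, n_pairs = _pair_correlations(
        _FragmentFeatures(a, cfg.hu_epsilon),
        _FragmentFeatures(b, cfg.hu_epsilon),
        cfg,
        (a.id, b.id),
    )
    return corr, n_pairs


def similarity_amplitude(correlations: np.ndarray) -> float:
    """Amplitude ``A``: the maximum pair correlation (0 for an empty list)."""
    correlations = np.asarray(correlations, dtype=np.float64)
    if correlations.size == 0:
        return 0.0
    return float(correlations.max())


def weighted_distribution(
    correlations: np.ndarray, n_pairs: int, cfg: SimilarityConfig
) -> float:
    """Gaussian-weighted distribution of pair correlations over ``Ln`` levels.

    Level ``L`` covers ``[L/Ln, (L+1)/Ln)``; a correlation of exactly 1 goes
    to the top level, negative correlations fall in no level but still count
    in the denominator.  The weight is the unnormalised Gaussian kernel
    ``exp(-(m_L - mu)^2 / (2 sigma^2))`` at the level midpoint ``m_L``.
    """
    correlations = np.asarray(correlations, dtype=np.float64)
    if n_pairs < correlations.size:
        raise ValueError("n_pairs must be >= number of correlations")
    if n_pairs == 0:
        return 0.0
    pos = correlations[correlations >= 0]
    if pos.size == 0:
        return 0.0
    levels = np.minimum(np.floor(pos * cfg.Ln).astype(np.intp), cfg.Ln - 1)
    counts = np.bincount(levels, minlength=cfg.Ln)
    mids = (np.arange(cfg.Ln) + 0.5) / cfg.Ln
    weights = np.exp(-((mids - cfg.mu) ** 2) / (2.0 * cfg.sigma**2))
    return float((weights * counts).sum() / n_pairs)


def fragment_similarity(fR: Fragment, fC: Fragment, cfg: SimilarityConfig) -> float:
    """Appearance similarity ``Sim = A * sum(w_L r_L)``, clamped to ``>= 0``."""
    corr, n_pairs = pair_correlations(fR, fC, cfg)
    A = similarity_amplitude(corr)
    if A <= 0.0:
        return 0.0
    return A * weighted_distribution(corr, n_pairs, cfg)


def coexist(fR: Fragment, fC: Fragment) -> bool:
    """True iff the two fragments' inclusive frame intervals overlap."""
    if not fR.detections or not fC.detections:
        return False
    return fR.start_frame <= fC.end_frame and fC.start_frame <= fR.end_frame


@dataclass
class SimMatrix:
    """Symmetric matrix of raw fragment similarities."""

    values: np.ndarray
    fragment_ids: list[int]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.fragment_ids, columns=self.fragment_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SimMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=np.float64), [int(c) for c in df.columns])


@dataclass
class IdMatrix:
    """Identity-likelihood matrix: entries in [0, 1], diagonal 1, coexistence zeros."""

    values: np.ndarray
    fragment_ids: list[int]

    def index_of(self, fragment_id: int) -> int:
        return self.fragment_ids.index(fragment_id)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.fragment_ids, columns=self.fragment_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "IdMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=np.float64), [int(c) for c in df.columns])


def build_sim_matrix(fragments: list[Fragment], cfg: SimilarityConfig) -> SimMatrix:
    """All pairwise fragment similarities (diagonal left at 0; never used)."""
    n = len(fragments)
    feats = [_FragmentFeatures(f, cfg.hu_epsilon) for f in fragments]
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = (i, j) if fragments[i].id <= fragments[j].id else (j, i)
            corr, n_pairs = _pair_correlations(
                feats[a], feats[b], cfg, (fragments[a].id, fragments[b].id)
            )
            A = similarity_amplitude(corr)
            sim = A * weighted_distribution(corr, n_pairs, cfg) if A > 0 else 0.0
            S[i, j] = S[j, i] = sim
    return SimMatrix(S, [f.id for f in fragments])


def build_id_matrix(
    fragments: list[Fragment],
    cfg: SimilarityConfig,
    sim: SimMatrix | None = None,
) -> IdMatrix:
    """Identity likelihoods from correlations of similarity profiles.

    ``Id[R, C]`` is the Pearson correlation of rows R and C of the similarity
    matrix with the self-columns R and C removed, clamped to [0, 1].
    Coexisting pairs are hard zeros, the diagonal is 1.  When fewer than two
    profile entries remain (fewer than 4 fragments) the profile correlation
    is undefined and the entry falls back to the similarity normalised by the
    matrix maximum.
    """
    n = len(fragments)
    if n < 2:
        raise ValueError("need at least two fragments")
    if sim is None:
        sim = build_sim_matrix(fragments, cfg)
    S = sim.values
    smax = S.max()
    Id = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if coexist(fragments[i], fragments[j]):
                continue  # stays 0
            mask = np.ones(n, dtype=bool)
            mask[[i, j]] = False
            u, v = S[i, mask], S[j, mask]
            if u.size >= 2:
                p = pearson(u, v)
            else:
                p = S[i, j] / smax if smax > 0 else 0.0
            Id[i, j] = Id[j, i] = min(max(p, 0.0), 1.0)
    return IdMatrix(Id, [f.id for f in fragments])
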
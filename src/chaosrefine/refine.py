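"""Refined-subsequence extraction: the core of the package.

A chaotic system's hallmark is sensitive dependence on initial conditions:
trajectories launched from nearly identical states diverge strongly, while a
non-chaotic system keeps their gap bounded.  Starting from a single observed
signal, this module finds moments where the reconstructed state revisits
(nearly) the same point in phase space, far apart in time, and cuts out the
length-T subsequences that start at those moments.  Subsequences sharing a
subcluster therefore share near-identical initial conditions (value and its
first M-1 derivatives) and expose the divergence — or lack of it — directly.

Pipeline (``refine_signal``):

1. reconstruct an M-dimensional phase portrait (``embedding``),
2. cluster the state vectors with fuzzy c-means into C clusters (``fcm``),
3. per cluster, keep the P vectors nearest its center (a *subcluster*),
4. thin each subcluster so retained members are pairwise >= T apart in time,
5. randomly select subclusters with >= ``min_members`` members until the
   total refined material covers the source (sum of Rw * T >= N),
6. slice one length-T subsequence per retained member out of the source.

``divergence_ratio`` quantifies the end-to-start gap growth within each
subcluster, the diagnostic that separates chaotic from non-chaotic signals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dynamics import SignalSeries
from .embedding import PhasePortrait, derivative_embed
from .errors import RefinementError
from .fcm import ClusterModel, choose_cluster_count, fcm_fit, hard_assign

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RefineConfig:
    """Parameters of the refinement pipeline.

    Attributes
    ----------
    order : int
        Embedding dimension M (the dynamical order of the source system, or
        an estimate of it).
    n_clusters : int or None
        Cluster count C; ``None`` selects ``min(20, floor(sqrt(K)))`` from
        the portrait size K.
    subcluster_size : int
        P, the number of nearest-to-center vectors kept per cluster.
    time_separation : int
        T, both the minimum time gap between subcluster members and the
        length of every extracted subsequence (samples).
    min_members : int
        Minimum Rw: a subcluster is selectable only with at least this many
        time-separated members (>= 2 so divergence can be measured).
    coverage_target : int or None
        Minimum total refined samples, sum of Rw * T; ``None`` means N, the
        source length.
    seed : int
        Drives FCM initialization and subcluster shuffling through
        independent derived streams.
    """

    order: int = 3
    n_clusters: int | None = 20
    subcluster_size: int = 5
    time_separation: int = 100
    min_members: int = 2
    coverage_target: int | None = None
    seed: int = 0
    scale_by_dt: bool = True
    standardize: bool = False
    fuzzifier: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 300

    def __post_init__(self):
        if self.min_members < 2:
            raise ValueError("min_members must be >= 2")
        if self.subcluster_size < self.min_members:
            raise ValueError("subcluster_size (P) must be >= min_members")
        if self.time_separation < 1:
            raise ValueError("time_separation (T) must be >= 1")
        if self.n_clusters is not None and self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


@dataclass
class Subcluster:
    """Members of one cluster that are near its center (and, after step 4,
    pairwise time-separated).  Member arrays are ordered nearest-first."""

    cluster_id: int
    member_time_indices: np.ndarray  # (Rc,)
    center: np.ndarray               # (M,) parent cluster center
    member_vectors: np.ndarray       # (Rc, M)

    @property
    def size(self) -> int:
        return self.member_time_indices.size


@dataclass
class RefinedSubsequence:
    """One refined signal: a contiguous length-T slice of the source."""

    subcluster_id: int
    time_shift: int
    samples: np.ndarray


@dataclass
class RefinedSet:
    """The output of a refinement run: subsequences plus provenance."""

    source: SignalSeries
    subsequences: list[RefinedSubsequence]
    subcluster_centers: np.ndarray  # (W, M)
    config: RefineConfig
    coverage_met: bool = True
    step_counts: dict = field(default_factory=dict)

    @property
    def n_subsequences(self) -> int:
        return len(self.subsequences)

    @property
    def total_samples(self) -> int:
        return sum(s.samples.size for s in self.subsequences)

    def counts_per_subcluster(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for s in self.subsequences:
            out[s.subcluster_id] = out.get(s.subcluster_id, 0) + 1
        return out


# ---------------------------------------------------------------------------
# Steps 3-6

def select_nearest(portrait: PhasePortrait, model: ClusterModel,
                   labels: np.ndarray, P: int) -> list[Subcluster]:
    """Step 3: per cluster, the min(P, size) members nearest its center.

    Distance ties are broken by the earlier time index.  An empty cluster
    yields an empty subcluster, not an error.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    subclusters = []
    for c in range(model.n_clusters):
        idx = np.nonzero(labels == c)[0]
        center = model.centers[c]
        if idx.size == 0:
            subclusters.append(Subcluster(c, np.empty(0, dtype=int), center,
                                          np.empty((0, portrait.order))))
            continue
        d = np.linalg.norm(portrait.vectors[idx] - center, axis=1)
        t = portrait.time_index[idx]
        order = np.lexsort((t, d))[:min(P, idx.size)]
        keep = idx[order]
        subclusters.append(Subcluster(c, portrait.time_index[keep].copy(),
                                      center, portrait.vectors[keep].copy()))
    return subclusters


def filter_time_separated(subcluster: Subcluster, T: int) -> Subcluster:
    """Step 4: greedy thinning, nearest-to-center first.

    Scanning members in their stored (distance) order, a member is retained
    iff its time index differs by >= T from every already-retained member, so
    the most representative initial conditions win conflicts.
    """
    kept: list[int] = []
    for j, t in enumerate(subcluster.member_time_indices):
        if all(abs(int(t) - int(subcluster.member_time_indices[i])) >= T for i in kept):
            kept.append(j)
    kept_arr = np.asarray(kept, dtype=int)
    return Subcluster(subcluster.cluster_id,
                      subcluster.member_time_indices[kept_arr],
                      subcluster.center,
                      subcluster.member_vectors[kept_arr])


def select_subclusters(subclusters: Sequence[Subcluster], N: int, T: int,
                       min_members: int = 2, seed: int = 0,
                       coverage_target: int | None = None
                       ) -> tuple[list[Subcluster], bool]:
    """Step 5: seeded random selection of subclusters under the coverage rule.

    Members whose subsequence would overrun the source (time index > N - T)
    are dropped first; a subcluster is then *eligible* if it retains at least
    ``min_members`` members.  Eligible subclusters are uniformly shuffled and
    the shortest prefix with total refined samples sum(Rw)*T >= target
    (default: N) is returned.  If even all eligible subclusters fall short,
    all are returned with ``coverage_met=False``.

    Raises
    ------
    RefinementError
        If no subcluster is eligible, naming the constraint that emptied the
        pool.
    """
    if N < 1 or T < 1:
        raise ValueError("N and T must be positive")
    target = N if coverage_target is None else coverage_target

    eligible: list[Subcluster] = []
    for sub in subclusters:
        fits = sub.member_time_indices <= N - T
        if not np.all(fits):
            sub = Subcluster(sub.cluster_id, sub.member_time_indices[fits],
                             sub.center, sub.member_vectors[fits])
        if sub.size >= min_members:
            eligible.append(sub)

    if not eligible:
        raise RefinementError(
            "select_subclusters",
            f"no subcluster has >= {min_members} time-separated members with "
            f"start index <= N-T = {N - T}; cannot refine this signal")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(eligible))
    chosen: list[Subcluster] = []
    covered = 0
    for i in order:
        chosen.append(eligible[i])
        covered += eligible[i].size * T
        if covered >= target:
            return chosen, True
    return chosen, False


def extract_subsequences(signal: SignalSeries, chosen: Sequence[Subcluster],
                         T: int) -> RefinedSet:
    """Step 6: one length-T slice of the source per subcluster member."""
    n = len(signal)
    subsequences: list[RefinedSubsequence] = []
    centers = []
    for w, sub in enumerate(chosen):
        centers.append(sub.center)
        for t in sub.member_time_indices:
            t = int(t)
            if t + T > n:
                raise ValueError(
                    f"subsequence at time shift {t} overruns the {n}-sample source")
            subsequences.append(RefinedSubsequence(
                subcluster_id=w, time_shift=t,
                samples=signal.samples[t:t + T].copy()))
    centers_arr = np.vstack(centers) if centers else np.empty((0, 0))
    return RefinedSet(source=signal, subsequences=subsequences,
                      subcluster_centers=centers_arr,
                      config=RefineConfig(time_separation=T))


# ---------------------------------------------------------------------------
# End-to-end

def refine_signal(signal: SignalSeries, config: RefineConfig | None = None) -> RefinedSet:
    """Run the full refinement pipeline on one signal.

    Fully reproducible from (signal, config, seed); per-step counts are
    logged at info level and recorded in ``RefinedSet.step_counts``.
    """
    config = config or RefineConfig()
    N = len(signal)
    T = config.time_separation

    ss = np.random.SeedSequence(config.seed)
    fcm_seed, select_seed = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))

    portrait = derivative_embed(signal, config.order, scale_by_dt=config.scale_by_dt)
    X = portrait.vectors
    if config.standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    K = X.shape[0]
    C = config.n_clusters if config.n_clusters is not None else choose_cluster_count(K)
    if C > K:
        raise RefinementError("fcm", f"C={C} exceeds the {K} reconstructed vectors")

    model = fcm_fit(X, C, fuzzifier=config.fuzzifier, tol=config.fcm_tol,
                    max_iter=config.fcm_max_iter, seed=fcm_seed)
    if config.standardize:
        # report centers in the original (unscaled) coordinates
        model = ClusterModel(centers=model.centers * sd + portrait.vectors.mean(axis=0),
                             membership=model.membership, fuzzifier=model.fuzzifier,
                             n_iter=model.n_iter, objective_trace=model.objective_trace,
                             seed=model.seed)
    labels = hard_assign(model)

    subclusters = select_nearest(portrait, model, labels, config.subcluster_size)
    filtered = [filter_time_separated(s, T) for s in subclusters]
    chosen, coverage_met = select_subclusters(
        filtered, N, T, min_members=config.min_members, seed=select_seed,
        coverage_target=config.coverage_target)
    refined = extract_subsequences(signal, chosen, T)
    refined.config = config
    refined.coverage_met = coverage_met
    refined.step_counts = {
        "n_vectors": K,
        "n_clusters": C,
        "nonempty_subclusters": sum(1 for s in subclusters if s.size > 0),
        "eligible_after_time_filter": sum(1 for s in filtered if s.size >= config.min_members),
        "selected_subclusters": len(chosen),
        "n_subsequences": refined.n_subsequences,
        "total_samples": refined.total_samples,
        "coverage_met": coverage_met,
    }
    logger.info("refine %s (seed=%d, fcm_seed=%d, select_seed=%d): %s",
                signal.name, config.seed, fcm_seed, select_seed, refined.step_counts)
    return refined


def divergence_ratio(refined: RefinedSet, window_frac: float = 0.1,
                     eps: float = 1e-12) -> tuple[dict[int, float], float]:
    """End/start gap-growth ratio per subcluster, and the overall median.

    For each pair of subsequences in a subcluster the gap course is the
    absolute difference; the ratio compares the maximum gap over the final
    ``window_frac`` of T against the maximum over the initial ``window_frac``
    (denominator floored at ``eps``; two identical subsequences give 1 by
    convention).  Ratios near 1 indicate bounded gaps (non-chaotic); large
    ratios indicate sensitive dependence on initial conditions.

    Returns ``(per_subcluster, median)``; subclusters with fewer than two
    subsequences are skipped with a warning.
    """
    groups: dict[int, list[np.ndarray]] = {}
    for s in refined.subsequences:
        groups.setdefault(s.subcluster_id, []).append(s.samples)

    per_subcluster: dict[int, float] = {}
    for w, seqs in sorted(groups.items()):
        if len(seqs) < 2:
            warnings.warn(f"subcluster {w} has < 2 subsequences; skipped", stacklevel=2)
            continue
        T = seqs[0].size
        win = max(1, int(round(window_frac * T)))
        ratios = []
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                gap = np.abs(seqs[i] - seqs[j])
                start = gap[:win].max()
                end = gap[-win:].max()
                if end == 0.0 and start == 0.0:
                    ratios.append(1.0)
                else:
                    ratios.append(end / max(start, eps))
        per_subcluster[w] = float(np.mean(ratios))

    if not per_subcluster:
        raise ValueError("no subcluster with >= 2 subsequences to measure")
    return per_subcluster, float(np.median(list(per_subcluster.values())))
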
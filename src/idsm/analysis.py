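"""Quantitative trajectory summaries.

Estimators used to characterize trained and emergent habits: mean
distance to the light under the periodic arena metric, first-visit
region coding of SM space on a 10-per-dimension lattice, pooled PCA
projection of SM trajectories, oscillation amplitude/period/mean, and a
recurrence fraction quantifying how repetitive a trajectory is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA

from .bodies import ARENA_WIDTH, minimal_image

__all__ = [
    "RegionSequence",
    "mean_distance_to_light",
    "region_id_sequence",
    "pca_projection",
    "oscillation_stats",
    "recurrence_fraction",
]


@dataclass(frozen=True)
class RegionSequence:
    """A trajectory re-coded as lattice-region visits.

    ``region_ids[i]`` is the id of the hypercube occupied at ``times[i]``;
    ids are assigned in order of first visitation (0, 1, 2, ...).
    """

    times: np.ndarray
    region_ids: np.ndarray

    @property
    def n_regions(self) -> int:
        return int(self.region_ids.max()) + 1 if self.region_ids.size else 0


def mean_distance_to_light(xy: np.ndarray, light=(0.0, 0.0),
                           width: float = ARENA_WIDTH) -> float:
    """Time-averaged minimal-image distance from robot center to the light.

    ``xy`` is an (n, 2) array of positions at uniform time spacing.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    if xy.size == 0:
        raise ValueError("empty window")
    delta = minimal_image(xy - np.asarray(light, dtype=float), width)
    return float(np.mean(np.hypot(delta[:, 0], delta[:, 1])))


def region_id_sequence(sm: np.ndarray, bins_per_dim: int = 10,
                       times: np.ndarray | None = None) -> RegionSequence:
    """Map each normalized SM state to its lattice hypercube, numbering
    hypercubes in first-visit order.

    Bins are half-open [i/b, (i+1)/b) with the top bin closed, so a
    coordinate of exactly 1.0 falls in the last bin.
    """
    sm = np.atleast_2d(np.asarray(sm, dtype=float))
    n = sm.shape[0]
    idx = np.minimum((sm * bins_per_dim).astype(int), bins_per_dim - 1)
    # one integer key per hypercube
    keys = np.zeros(n, dtype=np.int64)
    for j in range(sm.shape[1]):
        keys = keys * bins_per_dim + idx[:, j]
    seen: dict[int, int] = {}
    ids = np.empty(n, dtype=int)
    for i, key in enumerate(keys):
        k = int(key)
        if k not in seen:
            seen[k] = len(seen)
        ids[i] = seen[k]
    if times is None:
        times = np.arange(n, dtype=float)
    return RegionSequence(np.asarray(times, dtype=float), ids)


def pca_projection(trajectories) -> tuple[list[np.ndarray], np.ndarray]:
    """Project SM trajectories onto the top-2 principal components.

    The PCA is fit on the pooled states of all trajectories (so different
    trials share one projection space).  Returns the per-trajectory 2-D
    coordinates and the explained-variance ratios of the two components.
    """
    trajs = [np.atleast_2d(np.asarray(t, dtype=float)) for t in trajectories]
    pooled = np.vstack(trajs)
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 states")
    if np.allclose(pooled.var(axis=0), 0.0):
        raise ValueError("zero-variance input")
    pca = PCA(n_components=2)
    pca.fit(pooled)
    return [pca.transform(t) for t in trajs], pca.explained_variance_ratio_


def oscillation_stats(signal: np.ndarray, dt: float
                      ) -> tuple[float, float | None, float]:
    """Amplitude, period and mean of a (roughly periodic) scalar signal.

    Amplitude is half the 5-95% interquantile span; the period is the mean
    interval between rising crossings of the signal mean (None when the
    signal never crosses its mean twice rising).
    """
    y = np.asarray(signal, dtype=float)
    if y.size < 2:
        raise ValueError("signal too short")
    mean = float(np.mean(y))
    lo, hi = np.quantile(y, [0.05, 0.95])
    amplitude = float(hi - lo) / 2.0
    above = y > mean
    rising = np.flatnonzero(~above[:-1] & above[1:])
    period = float(np.mean(np.diff(rising)) * dt) if rising.size >= 2 else None
    return amplitude, period, mean


def recurrence_fraction(sm: np.ndarray, delta: float, dt: float,
                        guard: float = 1.0) -> float:
    """Fraction of states whose nearest *earlier* state (at least ``guard``
    time-units older) lies within ``delta`` in normalized SM space.

    Quantifies how repetitive a trajectory is: a re-enacted closed loop
    scores near 1, a large-step random walk near 0.  States too early in
    the window to have an eligible predecessor are excluded from both
    numerator and denominator.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    sm = np.atleast_2d(np.asarray(sm, dtype=float))
    n = sm.shape[0]
    g = max(1, int(round(guard / dt)))
    if n <= g:
        return 0.0
    hits = 0
    total = 0
    # incremental KD-trees over chunks keep this near O(n log n)
    chunk = 512
    tree_upto = 0
    tree = None
    for start in range(g, n, chunk):
        stop = min(start + chunk, n)
        # all queried states in [start, stop) may see predecessors < start - ? :
        # predecessor set for state i is [0, i - g]; use tree over [0, start - g]
        # plus a direct scan of the ragged remainder
        upto = start - g + 1
        if upto > tree_upto:
            tree = cKDTree(sm[:upto])
            tree_upto = upto
        q = sm[start:stop]
        dists, _ = tree.query(q, k=1)
        for off, i in enumerate(range(start, stop)):
            dmin = dists[off]
            hi = i - g + 1
            if hi > tree_upto:  # remainder not in the tree
                rem = sm[tree_upto:hi] - sm[i]
                dmin = min(dmin, float(np.sqrt((rem * rem).sum(axis=1).min())))
            total += 1
            if dmin <= delta:
                hits += 1
    return hits / total if total else 0.0
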
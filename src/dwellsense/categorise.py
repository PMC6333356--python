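"""MAD-based categorisation of pattern clusters and classification of new windows.

Cluster repeatability is summarised by the Median Absolute Deviation (MAD)
score of cluster sizes: clusters whose member count sits close to the median
count are "highly repetitive" patterns (HSFP, the resident's routine), while
clusters whose count deviates strongly are "rarely repetitive" (RSFP) and are
the ones treated as behavioural anomalies.  The rejection thresholds are 1
(below: HSFP) and 2.5 (at or above: RSFP), with the in-between band labelled
"low repetitive" (LSFP).

A new six-hour window is classified by projecting it onto the learned factor
basis W with non-negative least squares, normalising the coordinates the same
way as in training, and inheriting the category of the nearest cluster
centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .nmf import ClusterAssignment, NMFModel, l1_normalise_columns
from .sfp import SixHourSFP

HSFP = "HSFP"
LSFP = "LSFP"
RSFP = "RSFP"

#: Consistency constant making the MAD an unbiased scale estimate under
#: normality (1 / Phi^{-1}(3/4)).
MAD_CONSISTENCY = 1.4826


def mad_deviation_scores(
    counts, b: float = MAD_CONSISTENCY, one_sided: bool = False
) -> np.ndarray:
    """MAD deviation score of each cluster size.

    ``score_i = |count_i - median| / (b * median_j |count_j - median|)``.
    If the MAD denominator is zero (all counts equal, or a strict majority
    tied at the median), every score is 0.  In ``one_sided`` mode only
    clusters *smaller* than the median can score above zero, so unusually
    large clusters are never flagged as rare.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    if (counts < 1).any():
        raise ValueError("cluster sizes must be >= 1")
    med = np.median(counts)
    abs_dev = np.abs(counts - med)
    mad = np.median(abs_dev)
    if mad == 0:
        return np.zeros_like(counts)
    scores = abs_dev / (b * mad)
    if one_sided:
        scores = np.where(counts >= med, 0.0, scores)
    return scores


def categorise_scores(
    scores, d_low: float = 1.0, d_high: float = 2.5
) -> list[str]:
    """Band MAD scores into pattern categories.

    score < d_low -> HSFP; d_low <= score < d_high -> LSFP;
    score >= d_high -> RSFP.  A score exactly at d_low is assigned LSFP (the
    conservative side: fewer windows declared fully routine); a score exactly
    at d_high is RSFP.
    """
    if not d_low < d_high:
        raise ValueError("require d_low < d_high")
    out = []
    for s in np.asarray(scores, dtype=float):
        if s < d_low:
            out.append(HSFP)
        elif s < d_high:
            out.append(LSFP)
        else:
            out.append(RSFP)
    return out


@dataclass
class CategoryProfile:
    """Learned profile for one time category: factors, clusters, categories."""

    category: str
    model: NMFModel
    assignment: ClusterAssignment
    member_counts: np.ndarray
    mad_scores: np.ndarray
    cluster_categories: list[str]
    d_low: float = 1.0
    d_high: float = 2.5
    normalise: bool = True


@dataclass
class ClusterProfile:
    """Per-home profile: one :class:`CategoryProfile` per time category."""

    home_id: str
    categories: dict[str, CategoryProfile] = field(default_factory=dict)

    def for_category(self, category: str) -> CategoryProfile:
        if category not in self.categories:
            raise KeyError(f"no profile for time category {category!r}")
        return self.categories[category]


def categorise_clusters(
    category: str,
    model: NMFModel,
    assignment: ClusterAssignment,
    d_low: float = 1.0,
    d_high: float = 2.5,
    b: float = MAD_CONSISTENCY,
    one_sided: bool = False,
    normalise: bool = True,
) -> CategoryProfile:
    """Attach member counts, MAD scores and HSFP/LSFP/RSFP labels to clusters."""
    counts = np.array(
        [int(np.sum(assignment.labels == c)) for c in range(1, assignment.k + 1)]
    )
    if assignment.degenerate or assignment.k == 1:
        scores = np.zeros(assignment.k)
    else:
        scores = mad_deviation_scores(counts, b=b, one_sided=one_sided)
    cats = categorise_scores(scores, d_low=d_low, d_high=d_high)
    return CategoryProfile(
        category=category,
        model=model,
        assignment=assignment,
        member_counts=counts,
        mad_scores=scores,
        cluster_categories=cats,
        d_low=d_low,
        d_high=d_high,
        normalise=normalise,
    )


def project_window(window_vector: np.ndarray, model: NMFModel) -> np.ndarray:
    """Non-negative least-squares coordinates of a flattened window in W's span."""
    h, _ = nnls(model.W, np.asarray(window_vector, dtype=float))
    return h


def classify_window(
    sfp: SixHourSFP, profile: ClusterProfile | CategoryProfile
) -> tuple[str, int]:
    """Classify a six-hour window against a learned profile.

    Returns the inherited cluster category (HSFP/LSFP/RSFP) and the 1-based id
    of the nearest cluster centroid (Euclidean distance in the, optionally
    L1-normalised, feature space).
    """
    cp = profile.for_category(sfp.category) if isinstance(profile, ClusterProfile) else profile
    h = project_window(sfp.flatten(), cp.model)
    if cp.normalise:
        h = l1_normalise_columns(h[:, None])[:, 0]
    d = np.linalg.norm(cp.assignment.centroids - h[None, :], axis=1)
    cluster = int(np.argmin(d)) + 1
    return cp.cluster_categories[cluster - 1], cluster
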
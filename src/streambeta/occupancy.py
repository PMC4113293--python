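"""Occupancy-frequency distributions and Tokeshi's modality test.

For a group of sites (an island, a region), each taxon's occupancy is the
fraction of the group's sites where it occurs. The histogram of occupancies
over equal-width classes is the occupancy-frequency distribution; its shape
separates communities dominated by rare, patchily distributed taxa from
those dominated by ubiquitous taxa, or bimodal core-satellite structure.

The modality test treats each of the S taxa as falling into one of the c
occupancy classes with equal probability 1/c under a uniform null. The
extreme-class counts are then binomial, and exceedance of the leftmost
(lowest-occupancy) class, the rightmost (highest-occupancy) class, or
jointly both, gives exact tail p-values.

Naming convention: ``p_left``/``p_right`` and the left-/right-skewed labels
refer to the histogram's extreme *classes* (left = lowest occupancy,
right = highest). Note that in the core-satellite literature a community of
mostly rare species — excess mass in the *leftmost* class — is often
described as a "right-skewed" occupancy-frequency distribution (long right
tail); here that situation is reported as ``p_left`` small, classification
"left-skewed". Check which extreme class carries the excess rather than
relying on the adjective.
"""

from __future__ import annotations

import dataclasses
import functools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data_model import CommunityMatrix, StructuralError, ValidationError

__all__ = [
    "OccupancyDistribution",
    "ModalityTestResult",
    "occupancy_distribution",
    "count_low_occupancy",
    "tokeshi_test",
    "OccupancyModality",
]


@dataclasses.dataclass(frozen=True)
class OccupancyDistribution:
    """Histogram of per-taxon occupancy proportions for one site group."""

    group: str
    occupancy: pd.Series  # per-taxon occupancy in (0, 1], zero-occupancy taxa dropped
    class_edges: tuple[float, ...]
    class_counts: tuple[int, ...]
    n_taxa: int
    n_sites: int


@dataclasses.dataclass(frozen=True)
class ModalityTestResult:
    group: str
    p_right: float
    p_left: float
    p_bimodal: float
    classification: str  # right-skewed | left-skewed | bimodal | uniform/NS
    n_taxa: int
    n_classes: int


def occupancy_distribution(
    cm: CommunityMatrix,
    sites: Sequence[str],
    class_width: float = 0.05,
    group: str = "group",
) -> OccupancyDistribution:
    """Occupancy-frequency distribution over a group of sites.

    Classes are ``(0, w], (w, 2w], ..., (1-w, 1]``: a proportion exactly on
    an edge belongs to the lower class, except that the first class is
    left-open at zero. Taxa absent from every site in the group are
    excluded. Class membership is computed in integer arithmetic (occupancy
    is always a ratio of site counts), so edge cases are exact.
    """
    if not sites:
        raise StructuralError("empty site group")
    c = round(1.0 / class_width)
    if not math.isclose(c * class_width, 1.0, rel_tol=1e-9):
        raise ValueError(f"class_width {class_width} does not divide 1 evenly")
    sub = cm.subset_sites(sites)
    n_sites = len(sites)
    present = (sub.counts > 0).sum(axis=0)  # sites occupied per taxon
    occupied = present > 0
    k = present[occupied]
    occ = pd.Series(
        k / n_sites, index=np.asarray(sub.taxon_ids)[occupied], name="occupancy"
    )
    # exact class index: smallest j with k/n <= j*w  <=>  ceil(k*c/n) - 1
    idx = (k * c + n_sites - 1) // n_sites - 1
    counts = np.bincount(idx, minlength=c)
    edges = tuple(np.round(np.arange(c + 1) * class_width, 12))
    return OccupancyDistribution(
        group=str(group),
        occupancy=occ,
        class_edges=edges,
        class_counts=tuple(int(x) for x in counts),
        n_taxa=int(occupied.sum()),
        n_sites=n_sites,
    )


def count_low_occupancy(dist: OccupancyDistribution, threshold: float = 0.2) -> int:
    """Number of taxa occupying strictly fewer than ``threshold`` of the sites."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return int((dist.occupancy < threshold).sum())


def tokeshi_test(
    dist: OccupancyDistribution, alpha: float = 0.05, n_extreme: int = 1
) -> ModalityTestResult:
    """Exact modality test of an occupancy-frequency distribution.

    Under the uniform null each of the ``n_taxa`` species falls in any of
    the c classes with probability 1/c. With X ~ Binomial(n_taxa, m/c) and
    m = ``n_extreme`` classes pooled per tail, ``p_right`` is the upper tail
    P[X >= k_right] at the observed count in the rightmost class(es),
    ``p_left`` the analogue for the leftmost, and ``p_bimodal`` the joint
    exceedance of both extremes under the corresponding multinomial.
    """
    counts = np.asarray(dist.class_counts)
    c = counts.size
    n = int(counts.sum())
    if c < 3:
        raise ValueError("modality test needs at least 3 occupancy classes")
    if n < 1:
        raise ValidationError("no taxa in the distribution")
    if not 1 <= n_extreme <= c // 2:
        raise ValueError("n_extreme must be in [1, n_classes // 2]")
    k_right = int(counts[-n_extreme:].sum())
    k_left = int(counts[:n_extreme].sum())
    p_tail = n_extreme / c
    p_right = float(stats.binom.sf(k_right - 1, n, p_tail))
    p_left = float(stats.binom.sf(k_left - 1, n, p_tail))
    p_bimodal = _joint_multinomial_tail(n, p_tail, k_left, k_right)
    if p_left < alpha and p_right < alpha and p_bimodal < alpha:
        classification = "bimodal"
    elif p_right < alpha:
        classification = "right-skewed"
    elif p_left < alpha:
        classification = "left-skewed"
    else:
        classification = "uniform/NS"
    return ModalityTestResult(
        group=dist.group,
        p_right=p_right,
        p_left=p_left,
        p_bimodal=p_bimodal,
        classification=classification,
        n_taxa=n,
        n_classes=c,
    )


@functools.lru_cache(maxsize=4096)
def _joint_multinomial_tail(n: int, p_tail: float, k_left: int, k_right: int) -> float:
    """Joint exceedance P[L>=k_left, R>=k_right], tails each with mass p_tail."""
    rest = 1.0 - 2.0 * p_tail
    lf = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, n + 1)))))
    logp = math.log(p_tail)
    logrest = math.log(rest) if rest > 0 else -math.inf
    total = 0.0
    for i in range(k_left, n + 1):
        for j in range(k_right, n - i + 1):
            m = n - i - j
            if rest == 0 and m > 0:
                continue
            lr = 0.0 if m == 0 else m * logrest
            total += math.exp(lf[n] - lf[i] - lf[j] - lf[m] + (i + j) * logp + lr)
    return min(total, 1.0)


class OccupancyModality(BaseEstimator):
    """Occupancy-frequency distributions and modality tests per site group.

    Attributes
    ----------
    distributions_ : dict[str, OccupancyDistribution]
    tests_ : dict[str, ModalityTestResult]
    summary_ : pandas.DataFrame
    """

    def __init__(self, class_width: float = 0.05, alpha: float = 0.05, n_extreme: int = 1):
        self.class_width = class_width
        self.alpha = alpha
        self.n_extreme = n_extreme

    def fit(self, cm: CommunityMatrix, groups: Mapping[str, Sequence[str]]):
        self.distributions_ = {}
        self.tests_ = {}
        rows = []
        for name, sites in groups.items():
            dist = occupancy_distribution(cm, sites, self.class_width, group=name)
            test = tokeshi_test(dist, alpha=self.alpha, n_extreme=self.n_extreme)
            self.distributions_[str(name)] = dist
            self.tests_[str(name)] = test
            rows.append(dataclasses.asdict(test))
        self.summary_ = pd.DataFrame(rows)
        return self
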
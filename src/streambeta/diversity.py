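"""Multiplicative diversity partitioning with Hill numbers of order 0 and 1.

Alpha diversity is the average diversity of a single site, gamma the
diversity of the region's pooled counts, and Whittaker's multiplicative beta
the ratio beta_w = gamma / alpha — the number of compositionally distinct
communities the region effectively contains. Order q=0 uses species
richness; q=1 uses the exponential of Shannon entropy ("effective
diversity"), which weights species by relative abundance.

Two alpha conventions are supported for q=1: the arithmetic mean of per-site
effective diversities (mean of exp H'), and the Hill/Jost decomposition
alpha (exp of mean H'), under which beta_w is bounded by [1, n_sites]
exactly.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data_model import CommunityMatrix, ValidationError

__all__ = [
    "DiversityPartition",
    "shannon_entropy",
    "effective_diversity",
    "partition_region",
    "BetaPartitioner",
]


@dataclasses.dataclass(frozen=True)
class DiversityPartition:
    """Alpha/gamma/beta_w partition of one region for one diversity order."""

    region: str
    q: int
    alpha: float
    gamma: float
    beta_w: float
    n_sites: int
    alpha_mode: str
    alpha_median: float  # descriptive companion to the mean-based alpha


def shannon_entropy(abundances) -> float:
    """Shannon entropy H' (nats) of a count vector; zero counts ignored."""
    n = np.asarray(abundances, dtype=float).ravel()
    if (n < 0).any():
        raise ValidationError("abundances must be non-negative")
    total = n.sum()
    if total <= 0:
        raise ValidationError("all-zero abundance vector has undefined entropy")
    p = n[n > 0] / total
    return float(-(p * np.log(p)).sum())


def effective_diversity(abundances) -> float:
    """exp(H'): the number of equally abundant species matching the entropy."""
    return float(np.exp(shannon_entropy(abundances)))


def _partition_arrays(
    counts: np.ndarray, q: int, alpha_mode: str
) -> tuple[float, float, float]:
    """(alpha, gamma, alpha_median) for a region's site-by-taxon count block."""
    if q == 0:
        site_rich = (counts > 0).sum(axis=1).astype(float)
        alpha = float(site_rich.mean())
        gamma = float(((counts.sum(axis=0)) > 0).sum())
        med = float(np.median(site_rich))
    elif q == 1:
        totals = counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / totals
            logp = np.where(counts > 0, np.log(np.where(counts > 0, p, 1.0)), 0.0)
        h_sites = -(np.where(counts > 0, p, 0.0) * logp).sum(axis=1)
        if alpha_mode == "arithmetic":
            alpha = float(np.exp(h_sites).mean())
        elif alpha_mode == "jost":
            alpha = float(np.exp(h_sites.mean()))
        else:
            raise ValueError(f"unknown alpha_mode {alpha_mode!r}")
        pooled = counts.sum(axis=0)
        gamma = effective_diversity(pooled)
        med = float(np.median(np.exp(h_sites)))
    else:
        raise ValueError(f"diversity order q must be 0 or 1, got {q!r}")
    return alpha, gamma, med


def partition_region(
    cm: CommunityMatrix,
    sites: Sequence[str],
    q: int = 0,
    alpha_mode: str = "arithmetic",
    region: str = "region",
) -> DiversityPartition:
    """Partition one region's diversity into alpha, gamma and beta_w = gamma/alpha.

    Parameters
    ----------
    sites:
        The region's site labels (each must carry at least one individual).
    q:
        Diversity order: 0 for richness, 1 for effective Shannon diversity.
    alpha_mode:
        For q=1 only — "arithmetic" (mean of per-site exp H') or "jost"
        (exp of mean per-site H').
    """
    sub = cm.subset_sites(sites)
    counts = sub.counts
    empty = np.asarray(sub.site_ids)[counts.sum(axis=1) == 0]
    if empty.size:
        raise ValidationError(f"site(s) with zero individuals: {empty.tolist()}")
    alpha, gamma, med = _partition_arrays(counts, q, alpha_mode)
    return DiversityPartition(
        region=str(region),
        q=q,
        alpha=alpha,
        gamma=gamma,
        beta_w=gamma / alpha,
        n_sites=len(sites),
        alpha_mode=alpha_mode if q == 1 else "arithmetic",
        alpha_median=med,
    )


class BetaPartitioner(BaseEstimator):
    """Per-group multiplicative diversity partitioning (sklearn-style).

    Parameters
    ----------
    q : int, default 0
        Diversity order (0 = richness, 1 = effective Shannon diversity).
    alpha_mode : {"arithmetic", "jost"}, default "arithmetic"
        Alpha convention for q=1.

    Attributes
    ----------
    partitions_ : list[DiversityPartition]
        One partition per group, in group order.
    summary_ : pandas.DataFrame
        Tidy table: region, q, alpha, gamma, beta_w, n_sites, alpha_mode,
        alpha_median.
    """

    def __init__(self, q: int = 0, alpha_mode: str = "arithmetic"):
        self.q = q
        self.alpha_mode = alpha_mode

    def fit(self, cm: CommunityMatrix, groups: Mapping[str, Sequence[str]]):
        self.partitions_ = [
            partition_region(cm, sites, q=self.q, alpha_mode=self.alpha_mode, region=name)
            for name, sites in groups.items()
        ]
        self.summary_ = pd.DataFrame([dataclasses.asdict(p) for p in self.partitions_])
        return self
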
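"""Individual-based null model and beta-deviation standardized effect sizes.

The randomisation pools every individual in a region as a species-labelled
token, applies a uniform random permutation, and partitions the permuted
tokens back into sites by the original per-site totals. This preserves, by
construction, each site's number of individuals (row sums) and each
species' regional abundance (column sums over the region's sites) — hence
also regional gamma diversity — while erasing any site-level structure.

Beta deviation is the standardized effect size
``(observed beta_w - null mean) / null SD`` against the null distribution of
beta_w over many shuffles: positive values mean sites are more
compositionally differentiated than random sampling from the regional
species pool would produce. This corrects the gamma-dependence of raw
beta_w, so regions with different pool sizes can be compared.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data_model import CommunityMatrix, ValidationError
from .diversity import _partition_arrays, partition_region

__all__ = ["NullModelResult", "shuffle_region", "beta_deviation", "BetaDeviation"]


@dataclasses.dataclass(frozen=True)
class NullModelResult:
    region: str
    q: int
    observed_beta: float
    null_mean: float
    null_sd: float
    beta_deviation: float  # NaN when degenerate
    p_value: float
    n_iterations: int
    seed: int | None
    degenerate: bool


def _tokens(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Species-labelled tokens and the fixed site index of each token slot."""
    n_sites, n_taxa = counts.shape
    species = np.repeat(
        np.tile(np.arange(n_taxa), n_sites), counts.ravel()
    )
    site_idx = np.repeat(np.arange(n_sites), counts.sum(axis=1))
    return species, site_idx


def _shuffled_counts(
    species: np.ndarray, site_idx: np.ndarray, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """One token shuffle realised as a site-by-taxon count matrix."""
    rng.shuffle(species)
    n_sites, n_taxa = shape
    flat = np.bincount(site_idx * n_taxa + species, minlength=n_sites * n_taxa)
    return flat.reshape(n_sites, n_taxa)


def shuffle_region(
    cm: CommunityMatrix, sites: Sequence[str], rng: np.random.Generator | int | None = None
) -> CommunityMatrix:
    """Return a copy of ``cm`` with individuals shuffled among the given sites.

    Row sums of the region's sites and regional per-species totals are
    preserved exactly; sites outside ``sites`` are untouched.
    """
    rng = np.random.default_rng(rng)
    sub = cm.subset_sites(sites)
    counts = sub.counts
    if counts.sum() < 1:
        raise ValidationError("region holds no individuals")
    species, site_idx = _tokens(counts)
    shuffled = _shuffled_counts(species, site_idx, counts.shape, rng)
    out = cm.data.copy()
    out.loc[list(sites), :] = shuffled
    return CommunityMatrix(out)


def _beta_from_counts(counts: np.ndarray, q: int, alpha_mode: str) -> float:
    alpha, gamma, _ = _partition_arrays(counts, q, alpha_mode)
    return gamma / alpha


def beta_deviation(
    cm: CommunityMatrix,
    sites: Sequence[str],
    q: int = 0,
    alpha_mode: str = "arithmetic",
    n_iter: int = 999,
    seed: int | np.random.Generator | None = None,
    region: str = "region",
) -> NullModelResult:
    """Beta deviation (SES) of one region's beta_w against the shuffle null.

    The p-value is the one-sided permutation probability of a null beta_w at
    least as large as the observed one, with the (r+1)/(n+1) correction. The
    SES uses the sample SD (n-1 denominator) of the null distribution; when
    the null distribution is constant (e.g. a single-species region) the
    result is flagged degenerate and the SES reported as NaN.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be at least 2")
    rng = np.random.default_rng(seed)
    observed = partition_region(cm, sites, q=q, alpha_mode=alpha_mode, region=region)
    counts = cm.subset_sites(sites).counts
    null = _null_distribution(counts, q, alpha_mode, n_iter, rng)
    return _summarise(
        region, q, observed.beta_w, null, n_iter,
        seed if isinstance(seed, int) else None,
    )


def _null_distribution(
    counts: np.ndarray, q: int, alpha_mode: str, n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    species, site_idx = _tokens(counts)
    species = species.copy()
    shape = counts.shape
    null = np.empty(n_iter)
    for i in range(n_iter):
        null[i] = _beta_from_counts(
            _shuffled_counts(species, site_idx, shape, rng), q, alpha_mode
        )
    return null


def _summarise(
    region: str,
    q: int,
    observed: float,
    null: np.ndarray,
    n_iter: int,
    seed: int | None,
) -> NullModelResult:
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    p = (int((null >= observed).sum()) + 1) / (n_iter + 1)
    degenerate = sd == 0.0
    ses = math.nan if degenerate else (observed - mean) / sd
    return NullModelResult(
        region=str(region),
        q=q,
        observed_beta=observed,
        null_mean=mean,
        null_sd=sd,
        beta_deviation=ses,
        p_value=p,
        n_iterations=n_iter,
        seed=seed,
        degenerate=degenerate,
    )


class BetaDeviation(BaseEstimator):
    """Per-group beta-deviation effect sizes (sklearn-style).

    Parameters
    ----------
    q : int, default 0
        Diversity order of the beta_w being standardized.
    alpha_mode : str, default "arithmetic"
        Alpha convention for q=1.
    n_iter : int, default 999
        Number of null shuffles per group.
    random_state : int or numpy Generator, optional
        Seed for the shuffle stream; groups consume independent substreams
        so results do not depend on group evaluation order.

    Attributes
    ----------
    results_ : list[NullModelResult]
    summary_ : pandas.DataFrame
    """

    def __init__(
        self,
        q: int = 0,
        alpha_mode: str = "arithmetic",
        n_iter: int = 999,
        random_state: int | None = None,
    ):
        self.q = q
        self.alpha_mode = alpha_mode
        self.n_iter = n_iter
        self.random_state = random_state

    def fit(self, cm: CommunityMatrix, groups: Mapping[str, Sequence[str]]):
        ss = np.random.SeedSequence(self.random_state)
        children = ss.spawn(len(groups))
        self.results_ = []
        for child, (name, sites) in zip(children, groups.items()):
            rng = np.random.default_rng(child)
            observed = partition_region(
                cm, sites, q=self.q, alpha_mode=self.alpha_mode, region=name
            )
            counts = cm.subset_sites(sites).counts
            null = _null_distribution(counts, self.q, self.alpha_mode, self.n_iter, rng)
            self.results_.append(
                _summarise(
                    name, self.q, observed.beta_w, null, self.n_iter, self.random_state
                )
            )
        self.summary_ = pd.DataFrame([dataclasses.asdict(r) for r in self.results_])
        return self
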
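"""Synthetic multi-region community and environment generator.

Emulates the sampling design the analysis stack expects — a balanced survey
of R regions with a fixed number of sites each — with known ground truth at
every stage:

* each region has a species pool (a contiguous, partially overlapping
  window of a global species list, so neighbouring regions share taxa and
  island-level pooling is meaningful) whose pool relative abundances follow
  a lognormal species-abundance distribution;
* each species has a niche optimum on a latent environmental axis, each
  site a position on that axis drawn from the region's gradient range;
* site-level sampling weights are the pool SAD multiplied by a Gaussian
  niche filter ``exp(-(e_j - mu_s)^2 / (2 tau^2))``. Infinite niche breadth
  tau recovers the neutral limit exactly (weights reduce to the SAD), so
  the null model's own generative process is available as a special case;
* per-site individual totals are negative-binomial, and site counts are
  multinomial draws — the same conditional structure the individual-based
  null model preserves.

The habitat table is derived from the latent axis (plus noise), so widening
a region's gradient range increases both its realized habitat heterogeneity
and its compositional dispersion. A companion generator produces regression
datasets with a known linear model for the inference stage.

All randomness flows from one seed through per-region substreams
(numpy ``SeedSequence.spawn``), so adding a region never perturbs the draws
of earlier regions.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import CommunityMatrix, SiteMetadata

__all__ = ["SyntheticConfig", "generate_community", "generate_regression_dataset"]


@dataclasses.dataclass
class SyntheticConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror a balanced eight-region, fifteen-sites-per-region
    survey with a north-to-south decline in regional pool size and neutral
    (no-filtering) community assembly.
    """

    seed: int
    n_regions: int = 8
    sites_per_region: int = 15
    gamma_per_region: int | Sequence[int] | None = None  # None -> linear 60..32
    sad_sigma: float = 1.0
    site_total_mean: float = 200.0
    site_total_dispersion: float = 5.0
    niche_breadth: float = math.inf  # tau; inf = neutral
    gradient_range: tuple[float, float] | Sequence[tuple[float, float]] = (0.0, 1.0)
    env_coefficients: Mapping[str, float] | None = None
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_regions < 1 or self.sites_per_region < 1:
            raise ValueError("n_regions and sites_per_region must be at least 1")
        if not (self.niche_breadth > 0):
            raise ValueError("niche_breadth must be positive (math.inf = neutral)")
        if self.sad_sigma <= 0:
            raise ValueError("sad_sigma must be positive")
        if self.site_total_mean < 1 or self.site_total_dispersion <= 0:
            raise ValueError("site totals need mean >= 1 and positive dispersion")

    # ------------------------------------------------------------- resolved
    def gammas(self) -> np.ndarray:
        g = self.gamma_per_region
        if g is None:
            out = np.round(np.linspace(60, 32, self.n_regions)).astype(int)
        elif np.isscalar(g):
            out = np.full(self.n_regions, int(g))
        else:
            out = np.asarray(g, dtype=int)
            if out.size != self.n_regions:
                raise ValueError("gamma_per_region length must equal n_regions")
        if (out < 2).any():
            raise ValueError("gamma_per_region must be at least 2")
        return out

    def ranges(self) -> list[tuple[float, float]]:
        gr = self.gradient_range
        if isinstance(gr[0], (int, float)):
            return [tuple(gr)] * self.n_regions  # type: ignore[list-item]
        ranges = [tuple(r) for r in gr]  # type: ignore[arg-type]
        if len(ranges) != self.n_regions:
            raise ValueError("gradient_range list length must equal n_regions")
        return ranges

    def coefficients(self) -> dict[str, float]:
        if self.env_coefficients is None:
            return {
                "intercept": 2.9,
                "heterogeneity": 11.9,
                "chl_a": -0.8,
                "pfankuch_bottom": 0.0,
                "steepness": 0.0,
            }
        return {str(k): float(v) for k, v in self.env_coefficients.items()}


def _region_names(n: int) -> list[str]:
    return [f"R{i+1}" for i in range(n)]


def _pool_windows(gammas: np.ndarray) -> list[np.ndarray]:
    """Contiguous, overlapping windows of a global species list (~50% overlap)."""
    step = max(1, int(round(gammas.mean() * 0.5)))
    starts = np.arange(gammas.size) * step
    return [np.arange(s, s + g) for s, g in zip(starts, gammas)]


def _site_weights(
    sad: np.ndarray, optima: np.ndarray, e: np.ndarray, tau: float
) -> np.ndarray:
    """Per-site sampling probabilities: SAD x Gaussian niche filter, row-normalized."""
    if math.isinf(tau):
        w = np.tile(sad, (e.size, 1))
    else:
        filt = np.exp(-((e[:, None] - optima[None, :]) ** 2) / (2.0 * tau**2))
        w = sad[None, :] * filt
    total = w.sum(axis=1, keepdims=True)
    if (total == 0).any():
        # numerically dead site (all filters underflowed): fall back to SAD
        dead = total.ravel() == 0
        w[dead] = sad
        total = w.sum(axis=1, keepdims=True)
    return w / total


def generate_community(
    cfg: SyntheticConfig,
) -> tuple[CommunityMatrix, SiteMetadata, dict]:
    """Generate a community matrix, a site-metadata table and a truth record."""
    gammas = cfg.gammas()
    ranges = cfg.ranges()
    pools = _pool_windows(gammas)
    n_species_global = int(max(p[-1] for p in pools)) + 1
    taxa = [f"sp{i+1:04d}" for i in range(n_species_global)]
    regions = _region_names(cfg.n_regions)
    n_north = (cfg.n_regions + 1) // 2

    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(cfg.n_regions)

    count_rows, meta_rows, site_ids = [], [], []
    truth: dict = {"config": dataclasses.asdict(cfg), "regions": {}}
    p_nb = cfg.site_total_dispersion / (cfg.site_total_dispersion + cfg.site_total_mean)

    for r, (region, pool, gamma_r, (lo, hi)) in enumerate(
        zip(regions, pools, gammas, ranges)
    ):
        rng = np.random.default_rng(streams[r])
        sad = rng.lognormal(mean=0.0, sigma=cfg.sad_sigma, size=gamma_r)
        sad /= sad.sum()
        optima = rng.uniform(0.0, 1.0, size=gamma_r)
        e = rng.uniform(lo, hi, size=cfg.sites_per_region)
        weights = _site_weights(sad, optima, e, cfg.niche_breadth)
        totals = np.maximum(
            1, rng.negative_binomial(cfg.site_total_dispersion, p_nb, size=cfg.sites_per_region)
        )
        island = "North" if r < n_north else "South"
        region_chl_mu = rng.normal(0.5, 0.5)
        region_pfankuch = rng.uniform(20.0, 45.0)
        region_steepness = rng.uniform(5.0, 60.0)
        region_pet = rng.uniform(700.0, 1200.0)
        for j in range(cfg.sites_per_region):
            counts = rng.multinomial(totals[j], weights[j])
            row = np.zeros(n_species_global, dtype=np.int64)
            row[pool] = counts
            count_rows.append(row)
            sid = f"{region}_S{j+1:02d}"
            site_ids.append(sid)
            ej = e[j]
            meta_rows.append(
                {
                    "site_id": sid,
                    "region": region,
                    "island": island,
                    "depth": max(0.02, 0.15 + 0.5 * ej + rng.normal(0, 0.05)),
                    "velocity": max(0.01, 0.2 + 0.6 * ej + rng.normal(0, 0.08)),
                    "slope": max(0.05, 0.5 + 4.5 * ej + rng.normal(0, 0.3)),
                    "canopy": float(np.clip(15 + 60 * ej + rng.normal(0, 8), 0, 100)),
                    "substrate_index": max(5.0, 40 + 150 * ej + rng.normal(0, 10)),
                    "macrophytes": float(np.clip(40 * (1 - ej) + rng.normal(0, 5), 0, 100)),
                    "chl_a": float(rng.lognormal(region_chl_mu, 0.5)),
                    "pfankuch_bottom": float(region_pfankuch + rng.normal(0, 3)),
                    "steepness": float(np.clip(region_steepness + rng.normal(0, 3), 0, 100)),
                    "pet": float(region_pet + rng.normal(0, 20)),
                }
            )
        truth["regions"][region] = {
            "pool_species": [taxa[i] for i in pool],
            "sad": sad,
            "niche_optima": optima,
            "site_environment": e,
            "site_totals": totals,
            "niche_breadth": cfg.niche_breadth,
            "gradient_range": (lo, hi),
            "island": island,
        }

    data = pd.DataFrame(np.vstack(count_rows), index=site_ids, columns=taxa)
    data.index.name = "site_id"
    # drop globally absent species so the matrix mirrors a real survey table
    data = data.loc[:, (data != 0).any(axis=0)]
    cm = CommunityMatrix(data)
    meta = SiteMetadata(pd.DataFrame(meta_rows).set_index("site_id"))
    return cm, meta, truth


def generate_regression_dataset(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Generate a region-structured design matrix and a linear response.

    Predictors are the keys of ``cfg.coefficients()`` other than
    ``intercept``; each has a region-level mean (SD 1 across regions) plus
    site-level noise (SD 1), so observations within a region are correlated
    as in a real survey. The response is the stated linear combination plus
    Normal(0, ``noise_sd``) noise.
    """
    coefs = cfg.coefficients()
    predictors = [k for k in coefs if k != "intercept"]
    regions = _region_names(cfg.n_regions)
    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(cfg.n_regions)
    rows, site_ids, region_col = [], [], []
    for r, region in enumerate(regions):
        rng = np.random.default_rng(streams[r])
        region_means = rng.normal(0.0, 1.0, size=len(predictors))
        x = region_means[None, :] + rng.normal(
            0.0, 1.0, size=(cfg.sites_per_region, len(predictors))
        )
        rows.append(x)
        site_ids += [f"{region}_S{j+1:02d}" for j in range(cfg.sites_per_region)]
        region_col += [region] * cfg.sites_per_region
    env = pd.DataFrame(np.vstack(rows), index=site_ids, columns=predictors)
    env.index.name = "site_id"
    env["region"] = region_col
    noise_rng = np.random.default_rng(ss.spawn(1)[0])
    beta = np.array([coefs[p] for p in predictors])
    y = (
        coefs.get("intercept", 0.0)
        + env[predictors].to_numpy() @ beta
        + noise_rng.normal(0.0, cfg.noise_sd, size=len(env))
    )
    response = pd.Series(y, index=env.index, name="response")
    truth = {"coefficients": coefs, "noise_sd": cfg.noise_sd, "predictors": predictors}
    return env, response, truth
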
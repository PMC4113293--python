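"""Multivariate dispersion: distance matrices, PCoA, centroid distances and
the permutation F-test of homogeneity of dispersion.

Beta diversity of a region is measured as the average distance of its sites
to the region centroid in the space defined by a dissimilarity measure
(Sørensen on presence/absence for community composition, standardized
Euclidean on habitat variables for habitat heterogeneity). Sørensen is
semi-metric, so the principal-coordinates embedding can carry negative
eigenvalues; distances to centroids are computed as the real-axis squared
distance minus the imaginary-axis squared distance, floored at zero
(Anderson's correction). Group dispersions are compared with a one-way
ANOVA F on the centroid distances, with significance from permuting the
least-squares residuals of the distances.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator

from .data_model import CommunityMatrix, StructuralError, ValidationError

__all__ = [
    "DistanceMatrix",
    "PCoASpace",
    "DispersionResult",
    "sorensen_matrix",
    "euclidean_std_matrix",
    "pcoa",
    "distances_to_centroid",
    "permdisp",
    "habitat_heterogeneity",
    "PermDisp",
    "HabitatHeterogeneity",
]

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-10


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric dissimilarity matrix with site labels and a metric tag."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise StructuralError("distance matrix must be square")
        if v.shape[0] != len(self.labels):
            raise StructuralError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, metric: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(df.index.astype(str)), df.to_numpy(float), metric)


@dataclasses.dataclass(frozen=True)
class PCoASpace:
    """Principal-coordinates embedding, keeping imaginary axes explicitly."""

    labels: tuple[str, ...]
    real: np.ndarray  # n x p coordinates on positive-eigenvalue axes
    imag: np.ndarray  # n x m coordinates on negative-eigenvalue axes
    eigvals_pos: np.ndarray
    eigvals_neg: np.ndarray  # negative values, descending magnitude last

    def squared_distance(self, i: int, j: int) -> float:
        """Reconstructed squared dissimilarity: real part minus imaginary part."""
        dr = float(((self.real[i] - self.real[j]) ** 2).sum())
        di = float(((self.imag[i] - self.imag[j]) ** 2).sum())
        return dr - di


@dataclasses.dataclass(frozen=True)
class DispersionResult:
    groups: tuple[str, ...]
    distances: pd.Series  # per-site distance to own-group centroid
    group_means: pd.DataFrame  # mean, se, n per group
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    n_perm: int
    seed: int | None
    permute: str


def sorensen_matrix(cm: CommunityMatrix, binary: bool = True) -> DistanceMatrix:
    """Pairwise Sørensen dissimilarity, d = 1 - 2a/(2a+b+c) on presence/absence.

    With ``binary=False`` the quantitative analogue (Bray–Curtis on counts)
    is used instead.
    """
    counts = cm.counts
    if counts.shape[0] < 2:
        raise StructuralError("need at least two sites for a dissimilarity matrix")
    empty = np.asarray(cm.site_ids)[counts.sum(axis=1) == 0]
    if empty.size:
        raise ValidationError(
            f"dissimilarity undefined for site(s) with no taxa: {empty.tolist()}"
        )
    if binary:
        d = pdist(counts > 0, metric="dice")
        tag = "sorensen"
    else:
        d = pdist(counts.astype(float), metric="braycurtis")
        tag = "bray_curtis"
    return DistanceMatrix(tuple(cm.site_ids), squareform(d), tag)


def euclidean_std_matrix(env: pd.DataFrame, variables: Sequence[str]) -> DistanceMatrix:
    """Euclidean distance on variables z-scored across *all* sites.

    Standardisation uses the sample SD (ddof=1). Z-scoring across the full
    table (not within groups) keeps between-group differences in spread,
    which is what the heterogeneity comparison measures.
    """
    missing_cols = [v for v in variables if v not in env.columns]
    if missing_cols:
        raise StructuralError(f"environment table missing column(s): {missing_cols}")
    x = env[list(variables)].astype(float)
    if x.isna().any().any():
        bad = x.columns[x.isna().any()].tolist()
        raise ValidationError(f"missing values in variable(s): {bad}")
    sd = x.std(ddof=1)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise ValidationError(f"zero-variance variable(s): {zero}")
    z = (x - x.mean()) / sd
    d = pdist(z.to_numpy(), metric="euclidean")
    return DistanceMatrix(tuple(env.index.astype(str)), squareform(d), "euclidean_std")


def pcoa(dm: DistanceMatrix) -> PCoASpace:
    """Principal-coordinates analysis with explicit imaginary axes.

    The Gower-centered matrix G = -1/2 J D^2 J is eigendecomposed; axes with
    positive eigenvalues hold real coordinates, axes with negative
    eigenvalues (expected for semi-metric input) hold imaginary-part
    coordinates. For every site pair, (real squared distance) - (imaginary
    squared distance) reconstructs the input squared dissimilarity.
    """
    d2 = dm.values**2
    n = dm.n
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    g = -0.5 * j @ d2 @ j
    g = (g + g.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = _EIG_TOL * max(1.0, float(np.abs(eigvals).max()))
    pos = eigvals > tol
    neg = eigvals < -tol
    real = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    imag = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    return PCoASpace(
        labels=dm.labels,
        real=real,
        imag=imag,
        eigvals_pos=eigvals[pos],
        eigvals_neg=eigvals[neg],
    )


def _group_codes(
    labels: Sequence[str], groups: Mapping[str, Sequence[str]]
) -> tuple[np.ndarray, list[str]]:
    """Integer group code per site (in label order); sites must be covered once."""
    assignment: dict[str, int] = {}
    names = list(groups)
    for gi, name in enumerate(names):
        for s in groups[name]:
            if s in assignment:
                raise StructuralError(f"site {s!r} assigned to multiple groups")
            assignment[str(s)] = gi
    missing = [s for s in labels if s not in assignment]
    if missing:
        raise StructuralError(f"site(s) not assigned to any group: {missing}")
    return np.array([assignment[s] for s in labels]), [str(n) for n in names]


def distances_to_centroid(
    space: PCoASpace, groups: Mapping[str, Sequence[str]]
) -> pd.Series:
    """Per-site distance to its own group centroid, with imaginary correction.

    z_j^2 = (squared distance to the centroid on real axes) - (squared
    distance on imaginary axes); negative z^2 (possible for semi-metric
    input) is floored at 0 before the square root, with a logged count.
    """
    codes, names = _group_codes(space.labels, groups)
    for gi, name in enumerate(names):
        if (codes == gi).sum() == 0:
            raise StructuralError(f"group {name!r} has no sites")
    z2 = np.empty(len(space.labels))
    for gi in range(len(names)):
        mask = codes == gi
        cr = space.real[mask].mean(axis=0) if space.real.size else np.zeros(0)
        ci = space.imag[mask].mean(axis=0) if space.imag.size else np.zeros(0)
        dr = ((space.real[mask] - cr) ** 2).sum(axis=1) if space.real.size else 0.0
        di = ((space.imag[mask] - ci) ** 2).sum(axis=1) if space.imag.size else 0.0
        z2[mask] = dr - di
    n_floored = int((z2 < 0).sum())
    if n_floored:
        logger.warning(
            "floored %d negative squared centroid distance(s) at 0", n_floored
        )
    return pd.Series(np.sqrt(np.clip(z2, 0.0, None)), index=list(space.labels), name="z")


def _anova_f(z: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way ANOVA F on values z with integer group codes."""
    n = z.size
    sizes = np.bincount(codes, minlength=n_groups).astype(float)
    sums = np.bincount(codes, weights=z, minlength=n_groups)
    means = sums / sizes
    grand = z.mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float((z**2).sum() - (sizes * means**2).sum())
    df_b, df_w = n_groups - 1, n - n_groups
    tol = 1e-12 * max(1.0, float((z**2).sum()))
    if ssw <= tol:
        return 0.0 if ssb <= tol else np.inf
    return (ssb / df_b) / (ssw / df_w)


def permdisp(
    dm: DistanceMatrix,
    groups: Mapping[str, Sequence[str]],
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    permute: str = "residuals",
) -> DispersionResult:
    """Permutation test of homogeneity of multivariate dispersion.

    Centroid distances z come from the PCoA embedding of ``dm``; the
    observed statistic is the one-way ANOVA F over groups. Under
    ``permute="residuals"`` (default) the least-squares residuals
    z_j - mean(z in own group) are randomly reassigned across all sites
    (group sizes fixed) and F recomputed on the permuted residuals; under
    ``permute="raw"`` the z values themselves are permuted. The p-value uses
    the (r+1)/(n_perm+1) convention.
    """
    if permute not in {"residuals", "raw"}:
        raise ValueError(f"unknown permutation scheme {permute!r}")
    codes, names = _group_codes(dm.labels, groups)
    n_groups = len(names)
    if n_groups < 2:
        raise StructuralError("need at least two groups")
    sizes = np.bincount(codes, minlength=n_groups)
    small = [names[i] for i in range(n_groups) if sizes[i] < 2]
    if small:
        raise StructuralError(f"group(s) with fewer than 2 sites: {small}")
    space = pcoa(dm)
    z_series = distances_to_centroid(space, groups)
    z = z_series.to_numpy()
    f_obs = _anova_f(z, codes, n_groups)

    rng = np.random.default_rng(seed)
    group_means = np.bincount(codes, weights=z, minlength=n_groups) / sizes
    base = z - group_means[codes] if permute == "residuals" else z
    perm_idx = rng.permuted(
        np.tile(np.arange(z.size), (n_perm, 1)), axis=1
    )
    permuted = base[perm_idx]  # n_perm x n
    onehot = np.zeros((z.size, n_groups))
    onehot[np.arange(z.size), codes] = 1.0
    pm = permuted @ onehot / sizes  # per-perm group means
    grand = permuted.mean(axis=1, keepdims=True)
    ssb = ((pm - grand) ** 2 * sizes).sum(axis=1)
    ssw = (permuted**2).sum(axis=1) - (pm**2 * sizes).sum(axis=1)
    df_b, df_w = n_groups - 1, z.size - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ssb / df_b) / (ssw / df_w)
    tol = 1e-12 * np.maximum(1.0, (permuted**2).sum(axis=1))
    f_perm = np.where(ssw <= tol, np.where(ssb <= tol, 0.0, np.inf), f_perm)
    p = (int((f_perm >= f_obs).sum()) + 1) / (n_perm + 1)

    se = np.array(
        [z[codes == gi].std(ddof=1) / np.sqrt(sizes[gi]) for gi in range(n_groups)]
    )
    gm = pd.DataFrame(
        {"mean": group_means, "se": se, "n": sizes.astype(int)}, index=names
    )
    return DispersionResult(
        groups=tuple(names),
        distances=z_series,
        group_means=gm,
        f_statistic=float(f_obs),
        df_between=df_b,
        df_within=df_w,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed if isinstance(seed, int) else None,
        permute=permute,
    )


def habitat_heterogeneity(
    env: pd.DataFrame,
    variables: Sequence[str],
    groups: Mapping[str, Sequence[str]],
) -> tuple[pd.Series, pd.DataFrame]:
    """Habitat heterogeneity: per-site Euclidean dispersion from the group centroid.

    Composition of :func:`euclidean_std_matrix` -> :func:`pcoa` ->
    :func:`distances_to_centroid`. Returns the per-site score and a
    per-group mean ± SE summary.
    """
    dm = euclidean_std_matrix(env, variables)
    z = distances_to_centroid(pcoa(dm), groups)
    rows = {}
    for name, sites in groups.items():
        vals = z.loc[[str(s) for s in sites]]
        rows[str(name)] = {
            "mean": float(vals.mean()),
            "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
            "n": len(vals),
        }
    return z.rename("heterogeneity"), pd.DataFrame(rows).T


class PermDisp(BaseEstimator):
    """Homogeneity-of-dispersion test as an sklearn-style estimator.

    Parameters
    ----------
    n_perm : int, default 999
    permute : {"residuals", "raw"}, default "residuals"
    random_state : int, optional

    Attributes
    ----------
    result_ : DispersionResult
    distances_ : pandas.Series           per-site distance to group centroid
    f_statistic_, p_value_ : float
    df_between_, df_within_ : int
    """

    def __init__(
        self,
        n_perm: int = 999,
        permute: str = "residuals",
        random_state: int | None = None,
    ):
        self.n_perm = n_perm
        self.permute = permute
        self.random_state = random_state

    def fit(self, dm: DistanceMatrix, groups: Mapping[str, Sequence[str]]):
        self.result_ = permdisp(
            dm, groups, n_perm=self.n_perm, seed=self.random_state, permute=self.permute
        )
        self.distances_ = self.result_.distances
        self.f_statistic_ = self.result_.f_statistic
        self.p_value_ = self.result_.p_value
        self.df_between_ = self.result_.df_between
        self.df_within_ = self.result_.df_within
        return self


class HabitatHeterogeneity(BaseEstimator):
    """Per-site habitat-heterogeneity scores from standardized habitat variables.

    Attributes
    ----------
    scores_ : pandas.Series
    group_summary_ : pandas.DataFrame (mean, se, n per group)
    """

    def __init__(self, variables: Sequence[str] | None = None):
        self.variables = variables

    def fit(self, env: pd.DataFrame, groups: Mapping[str, Sequence[str]]):
        from .data_model import HABITAT_VARIABLES

        variables = self.variables if self.variables is not None else HABITAT_VARIABLES
        self.scores_, self.group_summary_ = habitat_heterogeneity(env, variables, groups)
        return self
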
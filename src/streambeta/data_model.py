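"""Core data containers, file I/O, validation and the substrate-size index.

The central object is the :class:`CommunityMatrix`: a sites-by-taxa table of
integer abundances (individuals counted in a sample). Downstream
randomisations shuffle *individuals*, so counts are validated as exact
integers rather than silently rounded. Site metadata carries the region and
island grouping plus the in-stream habitat and catchment variables used by
the dispersion and inference stages.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "SiteMetadata",
    "StoneTally",
    "ValidationError",
    "StructuralError",
    "read_community",
    "write_community",
    "read_metadata",
    "exclude_taxa",
    "substrate_index",
    "HABITAT_VARIABLES",
]

#: The six in-stream habitat variables used for the heterogeneity score.
HABITAT_VARIABLES = (
    "depth",
    "velocity",
    "slope",
    "canopy",
    "substrate_index",
    "macrophytes",
)

PERCENT_VARIABLES = ("canopy", "macrophytes", "steepness")


class StructuralError(ValueError):
    """Malformed input structure (duplicate labels, empty tables)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


class CommunityMatrix:
    """Site-by-taxon abundance matrix with non-negative integer counts.

    Parameters
    ----------
    data:
        DataFrame indexed by site label with one column per taxon. Values
        must be non-negative and exactly integral.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise StructuralError("community matrix needs at least one site and one taxon")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise StructuralError(f"duplicate site id(s): {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise StructuralError(f"duplicate taxon id(s): {dups}")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("community matrix body must be numeric")
        if np.isnan(values.astype(float)).any():
            r, c = np.argwhere(np.isnan(values.astype(float)))[0]
            raise ValidationError(
                f"missing count at site {data.index[r]!r}, taxon {data.columns[c]!r}"
            )
        rounded = np.rint(values.astype(float))
        if not np.allclose(values.astype(float), rounded, rtol=0, atol=0):
            r, c = np.argwhere(values.astype(float) != rounded)[0]
            raise ValidationError(
                f"non-integral count at site {data.index[r]!r}, taxon {data.columns[c]!r}: "
                f"{values[r, c]!r}"
            )
        if (rounded < 0).any():
            r, c = np.argwhere(rounded < 0)[0]
            raise ValidationError(
                f"negative count at site {data.index[r]!r}, taxon {data.columns[c]!r}"
            )
        self._data = pd.DataFrame(
            rounded.astype(np.int64), index=data.index.astype(str), columns=data.columns.astype(str)
        )
        self._data.index.name = "site_id"

    # ------------------------------------------------------------------ views
    @property
    def data(self) -> pd.DataFrame:
        """The validated counts table (int64, sites in rows)."""
        return self._data

    @property
    def site_ids(self) -> list[str]:
        return self._data.index.tolist()

    @property
    def taxon_ids(self) -> list[str]:
        return self._data.columns.tolist()

    @property
    def counts(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def subset_sites(self, sites: Sequence[str]) -> "CommunityMatrix":
        missing = [s for s in sites if s not in self._data.index]
        if missing:
            raise StructuralError(f"unknown site id(s): {missing}")
        return CommunityMatrix(self._data.loc[list(sites)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityMatrix):
            return NotImplemented
        return self._data.equals(other._data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, s = self.shape
        return f"CommunityMatrix({n} sites x {s} taxa, {int(self.counts.sum())} individuals)"


@dataclasses.dataclass
class SiteMetadata:
    """Per-site environment table with region/island grouping.

    ``table`` is indexed by ``site_id`` and must contain ``region`` and
    ``island`` columns; habitat and catchment variables use the canonical
    names in :data:`HABITAT_VARIABLES` plus ``chl_a``, ``pfankuch_bottom``,
    ``steepness`` and optionally ``pet``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name != "site_id":
            if "site_id" in t.columns:
                t = t.set_index("site_id")
            else:
                t = t.copy()
                t.index.name = "site_id"
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise StructuralError(f"duplicate site id(s) in metadata: {dups}")
        for col in ("region", "island"):
            if col not in t.columns:
                raise StructuralError(f"metadata missing mandatory column {col!r}")
        # each region maps to exactly one island
        mapping = t.groupby("region")["island"].nunique()
        bad = mapping[mapping > 1].index.tolist()
        if bad:
            raise ValidationError(f"region(s) mapped to multiple islands: {bad}")
        for col in PERCENT_VARIABLES:
            if col in t.columns:
                vals = t[col].dropna()
                if ((vals < 0) | (vals > 100)).any():
                    raise ValidationError(f"{col!r} outside [0, 100]")
        if "chl_a" in t.columns and (t["chl_a"].dropna() < 0).any():
            raise ValidationError("chl_a must be non-negative")
        self.table = pd.DataFrame(t)
        self.table.index = self.table.index.astype(str)

    @property
    def site_ids(self) -> list[str]:
        return self.table.index.tolist()

    def regions(self) -> dict[str, list[str]]:
        """Map region label -> ordered list of its site ids."""
        return {str(r): g.index.tolist() for r, g in self.table.groupby("region", sort=False)}

    def islands(self) -> dict[str, list[str]]:
        return {str(r): g.index.tolist() for r, g in self.table.groupby("island", sort=False)}

    def check_sites(self, cm: CommunityMatrix) -> None:
        """Every metadata site must exist exactly once in the community matrix."""
        missing = [s for s in self.site_ids if s not in cm.data.index]
        if missing:
            raise StructuralError(f"metadata site(s) absent from community matrix: {missing}")


@dataclasses.dataclass(frozen=True)
class StoneTally:
    """Stone counts per substrate size class; bedrock is assigned 400 mm."""

    class_midpoints: tuple[float, ...]
    class_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        mids = np.asarray(self.class_midpoints, dtype=float)
        counts = np.asarray(self.class_counts)
        if mids.shape != counts.shape:
            raise StructuralError("midpoints and counts must have equal length")
        if (mids <= 0).any():
            raise ValidationError("size-class midpoints must be strictly positive")
        if (counts < 0).any():
            raise ValidationError("stone counts must be non-negative")
        if counts.sum() <= 0:
            raise ValidationError("stone tally is empty (zero total stones)")


# --------------------------------------------------------------------- I/O


def read_community(path: str | Path, dialect: str | None = None) -> CommunityMatrix:
    """Read a community matrix from a delimited text file.

    First column holds site ids, the header row taxon ids. ``dialect`` is a
    delimiter override; by default ``.tsv`` files are tab-separated and
    everything else comma-separated.
    """
    path = Path(path)
    sep = dialect or ("\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ",")
    raw = pd.read_csv(path, sep=sep, index_col=0)
    return CommunityMatrix(raw)


def write_community(cm: CommunityMatrix, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    sep = dialect or ("\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ",")
    cm.data.to_csv(path, sep=sep)


def read_metadata(path: str | Path) -> SiteMetadata:
    """Read a TSV site-metadata table (mandatory columns site_id, region, island)."""
    raw = pd.read_csv(path, sep="\t")
    if "site_id" not in raw.columns:
        raise StructuralError("metadata file missing 'site_id' column")
    raw["site_id"] = raw["site_id"].astype(str)
    return SiteMetadata(raw.set_index("site_id"))


# ---------------------------------------------------------------- filtering


def exclude_taxa(
    cm: CommunityMatrix,
    exclusion: Iterable[str] | None = None,
    prefix: str | None = None,
    drop_empty: bool = False,
) -> CommunityMatrix:
    """Drop taxa by explicit label list and/or label prefix.

    Labels absent from the matrix are ignored. With ``drop_empty`` the taxa
    whose remaining counts are all zero are dropped as well; by default they
    are retained.
    """
    labels = set(exclusion or ())
    keep = [
        t
        for t in cm.taxon_ids
        if t not in labels and not (prefix is not None and t.startswith(prefix))
    ]
    if not keep:
        raise StructuralError("exclusion would remove every taxon")
    out = cm.data[keep]
    if drop_empty:
        nonzero = out.columns[(out != 0).any(axis=0)]
        if len(nonzero) == 0:
            raise StructuralError("drop_empty would remove every taxon")
        out = out[nonzero]
    return CommunityMatrix(out)


# ------------------------------------------------------------ substrate index


def substrate_index(tally: StoneTally, mode: str = "weighted_mean") -> float:
    """Substrate-size index from a stone tally.

    ``weighted_mean`` (default): sum(n_k * mid_k) / sum(n_k), a scale-free
    average particle size in mm, robust to unequal tally sizes.
    ``weighted_sum``: sum(n_k * mid_k), the literal count-weighted sum; with
    a fixed 100-stone protocol the two differ only by a constant factor.
    """
    mids = np.asarray(tally.class_midpoints, dtype=float)
    counts = np.asarray(tally.class_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("stone tally is empty (zero total stones)")
    weighted = float(np.dot(counts, mids))
    if mode == "weighted_mean":
        return weighted / total
    if mode == "weighted_sum":
        return weighted
    raise ValueError(f"unknown substrate_index mode {mode!r}")


def region_island_map(metadata: SiteMetadata) -> Mapping[str, str]:
    """Region label -> island label (validated one-to-one in SiteMetadata)."""
    return {
        str(r): str(v.iloc[0]) for r, v in metadata.table.groupby("region")["island"]
    }
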
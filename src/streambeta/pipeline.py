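"""End-to-end orchestration of the beta-diversity analysis pipeline.

Stages: taxon filtering -> diversity partitioning -> beta-deviation null
model -> occupancy/modality -> dispersion tests (region and island
groupings) -> habitat heterogeneity -> univariate regressions ->
all-subsets AICc model selection. Every stage writes a TSV (tables) or JSON
(test summaries), and a run manifest records the configuration hash, seed
and package version so runs are reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    HABITAT_VARIABLES,
    CommunityMatrix,
    SiteMetadata,
    StructuralError,
    exclude_taxa,
    read_community,
    read_metadata,
)
from .diversity import BetaPartitioner
from .null_model import BetaDeviation
from .occupancy import OccupancyModality, count_low_occupancy
from .dispersion import PermDisp, HabitatHeterogeneity, sorensen_matrix
from .inference import model_select, ols_fit

logger = logging.getLogger(__name__)

DEFAULT_PREDICTORS = ("heterogeneity", "chl_a", "pfankuch_bottom", "steepness")


@dataclasses.dataclass
class PipelineConfig:
    """Configuration for a full pipeline run (see the CLI ``run`` command)."""

    community_path: str
    metadata_path: str
    output_dir: str
    seed: int
    taxon_exclusions: Sequence[str] = ()
    taxon_exclusion_prefix: str | None = None
    orders: Sequence[int] = (0, 1)
    alpha_mode: str = "arithmetic"
    n_iter: int = 999
    occupancy_class_width: float = 0.05
    low_occupancy_threshold: float = 0.2
    n_perm: int = 999
    permute: str = "residuals"
    heterogeneity_variables: Sequence[str] = HABITAT_VARIABLES
    predictors: Sequence[str] = DEFAULT_PREDICTORS
    unit: str = "site"  # or "region": aggregate to region means before regression

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise StructuralError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(
    config: PipelineConfig,
    cm: CommunityMatrix | None = None,
    metadata: SiteMetadata | None = None,
) -> dict[str, Any]:
    """Execute every stage and write the result bundle to ``output_dir``.

    ``cm``/``metadata`` may be passed in-memory (e.g. straight from the
    synthetic generator); otherwise they are read from the configured paths.
    Returns a dict of in-memory stage results keyed by stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if cm is None:
            cm = read_community(config.community_path)
        if metadata is None:
            metadata = read_metadata(config.metadata_path)
        metadata.check_sites(cm)
        missing = [
            v for v in config.heterogeneity_variables if v not in metadata.table.columns
        ]
        if missing:
            raise StructuralError(f"metadata missing heterogeneity column(s): {missing}")
        regions = metadata.regions()
        islands = metadata.islands()
        results: dict[str, Any] = {}

        stage = "filter"
        if config.taxon_exclusions or config.taxon_exclusion_prefix:
            cm = exclude_taxa(
                cm, config.taxon_exclusions, prefix=config.taxon_exclusion_prefix
            )
        cm = cm.subset_sites(metadata.site_ids)

        stage = "divpart"
        seed_seq = np.random.SeedSequence(config.seed)
        sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(3)]
        parts = []
        for q in config.orders:
            part = BetaPartitioner(q=q, alpha_mode=config.alpha_mode).fit(cm, regions)
            parts.append(part.summary_)
        results["divpart"] = pd.concat(parts, ignore_index=True)
        _write_tsv(results["divpart"], out / "divpart.tsv")

        stage = "betadev"
        devs = []
        for q in config.orders:
            bd = BetaDeviation(
                q=q,
                alpha_mode=config.alpha_mode,
                n_iter=config.n_iter,
                random_state=sub_seeds[0] + q,
            ).fit(cm, regions)
            devs.append(bd.summary_)
        results["beta_deviation"] = pd.concat(devs, ignore_index=True)
        _write_tsv(results["beta_deviation"], out / "beta_deviation.tsv")

        stage = "occupancy"
        occ = OccupancyModality(class_width=config.occupancy_class_width).fit(cm, islands)
        results["occupancy"] = occ
        occ_rows = []
        for name, dist in occ.distributions_.items():
            for edge_lo, edge_hi, count in zip(
                dist.class_edges[:-1], dist.class_edges[1:], dist.class_counts
            ):
                occ_rows.append(
                    {"group": name, "class_low": edge_lo, "class_high": edge_hi, "n_taxa": count}
                )
        _write_tsv(pd.DataFrame(occ_rows).set_index("group"), out / "occupancy_classes.tsv")
        occ_json = {
            name: {
                **dataclasses.asdict(t),
                "n_low_occupancy": count_low_occupancy(
                    occ.distributions_[name], config.low_occupancy_threshold
                ),
            }
            for name, t in occ.tests_.items()
        }
        _write_json(occ_json, out / "occupancy_tests.json")

        stage = "permdisp"
        dm = sorensen_matrix(cm)
        results["permdisp_region"] = PermDisp(
            n_perm=config.n_perm, permute=config.permute, random_state=sub_seeds[1]
        ).fit(dm, regions)
        results["permdisp_island"] = PermDisp(
            n_perm=config.n_perm, permute=config.permute, random_state=sub_seeds[2]
        ).fit(dm, islands)
        for tag in ("region", "island"):
            res = results[f"permdisp_{tag}"].result_
            _write_tsv(res.distances.to_frame(), out / f"permdisp_{tag}_distances.tsv")
            _write_json(
                {
                    "F": res.f_statistic,
                    "df_between": res.df_between,
                    "df_within": res.df_within,
                    "p_value": res.p_value,
                    "n_perm": res.n_perm,
                    "permute": res.permute,
                    "seed": res.seed,
                    "group_means": res.group_means.to_dict(orient="index"),
                },
                out / f"permdisp_{tag}.json",
            )

        stage = "heterogeneity"
        het = HabitatHeterogeneity(variables=config.heterogeneity_variables).fit(
            metadata.table, regions
        )
        results["heterogeneity"] = het
        _write_tsv(het.scores_.to_frame(), out / "heterogeneity.tsv")

        stage = "inference"
        beta_d = results["permdisp_region"].distances_
        env = metadata.table.copy()
        env["heterogeneity"] = het.scores_
        frame = env.loc[beta_d.index].copy()
        frame["beta_d"] = beta_d
        if config.unit == "region":
            frame = frame.groupby("region", sort=False).mean(numeric_only=True)
        elif config.unit != "site":
            raise StructuralError(f"unknown analysis unit {config.unit!r}")
        uni_rows = []
        for pred in config.predictors:
            if pred not in frame.columns:
                raise StructuralError(f"predictor {pred!r} absent from metadata")
            fit = ols_fit(frame["beta_d"], frame[pred], predictors=[pred])
            uni_rows.append(
                {
                    "predictor": pred,
                    "slope": fit.coefficients[pred],
                    "intercept": fit.coefficients["intercept"],
                    "r2": fit.r2,
                    "adjusted_r2": fit.adjusted_r2,
                    "p_value": fit.slope_p_values[pred],
                    "n": fit.n,
                }
            )
        results["univariate"] = pd.DataFrame(uni_rows).set_index("predictor")
        _write_tsv(results["univariate"], out / "univariate.tsv")

        table = model_select(
            frame["beta_d"],
            frame,
            list(config.predictors),
            skip_infeasible=config.unit == "region",
        )
        results["model_table"] = table
        _write_tsv(table.table, out / "model_table.tsv")
        _write_json(
            {
                "predictor_importance": dict(table.predictor_importance),
                "best_model": {
                    "subset": list(table.fits[0].predictors),
                    "coefficients": dict(table.fits[0].coefficients),
                    "aicc": table.fits[0].aicc,
                    "weight": table.fits[0].akaike_weight,
                    "adjusted_r2": table.fits[0].adjusted_r2,
                },
                "n_top_models": len(table.top_models),
            },
            out / "model_selection.json",
        )

        stage = "manifest"
        _write_json(
            {
                "package": "streambeta",
                "version": __version__,
                "seed": config.seed,
                "config_hash": config.digest(),
                "config": dataclasses.asdict(config),
                "n_sites": cm.shape[0],
                "n_taxa": cm.shape[1],
            },
            out / "manifest.json",
        )
        return results
    except Exception as exc:
        exc.add_note(f"pipeline aborted at stage {stage!r}")
        raise
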
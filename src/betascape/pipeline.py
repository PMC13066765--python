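"""End-to-end orchestration: simulate -> design -> metrics -> beta ->
endemism -> model, with manifests and a human-readable summary report.

Each stage reads delimited-text tables written by earlier stages into the run
directory, writes its own table plus a ``<stage>.manifest.json`` (input
hashes, derived seed), and the whole chain is reproducible under the master
seed.  Thresholds default to the study protocol: effort >= 0.10 ha, DBH
cutoff >= 5 cm, >= 2 inventories per landscape, correlation screen at
r = 0.70, best-model set at delta AIC <= 2.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beta as beta_mod
from . import design as design_mod
from . import endemism as endemism_mod
from . import metrics as metrics_mod
from . import stats as stats_mod
from .errors import ConfigurationError, DataError
from .rasters import read_ascii_grid
from .synthetic import CLIMATE_VARIABLES, SimulationConfig, generate_study, write_study

log = logging.getLogger("betascape")

STAGES = ("simulate", "design", "metrics", "beta", "endemism", "model")

RESPONSES = ("beta_total", "rc_rescaled", "endemism")

PREDICTORS = (
    "habitat_cover",
    "n_patches",
    "mean_patch_size",
    "enn_mn",
    "mean_spatial_distance",
    "temperature",
    "temperature_seasonality",
    "precipitation",
    "precipitation_seasonality",
)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: tuple[str, ...] = STAGES
    n_reps: int = 999
    min_effort: float = 0.10
    min_dbh: float = 5.0
    min_inventories: int = 2
    r_threshold: float = 0.70
    delta_aic: float = 2.0
    connectivity: int = 8
    interaction: tuple[str, str] | None = ("habitat_cover", "n_patches")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        sim = raw.pop("simulation", {})
        cfg = cls(simulation=SimulationConfig.from_dict(sim), **{
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        })
        return cfg

    def stage_seed(self, stage: str) -> int:
        return int(
            np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
            .generate_state(1)[0]
        )


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _manifest(outdir: Path, stage: str, inputs: list[Path], seed: int | None) -> None:
    payload = {
        "stage": stage,
        "seed": seed,
        "inputs": {p.name: _hash_file(p) for p in inputs if p.exists()},
    }
    (outdir / f"{stage}.manifest.json").write_text(json.dumps(payload, indent=2))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute enabled stages in order; outputs accumulate under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("[%s] starting", stage)
        _RUNNERS[stage](config, outdir)
        log.info("[%s] done", stage)
    return outdir


def _run_simulate(config: PipelineConfig, outdir: Path) -> None:
    sim = config.simulation
    study = generate_study(sim)
    write_study(study, outdir)
    _manifest(outdir, "simulate", [], sim.seed)


def _run_design(config: PipelineConfig, outdir: Path) -> None:
    inventories = design_mod.read_inventories(outdir / "inventories.csv")
    abundances = design_mod.read_abundances(outdir / "abundances.csv")
    kept, dropped = design_mod.filter_inventories(
        inventories, abundances, config.min_effort, config.min_dbh
    )
    grid = design_mod.HexGrid(cell_area=config.simulation.landscape_area)
    units = design_mod.assign_landscapes(kept, grid, config.min_inventories)
    table = design_mod.membership_table(units)
    table.to_csv(outdir / "landscapes.csv", index=False)
    dropped.to_csv(outdir / "dropped.csv", index=False)
    _manifest(outdir, "design", [outdir / "inventories.csv"], None)


def _load_membership(outdir: Path) -> pd.DataFrame:
    path = outdir / "landscapes.csv"
    if not path.exists():
        raise DataError("design stage output missing (landscapes.csv)")
    return pd.read_csv(path)


def _raster_for(outdir: Path, source_id: str):
    rdir = outdir / "rasters"
    hits = sorted(rdir.glob(f"{source_id}*.asc"))
    if not hits:
        raise DataError(f"no raster found for landscape source {source_id!r}")
    return [read_ascii_grid(p) for p in hits]


def _run_metrics(config: PipelineConfig, outdir: Path) -> None:
    membership = _load_membership(outdir)
    inventories = design_mod.read_inventories(outdir / "inventories.csv")
    climate = pd.read_csv(outdir / "climate.csv")
    grid = design_mod.HexGrid(cell_area=config.simulation.landscape_area)
    merged = membership.merge(
        inventories, on="inventory_id", suffixes=("", "_true")
    )
    records = []
    for lid, grp in merged.groupby("landscape_id", sort=True):
        coords = grp[["x", "y"]].to_numpy(dtype=float)
        q, r = (int(v) for v in lid[1:].split("_"))
        polygon = grid.polygon(q, r)
        # synthetic rasters are stored under the generating landscape id
        source = grp["inventory_id"].iloc[0].split("-")[0]
        rasters = _raster_for(outdir, source)
        raster = metrics_mod.reference_raster(rasters, int(grp["reference_year"].iloc[0]))
        records.append(
            metrics_mod.landscape_metrics(
                lid, raster, polygon, coords, config.connectivity
            )
        )
    table = metrics_mod.metrics_table(records)
    # climate is tabulated per generating landscape; join through the source id
    src = (
        merged.groupby("landscape_id", sort=True)["inventory_id"]
        .first()
        .str.split("-")
        .str[0]
        .rename("source_id")
        .reset_index()
    )
    climate = src.merge(climate, left_on="source_id", right_on="landscape_id",
                        suffixes=("", "_src")).drop(columns=["source_id", "landscape_id_src"])
    table = table.merge(climate, on="landscape_id")
    table.to_csv(outdir / "metrics.csv", index=False)
    _manifest(outdir, "metrics", [outdir / "landscapes.csv"], None)


def _run_beta(config: PipelineConfig, outdir: Path) -> None:
    membership = _load_membership(outdir)
    abundances = design_mod.read_abundances(outdir / "abundances.csv")
    seed = config.stage_seed("beta")
    table = beta_mod.beta_table(abundances, membership, config.n_reps, seed)
    table.to_csv(outdir / "beta.csv", index=False)
    _manifest(outdir, "beta", [outdir / "abundances.csv"], seed)


def _run_endemism(config: PipelineConfig, outdir: Path) -> None:
    membership = _load_membership(outdir)
    abundances = design_mod.read_abundances(outdir / "abundances.csv")
    species = pd.read_csv(outdir / "species.csv")
    used = abundances.loc[membership["inventory_id"]]
    per_comm, per_land = endemism_mod.endemism_tables(used, species, membership)
    per_comm.to_csv(outdir / "endemism_communities.csv", index=False)
    per_land.to_csv(outdir / "endemism.csv", index=False)
    _manifest(outdir, "endemism", [outdir / "abundances.csv"], None)


def merged_landscape_table(outdir: Path) -> pd.DataFrame:
    """Join metrics, beta, and endemism stage outputs into one row per landscape."""
    parts = []
    for name in ("metrics", "beta", "endemism"):
        path = outdir / f"{name}.csv"
        if not path.exists():
            raise DataError(f"stage output missing: {path.name}")
        parts.append(pd.read_csv(path))
    table = parts[0].merge(parts[1], on="landscape_id").merge(parts[2], on="landscape_id")
    return table


def model_responses(
    table: pd.DataFrame,
    responses: tuple[str, ...] = RESPONSES,
    r_threshold: float = 0.70,
    interaction: tuple[str, str] | None = ("habitat_cover", "n_patches"),
) -> dict[str, object]:
    """Screen predictors, run PCA, and fit all-subsets selections per response.

    Rows with missing values for retained predictors are dropped (logged).
    Beta-family responses are squeezed off the [0, 1] boundaries first.
    """
    predictors = table[[c for c in PREDICTORS if c in table.columns]]
    screen = stats_mod.pearson_screen(
        predictors.dropna(), threshold=r_threshold,
        drop_priority=("mean_patch_size",),
    )
    retained = screen.retained
    use = table[["landscape_id", *retained, *[r for r in responses if r in table.columns]]]
    n_before = len(use)
    use = use.dropna()
    if len(use) < n_before:
        log.info("dropped %d landscapes with missing predictor values", n_before - len(use))
    Z = stats_mod.standardize(use[retained])
    pca_result = stats_mod.pca(use[retained])
    selections = {}
    for resp in responses:
        if resp not in use.columns:
            continue
        y = use[resp].to_numpy(dtype=float)
        if resp in ("beta_total", "rc_rescaled"):
            family = "beta_logit"
            y = stats_mod.squeeze_unit_interval(y)
        else:
            family = "gaussian"
        inter = interaction if interaction and all(t in retained for t in interaction) else None
        selections[resp] = stats_mod.all_subsets(y, Z, family=family, interaction=inter)
    return {
        "screen": screen,
        "pca": pca_result,
        "selections": selections,
        "table": use,
        "standardized": Z,
    }


def _run_model(config: PipelineConfig, outdir: Path) -> None:
    table = merged_landscape_table(outdir)
    result = model_responses(
        table, RESPONSES, config.r_threshold, config.interaction
    )
    screen: stats_mod.ScreenReport = result["screen"]
    screen.correlations.to_csv(outdir / "screen_correlations.csv")
    pd.DataFrame(
        screen.dropped, columns=["dropped", "partner", "r"]
    ).to_csv(outdir / "screen_dropped.csv", index=False)
    pca_result: stats_mod.PCAResult = result["pca"]
    pca_result.loadings.assign().to_csv(outdir / "pca_loadings.csv")
    pd.DataFrame(
        {"axis": [f"PC{i+1}" for i in range(len(pca_result.variance_explained))],
         "variance_pct": pca_result.variance_explained}
    ).to_csv(outdir / "pca_variance.csv", index=False)
    use = result["table"]
    coords = None
    truth_path = outdir / "truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
        src = use["landscape_id"]
        # landscape ids from design are hex ids; map through inventories
        inv = design_mod.read_inventories(outdir / "inventories.csv")
        memb = _load_membership(outdir)
        cent = (
            memb.merge(inv, on="inventory_id", suffixes=("", "_true"))
            .groupby("landscape_id")[["x", "y"]]
            .mean()
        )
        coords = cent.loc[src].to_numpy(dtype=float)
    diag_rows = []
    for resp, sel in result["selections"].items():
        report = stats_mod.selection_report(sel)
        report.to_csv(outdir / f"selection_{resp}.csv", index=False)
        sel.rows.to_csv(outdir / f"selection_{resp}_full.csv", index=False)
        best = sel.fits[0]
        if len(best.terms) >= 2:
            main_terms = [t for t in best.terms if ":" not in t]
            if len(main_terms) >= 2:
                for term, v in stats_mod.vif(result["standardized"][main_terms]).items():
                    diag_rows.append({"response": resp, "diagnostic": "vif",
                                      "term": term, "value": v, "p": np.nan})
        if coords is not None and len(coords) >= 5:
            mi = stats_mod.morans_i(best.residuals, coords)
            diag_rows.append({"response": resp, "diagnostic": "morans_i", "term": "",
                              "value": mi.statistic, "p": mi.pvalue})
        elif coords is not None:
            log.warning("skipping Moran's I for %s: fewer than 5 landscapes", resp)
    pd.DataFrame(diag_rows).to_csv(outdir / "diagnostics.csv", index=False)
    _manifest(outdir, "model", [outdir / "metrics.csv", outdir / "beta.csv",
                                outdir / "endemism.csv"], None)


_RUNNERS = {
    "simulate": _run_simulate,
    "design": _run_design,
    "metrics": _run_metrics,
    "beta": _run_beta,
    "endemism": _run_endemism,
    "model": _run_model,
}


def mean_inventories_per_landscape(n_inventories: int, n_landscapes: int) -> float:
    """Mean inventories per landscape, reported to two decimals."""
    if n_landscapes <= 0:
        raise DataError("n_landscapes must be positive")
    return round(n_inventories / n_landscapes, 2)


def summarize_run(outdir: str | Path, config: PipelineConfig | None = None) -> str:
    """Human-readable report over a completed run directory."""
    outdir = Path(outdir)
    missing = [
        name for name in ("landscapes.csv", "metrics.csv", "beta.csv", "endemism.csv")
        if not (outdir / name).exists()
    ]
    if missing:
        raise DataError(f"run is incomplete; missing outputs: {missing}")
    membership = pd.read_csv(outdir / "landscapes.csv")
    metrics = pd.read_csv(outdir / "metrics.csv")
    sizes = membership.groupby("landscape_id").size()
    n_land = len(sizes)
    n_inv = int(sizes.sum())
    lines = [
        "betascape run summary",
        "=====================",
        f"landscapes: {n_land}",
        f"inventories: {n_inv}",
        f"inventories per landscape: mean {mean_inventories_per_landscape(n_inv, n_land):.2f}, "
        f"min {int(sizes.min())}, max {int(sizes.max())}",
        f"habitat cover range: {metrics['habitat_cover'].min():.1f}% - "
        f"{metrics['habitat_cover'].max():.1f}%",
    ]
    if config is not None:
        lines.append(
            f"thresholds: effort >= {config.min_effort} ha, dbh >= {config.min_dbh} cm, "
            f"r <= {config.r_threshold}, delta AIC <= {config.delta_aic}, "
            f"min inventories {config.min_inventories}; master seed {config.seed}"
        )
    for resp in RESPONSES:
        path = outdir / f"selection_{resp}.csv"
        if path.exists():
            report = pd.read_csv(path)
            lines.append("")
            lines.append(f"best models for {resp} (delta AIC <= 2):")
            if report.empty:
                lines.append("  (intercept-only model selected)")
            else:
                for rank, grp in report.groupby("rank"):
                    head = grp.iloc[0]
                    lines.append(
                        f"  model {rank}: AIC {head['aic']:.2f}, dAIC {head['delta_aic']:.2f}, "
                        f"R2 {head['r2']:.2f}"
                    )
                    for _, row in grp.iterrows():
                        lines.append(
                            f"    {row['term']}: effect {row['effect']:+.2f}, p {row['p']:.4f}"
                        )
    return "\n".join(lines) + "\n"
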
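"""End-to-end experiment: areas x designs x sizes x iterations -> metrics -> trends.

The experiment emulates a meso-scale sampling-design study: many 5x5 km
elevation-like areas are generated with heterogeneity (SD) drawn from a
configured range, each is sampled with regular lattices at several
sample sizes (several randomized-offset iterations per size), samples
are interpolated back onto the population grid with IDW, and each sample
and interpolation is scored (KS representativeness; correlation and RMSE
for interpolations).  Iteration means feed trend smooths and
conditional-inference trees over sample size and SD.

Seeding: per-area seeds are spawned from ``master_seed`` through
``numpy.random.SeedSequence`` (area i uses child i), so the run is
deterministic end to end and any area can be recomputed independently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .interpolate import IdwConfig, idw_grid
from .metrics import METRIC_COLUMNS, MetricRecord, score
from .sampling import SampleDesign, extract_values, rapeld_design, regular_lattice
from .terrain import Raster, TerrainSpec, make_gaussian_field
from .thresholds import SmoothFit, TreeNode, fit_ctree, fit_smooth

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "evaluate_area",
    "evaluate_rapeld",
    "evaluate_design",
    "run_experiment",
]

log = logging.getLogger("gridrep")

#: default sizes of the simulated regular designs
DEFAULT_SIZES = (4, 8, 16, 30, 60, 120)

#: responses fitted with smooths and trees on the mean table
RESPONSES = (
    ("sample", "ks_p"),
    ("interpolation", "ks_p"),
    ("interpolation", "pearson_r"),
    ("interpolation", "rmse"),
)


@dataclass
class ExperimentConfig:
    """Configuration of a full simulation experiment.

    ``sd_range`` is the uniform range the per-area surface SD is drawn
    from; the default (1, 56) spans the heterogeneity band that covers
    95% of the legal Brazilian Amazon.  ``terrain`` is the template for
    each area (its ``target_sd`` and ``seed`` are overridden per area).
    """

    n_areas: int = 50
    terrain: TerrainSpec = field(default_factory=TerrainSpec)
    sd_range: tuple[float, float] = (1.0, 56.0)
    long_tailed_fraction: float = 0.0
    sizes: tuple[int, ...] = DEFAULT_SIZES
    iterations: int = 10
    idw: IdwConfig = field(default_factory=IdwConfig)
    alpha: float = 0.05
    permutations: int = 999
    min_node: int = 20
    master_seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_areas < 1:
            raise ValueError("n_areas must be >= 1")
        if not self.sizes or any(s < 1 for s in self.sizes):
            raise ValueError("sizes must be non-empty positive integers")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        lo, hi = self.sd_range
        if lo < 0 or hi < lo:
            raise ValueError("sd_range must satisfy 0 <= lo <= hi")
        if not 0.0 <= self.long_tailed_fraction <= 1.0:
            raise ValueError("long_tailed_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "terrain" in raw:
            raw["terrain"] = TerrainSpec(**raw["terrain"])
        if "idw" in raw:
            raw["idw"] = IdwConfig(**raw["idw"])
        for key in ("sd_range", "sizes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["terrain"] = dataclasses.asdict(self.terrain)
        d["idw"] = dataclasses.asdict(self.idw)
        return d


@dataclass
class ExperimentResult:
    """Raw and mean metric tables plus fitted trends and trees."""

    raw: pd.DataFrame
    means: pd.DataFrame
    smooths: dict[str, SmoothFit]
    trees: dict[str, TreeNode]
    skipped_areas: list[str] = field(default_factory=list)


def _records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records], columns=METRIC_COLUMNS)


def evaluate_design(
    raster: Raster,
    design: SampleDesign,
    idw: IdwConfig = IdwConfig(),
    area_id: str = "",
    sample_size: int | None = None,
    iteration: int = 0,
) -> list[MetricRecord]:
    """Score one design on one raster: a sample row and an interpolation row."""
    sv = extract_values(raster, design, area_id=area_id)
    n = sample_size if sample_size is not None else design.n
    rec_s = score(sv, raster, area_id=area_id, sample_size=n, iteration=iteration)
    surf = idw_grid(sv, raster, idw)
    rec_i = score(surf, raster, area_id=area_id, sample_size=n, iteration=iteration)
    return [rec_s, rec_i]


def evaluate_area(
    raster: Raster,
    sizes=DEFAULT_SIZES,
    iterations: int = 10,
    idw: IdwConfig = IdwConfig(),
    rng: np.random.Generator | int | None = None,
    area_id: str = "area",
) -> list[MetricRecord]:
    """Evaluate one area across sizes and randomized-offset iterations.

    Emits 2 rows (sample + interpolation) per (size, iteration).
    """
    rng = np.random.default_rng(rng)
    records: list[MetricRecord] = []
    for size in sizes:
        for it in range(iterations):
            design = regular_lattice((raster.width, raster.height), size, rng)
            records.extend(
                evaluate_design(
                    raster, design, idw, area_id=area_id, sample_size=size,
                    iteration=it,
                )
            )
    return records


def evaluate_rapeld(
    raster: Raster, idw: IdwConfig = IdwConfig(), area_id: str = "rapeld"
) -> list[MetricRecord]:
    """Deterministic evaluation of the standard RAPELD 30-plot grid."""
    return evaluate_design(raster, rapeld_design(raster), idw, area_id=area_id)


def mean_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-(area, size, source) means over iterations.

    ``pearson_r`` means ignore NaN only when *all* iterations are NaN is
    the mean NaN; partial NaN rows are averaged over defined iterations.
    ``area_sd`` is constant within a group and carried through.
    """
    grouped = (
        raw.groupby(["area_id", "sample_size", "source"], as_index=False)
        .agg(
            ks_D=("ks_D", "mean"),
            ks_p=("ks_p", "mean"),
            pearson_r=("pearson_r", "mean"),
            rmse=("rmse", "mean"),
            area_sd=("area_sd", "first"),
            n_iterations=("iteration", "size"),
        )
    )
    return grouped


def fit_trends(
    means: pd.DataFrame,
    alpha: float = 0.05,
    permutations: int = 999,
    min_node: int = 20,
    rng: np.random.Generator | int | None = None,
) -> tuple[dict[str, SmoothFit], dict[str, TreeNode]]:
    """Fit the four trend smooths and trees on a mean table.

    Responses: sample KS p; interpolation KS p, correlation and RMSE —
    each modeled against sample_size + sd.  Rows with undefined
    (NaN) correlation are excluded listwise from that response's fits.
    """
    rng = np.random.default_rng(rng)
    smooths: dict[str, SmoothFit] = {}
    trees: dict[str, TreeNode] = {}
    for source, metric in RESPONSES:
        key = f"{source}_{metric}"
        sub = means[means["source"] == source]
        x = sub[["sample_size", "area_sd"]].rename(columns={"area_sd": "sd"})
        y = sub[metric].to_numpy(dtype=float)
        try:
            smooths[key] = fit_smooth(x, y, response_name=key)
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.warning("smooth for %s not fitted: %s", key, exc)
        trees[key] = fit_ctree(
            x, y, alpha=alpha, permutations=permutations, min_node=min_node, rng=rng
        )
    return smooths, trees


def _area_terrain_spec(
    template: TerrainSpec, sd: float, seed: int, long_tailed: bool
) -> TerrainSpec:
    return dataclasses.replace(
        template,
        target_sd=float(sd),
        seed=int(seed),
        tail="long_tailed" if long_tailed else template.tail,
    )


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full experiment defined by ``config``.

    Generates ``n_areas`` synthetic areas (SD drawn uniformly from
    ``sd_range``), evaluates each across sizes and iterations, builds
    the raw and mean tables, then fits trend smooths and trees on the
    mean rows.  If ``output_dir`` is set, tables, trees, smooth bands,
    plots and a run manifest are written there (partial tables are
    flushed per area).
    """
    t0 = time.time()
    out = Path(config.output_dir) if config.output_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.master_seed)
    children = ss.spawn(config.n_areas + 1)
    # one dedicated stream for area-level draws (SD, tail, tree permutations)
    meta_rng = np.random.default_rng(children[0])
    sds = meta_rng.uniform(config.sd_range[0], config.sd_range[1], config.n_areas)
    tails = meta_rng.random(config.n_areas) < config.long_tailed_fraction

    records: list[MetricRecord] = []
    skipped: list[str] = []
    for i in range(config.n_areas):
        area_id = f"area{i:04d}"
        child = children[i + 1]
        area_seed = int(child.generate_state(1)[0] % (2**31))
        spec = _area_terrain_spec(config.terrain, sds[i], area_seed, tails[i])
        tic = time.time()
        try:
            raster = make_gaussian_field(spec)
            rows = evaluate_area(
                raster,
                sizes=config.sizes,
                iterations=config.iterations,
                idw=config.idw,
                rng=np.random.default_rng(child),
                area_id=area_id,
            )
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("area %s failed and was skipped: %s", area_id, exc)
            skipped.append(area_id)
            continue
        records.extend(rows)
        log.info(
            "area %s: sd=%.2f, %d rows, %.2fs", area_id, sds[i], len(rows),
            time.time() - tic,
        )
        if out is not None:
            _records_to_frame(records).to_csv(out / "metrics_raw.csv", index=False)

    raw = _records_to_frame(records)
    means = mean_table(raw)
    smooths, trees = fit_trends(
        means,
        alpha=config.alpha,
        permutations=config.permutations,
        min_node=config.min_node,
        rng=np.random.default_rng(ss.spawn(1)[0]),
    )

    if out is not None:
        raw.to_csv(out / "metrics_raw.csv", index=False)
        means.to_csv(out / "metrics_mean.csv", index=False)
        for key, tree in trees.items():
            tree.to_json(out / f"tree_{key}.json")
            (out / f"tree_{key}.txt").write_text(tree.to_text())
        for key, fit in smooths.items():
            sub = means[means["source"] == key.split("_", 1)[0]]
            grid = sub[["sample_size", "area_sd"]].rename(columns={"area_sd": "sd"})
            fit.band(grid.reset_index(drop=True)).to_csv(
                out / f"smooth_{key}.csv", index=False
            )
        _write_plots(means, smooths, out)
        manifest = {
            "config": config.to_manifest(),
            "n_skipped_areas": len(skipped),
            "skipped_areas": skipped,
            "elapsed_s": round(time.time() - t0, 2),
            "versions": _versions(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if skipped:
        log.warning("%d area(s) skipped: %s", len(skipped), ", ".join(skipped))
    return ExperimentResult(raw, means, smooths, trees, skipped)


def _versions() -> dict:
    import matplotlib
    import scipy

    from . import __version__

    return {
        "gridrep": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "matplotlib": matplotlib.__version__,
    }


def _write_plots(means: pd.DataFrame, smooths: dict[str, SmoothFit], out: Path) -> None:
    """Trend plots: mean metric vs sample size, points colored by area SD,
    smooth fit (at the median SD) with its 95% band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = {
        "sample_ks_p": "sample KS p-value",
        "interpolation_ks_p": "interpolation KS p-value",
        "interpolation_pearson_r": "interpolation Pearson r",
        "interpolation_rmse": "interpolation RMSE (m)",
    }
    for key, fit in smooths.items():
        source, metric = key.split("_", 1)
        sub = means[means["source"] == source]
        fig, ax = plt.subplots(figsize=(6, 4))
        sc = ax.scatter(
            sub["sample_size"], sub[metric], c=sub["area_sd"], s=14,
            cmap="viridis", alpha=0.7,
        )
        fig.colorbar(sc, ax=ax, label="area SD (m)")
        sizes = np.linspace(sub["sample_size"].min(), sub["sample_size"].max(), 100)
        grid = pd.DataFrame(
            {"sample_size": sizes, "sd": np.full_like(sizes, sub["area_sd"].median())}
        )
        band = fit.band(grid)
        ax.plot(band["sample_size"], band["fit"], color="C0")
        ax.fill_between(
            band["sample_size"], band["lower"], band["upper"],
            color="C0", alpha=0.25,
        )
        ax.set_xlabel("sample size (n)")
        ax.set_ylabel(labels.get(key, key))
        fig.tight_layout()
        fig.savefig(out / f"trend_{key}.png", dpi=120)
        plt.close(fig)
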
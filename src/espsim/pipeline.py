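"""Config-driven orchestration of ESP construction and scenario simulation.

Two tracks share one YAML-configurable parameter set: ``run_esp`` builds
the ecological security pattern (MSPA → connectivity → corridors) and
``run_simulation`` drives the land-use forecast (Markov demand → ANN-CA
allocation → expansion metrics), with the ESP as the restricted area under
the ecological-security scenario. ``run_all`` wires everything together on
synthetic epochs, including a hindcast validation (fit on t0→t1, simulate
t2, kappa against the known t2).

One global seed fans out to per-stage seeds by fixed offsets so any stage
can be re-run in isolation with identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from shapely.geometry import LineString, mapping

from . import connectivity, corridors, demand, flus, metrics, mspa, synthetic
from .grids import CONSTRUCTION, WATER, BinaryMask, LandUseGrid, write_raster

log = logging.getLogger("espsim")

#: Per-step (one epoch interval) class-transition matrix of the default
#: synthetic study area: gentle urbanization — arable loses most to
#: construction, construction is nearly absorbing.
DEFAULT_EVOLUTION = [
    [0.90, 0.02, 0.01, 0.005, 0.06, 0.005],
    [0.02, 0.95, 0.01, 0.0, 0.02, 0.0],
    [0.03, 0.02, 0.91, 0.0, 0.03, 0.01],
    [0.01, 0.005, 0.005, 0.97, 0.01, 0.0],
    [0.005, 0.0, 0.005, 0.0, 0.99, 0.0],
    [0.05, 0.02, 0.02, 0.01, 0.05, 0.85],
]

_STAGE_OFFSETS = {
    "landscape": 0,
    "evolution": 1,
    "factors": 2,
    "ann": 3,
    "natural": 4,
    "ecological": 5,
    "validation": 6,
}


@dataclass
class PipelineConfig:
    # synthetic landscape
    shape: tuple[int, int] = (200, 200)
    cell_size: float = 30.0
    class_fractions: dict[int, float] = field(
        default_factory=lambda: dict(synthetic.DEFAULT_FRACTIONS)
    )
    autocorrelation_range: float = 18.0
    evolution_matrix: list = field(default_factory=lambda: [r[:] for r in DEFAULT_EVOLUTION])
    n_epochs: int = 3
    spatial_kernel_size: int = 5
    # ESP parameters
    edge_width: int = 1
    core_min_hm2: float = 100.0
    dpc_min: float = 1.0
    distance_threshold_m: float = 1500.0
    p_at_threshold: float = 0.5
    water_min_hm2: float = 100.0
    elongation_threshold: float = 10.0
    corridor_k: int = 14
    buffer_m: float = 100.0
    river_min_width_m: float = 30.0
    river_min_length_m: float = 5000.0
    n_nodes: int = 7
    node_min_hm2: float = 10.0
    node_max_dist_m: float | None = None
    # simulation parameters
    interval_years: float = 10.0
    horizon_years: float = 10.0
    sample_fraction: float = 0.05
    hidden_units: int = 12
    window: int = 3
    max_iterations: int = 500
    validation_fraction: float = 0.1
    # metrics
    n_rings: int = 12
    ring_width_m: float = 5000.0
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) * 131 + _STAGE_OFFSETS[stage]) % (2**31 - 1)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["shape"] = list(self.shape)
        path.write_text(yaml.safe_dump(d))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        if "class_fractions" in d:
            d["class_fractions"] = {int(k): v for k, v in d["class_fractions"].items()}
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def generate_inputs(config: PipelineConfig):
    """Synthetic epoch sequence and driving-factor stack."""
    spec = synthetic.LandscapeSpec(
        shape=config.shape,
        cell_size=config.cell_size,
        class_fractions=config.class_fractions,
        autocorrelation_range=config.autocorrelation_range,
        seed=config.stage_seed("landscape"),
    )
    first = synthetic.generate_landscape(spec)
    evo = synthetic.EvolutionSpec(
        transition_matrix=np.asarray(config.evolution_matrix),
        steps=config.n_epochs - 1,
        spatial_kernel_size=config.spatial_kernel_size,
        seed=config.stage_seed("evolution"),
    )
    epochs = [first] + synthetic.evolve_landscape(first, evo)
    factors = synthetic.generate_factors(
        epochs[-1], seed=config.stage_seed("factors")
    )
    return epochs, factors


@dataclass
class ESPReport:
    esp: corridors.EcologicalSecurityPattern
    cores: object
    sources: connectivity.SourceSelection
    dpc: connectivity.DPCTable | None
    selected_paths: list
    nodes: object

    def summary(self) -> dict:
        return {
            "n_core_patches": len(self.cores),
            "n_sources": len(self.sources.sources),
            "source_area_km2": self.sources.sources.total_area_hm2() / 100.0,
            "n_corridors": len(self.selected_paths),
            "n_nodes": len(self.nodes),
            "restricted_area_km2": self.esp.restricted.area_km2(),
        }


def run_esp(
    config: PipelineConfig,
    landuse: LandUseGrid,
    relief,
) -> ESPReport:
    """MSPA → connectivity → corridors → ESP on one land-use epoch."""
    fg = mspa.make_foreground(landuse)
    result = mspa.classify_mspa(fg, edge_width=config.edge_width)
    cores = mspa.extract_cores(result, min_area_hm2=config.core_min_hm2)
    water_patches = corridors.label_mask(landuse.class_mask(WATER))
    empty = BinaryMask.empty_like(landuse)
    if len(cores) == 0:
        warnings.warn("no core patches above the area threshold; ESP is empty")
        sel = connectivity.SourceSelection(
            connectivity.PatchSet([], landuse.cell_size, landuse.origin, landuse.shape),
            [], [],
        )
        esp = corridors.assemble_esp(empty, empty, None, None)
        return ESPReport(esp, cores, sel, None, [], cores)
    graph = connectivity.build_graph(
        cores,
        threshold=config.distance_threshold_m,
        p_thr=config.p_at_threshold,
    )
    dpc = connectivity.dpc_table(graph)
    sel = connectivity.select_sources(
        cores,
        dpc,
        water_patches,
        dpc_min=config.dpc_min,
        water_min_area_hm2=config.water_min_hm2,
        elongation_threshold=config.elongation_threshold,
    )
    res = corridors.build_resistance(landuse, relief)
    selected: list = []
    buffered = empty
    if len(sel.sources) >= 2:
        paths = corridors.all_corridors(res, sel.sources)
        gm = corridors.gravity_matrix(paths, sel.sources, res)
        selected = corridors.select_corridors(gm, rule="top_k", k=config.corridor_k)
        buffered = corridors.buffer_paths(selected, config.buffer_m, res)
    rivers = corridors.river_corridors(
        landuse.class_mask(WATER),
        min_width_m=config.river_min_width_m,
        min_length_m=config.river_min_length_m,
    )
    # Node candidates: smaller core patches too (stepping stones), labeled
    # consistently with the source cores since both come from one core mask.
    node_candidates = mspa.extract_cores(result, min_area_hm2=config.node_min_hm2)
    nodes = corridors.select_nodes(
        node_candidates,
        sel.core_ids,
        n=config.n_nodes,
        corridor_mask=buffered if buffered.bits.any() else None,
        max_dist_m=config.node_max_dist_m,
    )
    esp = corridors.assemble_esp(
        sel.sources.mask(), buffered, rivers, nodes.mask()
    )
    log.info("ESP: %s", ESPReport(esp, cores, sel, dpc, selected, nodes).summary())
    return ESPReport(esp, cores, sel, dpc, selected, nodes)


def make_scenario(
    config: PipelineConfig,
    name: str,
    esp: corridors.EcologicalSecurityPattern | None,
) -> flus.ScenarioConfig:
    if name == "natural":
        return flus.ScenarioConfig(
            name=name,
            transfer_matrix=flus.TRANSFER_NATURAL.copy(),
            restricted=None,
            window=config.window,
            max_iterations=config.max_iterations,
            seed=config.stage_seed("natural"),
        )
    if name == "ecological":
        if esp is None:
            raise ValueError("ecological scenario requires an ESP")
        return flus.ScenarioConfig(
            name=name,
            transfer_matrix=flus.TRANSFER_ECOLOGICAL.copy(),
            restricted=esp.restricted,
            window=config.window,
            max_iterations=config.max_iterations,
            seed=config.stage_seed("ecological"),
        )
    raise ValueError(f"unknown scenario {name!r}")


def run_simulation(
    config: PipelineConfig,
    epochs: list[LandUseGrid],
    factors: dict,
    scenario: flus.ScenarioConfig,
) -> flus.AllocationResult:
    """Markov demand from the last epoch pair, then spatial allocation."""
    tm = demand.estimate_transition_matrix(
        epochs[-2], epochs[-1], interval_years=config.interval_years
    )
    dv = demand.project_demand(tm, epochs[-1], config.horizon_years)
    return flus.simulate_scenario(
        epochs[-1],
        factors,
        dv,
        scenario,
        sample_fraction=config.sample_fraction,
        hidden_units=config.hidden_units,
    )


def hindcast_validate(
    config: PipelineConfig, epochs: list[LandUseGrid], factors: dict
) -> metrics.ValidationReport:
    """Fit demand on (t0, t1), allocate to t2's date, score against t2."""
    if len(epochs) < 3:
        raise ValueError("hindcast needs at least three epochs")
    tm = demand.estimate_transition_matrix(
        epochs[-3], epochs[-2], interval_years=config.interval_years
    )
    dv = demand.project_demand(tm, epochs[-2], config.interval_years)
    scen = flus.ScenarioConfig(
        name="hindcast",
        transfer_matrix=flus.TRANSFER_NATURAL.copy(),
        window=config.window,
        max_iterations=config.max_iterations,
        seed=config.stage_seed("validation"),
    )
    hind_factors = synthetic.generate_factors(
        epochs[-2], seed=config.stage_seed("factors")
    )
    result = flus.simulate_scenario(
        epochs[-2],
        hind_factors,
        dv,
        scen,
        sample_fraction=config.sample_fraction,
        hidden_units=config.hidden_units,
    )
    return metrics.kappa_validate(
        epochs[-1],
        result.landuse,
        fraction=config.validation_fraction,
        seed=config.stage_seed("validation"),
    )


def corridors_to_geojson(paths: list, like: LandUseGrid) -> dict:
    feats = []
    for p in paths:
        xy = [
            (
                like.origin[0] + (c + 0.5) * like.cell_size,
                like.origin[1] - (r + 0.5) * like.cell_size,
            )
            for r, c in p.cells
        ]
        if len(xy) < 2:
            xy = xy * 2
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(LineString(xy)),
                "properties": {
                    "i": int(p.i), "j": int(p.j),
                    "L": float(p.cost), "G": float(p.gravity),
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Full study: inputs → ESP → hindcast → both scenarios → metrics."""
    epochs, factors = generate_inputs(config)
    elevation = factors["elevation"]
    relief_values = synthetic.generate_relief(
        type(elevation)(
            elevation.cell_size, elevation.origin, 100.0 * elevation.values
        ),
        window=3,
    )
    esp_report = run_esp(config, epochs[-1], relief_values)
    validation = hindcast_validate(config, epochs, factors)
    results = {}
    for name in ("natural", "ecological"):
        scen = make_scenario(config, name, esp_report.esp)
        results[name] = run_simulation(config, epochs, factors, scen)

    base = epochs[-1]
    center = metrics.center_of_gravity(base, CONSTRUCTION)
    quad, rings = metrics.make_zonings(
        base, center, n_rings=config.n_rings, ring_width_m=config.ring_width_m
    )
    series = {
        name: metrics.zonal_series(
            {"0": base, "1": res.landuse}, quad, CONSTRUCTION
        )
        for name, res in results.items()
    }
    manifest = {
        "config_hash": config.config_hash(),
        "esp": esp_report.summary(),
        "validation": {
            "kappa": validation.kappa,
            "overall_accuracy": validation.overall_accuracy,
        },
        "scenarios": {
            name: {
                "construction_km2": res.landuse.class_area_km2(CONSTRUCTION),
                "converged": res.converged,
                "iterations": res.iterations,
            }
            for name, res in results.items()
        },
        "artifacts": {},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["config.yaml"] = config.to_yaml(outdir / "config.yaml")
        for i, ep in enumerate(epochs):
            paths[f"epoch_{i}.asc"] = write_raster(ep, outdir / f"epoch_{i}.asc")
        for name, res in results.items():
            paths[f"simulated_{name}.asc"] = write_raster(
                res.landuse, outdir / f"simulated_{name}.asc"
            )
        restricted = esp_report.esp.restricted
        esp_grid = LandUseGrid(
            base.cell_size,
            base.origin,
            np.where(restricted.bits, 5, 6).astype(np.int64),
        )
        paths["esp_restricted.asc"] = write_raster(
            esp_grid, outdir / "esp_restricted.asc"
        )
        gj = corridors_to_geojson(esp_report.selected_paths, base)
        (outdir / "corridors.geojson").write_text(json.dumps(gj))
        paths["corridors.geojson"] = outdir / "corridors.geojson"
        for name, (levels, changes) in series.items():
            levels.to_csv(outdir / f"quadrant_levels_{name}.csv", index=False)
            changes.to_csv(outdir / f"quadrant_changes_{name}.csv", index=False)
            paths[f"quadrant_levels_{name}.csv"] = outdir / f"quadrant_levels_{name}.csv"
            paths[f"quadrant_changes_{name}.csv"] = outdir / f"quadrant_changes_{name}.csv"
        manifest["artifacts"] = {
            k: hashlib.sha256(Path(v).read_bytes()).hexdigest()[:16]
            for k, v in paths.items()
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["_objects"] = {
        "epochs": epochs,
        "factors": factors,
        "esp": esp_report,
        "validation": validation,
        "results": results,
        "series": series,
    }
    return manifest
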
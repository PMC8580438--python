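"""End-to-end orchestration: ingest -> diversity -> bioregion -> models -> nullsim.

A :class:`RunConfig` holds every stage parameter plus one master seed; a run
executes the stages in order, writes each stage's outputs as CSV (plus a
GeoJSON of cells for mapping), and records a manifest with the SHA-256 of
every input and output file, so a run is fully reproducible from the config
and its inputs.  A stage failure is recorded in the manifest and aborts the
remaining stages while leaving completed outputs intact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import bioregion, diversity, ingest, models, nullmodel, synth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "PipelineError"]

_STAGES = ("ingest", "diversity", "bioregion", "models", "nullsim")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Flat configuration of a full pipeline run."""

    outdir: str = "run_output"
    seed: int = 0
    log_level: str = "INFO"

    # inputs: either file paths, or a synthetic scenario generated in-run
    occurrences: Optional[str] = None
    env: Optional[str] = None
    synth_scenario: Optional[str] = "default"

    # ingest
    min_species: int = 10
    min_records: int = 150

    # diversity
    quorum: float = 0.5
    simpson_form: str = "inverse"

    # bioregion
    n_factors: Optional[int] = None      # None -> parallel analysis
    n_random: int = 100
    pam_metric: str = "sorensen"
    extraction: str = "pa"

    # models
    metrics: Sequence[str] = models.DEFAULT_METRICS
    alpha_tables: float = 0.001
    alpha_paths: float = 0.01
    k_neighbors: int = 5
    sar_model: str = "error"
    log_response: bool = True
    key_set_size: int = 7

    # null simulation
    null_reps: int = 100
    null_metric: str = "fisher_alpha"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["metrics"] = list(self.metrics)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _coords_from_index(index: pd.Index) -> pd.DataFrame:
    rows = []
    for key in index:
        cid = ingest.parse_cell_key(key)
        clat, clon = ingest.cell_center(cid)
        rows.append({"center_lat": clat, "center_lon": clon})
    return pd.DataFrame(rows, index=index)


def _write_matrix_triplets(matrix: pd.DataFrame, path: Path) -> None:
    rows = []
    for cell_id, row in matrix.iterrows():
        nz = row[row > 0]
        for sp, cnt in nz.items():
            rows.append({"cell_id": cell_id, "species": sp, "count": int(cnt)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_matrix_triplets(path: str | Path) -> pd.DataFrame:
    """Rebuild the cell x species count matrix from its triplet CSV."""
    df = pd.read_csv(path)
    mat = df.pivot_table(
        index="cell_id", columns="species", values="count", fill_value=0,
        aggfunc="sum",
    )
    return mat.astype(np.int64)


def _write_geojson(loadings: pd.DataFrame, path: Path) -> None:
    features = []
    dominant = loadings.abs().idxmax(axis=1)
    for key in loadings.index:
        cid = ingest.parse_cell_key(key)
        clat, clon = ingest.cell_center(cid)
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [clon, clat]},
                "properties": {
                    "cell_id": key,
                    "dominant_factor": str(dominant[key]),
                    "max_loading": float(loadings.loc[key].abs().max()),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def run_all(config: RunConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    seeds = {
        name: np.random.SeedSequence((config.seed, i))
        for i, name in enumerate(_STAGES)
    }
    state: dict = {}

    def record(stage: str, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "status": "complete",
            "outputs": {p.name: _sha256(p) for p in outputs},
        }

    def fail(stage: str, exc: Exception) -> dict:
        manifest["stages"][stage] = {
            "status": "failed",
            "error": f"{type(exc).__name__}: {exc}",
        }
        for later in _STAGES[_STAGES.index(stage) + 1:]:
            manifest["stages"][later] = {"status": "not_attempted"}
        _write_manifest()
        logger.error("stage %s failed:\n%s", stage, traceback.format_exc())
        return manifest

    def _write_manifest() -> None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    # ingest ---------------------------------------------------------------
    try:
        if config.occurrences is None:
            scen = config.synth_scenario or "default"
            world = synth.generate_world(
                synth.SynthConfig(seed=int(seeds["ingest"].generate_state(1)[0] % 2**31)),
                scenario=scen,
            )
            records, env_table = world.records, world.env
            manifest["inputs"] = {"synthetic_scenario": scen}
        else:
            if config.env is None:
                raise PipelineError("env table path required with occurrence file")
            records = ingest.read_occurrences(config.occurrences)
            env_table = ingest.read_env_table(config.env)
            manifest["inputs"] = {
                "occurrences": _sha256(Path(config.occurrences)),
                "env": _sha256(Path(config.env)),
            }
        kept = ingest.filter_records(records)
        cells = ingest.grid_records(kept)
        retained, _ = ingest.filter_cells(
            cells, min_species=config.min_species, min_records=config.min_records
        )
        matrix, env = ingest.build_matrix(retained, env_table)
        meta = ingest.cell_metadata(retained).loc[matrix.index]
        _write_matrix_triplets(matrix, outdir / "matrix.csv")
        meta.to_csv(outdir / "cells.csv")
        env.to_csv(outdir / "env_aligned.csv")
        state.update(matrix=matrix, env=env, meta=meta)
        record("ingest", [outdir / "matrix.csv", outdir / "cells.csv",
                          outdir / "env_aligned.csv"])
    except Exception as exc:
        return fail("ingest", exc)

    # diversity ------------------------------------------------------------
    try:
        div = diversity.diversity_table(
            state["matrix"], quorum=config.quorum, simpson_form=config.simpson_form
        )
        div.to_csv(outdir / "diversity.csv")
        state["diversity"] = div
        record("diversity", [outdir / "diversity.csv"])
    except Exception as exc:
        return fail("diversity", exc)

    # bioregion ------------------------------------------------------------
    try:
        rng = np.random.default_rng(seeds["bioregion"])
        n_factors = config.n_factors
        if n_factors is None:
            n_factors = max(
                1,
                bioregion.parallel_analysis(
                    state["matrix"], n_random=config.n_random, rng=rng
                ),
            )
        corr = bioregion.cell_correlation(state["matrix"])
        sol = bioregion.varimax_fa(corr, n_factors, method=config.extraction)
        sol.loadings.to_csv(outdir / "province_loadings.csv")
        dis = bioregion.dissimilarity(state["matrix"], metric=config.pam_metric)
        clusters = bioregion.pam(dis, n_factors)
        clusters.assignment.to_frame().to_csv(outdir / "clusters.csv")
        ca_scores, inertia = bioregion.correspondence_analysis(state["matrix"])
        ca_scores.to_csv(outdir / "ca_scores.csv")
        _write_geojson(sol.loadings, outdir / "cells.geojson")
        state.update(provinces=sol, n_factors=n_factors)
        manifest["n_factors"] = int(n_factors)
        record("bioregion", [outdir / "province_loadings.csv",
                             outdir / "clusters.csv", outdir / "ca_scores.csv",
                             outdir / "cells.geojson"])
    except Exception as exc:
        return fail("bioregion", exc)

    # models ---------------------------------------------------------------
    try:
        abiotic = models.abiotic_fa(state["env"])
        abiotic.loadings.to_csv(outdir / "abiotic_loadings.csv")
        coords = _coords_from_index(state["matrix"].index)
        t1 = models.model_suite(
            state["diversity"], abiotic, None, coords=coords,
            metrics=config.metrics, alpha=config.alpha_tables,
            log_response=config.log_response, k_neighbors=config.k_neighbors,
            sar_model=config.sar_model,
        )
        t2 = models.model_suite(
            state["diversity"], abiotic, state["provinces"].loadings,
            coords=coords, metrics=config.metrics, alpha=config.alpha_tables,
            log_response=config.log_response, k_neighbors=config.k_neighbors,
            sar_model=config.sar_model,
        )
        for name, suite in (("table_abiotic", t1), ("table_combined", t2)):
            frames = []
            for metric, res in suite.items():
                f = res.to_frame()
                f.insert(0, "metric", metric)
                f["adjusted_R2"] = res.adjusted_R2
                f["spatial_param"] = res.spatial_param
                frames.append(f)
            pd.concat(frames).to_csv(outdir / f"{name}.csv", index=False)
        key_vars = models.select_key_variables(
            abiotic, key_set_size=config.key_set_size
        )
        env_keys = state["env"].copy()
        env_keys["latitude"] = coords["center_lat"]
        key_df = env_keys[[v for v in key_vars]]
        div_metric = state["diversity"][config.null_metric].dropna()
        aligned = key_df.index.intersection(div_metric.index)
        graph = models.path_suite(
            key_df.loc[aligned],
            state["provinces"].loadings.loc[aligned],
            div_metric.loc[aligned],
            alpha=config.alpha_paths,
        )
        graph.to_frame().to_csv(outdir / "path_edges.csv", index=False)
        state.update(abiotic=abiotic, coords=coords)
        record("models", [outdir / "abiotic_loadings.csv",
                          outdir / "table_abiotic.csv",
                          outdir / "table_combined.csv",
                          outdir / "path_edges.csv"])
    except Exception as exc:
        return fail("models", exc)

    # nullsim --------------------------------------------------------------
    try:
        reps, summary = nullmodel.null_experiment(
            state["matrix"], state["env"], state["diversity"], state["coords"],
            n_reps=config.null_reps, n_factors=state["n_factors"],
            seed=int(seeds["nullsim"].generate_state(1)[0] % 2**31),
            metric=config.null_metric, abiotic=state["abiotic"],
            log_response=config.log_response, alpha=config.alpha_tables,
            k_neighbors=config.k_neighbors,
        )
        reps.to_csv(outdir / "null_replicates.csv", index=False)
        summary.to_csv(outdir / "null_summary.csv", index=False)
        record("nullsim", [outdir / "null_replicates.csv",
                           outdir / "null_summary.csv"])
    except Exception as exc:
        return fail("nullsim", exc)

    _write_manifest()
    return manifest
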
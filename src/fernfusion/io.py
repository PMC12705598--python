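"""Readers/writers for on-disk artifacts and the end-to-end pipeline.

All artifacts are plain text: CSV for observations, covariates, meshes and
reports; GeoJSON for polygons and line features; Matrix Market for sparse
precision matrices; YAML for configuration.  Coordinates are projected
meters in one CRS declared in the run configuration (the study uses
EPSG:25830); cell ids are row-major from the south-west corner.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .observations import COUNT_COLUMNS, PRESENCE_COLUMNS, ObservationSet

log = logging.getLogger("fernfusion")


# --- observation tables -----------------------------------------------------

def save_observations(obs: ObservationSet, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = outdir / "counts.csv"
    obs.counts.to_csv(p, index=False)
    paths["counts"] = p
    if obs.presences is not None:
        p = outdir / "presences.csv"
        obs.presences.to_csv(p, index=False)
        paths["presences"] = p
    if obs.populations is not None:
        p = outdir / "populations.geojson"
        feats = []
        for _, r in obs.populations.iterrows():
            feats.append({"type": "Feature",
                          "geometry": mapping(r["geometry"]),
                          "properties": {"population": r["population"],
                                         "species": int(r["species"]),
                                         "area": float(r["area"])}})
        p.write_text(json.dumps({"type": "FeatureCollection",
                                 "features": feats}))
        paths["populations"] = p
    return paths


def _validate(df: pd.DataFrame, columns, dtypes: dict, path) -> pd.DataFrame:
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    for col, dtype in dtypes.items():
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(f"{path}: malformed value {df.loc[row, col]!r} "
                             f"in column {col!r}, row {row}")
        df[col] = coerced.astype(dtype) if not coerced.isna().any() else coerced
    return df


def load_observations(counts_path, presences_path=None,
                      populations_path=None) -> ObservationSet:
    """Load and validate the observation tables, naming offending rows."""
    counts = pd.read_csv(counts_path)
    counts = _validate(counts, COUNT_COLUMNS,
                       {"species": int, "cell": int, "year": int,
                        "count": float, "area": float}, counts_path)
    counts["missing"] = counts["missing"].astype(bool)
    presences = None
    if presences_path is not None and Path(presences_path).exists():
        presences = pd.read_csv(presences_path)
        if len(presences):
            presences = _validate(presences, PRESENCE_COLUMNS,
                                  {"species": int, "cell": int, "year": int,
                                   "presence": int}, presences_path)
    populations = None
    if populations_path is not None and Path(populations_path).exists():
        gj = json.loads(Path(populations_path).read_text())
        rows = [{"population": f["properties"]["population"],
                 "species": int(f["properties"]["species"]),
                 "geometry": shape(f["geometry"]),
                 "area": float(f["properties"].get(
                     "area", shape(f["geometry"]).area))}
                for f in gj["features"]]
        populations = pd.DataFrame(rows)
    log.info("loaded %d count rows, %s presence rows", len(counts),
             len(presences) if presences is not None else 0)
    return ObservationSet(counts=counts, presences=presences,
                          populations=populations)


# --- covariates, meshes, matrices ------------------------------------------

def save_covariate_table(stack, path):
    stack.table().to_csv(path, index=False)


def load_covariate_table(path, domain) -> np.ndarray:
    """Long CSV (cell_id, year, name, value) -> (n_cells, T, P) array."""
    df = pd.read_csv(path)
    names = list(dict.fromkeys(df["name"]))
    X = np.zeros((domain.n_cells, domain.n_years, len(names)))
    for p, name in enumerate(names):
        sub = df[df["name"] == name]
        t = domain.year_index(sub["year"].to_numpy(int))
        X[sub["cell_id"].to_numpy(int), t, p] = sub["value"].to_numpy(float)
    return X, names


def save_mesh(mesh, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(mesh.nodes, columns=["x", "y"]).assign(
        interior=mesh.interior).to_csv(outdir / "mesh_nodes.csv", index=False)
    pd.DataFrame(mesh.triangles, columns=["v0", "v1", "v2"]).to_csv(
        outdir / "mesh_triangles.csv", index=False)


def save_precision_mtx(Q, path):
    from scipy.io import mmwrite
    mmwrite(str(path), Q)


# --- run configuration ------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    seed: int = 0
    outdir: str = "fernfusion_run"
    model: str = "M21"
    crs: str = "EPSG:25830"
    simulate: dict = field(default_factory=dict)   # make_fixture kwargs
    fit: dict = field(default_factory=dict)        # IntegratedSDM kwargs
    predict_years: list = field(default_factory=list)
    change_years: list = field(default_factory=list)
    n_samples: int = 200
    skip_evaluate: bool = False

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path):
        return cls(**yaml.safe_load(Path(path).read_text()))


def _child_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def write_manifest(outdir):
    """Checksum every artifact in the output directory."""
    outdir = Path(outdir)
    entries = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries[str(p.relative_to(outdir))] = hashlib.sha256(
                p.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(entries, indent=1))
    return entries


def run_pipeline(config: RunConfig) -> Path:
    """simulate -> fit -> predict -> change map -> evaluate -> manifest."""
    from .model import IntegratedSDM, change_map, predict_intensity
    from .evaluation import coverage_report, waic
    from .synthetic import make_fixture

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "simulate"
    try:
        domain, mesh, cov, truth, obs = make_fixture(
            seed=_child_seed(config.seed, "simulate"), **config.simulate)
        save_observations(obs, out)
        save_covariate_table(cov, out / "covariates.csv")
        save_mesh(mesh, out)
        truth_summary = {"hypers": {k: (list(v) if isinstance(v, (tuple, list))
                                        else float(v))
                                    for k, v in truth.hypers.items()},
                         "beta": [float(b) for b in truth.beta],
                         "intercepts": [float(b) for b in truth.intercepts]}
        (out / "truth.yaml").write_text(yaml.safe_dump(truth_summary))
        log.info("stage simulate done in %.1fs", time.time() - t0)

        stage = "fit"
        X = cov.X
        est = IntegratedSDM(model=config.model,
                            seed=_child_seed(config.seed, "fit"),
                            **config.fit)
        est.fit(obs, domain, X, mesh=mesh)
        res = est.result_
        theta_out = {k: float(v) for k, v in res.theta.items()}
        (out / "hyperparameters.yaml").write_text(yaml.safe_dump(
            {"theta": theta_out, "converged": bool(res.converged),
             "log_marginal": float(res.log_marginal)}))

        stage = "predict"
        samples = est.sample(config.n_samples,
                             seed=_child_seed(config.seed, "sample"))
        years = config.predict_years or [int(domain.years[0]),
                                         int(domain.years[-1])]
        surf = predict_intensity(res, domain, years, samples=samples)
        surf.summaries.to_csv(out / "surfaces.csv", index=False)

        stage = "changemap"
        ya, yb = (config.change_years or
                  [int(domain.years[0]), int(domain.years[-1])])
        cm_rows = []
        for j in range(truth.lam.shape[0]):
            cm = change_map(res, domain, j, ya, yb, samples=samples)
            cm_rows.append(pd.DataFrame({
                "species": j, "cell": cm.cell, "mean": cm.mean,
                "lower": cm.lower, "upper": cm.upper,
                "significant": cm.significant}))
        pd.concat(cm_rows, ignore_index=True).to_csv(
            out / "change_map.csv", index=False)

        if not config.skip_evaluate:
            stage = "evaluate"
            rep = coverage_report(res, obs, samples=samples,
                                  seed=_child_seed(config.seed, "evaluate"))
            rep.per_species.to_csv(out / "evaluation.csv")
            w, p_w, _ = waic(res, samples=samples)
            (out / "evaluation.json").write_text(json.dumps(
                {"model": config.model, "waic": w, "p_waic": p_w,
                 "log_marginal": float(res.log_marginal)}, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    config.to_yaml(out / "run_config.yaml")
    write_manifest(out)
    log.info("pipeline complete in %.1fs", time.time() - t0)
    return out
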
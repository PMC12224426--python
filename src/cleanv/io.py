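"""Readers/writers for the delimited-text interchange formats and run config.

Delimited text (comma or tab, autodetected) is the canonical interchange:
a data matrix with one row per image, a design table, an optional covariate
table, and either mesh coordinate/face tables, a standard mesh file, or a
precomputed square distance matrix. Per-vertex results round-trip exactly
through `write_results` / `pandas.read_csv`. GIFTI export of the per-vertex
statistic map is available when nibabel is installed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import (
    DesignError,
    RelatednessMatrix,
    kinship_test_retest,
    kinship_twins,
    load_custom_kinship,
)
from .inference import CleanVResult
from .mesh import SurfaceGeometry, geodesic_distances, load_mesh, load_mesh_file

logger = logging.getLogger("cleanv")


@dataclass
class RunConfig:
    """Serializable description of a run; reproduces it bit-identically."""

    data: str
    design: str
    design_type: str = "test-retest"
    covariates: str | None = None
    mesh_coords: str | None = None
    mesh_faces: str | None = None
    mesh_file: str | None = None
    distances: str | None = None
    mask: str | None = None
    radii: list[float] | None = None
    rmax: float | None = None
    permutations: int = 5000
    alpha: float = 0.05
    seed: int = 0
    variant: str = "full"
    out: str = "cleanv_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_data_matrix(path, design_ids=None):
    """Read the N x V data matrix; align rows to the design's image order.

    The first column is treated as image ids when named ``image_id`` (or
    when it is non-numeric); otherwise rows are numbered. Misordered rows
    relative to ``design_ids`` are reordered with a log entry. Missing or
    non-numeric cells raise with their location.
    """
    df = _read_table(path)
    first = df.columns[0]
    if first == "image_id" or df[first].dtype == object:
        ids = df[first].astype(str).to_numpy()
        df = df.drop(columns=[first])
    else:
        ids = np.array([str(i) for i in range(len(df))])

    bad = df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"missing/non-numeric value in data matrix at row {r} "
            f"(image {ids[r]}), column {df.columns[c]!r}"
        )
    try:
        Y = df.to_numpy(dtype=float)
    except ValueError as err:
        raise ValueError(f"non-numeric cell in data matrix: {err}") from err

    if design_ids is not None:
        want = np.array([str(i) for i in design_ids])
        if not np.array_equal(ids, want):
            pos = {v: k for k, v in enumerate(ids)}
            missing = [w for w in want if w not in pos]
            if missing:
                raise ValueError(f"data matrix missing image ids: {missing[:5]}")
            order = np.array([pos[w] for w in want])
            Y = Y[order]
            ids = ids[order]
            logger.info("reordered %d data rows to match the design table", len(order))
    return Y, ids


def read_design(path, design_type: str):
    """Read the design table and build the relatedness kernel.

    test-retest: columns image_id, subject_id. twin: image_id, pair_id,
    zygosity. custom: the path is a square kinship matrix with id headers.
    Returns (RelatednessMatrix, image_ids).
    """
    if design_type == "custom":
        rel = load_custom_kinship(path)
        ids = pd.read_csv(path, sep=None, engine="python", index_col=0).index.astype(str)
        return rel, np.asarray(ids)
    df = _read_table(path)
    if "image_id" not in df.columns:
        raise DesignError("design table needs an image_id column")
    ids = df["image_id"].astype(str).to_numpy()
    if design_type == "test-retest":
        if "subject_id" not in df.columns:
            raise DesignError("test-retest design needs a subject_id column")
        return kinship_test_retest(df["subject_id"].to_numpy()), ids
    if design_type == "twin":
        for col in ("pair_id", "zygosity"):
            if col not in df.columns:
                raise DesignError(f"twin design needs a {col} column")
        return kinship_twins(df["pair_id"].to_numpy(), df["zygosity"].to_numpy()), ids
    raise DesignError(f"unknown design type {design_type!r}")


def read_covariates(path, image_ids):
    """Covariate table aligned to the image order; intercept column added."""
    df = _read_table(path)
    if "image_id" in df.columns:
        df = df.set_index(df["image_id"].astype(str)).drop(columns=["image_id"])
        df = df.loc[[str(i) for i in image_ids]]
    X = df.to_numpy(dtype=float)
    return np.column_stack([np.ones(X.shape[0]), X])


def read_mask(path) -> np.ndarray:
    vals = np.loadtxt(path, ndmin=1)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask file must contain only 0/1 values")
    return vals.astype(bool)


def load_geometry(config: RunConfig) -> SurfaceGeometry:
    """Build the surface geometry a config points at, with distances filled."""
    mask = read_mask(config.mask) if config.mask else None
    if config.distances:
        D = pd.read_csv(config.distances, header=None, sep=None, engine="python").to_numpy(
            dtype=float
        )
        return SurfaceGeometry.from_distances(D, mask=mask)
    if config.mesh_file:
        geom = load_mesh_file(config.mesh_file, mask=mask)
    else:
        if not (config.mesh_coords and config.mesh_faces):
            raise ValueError(
                "need mesh_coords+mesh_faces, mesh_file, or distances"
            )
        coords = pd.read_csv(config.mesh_coords, sep=None, engine="python", header=None)
        faces = pd.read_csv(config.mesh_faces, sep=None, engine="python", header=None)
        geom = load_mesh(coords, faces, mask=mask)
    return geodesic_distances(geom)


def per_vertex_table(result: CleanVResult, threshold_column: bool = True) -> pd.DataFrame:
    """Deterministically ordered per-vertex result table."""
    V = result.U.size
    sig = np.zeros(V, dtype=int)
    sig[result.significant] = 1
    df = pd.DataFrame(
        {
            "vertex_id": np.arange(V),
            "U": result.U,
            "Tv": result.Tv,
            "argmax_radius": result.argmax_radius,
            "significant": sig,
        }
    )
    if threshold_column:
        # thresholded map convention: statistics below t_alpha shrink to zero
        df["Tv_thresholded"] = np.where(
            np.nan_to_num(result.Tv, nan=-np.inf) > result.t_alpha, result.Tv, 0.0
        )
    return df


def run_summary(result: CleanVResult) -> dict:
    summary = {
        "T": result.T,
        "t_alpha": result.t_alpha,
        "p_global": result.p_global,
        "rejects": bool(result.rejects),
        "n_significant": int(result.significant.size),
        "config": result.config,
    }
    if result.params is not None:
        summary["sigma2"] = result.params.sigma2
        summary["tau2"] = result.params.tau2
        summary["phi"] = result.params.phi
    return summary


def write_results(result: CleanVResult, outdir) -> dict[str, Path]:
    """Write the per-vertex table, run summary, and config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vertices": outdir / "vertices.csv",
        "summary": outdir / "summary.json",
        "config": outdir / "config.yaml",
    }
    per_vertex_table(result).to_csv(paths["vertices"], index=False)
    with open(paths["summary"], "w") as fh:
        json.dump(run_summary(result), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(result.config, fh, sort_keys=True)
    return paths


def export_gifti(result: CleanVResult, path) -> None:
    """Optional per-vertex overlay export (requires nibabel)."""
    try:
        import nibabel as nib
    except ImportError as err:  # pragma: no cover
        raise ImportError("GIFTI export requires nibabel (pip install cleanv[surface])") from err
    data = np.nan_to_num(result.Tv, nan=0.0).astype(np.float32)
    img = nib.gifti.GiftiImage(
        darrays=[nib.gifti.GiftiDataArray(data, intent="NIFTI_INTENT_NONE")]
    )
    nib.save(img, str(path))
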
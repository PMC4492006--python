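"""CSV and HDF5 interchange for rasters, trace sets, and catalogs.

CSV is the canonical format: rows are time bins/frames, columns are
units/ROIs, metadata travels in leading comment lines::

    # dt=0.25
    # coords=12.0,3.5;40.1,22.0
    unit_0,unit_1
    0,1
    ...

Numbers are written with 10 significant digits so value round-trips are
stable. HDF5 mirrors the same content in datasets ``/counts`` (or
``/lam`` / ``/ratio``), ``/dt`` and ``/coords``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np

from .avalanches import AvalancheCatalog, Cluster
from .containers import CalciumTraceSet, RateRaster, SpikeRaster

__all__ = [
    "read_raster", "write_raster", "read_traces", "write_traces",
    "read_catalog", "write_catalog",
    "read_raster_h5", "write_raster_h5",
]

_FMT = "%.10g"


def _write_matrix_csv(path, matrix, dt, coords, prefix):
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# dt={_FMT % dt}\n")
        if coords is not None:
            pairs = ";".join(f"{_FMT % x},{_FMT % y}" for x, y in coords)
            fh.write(f"# coords={pairs}\n")
        n = matrix.shape[0]
        fh.write(",".join(f"{prefix}_{i}" for i in range(n)) + "\n")
        w = csv.writer(fh)
        for row in matrix.T:
            w.writerow([_FMT % v for v in row])


def _read_matrix_csv(path):
    path = Path(path)
    dt = None
    coords = None
    rows = []
    header_seen = False
    n_cols = None
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("dt="):
                    dt = float(body[3:])
                elif body.startswith("coords="):
                    pairs = [p for p in body[len("coords="):].split(";") if p]
                    coords = np.array([[float(v) for v in p.split(",")]
                                       for p in pairs])
                continue
            if not header_seen:
                header_seen = True
                n_cols = len(line.split(","))
                continue
            vals = line.split(",")
            if len(vals) != n_cols:
                raise ValueError(
                    f"{path}: ragged row at line {i} "
                    f"({len(vals)} fields, expected {n_cols})")
            rows.append([float(v) for v in vals])
    if dt is None:
        raise ValueError(f"{path}: missing '# dt=' metadata line")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    matrix = np.asarray(rows).T  # stored rows = bins; in memory rows = units
    return matrix, dt, coords


def write_raster(path, raster) -> None:
    if isinstance(raster, SpikeRaster):
        _write_matrix_csv(path, raster.counts, raster.dt, raster.unit_coords,
                          "unit")
    else:
        _write_matrix_csv(path, raster.lam, raster.dt, raster.roi_coords,
                          "roi")


def read_raster(path, kind: str = "rate"):
    """Read a raster CSV; ``kind`` is ``"rate"`` or ``"spike"``."""
    matrix, dt, coords = _read_matrix_csv(path)
    if kind == "spike":
        return SpikeRaster(np.round(matrix).astype(np.int64), dt, coords)
    if kind == "rate":
        return RateRaster(matrix, dt, coords)
    raise ValueError(f"unknown raster kind {kind!r}")


def write_traces(path, traces: CalciumTraceSet) -> None:
    _write_matrix_csv(path, traces.ratio, traces.dt, traces.roi_coords, "roi")


def read_traces(path, is_drr: bool = True) -> CalciumTraceSet:
    matrix, dt, coords = _read_matrix_csv(path)
    return CalciumTraceSet(matrix, dt, roi_coords=coords, is_drr=is_drr)


def write_catalog(path, catalog: AvalancheCatalog) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# dt={_FMT % catalog.dt}\n")
        fh.write(f"# lam_thr={_FMT % catalog.lam_thr}\n")
        fh.write(f"# n_rois={catalog.n_rois}\n")
        fh.write(f"# lam_avg_pop={_FMT % catalog.lam_avg_pop}\n")
        fh.write(f"# duration_s={_FMT % catalog.duration_s}\n")
        fh.write("id,start_bin,n_bins,s_k,s_lambda,s_norm,lifetime_s,"
                 "participation\n")
        lim = catalog.size_limit
        for i, c in enumerate(catalog.clusters):
            part = ";".join(str(int(p)) for p in c.per_bin_participation)
            fh.write(f"{i},{c.start_bin},{c.n_bins},{c.s_k},"
                     f"{_FMT % c.s_lambda},{_FMT % (c.s_lambda / lim)},"
                     f"{_FMT % c.lifetime_s},{part}\n")


def read_catalog(path) -> AvalancheCatalog:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    body = []
    for ln in lines:
        if ln.startswith("#"):
            k, _, v = ln[1:].strip().partition("=")
            meta[k.strip()] = v
        else:
            body.append(ln)
    for key in ("dt", "lam_thr", "n_rois", "lam_avg_pop", "duration_s"):
        if key not in meta:
            raise ValueError(f"{path}: missing '# {key}=' metadata line")
    clusters = []
    for ln in body[1:]:
        (_, start, nb, s_k, s_lam, _s_norm, life, part) = ln.split(",")
        participation = np.array([int(p) for p in part.split(";") if p])
        clusters.append(Cluster(int(start), int(nb), participation,
                                float(s_lam), int(s_k), float(life)))
    return AvalancheCatalog(clusters, float(meta["lam_thr"]),
                            float(meta["dt"]), int(meta["n_rois"]),
                            float(meta["lam_avg_pop"]),
                            float(meta["duration_s"]))


def write_raster_h5(path, raster) -> None:
    with h5py.File(path, "w") as fh:
        if isinstance(raster, SpikeRaster):
            fh.create_dataset("counts", data=raster.counts)
            coords = raster.unit_coords
        else:
            fh.create_dataset("lam", data=raster.lam)
            coords = raster.roi_coords
        fh.create_dataset("dt", data=raster.dt)
        if coords is not None:
            fh.create_dataset("coords", data=coords)


def read_raster_h5(path):
    with h5py.File(path, "r") as fh:
        dt = float(fh["dt"][()])
        coords = fh["coords"][()] if "coords" in fh else None
        if "counts" in fh:
            return SpikeRaster(fh["counts"][()], dt, coords)
        return RateRaster(fh["lam"][()], dt, coords)
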
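"""Gridded habitat-suitability projection of a fitted occupancy model.

The study region (already in a projected CRS, meters) is tiled into 500 m
cells; each cell carries the same covariates the model was trained on, is
standardized with the *training* transform parameters, and gets a posterior
habitat-use probability per cell: mean and central 95% interval of
inverse-logit(beta0 + X beta + alpha*) over the posterior draws. By default
alpha* = 0 (the typical-station surface, "conditional" mode); "marginal"
mode draws a fresh station effect per cell and draw. Detection-side
covariates play no role here — the surface is the psi side only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import PosteriorFit


@dataclass
class PredictionGrid:
    """Row-major grid cells over a rectangular extent.

    ``cells`` has one row per cell: cell_id, x, y (true centroid, partial
    edge cells included) and, after prediction, psi_mean / psi_lo / psi_hi.
    """

    cells: pd.DataFrame
    cell_size: float
    extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    nx: int
    ny: int

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def make_grid(
    extent: tuple[float, float, float, float], cell_size: float = 500.0
) -> PredictionGrid:
    """Tile a projected-meter extent with square cells, row-major from the
    lower-left corner; partial edge cells are retained with the centroid of
    their clipped area."""
    xmin, ymin, xmax, ymax = map(float, extent)
    if cell_size <= 0:
        raise ValueError("cell size must be positive")
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("extent is degenerate")
    nx = int(np.ceil((xmax - xmin) / cell_size))
    ny = int(np.ceil((ymax - ymin) / cell_size))
    rows = []
    cid = 0
    for iy in range(ny):
        y0 = ymin + iy * cell_size
        y1 = min(y0 + cell_size, ymax)
        for ix in range(nx):
            x0 = xmin + ix * cell_size
            x1 = min(x0 + cell_size, xmax)
            rows.append(
                {
                    "cell_id": cid,
                    "row": iy,
                    "col": ix,
                    "x": 0.5 * (x0 + x1),
                    "y": 0.5 * (y0 + y1),
                }
            )
            cid += 1
    return PredictionGrid(
        cells=pd.DataFrame(rows),
        cell_size=cell_size,
        extent=(xmin, ymin, xmax, ymax),
        nx=nx,
        ny=ny,
    )


def predict_psi(
    fit: PosteriorFit,
    grid: PredictionGrid,
    transform_params: dict[str, tuple[float, float]] | None = None,
    mode: str = "conditional",
    seed: int = 0,
    ci: float = 0.95,
    extrapolation_sd: float = 4.0,
) -> PredictionGrid:
    """Attach posterior habitat-use summaries to every grid cell.

    Grid covariates must be raw-scale; they are standardized here with the
    training ``transform_params`` (defaults to the ones stored in the fit).
    Cells whose standardized covariates sit more than ``extrapolation_sd``
    SDs from the training mean trigger an extrapolation warning.
    """
    if mode not in ("conditional", "marginal"):
        raise ValueError("mode must be 'conditional' or 'marginal'")
    tp = transform_params or fit.design.transform_params
    terms = [t for t in fit.design.psi_names if t != "_alpha_offset"]
    missing = [t for t in terms if t not in grid.cells.columns]
    if missing:
        raise KeyError(f"grid lacks model covariates: {missing}")
    X = np.zeros((grid.n_cells, len(terms)))
    for j, t in enumerate(terms):
        x = grid.cells[t].to_numpy(dtype=float)
        if t in tp:
            mean, sd = tp[t]
            x = (x - mean) / sd
        X[:, j] = x
        far = np.abs(x) > extrapolation_sd
        if far.any():
            warnings.warn(
                f"{int(far.sum())} cell(s) extrapolate beyond "
                f"{extrapolation_sd} SD of the training range in {t!r}",
                stacklevel=2,
            )

    beta0 = fit.draws[:, 0]
    beta = fit.draws[:, 1 : 1 + len(terms)]
    sigma = fit.sigma_draws()
    rng = np.random.default_rng(seed)
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2

    n = fit.n_draws
    mean = np.zeros(grid.n_cells)
    lo = np.zeros(grid.n_cells)
    hi = np.zeros(grid.n_cells)
    chunk = max(1, int(5e6 // max(n, 1)))
    for a in range(0, grid.n_cells, chunk):
        eta = beta0[None, :] + X[a : a + chunk] @ beta.T  # (C, n_draws)
        if mode == "marginal":
            eta = eta + rng.standard_normal(eta.shape) * sigma[None, :]
        psi = expit(eta)
        mean[a : a + chunk] = psi.mean(axis=1)
        lo[a : a + chunk] = np.percentile(psi, lo_q, axis=1)
        hi[a : a + chunk] = np.percentile(psi, hi_q, axis=1)

    cells = grid.cells.copy()
    cells["psi_mean"] = mean
    cells["psi_lo"] = lo
    cells["psi_hi"] = hi
    return PredictionGrid(
        cells=cells,
        cell_size=grid.cell_size,
        extent=grid.extent,
        nx=grid.nx,
        ny=grid.ny,
    )


def write_surface(grid: PredictionGrid, path: str, fmt: str = "csv") -> list[str]:
    """Write the predicted surface.

    ``csv`` writes one row per cell (cell_id, x, y, psi_mean, psi_lo,
    psi_hi). ``asc`` additionally needs nothing beyond the grid geometry and
    writes one ESRI ASCII raster per summary (``<path>_mean.asc`` etc.), a
    plain-text georeferenced format GIS tools read directly; raster rows run
    top-down while grid rows run bottom-up, so rows are flipped on write.
    Returns the list of files written.
    """
    for col in ("psi_mean", "psi_lo", "psi_hi"):
        if col not in grid.cells.columns:
            raise ValueError("grid has no predictions; run predict_psi first")
    written = []
    if fmt == "csv":
        out = grid.cells[["cell_id", "x", "y", "psi_mean", "psi_lo", "psi_hi"]]
        out.to_csv(path, index=False)
        written.append(path)
    elif fmt == "asc":
        base = path[:-4] if path.endswith(".asc") else path
        header = (
            f"ncols {grid.nx}\nnrows {grid.ny}\n"
            f"xllcorner {grid.extent[0]}\nyllcorner {grid.extent[1]}\n"
            f"cellsize {grid.cell_size}\nNODATA_value -9999\n"
        )
        for col, tag in (
            ("psi_mean", "mean"),
            ("psi_lo", "lo"),
            ("psi_hi", "hi"),
        ):
            vals = grid.cells[col].to_numpy().reshape(grid.ny, grid.nx)
            fname = f"{base}_{tag}.asc"
            with open(fname, "w") as fh:
                fh.write(header)
                for r in vals[::-1]:
                    fh.write(" ".join(f"{v:.6f}" for v in r) + "\n")
            written.append(fname)
    else:
        raise ValueError(f"unknown surface format {fmt!r}")
    return written


def read_surface(path: str) -> pd.DataFrame:
    """Read back a CSV surface written by :func:`write_surface`."""
    return pd.read_csv(path)
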
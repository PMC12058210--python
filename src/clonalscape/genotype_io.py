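"""Data model and I/O for microsatellite genotypes, site metadata and water rasters.

The package works on diploid codominant marker data: each sample carries an
unordered pair of integer allele sizes at each locus.  Missing data applies to
a whole locus call, never to a single allele; a half-missing call read from
disk is promoted to fully missing with a warning.

Formats handled here:

* genotype CSV -- header ``sample_id,site_id,<locus>_1,<locus>_2,...``; a
  missing allele is encoded as ``0`` or an empty field;
* site metadata CSV -- ``site_id,x,y,river_km,regime,year`` with planar
  (UTM-like, metre) coordinates and ``regime`` in {nontidal, tidal};
* ESRI ASCII grids for the binary water mask (water = 1, land = 0).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing allele inside the calls array (whole-call missing
#: means both entries are MISSING_ALLELE)
MISSING_ALLELE = 0

REGIMES = ("nontidal", "tidal")


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class GenotypeTable:
    """Diploid genotype calls for N samples at L microsatellite loci.

    ``calls`` has shape (N, L, 2) with positive integer allele sizes, stored
    order-normalised (low, high); a fully missing call is (0, 0).
    """

    sample_ids: list[str]
    site_ids: list[str]
    locus_names: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.sample_ids), len(self.locus_names)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)")
        if len(self.site_ids) != n:
            raise ValueError("site_ids length mismatch")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample_id")
        if L < 1:
            raise ValueError("need at least one locus")
        # order-normalise and enforce whole-call missingness
        self.calls = np.sort(self.calls, axis=2)
        half = (self.calls[:, :, 0] == MISSING_ALLELE) & (
            self.calls[:, :, 1] != MISSING_ALLELE)
        if half.any():
            self.calls[half] = MISSING_ALLELE

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def missing_mask(self) -> np.ndarray:
        """(N, L) boolean; True where the locus call is missing."""
        return self.calls[:, :, 0] == MISSING_ALLELE

    def subset(self, idx) -> "GenotypeTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeTable(
            [self.sample_ids[i] for i in idx],
            [self.site_ids[i] for i in idx],
            list(self.locus_names),
            self.calls[idx].copy(),
        )

    def subset_loci(self, loci_idx) -> "GenotypeTable":
        loci_idx = list(loci_idx)
        return GenotypeTable(
            list(self.sample_ids),
            list(self.site_ids),
            [self.locus_names[j] for j in loci_idx],
            self.calls[:, loci_idx].copy(),
        )

    def by_site(self) -> dict[str, np.ndarray]:
        """Map site_id -> sample index array (order of first appearance)."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.site_ids):
            out.setdefault(s, []).append(i)
        return {k: np.array(v) for k, v in out.items()}

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, object] = {
            "sample_id": self.sample_ids, "site_id": self.site_ids}
        for j, locus in enumerate(self.locus_names):
            cols[f"{locus}_1"] = self.calls[:, j, 0]
            cols[f"{locus}_2"] = self.calls[:, j, 1]
        return pd.DataFrame(cols)


@dataclass
class SiteMeta:
    """Site locations and covariates along the riverscape."""

    table: pd.DataFrame  # site_id, x, y, river_km, regime, year

    def __post_init__(self) -> None:
        required = {"site_id", "x", "y", "river_km", "regime", "year"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"site metadata missing columns: {sorted(missing)}")
        t = self.table
        if t["site_id"].duplicated().any():
            raise FormatError("duplicate site_id in site metadata")
        if (t["river_km"] < 0).any():
            raise ValueError("river_km must be >= 0")
        if not np.isfinite(t[["x", "y"]].to_numpy(float)).all():
            raise ValueError("non-finite site coordinates")
        bad = set(t["regime"]) - set(REGIMES)
        if bad:
            raise ValueError(f"unknown regime values: {sorted(bad)}")
        self.table = t.reset_index(drop=True)

    @property
    def site_ids(self) -> list[str]:
        return list(self.table["site_id"])

    def regime_of(self) -> dict[str, str]:
        return dict(zip(self.table["site_id"], self.table["regime"]))

    def river_km_of(self) -> dict[str, float]:
        return dict(zip(self.table["site_id"], self.table["river_km"]))

    def coords(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(float)

    def validate_against(self, gt: GenotypeTable) -> None:
        unknown = set(gt.site_ids) - set(self.site_ids)
        if unknown:
            raise FormatError(
                f"genotype table references unknown sites: {sorted(unknown)}")


@dataclass
class WaterGrid:
    """Binary conductance raster: 1 = water (passable), 0 = land."""

    xll: float
    yll: float
    cell_size: float
    conductance: np.ndarray  # (nrows, ncols) of {0, 1}; row 0 = top (north)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.conductance = np.asarray(self.conductance)
        if self.conductance.ndim != 2:
            raise ValueError("conductance must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        vals = np.unique(self.conductance)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("conductance must be binary")
        self.conductance = self.conductance.astype(np.uint8)

    @property
    def nrows(self) -> int:
        return self.conductance.shape[0]

    @property
    def ncols(self) -> int:
        return self.conductance.shape[1]

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing a point (row 0 at the top edge)."""
        col = int(np.floor((x - self.xll) / self.cell_size))
        row = int(self.nrows - 1 - np.floor((y - self.yll) / self.cell_size))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) outside grid")
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        x = self.xll + (col + 0.5) * self.cell_size
        y = self.yll + (self.nrows - 1 - row + 0.5) * self.cell_size
        return x, y


# ---------------------------------------------------------------------------
# readers / writers

def read_genotype_table(path) -> GenotypeTable:
    """Read a genotype CSV (see module docstring for the dialect).

    Half-missing calls are promoted to fully missing with one warning per
    affected call; an odd number of allele columns is a format error.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "site_id": str})
    cols = list(df.columns)
    if cols[:2] != ["sample_id", "site_id"]:
        raise FormatError("first two columns must be sample_id, site_id")
    allele_cols = cols[2:]
    if len(allele_cols) % 2 != 0:
        raise FormatError("odd number of allele columns")
    loci = []
    for a, b in zip(allele_cols[::2], allele_cols[1::2]):
        if not (a.endswith("_1") and b.endswith("_2") and a[:-2] == b[:-2]):
            raise FormatError(f"allele columns {a!r}, {b!r} not a <locus>_1/_2 pair")
        loci.append(a[:-2])
    raw = df[allele_cols].fillna(0).to_numpy()
    try:
        raw = raw.astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-integer allele call: {exc}") from exc
    calls = raw.reshape(len(df), len(loci), 2)
    half = ((calls == MISSING_ALLELE).sum(axis=2) == 1)
    for i, j in zip(*np.nonzero(half)):
        logger.warning(
            "half-missing call for sample %s at locus %s promoted to missing",
            df["sample_id"].iloc[i], loci[j])
    return GenotypeTable(
        list(df["sample_id"]), list(df["site_id"]), loci, calls)


def write_genotype_table(gt: GenotypeTable, path) -> None:
    gt.to_frame().to_csv(path, index=False)


def read_site_meta(path) -> SiteMeta:
    df = pd.read_csv(path, dtype={"site_id": str})
    return SiteMeta(df)


def write_site_meta(meta: SiteMeta, path) -> None:
    meta.table.to_csv(path, index=False)


_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_water_grid(path) -> WaterGrid:
    """Read an ESRI ASCII grid; NODATA cells become land (conductance 0)."""
    with open(path) as fh:
        header: dict[str, float] = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _ASC_HEADER_KEYS + ("nodata_value",):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        for key in _ASC_HEADER_KEYS:
            if key not in header:
                raise FormatError(f"ESRI ASCII header missing {key}")
        nrows, ncols = int(header["nrows"]), int(header["ncols"])
        nodata = header.get("nodata_value", -9999.0)
        try:
            data = np.loadtxt(fh, dtype=float)
        except ValueError as exc:
            raise FormatError(f"malformed grid body: {exc}") from exc
    data = np.atleast_2d(data)
    if data.shape != (nrows, ncols):
        raise FormatError(
            f"grid body shape {data.shape} != header ({nrows}, {ncols})")
    cond = np.where(data == nodata, 0, data)
    if not np.isin(np.unique(cond), [0, 1]).all():
        raise FormatError("water grid values must be 0/1 (or NODATA)")
    return WaterGrid(header["xllcorner"], header["yllcorner"],
                     header["cellsize"], cond.astype(np.uint8), nodata)


def write_water_grid(grid: WaterGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll:.6f}\n")
        fh.write(f"yllcorner {grid.yll:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata:g}\n")
        np.savetxt(fh, grid.conductance, fmt="%d")


def write_matrix_csv(ids: list[str], matrix: np.ndarray, path) -> None:
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, index_label="id")


def write_run_summary(summary: dict, path) -> None:
    """Deterministic JSON run summary (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
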
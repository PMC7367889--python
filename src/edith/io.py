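"""Readers and writers for the plain-text formats of the pipeline.

DEMs travel as ESRI ASCII grids; everything else (stations, networks,
covariates, read counts, reference presence, predictions) is CSV with a
header row, comma separators and '.' decimals.  Run configuration is YAML
and round-trips unchanged.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import TaxonReads
from .covariates import CovariateMatrix
from .dem import ElevationGrid
from .network import RiverNetwork

__all__ = [
    "ParseError",
    "read_dem",
    "write_dem",
    "read_network",
    "write_network",
    "read_covariates",
    "write_covariates",
    "read_reads_table",
    "write_reads_table",
    "read_stations",
    "read_reference_presence",
    "RunConfig",
]


class ParseError(ValueError):
    """Malformed input file."""


# -- ESRI ASCII grids -----------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_dem(path) -> ElevationGrid:
    """Read an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize
    header, optional NODATA_value, then rows north to south)."""
    path = Path(path)
    header: dict[str, float] = {}
    n_header = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
                try:
                    header[parts[0].lower()] = float(parts[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad header value") from exc
                n_header = lineno
            else:
                break
    for key in _HEADER_KEYS:
        if key not in header:
            raise ParseError(f"{path}: missing header field {key!r} "
                             f"(after line {n_header})")
    data = np.loadtxt(path, skiprows=n_header)
    data = np.atleast_2d(data)
    shape = (int(header["nrows"]), int(header["ncols"]))
    if data.shape != shape:
        raise ParseError(
            f"{path}: data shape {data.shape} does not match header {shape}")
    return ElevationGrid(
        elevation=data,
        cell_size=header["cellsize"],
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_dem(grid: ElevationGrid, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.xllcorner}\n")
        fh.write(f"yllcorner {grid.yllcorner}\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        fh.write(f"NODATA_value {grid.nodata}\n")
        np.savetxt(fh, grid.elevation, fmt="%.6f")


# -- networks -------------------------------------------------------------


def write_network(net: RiverNetwork, path) -> None:
    net.to_dataframe().to_csv(path, index=False)


def read_network(path) -> RiverNetwork:
    return RiverNetwork.from_dataframe(pd.read_csv(path))


# -- covariates -----------------------------------------------------------


def write_covariates(X: CovariateMatrix, path, kinds_path) -> None:
    """Write the reach-by-covariate table plus a YAML sidecar mapping each
    covariate to its kind and (if normalized) its scaling statistics."""
    df = X.values.copy()
    df.insert(0, "id", df.index)
    df.to_csv(path, index=False)
    meta = {
        "kinds": dict(X.kinds),
        "stats": {k: [float(m), float(s)] for k, (m, s) in X.stats.items()},
    }
    Path(kinds_path).write_text(yaml.safe_dump(meta))


def read_covariates(path, kinds_path) -> CovariateMatrix:
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ParseError(f"{path}: missing 'id' column")
    df = df.set_index("id")
    df.index = df.index.astype(str)
    meta = yaml.safe_load(Path(kinds_path).read_text())
    stats = {k: (v[0], v[1]) for k, v in meta.get("stats", {}).items()}
    return CovariateMatrix(values=df, kinds=meta["kinds"], stats=stats)


# -- read-count tables ----------------------------------------------------

READS_COLUMNS = ("site_id", "taxon", "replicate", "n_reads")


def write_reads_table(reads_by_taxon: dict[str, TaxonReads], path) -> None:
    rows = []
    for taxon, reads in reads_by_taxon.items():
        for j, site in enumerate(reads.site_ids):
            for o in range(reads.n_replicates):
                rows.append((site, taxon, o + 1, int(reads.counts[j, o])))
    pd.DataFrame(rows, columns=READS_COLUMNS).to_csv(path, index=False)


def read_reads_table(path) -> dict[str, TaxonReads]:
    """Read a long-format read-count table grouped by taxon.

    Every (site, replicate) combination must be present exactly once per
    taxon — missing combinations are an error, never a silent zero.
    """
    df = pd.read_csv(path)
    missing = set(READS_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df.duplicated(["site_id", "taxon", "replicate"]).any():
        raise ParseError(f"{path}: duplicate (site, taxon, replicate) rows")
    if (df["n_reads"] < 0).any():
        raise ParseError(f"{path}: negative read counts")
    if not np.all(df["n_reads"] == np.floor(df["n_reads"])):
        raise ParseError(f"{path}: non-integer read counts")
    out: dict[str, TaxonReads] = {}
    for taxon, grp in df.groupby("taxon", sort=True):
        pivot = grp.pivot(index="site_id", columns="replicate",
                          values="n_reads")
        if pivot.isna().any().any():
            raise ParseError(
                f"{path}: taxon {taxon!r} is missing (site, replicate) "
                "combinations")
        out[str(taxon)] = TaxonReads(
            site_ids=[str(s) for s in pivot.index],
            counts=pivot.to_numpy().astype(np.int64),
            taxon=str(taxon),
        )
    return out


# -- stations and reference presence -------------------------------------


def read_stations(path) -> pd.DataFrame:
    """Hydrological-station table with columns area_km2, Q, w, D."""
    df = pd.read_csv(path)
    required = {"area_km2", "Q", "w", "D"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_reference_presence(path) -> dict[str, dict[str, bool]]:
    """Reference (e.g. kicknet) presence table: site_id, taxon, present."""
    df = pd.read_csv(path)
    missing = {"site_id", "taxon", "present"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, dict[str, bool]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["taxon"]), {})[str(row["site_id"])] = bool(
            int(row["present"]))
    return out


# -- run configuration ----------------------------------------------------


@dataclass
class RunConfig:
    """Seeds, chain settings and paths for a reproducible pipeline run."""

    network_path: str = "network.csv"
    covariates_path: str = "covariates.csv"
    covariate_kinds_path: str = "covariates.yaml"
    reads_path: str = "reads.csv"
    stations_path: str | None = None
    reference_path: str | None = None
    hydraulic_laws: dict[str, list[float]] = field(
        default_factory=lambda: {"Q": [0.072, 1.056], "w": [1.586, 0.526],
                                 "D": [0.073, 0.463]})
    n_burn: int = 5000
    n_keep: int = 10000
    presence_threshold: float = 2.0 / 3.0
    bootstrap_H: int = 100_000
    n_replicates: int = 3
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
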
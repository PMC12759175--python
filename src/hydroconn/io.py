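"""Readers and writers for the tabular interchange formats.

CSV is the canonical interchange. Schemas:

- ``reaches.csv``: reach_id, length_km, catchment_id, next_down (empty for
  the outlet), optional ``wkt`` geometry.
- ``barriers.csv``: barrier_id, kind {waterfall|anthropogenic}, status
  {existing|planned}, either up_reach/down_reach or reach_id/fraction, and
  optional pass_up/pass_down overrides.
- ``suitability.csv`` (long): reach_id, group (or species_id), climate,
  epoch, suitability.

Outputs (``rci.csv``, ``cci.csv``, ``summary.csv``, ``ranking.csv``,
``sensitivity.csv``) use a fixed column order, floats at 6 significant
digits, and a JSON run manifest recording config, seed and versions, so two
identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .connectivity import ConnectivityResult, PassabilityPolicy
from .river_graph import NetworkError, RiverNetwork, build_network
from .suitability import SuitabilitySet

__all__ = [
    "read_reaches",
    "read_barriers",
    "read_suitability",
    "read_inputs",
    "write_network",
    "write_suitability",
    "write_results",
    "write_ranking",
    "write_sensitivity",
    "export_geojson",
]

FLOAT_FMT = "%.6g"


def _table_error(path, row: int, msg: str) -> NetworkError:
    return NetworkError(f"{path}, row {row}: {msg}")


def read_reaches(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"reach_id": str, "next_down": str})
    for col in ("reach_id", "length_km"):
        if col not in df.columns:
            raise NetworkError(f"{path}: missing required column {col!r}")
    if "catchment_id" not in df.columns:
        df["catchment_id"] = "C0"
    if "next_down" not in df.columns:
        df["next_down"] = None
    for i, v in df["length_km"].items():
        try:
            ok = float(v) > 0
        except (TypeError, ValueError):
            ok = False
        if not ok:
            raise _table_error(path, i + 2, f"length_km must be a positive number, got {v!r}")
    return df


def read_barriers(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"barrier_id": str, "reach_id": str, "up_reach": str, "down_reach": str}
    )
    for col in ("barrier_id", "kind"):
        if col not in df.columns:
            raise NetworkError(f"{path}: missing required column {col!r}")
    for i, row in df.iterrows():
        if row["kind"] not in ("waterfall", "anthropogenic"):
            raise _table_error(path, i + 2, f"unknown kind {row['kind']!r}")
        status = row.get("status")
        if status is not None and not pd.isna(status) and status not in ("existing", "planned"):
            raise _table_error(path, i + 2, f"unknown status {status!r}")
        for col in ("pass_up", "pass_down"):
            v = row.get(col)
            if v is not None and not pd.isna(v) and not 0.0 <= float(v) <= 1.0:
                raise _table_error(path, i + 2, f"{col} = {v} outside [0, 1]")
        has_edge = "up_reach" in df.columns and not pd.isna(row.get("up_reach"))
        has_frac = "fraction" in df.columns and not pd.isna(row.get("fraction"))
        if not has_edge and not has_frac:
            raise _table_error(
                path, i + 2, "barrier needs up_reach/down_reach or reach_id/fraction"
            )
    return df


def read_suitability(path: Union[str, Path]) -> SuitabilitySet:
    df = pd.read_csv(path, dtype={"reach_id": str, "epoch": str})
    need = {"reach_id", "climate", "epoch", "suitability"}
    missing = need - set(df.columns)
    if missing:
        raise NetworkError(f"{path}: missing required columns {sorted(missing)}")
    if "group" not in df.columns and "species_id" not in df.columns:
        raise NetworkError(f"{path}: needs a 'group' or 'species_id' column")
    bad = df.index[(df["suitability"] < 0) | (df["suitability"] > 1)]
    if len(bad):
        raise _table_error(path, bad[0] + 2, f"suitability {df.loc[bad[0], 'suitability']} outside [0, 1]")
    return SuitabilitySet.from_long(df)


def read_inputs(
    in_dir: Union[str, Path],
    reaches: str = "reaches.csv",
    barriers: str = "barriers.csv",
    suitability: str = "suitability.csv",
) -> tuple[RiverNetwork, PassabilityPolicy, Optional[SuitabilitySet]]:
    """Load a directory of input tables into validated domain objects.

    ``barriers.csv`` and ``suitability.csv`` are optional (a barrier-free
    network, or connectivity without suitability weighting). Explicit
    per-barrier passabilities ride on the links; the returned policy carries
    the field defaults.
    """
    in_dir = Path(in_dir)
    reach_df = read_reaches(in_dir / reaches)
    barrier_path = in_dir / barriers
    barrier_df = read_barriers(barrier_path) if barrier_path.exists() else None
    try:
        net = build_network(reach_df, barrier_df)
    except NetworkError as e:
        raise NetworkError(f"{in_dir}: {e}") from e
    suit_path = in_dir / suitability
    suit = read_suitability(suit_path) if suit_path.exists() else None
    return net, PassabilityPolicy(), suit


# -- writers ---------------------------------------------------------------


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_network(network: RiverNetwork, out_dir: Union[str, Path]) -> None:
    """Emit reaches.csv / barriers.csv (barriers by up/down reach adjacency)."""
    out = Path(out_dir)
    reaches = pd.DataFrame(
        [
            {
                "reach_id": r.reach_id,
                "length_km": r.length_km,
                "catchment_id": r.catchment_id,
                "next_down": r.downstream_reach_id or "",
            }
            for r in network.reaches
        ]
    ).sort_values("reach_id", ignore_index=True)
    _write_csv(reaches, out / "reaches.csv")
    barriers = pd.DataFrame(
        [
            {
                "barrier_id": lk.link_id,
                "kind": lk.kind,
                "status": lk.status,
                "up_reach": lk.upstream_reach,
                "down_reach": lk.downstream_reach,
                "pass_up": lk.pass_up,
                "pass_down": lk.pass_down,
            }
            for lk in network.barriers
        ]
    )
    if len(barriers):
        barriers = barriers.sort_values("barrier_id", ignore_index=True)
    _write_csv(barriers, out / "barriers.csv")


def write_suitability(suit: SuitabilitySet, out_dir: Union[str, Path]) -> None:
    _write_csv(suit.to_long(), Path(out_dir) / "suitability.csv")


def write_manifest(
    out_dir: Union[str, Path], seed: Optional[int], config: Mapping
) -> None:
    import numpy, pandas, scipy, networkx  # versions for the record

    manifest = {
        "hydroconn": __version__,
        "seed": seed,
        "config": dict(config),
        "versions": {
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "scipy": scipy.__version__,
            "networkx": networkx.__version__,
        },
    }
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _cell_cols(scenario) -> dict:
    return {
        "barrier_set": scenario.barrier_set,
        "climate": scenario.climate,
        "epoch": scenario.epoch,
        "group": scenario.group,
    }


def write_results(
    results: Mapping, out_dir: Union[str, Path]
) -> None:
    """rci.csv, cci.csv and summary.csv from a scenario_grid result mapping."""
    if not results:
        raise ValueError("no results to write")
    out = Path(out_dir)
    rci_rows, cci_rows, sum_rows = [], [], []
    for spec in sorted(results, key=lambda s: s.label):
        res: ConnectivityResult = results[spec][0] if isinstance(results[spec], tuple) else results[spec]
        cell = _cell_cols(spec)
        suit = (res.rcisuit / res.rci).where(res.rci > 0)
        df = pd.DataFrame(
            {
                "reach_id": res.rci.index,
                **{k: v for k, v in cell.items()},
                "RCI": res.rci.to_numpy(),
                "suitability": suit.to_numpy(),
                "RCIsuit": res.rcisuit.to_numpy(),
            }
        )
        rci_rows.append(df)
        for cid, v in res.cci.items():
            cci_rows.append({"catchment_id": cid, **cell, "CCI": v})
        sum_rows.append({**cell, **res.summary()})
    _write_csv(pd.concat(rci_rows, ignore_index=True), out / "rci.csv")
    _write_csv(pd.DataFrame(cci_rows), out / "cci.csv")
    _write_csv(pd.DataFrame(sum_rows), out / "summary.csv")


def write_ranking(
    results: Mapping, network: RiverNetwork, out_dir: Union[str, Path]
) -> bool:
    """ranking.csv across scenario cells, with per-barrier mean rank appended.

    Returns False (and writes nothing) when no cell produced a ranking.
    """
    from .prioritization import mean_rank

    rows, per_cell = [], []
    for spec in sorted(results, key=lambda s: s.label):
        ranking = results[spec][1]
        if ranking is None:
            continue
        per_cell.append(ranking)
        kind = {lk.link_id: lk.kind for lk in network.barriers}
        status = {lk.link_id: lk.status for lk in network.barriers}
        df = ranking.copy()
        df.insert(1, "kind", df["barrier_id"].map(kind))
        df.insert(2, "status", df["barrier_id"].map(status))
        for k, v in reversed(_cell_cols(spec).items()):
            df.insert(3, k, v)
        rows.append(df)
    if not rows:
        return False
    table = pd.concat(rows, ignore_index=True)
    mr = mean_rank(per_cell)
    table["mean_rank"] = table["barrier_id"].map(mr)
    _write_csv(table, Path(out_dir) / "ranking.csv")
    return True


def write_sensitivity(report: pd.DataFrame, out_dir: Union[str, Path]) -> None:
    _write_csv(report, Path(out_dir) / "sensitivity.csv")


def export_geojson(network: RiverNetwork, path: Union[str, Path]) -> None:
    """Decorative GeoJSON export of reach polylines (reaches with geometry only)."""
    feats = []
    for r in network.reaches:
        if r.geometry is None:
            continue
        feats.append(
            {
                "type": "Feature",
                "geometry": r.geometry.__geo_interface__,
                "properties": {
                    "reach_id": r.reach_id,
                    "length_km": r.length_km,
                    "catchment_id": r.catchment_id,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )
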
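"""Readers and writers for the interchange formats the tool touches.

Time-series tables travel either as OpenSim storage files (``.sto`` /
``.mot``: a free-form header terminated by ``endheader`` with ``nRows`` /
``nColumns`` declarations, then a tab-delimited body whose first column is
``time``) or as plain CSV with a header row. A trial bundle is a directory
holding one moments file, one muscle-tendon-length file, one moment-arm
file per DOF (columns = muscles) and a small JSON sidecar with condition
metadata (gait-cycle boundaries, labels).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .trial import TrialData

__all__ = ["read_storage", "write_storage", "read_trial_bundle",
           "write_trial_bundle"]


def read_storage(path: str | Path) -> pd.DataFrame:
    """Read a labeled time-series table (.sto/.mot storage or CSV).

    Returns a DataFrame whose first column is ``time`` (strictly
    increasing). Raises on header/body row mismatches, non-monotonic time
    and duplicate column names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".sto", ".mot"):
        df = _read_opensim_storage(path)
    else:
        # round_trip parsing keeps the 17-digit writer value-exact
        df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "time":
        raise ValueError(f"{path}: first column must be 'time', got "
                         f"{df.columns[0]!r}")
    if len(set(df.columns)) != len(df.columns):
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate column names {dupes}")
    t = df["time"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    return df


def _read_opensim_storage(path: Path) -> pd.DataFrame:
    lines = path.read_text().splitlines()
    n_rows = n_cols = None
    body_start = None
    for i, line in enumerate(lines):
        s = line.strip()
        if s.lower().startswith("nrows"):
            n_rows = int(s.split("=", 1)[1])
        elif s.lower().startswith("ncolumns"):
            n_cols = int(s.split("=", 1)[1])
        elif s.lower() == "endheader":
            body_start = i + 1
            break
    if body_start is None:
        raise ValueError(f"{path}: no 'endheader' terminator found")
    header = lines[body_start].split()
    rows = [ln.split() for ln in lines[body_start + 1:] if ln.strip()]
    if n_rows is not None and len(rows) != n_rows:
        raise ValueError(
            f"{path}: header declares nRows={n_rows} but body has {len(rows)}"
        )
    if n_cols is not None and len(header) != n_cols:
        raise ValueError(
            f"{path}: header declares nColumns={n_cols} but body has "
            f"{len(header)}"
        )
    data = np.array(rows, dtype=float)
    if data.ndim != 2 or data.shape[1] != len(header):
        raise ValueError(f"{path}: ragged storage body")
    return pd.DataFrame(data, columns=header)


def write_storage(table: pd.DataFrame, path: str | Path,
                  dialect: str | None = None, name: str | None = None) -> None:
    """Write a labeled table as OpenSim storage or CSV (by suffix/dialect).

    Values are formatted with 17 significant digits so a read/write round
    trip is value-exact.
    """
    path = Path(path)
    dialect = dialect or ("storage" if path.suffix.lower() in (".sto", ".mot")
                          else "csv")
    if table.columns[0] != "time":
        raise ValueError("first column must be 'time'")
    if dialect == "csv":
        table.to_csv(path, index=False, float_format="%.17g")
        return
    if dialect != "storage":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write(f"{name or path.stem}\n")
        fh.write("version=1\n")
        fh.write(f"nRows={len(table)}\n")
        fh.write(f"nColumns={len(table.columns)}\n")
        fh.write("inDegrees=no\n")
        fh.write("endheader\n")
        fh.write("\t".join(map(str, table.columns)) + "\n")
        for _, row in table.iterrows():
            fh.write("\t".join(f"{v:.17g}" for v in row.to_numpy()) + "\n")


# ---------------------------------------------------------------------------
# trial bundles
# ---------------------------------------------------------------------------

def write_trial_bundle(trials: list[TrialData], out_dir: str | Path,
                       dialect: str = "csv") -> None:
    """Write one directory per condition with the standard file layout."""
    ext = {"csv": ".csv", "storage": ".sto"}[dialect]
    out = Path(out_dir)
    for tr in trials:
        d = out / tr.condition
        d.mkdir(parents=True, exist_ok=True)
        mom = pd.DataFrame(tr.moments, columns=tr.dof_names)
        mom.insert(0, "time", tr.time)
        write_storage(mom, d / f"moments{ext}", dialect)
        lng = pd.DataFrame(tr.mt_lengths, columns=tr.muscle_names)
        lng.insert(0, "time", tr.time)
        write_storage(lng, d / f"mt_lengths{ext}", dialect)
        for j, dof in enumerate(tr.dof_names):
            arm = pd.DataFrame(tr.moment_arms[:, :, j], columns=tr.muscle_names)
            arm.insert(0, "time", tr.time)
            write_storage(arm, d / f"moment_arms_{dof}{ext}", dialect)
        meta = {
            "condition": tr.condition,
            "cycle_times": [float(x) for x in tr.cycle_times],
            "dof_names": list(tr.dof_names),
            "muscle_names": list(tr.muscle_names),
        }
        (d / "trial.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_trial_bundle(in_dir: str | Path) -> list[TrialData]:
    """Read every condition directory under ``in_dir`` back into TrialData."""
    in_dir = Path(in_dir)
    trials = []
    for d in sorted(p for p in in_dir.iterdir() if (p / "trial.json").exists()):
        meta = json.loads((d / "trial.json").read_text())
        dofs = meta["dof_names"]
        muscles = meta["muscle_names"]

        def find(stem):
            for ext in (".csv", ".sto", ".mot"):
                p = d / f"{stem}{ext}"
                if p.exists():
                    return read_storage(p)
            raise FileNotFoundError(f"{d}: no {stem} file")

        mom = find("moments")
        lng = find("mt_lengths")
        arms = np.stack(
            [find(f"moment_arms_{dof}")[muscles].to_numpy() for dof in dofs],
            axis=2,
        )
        trials.append(TrialData(
            condition=meta["condition"],
            time=mom["time"].to_numpy(),
            moments=mom[dofs].to_numpy(),
            mt_lengths=lng[muscles].to_numpy(),
            moment_arms=arms,
            cycle_times=np.asarray(meta["cycle_times"], dtype=float),
            dof_names=dofs,
            muscle_names=muscles,
        ))
    if not trials:
        raise FileNotFoundError(f"no trial bundles under {in_dir}")
    return trials
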
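"""Reading and writing of traces, ground truth, fits and frame stacks.

Traces travel as long-format CSV with the columns
``cell_id, t_s, long_um, short_um, orient_deg, brightness`` (one protocol
per file, stored as a JSON sidecar or passed explicitly), optionally as
HDF5.  Frame stacks are multi-page TIFF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .protocols import StretchProtocol
from .rheology import KVFit
from .synthetic import CellGroundTruth
from .tracking import AxisTrace, phase_marks_from_protocol

TRACE_COLUMNS = ["cell_id", "t_s", "long_um", "short_um", "orient_deg", "brightness"]


def traces_to_frame(traces: list[AxisTrace]) -> pd.DataFrame:
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "t_s": tr.time,
                    "long_um": tr.long_um,
                    "short_um": tr.short_um,
                    "orient_deg": tr.orientation_deg,
                    "brightness": tr.brightness,
                }
            )
        )
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=TRACE_COLUMNS)


def write_traces(traces: list[AxisTrace], path: str | Path) -> None:
    """Write traces as CSV (or HDF5 when the suffix is .h5/.hdf5)."""
    path = Path(path)
    df = traces_to_frame(traces)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            for col in TRACE_COLUMNS[1:]:
                f.create_dataset(col, data=df[col].to_numpy())
            f.create_dataset(
                "cell_id", data=np.array(df["cell_id"], dtype=h5py.string_dtype())
            )
    else:
        df.to_csv(path, index=False)


def read_traces(path: str | Path, protocol: StretchProtocol) -> list[AxisTrace]:
    """Read a trace CSV/HDF5 back into per-cell :class:`AxisTrace` objects."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            df = pd.DataFrame(
                {
                    "cell_id": [s.decode() for s in f["cell_id"][:]],
                    **{col: f[col][:] for col in TRACE_COLUMNS[1:]},
                }
            )
    else:
        df = pd.read_csv(path)
    traces = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        time = g["t_s"].to_numpy()
        traces.append(
            AxisTrace(
                cell_id=str(cell_id),
                time=time,
                long_um=g["long_um"].to_numpy(),
                short_um=g["short_um"].to_numpy(),
                orientation_deg=g["orient_deg"].to_numpy(),
                brightness=g["brightness"].to_numpy(),
                phase_marks=phase_marks_from_protocol(protocol, time),
                protocol=protocol,
            )
        )
    return traces


def write_ground_truth(truths: list[CellGroundTruth], path: str | Path) -> None:
    pd.DataFrame([vars(t) for t in truths]).to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> list[CellGroundTruth]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [CellGroundTruth(**row) for row in df.to_dict(orient="records")]


def write_fits(fits: list[KVFit], path: str | Path) -> None:
    """One row per cell x signal x window x model."""
    pd.DataFrame([vars(f) for f in fits]).to_csv(path, index=False)


def read_fits(path: str | Path) -> list[KVFit]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [KVFit(**row) for row in df.to_dict(orient="records")]


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(stack))


def read_stack(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)
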
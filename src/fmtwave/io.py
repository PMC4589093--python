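"""HDF5/CSV round-trips for measurements and reconstruction results."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .errors import DataError

__all__ = [
    "write_measurements",
    "read_measurements",
    "write_result",
    "read_result",
    "write_measurements_csv",
]


def write_measurements(
    path,
    y: np.ndarray,
    source_angles_deg: np.ndarray,
    detector_angles_deg: np.ndarray,
    omega: float = 0.0,
    snr_db: float | None = None,
    seed: int | None = None,
    theta_deg: np.ndarray | None = None,
    metadata: dict | None = None,
) -> None:
    """Measurement file: /y_real, /y_imag plus acquisition geometry.

    ``y`` may be (n_meas,) for a single acquisition or (n_angles, n_meas)
    for a rotation schedule (with ``theta_deg`` giving the angles).
    """
    y = np.atleast_2d(np.asarray(y))
    with h5py.File(path, "w") as f:
        f.create_dataset("y_real", data=np.real(y))
        f.create_dataset("y_imag", data=np.imag(y))
        f.create_dataset("source_angles_deg", data=np.asarray(source_angles_deg))
        f.create_dataset("detector_angles_deg", data=np.asarray(detector_angles_deg))
        f.create_dataset("omega", data=float(omega))
        f.create_dataset("snr_db", data=np.nan if snr_db is None else float(snr_db))
        f.create_dataset("seed", data=-1 if seed is None else int(seed))
        if theta_deg is not None:
            f.create_dataset("theta_deg", data=np.asarray(theta_deg))
        if metadata:
            f.attrs["metadata"] = json.dumps(metadata, sort_keys=True)


def read_measurements(path) -> dict:
    try:
        with h5py.File(path, "r") as f:
            out = {
                "y": f["y_real"][()] + 1j * f["y_imag"][()],
                "source_angles_deg": f["source_angles_deg"][()],
                "detector_angles_deg": f["detector_angles_deg"][()],
                "omega": float(f["omega"][()]),
                "snr_db": float(f["snr_db"][()]),
                "seed": int(f["seed"][()]),
                "theta_deg": f["theta_deg"][()] if "theta_deg" in f else None,
                "metadata": json.loads(f.attrs.get("metadata", "{}")),
            }
    except (OSError, KeyError) as exc:
        raise DataError(f"cannot read measurement file {path}") from exc
    if np.isnan(out["snr_db"]):
        out["snr_db"] = None
    if out["omega"] == 0.0:
        out["y"] = np.real(out["y"])
    return out


def write_measurements_csv(path, y: np.ndarray, theta_deg=None) -> None:
    """Flat CSV fallback: columns angle_index, measurement_index, real, imag."""
    y = np.atleast_2d(np.asarray(y))
    with open(path, "w") as f:
        f.write("theta_deg,measurement_index,y_real,y_imag\n")
        for a in range(y.shape[0]):
            th = 0.0 if theta_deg is None else float(np.atleast_1d(theta_deg)[a])
            for m in range(y.shape[1]):
                f.write(f"{th},{m},{float(np.real(y[a, m]))!r},{float(np.imag(y[a, m]))!r}\n")


def write_result(path, result, config_dict: dict | None = None, x_true=None) -> None:
    """Reconstruction result: /x_final, /history table, serialized config."""
    with h5py.File(path, "w") as f:
        f.create_dataset("x_final", data=result.x)
        hist = np.array(
            [
                (
                    h.i,
                    h.theta_deg,
                    h.objective,
                    np.nan if h.mse is None else h.mse,
                    h.cg_iterations,
                    h.wall_s,
                )
                for h in result.history
            ],
            dtype=float,
        )
        f.create_dataset("history", data=hist)
        f["history"].attrs["columns"] = "i,theta_deg,objective,mse,cg_iterations,wall_s"
        f.create_dataset("converged", data=bool(result.converged))
        if x_true is not None:
            f.create_dataset("x_true", data=np.asarray(x_true))
        if config_dict is not None:
            f.attrs["config"] = json.dumps(config_dict, sort_keys=True, default=str)


def read_result(path) -> dict:
    try:
        with h5py.File(path, "r") as f:
            return {
                "x_final": f["x_final"][()],
                "history": f["history"][()],
                "history_columns": f["history"].attrs["columns"].split(","),
                "converged": bool(f["converged"][()]),
                "x_true": f["x_true"][()] if "x_true" in f else None,
                "config": json.loads(f.attrs.get("config", "{}")),
            }
    except (OSError, KeyError) as exc:
        raise DataError(f"cannot read result file {path}") from exc


def dump_sensitivity(path, J: np.ndarray, K: np.ndarray, b: np.ndarray) -> None:
    """Debug dump of the linearized system (/J, /K, /b)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("J", data=np.asarray(J))
        f.create_dataset("K", data=np.asarray(K))
        f.create_dataset("b", data=np.asarray(b))
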
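"""Reading and writing epoched signals (NPY, NPZ, CSV)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import EpochedSignal

__all__ = ["read_signal", "write_signal"]


def read_signal(path: str | Path, sf: float | None = None) -> EpochedSignal:
    """Load an epochs × times array from .npy, .npz or .csv.

    NPZ files carry their own ``sf``; NPY and CSV require ``sf`` from the
    caller. CSV rows are epochs (no header, no index).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    suffix = path.suffix.lower()
    if suffix == ".npz":
        with np.load(path) as f:
            if "data" not in f:
                raise ValueError(f"{path}: NPZ must contain a 'data' array")
            data = f["data"]
            file_sf = float(f["sf"]) if "sf" in f else None
        sf = sf if sf is not None else file_sf
        if sf is None:
            raise ValueError(f"{path}: no sampling frequency in file; pass sf")
        return EpochedSignal(data, sf)
    if suffix == ".npy":
        if sf is None:
            raise ValueError("sampling frequency sf is required for NPY input")
        return EpochedSignal(np.load(path), sf)
    if suffix == ".csv":
        if sf is None:
            raise ValueError("sampling frequency sf is required for CSV input")
        try:
            data = pd.read_csv(path, header=None).to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed CSV ({exc})") from exc
        return EpochedSignal(data, sf)
    raise ValueError(f"unsupported input format {suffix!r} (use .npy, .npz or .csv)")


def write_signal(path: str | Path, sig: EpochedSignal) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        pd.DataFrame(sig.data).to_csv(path, header=False, index=False)
    else:
        sig.save_npz(path)
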
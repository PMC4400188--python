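"""The FidSeries container: a stack of complex FIDs plus acquisition metadata.

On disk this is a self-describing HDF5 file with one dataset ``fids`` of shape
``(n_repetitions, n_points)`` and the acquisition parameters, creation stamp
and generator seed stored as root attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np

from .acquisition import AcquisitionParams
from .errors import ValidationError

__all__ = ["FidSeries"]

_ACQ_ATTRS = (
    "repetition_time",
    "flip_angle_deg",
    "sweep_width",
    "n_points",
    "n_repetitions",
    "reference_frequency_mhz",
)


@dataclass
class FidSeries:
    """Complex time-domain signal per repetition, with acquisition metadata."""

    data: np.ndarray                  # complex128, (n_repetitions, n_points)
    acq: AcquisitionParams
    metabolites: tuple[str, ...] = ()  # provenance only: pools used to render
    seed: int | None = None
    created: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2:
            raise ValidationError("FidSeries data must be 2-D (repetitions x points)")
        if self.data.shape != (self.acq.n_repetitions, self.acq.n_points):
            raise ValidationError(
                f"data shape {self.data.shape} does not match acquisition "
                f"({self.acq.n_repetitions}, {self.acq.n_points})"
            )

    @property
    def n_repetitions(self) -> int:
        return self.data.shape[0]

    def to_hdf5(self, path: str | Path) -> Path:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("fids", data=self.data)
            for name in _ACQ_ATTRS:
                f.attrs[name] = getattr(self.acq, name)
            f.attrs["created"] = self.created
            f.attrs["metabolites"] = list(self.metabolites)
            if self.seed is not None:
                f.attrs["seed"] = int(self.seed)
        return path

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "FidSeries":
        with h5py.File(path, "r") as f:
            data = f["fids"][()]
            raw = {k: f.attrs[k] for k in _ACQ_ATTRS}
            for k in ("n_points", "n_repetitions"):
                raw[k] = int(raw[k])
            for k in ("repetition_time", "flip_angle_deg", "sweep_width", "reference_frequency_mhz"):
                raw[k] = float(raw[k])
            acq = AcquisitionParams(**raw)
            seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
            created = str(f.attrs.get("created", ""))
            metabolites = tuple(str(m) for m in f.attrs.get("metabolites", []))
        return cls(data=data, acq=acq, metabolites=metabolites, seed=seed, created=created)
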
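"""Polar radar volumes and an ODIM-style HDF5 layout.

A volume is one scan time: a stack of PPI sweeps, one per elevation angle,
each carrying gate-wise reflectivity factor (Z, dBZ), differential
reflectivity (ZDR, dB) and co-polar correlation (RHOHV).  Missing gates are
NaN in memory and encoded via a ``nodata`` attribute on disk.

On disk each sweep is a ``/dataset<i>`` group with ``where`` attributes
(elangle, rscale, nbins, nrays) and one ``data<j>`` subgroup per moment
whose ``what/quantity`` names it (DBZH / ZDR / RHOHV), following the ODIM
convention for polar volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

MOMENTS = ("DBZH", "ZDR", "RHOHV")
_ATTR = {"DBZH": "z", "ZDR": "zdr", "RHOHV": "rhohv"}


@dataclass
class Sweep:
    """One PPI: (n_azimuth, n_range) arrays for each polarimetric moment."""

    elevation: float
    z: np.ndarray
    zdr: np.ndarray
    rhohv: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.z.shape, self.zdr.shape, self.rhohv.shape}
        if len(shapes) != 1:
            raise ValueError("moment arrays must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape


@dataclass
class PolarVolume:
    site_id: str
    timestamp: pd.Timestamp
    gate_length: float  # m
    azimuth_step: float  # degrees
    sweeps: dict[float, Sweep] = field(default_factory=dict)

    @property
    def elevations(self) -> tuple[float, ...]:
        return tuple(sorted(self.sweeps))

    def copy(self) -> "PolarVolume":
        return PolarVolume(
            site_id=self.site_id,
            timestamp=self.timestamp,
            gate_length=self.gate_length,
            azimuth_step=self.azimuth_step,
            sweeps={
                el: Sweep(s.elevation, s.z.copy(), s.zdr.copy(), s.rhohv.copy())
                for el, s in self.sweeps.items()
            },
        )

    # -- HDF5 ---------------------------------------------------------------

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["Conventions"] = "ODIM_H5/V2_2-style"
            what = f.create_group("what")
            what.attrs["object"] = "PVOL"
            what.attrs["source"] = self.site_id
            what.attrs["date"] = self.timestamp.strftime("%Y%m%d")
            what.attrs["time"] = self.timestamp.strftime("%H%M%S")
            for i, el in enumerate(self.elevations, start=1):
                sw = self.sweeps[el]
                grp = f.create_group(f"dataset{i}")
                where = grp.create_group("where")
                where.attrs["elangle"] = el
                where.attrs["rscale"] = self.gate_length
                where.attrs["ascale"] = self.azimuth_step
                where.attrs["nrays"], where.attrs["nbins"] = sw.shape
                for j, qty in enumerate(MOMENTS, start=1):
                    arr = getattr(sw, _ATTR[qty])
                    dg = grp.create_group(f"data{j}")
                    dw = dg.create_group("what")
                    dw.attrs["quantity"] = qty
                    dw.attrs["gain"] = 1.0
                    dw.attrs["offset"] = 0.0
                    dw.attrs["nodata"] = -9999.0
                    dg.create_dataset(
                        "data",
                        data=np.where(np.isfinite(arr), arr, -9999.0),
                        compression="gzip",
                        compression_opts=4,
                    )

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "PolarVolume":
        with h5py.File(path, "r") as f:
            what = f["what"].attrs
            ts = pd.Timestamp(f"{_dec(what['date'])}T{_dec(what['time'])}")
            vol = None
            for name in sorted(k for k in f if k.startswith("dataset")):
                grp = f[name]
                where = grp["where"].attrs
                moments: dict[str, np.ndarray] = {}
                for dname in sorted(k for k in grp if k.startswith("data")):
                    dg = grp[dname]
                    qty = _dec(dg["what"].attrs["quantity"])
                    nodata = float(dg["what"].attrs["nodata"])
                    arr = np.asarray(dg["data"], dtype=float)
                    arr[arr == nodata] = np.nan
                    moments[qty] = arr
                missing = set(MOMENTS) - set(moments)
                if missing:
                    raise ValueError(f"sweep {name} lacks moments: {sorted(missing)}")
                if vol is None:
                    vol = cls(
                        site_id=_dec(what["source"]),
                        timestamp=ts,
                        gate_length=float(where["rscale"]),
                        azimuth_step=float(where["ascale"]),
                    )
                el = float(where["elangle"])
                vol.sweeps[el] = Sweep(el, moments["DBZH"], moments["ZDR"], moments["RHOHV"])
        if vol is None:
            raise ValueError("no sweeps in file")
        return vol


def _dec(v) -> str:
    return v.decode() if isinstance(v, bytes) else str(v)
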
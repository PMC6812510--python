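"""MGF spectrum I/O (pyteomics-backed) and the in-memory Spectrum type."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from pyteomics import mgf as _mgf

__all__ = ["Spectrum", "read_mgf", "write_mgf"]


@dataclass
class Spectrum:
    spectrum_id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray
    rt: Optional[float] = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def neutral_mass(self) -> float:
        from .masses import PROTON

        return self.precursor_mz * self.charge - self.charge * PROTON

    def __len__(self) -> int:
        return len(self.mz)


def read_mgf(path: str | Path) -> list[Spectrum]:
    out = []
    with _mgf.read(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            charge = int(params["charge"][0]) if "charge" in params else 2
            rt = params.get("rtinseconds")
            out.append(
                Spectrum(
                    spectrum_id=params.get("title", f"spectrum_{i}"),
                    precursor_mz=float(params["pepmass"][0]),
                    charge=charge,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    rt=float(rt) if rt is not None else None,
                )
            )
    return out


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        params = {"title": s.spectrum_id, "pepmass": s.precursor_mz, "charge": s.charge}
        if s.rt is not None:
            params["rtinseconds"] = s.rt
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _mgf.write(entries, str(path), file_mode="w")
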
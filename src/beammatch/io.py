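"""Plain-text readers and writers for curves, planes and spectra.

Formats:

* IDD curve — two-column CSV ``depth_mm,dose`` with an optional
  ``# nominal_energy_MeV: <E>`` comment line.
* Planar dose — ASCII grid with a three-line header
  (``# z_mm``, ``# pitch_mm``, ``# origin_xy_mm``) followed by
  whitespace-separated rows (row index = y, column index = x).
* Spectrum — two-column CSV ``energy_MeV,weight``.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .gamma import DosePlane
from .idd import EnergySpectrum, IDDCurve
from .optics import SpotPlane

__all__ = [
    "write_idd_csv",
    "read_idd_csv",
    "write_plane_ascii",
    "read_plane_ascii",
    "write_spectrum_csv",
    "read_spectrum_csv",
]


def write_idd_csv(curve: IDDCurve, path: str | Path) -> None:
    path = Path(path)
    lines = []
    if curve.nominal_energy is not None:
        lines.append(f"# nominal_energy_MeV: {curve.nominal_energy}")
    lines.append("depth_mm,dose")
    lines += [f"{z:.6g},{d:.9g}" for z, d in zip(curve.depth_mm, curve.dose)]
    path.write_text("\n".join(lines) + "\n")


def read_idd_csv(path: str | Path) -> IDDCurve:
    path = Path(path)
    energy = None
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "nominal_energy_MeV" in line:
                energy = float(line.split(":")[1])
            continue
        if line.lower().startswith("depth"):
            continue
        z, d = line.split(",")
        rows.append((float(z), float(d)))
    arr = np.asarray(rows)
    return IDDCurve(arr[:, 0], arr[:, 1], energy)


def write_plane_ascii(plane: DosePlane, path: str | Path) -> None:
    z = getattr(plane, "z_mm", 0.0)
    header = (
        f"# z_mm {z:.6g}\n"
        f"# pitch_mm {plane.pitch_mm:.6g}\n"
        f"# origin_xy_mm {plane.origin_mm[0]:.6g} {plane.origin_mm[1]:.6g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, plane.dose, fmt="%.7g")


def read_plane_ascii(path: str | Path, energy: float | None = None) -> SpotPlane:
    path = Path(path)
    with open(path) as fh:
        z = float(fh.readline().split()[-1])
        pitch = float(fh.readline().split()[-1])
        parts = fh.readline().split()
        origin = (float(parts[-2]), float(parts[-1]))
        dose = np.loadtxt(fh)
    return SpotPlane(dose=dose, pitch_mm=pitch, origin_mm=origin, z_mm=z, energy=energy)


def write_spectrum_csv(spectrum: EnergySpectrum, path: str | Path) -> None:
    lines = ["energy_MeV,weight"]
    lines += [f"{e:.6g},{w:.9g}" for e, w in zip(spectrum.energies, spectrum.weights)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum_csv(path: str | Path) -> EnergySpectrum:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    arr = np.atleast_2d(arr)
    return EnergySpectrum(arr[:, 0], arr[:, 1])
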
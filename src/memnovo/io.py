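"""Mascot generic format (MGF) and delimited-table input/output.

Reading uses :mod:`pyteomics.mgf` after a light structural validation that
reports the offending line number on malformed block nesting.  Writing uses a
fixed key order and number formatting so that files produced here round-trip
byte-identically through read → write.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
from pyteomics import mgf as _mgf

from .ion_recall import Spectrum

__all__ = ["read_mgf", "write_mgf"]

_KNOWN_KEYS = ("title", "pepmass", "charge")


def _validate_structure(path: Path) -> None:
    in_block = False
    begin_line = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped == "BEGIN IONS":
                if in_block:
                    raise ValueError(
                        f"{path}: line {lineno}: BEGIN IONS inside an open block "
                        f"(started at line {begin_line})"
                    )
                in_block, begin_line = True, lineno
            elif stripped == "END IONS":
                if not in_block:
                    raise ValueError(f"{path}: line {lineno}: END IONS without BEGIN IONS")
                in_block = False
    if in_block:
        raise ValueError(
            f"{path}: block started at line {begin_line} has no END IONS"
        )


def read_mgf(path: str | Path) -> dict[str, Spectrum]:
    """Spectra keyed by title.  Unknown block keys are retained verbatim."""
    path = Path(path)
    _validate_structure(path)
    store: dict[str, Spectrum] = {}
    with _mgf.read(str(path), convert_arrays=1, read_charges=False) as reader:
        for entry in reader:
            params = entry["params"]
            title = str(params.get("title", f"spectrum{len(store) + 1}"))
            pepmass = params.get("pepmass", (0.0,))
            charge = params.get("charge", [2])
            extra = tuple(
                (k.upper(), str(v))
                for k, v in params.items()
                if k not in _KNOWN_KEYS
            )
            store[title] = Spectrum(
                spectrum_id=title,
                precursor_mz=float(pepmass[0]),
                precursor_charge=int(charge[0]),
                mz=np.asarray(entry["m/z array"], dtype=float),
                intensity=np.asarray(entry["intensity array"], dtype=float),
                extra=extra,
            )
    return store


def write_mgf(store: Mapping[str, Spectrum], path: str | Path) -> None:
    """Deterministic MGF writer (fixed key order, %.6f m/z, %.1f intensity)."""
    with open(path, "w") as fh:
        for spec in store.values():
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={spec.spectrum_id}\n")
            fh.write(f"PEPMASS={spec.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={spec.precursor_charge}+\n")
            for key, value in spec.extra:
                fh.write(f"{key}={value}\n")
            for mz, inten in zip(spec.mz, spec.intensity):
                fh.write(f"{mz:.6f} {inten:.1f}\n")
            fh.write("END IONS\n")
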
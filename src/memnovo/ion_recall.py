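"""Fragment-ion recall: the fraction of expected b/y ions seen in a spectrum.

For a peptide of length n there are n−1 theoretical ions per series and
charge state.  The recall of a series is the fraction of those ions for which
at least one experimental peak lies within the ppm tolerance (matching is
presence-only; a peak may satisfy several theoretical ions).  Ion recall
quantifies how well a peptide fragments under the acquisition conditions and
is strongly predictive of whether its spectrum can be sequenced de novo.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem import DEFAULT_TABLE, Peptide, ResidueMassTable, theoretical_fragments
from .datasets import PeptideDataset

__all__ = ["Spectrum", "IonRecallRecord", "series_recall", "ion_recall_table"]


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS/MS spectrum with peaks sorted ascending by m/z."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray
    extra: tuple[tuple[str, str], ...] = ()  # unknown MGF keys, preserved

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            raise ValueError("peaks must be sorted ascending by m/z")
        if self.intensity.size and np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class IonRecallRecord:
    spectrum_id: str
    peptide: str
    b_recall: float
    y_recall: float
    charge_state_considered: int = 1


def series_recall(
    spectrum: Spectrum,
    peptide: Peptide,
    series: str,
    charge: int = 1,
    tol_ppm: float = 15.0,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> float:
    """Fraction of the n−1 theoretical series ions with a peak inside tolerance."""
    if series not in ("a", "b", "y"):
        raise ValueError("series must be 'a', 'b' or 'y'")
    frags = theoretical_fragments(peptide, table, ion_types=[(series, "none", charge)])
    if spectrum.mz.size == 0:
        return 0.0
    theo = np.array([f.mz for f in frags])
    lo = theo * (1 - tol_ppm * 1e-6)
    hi = theo * (1 + tol_ppm * 1e-6)
    # a theoretical ion is matched iff any observed peak falls in [lo, hi]
    left = np.searchsorted(spectrum.mz, lo, side="left")
    right = np.searchsorted(spectrum.mz, hi, side="right")
    return float(np.count_nonzero(right > left)) / len(frags)


def ion_recall_table(
    spectra: Mapping[str, Spectrum],
    annotations: PeptideDataset,
    tol_ppm: float = 15.0,
    charge: int = 1,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> list[IonRecallRecord]:
    """One b/y recall record per annotated spectrum.

    Raises if any annotation references a spectrum id absent from the store,
    listing every unresolved id.
    """
    missing = [r.spectrum_id for r in annotations.records if r.spectrum_id not in spectra]
    if missing:
        raise KeyError(f"unresolved spectrum ids: {sorted(set(missing))}")
    out: list[IonRecallRecord] = []
    for rec in annotations.records:
        spec = spectra[rec.spectrum_id]
        pep = Peptide.from_string(rec.peptide, table)
        out.append(
            IonRecallRecord(
                spectrum_id=rec.spectrum_id,
                peptide=rec.peptide,
                b_recall=series_recall(spec, pep, "b", charge, tol_ppm, table),
                y_recall=series_recall(spec, pep, "y", charge, tol_ppm, table),
                charge_state_considered=charge,
            )
        )
    return out
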
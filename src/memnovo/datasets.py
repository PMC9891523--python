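"""Peptide dataset assembly and termini-diversity metrics.

A *dataset* is a named collection of annotated peptides (sequence with
modification tokens, charge, precursor m/z, source enzyme, spectrum id).
Model-building style datasets are derived from it:

* SEM-style — peptides from a single protease;
* MoTM-style — restricted to a fixed residue at one terminus;
* MuTM/MEM-style — merged or balanced-sampled across several source datasets.

The diversity of a dataset's termini is summarised by the number of distinct
N-terminal (``Tn``) and C-terminal (``Tc``) residue trimers over its unique
bare sequences, and by the diversity factor ``DF = log10(Tn / Tc)``:
zero means balanced termini variability, positive means N-richer, negative
C-richer.  Trimers are well defined and non-overlapping because every
dataset enforces a minimum peptide length of 6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import DEFAULT_TABLE, ResidueMassTable, peptide_neutral_mass, ppm_match, strip_modifications, tokenize

__all__ = [
    "AnnotatedPeptide",
    "PeptideDataset",
    "DiversityProfile",
    "terminal_trimers",
    "diversity_factor",
    "diversity_profile",
    "sample_equal",
    "split_dataset",
    "build_motm",
    "build_mem",
    "read_dataset_table",
    "write_dataset_table",
]

MIN_PEPTIDE_LENGTH = 6
TRIMER_SPACE = 20**3  # bare-residue trimers


@dataclass(frozen=True)
class AnnotatedPeptide:
    """A confidently identified peptide-spectrum annotation."""

    peptide: str  # modified-sequence string, e.g. "AC(cam)DEFK"
    charge: int = 2
    precursor_mz: float | None = None
    source_enzyme: str = ""
    spectrum_id: str = ""
    sample_label: str = ""

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def tokens(self) -> list[str]:
        return tokenize(self.peptide)

    @property
    def bare_sequence(self) -> str:
        return strip_modifications(self.tokens)

    def neutral_mass(self, table: ResidueMassTable = DEFAULT_TABLE) -> float:
        return peptide_neutral_mass(self.tokens, table)

    def precursor_consistent(
        self, tol_ppm: float = 15.0, table: ResidueMassTable = DEFAULT_TABLE
    ) -> bool:
        """Whether the recorded precursor m/z matches the sequence within tolerance."""
        if self.precursor_mz is None:
            return True
        expected = (self.neutral_mass(table) + self.charge * table.proton) / self.charge
        return ppm_match(self.precursor_mz, expected, tol_ppm)


@dataclass(frozen=True)
class PeptideDataset:
    name: str
    records: tuple[AnnotatedPeptide, ...]
    role: str = "unsplit"  # train, valid, test or unsplit

    def __post_init__(self) -> None:
        if self.role not in ("train", "valid", "test", "unsplit"):
            raise ValueError(f"invalid role {self.role!r}")

    def __len__(self) -> int:
        return len(self.records)

    def unique_peptides(self) -> list[str]:
        """Unique modified-sequence strings, in first-appearance order."""
        return list(dict.fromkeys(r.peptide for r in self.records))

    def validate_lengths(self) -> None:
        for r in self.records:
            if len(r.tokens) < MIN_PEPTIDE_LENGTH:
                raise ValueError(
                    f"peptide {r.peptide!r} shorter than the minimum length "
                    f"{MIN_PEPTIDE_LENGTH} enforced for dataset {self.name!r}"
                )


@dataclass(frozen=True)
class DiversityProfile:
    name: str
    Tn: int
    Tc: int
    DF: float
    n_records: int


def terminal_trimers(dataset: PeptideDataset, terminus: str) -> set[str]:
    """Distinct terminal residue trimers over the dataset's unique sequences.

    Modifications are stripped first: the trimer space is the bare 20-residue
    alphabet.  ``terminus`` is ``"N"`` (first three residues) or ``"C"``
    (last three).
    """
    if terminus not in ("N", "C"):
        raise ValueError("terminus must be 'N' or 'C'")
    dataset.validate_lengths()
    trimers: set[str] = set()
    for pep in dict.fromkeys(r.bare_sequence for r in dataset.records):
        trimers.add(pep[:3] if terminus == "N" else pep[-3:])
    return trimers


def diversity_factor(Tn: int, Tc: int) -> float:
    """``DF = log10(Tn / Tc)``; positive means N-terminally richer."""
    if Tn < 1 or Tc < 1:
        raise ValueError("trimer counts must be >= 1")
    return math.log10(Tn / Tc)


def diversity_profile(dataset: PeptideDataset) -> DiversityProfile:
    tn = len(terminal_trimers(dataset, "N"))
    tc = len(terminal_trimers(dataset, "C"))
    return DiversityProfile(dataset.name, tn, tc, diversity_factor(tn, tc), len(dataset))


def _unique_records(dataset: PeptideDataset) -> list[AnnotatedPeptide]:
    """One record per unique modified sequence (first occurrence kept)."""
    seen: dict[str, AnnotatedPeptide] = {}
    for r in dataset.records:
        seen.setdefault(r.peptide, r)
    return list(seen.values())


def sample_equal(
    datasets: Sequence[PeptideDataset], n: int, seed: int
) -> list[PeptideDataset]:
    """Draw exactly ``n`` unique peptides without replacement from each dataset.

    Equal-size sampling makes diversity and recall metrics comparable across
    source enzymes.  Reproducible for a fixed seed; each dataset gets an
    independent substream so adding a dataset does not change the others'
    draws.
    """
    out: list[PeptideDataset] = []
    for i, ds in enumerate(datasets):
        uniq = _unique_records(ds)
        if len(uniq) < n:
            raise ValueError(
                f"dataset {ds.name!r} has only {len(uniq)} unique peptides, need {n}"
            )
        rng = np.random.default_rng([seed, i])
        idx = rng.choice(len(uniq), size=n, replace=False)
        out.append(PeptideDataset(ds.name, tuple(uniq[j] for j in sorted(idx)), ds.role))
    return out


def split_dataset(
    dataset: PeptideDataset,
    fractions: tuple[float, float, float] = (0.9, 0.05, 0.05),
    seed: int = 0,
) -> tuple[PeptideDataset, PeptideDataset, PeptideDataset]:
    """Random disjoint train/valid/test partition.

    Train takes ``floor(f_train * n)`` records; the remainder is split evenly
    between valid and test, with any odd record going to valid.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    n = len(dataset)
    rng = np.random.default_rng([seed, 0xD5])
    order = rng.permutation(n)
    n_train = int(math.floor(fractions[0] * n))
    rem = n - n_train
    n_valid = (rem + 1) // 2
    parts = (
        order[:n_train],
        order[n_train : n_train + n_valid],
        order[n_train + n_valid :],
    )
    roles = ("train", "valid", "test")
    return tuple(  # type: ignore[return-value]
        PeptideDataset(
            f"{dataset.name}-{role}",
            tuple(dataset.records[j] for j in sorted(part)),
            role,
        )
        for part, role in zip(parts, roles)
    )


def build_motm(
    dataset: PeptideDataset, residue: str, terminus: str, n: int, seed: int
) -> PeptideDataset:
    """Monoterminal training set: peptides sharing one residue at one terminus."""
    if terminus not in ("N", "C"):
        raise ValueError("terminus must be 'N' or 'C'")
    pos = 0 if terminus == "N" else -1
    matching = [
        r for r in _unique_records(dataset) if r.bare_sequence[pos] == residue
    ]
    if len(matching) < n:
        raise ValueError(
            f"only {len(matching)} peptides with {residue!r} at the {terminus}-terminus "
            f"in {dataset.name!r}, need {n}"
        )
    rng = np.random.default_rng([seed, ord(residue), 0 if terminus == "N" else 1])
    idx = sorted(rng.choice(len(matching), size=n, replace=False))
    name = f"{residue}{terminus}-MoTM({dataset.name})"
    return PeptideDataset(name, tuple(matching[j] for j in idx), dataset.role)


def build_mem(
    datasets: Sequence[PeptideDataset],
    mode: str = "union",
    n: int | None = None,
    seed: int = 0,
    name: str | None = None,
) -> PeptideDataset:
    """Merge source datasets into a multienzyme (or multiterminal) set.

    ``union`` keeps every unique peptide across sources.  ``balanced-sample``
    draws ``n`` peptides in equal parts from the sources (how a
    maximum-termini-variability set is built at single-enzyme size).
    """
    if len(datasets) < 2 and mode == "balanced-sample":
        raise ValueError("balanced-sample needs >= 2 source datasets")
    names = [d.name for d in datasets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate dataset names: {names}")
    label = name or "+".join(names)
    if mode == "union":
        merged: dict[str, AnnotatedPeptide] = {}
        for ds in datasets:
            for r in _unique_records(ds):
                merged.setdefault(r.peptide, r)
        return PeptideDataset(label, tuple(merged.values()), "unsplit")
    if mode == "balanced-sample":
        if n is None:
            raise ValueError("balanced-sample requires n")
        k = len(datasets)
        quota = [n // k + (1 if i < n % k else 0) for i in range(k)]
        picked = sample_equal(datasets, max(quota), seed)
        records: list[AnnotatedPeptide] = []
        for q, ds in zip(quota, picked):
            records.extend(ds.records[:q])
        return PeptideDataset(label, tuple(records), "unsplit")
    raise ValueError(f"unknown mode {mode!r}")


_COLUMNS = ["peptide", "charge", "precursor_mz", "enzyme", "spectrum_id", "sample_label"]


def write_dataset_table(dataset: PeptideDataset, path: str | Path) -> None:
    """Tab-separated annotation table, one row per record."""
    df = pd.DataFrame(
        {
            "peptide": [r.peptide for r in dataset.records],
            "charge": [r.charge for r in dataset.records],
            "precursor_mz": [r.precursor_mz for r in dataset.records],
            "enzyme": [r.source_enzyme for r in dataset.records],
            "spectrum_id": [r.spectrum_id for r in dataset.records],
            "sample_label": [r.sample_label for r in dataset.records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_dataset_table(
    path: str | Path, name: str | None = None, role: str = "unsplit"
) -> PeptideDataset:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table {path} lacks columns: {missing}")
    records = tuple(
        AnnotatedPeptide(
            peptide=row.peptide,
            charge=int(row.charge),
            precursor_mz=None if pd.isna(row.precursor_mz) else float(row.precursor_mz),
            source_enzyme="" if pd.isna(row.enzyme) else str(row.enzyme),
            spectrum_id="" if pd.isna(row.spectrum_id) else str(row.spectrum_id),
            sample_label="" if pd.isna(row.sample_label) else str(row.sample_label),
        )
        for row in df.itertuples()
    )
    return PeptideDataset(name or Path(path).stem, records, role)
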
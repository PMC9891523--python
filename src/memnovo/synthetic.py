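"""Synthetic ground truth for every pipeline stage.

The generator emulates the statistical structure of a multienzyme bottom-up
experiment with known, recoverable parameters:

* a random proteome drawn from a residue-composition model;
* per-enzyme in-silico digests annotated as peptide datasets;
* HCD-like MS/MS spectra containing each singly-charged b/y ion
  independently with probability ``1 − dropout``, m/z jitter within a ppm
  band, and uniform noise peaks;
* surrogate de novo predictions whose per-peptide correctness probability is
  ``clamp(p0 · decay^(length−6) + coupling · (mean b/y ion recall − 0.5))``,
  so that recall decays with peptide length and rises with spectrum quality.

Every stage derives its random stream from the scenario seed, so a scenario
is fully deterministic end to end.  Incorrect predictions are near-isobaric
single substitutions when one exists within the precursor tolerance, else a
random (non Ile/Leu) substitution — mimicking real de novo failure modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chem import (
    DEFAULT_TABLE,
    Peptide,
    ResidueMassTable,
    theoretical_fragments,
    tokenize,
)
from .datasets import AnnotatedPeptide, PeptideDataset
from .digestion import DigestParams, digest, get_rule
from .evaluation import PredictionRecord
from .ion_recall import IonRecallRecord, Spectrum

__all__ = [
    "SyntheticScenario",
    "COMPOSITIONS",
    "generate_proteome",
    "digest_proteome",
    "simulate_spectrum",
    "simulate_spectra",
    "simulate_predictions",
]

_RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Residue-composition presets.  "vertebrate" follows typical proteome-wide
#: frequencies (UniProt-style averages), which gives realistic cleavage-site
#: densities for the built-in proteases.
COMPOSITIONS: dict[str, dict[str, float]] = {
    "uniform": {r: 1.0 / 20 for r in _RESIDUES},
    "vertebrate": {
        "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
        "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
        "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
        "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
    },
}


@dataclass(frozen=True)
class SyntheticScenario:
    """All knobs of the generator, with study-scale defaults.

    ``ion_dropout`` maps series ('b', 'y') to the per-ion probability of the
    fragment being absent from the spectrum; ``mz_jitter_ppm`` bounds the
    uniform mass error applied to retained fragment peaks.
    """

    seed: int = 0
    n_proteins: int = 50
    protein_length_range: tuple[int, int] = (200, 600)
    enzymes: tuple[str, ...] = ("trypsin", "chymotrypsin", "elastase", "gluC", "pepsin")
    residue_frequencies: str | Mapping[str, float] = "vertebrate"
    ion_dropout: Mapping[str, float] = field(
        default_factory=lambda: {"b": 0.3, "y": 0.3}
    )
    mz_jitter_ppm: float = 5.0
    n_noise_peaks: int = 10
    predictor_base_accuracy: float = 0.6
    predictor_length_decay: float = 1.0
    predictor_ionrecall_coupling: float = 0.0
    digest_params: DigestParams = field(default_factory=DigestParams)

    def __post_init__(self) -> None:
        for series, d in self.ion_dropout.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"dropout for series {series!r} outside [0, 1]")
        if not 0.0 <= self.predictor_base_accuracy <= 1.0:
            raise ValueError("predictor_base_accuracy must be in [0, 1]")
        if not 0.0 < self.predictor_length_decay <= 1.0:
            raise ValueError("predictor_length_decay must be in (0, 1]")
        if self.mz_jitter_ppm < 0:
            raise ValueError("mz_jitter_ppm must be >= 0")

    def composition(self) -> tuple[tuple[str, ...], np.ndarray]:
        freqs = (
            COMPOSITIONS[self.residue_frequencies]
            if isinstance(self.residue_frequencies, str)
            else dict(self.residue_frequencies)
        )
        residues = tuple(freqs)
        probs = np.array([freqs[r] for r in residues], dtype=float)
        if np.any(probs < 0) or probs.sum() <= 0:
            raise ValueError("invalid residue frequencies")
        return residues, probs / probs.sum()

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])


def generate_proteome(scenario: SyntheticScenario) -> dict[str, str]:
    """Random protein sequences keyed ``sp0001`` …, reproducible per seed."""
    lo, hi = scenario.protein_length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"degenerate protein length range ({lo}, {hi})")
    residues, probs = scenario.composition()
    rng = scenario.rng(1)
    proteome: dict[str, str] = {}
    for i in range(scenario.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(residues, size=length, p=probs))
        proteome[f"sp{i + 1:04d}"] = seq
    return proteome


def digest_proteome(
    scenario: SyntheticScenario,
    proteome: Mapping[str, str] | None = None,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> dict[str, PeptideDataset]:
    """Per-enzyme annotated datasets from the in-silico digests.

    Each unique peptide becomes one annotation carrying the fixed Cys
    carbamidomethylation, a charge of 2 and a consistent precursor m/z.
    Spectrum ids encode the enzyme so stores from several enzymes can merge.
    """
    if proteome is None:
        proteome = generate_proteome(scenario)
    out: dict[str, PeptideDataset] = {}
    for enzyme in scenario.enzymes:
        rule = get_rule(enzyme)
        seen: dict[str, AnnotatedPeptide] = {}
        for name, seq in proteome.items():
            for dp in digest(seq, rule, scenario.digest_params, table):
                modseq = dp.sequence.replace("C", "C(cam)")
                if modseq in seen:
                    continue
                pep = Peptide.from_string(modseq, table)
                charge = 2
                seen[modseq] = AnnotatedPeptide(
                    peptide=modseq,
                    charge=charge,
                    precursor_mz=pep.mz(charge, table),
                    source_enzyme=enzyme,
                    spectrum_id=f"{enzyme}:{len(seen):06d}",
                    sample_label="synthetic",
                )
        out[enzyme] = PeptideDataset(enzyme, tuple(seen.values()), "unsplit")
    return out


def simulate_spectrum(
    peptide: Peptide,
    scenario: SyntheticScenario,
    rng: np.random.Generator,
    spectrum_id: str = "",
    charge: int = 2,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> Spectrum:
    """One HCD-like spectrum: surviving jittered b/y peaks plus uniform noise."""
    frags = theoretical_fragments(
        peptide, table, ion_types=[("b", "none", 1), ("y", "none", 1)]
    )
    mzs: list[float] = []
    span = (min(f.mz for f in frags), max(f.mz for f in frags))
    for f in frags:
        if rng.random() >= scenario.ion_dropout.get(f.series, 0.0):
            jitter = rng.uniform(-scenario.mz_jitter_ppm, scenario.mz_jitter_ppm)
            mzs.append(f.mz * (1 + jitter * 1e-6))
    if scenario.n_noise_peaks:
        mzs.extend(rng.uniform(span[0], span[1], size=scenario.n_noise_peaks))
    mz = np.sort(np.asarray(mzs, dtype=float))
    intensity = np.ones_like(mz)
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=peptide.mz(charge, table),
        precursor_charge=charge,
        mz=mz,
        intensity=intensity,
    )


def simulate_spectra(
    annotations: PeptideDataset,
    scenario: SyntheticScenario,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> dict[str, Spectrum]:
    """A spectra store for every annotation, keyed by spectrum id.

    Each spectrum draws its randomness from a stream derived from the
    scenario seed and the record's position, so stores are reproducible and
    independent of generation order.
    """
    store: dict[str, Spectrum] = {}
    for i, rec in enumerate(annotations.records):
        rng = scenario.rng(2, i)
        pep = Peptide.from_string(rec.peptide, table)
        store[rec.spectrum_id] = simulate_spectrum(
            pep, scenario, rng, rec.spectrum_id, rec.charge, table
        )
    return store


def _substitute(
    tokens: list[str],
    rng: np.random.Generator,
    neutral_mass: float,
    tol_ppm: float = 15.0,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> list[str]:
    """An incorrect variant: near-isobaric swap if one fits the tolerance."""
    tol_da = neutral_mass * tol_ppm * 1e-6
    candidates: list[tuple[int, str]] = []
    for pos, tok in enumerate(tokens):
        base = tok[0]
        for res in _RESIDUES:
            if res == base or {res, base} == {"I", "L"}:
                continue
            if abs(table.mass(res) - table.mass(tok)) <= tol_da:
                candidates.append((pos, res))
    if candidates:
        pos, res = candidates[int(rng.integers(len(candidates)))]
    else:
        pos = int(rng.integers(len(tokens)))
        base = tokens[pos][0]
        choices = [r for r in _RESIDUES if r != base and {r, base} != {"I", "L"}]
        res = choices[int(rng.integers(len(choices)))]
    out = list(tokens)
    out[pos] = res
    return out


def simulate_predictions(
    truths: PeptideDataset,
    scenario: SyntheticScenario,
    ion_records: Sequence[IonRecallRecord] | None = None,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> list[PredictionRecord]:
    """Surrogate predictor output with controllable error structure."""
    coupling = scenario.predictor_ionrecall_coupling
    ion_by_id: dict[str, IonRecallRecord] = {}
    if coupling != 0.0:
        if ion_records is None:
            raise ValueError("ion_records required when ion-recall coupling is nonzero")
        ion_by_id = {r.spectrum_id: r for r in ion_records}
        missing = [
            r.spectrum_id for r in truths.records if r.spectrum_id not in ion_by_id
        ]
        if missing:
            raise KeyError(f"no ion-recall record for: {sorted(set(missing))}")
    out: list[PredictionRecord] = []
    for i, rec in enumerate(truths.records):
        rng = scenario.rng(3, i)
        tokens = rec.tokens
        p = scenario.predictor_base_accuracy * (
            scenario.predictor_length_decay ** (len(tokens) - 6)
        )
        if coupling != 0.0:
            ion = ion_by_id[rec.spectrum_id]
            p += coupling * ((ion.b_recall + ion.y_recall) / 2 - 0.5)
        p = min(1.0, max(0.0, p))
        if rng.random() < p:
            predicted = rec.peptide
        else:
            predicted = "".join(
                _substitute(tokens, rng, rec.neutral_mass(table), table=table)
            )
        out.append(
            PredictionRecord(
                spectrum_id=rec.spectrum_id,
                predicted=predicted,
                truth=rec.peptide,
                source_enzyme=rec.source_enzyme,
            )
        )
    return out
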
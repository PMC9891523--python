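"""Monoisotopic mass bookkeeping and theoretical fragment-ion generation.

The fragment vocabulary is the twelve ion types relevant to HCD spectra of
tryptic-style peptides: singly charged a/b/y, doubly charged a/b/y, and the
water/ammonia neutral-loss variants of a/b/y at charge 1.  Peptides are held
as ordered residue tokens; modified residues use parenthesised tokens
(``C(cam)`` for carbamidomethyl-Cys, ``M(ox)`` for oxidised Met) so that a
peptide string such as ``"AC(cam)DEK"`` tokenises unambiguously.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PROTON",
    "WATER",
    "AMMONIA",
    "CARBON_MONOXIDE",
    "ION_TYPES",
    "ResidueMassTable",
    "Peptide",
    "FragmentIon",
    "tokenize",
    "strip_modifications",
    "peptide_neutral_mass",
    "theoretical_fragments",
    "ppm_match",
    "ppm_error",
]

# Monoisotopic constants (Da)
PROTON = 1.007276
WATER = 18.010565
AMMONIA = 17.026549
CARBON_MONOXIDE = 27.994915

# Monoisotopic residue masses (Da), standard 20 amino acids.
_STANDARD_RESIDUES: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

# Fixed Cys carbamidomethylation (+57.021464) and optional Met oxidation
# (+15.994915); the pipeline carries Cys as C(cam) throughout.
_MODIFIED_RESIDUES: dict[str, float] = {
    "C(cam)": _STANDARD_RESIDUES["C"] + 57.021464,
    "M(ox)": _STANDARD_RESIDUES["M"] + 15.994915,
}

#: The admissible (series, loss, charge) combinations.
ION_TYPES: tuple[tuple[str, str, int], ...] = (
    ("a", "none", 1),
    ("b", "none", 1),
    ("y", "none", 1),
    ("a", "none", 2),
    ("b", "none", 2),
    ("y", "none", 2),
    ("a", "H2O", 1),
    ("b", "H2O", 1),
    ("y", "H2O", 1),
    ("a", "NH3", 1),
    ("b", "NH3", 1),
    ("y", "NH3", 1),
)

_LOSS_MASS = {"none": 0.0, "H2O": WATER, "NH3": AMMONIA}

_TOKEN_RE = re.compile(r"[A-Z](?:\([a-z0-9]+\))?")


@dataclass(frozen=True)
class ResidueMassTable:
    """Residue-token → monoisotopic mass mapping plus the small-molecule constants.

    Overrides map a token either to an absolute mass or, via ``deltas``, to an
    offset on the unmodified residue (the config-file convention).
    """

    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: {**_STANDARD_RESIDUES, **_MODIFIED_RESIDUES}
    )
    proton: float = PROTON
    water: float = WATER
    ammonia: float = AMMONIA
    carbon_monoxide: float = CARBON_MONOXIDE

    def __post_init__(self) -> None:
        for token, mass in self.residue_masses.items():
            if mass <= 0:
                raise ValueError(f"non-positive mass for residue token {token!r}")

    def mass(self, token: str) -> float:
        try:
            return self.residue_masses[token]
        except KeyError:
            raise KeyError(f"unknown residue token {token!r}") from None

    def with_overrides(
        self,
        absolute: Mapping[str, float] | None = None,
        deltas: Mapping[str, float] | None = None,
    ) -> "ResidueMassTable":
        masses = dict(self.residue_masses)
        if absolute:
            masses.update(absolute)
        if deltas:
            for token, delta in deltas.items():
                base = re.match(r"[A-Z]", token)
                if base is None or base.group(0) not in masses:
                    raise KeyError(f"delta override for unknown base residue in {token!r}")
                masses[token] = masses[base.group(0)] + delta
        return ResidueMassTable(residue_masses=masses)


#: Default table shared across the package.
DEFAULT_TABLE = ResidueMassTable()


def tokenize(peptide: str) -> list[str]:
    """Split a peptide string into residue tokens.

    ``"AC(cam)DEK"`` → ``["A", "C(cam)", "D", "E", "K"]``.  Raises on any
    character run that is not an uppercase letter with an optional
    parenthesised lowercase modification tag.
    """
    tokens = _TOKEN_RE.findall(peptide)
    if "".join(tokens) != peptide:
        raise ValueError(f"cannot tokenize peptide string {peptide!r}")
    return tokens


def strip_modifications(tokens: Iterable[str]) -> str:
    """Bare-residue string: drop modification tags, keep the residue letters."""
    return "".join(t[0] for t in tokens)


def peptide_neutral_mass(
    tokens: Sequence[str], table: ResidueMassTable = DEFAULT_TABLE
) -> float:
    """Neutral monoisotopic peptide mass: residue masses plus one water."""
    if len(tokens) == 0:
        raise ValueError("cannot compute the mass of an empty peptide")
    return sum(table.mass(t) for t in tokens) + table.water


@dataclass(frozen=True)
class Peptide:
    """An ordered residue-token sequence with its cached neutral mass."""

    tokens: tuple[str, ...]
    neutral_mass: float

    @classmethod
    def from_tokens(
        cls, tokens: Sequence[str], table: ResidueMassTable = DEFAULT_TABLE
    ) -> "Peptide":
        return cls(tuple(tokens), peptide_neutral_mass(tokens, table))

    @classmethod
    def from_string(cls, peptide: str, table: ResidueMassTable = DEFAULT_TABLE) -> "Peptide":
        return cls.from_tokens(tokenize(peptide), table)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def sequence(self) -> str:
        return "".join(self.tokens)

    @property
    def bare_sequence(self) -> str:
        return strip_modifications(self.tokens)

    def mz(self, charge: int, table: ResidueMassTable = DEFAULT_TABLE) -> float:
        if charge < 1:
            raise ValueError("charge must be >= 1")
        return (self.neutral_mass + charge * table.proton) / charge


@dataclass(frozen=True)
class FragmentIon:
    series: str  # a, b or y
    loss: str  # none, H2O or NH3
    charge: int  # 1 or 2
    index: int  # 1-based ordinal within the series
    mz: float


def theoretical_fragments(
    peptide: Peptide,
    table: ResidueMassTable = DEFAULT_TABLE,
    ion_types: Sequence[tuple[str, str, int]] = ION_TYPES,
) -> list[FragmentIon]:
    """All requested fragment ions of a peptide: length−1 per ion type.

    Singly charged ``b_i`` is the i-residue prefix mass plus a proton;
    ``y_j`` the j-residue suffix mass plus water plus a proton; ``a_i``
    is ``b_i`` minus CO.  Neutral losses subtract H2O/NH3 from the neutral
    fragment; charge 2 puts (neutral + 2·proton)/2.
    """
    n = len(peptide)
    if n < 2:
        raise ValueError("no fragments definable for a peptide of length < 2")
    for ion_type in ion_types:
        if ion_type not in ION_TYPES:
            raise ValueError(f"unsupported ion type {ion_type!r}")

    masses = [table.mass(t) for t in peptide.tokens]
    # Neutral fragment masses (no proton): prefix sums for b, suffix + water for y.
    prefix = [0.0] * (n - 1)
    running = 0.0
    for i in range(n - 1):
        running += masses[i]
        prefix[i] = running
    suffix = [0.0] * (n - 1)
    running = 0.0
    for j in range(n - 1):
        running += masses[n - 1 - j]
        suffix[j] = running + table.water

    fragments: list[FragmentIon] = []
    for series, loss, charge in ion_types:
        for idx in range(1, n):
            if series == "y":
                neutral = suffix[idx - 1]
            else:
                neutral = prefix[idx - 1]
                if series == "a":
                    neutral -= table.carbon_monoxide
            neutral -= _LOSS_MASS[loss]
            mz = (neutral + charge * table.proton) / charge
            fragments.append(FragmentIon(series, loss, charge, idx, mz))
    return fragments


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed mass error in parts per million, relative to the theoretical m/z."""
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


def ppm_match(observed_mz: float, theoretical_mz: float, tol_ppm: float = 15.0) -> bool:
    """Inclusive ppm-tolerance match; denominator is the theoretical m/z."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be positive")
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    return abs(ppm_error(observed_mz, theoretical_mz)) <= tol_ppm
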
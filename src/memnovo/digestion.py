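"""In-silico fully-specific protease digestion.

Cleavage rules follow the standard Expasy-style specificities.  A rule names
the residues recognised by the protease, whether the scissile bond lies C- or
N-terminal of the matched residue, and an optional set of residues that block
cleavage when they immediately follow the site (the classic "not before
proline" exception).  Digestion enumerates fully-specific products spanning up
to ``missed_cleavages`` internal sites and filters them on length and mass.

Masses used for the ``max_mass`` filter assume the fixed Cys
carbamidomethylation carried everywhere else in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

from .chem import DEFAULT_TABLE, ResidueMassTable, peptide_neutral_mass

__all__ = [
    "ProteaseRule",
    "DigestParams",
    "DigestedPeptide",
    "BUILTIN_RULES",
    "get_rule",
    "compose_rules",
    "cleavage_sites",
    "digest",
    "read_fasta",
]


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage specificity: residues, side of the scissile bond, blockers."""

    name: str
    cleave_residues: frozenset[str]
    side: str = "C"  # "C" or "N" of the matched residue
    blocked_next: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.cleave_residues:
            raise ValueError("cleave_residues must be non-empty")
        if self.side not in ("C", "N"):
            raise ValueError("side must be 'C' or 'N'")


def _rule(name, residues, side="C", blocked=""):
    return ProteaseRule(name, frozenset(residues), side, frozenset(blocked))


BUILTIN_RULES: dict[str, ProteaseRule] = {
    "trypsin": _rule("trypsin", "KR", blocked="P"),
    "lysC": _rule("lysC", "K"),
    "chymotrypsin": _rule("chymotrypsin", "FWYL", blocked="P"),
    "elastase": _rule("elastase", "AVSGLI"),
    "gluC": _rule("gluC", "E"),
    "pepsin": _rule("pepsin", "FLWY"),
    "aspN": _rule("aspN", "D", side="N"),
}

# gluC in ammonium-bicarbonate buffers also cleaves after Asp.
GLUC_DE = _rule("gluC-DE", "ED")

_ALIASES = {name.lower(): name for name in BUILTIN_RULES}
_ALIASES.update({"glu-c": "gluC", "asp-n": "aspN", "lys-c": "lysC", "glucde": None})


def get_rule(
    name: str, registry: Mapping[str, ProteaseRule] | None = None
) -> ProteaseRule:
    """Look up a protease rule by name (case-insensitive for the built-ins)."""
    if registry and name in registry:
        return registry[name]
    key = _ALIASES.get(name.lower())
    if key is None or key not in BUILTIN_RULES:
        known = ", ".join(sorted(BUILTIN_RULES))
        raise KeyError(f"unknown enzyme {name!r}; known enzymes: {known}")
    return BUILTIN_RULES[key]


def compose_rules(rules: Iterable[ProteaseRule], name: str | None = None):
    """A pseudo-rule whose site set is the union of the given rules' sites.

    Emulates sequential digestion with several proteases (e.g. a LysC/trypsin
    pre-digestion followed by pepsin).  Returned as a callable usable wherever
    a rule is accepted by :func:`cleavage_sites` and :func:`digest`.
    """
    rules = list(rules)
    if not rules:
        raise ValueError("need at least one rule to compose")
    label = name or "+".join(r.name for r in rules)

    def site_fn(sequence: str) -> list[int]:
        sites: set[int] = set()
        for rule in rules:
            sites.update(cleavage_sites(sequence, rule))
        return sorted(sites)

    site_fn.name = label  # type: ignore[attr-defined]
    return site_fn


def cleavage_sites(sequence: str, rule) -> list[int]:
    """Between-residue cleavage indices (0 < i < len) satisfied by the rule.

    Index ``i`` denotes the bond between ``sequence[i-1]`` and ``sequence[i]``.
    Composite rules (from :func:`compose_rules`) are supported directly.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if callable(rule):
        return rule(sequence)
    sites: list[int] = []
    n = len(sequence)
    for i in range(1, n):
        if rule.side == "C":
            hit = sequence[i - 1] in rule.cleave_residues and (
                sequence[i] not in rule.blocked_next
            )
        else:
            hit = sequence[i] in rule.cleave_residues and (
                sequence[i - 1] not in rule.blocked_next if rule.blocked_next else True
            )
        if hit:
            sites.append(i)
    return sites


@dataclass(frozen=True)
class DigestParams:
    missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 30
    max_mass: float = 4000.0

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.min_length < 1 or self.max_length < self.min_length:
            raise ValueError("need 1 <= min_length <= max_length")


@dataclass(frozen=True)
class DigestedPeptide:
    sequence: str
    start: int  # 0-based, half-open interval [start, end) on the protein
    end: int
    missed: int  # internal cleavage sites retained

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("interval does not match sequence length")


def _mass_with_fixed_cam(sequence: str, table: ResidueMassTable) -> float:
    tokens = ["C(cam)" if ch == "C" else ch for ch in sequence]
    return peptide_neutral_mass(tokens, table)


def digest(
    sequence: str,
    rule,
    params: DigestParams = DigestParams(),
    table: ResidueMassTable = DEFAULT_TABLE,
) -> list[DigestedPeptide]:
    """Fully-specific digestion products, length/mass filtered.

    Products span ``k+1`` consecutive zero-missed-cleavage fragments for every
    ``k <= missed_cleavages``; each carries its 0-based half-open interval on
    the protein and its retained internal site count.  Ordered by start
    position, then missed-cleavage count.
    """
    sites = cleavage_sites(sequence, rule)
    bounds = [0, *sites, len(sequence)]
    out: list[DigestedPeptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for k in range(min(params.missed_cleavages, n_frag - 1 - i) + 1):
            start, end = bounds[i], bounds[i + 1 + k]
            length = end - start
            if length < params.min_length or length > params.max_length:
                continue
            pep = sequence[start:end]
            if _mass_with_fixed_cam(pep, table) > params.max_mass:
                continue
            out.append(DigestedPeptide(pep, start, end, k))
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id, uppercased."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
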
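"""Mapping de novo peptides onto target proteins and scoring the assembly.

For a target chain (e.g. an antibody heavy or light chain) and a set of
unique predicted peptides, the positional frequency ``f_i`` counts how many
matching peptide occurrences cover position ``i``; the confident positional
score compresses it as ``CS_i = log2(f_i + 1)``.  Relative coverage is the
fraction of positions with ``f_i > 0``.  High consecutive CS values flag
well-evidenced regions — critical for antibody variable domains, which are
absent from sequence databases — while zero-f runs flag blind spots such as
glycosylated stretches that resist digestion.

Matching is exact substring matching under Ile/Leu equivalence with
modifications stripped; every occurrence of a peptide (repeat regions
included) contributes to ``f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TargetProtein",
    "CoverageProfile",
    "match_peptides",
    "coverage_profile",
    "domain_summary",
    "zero_runs",
]


@dataclass(frozen=True)
class TargetProtein:
    name: str
    sequence: str
    chain: str = "other"  # heavy, light or other
    domains: tuple[tuple[str, int, int], ...] = ()  # (label, start, end), 0-based half-open

    def __post_init__(self) -> None:
        n = len(self.sequence)
        spans = sorted((s, e) for _, s, e in self.domains)
        for label, s, e in self.domains:
            if not (0 <= s < e <= n):
                raise ValueError(f"domain {label!r} interval [{s}, {e}) outside sequence")
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("domain intervals overlap")


def _canonical(seq: str) -> str:
    # I/L are isobaric; fold L onto I for matching
    return seq.replace("L", "I")


def match_peptides(
    protein: TargetProtein,
    peptides: Iterable[str],
    ile_leu_equivalent: bool = True,
) -> list[tuple[str, list[tuple[int, int]]]]:
    """All occurrences of each unique peptide as a protein substring.

    Peptides must already be bare residue strings (modifications stripped).
    Overlapping occurrences in repeat regions are all reported.  Returns one
    entry per unique peptide, in first-appearance order; peptides with no
    occurrence get an empty interval list.
    """
    target = _canonical(protein.sequence) if ile_leu_equivalent else protein.sequence
    out: list[tuple[str, list[tuple[int, int]]]] = []
    for pep in dict.fromkeys(peptides):
        query = _canonical(pep) if ile_leu_equivalent else pep
        intervals: list[tuple[int, int]] = []
        start = target.find(query)
        while start != -1:
            intervals.append((start, start + len(pep)))
            start = target.find(query, start + 1)
        out.append((pep, intervals))
    return out


@dataclass(frozen=True)
class CoverageProfile:
    protein: TargetProtein
    f: np.ndarray  # per-position match counts
    cs: np.ndarray  # log2(f + 1)
    coverage: float  # fraction of positions with f > 0
    n_matching_peptides: int  # unique peptides with >= 1 occurrence

    def to_frame(self) -> pd.DataFrame:
        """Per-position table; ``position`` is 1-based for reports."""
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.f) + 1),
                "residue": list(self.protein.sequence),
                "f": self.f,
                "cs": self.cs,
            }
        )


def coverage_profile(
    protein: TargetProtein,
    matches: Sequence[tuple[str, list[tuple[int, int]]]],
) -> CoverageProfile:
    """Positional frequency, confident positional score and relative coverage."""
    f = np.zeros(len(protein.sequence), dtype=int)
    n_matching = 0
    for _, intervals in matches:
        if intervals:
            n_matching += 1
        for s, e in intervals:
            f[s:e] += 1
    coverage = float(np.count_nonzero(f)) / len(f) if len(f) else 0.0
    return CoverageProfile(protein, f, np.log2(f + 1.0), coverage, n_matching)


def zero_runs(f: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zero positional frequency, 0-based half-open."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(f):
        if v == 0 and start is None:
            start = i
        elif v != 0 and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(f)))
    return runs


def domain_summary(profile: CoverageProfile) -> pd.DataFrame:
    """Per-domain medians, coverage and blind-spot runs.

    A protein without domain annotation is summarised as one whole-chain
    domain.  Zero-f runs are reported relative to the whole chain (1-based
    inclusive intervals in the ``zero_runs`` column) — candidate blind spots
    such as glycan-bearing stretches.
    """
    domains = profile.protein.domains or (
        ("whole", 0, len(profile.protein.sequence)),
    )
    rows = []
    for label, s, e in domains:
        f_dom = profile.f[s:e]
        runs = zero_runs(f_dom)
        rows.append(
            {
                "protein": profile.protein.name,
                "chain": profile.protein.chain,
                "domain": label,
                "start": s,
                "end": e,
                "median_f": float(np.median(f_dom)),
                "median_cs": float(np.median(np.log2(f_dom + 1.0))),
                "coverage": float(np.count_nonzero(f_dom)) / len(f_dom),
                "zero_runs": ";".join(f"{s + a + 1}-{s + b}" for a, b in runs),
            }
        )
    return pd.DataFrame(rows)
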
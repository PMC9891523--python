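"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own digestion/fragment code paths:
digestion is checked by enumerating candidate substrings directly, masses by
summing a locally defined monoisotopic table.
"""

from __future__ import annotations

# Independent monoisotopic residue table (C carried as carbamidomethylated,
# matching the package's fixed-modification convention for mass filters).
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919 + 57.02146, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.010565
PROTON = 1.007276

RULE_SPECS = {
    "trypsin": ("KR", "C", "P"),
    "lysC": ("K", "C", ""),
    "chymotrypsin": ("FWYL", "C", "P"),
    "elastase": ("AVSGLI", "C", ""),
    "gluC": ("E", "C", ""),
    "pepsin": ("FLWY", "C", ""),
    "aspN": ("D", "N", ""),
}


def oracle_sites(seq: str, enzyme: str) -> set[int]:
    residues, side, blocked = RULE_SPECS[enzyme]
    sites = set()
    for i in range(1, len(seq)):
        if side == "C":
            if seq[i - 1] in residues and seq[i] not in blocked:
                sites.add(i)
        else:
            if seq[i] in residues:
                sites.add(i)
    return sites


def oracle_digest(
    seq: str,
    enzyme: str,
    missed_cleavages: int,
    min_length: int = 6,
    max_length: int = 30,
    max_mass: float = 4000.0,
) -> set[tuple[str, int, int]]:
    """All substrings whose boundaries are cleavage sites or protein termini
    and whose internal site count does not exceed the missed-cleavage cap."""
    n = len(seq)
    sites = oracle_sites(seq, enzyme)
    boundary = sites | {0, n}
    # prefix[i] = number of sites at positions <= i
    prefix = [0] * (n + 1)
    for i in range(1, n + 1):
        prefix[i] = prefix[i - 1] + (1 if i in sites else 0)
    out = set()
    for a in sorted(boundary - {n}):
        for b in sorted(boundary - {0}):
            if b <= a:
                continue
            internal = prefix[b - 1] - prefix[a]  # sites strictly inside (a, b)
            if internal > missed_cleavages:
                continue
            length = b - a
            if not (min_length <= length <= max_length):
                continue
            pep = seq[a:b]
            if sum(RESIDUE_MASS[c] for c in pep) + WATER > max_mass:
                continue
            out.add((pep, a, b))
    return out
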
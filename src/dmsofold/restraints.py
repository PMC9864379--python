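"""NOE distance-restraint bookkeeping: sequence-range classes and density."""

from __future__ import annotations

from dataclasses import dataclass, field

CLASS_NAMES = ("intra", "sequential", "medium", "long")


class RestraintError(ValueError):
    """Raised for invalid restraint lists."""


@dataclass
class RestraintList:
    """Residue-index pairs of NOE distance restraints for one protein."""

    entries: list[tuple[int, int]]
    n_residues: int = 55

    def __post_init__(self) -> None:
        if self.n_residues <= 0:
            raise RestraintError("n_residues must be positive")
        for i, j in self.entries:
            if not (1 <= i <= self.n_residues and 1 <= j <= self.n_residues):
                raise RestraintError(
                    f"restraint ({i}, {j}) outside 1..{self.n_residues}"
                )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class RangeStats:
    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)
    n_total: int = 0


def classify_range(i: int, j: int) -> str:
    """Sequence-range class from |i-j|: 0 intra, 1 sequential, 2-4 medium,
    >= 5 long. Symmetric in (i, j)."""
    sep = abs(i - j)
    if sep == 0:
        return "intra"
    if sep == 1:
        return "sequential"
    if sep <= 4:
        return "medium"
    return "long"


def classify_ranges(restraints: RestraintList) -> RangeStats:
    """Counts and fractions per sequence-range class; fractions sum to 1."""
    if len(restraints) == 0:
        raise RestraintError("empty restraint list")
    counts = {name: 0 for name in CLASS_NAMES}
    for i, j in restraints.entries:
        counts[classify_range(i, j)] += 1
    n = len(restraints)
    fractions = {name: counts[name] / n for name in CLASS_NAMES}
    return RangeStats(counts, fractions, n)


def restraint_density(n_restraints: int, n_residues: int) -> float:
    """Restraints per residue, rounded to 2 decimals (e.g. 956/55 -> 17.38)."""
    if n_residues <= 0:
        raise RestraintError("n_residues must be positive")
    if n_restraints < 0:
        raise RestraintError("n_restraints must be non-negative")
    return round(n_restraints / n_residues, 2)
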
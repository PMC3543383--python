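"""Residue demand-index statistics over proteomes.

The demand index of a residue type in a protein is the number of
occurrences divided by the harmonic mean of the distances between
consecutive occurrences.  Proteins that use a residue both *often* and
in *closely spaced* runs score high; a protein whose occurrences are
spread out scores low even when the raw count is large.  Tallying
proteins above a count threshold and above an index threshold gives a
proteome-level signature of how freely an organism can afford to use
that amino acid — an organism for which charging the corresponding
tRNA is difficult is expected to avoid high-demand proteins.

Distances are differences of consecutive 1-based positions, so a run
of adjacent residues has all spacings equal to 1, a harmonic mean of 1
and a demand index equal to the count — the maximum attainable for
that count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

__all__ = [
    "ProteinRecord",
    "ResidueDemand",
    "ProteomeDemandProfile",
    "AMINO_ACIDS",
    "residue_positions",
    "demand_index",
    "proteome_profile",
    "compare_proteomes",
]

#: The twenty standard amino-acid letters.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Letters accepted in sequences: standard residues plus ambiguity /
#: non-standard codes (never counted as a target residue).
_SEQUENCE_ALPHABET = AMINO_ACIDS | frozenset("XBZU")

#: Packaged tally thresholds: strictly more than 50 occurrences,
#: strictly above a demand index of 7.0.
DEFAULT_COUNT_THRESHOLD = 50
DEFAULT_INDEX_THRESHOLD = 7.0


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence from a proteome.

    Sequences are uppercased on ingest and a trailing stop symbol
    ``*`` is stripped.  The alphabet is restricted to the twenty
    standard letters plus the ambiguity codes X/B/Z and U
    (selenocysteine); anything else is rejected.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().rstrip("*")
        if not seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(seq) - _SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: illegal sequence letters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ResidueDemand:
    """Count, spacings, harmonic-mean spacing and demand index for one
    residue type in one protein.

    ``harmonic_mean_spacing`` is ``None`` when fewer than two
    occurrences exist (the mean is undefined); the demand index is 0
    in that case, since a lone residue cannot be "closely spaced".
    """

    residue: str
    count: int
    spacings: tuple[int, ...]
    harmonic_mean_spacing: float | None
    demand_index: float


def _check_residue(residue: str) -> str:
    residue = residue.upper()
    if len(residue) != 1 or residue not in AMINO_ACIDS:
        raise ValueError(
            f"residue must be one of the 20 standard amino-acid letters, got {residue!r}"
        )
    return residue


def residue_positions(protein: ProteinRecord, residue: str) -> list[int]:
    """1-based positions of exact matches of *residue* in *protein*.

    Ambiguity codes in the sequence never match a standard residue.
    """
    residue = _check_residue(residue)
    return [i for i, aa in enumerate(protein.sequence, start=1) if aa == residue]


def demand_index(protein: ProteinRecord, residue: str) -> ResidueDemand:
    """Compute the demand index of *residue* in *protein*.

    With occurrences at consecutive-position distances ``s_1..s_{n-1}``,
    the harmonic mean is ``H = (n-1) / sum(1/s_i)`` and the index is
    ``D = n / H``.  ``D = 0`` when ``n < 2``.
    """
    positions = residue_positions(protein, residue)
    n = len(positions)
    spacings = tuple(b - a for a, b in zip(positions, positions[1:]))
    if n < 2:
        return ResidueDemand(residue, n, spacings, None, 0.0)
    # exact rational arithmetic, floated only at the boundary
    recip = sum(Fraction(1, s) for s in spacings)
    h = Fraction(n - 1) / recip
    d = Fraction(n) / h
    return ResidueDemand(residue, n, spacings, float(h), float(d))


@dataclass(frozen=True)
class ProteomeDemandProfile:
    """Per-protein demand statistics plus threshold tallies for one proteome."""

    residue: str
    per_protein: tuple[tuple[str, ResidueDemand], ...]
    count_threshold: int
    index_threshold: float
    label: str = "proteome"
    n_above_count_threshold: int = field(init=False)
    n_above_index_threshold: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "n_above_count_threshold",
            sum(1 for _, d in self.per_protein if d.count > self.count_threshold),
        )
        object.__setattr__(
            self,
            "n_above_index_threshold",
            sum(1 for _, d in self.per_protein if d.demand_index > self.index_threshold),
        )

    @property
    def n_proteins(self) -> int:
        return len(self.per_protein)

    def to_frame(self) -> pd.DataFrame:
        """Per-protein table: id, count, harmonic_mean_spacing, demand_index."""
        return pd.DataFrame(
            {
                "id": [pid for pid, _ in self.per_protein],
                "count": [d.count for _, d in self.per_protein],
                "harmonic_mean_spacing": [
                    d.harmonic_mean_spacing for _, d in self.per_protein
                ],
                "demand_index": [d.demand_index for _, d in self.per_protein],
            }
        )


def proteome_profile(
    proteome: list[ProteinRecord],
    residue: str = "N",
    count_threshold: int = DEFAULT_COUNT_THRESHOLD,
    index_threshold: float = DEFAULT_INDEX_THRESHOLD,
    label: str = "proteome",
) -> ProteomeDemandProfile:
    """Profile every protein and tally those above the two thresholds.

    Comparisons are strict (count > threshold, index > threshold).
    An empty proteome yields a valid profile with zero tallies.
    """
    residue = _check_residue(residue)
    if count_threshold <= 0 or index_threshold <= 0:
        raise ValueError("thresholds must be positive")
    per = tuple((p.id, demand_index(p, residue)) for p in proteome)
    return ProteomeDemandProfile(residue, per, count_threshold, index_threshold, label)


def compare_proteomes(profiles: list[ProteomeDemandProfile]) -> pd.DataFrame:
    """Tabulate tallies across proteomes, one row per profile, input order.

    All profiles must share the residue and both thresholds; mixing is
    rejected because the tallies would not be comparable.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    keys = {(p.residue, p.count_threshold, p.index_threshold) for p in profiles}
    if len(keys) > 1:
        raise ValueError(
            f"profiles mix residues or thresholds: {sorted(keys)}"
        )
    return pd.DataFrame(
        {
            "label": [p.label for p in profiles],
            "n_proteins": [p.n_proteins for p in profiles],
            "n_above_count_threshold": [p.n_above_count_threshold for p in profiles],
            "n_above_index_threshold": [p.n_above_index_threshold for p in profiles],
        }
    )
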
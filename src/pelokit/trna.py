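"""tRNA cloverleaf features: anticodon decoding, compensatory-mutation
classification and acceptor-end integrity.

A tRNA that accumulates point mutations can still be under selection
to keep its cloverleaf fold: substitutions at stem positions then come
in *reciprocal* (compensatory) pairs that replace one legal base pair
with another.  Given two aligned sequences and a pairing map of the
stems, :func:`classify_mutations` partitions every aligned position
into identical / compensatory / pair-breaking / unpaired-substitution
/ indel, which quantifies how far a mutant transcript preserves the
fold of its parent.

Legal stem pairs are the Watson-Crick pairs plus the G·U wobble pair,
which RNA helices tolerate: the question asked of a stem is whether the
fold survives, not whether pairing is strictly Watson-Crick.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio.Data.CodonTable import standard_rna_table

__all__ = [
    "TrnaSequence",
    "PairingMap",
    "MutationReport",
    "decode_anticodon",
    "classify_mutations",
    "acceptor_end_check",
    "read_pairing_map",
]

_RNA_BASES = frozenset("ACGU")

#: Legal stem pairs: Watson-Crick plus the G·U wobble.
LEGAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: One-letter code to full amino-acid name (standard code).
AMINO_ACID_NAMES = {
    "A": "alanine", "R": "arginine", "N": "asparagine", "D": "aspartate",
    "C": "cysteine", "Q": "glutamine", "E": "glutamate", "G": "glycine",
    "H": "histidine", "I": "isoleucine", "L": "leucine", "K": "lysine",
    "M": "methionine", "F": "phenylalanine", "P": "proline", "S": "serine",
    "T": "threonine", "W": "tryptophan", "Y": "tyrosine", "V": "valine",
}


@dataclass(frozen=True)
class TrnaSequence:
    """An RNA sequence; DNA input (T) is normalized to U on ingest."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        seq = self.bases.upper().replace("T", "U")
        if not seq:
            raise ValueError(f"tRNA {self.id!r}: empty sequence")
        bad = set(seq) - _RNA_BASES
        if bad:
            raise ValueError(f"tRNA {self.id!r}: non-RNA letters {sorted(bad)}")
        object.__setattr__(self, "bases", seq)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class PairingMap:
    """Cloverleaf stem pairs as disjoint 1-based (i, j) position pairs,
    plus the anticodon span and (optionally) the frameshift-control
    base at position 33."""

    pairs: tuple[tuple[int, int], ...]
    anticodon_span: tuple[int, int] | None = None
    position_33: int | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        cleaned = []
        for i, j in self.pairs:
            i, j = int(i), int(j)
            if not (1 <= i < j):
                raise ValueError(f"stem pair ({i}, {j}) must satisfy 1 <= i < j")
            if i in seen or j in seen:
                raise ValueError(f"stem pair ({i}, {j}) overlaps another pair")
            seen.update((i, j))
            cleaned.append((i, j))
        object.__setattr__(self, "pairs", tuple(cleaned))
        if self.anticodon_span is not None:
            start, end = self.anticodon_span
            if end - start != 2:
                raise ValueError("anticodon span must cover exactly 3 bases")
            object.__setattr__(self, "anticodon_span", (int(start), int(end)))

    @property
    def paired_positions(self) -> frozenset[int]:
        return frozenset(p for pair in self.pairs for p in pair)

    @property
    def partner(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


def decode_anticodon(anticodon: str) -> str:
    """Decode a 3-base anticodon (5'->3') to an amino-acid name.

    The anticodon pairs antiparallel with the codon, so the codon is
    the reverse complement; translation uses the standard code.
    Returns e.g. ``"asparagine"`` for ``GUU`` and ``"leucine"`` for
    ``CAG``; stop codons decode to ``"stop"``.
    """
    ac = anticodon.upper().replace("T", "U")
    if len(ac) != 3 or set(ac) - _RNA_BASES:
        raise ValueError(f"anticodon must be 3 RNA bases, got {anticodon!r}")
    codon = "".join(_COMPLEMENT[b] for b in reversed(ac))
    if codon in standard_rna_table.stop_codons:
        return "stop"
    return AMINO_ACID_NAMES[standard_rna_table.forward_table[codon]]


@dataclass(frozen=True)
class MutationReport:
    """Per-position categories and event-level summary counts.

    ``positions`` holds ``(a_position, category, a_base, b_base)`` for
    every alignment column (gap positions carry ``None`` for the
    missing base and the position of sequence *a* where available).
    Compensatory and pair-breaking counts in ``summary`` are *events*
    (stem pairs), not positions.
    """

    positions: tuple[tuple[int | None, str, str | None, str | None], ...]
    summary: dict[str, int]
    u33: tuple[str, str] | None = None  # (a base, b base) at position 33, if mapped

    @property
    def u33_mutated(self) -> bool:
        return self.u33 is not None and self.u33[0] != self.u33[1]


def _alignment_maps(aligned_a: str, aligned_b: str):
    """Map 1-based sequence-a positions to alignment columns and back."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    a_pos_of_col: list[int | None] = []
    col_of_a_pos: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(aligned_a):
        if ch == "-":
            a_pos_of_col.append(None)
        else:
            pos += 1
            a_pos_of_col.append(pos)
            col_of_a_pos[pos] = col
    return a_pos_of_col, col_of_a_pos


def classify_mutations(
    a: TrnaSequence,
    b: TrnaSequence,
    pairing: PairingMap,
    alignment: tuple[str, str] | None = None,
) -> MutationReport:
    """Classify every aligned position of *b* relative to *a*.

    *alignment* is a gapped pair of strings covering both sequences;
    when omitted the sequences must have equal length and are compared
    column by column.  Pairing-map positions are indexed on sequence
    *a* and must fall inside the alignment.

    Rules: a gap on either side is an ``indel``; equal bases are
    ``identical``; a stem pair in which both partners changed and the
    new duo is still legal is one ``compensatory`` event (both
    positions so labelled); a stem pair rendered illegal labels its
    substituted position(s) ``pair_breaking``; any other substitution
    is an ``unpaired_substitution`` (including the rare single-sided
    stem change that leaves a legal pair, e.g. G-C to G-U).
    """
    if alignment is None:
        if len(a) != len(b):
            raise ValueError(
                "sequences of unequal length require an explicit alignment"
            )
        alignment = (a.bases, b.bases)
    aligned_a, aligned_b = alignment
    if aligned_a.replace("-", "") != a.bases:
        raise ValueError("alignment row 1 does not spell sequence a")
    if aligned_b.replace("-", "") != b.bases:
        raise ValueError("alignment row 2 does not spell sequence b")
    a_pos_of_col, col_of_a_pos = _alignment_maps(aligned_a, aligned_b)

    n_a = len(a)
    for i, j in pairing.pairs:
        if j > n_a:
            raise ValueError(f"stem pair ({i}, {j}) lies outside sequence a")
    if pairing.position_33 is not None and pairing.position_33 > n_a:
        raise ValueError("position 33 lies outside sequence a")

    partner = pairing.partner

    def bases_at(apos: int) -> tuple[str, str | None]:
        col = col_of_a_pos[apos]
        bb = aligned_b[col]
        return aligned_a[col], (None if bb == "-" else bb)

    categories: dict[int, str] = {}  # keyed by alignment column
    compensatory_events = 0
    pair_breaking_events = 0

    # First pass: stem pairs, decided jointly.
    for i, j in pairing.pairs:
        (a_i, b_i), (a_j, b_j) = bases_at(i), bases_at(j)
        col_i, col_j = col_of_a_pos[i], col_of_a_pos[j]
        if b_i is None or b_j is None:
            continue  # indel handles these columns below
        changed_i, changed_j = a_i != b_i, a_j != b_j
        if not (changed_i or changed_j):
            continue
        legal = (b_i, b_j) in LEGAL_PAIRS
        if legal and changed_i and changed_j:
            categories[col_i] = categories[col_j] = "compensatory"
            compensatory_events += 1
        elif not legal:
            if changed_i:
                categories[col_i] = "pair_breaking"
            if changed_j:
                categories[col_j] = "pair_breaking"
            pair_breaking_events += 1
        else:
            # single-sided change, pair still legal (wobble-tolerated)
            categories[col_i if changed_i else col_j] = "unpaired_substitution"

    # Second pass: everything else, column by column.
    positions = []
    counts = {
        "identical": 0,
        "compensatory": compensatory_events,
        "pair_breaking": pair_breaking_events,
        "unpaired_substitution": 0,
        "indel": 0,
    }
    for col, (ca, cb) in enumerate(zip(aligned_a, aligned_b)):
        apos = a_pos_of_col[col]
        if ca == "-" or cb == "-":
            cat = "indel"
            counts["indel"] += 1
        elif col in categories:
            cat = categories[col]
            if cat == "unpaired_substitution":
                counts["unpaired_substitution"] += 1
        elif ca == cb:
            cat = "identical"
            counts["identical"] += 1
        else:
            cat = "unpaired_substitution"
            counts["unpaired_substitution"] += 1
        positions.append(
            (apos, cat, None if ca == "-" else ca, None if cb == "-" else cb)
        )

    u33 = None
    if pairing.position_33 is not None:
        a33, b33 = bases_at(pairing.position_33)
        if b33 is not None:
            u33 = (a33, b33)

    return MutationReport(positions=tuple(positions), summary=counts, u33=u33)


def acceptor_end_check(seq: TrnaSequence) -> str:
    """Integrity of the 3' aminoacylation site.

    Returns ``"terminal_CCA"`` when the last three bases are CCA,
    ``"internal_CCA_only"`` when CCA occurs but not terminally (the
    site is buried, e.g. recessed into the acceptor stem by a
    deletion), and ``"absent"`` otherwise.
    """
    if seq.bases.endswith("CCA"):
        return "terminal_CCA"
    if "CCA" in seq.bases:
        return "internal_CCA_only"
    return "absent"


def read_pairing_map(path) -> PairingMap:
    """Read a pairing map from tabular text: one ``i j`` stem pair per
    row; optional directives ``anticodon START END`` and
    ``position33 N``."""
    pairs = []
    anticodon = None
    pos33 = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0].lower() == "anticodon":
            anticodon = (int(parts[1]), int(parts[2]))
        elif parts[0].lower() == "position33":
            pos33 = int(parts[1])
        elif len(parts) == 2:
            pairs.append((int(parts[0]), int(parts[1])))
        else:
            raise ValueError(f"{path}:{lineno}: cannot parse pairing row {raw!r}")
    return PairingMap(tuple(pairs), anticodon_span=anticodon, position_33=pos33)
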
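"""FASTA and tabular I/O plus the packaged fixture registry."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .active_site import REFERENCE_ANNOTATIONS, TABLE_PROFILES, ResidueProfile
from .demand import (
    DEFAULT_COUNT_THRESHOLD,
    DEFAULT_INDEX_THRESHOLD,
    ProteinRecord,
)
from .energetics import Pathway
from .pathways import pathway_library
from .trna import TrnaSequence

__all__ = ["read_fasta", "read_trna_fasta", "write_fasta", "fixtures", "FixtureRegistry"]

logger = logging.getLogger("pelokit")


def _dedupe(ids: list[str]) -> list[str]:
    """Suffix duplicate ids deterministically (second copy of X -> X_2)."""
    seen: dict[str, int] = {}
    out = []
    for rid in ids:
        seen[rid] = seen.get(rid, 0) + 1
        if seen[rid] == 1:
            out.append(rid)
        else:
            new = f"{rid}_{seen[rid]}"
            logger.warning("duplicate FASTA id %r renamed to %r", rid, new)
            out.append(new)
    return out


def _read_records(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty FASTA file")
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if not first.startswith(">"):
        lineno = 1 + text.splitlines().index(first)
        raise ValueError(
            f"{path}:{lineno}: malformed FASTA, expected a '>' header, got {first!r}"
        )
    records = list(SeqIO.parse(str(path), "fasta"))
    for i, rec in enumerate(records, start=1):
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: record {i} ({rec.id!r}) has an empty sequence")
    ids = _dedupe([rec.id for rec in records])
    return [(rid, str(rec.seq)) for rid, rec in zip(ids, records)]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Order-preserving; only the first whitespace-delimited token of a
    header is taken as the id; duplicate ids are suffixed
    deterministically and logged.
    """
    return [ProteinRecord(rid, seq) for rid, seq in _read_records(path)]


def read_trna_fasta(path: str | Path) -> list[TrnaSequence]:
    """Read an RNA/DNA FASTA into :class:`TrnaSequence` objects (T -> U)."""
    return [TrnaSequence(rid, seq) for rid, seq in _read_records(path)]


def write_fasta(records, path: str | Path) -> None:
    """Write protein or tRNA records as wrapped FASTA."""
    seqs = [
        SeqRecord(
            Seq(getattr(r, "sequence", None) or r.bases), id=r.id, description=""
        )
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


@dataclass(frozen=True)
class FixtureRegistry:
    """Packaged inputs: the active-site reference table, the observed
    cell-yield ratios, the tally thresholds and the pathway library."""

    active_site_table: dict[str, ResidueProfile]
    reference_annotations: dict[str, str]
    observed_ratios: tuple[float, ...]
    count_threshold: int
    index_threshold: float
    pathways: dict[str, Pathway] = field(repr=False)


def fixtures() -> FixtureRegistry:
    """The packaged fixture registry (built fresh on each call)."""
    return FixtureRegistry(
        active_site_table=dict(TABLE_PROFILES),
        reference_annotations=dict(REFERENCE_ANNOTATIONS),
        observed_ratios=(1.49, 1.83),
        count_threshold=DEFAULT_COUNT_THRESHOLD,
        index_threshold=DEFAULT_INDEX_THRESHOLD,
        pathways=pathway_library(),
    )
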
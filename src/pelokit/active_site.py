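"""Active-site residue conservation and stereospecificity assignment.

2,3-butanediol dehydrogenases of the SDR family discriminate between
the (2S,3S) and meso stereoisomers through a pocket of eleven
active-site residues.  Given pre-aligned residue profiles (one
position label and residue per site), this module counts positional
matches/mismatches (a Hamming comparison — no alignment is computed
here) and assigns a query enzyme the stereospecificity of its nearest
characterized reference, surfacing ties explicitly rather than
breaking them.

The packaged reference table covers the characterized (2S,3S)-specific
enzyme of Corynebacterium glutamicum and the meso-specific enzyme of
Klebsiella pneumoniae alongside the three uncharacterized homologs
BudY (Pcar_0903), BudZ (Pcar_2068) and Ppro_3110.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ResidueProfile",
    "ConservationReport",
    "StereoAssignment",
    "compare_profiles",
    "assign_stereospecificity",
    "TABLE_PROFILES",
    "REFERENCE_ANNOTATIONS",
]


@dataclass(frozen=True)
class ResidueProfile:
    """An ordered list of (position label, residue) pairs for one enzyme."""

    label: str
    sites: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        cleaned = []
        for pos_label, residue in self.sites:
            residue = residue.upper()
            if len(residue) != 1 or not residue.isalpha():
                raise ValueError(
                    f"profile {self.label!r}: residue at {pos_label!r} must be a "
                    f"single letter, got {residue!r}"
                )
            cleaned.append((str(pos_label), residue))
        object.__setattr__(self, "sites", tuple(cleaned))

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def residues(self) -> str:
        return "".join(res for _, res in self.sites)


@dataclass(frozen=True)
class ConservationReport:
    """Positional match/mismatch summary between two equal-length profiles."""

    reference_label: str
    query_label: str
    n_sites: int
    n_matches: int
    mismatches: tuple[tuple[int, str, str], ...]  # (site index, ref residue, query residue)

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)


def compare_profiles(reference: ResidueProfile, query: ResidueProfile) -> ConservationReport:
    """Positional, case-insensitive residue comparison of two profiles.

    Profiles must be pre-aligned and of equal length; a length mismatch
    is rejected naming both profiles.
    """
    if len(reference) != len(query):
        raise ValueError(
            f"profiles {reference.label!r} ({len(reference)} sites) and "
            f"{query.label!r} ({len(query)} sites) have different lengths"
        )
    mismatches = tuple(
        (i, ref_res, q_res)
        for i, ((_, ref_res), (_, q_res)) in enumerate(zip(reference.sites, query.sites))
        if ref_res != q_res
    )
    return ConservationReport(
        reference_label=reference.label,
        query_label=query.label,
        n_sites=len(reference),
        n_matches=len(reference) - len(mismatches),
        mismatches=mismatches,
    )


@dataclass(frozen=True)
class StereoAssignment:
    """Nearest-reference assignment with all per-reference distances."""

    query_label: str
    annotation: str | None  # None when tied
    tied: bool
    mismatch_counts: tuple[tuple[str, str, int], ...]  # (ref label, annotation, mismatches)


def assign_stereospecificity(
    query: ResidueProfile,
    references: list[tuple[ResidueProfile, str]],
) -> StereoAssignment:
    """Assign the annotation of the reference with the fewest mismatches.

    A tie between references at the minimum distance is declared
    explicitly (``annotation=None, tied=True``) rather than silently
    broken: such assignments are tentative by nature.
    """
    if not references:
        raise ValueError("at least one annotated reference profile is required")
    counts = tuple(
        (ref.label, annotation, compare_profiles(ref, query).n_mismatches)
        for ref, annotation in references
    )
    best = min(c for _, _, c in counts)
    winners = [(label, ann) for label, ann, c in counts if c == best]
    tied = len(winners) > 1
    return StereoAssignment(
        query_label=query.label,
        annotation=None if tied else winners[0][1],
        tied=tied,
        mismatch_counts=counts,
    )


# ---------------------------------------------------------------------------
# Packaged reference table: the eleven-residue 2,3-butanediol dehydrogenase
# active site across five enzymes (rows are aligned sites; each cell is a
# position label in that enzyme's own numbering).
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = (
    "C_glutamicum",
    "K_pneumoniae",
    "Pcar_0903_BudY",
    "Pcar_2068_BudZ",
    "Ppro_3110",
)

_TABLE_ROWS = (
    ("S141", "S139", "S151", "C144", "S148"),
    ("I142", "Q140", "I152", "I145", "I149"),
    ("A143", "A141", "A153", "A146", "A150"),
    ("F148", "N146", "F158", "L151", "F155"),
    ("Y154", "Y152", "Y164", "Y157", "Y161"),
    ("P184", "P182", "P194", "P187", "P191"),
    ("G185", "G183", "G195", "G188", "G192"),
    ("I186", "I184", "I196", "I189", "I193"),
    ("M191", "M189", "M201", "M194", "M198"),
    ("W192", "W190", "W202", "W195", "W199"),
    ("I195", "I193", "I205", "I198", "I202"),
)

#: The five packaged active-site profiles, keyed by enzyme label.
TABLE_PROFILES: dict[str, ResidueProfile] = {
    label: ResidueProfile(
        label,
        tuple((cell, cell[0]) for cell in (row[j] for row in _TABLE_ROWS)),
    )
    for j, label in enumerate(_TABLE_COLUMNS)
}

#: Stereospecificity annotations of the two characterized references.
REFERENCE_ANNOTATIONS: dict[str, str] = {
    "C_glutamicum": "(2S,3S)-2,3-butanediol dehydrogenase",
    "K_pneumoniae": "meso-2,3-butanediol dehydrogenase",
}


def read_profile(path) -> ResidueProfile:
    """Read a profile from a simple tabular text file.

    Format: optional ``# label`` comment line, then one row per site:
    ``position_label<TAB or whitespace>residue``.
    """
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    label = Path(path).stem
    sites = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            comment = line.lstrip("#").strip()
            if comment:
                label = comment
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 'position_label residue', got {raw!r}"
            )
        sites.append((parts[0], parts[1]))
    if not sites:
        raise ValueError(f"{path}: no sites found")
    return ResidueProfile(label, tuple(sites))
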
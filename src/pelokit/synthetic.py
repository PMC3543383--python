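"""Seeded generators for synthetic proteomes and tRNA pairs.

These generators produce data with exactly the statistical structure
the analyses assume, so every stage of the package is testable without
downloading a genome.

Proteome model
--------------
Target residues are placed along each protein by a renewal process on
the inter-occurrence gaps.  With clustering parameter ``kappa = 0``
gaps are plain Geometric(f) — the placement a uniform-composition
sequence would show, with mean spacing ``1/f``.  For ``kappa > 0``
gaps come from a two-component geometric mixture: a *cluster*
component with mean ``max(1, (1/f)/(1+kappa))`` drawn with weight
``kappa/(1+kappa)``, and a *between-cluster* component whose mean is
solved so the overall mean gap stays exactly ``1/f``.  The marginal
target-residue frequency is therefore ``f`` for every ``kappa`` while
the harmonic mean of the gaps falls as ``kappa`` grows — which is
precisely what drives the demand index up.  Non-target positions are
filled from the background frequencies (which exclude the target
letter, so composition is controlled by ``f`` alone).

tRNA model
----------
A random cloverleaf-consistent sequence (all stem pairs legal,
3'-terminal CCA) is copied and mutated with a requested number of
compensatory events (a stem pair replaced by a different legal pair,
both bases changed), pair-breaking events (one stem base changed so
the pair becomes illegal), unpaired substitutions, and optionally a
3'-acceptor deletion.  The planted events are disjoint in position and
returned as ground truth, so classification can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demand import AMINO_ACIDS, ProteinRecord
from .trna import LEGAL_PAIRS, PairingMap, TrnaSequence

__all__ = [
    "ProteomeSpec",
    "TrnaPairSpec",
    "generate_proteome",
    "generate_trna_pair",
    "default_cloverleaf",
]

_RNA = ("A", "C", "G", "U")


def _uniform_background(target: str) -> dict[str, float]:
    others = sorted(AMINO_ACIDS - {target})
    return {aa: 1.0 / len(others) for aa in others}


@dataclass(frozen=True)
class ProteomeSpec:
    """Specification for a synthetic proteome.

    Parameters
    ----------
    n_proteins : number of proteins to generate.
    length_range : inclusive (min, max) protein length, sampled uniformly.
    target_residue : the residue whose spacing is being modelled.
    target_frequency : marginal frequency f of the target residue.
    kappa : clustering parameter; 0 = uniform placement, larger values
        concentrate occurrences into geometrically tighter runs at
        unchanged composition.
    background_frequencies : frequencies of the 19 non-target residues
        (must sum to 1); default uniform.
    seed : seed for the single random generator all draws flow from.
    """

    n_proteins: int = 100
    length_range: tuple[int, int] = (200, 600)
    target_residue: str = "N"
    target_frequency: float = 0.04
    kappa: float = 0.0
    background_frequencies: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be non-negative")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"degenerate length range {self.length_range}")
        if self.target_residue not in AMINO_ACIDS:
            raise ValueError(f"target residue {self.target_residue!r} is not standard")
        if not (0.0 < self.target_frequency < 0.5):
            raise ValueError("target frequency must lie in (0, 0.5)")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        bg = self.background_frequencies or _uniform_background(self.target_residue)
        if self.target_residue in bg:
            raise ValueError("background frequencies must exclude the target residue")
        if set(bg) - AMINO_ACIDS:
            raise ValueError("background frequencies contain non-standard letters")
        total = sum(bg.values())
        if abs(total - 1.0) > 1e-9 or min(bg.values()) < 0:
            raise ValueError("background frequencies must be non-negative and sum to 1")
        object.__setattr__(self, "background_frequencies", dict(bg))

    def gap_mixture(self) -> tuple[float, float, float]:
        """(weight of cluster component, cluster mean, between mean).

        Means are constrained so the marginal gap mean is exactly 1/f.
        """
        mean = 1.0 / self.target_frequency
        if self.kappa == 0:
            return 0.0, mean, mean
        w = self.kappa / (1.0 + self.kappa)
        m_short = max(1.0, mean / (1.0 + self.kappa))
        m_long = (mean - w * m_short) / (1.0 - w)
        if m_long < 1.0:
            raise ValueError(
                "degenerate spacing model: between-cluster mean gap below 1 "
                f"(f={self.target_frequency}, kappa={self.kappa})"
            )
        return w, m_short, m_long


def _draw_gap(rng: np.random.Generator, w: float, m_short: float, m_long: float) -> int:
    m = m_short if (w > 0 and rng.random() < w) else m_long
    return int(rng.geometric(1.0 / m))


def _equilibrium_weight(w: float, m_short: float, m_long: float) -> float:
    """Component weight for the *first* gap so the renewal process is
    stationary: components are chosen length-biased, and the forward
    recurrence time of a geometric gap is geometric again (discrete
    memorylessness), so the first arrival stays a two-geometric
    mixture.  This keeps the expected occurrence count at exactly
    ``L * f`` even when the between-cluster gaps have high variance."""
    mean = w * m_short + (1.0 - w) * m_long
    return w * m_short / mean


def generate_proteome(
    spec: ProteomeSpec,
) -> tuple[list[ProteinRecord], dict[str, list[int]]]:
    """Generate a proteome plus the ground-truth placement log.

    Returns the protein records and a mapping from protein id to the
    1-based positions where the target residue was planted.  Identical
    specs (same seed) give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    w, m_short, m_long = spec.gap_mixture()
    bg_letters = sorted(spec.background_frequencies)
    bg_probs = np.array([spec.background_frequencies[a] for a in bg_letters])
    bg_probs = bg_probs / bg_probs.sum()

    records: list[ProteinRecord] = []
    placements: dict[str, list[int]] = {}
    width = len(str(max(spec.n_proteins, 1)))
    for k in range(spec.n_proteins):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        positions: list[int] = []
        pos = 0
        first = True
        while True:
            weight = _equilibrium_weight(w, m_short, m_long) if first else w
            pos += _draw_gap(rng, weight, m_short, m_long)
            first = False
            if pos > length:
                break
            positions.append(pos)
        letters = list(rng.choice(bg_letters, size=length, p=bg_probs))
        for p in positions:
            letters[p - 1] = spec.target_residue
        pid = f"syn{k + 1:0{width}d}"
        records.append(ProteinRecord(pid, "".join(letters)))
        placements[pid] = positions
    return records, placements


# ---------------------------------------------------------------------------
# tRNA pairs
# ---------------------------------------------------------------------------


def default_cloverleaf(length: int = 76) -> PairingMap:
    """A canonical cloverleaf pairing map for a 76-base tRNA: acceptor
    stem 1-7/66-72, D stem 10-13/22-25, anticodon stem 27-31/39-43,
    T stem 49-53/61-65; anticodon 34-36; frameshift-control base 33."""
    if length < 76:
        raise ValueError("default cloverleaf needs length >= 76")
    pairs = (
        [(i, 73 - i) for i in range(1, 8)]        # acceptor stem 1-7 / 66-72
        + [(10 + k, 25 - k) for k in range(4)]    # D stem 10-13 / 22-25
        + [(27 + k, 43 - k) for k in range(5)]    # anticodon stem 27-31 / 39-43
        + [(49 + k, 65 - k) for k in range(5)]    # T stem 49-53 / 61-65
    )
    return PairingMap(tuple(pairs), anticodon_span=(34, 36), position_33=33)


@dataclass(frozen=True)
class TrnaPairSpec:
    """Specification for a synthetic aligned tRNA pair with planted events."""

    length: int = 76
    pairing: PairingMap | None = None
    n_compensatory: int = 0
    n_pair_breaking: int = 0
    n_unpaired: int = 0
    acceptor_deletion: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_compensatory", "n_pair_breaking", "n_unpaired", "acceptor_deletion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.pairing is None:
            object.__setattr__(self, "pairing", default_cloverleaf(self.length))
        if self.acceptor_deletion >= self.length:
            raise ValueError("acceptor deletion cannot remove the whole sequence")


def generate_trna_pair(
    spec: TrnaPairSpec,
) -> tuple[TrnaSequence, TrnaSequence, PairingMap, dict]:
    """Generate (reference, mutant, pairing map, ground truth).

    The ground truth records the planted event counts and positions;
    running :func:`pelokit.trna.classify_mutations` on the output
    recovers them exactly.
    """
    rng = np.random.default_rng(spec.seed)
    pairing = spec.pairing
    L = spec.length
    keep = L - spec.acceptor_deletion  # b retains a-positions 1..keep

    legal = sorted(LEGAL_PAIRS)
    a = [str(rng.choice(_RNA)) for _ in range(L)]
    for i, j in pairing.pairs:
        x, y = legal[int(rng.integers(len(legal)))]
        a[i - 1], a[j - 1] = x, y
    # canonical 3' aminoacylation site
    a[L - 3 : L] = ["C", "C", "A"]

    usable_pairs = [
        (i, j) for i, j in pairing.pairs if j <= keep and j < L - 2
    ]
    n_events = spec.n_compensatory + spec.n_pair_breaking
    if n_events > len(usable_pairs):
        raise ValueError(
            f"{n_events} stem events requested but only {len(usable_pairs)} "
            "stem pairs are available outside the deleted/terminal region"
        )
    order = rng.permutation(len(usable_pairs))
    chosen = [usable_pairs[int(t)] for t in order[:n_events]]
    comp_pairs = sorted(chosen[: spec.n_compensatory])
    break_pairs = sorted(chosen[spec.n_compensatory :])

    b = list(a)
    for i, j in comp_pairs:
        options = [
            (x, y) for x, y in legal if x != a[i - 1] and y != a[j - 1]
        ]
        x, y = options[int(rng.integers(len(options)))]
        b[i - 1], b[j - 1] = x, y
    for i, j in break_pairs:
        options = [
            x for x in _RNA if x != a[i - 1] and (x, a[j - 1]) not in LEGAL_PAIRS
        ]
        b[i - 1] = options[int(rng.integers(len(options)))]

    protected = set(pairing.paired_positions)
    if pairing.anticodon_span:
        protected.update(range(pairing.anticodon_span[0], pairing.anticodon_span[1] + 1))
    if pairing.position_33:
        protected.add(pairing.position_33)
    protected.update(range(L - 2, L + 1))  # the CCA end
    free = [p for p in range(1, keep + 1) if p not in protected]
    if spec.n_unpaired > len(free):
        raise ValueError(
            f"{spec.n_unpaired} unpaired substitutions requested but only "
            f"{len(free)} unpaired positions are available"
        )
    order = rng.permutation(len(free))
    unpaired_positions = sorted(free[int(t)] for t in order[: spec.n_unpaired])
    for p in unpaired_positions:
        options = [x for x in _RNA if x != a[p - 1]]
        b[p - 1] = options[int(rng.integers(len(options)))]

    a_seq = TrnaSequence("ref", "".join(a))
    b_seq = TrnaSequence("mut", "".join(b[:keep]))
    alignment = ("".join(a), "".join(b[:keep]) + "-" * spec.acceptor_deletion)
    truth = {
        "n_compensatory": spec.n_compensatory,
        "n_pair_breaking": spec.n_pair_breaking,
        "n_unpaired": spec.n_unpaired,
        "acceptor_deletion": spec.acceptor_deletion,
        "compensatory_pairs": comp_pairs,
        "pair_breaking_pairs": break_pairs,
        "unpaired_positions": unpaired_positions,
        "alignment": alignment,
    }
    return a_seq, b_seq, pairing, truth
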
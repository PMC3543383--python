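"""Cofactor-ledger stoichiometry and the chemiosmotic cation model.

A fermentation pathway is scored by an exact, signed ledger of the
energy and redox currencies it touches: ATP from substrate-level
phosphorylation, the electron-pair carriers NADH, NADPH and doubly
reduced ferredoxin (Fd2e), phosphoenolpyruvate (PEP, consumed by
phosphotransferase sugar import), transmembrane cations, and hydrogen
or formate (one interchangeable export species carrying one electron
pair).  All arithmetic is in exact rationals; printed yields are
rounded only at the reporting boundary.

The chemiosmotic model prices everything membrane-related in cations:

* ATP synthase with a c-ring of ``C`` subunits moves ``C`` cations per
  3 ATP, so one cation is worth ``3/C`` ATP.  ``C`` varies between 10
  and 15 across organisms depending on the c-subunit sequence.
* The Rnf complex exchanges one NADH for one Fd2e while moving ``r``
  cations; run forward (NADH -> Fd2e) it spends ``r * 3/C`` ATP
  equivalents, run reverse it earns the same.
* The Nfn transhydrogenase exchanges 1 NADH + 1 Fd2e for 2 NADPH at no
  cation cost, and NADPH leaves as hydrogen/formate through the
  NADPH-coupled hydrogenases / formate dehydrogenase, also free.

Because one ATP of substrate-level phosphorylation buys ``C/3``
cations while one Rnf exchange needs ``r``, the ratio of cell yields
on an NADH-generating versus an Fd2e/NADPH-generating electron donor
is predicted to be ``(C/3)/r``.  Fitting that prediction to observed
cell-yield ratios is an exhaustive grid search over the small integer
parameter space, exposed in statsmodels style as
:class:`CationYieldModel` / :class:`CationYieldResults`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, fields as dataclass_fields
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CofactorLedger",
    "Reaction",
    "Pathway",
    "CationModel",
    "UnbalancedLedgerError",
    "export_cost",
    "yield_ratio",
    "net_atp",
    "CationYieldModel",
    "CationYieldResults",
    "fit_cation_model",
]

#: Ledger species names, in canonical order.
LEDGER_SPECIES = ("atp", "nadh", "nadph", "fd2e", "pep", "h2_formate", "cations")

#: Species that carry exactly one electron pair each.
ELECTRON_PAIR_CARRIERS = ("nadh", "nadph", "fd2e", "h2_formate")


def _as_fraction(x) -> Fraction:
    if isinstance(x, Rational):
        return Fraction(x)
    if isinstance(x, str):
        return Fraction(x)
    if isinstance(x, float):
        # exact only for floats that are exactly representable ratios the
        # caller intended (0.5, 0.25 ...); pathway configs use strings/ints
        return Fraction(x).limit_denominator(10**6)
    raise TypeError(f"cannot coerce {x!r} to an exact rational")


@dataclass(frozen=True)
class CofactorLedger:
    """Signed exact-rational balances of the pathway currencies.

    Ledgers add component-wise under pathway concatenation and scale
    by reaction multiplicity.
    """

    atp: Fraction = Fraction(0)
    nadh: Fraction = Fraction(0)
    nadph: Fraction = Fraction(0)
    fd2e: Fraction = Fraction(0)
    pep: Fraction = Fraction(0)
    h2_formate: Fraction = Fraction(0)
    cations: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        for f in dataclass_fields(self):
            object.__setattr__(self, f.name, _as_fraction(getattr(self, f.name)))

    def __add__(self, other: "CofactorLedger") -> "CofactorLedger":
        return CofactorLedger(
            **{s: getattr(self, s) + getattr(other, s) for s in LEDGER_SPECIES}
        )

    def __mul__(self, k) -> "CofactorLedger":
        k = _as_fraction(k)
        return CofactorLedger(**{s: getattr(self, s) * k for s in LEDGER_SPECIES})

    __rmul__ = __mul__

    def electron_pairs(self) -> Fraction:
        """Net electron pairs held by the four one-pair carriers."""
        return sum((getattr(self, s) for s in ELECTRON_PAIR_CARRIERS), Fraction(0))

    def as_dict(self) -> dict[str, Fraction]:
        return {s: getattr(self, s) for s in LEDGER_SPECIES}


@dataclass(frozen=True)
class Reaction:
    """A named reaction step as a sparse ledger delta."""

    name: str
    deltas: Mapping[str, Fraction]

    def __post_init__(self) -> None:
        bad = set(self.deltas) - set(LEDGER_SPECIES)
        if bad:
            raise ValueError(f"reaction {self.name!r}: unknown species {sorted(bad)}")
        object.__setattr__(
            self, "deltas", {k: _as_fraction(v) for k, v in self.deltas.items()}
        )

    def ledger(self) -> CofactorLedger:
        return CofactorLedger(**dict(self.deltas))


@dataclass(frozen=True)
class Pathway:
    """An ordered list of (reaction, multiplicity) steps consuming
    ``substrate_multiplicity`` substrate molecules and releasing the
    listed products."""

    name: str
    substrate: str
    substrate_multiplicity: int
    reactions: tuple[tuple[Reaction, Fraction], ...]
    products: tuple[tuple[str, Fraction], ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        if self.substrate_multiplicity < 1:
            raise ValueError("substrate multiplicity must be a positive integer")
        names = [r.name for r, _ in self.reactions]
        if len(names) != len(set(names)):
            raise ValueError(f"pathway {self.name!r}: duplicate reaction names")
        object.__setattr__(
            self,
            "reactions",
            tuple((r, _as_fraction(m)) for r, m in self.reactions),
        )
        object.__setattr__(
            self,
            "products",
            tuple((p, _as_fraction(c)) for p, c in self.products),
        )

    def total_ledger(self) -> CofactorLedger:
        """Ledger for the whole pathway (all substrate molecules)."""
        total = CofactorLedger()
        for reaction, mult in self.reactions:
            total = total + reaction.ledger() * mult
        return total

    def per_substrate_ledger(self) -> CofactorLedger:
        return self.total_ledger() * Fraction(1, self.substrate_multiplicity)

    def product_ratio(self) -> dict[str, Fraction]:
        return {name: coeff for name, coeff in self.products}

    def concat(self, other: "Pathway", name: str | None = None) -> "Pathway":
        """Concatenate two pathways over the same substrate pool.

        Multiplicities add; the ledger of the result is the sum of the
        two ledgers (additivity of gross yields follows).
        """
        renamed = tuple(
            (Reaction(f"{other.name}:{r.name}", r.deltas), m)
            for r, m in other.reactions
        )
        own = tuple((Reaction(f"{self.name}:{r.name}", r.deltas), m) for r, m in self.reactions)
        return Pathway(
            name=name or f"{self.name}+{other.name}",
            substrate=self.substrate,
            substrate_multiplicity=self.substrate_multiplicity
            + other.substrate_multiplicity,
            reactions=own + renamed,
            products=self.products + other.products,
        )


class UnbalancedLedgerError(ValueError):
    """Raised when net-mode accounting cannot balance the ledger with
    the Rnf/Nfn/hydrogenase rules; names the offending species."""

    def __init__(self, species: str, value: Fraction):
        self.species = species
        self.value = value
        super().__init__(
            f"cannot balance ledger: species {species!r} has residual {value} "
            "that the Rnf/Nfn/hydrogenase rules cannot export"
        )


@dataclass(frozen=True)
class CationModel:
    """Chemiosmotic parameters: c-ring size ``C`` and Rnf cations ``r``.

    The Nfn stoichiometry (1 NADH + 1 Fd2e <-> 2 NADPH) and the
    hydrogenase/formate-dehydrogenase stoichiometry (1 NADPH <-> 1
    hydrogen-or-formate) are fixed properties of the machinery, not
    free parameters.
    """

    c_subunits: int = 10
    rnf_cations: int = 2

    #: fixed complex stoichiometries (per exchange event)
    NFN_NADH = 1
    NFN_FD2E = 1
    NFN_NADPH = 2
    HYD_NADPH = 1
    HYD_H2_FORMATE = 1

    def __post_init__(self) -> None:
        if not (10 <= self.c_subunits <= 15):
            raise ValueError(
                f"c-ring size must be between 10 and 15, got {self.c_subunits}"
            )
        if self.rnf_cations < 1:
            raise ValueError("Rnf must move a positive integer number of cations")

    @property
    def atp_per_cation(self) -> Fraction:
        """Exact ATP value of one translocated cation, 3/C."""
        return Fraction(3, self.c_subunits)

    @property
    def rnf_atp(self) -> Fraction:
        """ATP equivalents moved by one Rnf exchange, r * 3/C."""
        return self.rnf_cations * self.atp_per_cation

    def yield_ratio(self) -> Fraction:
        """Predicted cell-yield ratio (C/3)/r."""
        return Fraction(self.c_subunits, 3) / self.rnf_cations


def yield_ratio(model: CationModel) -> Fraction:
    """Predicted cell-yield ratio of the model, (C/3)/r, exact."""
    return model.yield_ratio()


def export_cost(nadh, fd2e, model: CationModel) -> Fraction:
    """ATP-equivalent of exporting *nadh* + *fd2e* electron pairs as
    hydrogen/formate (negative = cost, positive = gain).

    Matched NADH/Fd2e pairs leave free through Nfn and the NADPH-coupled
    hydrogenases.  A surplus of either species must be converted to the
    other through Rnf, pairwise: each forward conversion spends one
    surplus NADH (at ``r * 3/C`` ATP) and enables Nfn pairing of
    another, so ``s`` surplus NADH need ``s/2`` conversions.  A Fd2e
    surplus earns the same through reverse Rnf.
    """
    nadh, fd2e = _as_fraction(nadh), _as_fraction(fd2e)
    if nadh < 0 or fd2e < 0:
        raise ValueError("export_cost takes non-negative electron-pair surpluses")
    surplus = nadh - fd2e
    conversions = abs(surplus) / 2
    if surplus > 0:  # forward Rnf: spend cations
        return -conversions * model.rnf_atp
    if surplus < 0:  # reverse Rnf: earn cations
        return conversions * model.rnf_atp
    return Fraction(0)


def net_atp(pathway: Pathway, model: CationModel | None = None, mode: str = "gross") -> Fraction:
    """ATP yield per substrate molecule, exact.

    ``gross`` counts substrate-level phosphorylation only (PEP spent
    by phosphotransferase import is already debited inside the
    pathway, because import rather than pyruvate kinase turns that PEP
    into pyruvate).  ``net`` additionally prices the export of
    residual NADH/Fd2e through Rnf/Nfn/hydrogenase and charges or
    credits transmembrane cations at ``3/C`` ATP each.
    """
    if mode not in ("gross", "net"):
        raise ValueError(f"mode must be 'gross' or 'net', got {mode!r}")
    total = pathway.total_ledger()
    mult = Fraction(pathway.substrate_multiplicity)
    if mode == "gross":
        return total.atp / mult
    if model is None:
        raise ValueError("net mode requires a CationModel")
    if total.pep != 0:
        raise UnbalancedLedgerError("pep", total.pep)
    for species in ("nadh", "nadph", "fd2e"):
        if getattr(total, species) < 0:
            raise UnbalancedLedgerError(species, getattr(total, species))
    # residual NADPH leaves directly through hydrogenase / formate
    # dehydrogenase at no cation cost; NADH/Fd2e go through Rnf + Nfn.
    export = export_cost(total.nadh, total.fd2e, model)
    cation_term = total.cations * model.atp_per_cation
    return (total.atp + export + cation_term) / mult


def residual_after_export(pathway: Pathway) -> dict[str, Fraction]:
    """Redox residuals once net-mode export rules are applied.

    Every electron pair left in NADH, NADPH or Fd2e is exportable as
    hydrogen/formate, so the post-export residual of those three
    species is zero whenever the pre-export residuals are
    non-negative; the exported pairs accumulate in ``h2_formate``.
    """
    total = pathway.total_ledger()
    exported = total.nadh + total.nadph + total.fd2e
    return {
        "nadh": Fraction(0),
        "nadph": Fraction(0),
        "fd2e": Fraction(0),
        "h2_formate": total.h2_formate + exported,
    }


# ---------------------------------------------------------------------------
# fitting the cation model to observed cell-yield ratios
# ---------------------------------------------------------------------------

DEFAULT_C_RANGE = tuple(range(10, 16))
DEFAULT_R_RANGE = tuple(range(1, 6))


class CationYieldModel:
    """Grid-search model for the chemiosmotic parameters (C, r).

    Parameters
    ----------
    observed_ratios
        Cell-yield ratios of growth on an NADH-generating electron
        donor versus an Fd2e/NADPH-generating one (dimensionless).
    c_range, r_range
        Integer grids for the c-ring size and Rnf cation count.

    ``fit`` minimises the sum of squared differences between the
    predicted ratio ``(C/3)/r`` and each observation, exhaustively
    over the grid, breaking exact ties by the lexicographically
    smallest ``(C, r)``.
    """

    def __init__(
        self,
        observed_ratios: Sequence[float],
        c_range: Iterable[int] = DEFAULT_C_RANGE,
        r_range: Iterable[int] = DEFAULT_R_RANGE,
    ):
        ratios = [Fraction(x) if isinstance(x, Rational) else Fraction(str(x)) for x in observed_ratios]
        if not ratios:
            raise ValueError("at least one observed ratio is required")
        self.observed_ratios = tuple(ratios)
        self.c_range = tuple(sorted(set(int(c) for c in c_range)))
        self.r_range = tuple(sorted(set(int(r) for r in r_range)))
        if not self.c_range or not self.r_range:
            raise ValueError("parameter grids must be non-empty")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, column: str = "ratio", **kwargs) -> "CationYieldModel":
        return cls(list(data[column]), **kwargs)

    def predict(self, c_subunits: int, rnf_cations: int) -> Fraction:
        return CationModel(c_subunits, rnf_cations).yield_ratio()

    def fit(self) -> "CationYieldResults":
        rows = []
        for c, r in itertools.product(self.c_range, self.r_range):
            pred = Fraction(c, 3) / r
            loss = sum((pred - obs) ** 2 for obs in self.observed_ratios)
            rows.append((c, r, pred, loss))
        min_loss = min(row[3] for row in rows)
        minima = sorted((c, r) for c, r, _, loss in rows if loss == min_loss)
        best_c, best_r = minima[0]
        grid = pd.DataFrame(
            {
                "c_subunits": [c for c, _, _, _ in rows],
                "rnf_cations": [r for _, r, _, _ in rows],
                "predicted_ratio": [float(p) for _, _, p, _ in rows],
                "loss": [float(l) for _, _, _, l in rows],
            }
        )
        return CationYieldResults(
            model=self,
            c_subunits=best_c,
            rnf_cations=best_r,
            loss=float(min_loss),
            grid=grid,
            degenerate_minima=tuple(minima),
        )


@dataclass(frozen=True)
class CationYieldResults:
    """Results of a :class:`CationYieldModel` fit."""

    model: CationYieldModel
    c_subunits: int
    rnf_cations: int
    loss: float
    grid: pd.DataFrame
    degenerate_minima: tuple[tuple[int, int], ...]

    @property
    def best(self) -> tuple[int, int]:
        return (self.c_subunits, self.rnf_cations)

    @property
    def cation_model(self) -> CationModel:
        return CationModel(self.c_subunits, self.rnf_cations)

    @property
    def predicted_ratio(self) -> Fraction:
        return self.cation_model.yield_ratio()

    @property
    def resid(self) -> np.ndarray:
        pred = float(self.predicted_ratio)
        return np.array([float(obs) - pred for obs in self.model.observed_ratios])

    def summary(self) -> str:
        obs = ", ".join(f"{float(x):.2f}" for x in self.model.observed_ratios)
        lines = [
            "Chemiosmotic cation-model fit (exhaustive grid search)",
            "=" * 54,
            f"observed yield ratios : {obs}",
            f"grid                  : C in {self.model.c_range}, r in {self.model.r_range}",
            f"best c-ring size C    : {self.c_subunits}",
            f"best Rnf cations r    : {self.rnf_cations}",
            f"predicted ratio (C/3)/r : {self.predicted_ratio} = {float(self.predicted_ratio):.3f}",
            f"sum-of-squares loss   : {self.loss:.4f}",
            f"ATP per cation (3/C)  : {self.cation_model.atp_per_cation} = {float(self.cation_model.atp_per_cation):.2f}",
            f"Rnf exchange cost     : {self.cation_model.rnf_atp} = {float(self.cation_model.rnf_atp):.2f} ATP",
        ]
        if len(self.degenerate_minima) > 1:
            others = ", ".join(f"(C={c}, r={r})" for c, r in self.degenerate_minima)
            lines.append(f"degenerate minima     : {others} (smallest (C, r) reported)")
        return "\n".join(lines)


def fit_cation_model(
    observed_ratios: Sequence[float],
    c_range: Iterable[int] = DEFAULT_C_RANGE,
    r_range: Iterable[int] = DEFAULT_R_RANGE,
) -> CationYieldResults:
    """Convenience wrapper: build a :class:`CationYieldModel` and fit it."""
    return CationYieldModel(observed_ratios, c_range, r_range).fit()
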
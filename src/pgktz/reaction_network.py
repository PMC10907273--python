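"""Mass-action reaction network for the terazosin (TZ) - PGK1 interaction.

Phosphoglycerate kinase 1 (PGK1, "E") catalyzes reversible phosphotransfer
from 1,3-bisphosphoglycerate (BPG) to ADP, yielding 3-phosphoglycerate (PG)
and ATP.  Substrates and products bind in random order, giving two "diamonds"
of binding states joined by the phosphotransfer step:

    E <-> E.ADP / E.BPG <-> E.ADP.BPG  <=k=>  E.ATP.PG <-> E.ATP / E.PG <-> E

Terazosin occupies the ADP/ATP pocket and can bind E, E.BPG and E.PG, adding
three TZ-bound forms (E.TZ, E.TZ.BPG, E.TZ.PG) and a bypass route that
releases 3-PG from E.TZ.PG at the fast rate b- instead of the slow rate c-.

The canonical network has 10 enzyme forms, 5 free ligands and 14 reversible
reactions.  All concentrations are in uM and all times in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RateParameters",
    "Species",
    "RateRef",
    "Reaction",
    "ReactionNetwork",
    "build_canonical_network",
    "mass_action_rhs",
    "ENZYME_FORMS",
    "TZ_FREE_FORMS",
    "TZ_BOUND_FORMS",
    "FREE_LIGANDS",
    "SPECIES_ORDER",
]

# Canonical species ordering; every state vector, table and CSV follows it.
TZ_FREE_FORMS: tuple[str, ...] = (
    "E", "E.ADP", "E.BPG", "E.ADP.BPG", "E.ATP", "E.PG", "E.ATP.PG",
)
TZ_BOUND_FORMS: tuple[str, ...] = ("E.TZ", "E.TZ.BPG", "E.TZ.PG")
ENZYME_FORMS: tuple[str, ...] = TZ_FREE_FORMS + TZ_BOUND_FORMS
FREE_LIGANDS: tuple[str, ...] = ("ADP", "BPG", "ATP", "PG", "TZ")
SPECIES_ORDER: tuple[str, ...] = ENZYME_FORMS + FREE_LIGANDS

#: Species participating in the adenine-nucleotide conservation law.
ADENINE_SPECIES: tuple[str, ...] = (
    "ADP", "ATP", "E.ADP", "E.ADP.BPG", "E.ATP", "E.ATP.PG",
)
#: Species participating in the terazosin conservation law.
TZ_SPECIES: tuple[str, ...] = ("TZ", "E.TZ", "E.TZ.BPG", "E.TZ.PG")

_PARAM_NAMES = (
    "a_plus", "a_minus", "b_plus", "b_minus", "c_plus", "c_minus",
    "d_plus", "d_minus", "k_plus", "k_minus", "eta",
)


@dataclass(frozen=True)
class RateParameters:
    """Kinetic rate constants of the model.

    ``a``-``d`` are the bimolecular association (``*_plus``, s^-1 uM^-1) and
    unimolecular dissociation (``*_minus``, s^-1) constants for ADP/ATP and
    BPG/PG binding to the various enzyme forms.  ``k_plus``/``k_minus`` are
    the phosphotransfer rates (s^-1).  ``eta`` is the dimensionless factor
    by which terazosin's association rate exceeds that of the nucleotide
    edge it mirrors; defaults reproduce the published biphasic response.
    """

    a_plus: float = 6.1
    a_minus: float = 38.0
    b_plus: float = 170.0
    b_minus: float = 160.0
    c_plus: float = 450.0
    c_minus: float = 14.0
    d_plus: float = 4.1
    d_minus: float = 270.0
    k_plus: float = 5.0
    k_minus: float = 5.0
    eta: float = 562.0

    def __post_init__(self) -> None:
        for name in _PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(
                    f"rate parameter {name!r} must be finite and >= 0, got {value}"
                )

    def replace(self, **changes: float) -> "RateParameters":
        """Return a copy with the given parameters changed (re-validated)."""
        return replace(self, **changes)

    def value(self, name: str) -> float:
        if name not in _PARAM_NAMES:
            raise KeyError(f"unknown rate parameter {name!r}")
        return getattr(self, name)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class Species:
    """A chemical species: an enzyme form or a free ligand.

    ``clamped`` species are held constant during integration (the default
    protocol clamps only BPG, at 80 uM).
    """

    name: str
    role: str  # "enzyme-form" | "free-ligand"
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("enzyme-form", "free-ligand"):
            raise ValueError(f"invalid species role {self.role!r}")


@dataclass(frozen=True)
class RateRef:
    """Reference to a rate constant: a parameter name, optionally scaled by eta."""

    param: str
    eta_scaled: bool = False

    def evaluate(self, params: RateParameters) -> float:
        k = params.value(self.param)
        return k * params.eta if self.eta_scaled else k

    def label(self) -> str:
        return f"eta*{self.param}" if self.eta_scaled else self.param


@dataclass(frozen=True)
class Reaction:
    """One reversible elementary reaction, written in its forward direction.

    Every reaction converts exactly one enzyme form into another; binding
    reactions additionally consume one free ligand on the reactant side.
    """

    label: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    forward: RateRef
    reverse: RateRef

    def __post_init__(self) -> None:
        n_enz_r = sum(1 for s in self.reactants if s in ENZYME_FORMS)
        n_enz_p = sum(1 for s in self.products if s in ENZYME_FORMS)
        if n_enz_r != 1 or n_enz_p != 1:
            raise ValueError(
                f"{self.label}: each side must carry exactly one enzyme form"
            )


class ReactionNetwork:
    """Species, reactions and parameters of a mass-action ODE system.

    Provides the right-hand side and analytic Jacobian of the system
    dy/dt = S v(y), with clamped species' derivatives forced to zero.
    """

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        parameters: RateParameters,
    ) -> None:
        self.species: tuple[Species, ...] = tuple(species)
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self.parameters = parameters
        self._index = {s.name: i for i, s in enumerate(self.species)}
        if len(self._index) != len(self.species):
            raise ValueError("duplicate species names")
        for rxn in self.reactions:
            for name in rxn.reactants + rxn.products:
                if name not in self._index:
                    raise ValueError(f"{rxn.label}: unknown species {name!r}")
        self._compile()

    # -- structure ---------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def clamped_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species if s.clamped)

    def index(self, name: str) -> int:
        return self._index[name]

    def indices(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self._index[n] for n in names], dtype=int)

    def with_clamped(self, names: Iterable[str]) -> "ReactionNetwork":
        """Return a copy with exactly the given species clamped."""
        names = set(names)
        unknown = names - set(self._index)
        if unknown:
            raise ValueError(f"unknown species in clamp list: {sorted(unknown)}")
        species = [replace(s, clamped=(s.name in names)) for s in self.species]
        return ReactionNetwork(species, self.reactions, self.parameters)

    def with_parameters(self, parameters: RateParameters) -> "ReactionNetwork":
        return ReactionNetwork(self.species, self.reactions, parameters)

    def _compile(self) -> None:
        # Each reaction is (E_a [+ L]) <-> E_b: store the enzyme/ligand
        # reactant indices (ligand = virtual slot holding 1.0 for the
        # unimolecular phosphotransfer step) and the product index.
        n = self.n_species
        virt = n  # index of the constant-1 pad appended to the state
        s1, s2, prod, kf, kr = [], [], [], [], []
        for rxn in self.reactions:
            enz = [s for s in rxn.reactants if s in ENZYME_FORMS]
            lig = [s for s in rxn.reactants if s not in ENZYME_FORMS]
            (p,) = rxn.products
            s1.append(self._index[enz[0]])
            s2.append(self._index[lig[0]] if lig else virt)
            prod.append(self._index[p])
            kf.append(rxn.forward.evaluate(self.parameters))
            kr.append(rxn.reverse.evaluate(self.parameters))
        self._s1 = np.array(s1)
        self._s2 = np.array(s2)
        self._prod = np.array(prod)
        self._kf = np.array(kf)
        self._kr = np.array(kr)
        self._free_mask = np.array([not s.clamped for s in self.species])

    # -- dynamics ----------------------------------------------------------

    def reaction_fluxes(self, state: np.ndarray) -> np.ndarray:
        """Net flux (forward minus reverse rate, uM/s) of each reaction."""
        y = np.append(np.asarray(state, dtype=float), 1.0)
        return self._kf * y[self._s1] * y[self._s2] - self._kr * y[self._prod]

    def rhs(self, t: float, state: np.ndarray) -> np.ndarray:
        """Mass-action time derivative; clamped species are held at 0."""
        flux = self.reaction_fluxes(state)
        dy = np.zeros(self.n_species + 1)
        np.subtract.at(dy, self._s1, flux)
        np.subtract.at(dy, self._s2, flux)
        np.add.at(dy, self._prod, flux)
        dy = dy[:-1]
        dy[~self._free_mask] = 0.0
        return dy

    def jacobian(self, t: float, state: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of :meth:`rhs` (clamped rows are zero)."""
        n = self.n_species
        y = np.append(np.asarray(state, dtype=float), 1.0)
        J = np.zeros((n + 1, n + 1))
        for m in range(len(self._kf)):
            i, j, p = self._s1[m], self._s2[m], self._prod[m]
            dfi = self._kf[m] * y[j]   # d flux / d y_i
            dfj = self._kf[m] * y[i]   # d flux / d y_j
            dfp = -self._kr[m]         # d flux / d y_p
            for col, df in ((i, dfi), (j, dfj), (p, dfp)):
                J[i, col] -= df
                J[j, col] -= df
                J[p, col] += df
        J = J[:n, :n]
        J[~self._free_mask, :] = 0.0
        return J

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        """Plain JSON description for inspection and round-tripping."""
        doc = {
            "parameters": self.parameters.to_dict(),
            "species": [asdict(s) for s in self.species],
            "reactions": [
                {
                    "label": r.label,
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "forward": r.forward.label(),
                    "reverse": r.reverse.label(),
                }
                for r in self.reactions
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ReactionNetwork":
        doc = json.loads(text)
        params = RateParameters(**doc["parameters"])
        species = [Species(**s) for s in doc["species"]]

        def parse_ref(label: str) -> RateRef:
            if label.startswith("eta*"):
                return RateRef(label[4:], eta_scaled=True)
            return RateRef(label)

        reactions = [
            Reaction(
                label=r["label"],
                reactants=tuple(r["reactants"]),
                products=tuple(r["products"]),
                forward=parse_ref(r["forward"]),
                reverse=parse_ref(r["reverse"]),
            )
            for r in doc["reactions"]
        ]
        return cls(species, reactions, params)


def _canonical_reactions() -> tuple[Reaction, ...]:
    R = Reaction
    f = RateRef
    return (
        R("R1", ("E", "ADP"), ("E.ADP",), f("a_plus"), f("a_minus")),
        R("R2", ("E", "BPG"), ("E.BPG",), f("c_plus"), f("c_minus")),
        R("R3", ("E.ADP", "BPG"), ("E.ADP.BPG",), f("b_plus"), f("b_minus")),
        R("R4", ("E.BPG", "ADP"), ("E.ADP.BPG",), f("d_plus"), f("d_minus")),
        R("R5", ("E.ADP.BPG",), ("E.ATP.PG",), f("k_plus"), f("k_minus")),
        R("R6", ("E", "ATP"), ("E.ATP",), f("a_plus"), f("a_minus")),
        R("R7", ("E", "PG"), ("E.PG",), f("c_plus"), f("c_minus")),
        R("R8", ("E.ATP", "PG"), ("E.ATP.PG",), f("b_plus"), f("b_minus")),
        R("R9", ("E.PG", "ATP"), ("E.ATP.PG",), f("d_plus"), f("d_minus")),
        R("R10", ("E", "TZ"), ("E.TZ",), f("a_plus", True), f("a_minus")),
        R("R11", ("E.BPG", "TZ"), ("E.TZ.BPG",), f("d_plus", True), f("d_minus")),
        R("R12", ("E.PG", "TZ"), ("E.TZ.PG",), f("d_plus", True), f("d_minus")),
        R("R13", ("E.TZ", "BPG"), ("E.TZ.BPG",), f("b_plus"), f("b_minus")),
        R("R14", ("E.TZ", "PG"), ("E.TZ.PG",), f("b_plus"), f("b_minus")),
    )


REACTION_LABELS: tuple[str, ...] = tuple(r.label for r in _canonical_reactions())


def build_canonical_network(
    params: RateParameters | None = None,
    clamped: Iterable[str] = ("BPG",),
    include_tz: bool = True,
) -> ReactionNetwork:
    """Build the canonical terazosin-PGK1 network.

    Parameters
    ----------
    params
        Kinetic constants; defaults to the published values.
    clamped
        Species held constant during integration (default: BPG only).
    include_tz
        If False, build the 7-form TZ-free sub-network (reactions R1-R9 and
        no TZ species); used to verify that the full model reduces to it
        when no terazosin is present.
    """
    params = params if params is not None else RateParameters()
    clamped = set(clamped)
    if include_tz:
        forms, ligands = ENZYME_FORMS, FREE_LIGANDS
        reactions = _canonical_reactions()
    else:
        forms = TZ_FREE_FORMS
        ligands = tuple(l for l in FREE_LIGANDS if l != "TZ")
        reactions = _canonical_reactions()[:9]
    species = [
        Species(n, "enzyme-form", clamped=n in clamped) for n in forms
    ] + [
        Species(n, "free-ligand", clamped=n in clamped) for n in ligands
    ]
    return ReactionNetwork(species, reactions, params)


def mass_action_rhs(network: ReactionNetwork, state: np.ndarray) -> np.ndarray:
    """Time derivative (uM/s) of every species under mass-action kinetics.

    Raises ``ValueError`` on a negative concentration or wrong length; this
    is the validated entry point (the bare ``network.rhs`` is what the ODE
    solver calls and does not re-validate at every step).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (network.n_species,):
        raise ValueError(
            f"state must have length {network.n_species}, got {state.shape}"
        )
    if np.any(state < 0):
        bad = network.species_names[int(np.argmin(state))]
        raise ValueError(f"negative concentration for species {bad!r}")
    return network.rhs(0.0, state)
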
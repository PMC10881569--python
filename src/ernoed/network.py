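"""Kinetic model of the in vitro nucleotide salvage pathway.

The network couples PRPP to the nucleobases uracil and adenine (UPRT, APRT),
phosphorylates the resulting monophosphates plus GMP to diphosphates
(UMPK, GMPK, AK) using ATP as phosphate donor, and regenerates triphosphates
from PEP through a single pyruvate kinase (PK) that is shared between UDP,
GDP and ADP.  Six enzymes, eight reactions, fifteen chemical species.

Rate laws are saturation (Michaelis-Menten type) kinetics with one binding
site per substrate pair and multiplicative site denominators:

* irreversible two-substrate reactions (UPRT, APRT) carry competitive
  product binding (the nucleoside monophosphate at the base site, PPi at
  the PRPP site);
* reversible reactions use a two-term numerator
  ``Vf * substrate occupancy - Vr * product occupancy``;
* the three PK reactions share a single nucleotide site whose denominator
  sums the occupancies of all three NDPs and all three NTPs, so the
  substrates compete for the same enzyme.

Under this scheme the default network has 41 kinetic parameters
(catalytic rates in mM/min, Michaelis constants in mM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "SPECIES",
    "OBSERVABLES",
    "ENZYMES",
    "MOIETIES",
    "ReactionSpec",
    "KineticParameters",
    "EnzymeLoading",
    "NetworkModel",
    "assemble_salvage_network",
    "make_variant",
    "reaction_rate",
]

#: The fifteen chemical species tracked by the ODE state vector.
SPECIES: tuple[str, ...] = (
    "uracil", "adenine", "PRPP", "PPi", "UMP", "AMP", "GMP", "UDP",
    "ADP", "GDP", "UTP", "ATP", "GTP", "PEP", "pyruvate",
)

#: The eight species quantified by the (HPLC-like) observation step.
OBSERVABLES: tuple[str, ...] = (
    "uracil", "UMP", "GMP", "adenine", "ADP", "GTP", "UTP", "ATP",
)

ENZYMES: tuple[str, ...] = ("UPRT", "APRT", "UMPK", "GMPK", "AK", "PK")

#: Conserved moieties under batch (no-flow) operation: ring counts of the
#: three bases and the PEP/pyruvate carbon skeleton.
MOIETIES: dict[str, dict[str, int]] = {
    "uracil_ring": {"uracil": 1, "UMP": 1, "UDP": 1, "UTP": 1},
    "adenine_ring": {"adenine": 1, "AMP": 1, "ADP": 1, "ATP": 1},
    "guanine_ring": {"GMP": 1, "GDP": 1, "GTP": 1},
    "pep_skeleton": {"PEP": 1, "pyruvate": 1},
}

_RATE_LAWS = ("irreversible_mm", "reversible_mm", "shared_site_mm")

# Default parameter bounds: plausible enzymology ranges (catalytic rates in
# mM/min at reference enzyme loading, Michaelis/inhibition constants in mM).
_V_BOUNDS = (1e-2, 10.0)
_K_BOUNDS = (1e-2, 5.0)


class NetworkError(ValueError):
    """Invalid network definition or evaluation request."""


@dataclass(frozen=True)
class ReactionSpec:
    """One enzyme-catalysed reaction with its binding-site layout.

    ``sites`` lists the enzyme's binding sites; each site is a tuple of
    ``(species, km_parameter_name)`` pairs of every species that competes
    for that site.  Km parameter names are scoped either by reaction id
    (private site) or by enzyme name (shared site, e.g. ``PK.Km_UDP``).
    ``inhibitors`` are optional competitive modifiers ``(species, ki_name)``
    multiplying the rate by ``1 / (1 + I/Ki)``.
    """

    id: str
    enzyme: str
    substrates: Mapping[str, int]
    products: Mapping[str, int]
    reversible: bool
    rate_law: str
    sites: tuple[tuple[tuple[str, str], ...], ...]
    inhibitors: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.rate_law not in _RATE_LAWS:
            raise NetworkError(f"unknown rate law {self.rate_law!r}")

    def km_name(self, species: str) -> str:
        for site in self.sites:
            for sp_name, km in site:
                if sp_name == species:
                    return km
        raise NetworkError(f"{self.id}: no Km for species {species!r}")

    def parameter_names(self) -> list[str]:
        """Ordered parameter names introduced by this reaction."""
        names = [f"{self.id}.Vf"]
        if self.reversible:
            names.append(f"{self.id}.Vr")
        for site in self.sites:
            for _, km in site:
                if km not in names:
                    names.append(km)
        for _, ki in self.inhibitors:
            names.append(ki)
        return names


def _default_bounds(name: str) -> tuple[float, float]:
    tag = name.split(".", 1)[1]
    if tag.startswith(("Vf", "Vr")):
        return _V_BOUNDS
    return _K_BOUNDS


@dataclass
class KineticParameters:
    """Named, bounded kinetic parameter vector theta.

    Catalytic rates (``*.Vf``, ``*.Vr``) are expressed at reference enzyme
    loading in mM/min; Michaelis and inhibition constants in mM.
    """

    names: tuple[str, ...]
    values: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        n = len(self.names)
        if not (self.values.shape == self.lower.shape == self.upper.shape == (n,)):
            raise NetworkError("parameter vector/bounds shape mismatch")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))

    def replace_values(self, values: np.ndarray | Mapping[str, float]) -> "KineticParameters":
        if isinstance(values, Mapping):
            vec = self.values.copy()
            for k, v in values.items():
                vec[self.names.index(k)] = v
        else:
            vec = np.asarray(values, dtype=float)
        return KineticParameters(self.names, vec, self.lower, self.upper)

    def validate(self) -> None:
        if np.any(self.values <= 0):
            raise NetworkError("kinetic parameters must be strictly positive")
        if np.any(self.values < self.lower) or np.any(self.values > self.upper):
            raise NetworkError("kinetic parameters outside declared bounds")


@dataclass
class EnzymeLoading:
    """Relative enzyme activity factors (dimensionless, scale Vmax).

    Immobilised enzymes are retained in the reactor, so the loading is
    constant over a simulation; it may differ between experimental rounds.
    """

    loading: dict[str, float] = field(default_factory=dict)

    def factor(self, enzyme: str) -> float:
        return float(self.loading.get(enzyme, 1.0))

    def as_vector(self, enzymes: Sequence[str]) -> np.ndarray:
        vec = np.array([self.factor(e) for e in enzymes], dtype=float)
        if np.any(vec < 0):
            raise NetworkError("enzyme loading factors must be >= 0")
        return vec


class _Compiled:
    """Numpy-callable kinetics generated symbolically once per model.

    Exposes the reaction flux vector v(C, theta, load), the reaction part of
    the state derivative f = N @ v, and its exact Jacobians with respect to
    the state and the parameters (used by the stiff integrator and by the
    forward-sensitivity equations).
    """

    def __init__(self, model: "NetworkModel") -> None:
        from ._codegen import build_kernels

        c_syms = sp.symbols([f"c_{s}" for s in model.species], positive=False)
        p_syms = sp.symbols(
            [name.replace(".", "__") for name in model.parameter_names])
        l_syms = sp.symbols([f"load_{e}" for e in model.enzymes])
        cmap = dict(zip(model.species, c_syms))
        pmap = dict(zip(model.parameter_names, p_syms))
        lmap = dict(zip(model.enzymes, l_syms))

        rates = sp.Matrix([_rate_expression(r, cmap, pmap, lmap)
                           for r in model.reactions])
        f = sp.Matrix(model.stoichiometry) * rates
        jac_c = f.jacobian(c_syms)
        dfdtheta = f.jacobian(p_syms)

        self._k = build_kernels(c_syms, p_syms, l_syms, rates, f, jac_c,
                                dfdtheta)
        self.n_species = len(c_syms)
        self.n_parameters = len(p_syms)
        self.n_reactions = rates.shape[0]

    def rates(self, c, theta, load) -> np.ndarray:
        out = np.empty(self.n_reactions)
        return self._k["rates"](np.asarray(c, float), theta, load, out)

    def f(self, c, theta, load) -> np.ndarray:
        out = np.empty(self.n_species)
        return self._k["f"](np.asarray(c, float), theta, load, out)

    def jac_c(self, c, theta, load) -> np.ndarray:
        out = np.empty(self.n_species * self.n_species)
        self._k["jac_c"](np.asarray(c, float), theta, load, out)
        return out.reshape(self.n_species, self.n_species)

    def dfdtheta(self, c, theta, load) -> np.ndarray:
        out = np.empty(self.n_species * self.n_parameters)
        self._k["dfdtheta"](np.asarray(c, float), theta, load, out)
        return out.reshape(self.n_species, self.n_parameters)


def _rate_expression(rxn: ReactionSpec, cmap, pmap, lmap):
    def occ(species: str) -> sp.Expr:
        return cmap[species] / pmap[rxn.km_name(species)]

    forward = pmap[f"{rxn.id}.Vf"]
    for species, n in rxn.substrates.items():
        forward *= occ(species) ** n
    numerator = forward
    if rxn.reversible:
        reverse = pmap[f"{rxn.id}.Vr"]
        for species, n in rxn.products.items():
            reverse *= occ(species) ** n
        numerator = forward - reverse

    denom = sp.Integer(1)
    for site in rxn.sites:
        denom *= 1 + sum(cmap[s] / pmap[km] for s, km in site)
    for species, ki in rxn.inhibitors:
        denom *= 1 + cmap[species] / pmap[ki]
    return lmap[rxn.enzyme] * numerator / denom


class NetworkModel:
    """A stoichiometric/kinetic reaction network with compiled kinetics."""

    def __init__(
        self,
        species: Sequence[str],
        enzymes: Sequence[str],
        reactions: Sequence[ReactionSpec],
        bounds: Mapping[str, tuple[float, float]] | None = None,
    ) -> None:
        if len(set(species)) != len(species):
            raise NetworkError("duplicate species names")
        self.species = tuple(species)
        self.enzymes = tuple(enzymes)
        self.reactions = tuple(reactions)
        names: list[str] = []
        for rxn in self.reactions:
            for sp_name in list(rxn.substrates) + list(rxn.products):
                if sp_name not in self.species:
                    raise NetworkError(
                        f"{rxn.id}: unknown species {sp_name!r}")
            if rxn.enzyme not in self.enzymes:
                raise NetworkError(f"{rxn.id}: unknown enzyme {rxn.enzyme!r}")
            for name in rxn.parameter_names():
                if name not in names:
                    names.append(name)
        self.parameter_names: tuple[str, ...] = tuple(names)
        self.bounds: dict[str, tuple[float, float]] = {
            n: (bounds[n] if bounds and n in bounds else _default_bounds(n))
            for n in names
        }
        self._compiled: _Compiled | None = None
        self._rate_fns: dict[str, object] = {}
        self.validate_moieties()

    # -- structure -------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def stoichiometry(self) -> np.ndarray:
        """Net stoichiometric matrix N (species x reactions)."""
        N = np.zeros((self.n_species, self.n_reactions))
        for j, rxn in enumerate(self.reactions):
            for s, n in rxn.substrates.items():
                N[self.species.index(s), j] -= n
            for s, n in rxn.products.items():
                N[self.species.index(s), j] += n
        return N

    def reaction(self, rxn_id: str) -> ReactionSpec:
        for rxn in self.reactions:
            if rxn.id == rxn_id:
                return rxn
        raise NetworkError(f"unknown reaction {rxn_id!r}")

    def parameter_index(self, name: str) -> int:
        return self.parameter_names.index(name)

    def validate_moieties(self) -> None:
        """Check base-ring and PEP-skeleton balance of every reaction."""
        for rxn in self.reactions:
            for moiety, weights in MOIETIES.items():
                lhs = sum(n * weights.get(s, 0) for s, n in rxn.substrates.items())
                rhs = sum(n * weights.get(s, 0) for s, n in rxn.products.items())
                if lhs != rhs:
                    raise NetworkError(
                        f"{rxn.id}: moiety {moiety} unbalanced ({lhs} vs {rhs})")

    # -- parameters ------------------------------------------------------
    def nominal_parameters(self) -> KineticParameters:
        """Geometric mid-point of every parameter's bounds."""
        lo = np.array([self.bounds[n][0] for n in self.parameter_names])
        hi = np.array([self.bounds[n][1] for n in self.parameter_names])
        return KineticParameters(self.parameter_names, np.sqrt(lo * hi), lo, hi)

    def coerce_theta(self, theta) -> np.ndarray:
        if isinstance(theta, KineticParameters):
            theta = theta.values
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_parameters,):
            raise NetworkError(
                f"theta has shape {theta.shape}, expected ({self.n_parameters},)")
        return theta

    def coerce_loading(self, loading) -> np.ndarray:
        if loading is None:
            loading = EnzymeLoading()
        if isinstance(loading, EnzymeLoading):
            return loading.as_vector(self.enzymes)
        return np.asarray(loading, dtype=float)

    # -- kinetics --------------------------------------------------------
    @property
    def compiled(self) -> _Compiled:
        if self._compiled is None:
            self._compiled = _Compiled(self)
        return self._compiled

    def reaction_fluxes(self, state, theta, loading=None) -> np.ndarray:
        """All reaction rates v (mM/min) at the given state."""
        c = np.asarray(state, dtype=float)
        return self.compiled.rates(c, self.coerce_theta(theta),
                                   self.coerce_loading(loading))


def _salvage_reactions() -> list[ReactionSpec]:
    pk_nuc_site = tuple(
        (s, f"PK.Km_{s}") for s in ("UDP", "GDP", "ADP", "UTP", "GTP", "ATP"))
    pk_pep_site = (("PEP", "PK.Km_PEP"), ("pyruvate", "PK.Km_pyruvate"))

    def pk(rid: str, ndp: str, ntp: str) -> ReactionSpec:
        return ReactionSpec(
            id=rid, enzyme="PK",
            substrates={ndp: 1, "PEP": 1}, products={ntp: 1, "pyruvate": 1},
            reversible=True, rate_law="shared_site_mm",
            sites=(pk_nuc_site, pk_pep_site),
        )

    return [
        ReactionSpec(
            id="UPRT", enzyme="UPRT",
            substrates={"uracil": 1, "PRPP": 1}, products={"UMP": 1, "PPi": 1},
            reversible=False, rate_law="irreversible_mm",
            sites=(
                (("uracil", "UPRT.Km_uracil"), ("UMP", "UPRT.Km_UMP")),
                (("PRPP", "UPRT.Km_PRPP"), ("PPi", "UPRT.Km_PPi")),
            ),
        ),
        ReactionSpec(
            id="APRT", enzyme="APRT",
            substrates={"adenine": 1, "PRPP": 1}, products={"AMP": 1, "PPi": 1},
            reversible=False, rate_law="irreversible_mm",
            sites=(
                (("adenine", "APRT.Km_adenine"), ("AMP", "APRT.Km_AMP")),
                (("PRPP", "APRT.Km_PRPP"), ("PPi", "APRT.Km_PPi")),
            ),
        ),
        ReactionSpec(
            id="UMPK", enzyme="UMPK",
            substrates={"UMP": 1, "ATP": 1}, products={"UDP": 1, "ADP": 1},
            reversible=True, rate_law="reversible_mm",
            sites=(
                (("UMP", "UMPK.Km_UMP"), ("UDP", "UMPK.Km_UDP")),
                (("ATP", "UMPK.Km_ATP"), ("ADP", "UMPK.Km_ADP")),
            ),
        ),
        ReactionSpec(
            id="GMPK", enzyme="GMPK",
            substrates={"GMP": 1, "ATP": 1}, products={"GDP": 1, "ADP": 1},
            reversible=True, rate_law="reversible_mm",
            sites=(
                (("GMP", "GMPK.Km_GMP"), ("GDP", "GMPK.Km_GDP")),
                (("ATP", "GMPK.Km_ATP"), ("ADP", "GMPK.Km_ADP")),
            ),
        ),
        ReactionSpec(
            id="AK", enzyme="AK",
            substrates={"AMP": 1, "ATP": 1}, products={"ADP": 2},
            reversible=True, rate_law="reversible_mm",
            sites=(
                (("AMP", "AK.Km_AMP"), ("ADP", "AK.Km_ADP")),
                (("ATP", "AK.Km_ATP"), ("ADP", "AK.Km_ADP")),
            ),
        ),
        pk("PK_UDP", "UDP", "UTP"),
        pk("PK_GDP", "GDP", "GTP"),
        pk("PK_ADP", "ADP", "ATP"),
    ]


def assemble_salvage_network(reactor=None) -> NetworkModel:
    """Build the fixed-topology nucleotide salvage network.

    The ``reactor`` argument is accepted for interface symmetry (and so the
    feed species can be validated against the network) but the topology is
    fixed: 15 species, 6 enzymes, 8 reactions, 41 kinetic parameters.
    """
    model = NetworkModel(SPECIES, ENZYMES, _salvage_reactions())
    if reactor is not None:
        for inlet_species in reactor.inlets:
            if inlet_species not in model.species:
                raise NetworkError(
                    f"reactor inlet carries unknown species {inlet_species!r}")
    return model


def reaction_rate(rxn: ReactionSpec, theta, state, loading=None, *,
                  model: NetworkModel | None = None) -> float:
    """Flux (mM/min) of a single reaction at the given state.

    ``theta`` may be a KineticParameters object or a mapping of the
    parameter names this reaction uses; ``state`` a mapping species ->
    concentration (mM, non-negative).
    """
    if isinstance(state, Mapping):
        getc = lambda s: float(state.get(s, 0.0))
    else:
        if model is None:
            raise NetworkError("array state requires the model argument")
        state = np.asarray(state, dtype=float)
        getc = lambda s: float(state[model.species.index(s)])
    involved = set(rxn.substrates) | set(rxn.products)
    for site in rxn.sites:
        involved |= {s for s, _ in site}
    involved |= {s for s, _ in rxn.inhibitors}
    conc = {s: getc(s) for s in involved}
    if any(v < 0 for v in conc.values()):
        raise NetworkError(f"{rxn.id}: negative concentration in state")

    if isinstance(theta, KineticParameters):
        pval = theta.as_dict()
    else:
        pval = {k: float(v) for k, v in dict(theta).items()}
    if loading is None:
        loading = EnzymeLoading()
    factor = loading.factor(rxn.enzyme) if isinstance(loading, EnzymeLoading) \
        else float(loading)

    def occ(species: str) -> float:
        return conc[species] / pval[rxn.km_name(species)]

    forward = pval[f"{rxn.id}.Vf"]
    for s, n in rxn.substrates.items():
        forward *= occ(s) ** n
    numerator = forward
    if rxn.reversible:
        reverse = pval[f"{rxn.id}.Vr"]
        for s, n in rxn.products.items():
            reverse *= occ(s) ** n
        numerator -= reverse
    denom = 1.0
    for site in rxn.sites:
        denom *= 1.0 + sum(occ(s) for s, _ in site)
    for s, ki in rxn.inhibitors:
        denom *= 1.0 + conc[s] / pval[ki]
    return factor * numerator / denom


def make_variant(
    model: NetworkModel,
    *,
    irreversible: Iterable[str] = (),
    reversible: Iterable[str] = (),
    inhibition: Iterable[tuple[str, str, float]] = (),
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> NetworkModel:
    """Derive a mechanistic variant of a network.

    ``irreversible`` / ``reversible`` toggle the named reactions; making a
    reaction irreversible removes its reverse rate and any product Km not
    referenced by another reaction.  ``inhibition`` adds competitive
    allosteric terms ``(species, reaction_id, Ki)``; the Ki value is
    returned through the variant's ``bounds``-respecting nominal vector via
    ``variant_values`` on the result (parameter default = supplied Ki).
    """
    irreversible = set(irreversible)
    reversible = set(reversible)
    known = {r.id for r in model.reactions}
    for rid in irreversible | reversible | {r for _, r, _ in inhibition}:
        if rid not in known:
            raise NetworkError(f"unknown reaction {rid!r}")
    if irreversible & reversible:
        raise NetworkError("reaction toggled both ways")

    new_reactions: list[ReactionSpec] = []
    ki_defaults: dict[str, float] = {}
    for rxn in model.reactions:
        rev = rxn.reversible
        sites = rxn.sites
        if rxn.id in irreversible and rxn.reversible:
            rev = False
            # Drop product Kms private to this reaction from its sites.
            shared = {
                km for other in model.reactions if other.id != rxn.id
                for site in other.sites for _, km in site
            }
            keep_species = set(rxn.substrates)
            sites = tuple(
                tuple((s, km) for s, km in site
                      if s in keep_species or km in shared)
                for site in rxn.sites
            )
            sites = tuple(site for site in sites if site)
        elif rxn.id in reversible and not rxn.reversible:
            rev = True
        inhibitors = list(rxn.inhibitors)
        for species, rid, ki in inhibition:
            if rid == rxn.id:
                if species not in model.species:
                    raise NetworkError(f"unknown species {species!r}")
                ki_name = f"{rxn.id}.Ki_{species}"
                inhibitors.append((species, ki_name))
                ki_defaults[ki_name] = float(ki)
        new_reactions.append(replace(
            rxn, reversible=rev, sites=sites, inhibitors=tuple(inhibitors)))

    merged_bounds = dict(model.bounds)
    if bounds:
        merged_bounds.update(bounds)
    for ki_name, ki in ki_defaults.items():
        lo, hi = _K_BOUNDS
        merged_bounds[ki_name] = (min(lo, ki), max(hi, ki))
    variant = NetworkModel(model.species, model.enzymes, new_reactions,
                           bounds=merged_bounds)
    variant.ki_defaults = ki_defaults  # type: ignore[attr-defined]
    return variant


def carry_parameters(
    source: KineticParameters, target_model: NetworkModel,
    extra: Mapping[str, float] | None = None,
) -> KineticParameters:
    """Map a parameter vector onto a model variant by name.

    Parameters absent from the source (e.g. freshly added Ki values) must be
    supplied through ``extra`` or have defaults recorded by ``make_variant``.
    """
    defaults = dict(getattr(target_model, "ki_defaults", {}))
    if extra:
        defaults.update(extra)
    src = source.as_dict()
    values = []
    for name in target_model.parameter_names:
        if name in src:
            values.append(src[name])
        elif name in defaults:
            values.append(defaults[name])
        else:
            raise NetworkError(f"no value for parameter {name!r}")
    nominal = target_model.nominal_parameters()
    return KineticParameters(target_model.parameter_names,
                             np.asarray(values), nominal.lower, nominal.upper)
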
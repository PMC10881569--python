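"""Plain-text file formats: model definitions, flow profiles, time courses.

Model grammar (one directive per line, ``#`` comments allowed)::

    species uracil adenine ... pyruvate
    enzymes UPRT APRT UMPK GMPK AK PK
    reaction UPRT: UPRT | uracil + PRPP -> UMP + PPi | irreversible_mm
    reaction UMPK: UMPK | UMP + ATP <=> UDP + ADP | reversible_mm
    inhibit PK_UDP: UTP
    param UPRT.Vf = 0.316227766017 [0.01, 10]

``->`` marks irreversible, ``<=>`` reversible reactions; binding-site
layouts are reconstructed deterministically from the rate-law kind and the
stoichiometry by the same builder the salvage constructor uses, so a
write/read round-trip is lossless on the canonical form.

Flow profiles and time courses are CSV: profiles with columns
``t_start_min,duration_min,q_<inlet>...`` (ul/min) and observations in
long format ``time_min,species,concentration_mM,sigma_mM`` (one record per
row); numbers are serialised with 12+ significant digits.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import ExperimentRound, ParameterEnsemble, TimeCourseDataset
from .network import (EnzymeLoading, KineticParameters, NetworkModel,
                      ReactionSpec)
from .reactor import FlowProfile, ReactorConfig

__all__ = [
    "ParseError",
    "read_model", "write_model",
    "read_profile", "write_profile",
    "read_timecourse", "write_timecourse",
    "read_ensemble", "write_ensemble",
]

_FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    def __init__(self, message: str, line: int | None = None) -> None:
        where = f" (line {line})" if line is not None else ""
        super().__init__(message + where)
        self.line = line


def _parse_side(text: str, line_no: int) -> dict[str, int]:
    out: dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ParseError("empty stoichiometric term", line_no)
        m = re.fullmatch(r"(?:(\d+)\s+)?(\S+)", term)
        if not m:
            raise ParseError(f"cannot parse term {term!r}", line_no)
        n = int(m.group(1) or 1)
        out[m.group(2)] = out.get(m.group(2), 0) + n
    return out


def _build_sites(rxn_id: str, enzyme: str, rate_law: str,
                 substrates: dict, products: dict, reversible: bool):
    """Deterministic binding-site reconstruction.

    Two sites, one per substrate (substrate order); each substrate's site
    also binds a product: substrates and products are paired in
    declaration order (the second product pairs with the first substrate
    pair, etc.).  ``shared_site_mm`` reactions instead share an
    enzyme-scoped nucleotide site over all NDP/NTP partners plus a shared
    donor site, matching the pyruvate-kinase layout.
    """
    if rate_law == "shared_site_mm":
        nuc_site = tuple((s, f"{enzyme}.Km_{s}")
                         for s in ("UDP", "GDP", "ADP", "UTP", "GTP", "ATP"))
        donor_site = (("PEP", f"{enzyme}.Km_PEP"),
                      ("pyruvate", f"{enzyme}.Km_pyruvate"))
        return (nuc_site, donor_site)
    subs = list(substrates)
    # Products bind competitively when the reaction is reversible or uses
    # irreversible_mm (competitive product binding); a stoich-n product
    # occupies n site positions (e.g. 2 ADP spanning both kinase sites).
    prods: list[str] = []
    if reversible or rate_law == "irreversible_mm":
        for p, n in products.items():
            prods.extend([p] * n)
    sites = []
    for i, s in enumerate(subs):
        site = [(s, f"{rxn_id}.Km_{s}")]
        if i < len(prods):
            p = prods[i]
            site.append((p, f"{rxn_id}.Km_{p}"))
        sites.append(tuple(site))
    for p in prods[len(subs):]:
        sites[-1] = sites[-1] + ((p, f"{rxn_id}.Km_{p}"),)
    return tuple(sites)


def read_model(path) -> tuple[NetworkModel, KineticParameters]:
    """Parse a model file; returns the network and its parameter vector."""
    path = Path(path)
    species: list[str] = []
    enzymes: list[str] = []
    reactions: list[ReactionSpec] = []
    inhibitors: dict[str, list[tuple[str, str]]] = {}
    params: dict[str, float] = {}
    bounds: dict[str, tuple[float, float]] = {}

    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        head, _, rest = line.partition(" ")
        rest = rest.strip()
        if head == "species":
            species = rest.split()
        elif head == "enzymes":
            enzymes = rest.split()
        elif head == "reaction":
            m = re.fullmatch(
                r"(\S+)\s*:\s*(\S+)\s*\|(.+?)(->|<=>)(.+?)\|\s*(\S+)", rest)
            if not m:
                raise ParseError(f"malformed reaction line: {raw!r}", line_no)
            rid, enzyme, lhs, arrow, rhs, rate_law = m.groups()
            substrates = _parse_side(lhs, line_no)
            products = _parse_side(rhs, line_no)
            for s in list(substrates) + list(products):
                if s not in species:
                    raise ParseError(f"undeclared species {s!r}", line_no)
            if enzyme not in enzymes:
                raise ParseError(f"undeclared enzyme {enzyme!r}", line_no)
            reversible = arrow == "<=>"
            sites = _build_sites(rid, enzyme, rate_law, substrates,
                                 products, reversible)
            reactions.append(ReactionSpec(
                id=rid, enzyme=enzyme, substrates=substrates,
                products=products, reversible=reversible,
                rate_law=rate_law, sites=sites))
        elif head == "inhibit":
            m = re.fullmatch(r"(\S+)\s*:\s*(\S+)", rest)
            if not m:
                raise ParseError(f"malformed inhibit line: {raw!r}", line_no)
            rid, sp_name = m.groups()
            if sp_name not in species:
                raise ParseError(f"undeclared species {sp_name!r}", line_no)
            inhibitors.setdefault(rid, []).append(
                (sp_name, f"{rid}.Ki_{sp_name}"))
        elif head == "param":
            m = re.fullmatch(
                r"(\S+)\s*=\s*(\S+)\s*\[\s*(\S+)\s*,\s*(\S+)\s*\]", rest)
            if not m:
                raise ParseError(f"malformed param line: {raw!r}", line_no)
            name, value, lo, hi = m.groups()
            params[name] = float(value)
            bounds[name] = (float(lo), float(hi))
        else:
            raise ParseError(f"unknown directive {head!r}", line_no)

    if not species or not reactions:
        raise ParseError("model file must declare species and reactions")
    reactions = [
        ReactionSpec(id=r.id, enzyme=r.enzyme, substrates=r.substrates,
                     products=r.products, reversible=r.reversible,
                     rate_law=r.rate_law, sites=r.sites,
                     inhibitors=tuple(inhibitors.get(r.id, ())))
        for r in reactions
    ]
    model = NetworkModel(species, enzymes, reactions, bounds=bounds)
    nominal = model.nominal_parameters()
    missing = [n for n in model.parameter_names if n not in params]
    values = np.array([params.get(n, nominal[n])
                       for n in model.parameter_names])
    theta = nominal.replace_values(values)
    if missing:
        import warnings
        warnings.warn(f"{len(missing)} parameters missing from file; "
                      "nominal defaults used")
    return model, theta


def write_model(path, model: NetworkModel,
                theta: KineticParameters | None = None) -> None:
    theta = theta if theta is not None else model.nominal_parameters()
    lines = ["# ernoed network model v1"]
    lines.append("species " + " ".join(model.species))
    lines.append("enzymes " + " ".join(model.enzymes))
    for rxn in model.reactions:
        arrow = "<=>" if rxn.reversible else "->"
        lhs = " + ".join(f"{n} {s}" if n > 1 else s
                         for s, n in rxn.substrates.items())
        rhs = " + ".join(f"{n} {s}" if n > 1 else s
                         for s, n in rxn.products.items())
        lines.append(f"reaction {rxn.id}: {rxn.enzyme} | {lhs} {arrow} {rhs} "
                     f"| {rxn.rate_law}")
    for rxn in model.reactions:
        for sp_name, _ in rxn.inhibitors:
            lines.append(f"inhibit {rxn.id}: {sp_name}")
    for name in model.parameter_names:
        lo, hi = model.bounds[name]
        lines.append(
            f"param {name} = {_FLOAT_FMT % theta[name]} "
            f"[{_FLOAT_FMT % lo}, {_FLOAT_FMT % hi}]")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CSV formats


def profile_columns(reactor: ReactorConfig) -> list[str]:
    return ["t_start_min", "duration_min"] + [f"q_{s}" for s in reactor.inlets]


def write_profile(path, profile: FlowProfile, reactor: ReactorConfig) -> None:
    cols = profile_columns(reactor)
    df = pd.DataFrame(
        np.column_stack([profile.t_start, profile.duration, profile.rates]),
        columns=cols)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_profile(path, reactor: ReactorConfig | None = None) -> FlowProfile:
    df = pd.read_csv(path)
    required = {"t_start_min", "duration_min"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"profile CSV missing columns {sorted(missing)}")
    qcols = [c for c in df.columns if c.startswith("q_")]
    if reactor is not None:
        expected = [f"q_{s}" for s in reactor.inlets]
        missing = set(expected) - set(qcols)
        if missing:
            raise ParseError(f"profile CSV missing columns {sorted(missing)}")
        qcols = expected
    profile = FlowProfile(df["t_start_min"].to_numpy(),
                          df["duration_min"].to_numpy(),
                          df[qcols].to_numpy())
    return profile


def write_timecourse(path, data) -> None:
    """Write a long-format observation table (round or dataset)."""
    if isinstance(data, TimeCourseDataset):
        df = data.to_frame()
    elif isinstance(data, ExperimentRound):
        df = data.table.assign(round_id=data.round_id)[
            ["round_id", "time_min", "species", "concentration_mM", "sigma_mM"]]
    else:
        df = pd.DataFrame(data)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_timecourse(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("time_min", "species", "concentration_mM", "sigma_mM"):
        if col not in df.columns:
            raise ParseError(f"time-course CSV missing column {col!r}")
    return df


def write_ensemble(path, ensemble: ParameterEnsemble) -> None:
    ensemble.to_frame().to_csv(path, index=False, float_format="%.15g")


def read_ensemble(path, model: NetworkModel) -> ParameterEnsemble:
    df = pd.read_csv(path)
    if "score" not in df.columns:
        raise ParseError("ensemble CSV missing column 'score'")
    missing = set(model.parameter_names) - set(df.columns)
    if missing:
        raise ParseError(f"ensemble CSV missing parameters {sorted(missing)}")
    nominal = model.nominal_parameters()
    members = [nominal.replace_values(row[list(model.parameter_names)
                                          ].to_numpy(dtype=float))
               for _, row in df.iterrows()]
    scores = df["score"].astype(float).tolist()
    best = min(scores)
    tol = max(0.15, (max(scores) - best) / best if best > 0 else 0.15)
    return ParameterEnsemble(members=members, scores=scores,
                             best_score=best, tolerance=tol)
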
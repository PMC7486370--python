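"""Constraint-based community metabolic modelling of gut species.

Draft genome-scale models are assembled from each species' KEGG-ortholog
(KO) set against a universal reaction database, gap-filled to a minimal
functional model, and simulated anaerobically under a diet constraint with
flux balance analysis (FBA): maximise the biomass reaction subject to
steady state S·v = 0 and flux bounds. A two-phase community simulation
weights species fluxes by their relative abundance at each gut location and
summarises metabolite uptake/secretion per location; oxygen sweeps probe
each species' aerotolerance.

Sign conventions: an exchange reaction ``EX_m`` has stoichiometry
{m_e: -1}; positive flux secretes the metabolite, negative flux takes it up.
Diet uptake limits set the exchange lower bound to -rate.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linprog

log = logging.getLogger(__name__)

__all__ = [
    "Metabolite", "Reaction", "UniversalReactionDB", "DietConstraint",
    "MetabolicModel", "FluxResult", "CommunityResult", "OxygenSweepConfig",
    "build_draft", "gap_fill", "fba", "community_simulate",
    "exchange_jaccard", "jaccard_matrix", "oxygen_sweep",
    "oxygen_sensitivity", "trp_indole_report",
    "fermentation_universe", "default_diet", "community_fixture",
    "O2_REFERENCE_UPTAKE",
]

#: default flux capacity for an unconstrained direction (mmol/gDW/h)
BIG = 1000.0

#: Intestinal O2 reference uptake, 2 mL O2/min per 100 g tissue, converted
#: with ideal-gas molar volume 22.4 mL/mmol, 60 min/h, and an assumed
#: 1 gDW microbial biomass per 100 g tissue: 2/22.4*60 = 5.36 mmol/gDW/h.
O2_REFERENCE_UPTAKE = 2.0 / 22.4 * 60.0


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    compartment: str  # "cytosol" | "extracellular"

    def __post_init__(self) -> None:
        if self.compartment not in ("cytosol", "extracellular"):
            raise ValueError(f"{self.id}: bad compartment {self.compartment!r}")


@dataclass(frozen=True)
class Reaction:
    id: str
    stoich: dict[str, float]           # metabolite id -> coefficient
    reversible: bool = False
    lb: float = 0.0
    ub: float = BIG
    kos: frozenset[str] = frozenset()  # KOs licensing this reaction
    exchange: bool = False

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ValueError(f"{self.id}: lb > ub")
        if not self.reversible and self.lb < 0 and not self.exchange:
            raise ValueError(f"{self.id}: irreversible reaction with lb < 0")


class UniversalReactionDB:
    """Universal reaction database: metabolites, reactions, biomass."""

    def __init__(self, metabolites: list[Metabolite], reactions: list[Reaction],
                 biomass_id: str):
        self.metabolites = {m.id: m for m in metabolites}
        self.reactions = {r.id: r for r in reactions}
        if biomass_id not in self.reactions:
            raise ValueError(f"biomass reaction {biomass_id!r} not in database")
        self.biomass_id = biomass_id
        for r in reactions:
            unknown = set(r.stoich) - set(self.metabolites)
            if unknown:
                raise ValueError(f"{r.id}: unknown metabolite(s) {sorted(unknown)}")
            if r.exchange:
                ext = [m for m in r.stoich
                       if self.metabolites[m].compartment == "extracellular"]
                if len(r.stoich) != 1 or len(ext) != 1:
                    raise ValueError(
                        f"{r.id}: exchange must touch exactly one "
                        "extracellular metabolite")
        bm = self.reactions[biomass_id]
        if bm.reversible or bm.lb < 0:
            raise ValueError("biomass reaction must be irreversible forward")

    @property
    def exchange_ids(self) -> list[str]:
        return sorted(r.id for r in self.reactions.values() if r.exchange)

    def exchange_metabolite(self, rxn_id: str) -> str:
        return next(iter(self.reactions[rxn_id].stoich))

    def reactions_for_kos(self, ko_set: frozenset[str] | set[str]) -> list[str]:
        return sorted(r.id for r in self.reactions.values()
                      if r.kos & set(ko_set))

    def ko_reaction_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for r in self.reactions.values():
            for k in r.kos:
                out.setdefault(k, []).append(r.id)
        return {k: sorted(v) for k, v in out.items()}

    def to_json(self) -> str:
        return json.dumps({
            "metabolites": [vars(m) for m in self.metabolites.values()],
            "reactions": [
                {"id": r.id, "stoich": r.stoich, "reversible": r.reversible,
                 "lb": r.lb, "ub": r.ub, "kos": sorted(r.kos),
                 "exchange": r.exchange}
                for r in self.reactions.values()],
            "biomass_id": self.biomass_id,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "UniversalReactionDB":
        d = json.loads(text)
        mets = [Metabolite(**m) for m in d["metabolites"]]
        rxns = [Reaction(id=r["id"], stoich=r["stoich"],
                         reversible=r["reversible"], lb=r["lb"], ub=r["ub"],
                         kos=frozenset(r["kos"]), exchange=r["exchange"])
                for r in d["reactions"]]
        return cls(mets, rxns, d["biomass_id"])


@dataclass
class DietConstraint:
    """Maximum uptake rate (mmol/gDW/h) per extracellular metabolite.

    Unlisted metabolites cannot be taken up; secretion stays open.
    """

    uptake: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {m: r for m, r in self.uptake.items() if r < 0}
        if bad:
            raise ValueError(f"negative uptake rate(s): {bad}")

    def to_json(self) -> str:
        return json.dumps({"uptake": self.uptake}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DietConstraint":
        return cls(uptake=json.loads(text)["uptake"])

    def augmented(self, extra: dict[str, float]) -> "DietConstraint":
        up = dict(self.uptake)
        for m, r in extra.items():
            up[m] = up.get(m, 0.0) + r
        return DietConstraint(uptake=up)


class MetabolicModel:
    """A species model: a reaction subset of the universal database."""

    def __init__(self, db: UniversalReactionDB, reaction_ids: list[str],
                 species: str = "", provenance: dict[str, str] | None = None):
        unknown = set(reaction_ids) - set(db.reactions)
        if unknown:
            raise ValueError(f"reaction(s) not in database: {sorted(unknown)}")
        self.db = db
        self.reaction_ids = sorted(set(reaction_ids))
        self.species = species
        self.objective_id = db.biomass_id
        self.provenance = dict(provenance or {r: "draft" for r in self.reaction_ids})
        if self.objective_id not in self.reaction_ids:
            raise ValueError("model must contain the biomass reaction")

    def with_reactions(self, extra: list[str], tag: str = "gapfill"
                       ) -> "MetabolicModel":
        prov = dict(self.provenance)
        for r in extra:
            prov.setdefault(r, tag)
        return MetabolicModel(self.db, self.reaction_ids + list(extra),
                              self.species, prov)

    @property
    def metabolite_ids(self) -> list[str]:
        mets: set[str] = set()
        for r in self.reaction_ids:
            mets |= set(self.db.reactions[r].stoich)
        return sorted(mets)

    def stoichiometric_matrix(self) -> pd.DataFrame:
        mets = self.metabolite_ids
        S = pd.DataFrame(0.0, index=mets, columns=self.reaction_ids)
        for rid in self.reaction_ids:
            for m, c in self.db.reactions[rid].stoich.items():
                S.loc[m, rid] = c
        return S

    def bounds(self, diet: DietConstraint | None = None, *,
               anaerobic: bool = True,
               extra_bounds: dict[str, tuple[float, float]] | None = None
               ) -> dict[str, tuple[float, float]]:
        """Effective (lb, ub) per reaction under a diet.

        Exchange uptake (negative direction) is closed unless the diet lists
        the metabolite; ``anaerobic`` closes O2 uptake regardless of diet;
        ``extra_bounds`` overrides last.
        """
        out: dict[str, tuple[float, float]] = {}
        for rid in self.reaction_ids:
            r = self.db.reactions[rid]
            lb, ub = r.lb, r.ub
            if r.exchange:
                met = self.db.exchange_metabolite(rid)
                rate = diet.uptake.get(met, 0.0) if diet else 0.0
                lb = -rate
                if anaerobic and met.startswith("o2"):
                    lb = 0.0
            out[rid] = (lb, ub)
        if extra_bounds:
            for rid, b in extra_bounds.items():
                if rid in out:
                    out[rid] = b
        return out


@dataclass
class FluxResult:
    fluxes: pd.Series               # reaction id -> flux
    objective_value: float          # growth rate (1/h)
    status: str                     # optimal | infeasible | unbounded
    exchanges: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    # extracellular metabolite -> exchange flux (+ secretion, - uptake)


@dataclass
class CommunityResult:
    location: str
    growth_rates: dict[str, float]
    species_exchanges: pd.DataFrame       # species x metabolite fluxes
    weighted_exchange: pd.Series          # abundance-weighted net per met
    species_fluxes: dict[str, pd.Series]  # full phase-2 flux vectors
    abundances: dict[str, float]


@dataclass
class OxygenSweepConfig:
    reference_uptake: float = O2_REFERENCE_UPTAKE
    fractions: tuple[float, ...] = (0.0, 0.05, 0.1, 0.25, 0.5, 1.0)

    def __post_init__(self) -> None:
        fr = self.fractions
        if any(not 0.0 <= f <= 1.0 for f in fr):
            raise ValueError("fractions must lie in [0, 1]")
        if list(fr) != sorted(fr):
            raise ValueError("fractions must be sorted ascending")
        if 0.0 not in fr:
            raise ValueError("fractions must include 0 (anaerobic)")


# ---------------------------------------------------------------------------
# solving

_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded",
           4: "numerical trouble"}


def _solve_lp(S: pd.DataFrame, bounds: list[tuple[float, float]],
              c: np.ndarray) -> tuple[str, float | None, np.ndarray | None]:
    """max c.v s.t. S v = 0, bounds; returns (status, optimum, v)."""
    res = linprog(-c, A_eq=S.to_numpy(), b_eq=np.zeros(S.shape[0]),
                  bounds=bounds, method="highs")
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return status, None, None
    return status, float(-res.fun), res.x


def _min_total_flux(S: pd.DataFrame, bounds: list[tuple[float, float]]
                    ) -> np.ndarray | None:
    """min sum |v| s.t. S v = 0 within bounds (variables split v, t>=|v|)."""
    n = S.shape[1]
    A_eq = np.hstack([S.to_numpy(), np.zeros((S.shape[0], n))])
    # v - t <= 0 and -v - t <= 0
    A_ub = np.block([[np.eye(n), -np.eye(n)], [-np.eye(n), -np.eye(n)]])
    b_ub = np.zeros(2 * n)
    c = np.concatenate([np.zeros(n), np.ones(n)])
    full_bounds = list(bounds) + [(0.0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq,
                  b_eq=np.zeros(S.shape[0]), bounds=full_bounds,
                  method="highs")
    if res.status != 0:
        return None
    return res.x[:n]


def fba(model: MetabolicModel, diet: DietConstraint, *,
        objective: str | None = None, anaerobic: bool = True,
        extra_bounds: dict[str, tuple[float, float]] | None = None,
        parsimonious: bool = True) -> FluxResult:
    """Flux balance analysis: maximise the objective under diet and bounds.

    ``parsimonious`` re-solves with the optimum fixed while minimising total
    absolute flux, which makes the reported secretion profile a deterministic
    representative of the optimal face (plain FBA optima are degenerate).
    """
    objective = objective or model.objective_id
    S = model.stoichiometric_matrix()
    bdict = model.bounds(diet, anaerobic=anaerobic, extra_bounds=extra_bounds)
    blist = [bdict[r] for r in model.reaction_ids]
    c = np.array([1.0 if r == objective else 0.0 for r in model.reaction_ids])
    status, opt, v = _solve_lp(S, blist, c)
    if status != "optimal":
        if status == "unbounded":
            open_ex = [r for r in model.reaction_ids
                       if model.db.reactions[r].exchange and bdict[r][0] < 0]
            log.warning("unbounded objective; open exchanges: %s", open_ex)
        return FluxResult(pd.Series(dtype=float), float("nan"), status)
    if parsimonious:
        j = model.reaction_ids.index(objective)
        fixed = list(blist)
        fixed[j] = (opt - 1e-9, opt + 1e-9)
        v2 = _min_total_flux(S, fixed)
        if v2 is not None:
            v = v2
    fluxes = pd.Series(v, index=model.reaction_ids)
    _check_solution(S, fluxes, bdict)
    ex = pd.Series({model.db.exchange_metabolite(r): fluxes[r]
                    for r in model.reaction_ids
                    if model.db.reactions[r].exchange})
    return FluxResult(fluxes, opt, "optimal", exchanges=ex)


def _check_solution(S: pd.DataFrame, v: pd.Series,
                    bounds: dict[str, tuple[float, float]]) -> None:
    resid = np.abs(S.to_numpy() @ v.to_numpy())
    if resid.max() > 1e-6:
        raise RuntimeError(f"steady-state violation {resid.max():.2e} > 1e-6")
    for rid, (lb, ub) in bounds.items():
        x = v[rid]
        if x < lb - 1e-6 or x > ub + 1e-6:
            raise RuntimeError(f"{rid}: flux {x} outside [{lb}, {ub}]")


# ---------------------------------------------------------------------------
# reconstruction

def build_draft(ko_set: set[str] | frozenset[str], db: UniversalReactionDB,
                species: str = "") -> MetabolicModel:
    """Draft model: DB reactions licensed by the KO set, plus all exchange
    reactions (uptake closed until a diet opens them) and biomass."""
    licensed = db.reactions_for_kos(ko_set)
    rxns = sorted(set(licensed) | set(db.exchange_ids) | {db.biomass_id})
    prov = {r: "draft" for r in rxns}
    return MetabolicModel(db, rxns, species=species, provenance=prov)


def _growth(model: MetabolicModel, diet: DietConstraint) -> float:
    res = fba(model, diet, parsimonious=False)
    return res.objective_value if res.status == "optimal" else 0.0


def gap_fill(draft: MetabolicModel, db: UniversalReactionDB,
             diet: DietConstraint, min_growth: float = 0.01, *,
             exhaustive_limit: int = 12, max_additions: int = 6
             ) -> MetabolicModel:
    """Add a minimum-cardinality reaction set so biomass reaches min_growth.

    Candidate sets of up to ``exhaustive_limit`` reactions are searched
    exhaustively by ascending cardinality (ties resolved lexicographically
    by reaction id, so the result is deterministic and certified minimal).
    Larger universes fall back to an add-all-then-prune greedy pass.
    """
    if min_growth <= 0:
        raise ValueError("min_growth must be positive")
    if _growth(draft, diet) >= min_growth:
        return draft
    candidates = sorted(set(db.reactions) - set(draft.reaction_ids))
    full = draft.with_reactions(candidates)
    if _growth(full, diet) < min_growth:
        raise RuntimeError("infeasible biomass under diet even with the full "
                           "universal database")
    if len(candidates) <= exhaustive_limit:
        for k in range(1, min(max_additions, len(candidates)) + 1):
            for combo in itertools.combinations(candidates, k):
                trial = draft.with_reactions(list(combo))
                if _growth(trial, diet) >= min_growth:
                    return trial
        # fall through: minimal repair needs more than max_additions
        return full
    # greedy: start from everything, prune reactions (highest id first) whose
    # removal keeps the model functional; lowest ids are thereby kept first
    keep = list(candidates)
    for rid in sorted(candidates, reverse=True):
        trial = draft.with_reactions([r for r in keep if r != rid])
        if _growth(trial, diet) >= min_growth:
            keep.remove(rid)
    return draft.with_reactions(keep)


# ---------------------------------------------------------------------------
# community simulation

def community_simulate(models: dict[str, MetabolicModel],
                       abundances: dict[str, dict[str, float]],
                       diet: DietConstraint, *,
                       seed_metabolites: tuple[str, str] = ("ac_e", "lac_e"),
                       biomass_tolerance: float = 0.95
                       ) -> dict[str, CommunityResult]:
    """Two-phase, abundance-weighted community simulation per location.

    Phase 1 solves each species anaerobically under the diet; the mean
    acetate and lactate secretion across species is then added to the shared
    medium as extra uptake allowance (cross-feeding seed). Phase 2 re-solves
    each species with biomass fixed to its phase-1 growth scaled by its
    relative abundance at the location, under the augmented diet, minimising
    total flux. Location summaries weight each species' exchange fluxes by
    its abundance.
    """
    for loc, ab in abundances.items():
        tot = sum(ab.values())
        if abs(tot - 1.0) > 1e-6:
            raise ValueError(f"{loc}: abundances sum to {tot}, expected 1")
        unknown = set(ab) - set(models)
        if unknown:
            raise ValueError(f"{loc}: unmodelled species {sorted(unknown)}")

    phase1 = {s: fba(m, diet, anaerobic=True) for s, m in models.items()}
    for s, r in phase1.items():
        if r.status != "optimal":
            raise RuntimeError(f"phase-1 FBA failed for {s}: {r.status}")
    seed = {
        met: float(np.mean([max(phase1[s].exchanges.get(met, 0.0), 0.0)
                            for s in models]))
        for met in seed_metabolites
    }
    diet2 = diet.augmented(seed)

    results: dict[str, CommunityResult] = {}
    for loc, ab in sorted(abundances.items()):
        fluxes: dict[str, pd.Series] = {}
        exchanges: dict[str, pd.Series] = {}
        growth: dict[str, float] = {}
        for s in sorted(ab):
            model = models[s]
            target = phase1[s].objective_value * ab[s]
            res = fba(model, diet2, anaerobic=True,
                      extra_bounds={model.objective_id: (target, target)},
                      parsimonious=True)
            if res.status != "optimal":
                log.warning("%s/%s: phase-2 infeasible at fixed biomass %.4g; "
                            "relaxing to >= %.0f%% of target", loc, s, target,
                            100 * biomass_tolerance)
                res = fba(model, diet2, anaerobic=True,
                          extra_bounds={model.objective_id:
                                        (biomass_tolerance * target, BIG)})
                if res.status != "optimal":
                    raise RuntimeError(f"{loc}/{s}: phase-2 infeasible even "
                                       "with relaxed biomass")
            fluxes[s] = res.fluxes
            exchanges[s] = res.exchanges
            growth[s] = res.fluxes[model.objective_id]
        ex_df = pd.DataFrame(exchanges).T.fillna(0.0)
        weights = pd.Series({s: ab[s] for s in ex_df.index})
        weighted = ex_df.mul(weights, axis=0).sum(axis=0)
        results[loc] = CommunityResult(
            location=loc, growth_rates=growth, species_exchanges=ex_df,
            weighted_exchange=weighted, species_fluxes=fluxes,
            abundances=dict(ab))
    return results


def exchange_jaccard(result_a: FluxResult, result_b: FluxResult,
                     eps: float = 1e-6) -> float:
    """Jaccard similarity of signed active exchange sets of two solutions.

    A metabolite with |flux| > eps counts as (metabolite, secreted) or
    (metabolite, consumed) by flux sign. Two fully inactive profiles are
    defined as similarity 1 (identical inactivity).
    """
    def active(res: FluxResult) -> set[tuple[str, str]]:
        out = set()
        for met, f in res.exchanges.items():
            if f > eps:
                out.add((met, "secreted"))
            elif f < -eps:
                out.add((met, "consumed"))
        return out

    a, b = active(result_a), active(result_b)
    if not a and not b:
        log.info("both exchange sets inactive; Jaccard defined as 1")
        return 1.0
    return len(a & b) / len(a | b)


def jaccard_matrix(results: dict[str, FluxResult], eps: float = 1e-6
                   ) -> pd.DataFrame:
    species = sorted(results)
    out = pd.DataFrame(1.0, index=species, columns=species)
    for sa, sb in itertools.combinations(species, 2):
        j = exchange_jaccard(results[sa], results[sb], eps)
        out.loc[sa, sb] = out.loc[sb, sa] = j
    return out


def oxygen_sweep(model: MetabolicModel, diet: DietConstraint,
                 sweep: OxygenSweepConfig | None = None
                 ) -> dict[float, float]:
    """Growth rate as a function of the allowed O2 uptake fraction.

    Fraction f allows O2 uptake up to f x the intestinal reference; f = 0
    is exactly the anaerobic solve. Aerotolerant models (with respiration)
    grow faster as f rises; strict anaerobes stay flat.
    """
    sweep = sweep or OxygenSweepConfig()
    o2_ex = [r for r in model.reaction_ids
             if model.db.reactions[r].exchange
             and model.db.exchange_metabolite(r).startswith("o2")]
    if not o2_ex:
        raise ValueError("model has no O2 exchange reaction")
    curve: dict[float, float] = {}
    for f in sweep.fractions:
        res = fba(model, diet, anaerobic=False,
                  extra_bounds={o2_ex[0]: (-f * sweep.reference_uptake, BIG)},
                  parsimonious=False)
        curve[f] = res.objective_value if res.status == "optimal" else 0.0
    return curve


def oxygen_sensitivity(curve: dict[float, float]) -> float:
    """growth(0) / growth(0.05): 1 for aerotolerant-indifferent models,
    < 1 when micro-aerobic conditions boost growth."""
    if 0.05 not in curve or curve[0.05] == 0:
        return float("nan")
    return curve[0.0] / curve[0.05]


def trp_indole_report(community: dict[str, CommunityResult],
                      trp_met: str = "trp_e", indole_met: str = "ind_e",
                      tna_rxn: str = "TNA") -> pd.DataFrame:
    """Per-location tryptophan uptake and indole secretion summary.

    Indole comes 1:1 from tryptophanase (Trp -> indole + pyruvate + NH3), so
    the abundance-weighted tryptophanase flux is reported alongside for the
    stoichiometric cross-check.
    """
    rows = []
    for loc, res in sorted(community.items()):
        missing = [m for m in (trp_met, indole_met)
                   if m not in res.species_exchanges.columns]
        if missing:
            raise KeyError(f"metabolite(s) absent from exchanges: {missing}")
        tna_flux = 0.0
        for s, fl in res.species_fluxes.items():
            if tna_rxn in fl.index:
                tna_flux += res.abundances[s] * fl[tna_rxn]
        rows.append({
            "location": loc,
            "trp_uptake": -min(res.weighted_exchange.get(trp_met, 0.0), 0.0) + 0.0,
            "indole_secretion": max(res.weighted_exchange.get(indole_met, 0.0), 0.0),
            "tryptophanase_flux": tna_flux,
        })
    return pd.DataFrame(rows).set_index("location")


# ---------------------------------------------------------------------------
# fixture reaction universe

def fermentation_universe() -> UniversalReactionDB:
    """Small gut-fermentation reaction universe (v1).

    Glycolysis-like backbone, fermentation branches to acetate / propionate /
    butyrate / formate / lactate / ethanol / succinate, tryptophanase
    (Trp -> indole), amino-acid uptake routes, and optional O2 respiration.
    Stands in for a genome-scale reference database; the JSON schema accepts
    real ones.
    """
    ext = ["glc", "gal", "trp", "glu_L", "asp", "ac", "ppa", "but", "for",
           "lac", "ind", "nh3", "co2", "o2", "h2o", "etoh", "succ"]
    names = {"glc": "D-glucose", "gal": "D-galactose", "trp": "L-tryptophan",
             "glu_L": "L-glutamate", "asp": "L-aspartate", "ac": "acetate",
             "ppa": "propionate", "but": "butyrate", "for": "formate",
             "lac": "lactate", "ind": "indole", "nh3": "ammonia",
             "co2": "carbon dioxide", "o2": "oxygen", "h2o": "water",
             "etoh": "ethanol", "succ": "succinate"}
    mets = [Metabolite(f"{m}_e", names[m], "extracellular") for m in ext]
    cyt = ext + ["g6p", "pyr", "accoa", "atp", "adp"]
    names.update({"g6p": "glucose 6-phosphate", "pyr": "pyruvate",
                  "accoa": "acetyl-CoA", "atp": "ATP", "adp": "ADP"})
    mets += [Metabolite(f"{m}_c", names[m], "cytosol") for m in cyt]

    rxns: list[Reaction] = []
    for m in ext:
        rxns.append(Reaction(f"EX_{m}", {f"{m}_e": -1.0}, lb=0.0, ub=BIG,
                             exchange=True))

    def t(rid, met, rev=False, ko=None):
        # transporter ext <-> cyt; forward = import for substrates,
        # export for products (stoich written per direction below)
        return Reaction(rid, met, reversible=rev, lb=-BIG if rev else 0.0,
                        kos=frozenset([ko] if ko else []))

    rxns += [
        t("GLCt", {"glc_e": -1, "glc_c": 1}, ko="K02777"),
        t("GALt", {"gal_e": -1, "gal_c": 1}, ko="K02773"),
        t("TRPt", {"trp_e": -1, "trp_c": 1}, ko="K03835"),
        t("GLUt", {"glu_L_e": -1, "glu_L_c": 1}, ko="K10005"),
        t("ASPt", {"asp_e": -1, "asp_c": 1}, ko="K10010"),
        t("ACt", {"ac_c": -1, "ac_e": 1}, rev=True, ko="K03290"),
        t("PPAt", {"ppa_c": -1, "ppa_e": 1}, ko="K03291"),
        t("BUTt", {"but_c": -1, "but_e": 1}, ko="K03292"),
        t("FORt", {"for_c": -1, "for_e": 1}, ko="K21990"),
        t("LACt", {"lac_c": -1, "lac_e": 1}, rev=True, ko="K03303"),
        t("INDt", {"ind_c": -1, "ind_e": 1}, ko="K05802"),
        t("NH3t", {"nh3_c": -1, "nh3_e": 1}, rev=True, ko="K03320"),
        t("CO2t", {"co2_c": -1, "co2_e": 1}, rev=True, ko="K06287"),
        t("O2t", {"o2_e": -1, "o2_c": 1}, ko="K02441"),
        t("H2Ot", {"h2o_c": -1, "h2o_e": 1}, rev=True, ko="K06188"),
        t("ETOHt", {"etoh_c": -1, "etoh_e": 1}, ko="K03299"),
        t("SUCCt", {"succ_c": -1, "succ_e": 1}, ko="K07113"),
    ]

    def r(rid, stoich, ko, rev=False):
        return Reaction(rid, stoich, reversible=rev, lb=-BIG if rev else 0.0,
                        kos=frozenset([ko]))

    rxns += [
        # backbone: net 2 ATP per hexose through glycolysis
        r("HEX1", {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1}, "K00844"),
        r("GALK", {"gal_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1}, "K00849"),
        r("GLYC", {"g6p_c": -1, "adp_c": -3, "pyr_c": 2, "atp_c": 3}, "K01810"),
        # fermentation branches
        r("PFL", {"pyr_c": -1, "accoa_c": 1, "for_c": 1}, "K00656"),
        r("PTA_ACK", {"accoa_c": -1, "adp_c": -1, "ac_c": 1, "atp_c": 1},
          "K00925"),
        r("ACS", {"ac_c": -1, "atp_c": -1, "accoa_c": 1, "adp_c": 1}, "K01895"),
        r("LDH", {"pyr_c": -1, "lac_c": 1}, "K00016", rev=True),
        r("PPA_SYN", {"pyr_c": -1, "adp_c": -1, "ppa_c": 1, "atp_c": 1},
          "K01026"),
        r("BUT_SYN", {"accoa_c": -2, "adp_c": -1, "but_c": 1, "atp_c": 1},
          "K00248"),
        r("ETOH_SYN", {"accoa_c": -1, "etoh_c": 1}, "K04072"),
        r("SUCC_SYN", {"pyr_c": -1, "co2_c": -1, "succ_c": 1}, "K01902"),
        # amino-acid routes
        r("TNA", {"trp_c": -1, "ind_c": 1, "pyr_c": 1, "nh3_c": 1}, "K01667"),
        r("GLUD", {"glu_L_c": -1, "pyr_c": 1, "nh3_c": 1, "co2_c": 1},
          "K00261"),
        r("ASPD", {"asp_c": -1, "pyr_c": 1, "nh3_c": 1}, "K01744"),
        # aerobic respiration: big ATP yield per pyruvate when O2 available
        r("RESP", {"pyr_c": -1, "o2_c": -3, "adp_c": -5,
                   "co2_c": 3, "atp_c": 5, "h2o_c": 2}, "K02274"),
        # biomass drain: pyruvate + acetyl-CoA precursors + ATP
        Reaction("BIOMASS", {"pyr_c": -1.0, "accoa_c": -0.5, "atp_c": -2.0,
                             "adp_c": 2.0}, lb=0.0, ub=BIG,
                 kos=frozenset()),
    ]
    return UniversalReactionDB(mets, rxns, biomass_id="BIOMASS")


def community_fixture() -> tuple[dict[str, MetabolicModel],
                                 dict[str, dict[str, float]],
                                 DietConstraint]:
    """Designed 3-location community: (models, abundances, diet).

    Four species with disjoint fermentation endpoints — an acetate producer
    (dominant everywhere, Bacteroides-like), a propionate producer, a
    butyrate producer (rectum-enriched, Eubacterium rectale-like) and a
    tryptophan fermenter that carries tryptophanase and lives only in the
    proximal locations (TI*, TC). Abundances are chosen so the weighted
    secretion ordering is acetate > propionate > butyrate at every location
    and indole appears only where the tryptophanase carrier does.
    """
    db = fermentation_universe()
    diet = default_diet()
    ko_sets = {
        "acetogen": {"K02777", "K00844", "K01810", "K00656", "K00925",
                     "K03290", "K21990"},
        "propionogen": {"K02777", "K00844", "K01810", "K00656", "K21990",
                        "K01026", "K03291"},
        "butyrogen": {"K02777", "K00844", "K01810", "K00656", "K21990",
                      "K00248", "K03292"},
        "trp_fermenter": {"K03835", "K01667", "K05802", "K03320", "K00656",
                          "K00925", "K03290", "K21990"},
    }
    models = {
        name: gap_fill(build_draft(kos, db, species=name), db, diet)
        for name, kos in ko_sets.items()
    }
    abundances = {
        "TI*": {"acetogen": 0.55, "propionogen": 0.20, "butyrogen": 0.05,
                "trp_fermenter": 0.20},
        "TC": {"acetogen": 0.45, "propionogen": 0.25, "butyrogen": 0.10,
               "trp_fermenter": 0.20},
        "RE": {"acetogen": 0.40, "propionogen": 0.35, "butyrogen": 0.25,
               "trp_fermenter": 0.00},
    }
    return models, abundances, diet


def default_diet() -> DietConstraint:
    """Fixture diet: fermentable sugars plus amino acids, no oxygen."""
    return DietConstraint(uptake={
        "glc_e": 10.0, "gal_e": 5.0, "trp_e": 2.0, "glu_L_e": 5.0,
        "asp_e": 5.0, "h2o_e": 100.0,
    })
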
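"""Physiological predictions derived from a flux set.

From the completed flux map the module builds a per-reaction ledger of
reducing-equivalent and phosphate-transfer turnover (NADH by compartment,
FADH2, succinyl-CoA-synthetase GTP, NADPH, substrate-level ATP), moves
the cytosolic NADH surplus into the mitochondrion through the
malate-aspartate shuttle, and derives

* MRO2 = (NADH oxidized + FADH2 oxidized) / 2            [mmol O2/L-cell/h]
* oxidative ATP = P/O_NADH * NADH_mito + P/O_FADH2 * FADH2 + GTP
  with P/O ratios 2.5 (NADH) and 1.5 (FADH2)
* glycolytic ATP, both as net substrate-level phosphorylation
  (PGK + PK - HK - PFK, PPP-adjusted) and as the 1-ATP-per-lactate
  convention (the fraction reported uses the named convention)
* NADPH production (oxidative PPP: 2 per G6P; optional malic-enzyme and
  IDH contributions) against lipogenic consumption (14 NADPH per
  palmitate, i.e. 1.75 per acetyl unit)
* the Warburg parameter: net LDH flux / mitochondrial pyruvate carrier
  influx.

Cofactor stoichiometries are annotations per reaction name; the table for
the DB-1 preset ships as the default and can be overridden or extended
for other networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import FluxSet, NetworkError, NetworkModel

__all__ = [
    "Ledger",
    "DB1_COFACTORS",
    "reducing_equivalent_ledger",
    "predict_mro2",
    "atp_partition",
    "substrate_atp_yield",
    "nadph_balance",
    "warburg_parameter",
    "energetics_report",
]

PO_NADH = 2.5
PO_FADH2 = 1.5
NADPH_PER_PALMITATE = 14.0  # 7 elongation cycles x 2
ACETYL_PER_PALMITATE = 8.0

# per unit net flux: positive = produced, negative = consumed
# keys: nadh_c, nadh_m, fadh2, gtp, nadph_c, nadph_m, atp_c, atp_m
DB1_COFACTORS: dict[str, dict[str, float]] = {
    "HK": {"atp_c": -1.0},
    "ALD": {"atp_c": -1.0},  # carries the PFK phosphorylation of the lumped step
    "GLY": {"nadh_c": 1.0, "atp_c": 2.0},  # GAPDH + PGK + PK per triose
    "LDH": {"nadh_c": -1.0},
    "PDH": {"nadh_m": 1.0},
    "PC": {"atp_m": -1.0},
    "IDH": {"nadh_m": 1.0},
    "AKGDH": {"nadh_m": 1.0, "gtp": 1.0},  # includes succinyl-CoA synthetase
    "SDHFUM": {"fadh2": 1.0},
    "MDH_m": {"nadh_m": 1.0},
    "GLUX": {"nadh_m": 1.0},  # glutamate dehydrogenase on the net flux
    "ME1": {"nadph_c": 1.0},
    "PPP_OX": {"nadph_c": 2.0},  # G6PDH + 6PGDH
    "CITLY": {"nadh_c": -1.0, "atp_c": -1.0},  # ATP-citrate lyase + cytosolic MDH
    # explicitly cofactor-neutral steps (so routes can traverse them)
    "GLS": {},
    "CS": {},
    "MPC": {},
    "PGI": {},
    # ME2/ME3 and FAS entries are added at ledger build time (configurable)
}


@dataclass
class Ledger:
    """Per-reaction cofactor turnover plus aggregate totals."""

    entries: pd.DataFrame  # index: reaction, columns: cofactor species
    shuttle_nadh: float  # cytosolic NADH moved to the mitochondrion
    options: dict = field(default_factory=dict)

    def total(self, species: str) -> float:
        if species not in self.entries.columns:
            return 0.0
        return float(self.entries[species].sum())

    def production(self, species: str) -> float:
        if species not in self.entries.columns:
            return 0.0
        col = self.entries[species]
        return float(col[col > 0].sum())

    def consumption(self, species: str) -> float:
        if species not in self.entries.columns:
            return 0.0
        col = self.entries[species]
        return float(-col[col < 0].sum())

    @property
    def nadh_mito_oxidized(self) -> float:
        """Mitochondrial NADH delivered to the respiratory chain."""
        return self.production("nadh_m") + self.shuttle_nadh

    @property
    def fadh2_oxidized(self) -> float:
        return self.production("fadh2")


def reducing_equivalent_ledger(
    model: NetworkModel | None,
    fluxes: FluxSet,
    *,
    cofactors: dict | None = None,
    me2_nadh_fraction: float = 0.5,
    fa_units: str = "palmitate",
    redox_active: set | None = None,
) -> Ledger:
    """Build the cofactor ledger from net fluxes.

    ``me2_nadh_fraction`` splits the lumped mitochondrial malic enzyme
    between the NADH (ME2) and NADPH (ME3) isoforms; the published flux
    is the sum only.  ``fa_units`` states whether the FAS flux is counted
    per palmitate (NADPH demand 14 per unit) or per acetyl unit (1.75).
    Reactions listed in ``redox_active`` must have an annotation.
    """
    table = dict(DB1_COFACTORS if cofactors is None else cofactors)
    if not 0.0 <= me2_nadh_fraction <= 1.0:
        raise NetworkError("me2_nadh_fraction must be in [0, 1]")
    if fa_units not in ("palmitate", "acetyl"):
        raise NetworkError("fa_units must be 'palmitate' or 'acetyl'")
    table.setdefault(
        "ME2",
        {"nadh_m": me2_nadh_fraction, "nadph_m": 1.0 - me2_nadh_fraction},
    )
    nadph_per_fas = (
        NADPH_PER_PALMITATE
        if fa_units == "palmitate"
        else NADPH_PER_PALMITATE / ACETYL_PER_PALMITATE
    )
    table.setdefault("FAS", {"nadph_c": -nadph_per_fas, "atp_c": -nadph_per_fas / 2})

    if redox_active:
        missing = {r for r in redox_active if r not in table}
        if missing:
            raise NetworkError(
                f"reactions flagged redox-active lack cofactor annotations: "
                f"{sorted(missing)}"
            )

    species = sorted({s for d in table.values() for s in d})
    rows = {}
    for name, (net, _exch) in fluxes.items():
        ann = table.get(name)
        if not ann:
            continue
        rows[name] = {s: ann.get(s, 0.0) * net for s in species}
    frame = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=species).fillna(0.0)

    cyt_surplus = float(frame["nadh_c"].sum()) if "nadh_c" in frame else 0.0
    shuttle = max(cyt_surplus, 0.0)  # malate-aspartate shuttle import
    return Ledger(
        entries=frame,
        shuttle_nadh=shuttle,
        options={
            "me2_nadh_fraction": me2_nadh_fraction,
            "fa_units": fa_units,
        },
    )


def predict_mro2(ledger: Ledger) -> float:
    """MRO2 = (NADH oxidized + FADH2 oxidized) / 2 (mmol O2/L-cell/h)."""
    return (ledger.nadh_mito_oxidized + ledger.fadh2_oxidized) / 2.0


def atp_partition(
    ledger: Ledger,
    po_nadh: float = PO_NADH,
    po_fadh2: float = PO_FADH2,
    *,
    glycolytic_convention: str = "per_lactate",
    fluxes: FluxSet | None = None,
) -> dict:
    """Oxidative vs glycolytic ATP production fluxes.

    Oxidative ATP = po_nadh * NADH_mito + po_fadh2 * FADH2 + GTP.
    Glycolytic ATP is reported under both conventions; the fraction uses
    ``glycolytic_convention`` ('per_lactate': one ATP per LDH turnover;
    'substrate_level': net cytosolic substrate-level phosphorylation from
    the ledger).  The convention used is echoed in the output.
    """
    from_nadh = po_nadh * ledger.nadh_mito_oxidized
    from_fadh2 = po_fadh2 * ledger.fadh2_oxidized
    gtp = ledger.production("gtp")
    oxidative = from_nadh + from_fadh2 + gtp

    substrate_level = float(
        ledger.entries["atp_c"].sum() if "atp_c" in ledger.entries else 0.0
    )
    per_lactate = float(fluxes.net("LDH")) if fluxes is not None and "LDH" in fluxes else np.nan
    if glycolytic_convention == "per_lactate" and np.isfinite(per_lactate):
        glycolytic = per_lactate
    else:
        glycolytic_convention = "substrate_level"
        glycolytic = substrate_level
    total = oxidative + glycolytic
    return {
        "oxidative": oxidative,
        "oxidative_from_nadh": from_nadh,
        "oxidative_from_fadh2": from_fadh2,
        "oxidative_gtp": gtp,
        "glycolytic": glycolytic,
        "glycolytic_substrate_level": substrate_level,
        "glycolytic_per_lactate": per_lactate,
        "glycolytic_convention": glycolytic_convention,
        "total": total,
        "fraction_oxidative": oxidative / total if total else np.nan,
    }


#: oxidation routes as reaction multisets; cofactor overrides let a route
#: pin an isoform choice (e.g. glutaminolysis via the NADPH-linked ME3)
ROUTES: dict[str, dict] = {
    "glutaminolysis": {
        "reactions": [
            "GLS",
            "GLUX",
            "AKGDH",
            "SDHFUM",
            "MDH_m",
            "ME2",
            "PDH",
            "CS",
            "IDH",
            "AKGDH",
            "SDHFUM",
            "MDH_m",
        ],
        "overrides": {"ME2": {"nadh_m": 0.0, "nadph_m": 1.0}},  # ME3 isoform
    },
    "acetyl_coa_oxidation": {
        "reactions": ["CS", "IDH", "AKGDH", "SDHFUM", "MDH_m"],
        "overrides": {},
    },
    "glucose_to_lactate": {
        "reactions": ["HK", "ALD", "GLY", "GLY", "LDH", "LDH"],
        "overrides": {},
    },
}


def substrate_atp_yield(
    substrate_or_route: str,
    *,
    po_nadh: float = PO_NADH,
    po_fadh2: float = PO_FADH2,
    cofactors: dict | None = None,
) -> float:
    """ATP yield per molecule along a declared oxidation route.

    Traverses the route's reaction list accumulating cofactor turnover,
    then converts NADH/FADH2 at the P/O ratios and adds GTP and net
    substrate-level ATP.  E.g. full glutamine oxidation through the
    glutaminolysis route yields 7 NADH, 2 FADH2 and 2 GTP = 22.5 ATP.
    """
    key = {
        "glutamine": "glutaminolysis",
        "acetyl-coa": "acetyl_coa_oxidation",
        "acetyl_coa": "acetyl_coa_oxidation",
        "glucose": "glucose_to_lactate",
    }.get(substrate_or_route.lower(), substrate_or_route)
    if key not in ROUTES:
        raise NetworkError(
            f"route {substrate_or_route!r} is not a declared oxidation path "
            f"(known: {sorted(ROUTES)})"
        )
    route = ROUTES[key]
    table = dict(DB1_COFACTORS if cofactors is None else cofactors)
    table.setdefault("ME2", {"nadh_m": 0.5, "nadph_m": 0.5})
    totals: dict[str, float] = {}
    for rxn in route["reactions"]:
        if rxn not in table:
            raise NetworkError(f"route step {rxn!r} lacks a cofactor annotation")
        ann = dict(table[rxn])
        ann.update(route["overrides"].get(rxn, {}))
        for s, v in ann.items():
            totals[s] = totals.get(s, 0.0) + v
    nadh = totals.get("nadh_m", 0.0) + max(totals.get("nadh_c", 0.0), 0.0)
    return (
        po_nadh * nadh
        + po_fadh2 * totals.get("fadh2", 0.0)
        + totals.get("gtp", 0.0)
        + totals.get("atp_c", 0.0)
        + totals.get("atp_m", 0.0)
    )


def nadph_balance(
    fluxes: FluxSet,
    *,
    fa_units: str = "palmitate",
    include_me1: bool = False,
    include_me_mito_fraction: float = 0.0,
    include_idh: float = 0.0,
    ppp_name: str = "PPP_OX",
    fas_name: str = "FAS",
) -> dict:
    """Lipogenic NADPH production vs consumption.

    Production defaults to the oxidative PPP alone (2 NADPH per G6P);
    malic-enzyme and IDH contributions are opt-in because the cytosolic
    lipogenic pool is the relevant one and the mitochondrial isoforms
    serve other demands.  Consumption is the fatty-acid synthesis demand
    (14 per palmitate or 1.75 per acetyl unit).
    """
    if fa_units not in ("palmitate", "acetyl"):
        raise NetworkError("fa_units must be 'palmitate' or 'acetyl'")
    production = {"ppp_oxidative": 2.0 * fluxes.net(ppp_name)}
    if include_me1 and "ME1" in fluxes:
        production["me1"] = fluxes.net("ME1")
    if include_me_mito_fraction and "ME2" in fluxes:
        production["me_mito"] = include_me_mito_fraction * fluxes.net("ME2")
    if include_idh:
        production["idh"] = float(include_idh)
    per_unit = (
        NADPH_PER_PALMITATE
        if fa_units == "palmitate"
        else NADPH_PER_PALMITATE / ACETYL_PER_PALMITATE
    )
    consumption = {"fatty_acid_synthesis": per_unit * fluxes.net(fas_name)}
    tot_p = sum(production.values())
    tot_c = sum(consumption.values())
    return {
        "production": production,
        "consumption": consumption,
        "total_production": tot_p,
        "total_consumption": tot_c,
        "ratio_pct": 100.0 * tot_p / tot_c if tot_c else np.nan,
        "fa_units": fa_units,
    }


def warburg_parameter(fluxes: FluxSet, *, ldh: str = "LDH", mpc: str = "MPC") -> float:
    """Net LDH flux over mitochondrial pyruvate carrier influx."""
    denom = fluxes.net(mpc)
    if denom == 0:
        return float("nan")
    return fluxes.net(ldh) / denom


def energetics_report(
    model: NetworkModel | None,
    fluxes: FluxSet,
    *,
    me2_nadh_fraction: float = 0.5,
    fa_units_ledger: str = "acetyl",
    fa_units_nadph: str = "palmitate",
    glycolytic_convention: str = "per_lactate",
    mrglc_experimental: float | None = None,
) -> dict:
    """One-stop report: MRO2, ATP partition, NADPH balance, Warburg
    parameter, MRglc and CMRlac, with the conventions echoed.

    The carbon network counts the lipogenic citrate export in acetyl
    units (that is what balances the published citrate-synthase flux);
    the NADPH demand uses the palmitate convention of the published
    consumption figure.  Both switches are explicit here.
    """
    ledger = reducing_equivalent_ledger(
        model,
        fluxes,
        me2_nadh_fraction=me2_nadh_fraction,
        fa_units=fa_units_ledger,
    )
    atp = atp_partition(
        ledger, glycolytic_convention=glycolytic_convention, fluxes=fluxes
    )
    nadph = nadph_balance(fluxes, fa_units=fa_units_nadph)
    mrglc = fluxes.net("HK") if "HK" in fluxes else np.nan
    cmrlac = fluxes.net("LDH") if "LDH" in fluxes else np.nan
    return {
        "MRO2": predict_mro2(ledger),
        "ATP": atp,
        "NADPH": nadph,
        "warburg_parameter": warburg_parameter(fluxes),
        "MRglc": float(mrglc),
        "CMRlac": float(cmrlac),
        "oxppp_fraction_of_glucose_uptake_pct": (
            100.0 * fluxes.net("PPP_OX") / mrglc if np.isfinite(mrglc) and mrglc else np.nan
        ),
        # denominator choice is ambiguous in the field; report both
        "oxppp_fraction_of_experimental_mrglc_pct": (
            100.0 * fluxes.net("PPP_OX") / mrglc_experimental
            if mrglc_experimental
            else np.nan
        ),
        "ledger": ledger,
    }
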
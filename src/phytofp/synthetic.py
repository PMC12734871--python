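"""Synthetic study data with known ground truth.

Everything the pipeline consumes can be generated here, deterministically
from one seed, together with a ledger that predicts every downstream count
without running the pipeline:

* vendor-style feature tables with violations of each screening rule planted
  at controlled, mutually exclusive per-row rates;
* scaffold-labelled molecule sets built by random substitution on flavone,
  flavonol, anthraquinone, cinnamate and stilbene templates, so that the
  hierarchy-classification task is learnable at desk scale;
* four-species compound profiles realizing a planted Venn membership design
  (by default the sharing structure of the four-herbal-drug study: totals
  93/83/83/51, a 4-compound core, 21 shared by the two Rhamnaceae barks with
  10 exclusive to them, 13 shared by Senna and Rhubarb with 5 exclusive),
  with per-species lognormal intensity shifts.

Abundances are lognormal per species — multiplicative electrospray intensity
noise — and violations are mutually exclusive per row so that the first-fail
attribution of the screening report matches the ledger exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Descriptors import ExactMolWt
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

from .feature_io import DB_SOURCES, FeatureRecord, Ontology
from .screening import PROTON_MASS, RULE_ORDER, assign_msi_level
from .comparative import ProfileCompound, SpeciesProfile

__all__ = [
    "ScaffoldFamily",
    "DEFAULT_FAMILIES",
    "STUDY_REGION_DESIGN",
    "STUDY_SPECIES",
    "GeneratorSpec",
    "GroundTruthLedger",
    "LabelledMolecule",
    "build_ontology",
    "generate_molecules",
    "generate_labelled_molecules",
    "generate_cd_table",
    "generate_species_profiles",
    "generate_study_tables",
    "plant_expert_labels",
    "predictions_from_labels",
]


@dataclass(frozen=True)
class ScaffoldFamily:
    """A substitutable core structure with its hierarchy labels.

    ``template`` is a SMILES string with ``{}`` slots at substitutable ring
    positions; filling each slot with a (possibly empty) parenthesized branch
    yields a valid SMILES.
    """

    name: str
    template: str
    pathway: str
    superclass: str
    cls: str

    @property
    def n_slots(self) -> int:
        return self.template.count("{")


#: Substituents drawn for template slots: H, hydroxyl, methoxy, methyl,
#: hydroxymethyl, O-glycosyl.
SUBSTITUENTS = ("", "(O)", "(OC)", "(C)", "(CO)", "(OC1OC(CO)C(O)C(O)C1O)")
_SUB_WEIGHTS = (0.40, 0.22, 0.12, 0.12, 0.07, 0.07)

DEFAULT_FAMILIES = (
    ScaffoldFamily(
        "flavone", "O=c1cc(-c2cc{}c{}cc2)oc2c{}c{}ccc12",
        "Shikimates and Phenylpropanoids", "Flavonoids", "Flavones",
    ),
    ScaffoldFamily(
        "flavonol", "O=c1c(O)c(-c2cc{}c{}cc2)oc2c{}c{}ccc12",
        "Shikimates and Phenylpropanoids", "Flavonoids", "Flavonols",
    ),
    ScaffoldFamily(
        "anthraquinone", "O=C1c2cc{}c{}cc2C(=O)c2cc{}c{}cc12",
        "Polyketides", "Polycyclic aromatic polyketides",
        "Anthraquinones and anthrones",
    ),
    ScaffoldFamily(
        "cinnamate", "OC(=O)C=Cc1cc{}c{}c{}c1",
        "Shikimates and Phenylpropanoids", "Phenylpropanoids (C6-C3)",
        "Cinnamic acids",
    ),
    ScaffoldFamily(
        "stilbene", "c1cc{}c(C=Cc2cc{}c{}cc2)c{}c1",
        "Shikimates and Phenylpropanoids", "Stilbenoids", "Stilbenes",
    ),
)

STUDY_SPECIES = ("Cascara", "Frangula", "Rhubarb", "Senna")

# Exclusive Venn-region sizes reproducing the four-species study structure:
# species totals 93/83/83/51; 4-compound core; |Cascara∩Frangula| = 21 with
# 10 exclusive to the pair; |Senna∩Rhubarb| = 13 with 5 exclusive.
STUDY_REGION_DESIGN: dict[frozenset[str], int] = {
    frozenset({"Cascara"}): 66,
    frozenset({"Frangula"}): 56,
    frozenset({"Rhubarb"}): 60,
    frozenset({"Senna"}): 33,
    frozenset({"Cascara", "Frangula"}): 10,
    frozenset({"Cascara", "Rhubarb"}): 3,
    frozenset({"Cascara", "Senna"}): 1,
    frozenset({"Frangula", "Rhubarb"}): 3,
    frozenset({"Frangula", "Senna"}): 1,
    frozenset({"Rhubarb", "Senna"}): 5,
    frozenset({"Cascara", "Frangula", "Rhubarb"}): 4,
    frozenset({"Cascara", "Frangula", "Senna"}): 3,
    frozenset({"Cascara", "Rhubarb", "Senna"}): 2,
    frozenset({"Frangula", "Rhubarb", "Senna"}): 2,
    frozenset(STUDY_SPECIES): 4,
}

#: Family sampling weights shaped like the observed superclass distribution
#: (flavonoids dominant, then polyketides and phenylpropanoids).
DEFAULT_FAMILY_WEIGHTS = (0.32, 0.26, 0.20, 0.14, 0.08)

_DEFAULT_VIOLATION_RATES = {"db": 0.05, "ppm": 0.05, "rt": 0.05, "area": 0.05, "ms2": 0.05}

# Species-level log-intensity offsets: distinct electrospray response per
# matrix, driving the between-species axis of the abundance matrix.
_DEFAULT_LOG_AREA_MEAN = 16.0
_DEFAULT_SPECIES_SHIFT = (1.2, 0.6, 0.0, -1.2)


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs of the synthetic study, with the study design as default."""

    seed: int = 0
    species: tuple[str, ...] = STUDY_SPECIES
    replicates_per_species: int = 3
    n_compounds_per_species: int = 100
    region_design: Mapping[frozenset[str], int] | None = None
    filter_violation_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_VIOLATION_RATES)
    )
    scaffold_families: tuple[ScaffoldFamily, ...] = DEFAULT_FAMILIES
    family_weights: tuple[float, ...] = DEFAULT_FAMILY_WEIGHTS
    area_log_mean: float = _DEFAULT_LOG_AREA_MEAN
    species_log_shift: tuple[float, ...] | None = None
    area_log_sd: float = 0.8
    replicate_log_sd: float = 0.15
    rt_range: tuple[float, float] = (5.0, 50.0)

    def __post_init__(self) -> None:
        for rule, rate in self.filter_violation_rates.items():
            if rule not in RULE_ORDER:
                raise ValueError(f"unknown rule {rule!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate for {rule!r} outside [0,1]")
        if sum(self.filter_violation_rates.values()) > 1.0:
            raise ValueError("violation rates must sum to at most 1")
        if len(self.family_weights) != len(self.scaffold_families):
            raise ValueError("family_weights must align with scaffold_families")
        if self.n_compounds_per_species <= 0 or self.replicates_per_species <= 0:
            raise ValueError("counts must be positive")

    def resolved_region_design(self) -> dict[frozenset[str], int]:
        if self.region_design is not None:
            design = {frozenset(k): int(v) for k, v in self.region_design.items()}
        elif set(self.species) == set(STUDY_SPECIES):
            design = dict(STUDY_REGION_DESIGN)
        else:
            # fallback: mostly exclusive compounds plus a small all-species core
            core = min(4, self.n_compounds_per_species)
            design = {frozenset(self.species): core}
            for sp in self.species:
                design[frozenset({sp})] = self.n_compounds_per_species - core
        for region in design:
            if not region <= set(self.species):
                raise ValueError(f"region {set(region)} not within species {self.species}")
        totals = self.species_totals(design)
        for sp, tot in totals.items():
            if tot <= 0:
                raise ValueError(f"species {sp} ends up with no compounds")
        return design

    def species_totals(self, design: Mapping[frozenset[str], int] | None = None) -> dict[str, int]:
        design = design if design is not None else self.resolved_region_design()
        return {
            sp: sum(c for reg, c in design.items() if sp in reg) for sp in self.species
        }

    def species_shift(self, sp: str) -> float:
        shifts = self.species_log_shift
        if shifts is None:
            shifts = tuple(
                _DEFAULT_SPECIES_SHIFT[i % len(_DEFAULT_SPECIES_SHIFT)]
                for i in range(len(self.species))
            )
        return shifts[self.species.index(sp)]


@dataclass(frozen=True)
class LabelledMolecule:
    name: str
    smiles: str
    family: str
    pathway: str
    superclass: str
    cls: str
    formula: str
    exact_mass: float


@dataclass
class GroundTruthLedger:
    """Everything needed to predict pipeline outputs without running it."""

    feature_rows: pd.DataFrame | None = None          # per emitted table row
    membership: pd.DataFrame | None = None            # compounds x species bool
    molecule_labels: dict[str, dict[str, str]] = field(default_factory=dict)
    planted_abundance: pd.DataFrame | None = None     # compounds x sample columns
    catalog: pd.DataFrame | None = None               # name/smiles/labels of compounds

    # ---- screening predictions -------------------------------------------
    def expected_fail_counts(self) -> dict[str, int]:
        if self.feature_rows is None:
            raise ValueError("ledger holds no feature rows")
        counts = {rule: 0 for rule in RULE_ORDER}
        for rule in self.feature_rows["violated_rule"]:
            if rule:
                counts[rule] += 1
        return counts

    def expected_pass_count(self) -> int:
        if self.feature_rows is None:
            raise ValueError("ledger holds no feature rows")
        return int((self.feature_rows["violated_rule"] == "").sum())

    # ---- comparison predictions ------------------------------------------
    def expected_region_counts(self) -> dict[frozenset[str], int]:
        if self.membership is None:
            raise ValueError("ledger holds no membership matrix")
        counts: dict[frozenset[str], int] = {}
        for _, row in self.membership.iterrows():
            region = frozenset(self.membership.columns[row.values.astype(bool)])
            counts[region] = counts.get(region, 0) + 1
        return counts


def build_ontology(families: Sequence[ScaffoldFamily] = DEFAULT_FAMILIES) -> Ontology:
    """Hierarchy covering the scaffold families' labels."""
    pathways = frozenset(f.pathway for f in families)
    sc_parent = {f.superclass: f.pathway for f in families}
    cl_parent = {f.cls: f.superclass for f in families}
    return Ontology(pathways, sc_parent, cl_parent)


def _make_molecule(
    family: ScaffoldFamily, rng: np.random.Generator, seen: set[str], max_tries: int = 200
) -> tuple[str, Chem.Mol]:
    """Draw a unique substituted molecule from a family template."""
    for _ in range(max_tries):
        subs = rng.choice(len(SUBSTITUENTS), size=family.n_slots, p=_SUB_WEIGHTS)
        smi = family.template.format(*(SUBSTITUENTS[i] for i in subs))
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - templates are validated
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical not in seen:
            seen.add(canonical)
            return canonical, mol
    raise RuntimeError(
        f"could not draw a fresh {family.name} molecule after {max_tries} tries"
    )


def generate_molecules(
    spec: GeneratorSpec, n_per_family: int
) -> list[LabelledMolecule]:
    """n_per_family unique substituted molecules from every scaffold family."""
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    out: list[LabelledMolecule] = []
    for family in spec.scaffold_families:
        for i in range(n_per_family):
            smi, mol = _make_molecule(family, rng, seen)
            out.append(
                LabelledMolecule(
                    name=f"syn-{family.name}-{i:03d}",
                    smiles=smi,
                    family=family.name,
                    pathway=family.pathway,
                    superclass=family.superclass,
                    cls=family.cls,
                    formula=CalcMolFormula(mol),
                    exact_mass=ExactMolWt(mol),
                )
            )
    return out


def generate_labelled_molecules(
    spec: GeneratorSpec, n_per_family: int = 100
) -> tuple[list[LabelledMolecule], GroundTruthLedger]:
    """Labelled molecule set for classifier training, with its ledger."""
    if len(spec.scaffold_families) < 2:
        raise ValueError("need at least 2 scaffold families")
    molecules = generate_molecules(spec, n_per_family)
    ledger = GroundTruthLedger(
        molecule_labels={
            m.name: {"pathway": m.pathway, "superclass": m.superclass, "class": m.cls}
            for m in molecules
        }
    )
    return molecules, ledger


def molecules_to_frame(molecules: Sequence[LabelledMolecule]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [m.name for m in molecules],
            "smiles": [m.smiles for m in molecules],
            "pathway": [m.pathway for m in molecules],
            "superclass": [m.superclass for m in molecules],
            "class": [m.cls for m in molecules],
            "formula": [m.formula for m in molecules],
        }
    )


def _clean_row_fields(
    rng: np.random.Generator, spec: GeneratorSpec
) -> dict[str, object]:
    """Field values guaranteed to pass every screening rule."""
    lo, hi = spec.rt_range
    margin = 0.05 * (hi - lo)
    n_hits = 1 + rng.integers(0, 3)
    hits = frozenset(rng.choice(DB_SOURCES, size=n_hits, replace=False))
    return {
        "ppm": float(rng.uniform(-2.0, 2.0)),
        "rt": float(rng.uniform(lo + margin, hi - margin)),
        "db_hits": hits,
        "has_ms2": True,
    }


def generate_cd_table(
    spec: GeneratorSpec,
) -> tuple[list[FeatureRecord], GroundTruthLedger]:
    """Vendor-export-style feature rows with planted screening violations.

    One row per compound x species x replicate.  Each row violates at most
    one rule, chosen by a categorical draw at the spec's per-rule rates, so
    the report's first-fail attribution reproduces the ledger exactly.
    Clean rows are guaranteed to pass every rule.
    """
    rng = np.random.default_rng(spec.seed)
    molecules = generate_molecules(
        replace(spec, seed=int(rng.integers(2**31))),
        n_per_family=-(-spec.n_compounds_per_species // len(spec.scaffold_families)),
    )
    rates = [spec.filter_violation_rates.get(rule, 0.0) for rule in RULE_ORDER]
    p = np.array(rates + [1.0 - sum(rates)])
    lo, hi = spec.rt_range
    records: list[FeatureRecord] = []
    rows: list[dict[str, object]] = []
    catalog = molecules[: spec.n_compounds_per_species]
    for sp in spec.species:
        mu = spec.area_log_mean + spec.species_shift(sp)
        for rep in range(1, spec.replicates_per_species + 1):
            rid = f"R{rep}"
            for mol in catalog:
                draw = rng.choice(len(RULE_ORDER) + 1, p=p)
                rule = RULE_ORDER[draw] if draw < len(RULE_ORDER) else ""
                fields = _clean_row_fields(rng, spec)
                area = float(np.exp(rng.normal(mu, spec.area_log_sd)))
                area = max(area, 2.0e5)
                if rule == "db":
                    fields["db_hits"] = frozenset()
                elif rule == "ppm":
                    fields["ppm"] = float(rng.choice([-1, 1]) * rng.uniform(3.5, 8.0))
                elif rule == "rt":
                    fields["rt"] = float(
                        rng.uniform(0.2, lo - 0.5) if rng.random() < 0.5
                        else rng.uniform(hi + 1.0, hi + 10.0)
                    )
                elif rule == "area":
                    area = float(rng.uniform(1e3, 0.9e5))
                elif rule == "ms2":
                    fields["has_ms2"] = False
                ion_mode = "negative" if rng.random() < 0.5 else "positive"
                theo = mol.exact_mass + (PROTON_MASS if ion_mode == "positive" else -PROTON_MASS)
                rec = FeatureRecord(
                    compound_name=mol.name,
                    formula=mol.formula,
                    ion_mode=ion_mode,
                    precursor_mz=theo * (1.0 + fields["ppm"] / 1e6),
                    calc_mw=mol.exact_mass,
                    rt=fields["rt"],
                    peak_area=area,
                    db_hits=fields["db_hits"],
                    has_ms2=bool(fields["has_ms2"]),
                    msi_level=4,
                    species=sp,
                    replicate_id=rid,
                )
                rec = rec.with_msi_level(assign_msi_level(rec))
                records.append(rec)
                rows.append(
                    {
                        "compound": mol.name,
                        "species": sp,
                        "replicate": rid,
                        "violated_rule": rule,
                        "true_ppm": fields["ppm"],
                    }
                )
    ledger = GroundTruthLedger(feature_rows=pd.DataFrame(rows))
    return records, ledger


def generate_species_profiles(
    spec: GeneratorSpec,
) -> tuple[list[SpeciesProfile], GroundTruthLedger]:
    """Species profiles realizing the planted Venn membership design.

    Every compound is assigned to exactly one membership region; per-species
    abundances are lognormal around a compound-level base intensity plus the
    species' log shift, with small replicate noise, so replicates of one
    species cluster tightly and species separate.
    """
    rng = np.random.default_rng(spec.seed)
    design = spec.resolved_region_design()
    n_union = sum(design.values())
    molecules = generate_molecules(
        replace(spec, seed=int(rng.integers(2**31))),
        n_per_family=-(-n_union // len(spec.scaffold_families)),
    )
    # weighted, order-stable draw of the union catalog across families
    weights = np.repeat(spec.family_weights, -(-n_union // len(spec.scaffold_families)))
    weights = weights / weights.sum()
    idx = rng.choice(len(molecules), size=n_union, replace=False, p=weights)
    catalog = [molecules[i] for i in sorted(idx)]
    regions: list[frozenset[str]] = []
    for region in sorted(design, key=lambda r: (len(r), sorted(r))):
        regions.extend([region] * design[region])
    order = rng.permutation(n_union)
    assignment = {catalog[i].name: regions[order[i]] for i in range(n_union)}

    membership = pd.DataFrame(
        {
            sp: [sp in assignment[m.name] for m in catalog]
            for sp in spec.species
        },
        index=[m.name for m in catalog],
    )
    rep_ids = [f"R{r}" for r in range(1, spec.replicates_per_species + 1)]
    base_log = {m.name: rng.normal(spec.area_log_mean, spec.area_log_sd) for m in catalog}
    profiles: list[SpeciesProfile] = []
    abundance_cols: dict[str, np.ndarray] = {}
    for sp in spec.species:
        shift = spec.species_shift(sp)
        compounds: list[ProfileCompound] = []
        col_values = {rid: np.zeros(n_union) for rid in rep_ids}
        for ci, mol in enumerate(catalog):
            if sp not in assignment[mol.name]:
                continue
            areas = {}
            for rid in rep_ids:
                val = float(np.exp(base_log[mol.name] + shift
                                   + rng.normal(0.0, spec.replicate_log_sd)))
                val = max(val, 2.0e5)  # keep members clear of the area gate
                areas[rid] = val
                col_values[rid][ci] = val
            pred = None
            compounds.append(
                ProfileCompound(
                    name=mol.name,
                    formula=mol.formula,
                    prediction=pred,
                    msi_level=2,
                    areas=areas,
                )
            )
        for rid in rep_ids:
            abundance_cols[f"{sp}:{rid}"] = col_values[rid]
        profiles.append(
            SpeciesProfile(species=sp, compounds=compounds, replicate_ids=list(rep_ids))
        )
    planted = pd.DataFrame(abundance_cols, index=[m.name for m in catalog])
    ledger = GroundTruthLedger(
        membership=membership,
        molecule_labels={
            m.name: {"pathway": m.pathway, "superclass": m.superclass, "class": m.cls}
            for m in catalog
        },
        planted_abundance=planted,
        catalog=molecules_to_frame(catalog),
    )
    return profiles, ledger


def _split_by_rates(n: int, rates: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n decoys across rules."""
    total = sum(rates.values())
    if total <= 0:
        return {rule: 0 for rule in RULE_ORDER}
    shares = {rule: n * rates.get(rule, 0.0) / total for rule in RULE_ORDER}
    counts = {rule: int(shares[rule]) for rule in RULE_ORDER}
    rest = n - sum(counts.values())
    for rule in sorted(RULE_ORDER, key=lambda r: shares[r] - counts[r], reverse=True)[:rest]:
        counts[rule] += 1
    return counts


def generate_study_tables(
    spec: GeneratorSpec, decoys_per_replicate: int = 40
) -> tuple[dict[str, list[FeatureRecord]], list[SpeciesProfile], GroundTruthLedger]:
    """Per-species feature tables whose screening survivors realize the
    planted membership design exactly.

    Member compounds get one guaranteed-clean row per replicate with the
    planted abundance as peak area; each replicate additionally carries
    ``decoys_per_replicate`` background features, every one violating exactly
    one rule (apportioned across rules by the spec's violation rates), so
    per-rule failure counts are deterministic.
    """
    profiles, ledger = generate_species_profiles(spec)
    rng = np.random.default_rng(spec.seed + 1)
    catalog = ledger.catalog
    masses = {
        row["name"]: (row["smiles"], row["formula"])
        for _, row in catalog.iterrows()
    }
    mass_of = {
        name: ExactMolWt(Chem.MolFromSmiles(smi)) for name, (smi, _) in masses.items()
    }
    decoy_counts = _split_by_rates(decoys_per_replicate, spec.filter_violation_rates)
    lo, hi = spec.rt_range
    tables: dict[str, list[FeatureRecord]] = {}
    rows: list[dict[str, object]] = []
    names = list(masses)
    # ionization propensity is a property of the compound, not the injection
    mode_of = {
        name: ("negative" if rng.random() < 0.5 else "positive") for name in names
    }
    for profile in profiles:
        sp = profile.species
        records: list[FeatureRecord] = []
        for rid in profile.replicate_ids:
            for compound in profile.compounds:
                fields = _clean_row_fields(rng, spec)
                ion_mode = mode_of[compound.name]
                mw = mass_of[compound.name]
                theo = mw + (PROTON_MASS if ion_mode == "positive" else -PROTON_MASS)
                rec = FeatureRecord(
                    compound_name=compound.name,
                    formula=compound.formula,
                    ion_mode=ion_mode,
                    precursor_mz=theo * (1.0 + fields["ppm"] / 1e6),
                    calc_mw=mw,
                    rt=fields["rt"],
                    peak_area=compound.areas[rid],
                    db_hits=fields["db_hits"],
                    has_ms2=True,
                    species=sp,
                    replicate_id=rid,
                )
                records.append(rec.with_msi_level(assign_msi_level(rec)))
                rows.append({"compound": compound.name, "species": sp,
                             "replicate": rid, "violated_rule": "", "true_ppm": fields["ppm"]})
            di = 0
            for rule, count in decoy_counts.items():
                for _ in range(count):
                    fields = _clean_row_fields(rng, spec)
                    area = float(np.exp(rng.normal(
                        spec.area_log_mean + spec.species_shift(sp), spec.area_log_sd)))
                    area = max(area, 2.0e5)
                    if rule == "db":
                        fields["db_hits"] = frozenset()
                    elif rule == "ppm":
                        fields["ppm"] = float(rng.choice([-1, 1]) * rng.uniform(3.5, 8.0))
                    elif rule == "rt":
                        fields["rt"] = float(
                            rng.uniform(0.2, lo - 0.5) if rng.random() < 0.5
                            else rng.uniform(hi + 1.0, hi + 10.0)
                        )
                    elif rule == "area":
                        area = float(rng.uniform(1e3, 0.9e5))
                    elif rule == "ms2":
                        fields["has_ms2"] = False
                    ion_mode = "negative" if rng.random() < 0.5 else "positive"
                    mw = mass_of[names[int(rng.integers(len(names)))]]
                    theo = mw + (PROTON_MASS if ion_mode == "positive" else -PROTON_MASS)
                    name = f"decoy-{sp}-{rid}-{di:03d}"
                    di += 1
                    rec = FeatureRecord(
                        compound_name=name,
                        formula=None,
                        ion_mode=ion_mode,
                        precursor_mz=theo * (1.0 + fields["ppm"] / 1e6),
                        calc_mw=mw,
                        rt=fields["rt"],
                        peak_area=area,
                        db_hits=fields["db_hits"],
                        has_ms2=bool(fields["has_ms2"]),
                        species=sp,
                        replicate_id=rid,
                    )
                    records.append(rec.with_msi_level(assign_msi_level(rec)))
                    rows.append({"compound": name, "species": sp, "replicate": rid,
                                 "violated_rule": rule, "true_ppm": fields["ppm"]})
        tables[sp] = records
    ledger.feature_rows = pd.DataFrame(rows)
    return tables, profiles, ledger


def predictions_from_labels(
    labels: Mapping[str, Mapping[str, str]]
) -> dict[str, "ClassPrediction"]:
    """Oracle ClassPredictions (confidence 1, consistent) from a label ledger."""
    from .np_classifier import ClassPrediction

    return {
        name: ClassPrediction(
            name=name,
            labels=dict(levels),
            confidences={lvl: 1.0 for lvl in levels},
            consistent=True,
        )
        for name, levels in labels.items()
    }


def plant_expert_labels(
    compound_superclasses: Mapping[str, str],
    n_discordant: int,
    seed: int,
    n_unassigned: int = 0,
    wrong_label: str = "Misfiled",
) -> tuple[dict[str, str], set[str]]:
    """Expert label map agreeing with the given assignments except for
    ``n_discordant`` planted disagreements; ``n_unassigned`` compounds are
    omitted entirely.  Returns (expert map, names planted discordant)."""
    names = sorted(compound_superclasses)
    if n_discordant + n_unassigned > len(names):
        raise ValueError("more planted exceptions than compounds")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(names), size=n_discordant + n_unassigned, replace=False)
    discordant = {names[i] for i in chosen[:n_discordant]}
    unassigned = {names[i] for i in chosen[n_discordant:]}
    expert = {}
    for name, sc in compound_superclasses.items():
        if name in unassigned:
            continue
        expert[name] = wrong_label if name in discordant else sc
    return expert, discordant
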
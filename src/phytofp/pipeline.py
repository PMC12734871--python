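"""End-to-end orchestration: generate -> screen -> classify -> curate -> compare.

Every run writes a fixed set of CSVs plus a JSON manifest recording the
seed, a hash of the configuration, package versions, per-stage counts and
the SHA-256 of every output file, so identical configurations reproduce
identical manifests.  All randomness flows from the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparative import (
    SpeciesProfile,
    build_abundance_matrix,
    dedupe_profile,
    distribution_table,
    hca,
    heatmap_matrix,
    pca,
    venn_regions,
)
from .curation import concordance
from .feature_io import write_feature_table, write_ontology
from .gin import GinConfig
from .molgraph import FeatureVocab, smiles_to_graph
from .np_classifier import (
    HierarchyClassifier,
    flag_low_confidence,
    train_level_model,
)
from .screening import ScreeningConfig, apply_screening
from .synthetic import (
    GeneratorSpec,
    build_ontology,
    generate_labelled_molecules,
    generate_study_tables,
    molecules_to_frame,
)

__all__ = ["RunConfig", "run_pipeline"]

LEVEL_LABEL_FIELDS = {"pathway": "pathway", "superclass": "superclass", "class": "cls"}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a synthetic end-to-end run."""

    seed: int = 0
    output_dir: str = "phytofp-run"
    generator: GeneratorSpec = None  # type: ignore[assignment]
    screening: ScreeningConfig = ScreeningConfig()
    gin: GinConfig = GinConfig()
    n_train_per_family: int = 60
    decoys_per_replicate: int = 40
    run_cv: bool = False
    linkage: str = "average"
    scaling: str = "autoscale"
    confidence_threshold: float = 0.9
    figures: bool = False

    def __post_init__(self) -> None:
        if self.generator is None:
            object.__setattr__(self, "generator", GeneratorSpec(seed=self.seed))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seed = int(raw.get("seed", 0))
        gen = GeneratorSpec(seed=seed, **{
            k: v for k, v in raw.get("generator", {}).items() if k != "seed"
        })
        return cls(
            seed=seed,
            output_dir=raw.get("output_dir", "phytofp-run"),
            generator=gen,
            screening=ScreeningConfig(**raw.get("screening", {})),
            gin=GinConfig(**raw.get("classifier", {})),
            **{
                k: raw[k]
                for k in (
                    "n_train_per_family", "decoys_per_replicate", "run_cv",
                    "linkage", "scaling", "confidence_threshold", "figures",
                )
                if k in raw
            },
        )

    def canonical_json(self) -> str:
        def enc(obj):
            if isinstance(obj, frozenset):
                return sorted(obj)
            if isinstance(obj, Mapping):
                return {str(k): enc_v for k, enc_v in
                        sorted((str(k2), enc(v2)) for k2, v2 in obj.items())}
            return obj

        d = asdict(self)
        d.pop("output_dir")  # where a run lands does not change what it computes
        d["screening"]["standards_list"] = sorted(self.screening.standards_list)
        d["generator"]["filter_violation_rates"] = dict(
            sorted(self.generator.filter_violation_rates.items())
        )
        if d["generator"]["region_design"] is not None:
            d["generator"]["region_design"] = {
                "|".join(sorted(k)): v
                for k, v in sorted(
                    (tuple(sorted(k2)), v2)
                    for k2, v2 in self.generator.region_design.items()
                )
            }
        d["generator"]["scaffold_families"] = [
            asdict(f) for f in self.generator.scaffold_families
        ]
        return json.dumps(d, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_predictions(predictions, path: Path) -> None:
    rows = []
    for p in predictions:
        row = {"name": p.name}
        for lvl in ("pathway", "superclass", "class"):
            row[lvl] = p.labels.get(lvl, "")
            row[f"{lvl}_confidence"] = round(p.confidences.get(lvl, float("nan")), 6)
        row["consistent"] = p.consistent
        row["min_confidence"] = round(p.min_confidence, 6)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic study; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "phytofp_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.canonical_json().encode()).hexdigest(),
        "stages": {},
    }
    spec = replace(config.generator, seed=config.seed)

    # ---- generate ---------------------------------------------------------
    tables, planted_profiles, ledger = generate_study_tables(
        spec, decoys_per_replicate=config.decoys_per_replicate
    )
    ontology = build_ontology(spec.scaffold_families)
    write_ontology(ontology, out / "ontology.csv")
    for sp, records in tables.items():
        write_feature_table(records, out / f"features_{sp}.csv")
    ledger.catalog.to_csv(out / "catalog.csv", index=False)
    manifest["stages"]["generate"] = {
        "species": list(tables),
        "rows_per_species": {sp: len(v) for sp, v in tables.items()},
        "union_compounds": int(len(ledger.catalog)),
    }

    # ---- screen -----------------------------------------------------------
    screened_records = []
    screen_counts = {}
    for sp, records in tables.items():
        report = apply_screening(records, config.screening)
        screen_counts[sp] = {
            "input": report.n_input,
            "passed": report.n_pass,
            "failed": dict(report.n_fail_per_rule),
        }
        screened_records.extend(report.passed)
    write_feature_table(screened_records, out / "screened.csv")
    manifest["stages"]["screen"] = screen_counts

    # ---- profiles ---------------------------------------------------------
    profiles: list[SpeciesProfile] = []
    for sp in tables:
        sp_records = [r for r in screened_records if r.species == sp]
        profiles.append(dedupe_profile(sp_records, species=sp))
    manifest["stages"]["profiles"] = {p.species: len(p.compounds) for p in profiles}

    # ---- classify ---------------------------------------------------------
    train_spec = replace(spec, seed=spec.seed + 7919)
    train_mols, _ = generate_labelled_molecules(
        train_spec, n_per_family=config.n_train_per_family
    )
    molecules_to_frame(train_mols).to_csv(out / "training_molecules.csv", index=False)
    train_graphs = [smiles_to_graph(m.smiles, m.name) for m in train_mols]
    vocab = FeatureVocab.fit(train_graphs)
    models = {}
    cv_rows = []
    for level, fld in LEVEL_LABEL_FIELDS.items():
        labels = [getattr(m, fld) for m in train_mols]
        model, report = train_level_model(
            train_graphs, labels, level, vocab=vocab, config=config.gin,
            seed=config.seed, run_cv=config.run_cv,
        )
        models[level] = model
        if config.run_cv:
            cv_rows.append(
                {"level": level, "macro_f1_mean": report.mean_macro_f1,
                 "macro_f1_sd": report.sd_macro_f1,
                 "accuracy_mean": report.mean_accuracy,
                 "accuracy_sd": report.sd_accuracy}
            )
    if cv_rows:
        pd.DataFrame(cv_rows).to_csv(out / "cv_report.csv", index=False)
    classifier = HierarchyClassifier(models, ontology)
    catalog_graphs = [
        smiles_to_graph(row["smiles"], row["name"])
        for _, row in ledger.catalog.iterrows()
    ]
    predictions = classifier.predict(catalog_graphs)
    pred_by_name = {p.name: p for p in predictions}
    _write_predictions(predictions, out / "predictions.csv")
    flagged = flag_low_confidence(predictions, config.confidence_threshold)
    pd.DataFrame({"name": [p.name for p in flagged],
                  "min_confidence": [p.min_confidence for p in flagged]}
                 ).to_csv(out / "curation_queue.csv", index=False)
    manifest["stages"]["classify"] = {
        "n_train": len(train_mols),
        "n_predicted": len(predictions),
        "n_flagged": len(flagged),
    }

    # ---- curate: model assignments vs generator truth ---------------------
    expert_truth = {
        name: levels["superclass"] for name, levels in ledger.molecule_labels.items()
    }
    curation_rows = []
    for profile in profiles:
        preds = [pred_by_name[c.name] for c in profile.compounds if c.name in pred_by_name]
        rep = concordance(preds, expert_truth, species=profile.species)
        curation_rows.append(
            {"species": rep.species, "n_total": rep.n_total,
             "n_confirmed": rep.n_confirmed, "concordance_pct": rep.concordance_pct,
             "n_discordant": len(rep.discordant), "n_unassigned": len(rep.unassigned)}
        )
        for c in profile.compounds:  # attach for downstream tables
            c.prediction = pred_by_name.get(c.name)
    pd.DataFrame(curation_rows).to_csv(out / "concordance.csv", index=False)
    manifest["stages"]["curate"] = {
        r["species"]: r["concordance_pct"] for r in curation_rows
    }

    # ---- compare ----------------------------------------------------------
    venn = venn_regions(profiles)
    venn.to_frame().to_csv(out / "venn.csv", index=False)
    dist = distribution_table(profiles)
    dist.to_csv(out / "distribution.csv")
    matrix = build_abundance_matrix(profiles)
    pca_result = pca(matrix, scaling=config.scaling)
    pd.DataFrame(
        pca_result.scores,
        index=matrix.samples,
        columns=[f"PC{i+1}" for i in range(pca_result.scores.shape[1])],
    ).to_csv(out / "pca_scores.csv")
    pd.DataFrame(
        {"component": [f"PC{i+1}" for i in range(len(pca_result.explained_variance_pct))],
         "explained_variance_pct": np.round(pca_result.explained_variance_pct, 6)}
    ).to_csv(out / "pca_variance.csv", index=False)
    hca_result = hca(matrix, linkage=config.linkage)
    pd.DataFrame(hca_result.merges, columns=["cluster_a", "cluster_b", "height"]
                 ).to_csv(out / "hca_merges.csv", index=False)
    heat, row_order, col_order = heatmap_matrix(profiles)
    heat.to_csv(out / "heatmap_counts.csv")
    manifest["stages"]["compare"] = {
        "venn_core": venn.count(*[p.species for p in profiles]),
        "union": venn.union_size,
        "pc1_pct": round(float(pca_result.explained_variance_pct[0]), 3),
        "pc2_pct": round(float(pca_result.explained_variance_pct[1]), 3),
        "n_superclasses": int(heat.shape[0]),
    }

    if config.figures:
        from . import plots

        plots.plot_superclass_pies(profiles, out / "pies.svg")
        plots.plot_venn_counts(venn, out / "venn.svg")
        plots.plot_pca_scores(pca_result, matrix.sample_species, out / "pca.svg")
        plots.plot_dendrogram(hca_result, out / "hca.svg")
        plots.plot_heatmap(heat, out / "heatmap.svg")

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.csv"))
    }
    manifest["manifest_sha256_basis"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
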
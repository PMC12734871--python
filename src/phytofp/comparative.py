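"""Cross-species comparison of screened, classified metabolite profiles.

Covers the descriptive statistics of a multi-species fingerprinting study:
Venn membership regions over the species' compound sets, superclass
distribution tables, the compounds x replicates abundance matrix, PCA on the
autoscaled matrix, agglomerative clustering of samples (Euclidean distance),
and the superclass x replicate count matrix behind the clustered heatmap.

Compound identity across species is the *normalized name* (case, whitespace
and punctuation folded); molecular formulas are kept for auditing collisions
but never used as the key, since positional isomers share formulas.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .feature_io import FeatureRecord
from .np_classifier import ClassPrediction

__all__ = [
    "ProfileCompound",
    "SpeciesProfile",
    "VennResult",
    "AbundanceMatrix",
    "PcaResult",
    "HcaResult",
    "normalize_compound_name",
    "dedupe_profile",
    "venn_regions",
    "distribution_table",
    "build_abundance_matrix",
    "pca",
    "hca",
    "heatmap_matrix",
]

_PUNCT = re.compile(r"[^0-9a-z]+")


def normalize_compound_name(name: str) -> str:
    """Case/whitespace/punctuation-folded identity key for a compound name."""
    return _PUNCT.sub(" ", name.strip().lower()).strip()


@dataclass
class ProfileCompound:
    name: str
    formula: str | None = None
    prediction: ClassPrediction | None = None
    msi_level: int = 2
    areas: dict[str, float] = field(default_factory=dict)  # replicate_id -> area

    @property
    def superclass(self) -> str | None:
        return self.prediction.labels.get("superclass") if self.prediction else None


@dataclass
class SpeciesProfile:
    """Screened, deduplicated compound list for one botanical sample."""

    species: str
    compounds: list[ProfileCompound]
    replicate_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [normalize_compound_name(c.name) for c in self.compounds]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"{self.species}: duplicate compounds {dupes[:5]}")
        if not self.replicate_ids:
            reps = sorted({r for c in self.compounds for r in c.areas})
            self.replicate_ids = reps or ["rep1"]

    @property
    def names(self) -> set[str]:
        return {normalize_compound_name(c.name) for c in self.compounds}


def dedupe_profile(records: Sequence[FeatureRecord], species: str | None = None) -> SpeciesProfile:
    """Collapse screened feature records for one species into unique compounds.

    Records sharing a normalized compound name become one compound; each
    replicate keeps its maximum observed area.  When a name was detected in
    both ESI polarities, descriptive fields come from the higher-area mode.
    """
    if species is None:
        species_set = {r.species for r in records if r.species}
        species = species_set.pop() if len(species_set) == 1 else ""
    groups: dict[str, list[FeatureRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.compound_name is None:
            continue
        key = normalize_compound_name(rec.compound_name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    compounds: list[ProfileCompound] = []
    replicate_ids = sorted({r.replicate_id for r in records if r.replicate_id})
    for key in order:
        recs = groups[key]
        best = max(recs, key=lambda r: r.peak_area)
        chosen_mode = best.ion_mode
        areas: dict[str, float] = {}
        for r in recs:
            if r.ion_mode != chosen_mode:
                continue
            rid = r.replicate_id or "rep1"
            areas[rid] = max(areas.get(rid, 0.0), r.peak_area)
        compounds.append(
            ProfileCompound(
                name=best.compound_name or key,
                formula=best.formula,
                msi_level=best.msi_level,
                areas=areas,
            )
        )
    return SpeciesProfile(species=species or "", compounds=compounds,
                          replicate_ids=replicate_ids)


@dataclass
class VennResult:
    """Counts and member lists for every nonempty species-membership region."""

    species: tuple[str, ...]
    region_counts: dict[frozenset[str], int]
    region_members: dict[frozenset[str], list[str]]

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def count(self, *species: str) -> int:
        """Exclusive count of the region containing exactly these species."""
        return self.region_counts.get(frozenset(species), 0)

    def shared_by(self, *species: str) -> int:
        """Inclusive count: compounds present in at least all named species."""
        want = frozenset(species)
        return sum(c for reg, c in self.region_counts.items() if want <= reg)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region in sorted(self.region_counts, key=lambda r: (len(r), sorted(r))):
            rows.append(
                {
                    "region": " & ".join(sorted(region)),
                    "n_species": len(region),
                    "count": self.region_counts[region],
                    "members": ";".join(self.region_members[region]),
                }
            )
        return pd.DataFrame(rows, columns=["region", "n_species", "count", "members"])


def venn_regions(profiles: Sequence[SpeciesProfile]) -> VennResult:
    """Partition the union of compounds into 2^k - 1 membership regions."""
    if not 2 <= len(profiles) <= 6:
        raise ValueError("venn_regions supports 2-6 species")
    names = [p.species for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate species names: {names}")
    membership: dict[str, set[str]] = {p.species: p.names for p in profiles}
    display: dict[str, str] = {}
    for p in profiles:
        for c in p.compounds:
            display.setdefault(normalize_compound_name(c.name), c.name)
    counts: dict[frozenset[str], int] = {}
    members: dict[frozenset[str], list[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            counts[frozenset(combo)] = 0
            members[frozenset(combo)] = []
    union = sorted(set().union(*membership.values()))
    for key in union:
        region = frozenset(sp for sp in names if key in membership[sp])
        counts[region] += 1
        members[region].append(display[key])
    return VennResult(tuple(names), counts, members)


def distribution_table(profiles: Sequence[SpeciesProfile]) -> pd.DataFrame:
    """Superclass x species compound counts with per-species percentages.

    Rows are sorted by total count descending (ties alphabetical); a
    ``<species> %`` column accompanies each species column.
    """
    counts: dict[str, dict[str, int]] = {}
    for p in profiles:
        for c in p.compounds:
            sc = c.superclass or "Unclassified"
            counts.setdefault(sc, {})[p.species] = counts.setdefault(sc, {}).get(p.species, 0) + 1
    species = [p.species for p in profiles]
    df = pd.DataFrame(
        [[counts.get(sc, {}).get(sp, 0) for sp in species] for sc in counts],
        index=list(counts),
        columns=species,
    )
    df = df.reindex(sorted(df.index))  # alphabetical, then stable sort by total
    df = df.loc[df.sum(axis=1).sort_values(ascending=False, kind="stable").index]
    for sp in species:
        total = df[sp].sum()
        df[f"{sp} %"] = (100.0 * df[sp] / total).round(1) if total else 0.0
    df.index.name = "superclass"
    return df


@dataclass
class AbundanceMatrix:
    """Compounds x sample-replicates peak-area matrix (0 = not detected)."""

    values: np.ndarray
    compounds: list[str]
    samples: list[str]
    sample_species: list[str]

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValueError("peak areas must be nonnegative")
        if self.values.shape != (len(self.compounds), len(self.samples)):
            raise ValueError("matrix shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compounds, columns=self.samples)


def build_abundance_matrix(profiles: Sequence[SpeciesProfile]) -> AbundanceMatrix:
    """Union-of-compounds x all-replicates matrix across species."""
    for p in profiles:
        expected = set(p.replicate_ids)
        for c in p.compounds:
            extra = set(c.areas) - expected
            if extra:
                raise ValueError(
                    f"{p.species}/{c.name}: areas for unknown replicates {sorted(extra)}"
                )
    keys: list[str] = []
    display: dict[str, str] = {}
    for p in profiles:
        for c in p.compounds:
            k = normalize_compound_name(c.name)
            if k not in display:
                display[k] = c.name
                keys.append(k)
    samples: list[str] = []
    sample_species: list[str] = []
    for p in profiles:
        for rid in p.replicate_ids:
            samples.append(f"{p.species}:{rid}")
            sample_species.append(p.species)
    values = np.zeros((len(keys), len(samples)))
    row_of = {k: i for i, k in enumerate(keys)}
    col = 0
    for p in profiles:
        local = {normalize_compound_name(c.name): c for c in p.compounds}
        for rid in p.replicate_ids:
            for k, c in local.items():
                values[row_of[k], col] = c.areas.get(rid, 0.0)
            col += 1
    return AbundanceMatrix(values, [display[k] for k in keys], samples, sample_species)


@dataclass
class PcaResult:
    scores: np.ndarray  # samples x components
    explained_variance_pct: np.ndarray
    loadings: np.ndarray  # features x components
    dropped_constant_rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ev = self.explained_variance_pct
        if (np.diff(ev) > 1e-9).any():
            raise ValueError("explained variance must be nonincreasing")
        if ev.sum() > 100.0 + 1e-6:
            raise ValueError("explained variance exceeds 100%")


def _scale_rows(values: np.ndarray, scaling: str) -> np.ndarray:
    if scaling == "none":
        return values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    if scaling == "autoscale":
        return (values - mean) / sd
    if scaling == "pareto":
        return (values - mean) / np.sqrt(sd)
    raise ValueError(f"unknown scaling {scaling!r}")


def pca(matrix: AbundanceMatrix, scaling: str = "autoscale") -> PcaResult:
    """PCA of samples in feature space after per-feature row scaling.

    Autoscaling is the z-score normalization conventional in metabolomics
    fingerprinting.  Constant rows (zero variance across samples) carry no
    information and would divide by zero, so they are dropped first and
    reported.  Explained-variance percentages are eigenvalue shares of the
    sample covariance of the scaled data.
    """
    n_samples = len(matrix.samples)
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    values = matrix.values
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0 if scaling != "none" else np.ones(len(sd), bool)
    dropped = [c for c, k in zip(matrix.compounds, keep) if not k]
    values = values[keep]
    if values.shape[0] < 2:
        raise ValueError("fewer than 2 nonconstant compounds; PCA is degenerate")
    scaled = _scale_rows(values, scaling)
    x = scaled.T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    # SVD route: numerically stabler than forming the covariance
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2 / (n_samples - 1)
    total = var.sum()
    n_comp = min(n_samples - 1, x.shape[1])
    scores = (u * s)[:, :n_comp]
    # deterministic sign: largest-|loading| coordinate positive
    for j in range(n_comp):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1
            scores[:, j] *= -1
    return PcaResult(
        scores=scores,
        explained_variance_pct=100.0 * var[:n_comp] / total,
        loadings=vt[:n_comp].T,
        dropped_constant_rows=dropped,
    )


@dataclass
class HcaResult:
    """Agglomerative merge tree over samples."""

    merges: list[tuple[int, int, float]]  # scipy-style cluster ids + height
    leaf_order: list[int]
    labels: list[str]
    linkage_matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves")


def hca(matrix: AbundanceMatrix, linkage: str = "average",
        scaling: str = "none") -> HcaResult:
    """Hierarchical clustering of sample columns under Euclidean distance.

    ``linkage`` is one of average / ward / complete.  scipy's ordering is
    deterministic for tied distances (lowest cluster index first), which
    fixes the dendrogram for reproducible reports.
    """
    if linkage not in ("average", "ward", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if len(matrix.samples) < 2:
        raise ValueError("HCA needs at least 2 samples")
    values = matrix.values
    if scaling != "none":
        sd = values.std(axis=1, ddof=1)
        values = _scale_rows(values[sd > 0], scaling)
    x = values.T
    if np.isnan(x).any():
        raise ValueError("abundance matrix contains NaN cells")
    z = sch.linkage(pdist(x, metric="euclidean"), method=linkage)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    leaf_order = sch.leaves_list(z).tolist()
    return HcaResult(merges=merges, leaf_order=leaf_order,
                     labels=list(matrix.samples), linkage_matrix=z)


def heatmap_matrix(
    profiles: Sequence[SpeciesProfile], cluster: bool = True
) -> tuple[pd.DataFrame, list[int], list[int]]:
    """Superclass x replicate detected-compound counts, cluster-ordered.

    Cell (s, r) counts compounds of superclass s with area > 0 in replicate
    r.  Raw counts, not normalized.  Row/column orders come from
    average-linkage Euclidean clustering (identity order when ``cluster``
    is off or a dimension has < 2 entries).
    """
    superclasses: list[str] = []
    for p in profiles:
        for c in p.compounds:
            sc = c.superclass or "Unclassified"
            if sc not in superclasses:
                superclasses.append(sc)
    columns: list[str] = []
    for p in profiles:
        columns.extend(f"{p.species}:{rid}" for rid in p.replicate_ids)
    values = np.zeros((len(superclasses), len(columns)), dtype=int)
    col = 0
    for p in profiles:
        for rid in p.replicate_ids:
            for c in p.compounds:
                if c.areas.get(rid, 0.0) > 0:
                    values[superclasses.index(c.superclass or "Unclassified"), col] += 1
            col += 1
    df = pd.DataFrame(values, index=superclasses, columns=columns)
    row_order = list(range(len(superclasses)))
    col_order = list(range(len(columns)))
    if cluster and len(superclasses) > 1:
        z = sch.linkage(pdist(df.values.astype(float)), method="average")
        row_order = sch.leaves_list(z).tolist()
    if cluster and len(columns) > 1:
        z = sch.linkage(pdist(df.values.T.astype(float)), method="average")
        col_order = sch.leaves_list(z).tolist()
    return df, row_order, col_order
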
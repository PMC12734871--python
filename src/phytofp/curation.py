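"""Expert-concordance scoring of automated superclass assignments.

A model assignment is *confirmed* when its predicted superclass equals the
expert's label after whitespace/case normalization.  Compounds the experts
left unlabelled are reported as *unassigned*; by default they stay in the
denominator (counted unconfirmed), with an alternative mode excluding them —
published concordance percentages are ambiguous about this convention, so
raw counts are always emitted next to the percentage.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .np_classifier import ClassPrediction

__all__ = ["ConcordanceReport", "concordance", "read_expert_labels", "normalize_label"]

_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    return _WS.sub(" ", label.strip()).lower()


@dataclass
class ConcordanceReport:
    species: str
    n_total: int
    n_confirmed: int
    discordant: list[tuple[str, str, str]] = field(default_factory=list)
    unassigned: list[str] = field(default_factory=list)
    include_unassigned: bool = True

    @property
    def concordance_pct(self) -> float:
        """Percent confirmed, rounded to one decimal."""
        if self.n_total == 0:
            return 0.0
        return round(100.0 * self.n_confirmed / self.n_total, 1)

    def summary(self) -> str:
        mode = "incl." if self.include_unassigned else "excl."
        return (
            f"{self.species}: {self.n_confirmed}/{self.n_total} confirmed "
            f"({self.concordance_pct}% concordance, unassigned {mode} denominator; "
            f"{len(self.discordant)} discordant, {len(self.unassigned)} unassigned)"
        )


def concordance(
    predicted: Sequence[ClassPrediction],
    expert: Mapping[str, str],
    species: str = "",
    include_unassigned: bool = True,
) -> ConcordanceReport:
    """Score superclass predictions against expert labels.

    ``expert`` maps compound name -> expert superclass.  With
    ``include_unassigned=True`` (default) compounds missing from the expert
    map count toward the denominator as unconfirmed; otherwise they are
    dropped from the denominator entirely.
    """
    if not predicted:
        raise ValueError("predicted list must be nonempty")
    norm_expert: dict[str, str] = {}
    for name, label in expert.items():
        key = normalize_label(name)
        if key in norm_expert and normalize_label(norm_expert[key]) != normalize_label(label):
            raise ValueError(
                f"conflicting expert labels for {name!r}: "
                f"{norm_expert[key]!r} vs {label!r}"
            )
        norm_expert[key] = label
    confirmed = 0
    discordant: list[tuple[str, str, str]] = []
    unassigned: list[str] = []
    n_total = 0
    for pred in predicted:
        pred_sc = pred.labels.get("superclass", "")
        exp_sc = norm_expert.get(normalize_label(pred.name))
        if exp_sc is None:
            unassigned.append(pred.name)
            if include_unassigned:
                n_total += 1
            continue
        n_total += 1
        if normalize_label(pred_sc) == normalize_label(exp_sc):
            confirmed += 1
        else:
            discordant.append((pred.name, pred_sc, exp_sc))
    return ConcordanceReport(
        species=species,
        n_total=n_total,
        n_confirmed=confirmed,
        discordant=discordant,
        unassigned=unassigned,
        include_unassigned=include_unassigned,
    )


def read_expert_labels(path: str | Path) -> dict[str, str]:
    """Read a (compound, superclass) CSV into an expert label map."""
    labels: dict[str, str] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    if rows and normalize_label(rows[0][0]) in ("compound", "name", "compound_name"):
        rows = rows[1:]
    seen: dict[str, str] = {}
    for row in rows:
        if len(row) < 2 or not row[0].strip():
            continue
        name, label = row[0].strip(), row[1].strip()
        key = normalize_label(name)
        if key in seen and seen[key] != normalize_label(label):
            raise ValueError(f"conflicting expert labels for {name!r}")
        seen[key] = normalize_label(label)
        labels[name] = label
    return labels
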
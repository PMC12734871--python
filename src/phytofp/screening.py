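"""Five-rule metabolite screening and MSI confidence-level assignment.

A detected feature survives screening when it (1) matched at least one of the
five annotation databases, (2) lies within the ppm mass-accuracy gate of the
theoretical m/z for its ionization mode, (3) elutes inside the retention-time
window, (4) exceeds the minimum peak area, and (5) carries an MS2 spectrum.
Each rule is a pure predicate, so the surviving set does not depend on
evaluation order; only the attribution of a failure to its *first* failing
rule does, and that order is fixed (db, ppm, rt, area, ms2).

MSI levels follow the Metabolomics Standards Initiative ladder: level 1 for
standard-confirmed identities with MS2, level 2 for accurate-mass + MS2
database matches, level 3 for database hits lacking MS2, level 4 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .feature_io import FeatureRecord

__all__ = [
    "PROTON_MASS",
    "RULE_ORDER",
    "ScreeningConfig",
    "ScreeningReport",
    "ppm_error",
    "theoretical_mz",
    "record_ppm_error",
    "apply_screening",
    "assign_msi_level",
]

#: Mass of a proton in Da; used for [M+H]+ / [M-H]- theoretical m/z.
PROTON_MASS = 1.007276

#: Fixed failure-attribution order.
RULE_ORDER = ("db", "ppm", "rt", "area", "ms2")


@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds for the five screening rules.

    ``rt_extended``, when set, replaces the [rt_min, rt_max] elution window
    (the workflow allows widening to 0-120 min for special separations).
    ``standards_list`` holds compound names confirmed with authentic
    standards, used for MSI level-1 assignment, not for filtering.
    """

    ppm_tol: float = 3.0
    rt_min: float = 5.0
    rt_max: float = 50.0
    rt_extended: tuple[float, float] | None = None
    area_min: float = 1.0e5
    require_db_hit: bool = True
    require_ms2: bool = True
    standards_list: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.ppm_tol > 0:
            raise ValueError("ppm_tol must be positive")
        if not self.rt_min < self.rt_max:
            raise ValueError("rt_min must be below rt_max")
        if self.area_min < 0:
            raise ValueError("area_min must be nonnegative")
        object.__setattr__(self, "standards_list", frozenset(self.standards_list))

    @property
    def rt_window(self) -> tuple[float, float]:
        return self.rt_extended if self.rt_extended is not None else (self.rt_min, self.rt_max)


@dataclass
class ScreeningReport:
    n_input: int
    n_pass: int
    n_fail_per_rule: dict[str, int]
    passed: list[FeatureRecord]
    errors: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = self.n_pass + sum(self.n_fail_per_rule.values()) + len(self.errors)
        if total != self.n_input:
            raise ValueError(
                f"count conservation violated: {total} != n_input {self.n_input}"
            )


def ppm_error(observed_mz: float, theoretical: float) -> float:
    """Signed relative mass error, (observed - theoretical)/theoretical * 1e6."""
    if not theoretical > 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed_mz - theoretical) / theoretical * 1e6


def theoretical_mz(calc_mw: float, ion_mode: str) -> float:
    """[M+H]+ or [M-H]- m/z from the neutral monoisotopic mass."""
    if ion_mode == "positive":
        return calc_mw + PROTON_MASS
    if ion_mode == "negative":
        return calc_mw - PROTON_MASS
    raise ValueError(f"unknown ion mode {ion_mode!r}")


def record_ppm_error(record: FeatureRecord) -> float:
    return ppm_error(record.precursor_mz, theoretical_mz(record.calc_mw, record.ion_mode))


def _rule_predicates(config: ScreeningConfig) -> dict[str, Callable[[FeatureRecord], bool]]:
    lo, hi = config.rt_window
    return {
        "db": lambda r: bool(r.db_hits) or not config.require_db_hit,
        "ppm": lambda r: abs(record_ppm_error(r)) <= config.ppm_tol,
        "rt": lambda r: lo <= r.rt <= hi,
        "area": lambda r: r.peak_area >= config.area_min,
        "ms2": lambda r: r.has_ms2 or not config.require_ms2,
    }


def apply_screening(
    records: Sequence[FeatureRecord], config: ScreeningConfig = ScreeningConfig()
) -> ScreeningReport:
    """Screen records, attributing each failure to its first failing rule.

    Records that raise while a rule is evaluated (e.g. a nonpositive
    theoretical mass) are collected in ``report.errors`` and excluded.
    """
    preds = _rule_predicates(config)
    passed: list[FeatureRecord] = []
    fails = {rule: 0 for rule in RULE_ORDER}
    errors: list[tuple[int, str]] = []
    for idx, rec in enumerate(records):
        try:
            failing = next((rule for rule in RULE_ORDER if not preds[rule](rec)), None)
        except (ValueError, TypeError) as exc:
            errors.append((idx, str(exc)))
            continue
        if failing is None:
            passed.append(rec)
        else:
            fails[failing] += 1
    return ScreeningReport(
        n_input=len(records),
        n_pass=len(passed),
        n_fail_per_rule=fails,
        passed=passed,
        errors=errors,
    )


def assign_msi_level(record: FeatureRecord, standards_list: Iterable[str] = ()) -> int:
    """MSI annotation-confidence level for one feature.

    1: name on the authentic-standards list and MS2 present.
    2: MS2 present and at least one database hit.
    3: database hit without MS2.
    4: neither.
    """
    standards = set(standards_list)
    if record.compound_name in standards and record.has_ms2:
        return 1
    if record.has_ms2 and record.db_hits:
        return 2
    if record.db_hits:
        return 3
    return 4
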
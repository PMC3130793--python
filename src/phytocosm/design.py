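"""Design enumeration and validation for the factorial metacommunity layout.

A *metacommunity* is a set of three flasks ("patches") sharing species
composition, phosphorus supply and replicate number and differing only in
their N:P supply ratio.  Identifiers are deterministic so outputs are
diffable:

* metacommunity id:  ``P{level}-{composition}-r{replicate}``
* patch id:          ``P{level}-{np_ratio}-{composition}-r{replicate}``

Nitrogen supply is never configured independently: each patch starts at
``n_conc = p_sup * np_ratio`` and fresh exchange medium carries the same
concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import MIXTURE, ConfigurationError, ExperimentConfig

__all__ = [
    "TABLE_COLUMNS",
    "DesignPoint",
    "PatchState",
    "Finding",
    "ValidationReport",
    "enumerate_design",
    "design_frame",
    "initial_patch_state",
    "validate_table",
]

#: Canonical column order of the long-format community table.
TABLE_COLUMNS = (
    "metacommunity_id",
    "patch_id",
    "composition",
    "p_sup_level",
    "p_sup",
    "np_ratio",
    "replicate",
    "species",
    "biovolume_um3_per_ml",
)


def _np_label(np_ratio: float) -> str:
    return str(int(np_ratio)) if float(np_ratio).is_integer() else str(np_ratio)


@dataclass(frozen=True)
class DesignPoint:
    """One flask: its treatment factors and position in the design."""

    metacommunity_id: str
    patch_id: str
    composition: str
    p_sup_level: str
    p_sup: float  # µmol P L⁻¹
    np_ratio: float  # molar N:P of the supply
    replicate: int


@dataclass
class PatchState:
    """Dynamic state of one flask: dissolved nutrients and biovolumes."""

    design: DesignPoint
    volume_ml: float
    n_conc: float  # µmol N L⁻¹
    p_conc: float  # µmol P L⁻¹
    biovolume: dict[str, float]  # species -> µm³ mL⁻¹

    def total_biovolume(self) -> float:
        return float(sum(self.biovolume.values()))


def enumerate_design(config: ExperimentConfig) -> list[DesignPoint]:
    """Enumerate every flask of the design, metacommunity by metacommunity.

    The main block crosses all compositions with the main phosphorus levels;
    the extra block crosses ``extra_compositions`` (normally the mixture
    only) with the extra phosphorus levels.  Within a metacommunity the
    patches run over the configured N:P ratios.
    """
    config.validate()
    points: list[DesignPoint] = []

    def block(p_levels: Sequence[str], comps: Sequence[str]) -> None:
        for lvl in p_levels:
            p_sup = float(config.p_supply[lvl])
            for comp in comps:
                for rep in range(1, config.replicates + 1):
                    mc_id = f"P{lvl}-{comp}-r{rep}"
                    for np_ratio in config.np_ratios:
                        points.append(
                            DesignPoint(
                                metacommunity_id=mc_id,
                                patch_id=f"P{lvl}-{_np_label(np_ratio)}-{comp}-r{rep}",
                                composition=comp,
                                p_sup_level=lvl,
                                p_sup=p_sup,
                                np_ratio=float(np_ratio),
                                replicate=rep,
                            )
                        )

    block(config.main_p_levels, config.compositions)
    block(config.extra_p_levels, config.extra_compositions)
    return points


def design_frame(points: Iterable[DesignPoint]) -> pd.DataFrame:
    """Design points as a DataFrame (one row per flask)."""
    return pd.DataFrame(
        [
            {
                "metacommunity_id": p.metacommunity_id,
                "patch_id": p.patch_id,
                "composition": p.composition,
                "p_sup_level": p.p_sup_level,
                "p_sup": p.p_sup,
                "np_ratio": p.np_ratio,
                "replicate": p.replicate,
            }
            for p in points
        ]
    )


def initial_patch_state(
    dp: DesignPoint,
    traits: Mapping[str, object],
    total_inoculum: float,
    volume_ml: float = 50.0,
) -> PatchState:
    """Starting state of a flask under the substitutive inoculation design.

    A monoculture receives the whole inoculum as the single species; the
    mixture divides it evenly among all species in ``traits``.  Initial
    nitrogen is ``p_sup * np_ratio``.
    """
    if not total_inoculum > 0:
        raise ValueError("total_inoculum must be > 0")
    species = list(traits)
    if dp.composition == MIXTURE:
        share = total_inoculum / len(species)
        biovolume = {sp: share for sp in species}
    elif dp.composition in traits:
        biovolume = {sp: 0.0 for sp in species}
        biovolume[dp.composition] = total_inoculum
    else:
        raise ValueError(f"unknown composition label {dp.composition!r}")
    return PatchState(
        design=dp,
        volume_ml=volume_ml,
        n_conc=dp.p_sup * dp.np_ratio,
        p_conc=dp.p_sup,
        biovolume=biovolume,
    )


# ---------------------------------------------------------------------------
# Table validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Finding:
    """One validation finding; severity is 'error' or 'warning'."""

    kind: str
    severity: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    @property
    def has_errors(self) -> bool:
        return any(f.severity == "error" for f in self.findings)

    def count(self, kind: str) -> int:
        return sum(1 for f in self.findings if f.kind == kind)

    def add(self, kind: str, severity: str, message: str) -> None:
        self.findings.append(Finding(kind, severity, message))

    def summary(self) -> str:
        if self.ok:
            return "table valid: no findings"
        lines = [f"{len(self.findings)} finding(s):"]
        lines += [f"  [{f.severity}] {f.kind}: {f.message}" for f in self.findings]
        return "\n".join(lines)


def validate_table(
    table: pd.DataFrame, config: ExperimentConfig | None = None
) -> ValidationReport:
    """Check a long-format community table; returns a report, never raises.

    Checks: required columns, duplicated flask × species rows, negative
    biovolumes, species labels outside the configured assemblage,
    metacommunities whose patches do not cover all three N:P ratios, and —
    when a config is supplied — design cells missing relative to the full
    enumeration.
    """
    report = ValidationReport()
    missing_cols = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing_cols:
        report.add(
            "missing_columns", "error", f"missing required columns {missing_cols}"
        )
        return report

    dup = table.duplicated(subset=["patch_id", "species"])
    for _, row in table[dup].iterrows():
        report.add(
            "duplicate_row",
            "error",
            f"duplicate row for patch {row.patch_id!r} species {row.species!r}",
        )

    neg = table["biovolume_um3_per_ml"] < 0
    for _, row in table[neg].iterrows():
        report.add(
            "negative_value",
            "error",
            f"negative biovolume {row.biovolume_um3_per_ml} in patch "
            f"{row.patch_id!r} species {row.species!r}",
        )

    known = set(config.species) if config is not None else None
    if known is not None:
        for sp in sorted(set(table["species"]) - known):
            report.add("unknown_species", "error", f"species label {sp!r} not configured")

    expected_np = (
        set(float(x) for x in config.np_ratios) if config is not None else None
    )
    for mc_id, grp in table.groupby("metacommunity_id"):
        ratios = set(float(x) for x in grp["np_ratio"].unique())
        want = expected_np if expected_np is not None else ratios
        if expected_np is not None and ratios != expected_np:
            report.add(
                "incomplete_metacommunity",
                "error",
                f"metacommunity {mc_id!r} covers N:P {sorted(ratios)}, "
                f"expected {sorted(want)}",
            )
        elif expected_np is None and len(ratios) != 3:
            report.add(
                "incomplete_metacommunity",
                "error",
                f"metacommunity {mc_id!r} has {len(ratios)} N:P levels, expected 3",
            )

    if config is not None:
        expected_patches = {p.patch_id for p in enumerate_design(config)}
        seen = set(table["patch_id"].unique())
        for pid in sorted(expected_patches - seen):
            report.add("missing_cell", "error", f"design patch {pid!r} absent from table")

    return report
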
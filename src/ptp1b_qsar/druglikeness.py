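"""Lipinski rule-of-five drug-likeness evaluation.

Criteria, with the inequality directions as conventionally stated: molecular
mass strictly below 500 Da; at most 5 H-bond donors; at most 10 H-bond
acceptors; LogP not greater than 5; and, when a molar refractivity value is
supplied, MR within [40, 130]. The default policy requires every evaluable
criterion to pass; the classical "at most one violation" relaxation is
available via ``policy="lenient"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .compound_data import CompoundRecord, DescriptorTable

__all__ = ["LipinskiVerdict", "lipinski_evaluate", "lipinski_filter", "POLICIES"]

POLICIES = ("strict", "lenient")  # all-must-pass | ≤1 violation


@dataclass(frozen=True)
class LipinskiVerdict:
    """Per-criterion outcomes for one compound under one policy."""

    index: int
    name: str
    criteria: dict[str, bool | None]  # None = not evaluable (MR absent)
    violations: tuple[str, ...]
    policy: str
    passed: bool


def lipinski_evaluate(
    record: CompoundRecord, policy: str = "strict", mr: float | None = None
) -> LipinskiVerdict:
    """Evaluate one compound; the MR criterion is skipped-with-note when absent."""
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}, got {policy!r}")
    criteria: dict[str, bool | None] = {
        "MW<500": record.mw < 500.0,
        "HBD<=5": record.hbd <= 5,
        "HBA<=10": record.hba <= 10,
        "LogP<=5": record.logp <= 5.0,
        "MR40-130": (40.0 <= mr <= 130.0) if mr is not None else None,
    }
    violations = tuple(k for k, ok in criteria.items() if ok is False)
    allowed = 0 if policy == "strict" else 1
    return LipinskiVerdict(
        index=record.index,
        name=record.name,
        criteria=criteria,
        violations=violations,
        policy=policy,
        passed=len(violations) <= allowed,
    )


def lipinski_filter(
    table: DescriptorTable,
    policy: str = "strict",
    mr_values: dict[int, float] | None = None,
) -> tuple[DescriptorTable, list[LipinskiVerdict]]:
    """Filter a table to rule-of-five passers, preserving input order.

    Returns the passing table and the full verdict list for audit.
    ``mr_values`` optionally maps compound index to molar refractivity.
    """
    mr_values = mr_values or {}
    verdicts = [
        lipinski_evaluate(r, policy=policy, mr=mr_values.get(r.index)) for r in table
    ]
    passing = DescriptorTable(
        [r for r, v in zip(table.records, verdicts) if v.passed],
        provenance=f"{table.provenance} | lipinski[{policy}]",
    )
    return passing, verdicts
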
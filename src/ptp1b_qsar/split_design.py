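"""Descriptor-sorted train/test split design.

The splitting scheme sorts the compound table ascending by one descriptor
(ties broken by ascending compound index, i.e. a stable sort) and cuts the
ordering at one of four ratios — 50:50, 70:30, 75:25 or 25:75 — taking the
first ``round-half-to-even(fraction × n)`` compounds as the training set.
"Random sorting" in the published design is original table order; a genuinely
randomized variant is available behind an explicit seed.

The 8 sorting methods × 4 ratios grid over the packaged 46-compound table
regenerates the published membership lists; the handful of typographical slips
in those printed lists live in the errata registry, against which
:func:`verify_against_reference` audits any discrepancy it finds.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Sequence, Union

import numpy as np

from .compound_data import DESCRIPTOR_NAMES, DescriptorTable

__all__ = [
    "SORT_KEYS",
    "RATIOS",
    "SplitSpec",
    "SplitResult",
    "train_size",
    "sorted_split",
    "shuffled_split",
    "enumerate_splits",
    "verify_against_reference",
    "Discrepancy",
    "DiscrepancyReport",
    "load_reference_splits",
    "packaged_reference_splits",
    "ratio_label",
]

#: Sorting methods in the fixed published order.
SORT_KEYS = ("index_order",) + DESCRIPTOR_NAMES

#: Train fractions in the fixed published order.
RATIOS = (0.50, 0.70, 0.75, 0.25)

_RATIO_LABELS = {0.50: "50:50", 0.70: "70:30", 0.75: "75:25", 0.25: "25:75"}


def ratio_label(train_fraction: float) -> str:
    """Human label like ``"70:30"`` for a train fraction."""
    if train_fraction in _RATIO_LABELS:
        return _RATIO_LABELS[train_fraction]
    return f"{round(train_fraction * 100)}:{round((1 - train_fraction) * 100)}"


@dataclass(frozen=True)
class SplitSpec:
    """One sorting method at one train:test ratio."""

    sort_key: str
    train_fraction: float
    allow_any_fraction: bool = False

    def __post_init__(self):
        if self.sort_key not in SORT_KEYS:
            raise ValueError(
                f"unknown sort key {self.sort_key!r}; expected one of {SORT_KEYS}"
            )
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.train_fraction not in RATIOS and not self.allow_any_fraction:
            raise ValueError(
                f"train_fraction {self.train_fraction} is not one of the standard "
                f"ratios {RATIOS}; pass allow_any_fraction=True to override"
            )


@dataclass(frozen=True)
class SplitResult:
    """Ordered train/test memberships produced by one spec."""

    spec: SplitSpec
    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "sort_key": self.spec.sort_key,
            "train_fraction": self.spec.train_fraction,
            "train": list(self.train_indices),
            "test": list(self.test_indices),
        }


def train_size(n: int, train_fraction: float) -> int:
    """Training-set size: banker's rounding of fraction × n, clamped to [1, n−1].

    Round-half-to-even is the only rule reproducing all four published counts
    for n = 46 (23, 32, 34 and 12): round-half-up and floor each miss one.
    """
    if n < 2:
        raise ValueError(f"need at least 2 compounds to split, got {n}")
    k = round(train_fraction * n)  # Python round: half-to-even
    return int(min(max(k, 1), n - 1))


def _sorted_indices(table: DescriptorTable, sort_key: str) -> list[int]:
    if sort_key == "index_order":
        return list(table.indices)
    return [
        r.index
        for r in sorted(table, key=lambda r: (getattr(r, sort_key), r.index))
    ]


def sorted_split(table: DescriptorTable, spec: SplitSpec) -> SplitResult:
    """Sort ascending by the spec's key (stable in compound index) and cut.

    Pure function of (table, spec): repeated calls are identical.
    """
    order = _sorted_indices(table, spec.sort_key)
    k = train_size(len(order), spec.train_fraction)
    return SplitResult(spec, tuple(order[:k]), tuple(order[k:]))


def shuffled_split(
    table: DescriptorTable, train_fraction: float, seed: int
) -> SplitResult:
    """A genuinely randomized split (opt-in; not part of the published design)."""
    rng = np.random.default_rng(seed)
    order = list(table.indices)
    rng.shuffle(order)
    k = train_size(len(order), train_fraction)
    spec = SplitSpec("index_order", train_fraction, allow_any_fraction=True)
    return SplitResult(spec, tuple(order[:k]), tuple(order[k:]))


def enumerate_splits(table: DescriptorTable) -> list[SplitResult]:
    """All 32 splits in fixed order: 8 sorting methods × 4 ratios."""
    if len(table) == 0:
        raise ValueError("cannot split an empty table")
    return [
        sorted_split(table, SplitSpec(key, frac))
        for key in SORT_KEYS
        for frac in RATIOS
    ]


@dataclass(frozen=True)
class Discrepancy:
    """One id mismatching between a computed split and its printed reference."""

    sort_key: str
    ratio: str
    part: str  # "train" | "test"
    id: int
    kind: str  # "missing_in_reference" | "extra_in_reference" | "duplicated_in_reference"
    registered: bool


@dataclass
class DiscrepancyReport:
    discrepancies: list[Discrepancy] = field(default_factory=list)

    @property
    def unregistered(self) -> list[Discrepancy]:
        return [d for d in self.discrepancies if not d.registered]

    def __len__(self) -> int:
        return len(self.discrepancies)


def _registered_ids(errata: Sequence[dict], sort_key: str, ratio: str, part: str) -> set[int]:
    out: set[int] = set()
    for e in errata or ():
        if (
            e.get("table") == "reference_splits"
            and e.get("sort_key") == sort_key
            and e.get("ratio") == ratio
            and e.get("part") == part
        ):
            out.update(e.get("ids", ()))
    return out


def verify_against_reference(
    computed: Sequence[SplitResult],
    reference: dict,
    errata: Sequence[dict] | None = None,
) -> DiscrepancyReport:
    """Compare algorithmic splits with a printed-reference transcription.

    For every (sort_key, ratio, part) present in both, reports ids appearing
    in one list but not the other and ids duplicated in the reference, each
    flagged registered/unregistered against the errata registry.
    """
    ref_map = {
        (s["sort_key"], s["ratio"]): s for s in reference.get("splits", ())
    }
    report = DiscrepancyReport()
    for result in computed:
        key = (result.spec.sort_key, ratio_label(result.spec.train_fraction))
        if key not in ref_map:
            continue
        ref = ref_map[key]
        for part, computed_ids in (
            ("train", result.train_indices),
            ("test", result.test_indices),
        ):
            known = _registered_ids(errata or (), key[0], key[1], part)
            ref_counts = Counter(ref[part])
            comp_set = set(computed_ids)
            for i in sorted(comp_set - set(ref_counts)):
                report.discrepancies.append(
                    Discrepancy(key[0], key[1], part, i, "missing_in_reference", i in known)
                )
            for i in sorted(set(ref_counts) - comp_set):
                report.discrepancies.append(
                    Discrepancy(key[0], key[1], part, i, "extra_in_reference", i in known)
                )
            for i in sorted(i for i, c in ref_counts.items() if c > 1):
                report.discrepancies.append(
                    Discrepancy(key[0], key[1], part, i, "duplicated_in_reference", i in known)
                )
    return report


def load_reference_splits(source: Union[str, Path, IO[str]]) -> dict:
    """Load a JSON transcription of printed split memberships."""
    if hasattr(source, "read"):
        return json.load(source)  # type: ignore[arg-type]
    with open(source) as f:
        return json.load(f)


def packaged_reference_splits() -> dict:
    """The packaged verbatim transcription of the published split lists."""
    path = resources.files(__package__).joinpath("data", "reference_splits.json")
    with resources.as_file(path) as p:
        return load_reference_splits(p)
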
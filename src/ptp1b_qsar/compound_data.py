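"""Data model and I/O for compound descriptor/activity and binding-affinity tables.

The central container is :class:`DescriptorTable`, an ordered collection of
:class:`CompoundRecord` holding one flavonoid's measured PTP1B inhibitory
activity (IC50 in μM, and its base-10 log) together with seven molecular
descriptors: molecular weight (MW, g/mol), hydrogen-bond acceptor and donor
counts (HBA, HBD), rotatable-bond count (nrot), aromatic-bond count (naro),
topological polar surface area (TPSA, Å²) and the octanol–water partition
coefficient (LogP).

The packaged reference dataset of 46 antidiabetic flavonoids is transcribed
from published values; printed inconsistencies (duplicate rows, conflicting
molecular weights) are preserved verbatim and documented in a machine-readable
errata registry rather than silently corrected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

import pandas as pd

__all__ = [
    "DESCRIPTOR_NAMES",
    "DESCRIPTOR_COLUMNS",
    "CompoundRecord",
    "DescriptorTable",
    "BindingRecord",
    "Finding",
    "SchemaError",
    "RecordValidationError",
    "compute_log_ic50",
    "load_descriptor_table",
    "write_descriptor_table",
    "load_binding_table",
    "write_binding_table",
    "validate_table",
    "load_errata",
    "packaged_flavonoid_table",
    "packaged_binding_table",
    "packaged_errata",
]

#: Descriptor names in canonical (model-equation) order.
DESCRIPTOR_NAMES = ("mw", "hba", "hbd", "nrot", "naro", "tpsa", "logp")

#: Canonical CSV column order for descriptor tables.
DESCRIPTOR_COLUMNS = ("index", "name", "ic50_uM", "log_ic50") + DESCRIPTOR_NAMES

_INTEGER_DESCRIPTORS = frozenset({"hba", "hbd", "nrot", "naro"})

#: Tolerance for |log_ic50 - log10(ic50)| accepted as printed-value rounding.
LOG_CONSISTENCY_TOL = 0.002


class SchemaError(ValueError):
    """An input table is missing a required column."""


class RecordValidationError(ValueError):
    """A single row violates the data model; carries the offending row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class CompoundRecord:
    """One compound with activity and the seven molecular descriptors."""

    index: int
    name: str
    ic50: float  # μM, central value when printed as mean ± sd
    log_ic50: float  # log10(μM), printed value (not recomputed)
    mw: float
    hba: int
    hbd: int
    nrot: int
    naro: int
    tpsa: float
    logp: float

    def __post_init__(self):
        if self.index <= 0:
            raise RecordValidationError(self.index, "compound index must be positive")
        if not (self.ic50 > 0):
            raise RecordValidationError(self.index, f"IC50 must be positive, got {self.ic50}")
        for name in ("mw", "tpsa"):
            if getattr(self, name) < 0:
                raise RecordValidationError(self.index, f"{name} must be non-negative")
        for name in _INTEGER_DESCRIPTORS:
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise RecordValidationError(
                    self.index, f"{name} must be a non-negative integer, got {v!r}"
                )
        for name in ("ic50", "log_ic50", "mw", "tpsa", "logp"):
            if not math.isfinite(getattr(self, name)):
                raise RecordValidationError(self.index, f"{name} must be finite")

    def descriptor_vector(self) -> tuple[float, ...]:
        """The seven descriptors in canonical order."""
        return tuple(float(getattr(self, d)) for d in DESCRIPTOR_NAMES)


@dataclass
class DescriptorTable:
    """Ordered compound table; record order preserves input order."""

    records: list[CompoundRecord]
    provenance: str = ""

    def __post_init__(self):
        ids = [r.index for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound indices: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    @property
    def indices(self) -> list[int]:
        return [r.index for r in self.records]

    def record(self, index: int) -> CompoundRecord:
        for r in self.records:
            if r.index == index:
                return r
        raise KeyError(f"no compound with index {index}")

    def subset(self, indices: Iterable[int]) -> "DescriptorTable":
        """Records in the order of ``indices`` (not input order)."""
        return DescriptorTable([self.record(i) for i in indices], provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(r) for r in self.records])
        return df.rename(columns={"ic50": "ic50_uM"})[list(DESCRIPTOR_COLUMNS)]


@dataclass(frozen=True)
class BindingRecord:
    """One ligand's predicted binding thermodynamics.

    ``pkd`` is −log10 of the dissociation constant; ``delta_g`` the binding
    free energy in kcal/mol; ``ligand_efficiency`` is ΔG per heavy atom.
    ``n_heavy`` is the heavy (non-hydrogen) atom count, absent when unknown.
    Printed standard deviations are stored but consumed by no computation.
    """

    name: str
    mw: float
    pkd: float
    delta_g: float
    ligand_efficiency: float
    n_heavy: int | None = None
    n_heavy_provenance: str = ""
    pkd_std: float | None = None
    delta_g_std: float | None = None
    ligand_efficiency_std: float | None = None


@dataclass(frozen=True)
class Finding:
    """One validation finding; findings are data, not failures."""

    kind: str  # "log_inconsistency" | "duplicate_row" | "out_of_range"
    row: int
    detail: str


def compute_log_ic50(ic50: float) -> float:
    """log10 of an IC50 in μM.

    Used for validating printed LogIC50 columns and for synthetic data; the
    regression itself consumes the printed LogIC50 values as-is.
    """
    if not (ic50 > 0) or not math.isfinite(ic50):
        raise ValueError(f"IC50 must be a positive finite concentration, got {ic50}")
    return math.log10(ic50)


def _central_value(raw) -> float:
    """Strip a '± sd' suffix, keeping the central value."""
    if isinstance(raw, str) and "±" in raw:
        raw = raw.split("±")[0]
    return float(raw)


def load_descriptor_table(source: Union[str, Path, IO[str]], provenance: str = "") -> DescriptorTable:
    """Read a descriptor/activity table from the canonical CSV dialect.

    Header: ``index,name,ic50_uM,log_ic50,mw,hba,hbd,nrot,naro,tpsa,logp``.
    IC50 cells may carry a "value ± sd" suffix; only the central value is kept.
    """
    df = pd.read_csv(source, dtype={"name": str})
    missing = [c for c in DESCRIPTOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        idx = int(row["index"])
        try:
            ic50 = _central_value(row["ic50_uM"])
        except (TypeError, ValueError):
            raise RecordValidationError(idx, f"non-numeric IC50: {row['ic50_uM']!r}") from None
        records.append(
            CompoundRecord(
                index=idx,
                name=str(row["name"]),
                ic50=ic50,
                log_ic50=float(row["log_ic50"]),
                mw=float(row["mw"]),
                hba=int(row["hba"]),
                hbd=int(row["hbd"]),
                nrot=int(row["nrot"]),
                naro=int(row["naro"]),
                tpsa=float(row["tpsa"]),
                logp=float(row["logp"]),
            )
        )
    src = getattr(source, "name", str(source))
    return DescriptorTable(records, provenance=provenance or src)


def write_descriptor_table(table: DescriptorTable, dest: Union[str, Path, IO[str]]) -> None:
    """Write a table in the canonical CSV dialect (round-trips with the loader)."""
    table.to_frame().to_csv(dest, index=False)


def load_binding_table(source: Union[str, Path, IO[str]]) -> list[BindingRecord]:
    """Read a binding-affinity table (name, mw, pkd, ΔG, ligand efficiency, n_heavy)."""
    df = pd.read_csv(source)
    required = ["name", "mw", "pkd", "delta_g_kcal_mol", "ligand_efficiency"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    def _opt(row, col, cast=float):
        if col not in row or pd.isna(row[col]):
            return None
        return cast(row[col])

    records = []
    for _, row in df.iterrows():
        records.append(
            BindingRecord(
                name=str(row["name"]),
                mw=float(row["mw"]),
                pkd=float(row["pkd"]),
                delta_g=float(row["delta_g_kcal_mol"]),
                ligand_efficiency=float(row["ligand_efficiency"]),
                n_heavy=_opt(row, "n_heavy", int),
                n_heavy_provenance=str(row.get("n_heavy_provenance", "") or "")
                if not pd.isna(row.get("n_heavy_provenance", ""))
                else "",
                pkd_std=_opt(row, "pkd_std"),
                delta_g_std=_opt(row, "delta_g_std"),
                ligand_efficiency_std=_opt(row, "ligand_efficiency_std"),
            )
        )
    return records


def write_binding_table(records: list[BindingRecord], dest: Union[str, Path, IO[str]]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "name": r.name,
                "mw": r.mw,
                "pkd": r.pkd,
                "pkd_std": r.pkd_std,
                "delta_g_kcal_mol": r.delta_g,
                "delta_g_std": r.delta_g_std,
                "ligand_efficiency": r.ligand_efficiency,
                "ligand_efficiency_std": r.ligand_efficiency_std,
                "n_heavy": r.n_heavy,
                "n_heavy_provenance": r.n_heavy_provenance,
            }
        )
    pd.DataFrame(rows).to_csv(dest, index=False)


def validate_table(table: DescriptorTable) -> list[Finding]:
    """Audit a loaded table; never mutates it.

    Reports (a) printed LogIC50 values inconsistent with log10(IC50) beyond
    rounding level, (b) duplicate descriptor rows (identical values under
    different indices), and (c) descriptors outside plausible physical ranges.
    """
    findings: list[Finding] = []
    for r in table:
        if abs(r.log_ic50 - compute_log_ic50(r.ic50)) > LOG_CONSISTENCY_TOL:
            findings.append(
                Finding(
                    "log_inconsistency",
                    r.index,
                    f"log_ic50 {r.log_ic50} vs log10(ic50) {compute_log_ic50(r.ic50):.4f}",
                )
            )
    seen: dict[tuple, int] = {}
    for r in table:
        key = (r.name, r.ic50, r.log_ic50) + r.descriptor_vector()
        if key in seen:
            findings.append(
                Finding("duplicate_row", r.index, f"identical to row {seen[key]} ({r.name})")
            )
        else:
            seen[key] = r.index
    for r in table:
        if r.mw > 2000 or r.tpsa > 1000 or abs(r.logp) > 20:
            findings.append(Finding("out_of_range", r.index, "descriptor outside plausible range"))
    return findings


# -- packaged fixtures -------------------------------------------------------

def _data_path(filename: str):
    return resources.files(__package__).joinpath("data", filename)


def packaged_flavonoid_table() -> DescriptorTable:
    """The packaged 46-flavonoid descriptor/activity table."""
    with resources.as_file(_data_path("flavonoid_descriptors.csv")) as p:
        return load_descriptor_table(p, provenance="packaged flavonoid descriptor table")


def packaged_binding_table() -> list[BindingRecord]:
    """The packaged 27-ligand binding-affinity table (polyphenols + synthetic drugs)."""
    with resources.as_file(_data_path("binding_affinity.csv")) as p:
        return load_binding_table(p)


def packaged_errata() -> list[dict]:
    with resources.as_file(_data_path("errata.json")) as p:
        return load_errata(p)


def load_errata(source: Union[str, Path]) -> list[dict]:
    """The errata registry: a JSON list of documented printed inconsistencies."""
    with open(source) as f:  # type: ignore[arg-type]
        return json.load(f)
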
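"""Seeded generators emulating the statistical structure of the analysis.

``generate_descriptor_table`` draws descriptor vectors uniformly over the
empirical ranges of the packaged flavonoid table (integer descriptors as
integer-uniform) and builds the response from a known linear model,
LogIC50 = β0 + Σβᵢxᵢ + ε with Gaussian noise, so regression code can be
tested against ground truth. ``generate_binding_table`` emits (pKd, ΔG,
n_heavy, LE) records exactly consistent with the Gibbs relation ΔG = −c·pKd.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so one
integer seed fully determines output across platforms. Descriptors are drawn
independently by default — no stage under test depends on descriptor
correlation — but a correlation matrix hook (Gaussian copula) is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .compound_data import (
    DESCRIPTOR_NAMES,
    BindingRecord,
    CompoundRecord,
    DescriptorTable,
)

__all__ = ["DEFAULT_RANGES", "DEFAULT_BETA", "SyntheticSpec", "generate_descriptor_table", "generate_binding_table"]

#: Empirical descriptor ranges of the packaged 46-flavonoid table.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "mw": (110.0, 701.0),
    "hba": (2, 16),
    "hbd": (0, 9),
    "nrot": (0, 10),
    "naro": (1, 24),
    "tpsa": (40.0, 259.0),
    "logp": (-1.4, 10.4),
}

_INTEGER_DESCRIPTORS = ("hba", "hbd", "nrot", "naro")

#: Default true model: modest per-descriptor effects scaled so LogIC50 spans
#: roughly the observed −0.1..1.8 range over the default descriptor ranges.
DEFAULT_BETA: dict[str, float] = {
    "intercept": 0.4,
    "mw": 0.0008,
    "hba": -0.04,
    "hbd": 0.03,
    "nrot": -0.02,
    "naro": 0.02,
    "tpsa": 0.002,
    "logp": -0.05,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration for one synthetic descriptor table."""

    n: int = 46
    descriptor_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma: float = 0.1
    seed: int = 0
    correlation: np.ndarray | None = None  # optional 7×7 descriptor correlation

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if set(self.descriptor_ranges) != set(DESCRIPTOR_NAMES):
            raise ValueError(f"descriptor_ranges must cover exactly {DESCRIPTOR_NAMES}")
        for d, (lo, hi) in self.descriptor_ranges.items():
            if lo > hi:
                raise ValueError(f"invalid range for {d}: ({lo}, {hi})")
        expected = {"intercept", *DESCRIPTOR_NAMES}
        if set(self.beta) != expected:
            raise ValueError(f"beta must name intercept plus {DESCRIPTOR_NAMES}")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if c.shape != (7, 7) or not np.allclose(c, c.T):
                raise ValueError("correlation must be a symmetric 7×7 matrix")


def _draw_descriptors(spec: SyntheticSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Uniform draws over ranges; Gaussian copula when a correlation is given."""
    if spec.correlation is None:
        uniforms = {d: rng.uniform(size=spec.n) for d in DESCRIPTOR_NAMES}
    else:
        z = rng.multivariate_normal(
            np.zeros(7), np.asarray(spec.correlation, dtype=float), size=spec.n,
            method="cholesky",
        )
        u = stats.norm.cdf(z)
        uniforms = {d: u[:, j] for j, d in enumerate(DESCRIPTOR_NAMES)}
    out: dict[str, np.ndarray] = {}
    for d in DESCRIPTOR_NAMES:
        lo, hi = spec.descriptor_ranges[d]
        if d in _INTEGER_DESCRIPTORS:
            # integer-uniform over [lo, hi] inclusive
            out[d] = np.floor(uniforms[d] * (int(hi) - int(lo) + 1)).astype(int) + int(lo)
            out[d] = np.minimum(out[d], int(hi))
        else:
            out[d] = lo + uniforms[d] * (hi - lo)
    return out


def generate_descriptor_table(spec: SyntheticSpec) -> tuple[DescriptorTable, dict[str, float]]:
    """A synthetic descriptor table plus the true coefficient vector.

    LogIC50 = β0 + Σβᵢxᵢ + ε with ε ~ Normal(0, σ²); IC50 = 10^LogIC50, so
    activity and log-activity are exactly consistent. Fully reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    x = _draw_descriptors(spec, rng)
    signal = np.full(spec.n, spec.beta["intercept"], dtype=float)
    for d in DESCRIPTOR_NAMES:
        signal += spec.beta[d] * x[d].astype(float)
    noise = rng.normal(0.0, spec.sigma, size=spec.n) if spec.sigma > 0 else np.zeros(spec.n)
    log_ic50 = signal + noise
    records = [
        CompoundRecord(
            index=i + 1,
            name=f"synthetic-{i + 1}",
            ic50=float(10.0 ** log_ic50[i]),
            log_ic50=float(log_ic50[i]),
            mw=float(x["mw"][i]),
            hba=int(x["hba"][i]),
            hbd=int(x["hbd"][i]),
            nrot=int(x["nrot"][i]),
            naro=int(x["naro"][i]),
            tpsa=float(x["tpsa"][i]),
            logp=float(x["logp"][i]),
        )
        for i in range(spec.n)
    ]
    table = DescriptorTable(records, provenance=f"synthetic(seed={spec.seed}, n={spec.n}, sigma={spec.sigma})")
    return table, dict(spec.beta)


def generate_binding_table(n: int, c: float = 1.3503, seed: int = 0) -> list[BindingRecord]:
    """Synthetic binding records exactly consistent with ΔG = −c·pKd.

    pKd ~ Uniform(2, 6.5), n_heavy ~ integer-uniform(8, 40), LE = ΔG/n_heavy.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if c <= 0:
        raise ValueError("conversion constant must be positive")
    rng = np.random.default_rng(seed)
    pkd = rng.uniform(2.0, 6.5, size=n)
    n_heavy = rng.integers(8, 41, size=n)
    records = []
    for i in range(n):
        dg = -c * float(pkd[i])
        records.append(
            BindingRecord(
                name=f"synthetic-ligand-{i + 1}",
                mw=float(n_heavy[i]) * 13.5,  # rough heavy-atom mass scale
                pkd=float(pkd[i]),
                delta_g=dg,
                ligand_efficiency=dg / int(n_heavy[i]),
                n_heavy=int(n_heavy[i]),
                n_heavy_provenance="synthetic",
            )
        )
    return records
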
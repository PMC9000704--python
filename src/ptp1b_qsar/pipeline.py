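"""End-to-end pipeline tying the analysis stages together.

``run_pipeline`` loads (or defaults to the packaged) descriptor and binding
tables and emits, under one output directory: the 32 split listings, the
model-selection grid, the best-model equation report, Lipinski verdicts, the
ligand-efficiency ranking, a scatter of aromatic-bond count against LogIC50
with its univariate least-squares line, and a run log echoing configuration.
All CSV/JSON artifacts are deterministic functions of (inputs, config, seed);
plots are excluded from the byte-level determinism contract.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .binding_thermo import ThermoParams, calibrate_conversion, rank_by_efficiency
from .compound_data import (
    DescriptorTable,
    load_binding_table,
    load_descriptor_table,
    packaged_binding_table,
    packaged_errata,
    packaged_flavonoid_table,
)
from .druglikeness import lipinski_filter
from .qsar_regression import (
    equation_report,
    fit_ols,
    model_selection_grid,
    percent,
)
from .split_design import (
    enumerate_splits,
    packaged_reference_splits,
    verify_against_reference,
)

logger = logging.getLogger("ptp1b_qsar")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    descriptor_table: str | Path | None = None  # None → packaged fixture
    binding_table: str | Path | None = None
    output_dir: str | Path = "results"
    lipinski_policy: str = "strict"
    test_r2_definition: str = "det"
    temperature: float | None = None
    conversion_constant: float | None = None
    seed: int = 0
    verbosity: str = "INFO"

    def thermo_params(self) -> ThermoParams:
        if self.temperature is not None and self.conversion_constant is not None:
            raise ValueError("give either temperature or conversion constant, not both")
        return ThermoParams(c=self.conversion_constant, temperature=self.temperature)


def _load_inputs(config: RunConfig):
    if config.descriptor_table is None:
        table = packaged_flavonoid_table()
    else:
        p = Path(config.descriptor_table)
        if not p.exists():
            raise FileNotFoundError(f"descriptor table not found: {p}")
        table = load_descriptor_table(p)
    if config.binding_table is None:
        binding = packaged_binding_table()
    else:
        p = Path(config.binding_table)
        if not p.exists():
            raise FileNotFoundError(f"binding table not found: {p}")
        binding = load_binding_table(p)
    return table, binding


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage; returns a name → path map of the artifacts written.

    Any stage failure raises :class:`PipelineError`; artifacts written by
    earlier stages are retained.
    """
    logging.basicConfig(stream=sys.stderr, level=config.verbosity.upper(), force=False)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    stage = "load"
    try:
        table, binding = _load_inputs(config)
        logger.info("loaded %d compounds, %d binding records", len(table), len(binding))

        stage = "splits"
        splits = enumerate_splits(table)
        path = out / "splits.json"
        path.write_text(json.dumps([s.to_dict() for s in splits], indent=1))
        artifacts["splits"] = path
        report = verify_against_reference(splits, packaged_reference_splits(), packaged_errata())
        path = out / "split_discrepancies.json"
        path.write_text(
            json.dumps(
                {
                    "total": len(report.discrepancies),
                    "unregistered": len(report.unregistered),
                    "discrepancies": [vars(d) for d in report.discrepancies],
                },
                indent=1,
            )
        )
        artifacts["split_discrepancies"] = path

        stage = "grid"
        grid = model_selection_grid(table)
        path = out / "model_selection_grid.csv"
        grid.to_csv(path, index=False, float_format="%.6f")
        artifacts["grid"] = path
        path = out / "model_selection_grid.json"
        path.write_text(grid.to_json(orient="records", indent=1))
        artifacts["grid_json"] = path

        stage = "equation"
        est = grid.dropna(subset=["r2_train"])
        best = est.sort_values(["r2_train"], ascending=False).iloc[0]
        from .split_design import SplitSpec, sorted_split

        frac = {"50:50": 0.50, "70:30": 0.70, "75:25": 0.75, "25:75": 0.25}[best["ratio"]]
        spec = SplitSpec(best["sort_key"], frac)
        split = sorted_split(table, spec)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            model, stats = fit_ols(table, split.train_indices, fitted_on=spec)
        path = out / "best_model_equation.txt"
        path.write_text(
            equation_report(model)
            + f"\n# fitted on {best['sort_key']} {best['ratio']} training set "
            f"(n={stats.n}); R² = {percent(stats.r2)}%, adjusted R² = {percent(stats.adjusted_r2)}%\n"
        )
        artifacts["equation"] = path
        logger.info(
            "best training fit: %s %s R²=%.2f%%", best["sort_key"], best["ratio"], best["r2_train"] * 100
        )

        stage = "lipinski"
        passing, verdicts = lipinski_filter(table, policy=config.lipinski_policy)
        import pandas as pd

        vdf = pd.DataFrame(
            [
                {
                    "index": v.index,
                    "name": v.name,
                    **{k: ("" if ok is None else bool(ok)) for k, ok in v.criteria.items()},
                    "violations": ";".join(v.violations),
                    "pass": v.passed,
                }
                for v in verdicts
            ]
        )
        path = out / "lipinski_verdicts.csv"
        vdf.to_csv(path, index=False)
        artifacts["lipinski"] = path
        logger.info("lipinski[%s]: %d/%d pass", config.lipinski_policy, len(passing), len(table))

        stage = "thermo"
        params = config.thermo_params()
        calib = calibrate_conversion(binding)
        ranked = rank_by_efficiency(binding)
        rdf = pd.DataFrame(
            [
                {"rank": i + 1, "name": r.name, "ligand_efficiency": r.ligand_efficiency}
                for i, r in enumerate(ranked)
            ]
        )
        path = out / "ligand_efficiency_ranking.csv"
        rdf.to_csv(path, index=False)
        artifacts["ranking"] = path
        path = out / "thermo_calibration.json"
        path.write_text(
            json.dumps(
                {
                    "configured_c": params.c,
                    "calibrated_c": calib.c,
                    "max_abs_residual": calib.max_abs_residual,
                },
                indent=1,
            )
        )
        artifacts["calibration"] = path

        stage = "plot"
        artifacts["scatter"] = _naro_scatter(table, out / "naro_vs_logic50.png")

        stage = "log"
        path = out / "run_log.json"
        path.write_text(
            json.dumps(
                {
                    "package_version": __version__,
                    "seed": config.seed,
                    "config": {
                        k: (str(v) if isinstance(v, Path) else v)
                        for k, v in vars(config).items()
                    },
                },
                indent=1,
            )
        )
        artifacts["run_log"] = path
    except Exception as exc:  # noqa: BLE001 - stage name is the useful context
        logger.error("stage %r failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
    return artifacts


def _naro_scatter(table: DescriptorTable, path: Path) -> Path:
    """Aromatic-bond count vs LogIC50 with the univariate least-squares line.

    The univariate r² annotated here is a descriptive aid; the model-selection
    grid's figures come from the full seven-descriptor regression.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([r.naro for r in table], dtype=float)
    y = np.array([r.log_ic50 for r in table])
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18, alpha=0.8)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, intercept + slope * xs, lw=1.2)
    ax.set_xlabel("aromatic bond count (naro)")
    ax.set_ylabel("LogIC50 (log10 μM)")
    ax.set_title(f"univariate fit: r² = {r**2:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
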
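"""End-to-end orchestration: spectra -> features -> selection -> models.

``run_pipeline`` sequences the full analysis — synthesize (or read) spectra,
remove the fluorescence background by the zero-phase-filter difference,
measure the crest descriptors, assemble the feature table, run the four
selection variants (Initial passthrough, SKB, RFE, SFM), evaluate the
selector x model accuracy grid on a stratified 7:3 split, and attribute the
selected crests to grain constituents — writing each stage's table under the
output directory along with a JSON run summary that records every seed and
parameter needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import crests as _crests
from . import io as _io
from .attribution import attribute_features, rank_substances
from .classify import ForestConfig, evaluate_grid, train_test_split
from .preprocessing import correct_trace
from .selection import (
    SelectionResult,
    initial_select,
    rfe_select,
    select_k_best,
    selection_table,
    sfm_select,
)
from .synthetic import RamanSpectrum, SyntheticConfig, generate_dataset

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "feature_table_from_spectra"]

log = logging.getLogger("raman_rice")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run; defaults mirror the study design."""

    input_mode: str = "synthetic"  # "synthetic" | "files"
    manifest: str | None = None  # required in file mode
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    filter_order: int = 3
    filter_cutoff: float = 0.05
    min_prominence: float = 10.0
    rel_height: float = 0.5
    height_convention: str = "relative"
    match_tolerance: float = 30.0  # cm^-1
    skb_k: int = 10
    mi_bins: int = 8
    cv_folds: int = 5
    sfm_threshold: float | str = "mean"
    forest: ForestConfig = field(default_factory=ForestConfig)
    rfe_forest: ForestConfig | None = None  # smaller forest for RFE's CV, optional
    train_fraction: float = 0.7
    split_seed: int = 0
    selection_seed: int = 0
    fit_selector_on_all: bool = False
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        if "synthetic" in raw:
            raw["synthetic"] = SyntheticConfig(**{
                k: (tuple(v) if isinstance(v, list) else v) for k, v in raw["synthetic"].items()
            })
        for key in ("forest", "rfe_forest"):
            if raw.get(key) is not None:
                raw[key] = ForestConfig(**raw[key])
        return cls(**raw)

    def to_jsonable(self) -> dict[str, Any]:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if hasattr(o, "tolist"):
                return o.tolist()
            return str(o)

        return json.loads(json.dumps(dataclasses.asdict(self), default=default))


def feature_table_from_spectra(
    spectra: list[RamanSpectrum], config: PipelineConfig
) -> pd.DataFrame:
    """Preprocess every spectrum and assemble the N x 31 feature table."""
    samples = []
    for sp in spectra:
        corrected = correct_trace(
            sp.shifts, sp.intensity, order=config.filter_order, cutoff=config.filter_cutoff
        )
        peaks = _crests.detect_peaks(
            corrected,
            min_prominence=config.min_prominence,
            rel_height=config.rel_height,
            height_convention=config.height_convention,
        )
        features = _crests.match_reference_crests(
            peaks,
            reference_shifts=config.synthetic.reference_shifts,
            tolerance=config.match_tolerance,
        )
        samples.append((sp, features))
    return _crests.build_feature_table(samples, config.synthetic.reference_shifts)


def _selectors(config: PipelineConfig) -> dict:
    rfe_forest = config.rfe_forest or config.forest
    return {
        "Initial": initial_select,
        "SKB": lambda t: select_k_best(t, k=config.skb_k, n_bins=config.mi_bins),
        "RFE": lambda t: rfe_select(
            t, forest=rfe_forest, cv_folds=config.cv_folds, seed=config.selection_seed
        ),
        "SFM": lambda t: sfm_select(
            t, forest=config.forest, threshold=config.sfm_threshold, seed=config.selection_seed
        ),
    }


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage; returns the run summary (also written as JSON)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"config": config.to_jsonable(), "stages": {}}

    def stage(name: str):
        log.info("stage %s", name)
        return name

    try:
        name = stage("spectra")
        if config.input_mode == "synthetic":
            spectra = generate_dataset(config.synthetic)
        elif config.input_mode == "files":
            if not config.manifest:
                raise PipelineError("file mode requires a manifest path")
            spectra = _io.read_manifest(config.manifest)
        else:
            raise PipelineError(f"unknown input mode {config.input_mode!r}")
        summary["stages"][name] = {"n_spectra": len(spectra)}

        name = stage("features")
        table = feature_table_from_spectra(spectra, config)
        table.to_csv(out / "feature_table.csv", index=False)
        summary["stages"][name] = {"rows": len(table), "columns": len(table.columns)}

        name = stage("selection")
        results: dict[str, SelectionResult] = {}
        for method, selector in _selectors(config).items():
            results[method] = selector(table)
        sel_table = selection_table(list(results.values()))
        sel_table.to_csv(out / "selection_table.csv", index=False)
        summary["stages"][name] = {
            m: {
                "n_selected": r.n_selected,
                "feature_select_rate": r.feature_select_rate,
                "crest_select_rate": r.crest_select_rate,
                "selected_columns": list(r.selected_columns),
            }
            for m, r in results.items()
        }

        name = stage("classification")
        split = train_test_split(
            table, train_fraction=config.train_fraction, seed=config.split_seed
        )
        grid = evaluate_grid(
            table,
            _selectors(config),
            split,
            forest=config.forest,
            fit_selector_on_all=config.fit_selector_on_all,
        )
        grid.to_csv(out / "accuracy_grid.csv", index=False)
        summary["stages"][name] = {
            "n_train": int(split.train_index.size),
            "n_test": int(split.test_index.size),
            "grid": grid.to_dict(orient="records"),
        }

        name = stage("attribution")
        best_row = grid.loc[grid["RFM"].idxmax()]
        best_method = str(best_row["Feature Selection"])
        report = attribute_features(results[best_method])
        report.to_csv(out / "attribution.csv", index=False)
        ranking = rank_substances(results[best_method])
        summary["stages"][name] = {
            "based_on": best_method,
            "substance_ranking": ranking,
            "top_substance": ranking[0][0] if ranking else None,
        }
    except PipelineError:
        summary["failed_stage"] = name
        (out / "FAILED").write_text(name)
        raise
    except Exception as exc:
        summary["failed_stage"] = name
        (out / "FAILED").write_text(f"{name}: {exc}")
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
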
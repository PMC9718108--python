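"""End-to-end orchestration: landmarks + clinical table -> result bundle.

Stage order mirrors the analysis design: load and validate inputs, exclude
hips with radiographic OA (KL > 0), mirror left hips into the right-hip
convention, split by sex, run GPA and fit a per-sex shape model, standardize
and select modes, dichotomize the MRI outcomes, and scan per-mode GEE
associations per sex and outcome.  Outputs are plain-text artifacts: CSV
tables (variance, associations, cohort summary, standardized scores), mode
shapes at +/- k SD as .pts files, and a JSON run manifest.  Reruns with the
same seed produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import bonferroni_alpha, run_association_scan
from .clinical import add_outcome_flags, cohort_summary, exclude_kl, summary_frame
from .io import (
    LandmarkConfiguration,
    read_hip_table,
    read_points_dir,
    records_to_frame,
    write_points_file,
)
from .procrustes import generalized_procrustes, mirror_left
from .shape_model import (
    fit_shape_model,
    mode_shape_at,
    select_modes,
    variance_table,
)
from .synthetic import GeneratorConfig, simulate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage label."""


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Provide either a :class:`~hipshape.synthetic.GeneratorConfig` (synthetic
    cohort) or both ``landmark_dir`` and ``clinical_table``.  ``seed``, when
    given, overrides the generator's seed.
    """

    out_dir: str
    landmark_dir: str | None = None
    clinical_table: str | None = None
    generator: GeneratorConfig | None = None
    variance_threshold: float = 0.01
    working: str = "exchangeable"
    viz_sds: float = 3.0
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.variance_threshold < 1:
            raise ValueError("variance_threshold must lie in (0, 1)")
        has_files = self.landmark_dir is not None and self.clinical_table is not None
        if (self.generator is None) == (not has_files):
            pass
        if self.generator is None and not has_files:
            raise ValueError(
                "either a generator config or both landmark_dir and "
                "clinical_table must be provided"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            for key in ("effect_spec", "labral_effect_spec"):
                if key in gen:
                    gen[key] = tuple((int(m), float(b)) for m, b in gen[key])
            for key in ("scale_range", "status_probs"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            cfg.generator = GeneratorConfig(**gen)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            g = dataclasses.asdict(self.generator)
            g["effect_spec"] = [list(e) for e in self.generator.effect_spec]
            g["labral_effect_spec"] = [list(e) for e in self.generator.labral_effect_spec]
            g["scale_range"] = list(self.generator.scale_range)
            g["status_probs"] = list(self.generator.status_probs)
            d["generator"] = g
        return d


def _sd_label(k: float) -> str:
    if k == 0:
        return "mean"
    sign = "plus" if k > 0 else "minus"
    mag = abs(k)
    mag_txt = f"{int(mag)}" if float(mag).is_integer() else f"{mag:g}".replace(".", "p")
    return f"{sign}{mag_txt}sd"


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns paths and in-memory results.

    Any stage error aborts with a stage-labelled :class:`PipelineError` and
    removes the files written during this run.
    """
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    captured_warnings: list[str] = []
    config_echo = cfg.to_dict()
    config_echo.pop("out_dir", None)  # run content must not depend on the target path
    manifest: dict = {
        "package": "hipshape",
        "version": __version__,
        "config": config_echo,
        "stages": {},
        "warnings": captured_warnings,
    }
    results: dict = {"out_dir": out_dir, "manifest": manifest}

    def track(path: Path) -> Path:
        created.append(path)
        return path

    stage = "load"
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")

            if cfg.generator is not None:
                gen = cfg.generator
                if cfg.seed is not None:
                    gen = dataclasses.replace(gen, seed=cfg.seed)
                configs, table, truth = simulate_cohort(gen)
                results["truth"] = truth
                manifest["stages"]["load"] = {
                    "source": "synthetic", "seed": gen.seed, "n_hips": len(configs)
                }
            else:
                configs = read_points_dir(cfg.landmark_dir)
                records = read_hip_table(cfg.clinical_table)
                table = records_to_frame(records)
                manifest["stages"]["load"] = {
                    "source": "files", "n_hips": len(configs)
                }

            table = table.copy()
            table["hip_id"] = table["participant_id"] + "_" + table["side"]
            by_id = {c.hip_id: c for c in configs}
            missing = sorted(set(table["hip_id"]) - set(by_id))
            if missing:
                raise ValueError(f"hips in clinical table without landmarks: {missing[:5]}")
            extra = sorted(set(by_id) - set(table["hip_id"]))
            if extra:
                raise ValueError(f"landmark files without clinical rows: {extra[:5]}")

            stage = "exclude-kl"
            table, n_excluded = exclude_kl(table)
            manifest["stages"]["exclude_kl"] = {
                "n_excluded": n_excluded, "n_retained": len(table)
            }

            stage = "mirror"
            ordered: list[LandmarkConfiguration] = []
            for hip_id in table["hip_id"]:
                c = by_id[hip_id]
                ordered.append(mirror_left(c) if c.side == "left" else c)

            stage = "outcomes"
            table = add_outcome_flags(table)

            stage = "cohort-summary"
            summary = cohort_summary(table)
            results["summary"] = summary
            track(out_dir / "cohort_summary.csv")
            summary_frame(summary).to_csv(out_dir / "cohort_summary.csv", index=False)

            results["models"] = {}
            results["associations"] = {}
            empty_strata: list[str] = []
            for sex in ("male", "female"):
                mask = (table["sex"] == sex).to_numpy()
                n_sex = int(mask.sum())
                if n_sex < 3:
                    empty_strata.append(sex)
                    manifest["stages"][f"{sex}_stratum"] = {
                        "n_hips": n_sex, "note": "stratum too small; skipped"
                    }
                    continue
                sub_table = table.loc[mask].reset_index(drop=True)
                sub_configs = [c for c, m in zip(ordered, mask) if m]

                stage = f"gpa-{sex}"
                aligned = generalized_procrustes([c.points for c in sub_configs])

                stage = f"shape-model-{sex}"
                model = fit_shape_model(aligned, sex=sex)
                selected = select_modes(model, cfg.variance_threshold)
                results["models"][sex] = model
                manifest["stages"][f"{sex}_stratum"] = {
                    "n_hips": n_sex,
                    "gpa_iterations": aligned.iterations,
                    "gpa_converged": aligned.converged,
                    "n_modes_selected": int(selected.size),
                    "bonferroni_alpha": bonferroni_alpha(selected.size)
                    if selected.size else None,
                }

                vt = variance_table(model)
                track(out_dir / f"variance_table_{sex}.csv")
                vt.to_csv(out_dir / f"variance_table_{sex}.csv", index=False)

                stage = f"mode-shapes-{sex}"
                mode_dir = out_dir / f"modes_{sex}"
                for m in selected:
                    for k in (-cfg.viz_sds, 0.0, cfg.viz_sds):
                        pts = mode_shape_at(model, int(m), k)
                        name = f"mode_{int(m) + 1:02d}_{_sd_label(k)}.pts"
                        shape_cfg = LandmarkConfiguration(
                            hip_id=f"{sex}_mode_{int(m) + 1:02d}_{_sd_label(k)}",
                            participant_id=f"model_{sex}",
                            side="right",
                            sex=sex,
                            points=pts,
                        )
                        track(mode_dir / name)
                        write_points_file(shape_cfg, mode_dir / name, sidecar=False)

                stage = f"scores-{sex}"
                scores_df = pd.DataFrame(
                    model.standardized_scores[:, : model.n_modes],
                    columns=[f"mode_{j + 1}" for j in range(model.n_modes)],
                )
                scores_df.insert(0, "hip_id", sub_table["hip_id"].to_numpy())
                scores_df.insert(1, "participant_id", sub_table["participant_id"].to_numpy())
                track(out_dir / f"scores_{sex}.csv")
                scores_df.to_csv(out_dir / f"scores_{sex}.csv", index=False)

                stage = f"association-{sex}"
                outcomes = {
                    "cartilage_defect": sub_table["cartilage_defect_present"].to_numpy(),
                    "labral_tear": sub_table["labral_tear_present"].to_numpy(),
                }
                scan = run_association_scan(
                    model.standardized_scores,
                    outcomes,
                    sub_table[["age", "bmi", "symptomatic_status"]],
                    sub_table["participant_id"].to_numpy(),
                    selected,
                    working=cfg.working,
                )
                results["associations"][sex] = scan
                track(out_dir / f"association_{sex}.csv")
                scan.to_csv(out_dir / f"association_{sex}.csv", index=False)

            manifest["empty_strata"] = empty_strata
            captured_warnings.extend(str(w.message) for w in wlist)

        stage = "manifest"
        track(out_dir / "manifest.json")
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=1, default=str) + "\n"
        )
    except Exception as exc:
        for path in created:
            try:
                if path.exists():
                    path.unlink()
            except OSError:
                pass
        raise PipelineError(f"stage '{stage}': {exc}") from exc

    return results


__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]
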
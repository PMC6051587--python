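"""End-to-end driver: folder of micrographs -> profiles, CSVs, statistics."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .io import DEFAULT_PIXEL_SCALE_UM, ExplantMeta, Micrograph, crawl_experiment, export_results
from .masking import ThresholdParams, apply_threshold
from .orientation import detect_ganglion_corner, orient_to_origin
from .profile import (
    DEFAULT_BIN_WIDTH_UM,
    DEFAULT_COARSE_WIDTH_UM,
    RadialProfile,
    radial_density,
)
from .stats import AnovaResult, ExperimentTable, rm_anova_dunnett, well_means

__all__ = ["process_micrograph", "profiles_from_specs", "run_experiment", "ExperimentRun"]


def process_micrograph(
    micrograph: Micrograph,
    threshold_k: float = 1.5,
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    corner_window_frac: float = 0.25,
) -> RadialProfile:
    """Orient, threshold and radially profile one quarter-field image."""
    corner = detect_ganglion_corner(micrograph.pixels, window_frac=corner_window_frac)
    oriented = orient_to_origin(micrograph.pixels, corner)
    mask = apply_threshold(oriented, ThresholdParams(k=threshold_k))
    return radial_density(
        mask,
        pixel_scale_um=micrograph.pixel_scale_um,
        bin_width_um=bin_width_um,
        meta=micrograph.meta,
    )


def profiles_from_specs(
    specs_by_condition: Mapping[tuple[str, str, str], Sequence],
    *,
    threshold_k: float = 1.5,
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    corner_window_frac: float = 0.25,
) -> list[RadialProfile]:
    """Generate synthetic wells in memory and run the analysis on each.

    ``specs_by_condition`` maps ``(embryo_id, treatment, rep)`` to the
    :class:`~axoquant.synthetic.SyntheticFieldSpec` of each explant in that
    well — the in-memory equivalent of writing a fixture experiment to disk
    and crawling it, used for simulation studies.
    """
    from .synthetic import generate_field  # deferred: synthetic imports io

    profiles = []
    for (embryo, treatment, rep), specs in sorted(specs_by_condition.items()):
        for i, spec in enumerate(specs):
            micrograph, _ = generate_field(spec)
            micrograph.meta = ExplantMeta(
                embryo_id=embryo, treatment=treatment, rep=rep,
                explant_id=f"drg{i + 1:02d}",
            )
            profiles.append(
                process_micrograph(
                    micrograph,
                    threshold_k=threshold_k,
                    bin_width_um=bin_width_um,
                    corner_window_frac=corner_window_frac,
                )
            )
    return profiles


@dataclass
class ExperimentRun:
    """Everything one pipeline invocation produced."""

    profiles: list[RadialProfile]
    table: ExperimentTable
    anova: AnovaResult | None
    results_csv: Path | None


def run_experiment(
    experiment_folder: str | Path,
    *,
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    threshold_k: float = 1.5,
    coarse_width_um: float = DEFAULT_COARSE_WIDTH_UM,
    control_treatment: str | None = None,
    corner_window_frac: float = 0.25,
    naming_pattern: str = "{embryo}_{treatment}_{rep}",
    channel: int = 0,
    out_dir: str | Path | None = None,
    progress: bool = False,
) -> ExperimentRun:
    """Process an experiment folder end to end.

    Crawls the folder, profiles every image, aggregates well means, writes
    ``axoquant_results.csv`` (plus a bins-as-columns ``_wide`` variant) to
    ``out_dir`` (default: the experiment folder itself), and — when a control
    treatment is named — runs the mixed ANOVA + Dunnett comparison and writes
    ``anova.csv``, ``dunnett.csv`` and ``stats_summary.txt``.
    """
    micrographs = crawl_experiment(
        experiment_folder,
        naming_pattern,
        channel=channel,
        pixel_scale_um=pixel_scale_um,
        progress=progress,
    )
    if not micrographs:
        raise ValueError(f"no analyzable images under {experiment_folder}")
    profiles = [
        process_micrograph(
            m,
            threshold_k=threshold_k,
            bin_width_um=bin_width_um,
            corner_window_frac=corner_window_frac,
        )
        for m in micrographs
    ]
    table = well_means(profiles, control_treatment=control_treatment)

    out = Path(out_dir) if out_dir is not None else Path(experiment_folder)
    out.mkdir(parents=True, exist_ok=True)
    results_csv = export_results(table, out / "axoquant_results.csv")
    export_results(table, out / "axoquant_results_wide.csv", wide=True)

    anova = None
    if control_treatment is not None:
        anova = rm_anova_dunnett(table, coarse_width_um, control_treatment)
        anova.anova_table.to_csv(out / "anova.csv", index=False)
        anova.dunnett.to_csv(out / "dunnett.csv", index=False)
        (out / "stats_summary.txt").write_text(anova.summary() + "\n")
    return ExperimentRun(profiles=profiles, table=table, anova=anova, results_csv=results_csv)
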
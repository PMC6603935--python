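"""End-to-end pipeline: panel + frequencies -> RR grids -> indices -> PCA.

``run_pipeline`` executes the whole procedure and writes a deterministic set
of machine artifacts (CSV/TSV/JSON, full precision, no timestamps) into an
output directory; ``render_report`` turns a completed run directory into a
human-readable Markdown summary with display rounding.  ``manifest.json``
records everything needed to reproduce the run: tool version, full
configuration, panel name/version, data provenance and area rule.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .errors import ConfigError, EthnoriskError
from .frequency import (
    FrequencyTable,
    aggregate_worldwide,
    read_frequency_tsv,
    read_vcf_population_afs,
)
from .panel import GenePanel, load_panel, validate_panel
from .pca import export_biplot_data, run_pca
from .profile import RiskProfileIndexer, format_index
from .risk import DEFAULT_ETHNICITIES, ETHNICITY_LABELS, RelativeRiskModel, export_rr_matrix
from .simulate import SimulationConfig, simulate_frequency_table

logger = logging.getLogger(__name__)

WORLDWIDE_MODES = ("use_all_column", "aggregate_by_n", "explicit_weights")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (exactly one frequency source)."""

    out_dir: str
    panel: str = "builtin"
    freq_tsv: str | None = None
    vcf: str | None = None
    simulate: SimulationConfig | None = None
    ethnicities: tuple[str, ...] = DEFAULT_ETHNICITIES
    worldwide_mode: str = "use_all_column"
    weights: Mapping[str, float] | None = None
    area_rule: str = "trapezoid"
    pca_scale: bool = False
    pseudo_freq: float = 0.0

    def __post_init__(self) -> None:
        sources = [s is not None for s in (self.freq_tsv, self.vcf, self.simulate)]
        if sum(sources) != 1:
            raise ConfigError("exactly one frequency source (tsv, vcf or simulate) required")
        if self.worldwide_mode not in WORLDWIDE_MODES:
            raise ConfigError(f"worldwide_mode must be one of {WORLDWIDE_MODES}")
        if self.worldwide_mode == "explicit_weights" and not self.weights:
            raise ConfigError("explicit_weights mode requires a weights mapping")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"] = None if self.simulate is None else self.simulate.to_dict()
        d["weights"] = None if self.weights is None else dict(self.weights)
        # the output location is implied by where the manifest sits; omitting it
        # keeps runs on identical inputs byte-identical across directories
        d.pop("out_dir")
        return d


def _load_frequencies(config: RunConfig) -> FrequencyTable:
    if config.freq_tsv is not None:
        table = read_frequency_tsv(config.freq_tsv)
    elif config.vcf is not None:
        table = read_vcf_population_afs(config.vcf)
    else:
        table = simulate_frequency_table(config.simulate)
    if config.worldwide_mode == "use_all_column":
        if not table.has_worldwide:
            raise ConfigError(
                "worldwide_mode=use_all_column but the table has no ALL population; "
                "use aggregate_by_n or explicit_weights"
            )
        return table
    if table.has_worldwide:
        raise ConfigError(
            f"worldwide_mode={config.worldwide_mode} but the table already has an ALL "
            "population; use use_all_column"
        )
    weights = "by_n" if config.worldwide_mode == "aggregate_by_n" else dict(config.weights)
    return aggregate_worldwide(table, weights=weights)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run panel load -> frequencies -> RR matrix -> indices -> PCA, writing
    all artifacts into ``config.out_dir``.  Returns artifact paths.

    On failure a ``FAILED`` marker naming the stage is left in the output
    directory alongside whatever artifacts were already written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_panel"
    try:
        panel = load_panel(config.panel)
        for finding in validate_panel(panel):
            logger.log(
                logging.ERROR if finding.severity == "error" else logging.WARNING,
                "panel: %s", finding.message,
            )

        stage = "load_frequencies"
        table = _load_frequencies(config)

        stage = "build_rr_matrix"
        model = RelativeRiskModel(
            panel=panel, ethnicities=config.ethnicities, pseudo_freq=config.pseudo_freq
        ).fit(table)
        matrix = model.matrix_
        paths = export_rr_matrix(matrix, out)

        stage = "group_indices"
        indexer = RiskProfileIndexer(area_rule=config.area_rule).fit(matrix)
        groups = matrix.groups
        areas = pd.DataFrame(
            {g: indexer.group_indices_[g].areas for g in groups}
        ).rename_axis("ethnicity")
        paths["areas"] = out / "areas.csv"
        areas.to_csv(paths["areas"], float_format="%.12g")
        paths["indices"] = out / "indices.csv"
        indexer.indices_.to_csv(paths["indices"], float_format="%.12g")

        stage = "run_pca"
        pca_meta = {}
        for g in groups:
            result = run_pca(matrix, g, scale=config.pca_scale)
            sub = export_biplot_data(result, out / f"pca_{g}")
            paths[f"pca_{g}"] = out / f"pca_{g}"
            pca_meta[g] = {
                "degenerate": result.degenerate,
                "explained_ratio": list(result.explained_ratio),
            }

        stage = "manifest"
        manifest = {
            "tool": "ethnorisk",
            "version": __version__,
            "config": config.to_dict(),
            "panel": {"name": panel.name, "version": panel.version, "n_snps": len(panel)},
            "data_source": table.source,
            "area_rule": config.area_rule,
            "groups": list(groups),
            "reference_ethnicity": {
                g: indexer.group_indices_[g].reference_ethnicity for g in groups
            },
            "tied_reference": {
                g: indexer.group_indices_[g].tied_reference for g in groups
            },
            "dropped_snps": matrix.dropped_snps,
            "pca": pca_meta,
        }
        paths["manifest"] = out / "manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return paths
    except EthnoriskError:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        logger.error("pipeline failed at stage %s", stage)
        raise


def render_report(run_dir: str | Path) -> str:
    """Render a completed run directory to a Markdown summary (also written to
    ``report.md``): the per-group/average index table with display rounding,
    reference ethnicities, tie notices, dropped SNPs and PCA variance."""
    run_dir = Path(run_dir)
    required = ["manifest.json", "indices.csv", "areas.csv", "dropped.tsv"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise ConfigError(f"incomplete run directory {run_dir}: missing {missing}")
    manifest = json.loads((run_dir / "manifest.json").read_text())
    indices = pd.read_csv(run_dir / "indices.csv", index_col="ethnicity")
    dropped = pd.read_csv(run_dir / "dropped.tsv", sep="\t")

    lines = ["# Ethnicity susceptibility-risk report", ""]
    lines.append(f"Panel: {manifest['panel']['name']} v{manifest['panel']['version']} "
                 f"({manifest['panel']['n_snps']} SNPs)")
    lines.append(f"Data source: {manifest['data_source']}")
    lines.append(f"Area rule: {manifest['area_rule']}")
    lines.append("")
    lines.append("## Group risk indices (area / minimum area)")
    lines.append("")
    cols = list(indices.columns)
    lines.append("| Ethnicity | " + " | ".join(cols) + " |")
    lines.append("|" + "---|" * (len(cols) + 1))
    for eth, row in indices.iterrows():
        label = ETHNICITY_LABELS.get(str(eth), str(eth))
        lines.append(
            f"| {label} | " + " | ".join(format_index(v) for v in row) + " |"
        )
    lines.append("")
    lines.append("## Reference (minimum-risk) ethnicity per group")
    lines.append("")
    for g, eth in manifest["reference_ethnicity"].items():
        note = " (tie for minimum area; first in order chosen)" if manifest[
            "tied_reference"].get(g) else ""
        lines.append(f"- {g}: {ETHNICITY_LABELS.get(eth, eth)}{note}")
    lines.append("")
    if len(dropped):
        lines.append("## Dropped SNPs")
        lines.append("")
        for _, row in dropped.iterrows():
            lines.append(f"- {row['rsid']}: {row['reason']}")
        lines.append("")
    lines.append("## PCA explained-variance ratios")
    lines.append("")
    for g, meta in manifest["pca"].items():
        if meta["degenerate"]:
            lines.append(f"- {g}: degenerate (zero total variance)")
        else:
            top = ", ".join(f"{r:.3f}" for r in meta["explained_ratio"][:2])
            lines.append(f"- {g}: PC1, PC2 ratios = {top}")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.md").write_text(text)
    return text
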
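"""The relative-risk statistic and the ethnicity-by-SNP risk matrix.

For each SNP the *relative risk* (RR) of an ethnic group is the ratio of its
unfavorable-homozygote genotype frequency to the worldwide frequency of the
same genotype.  For most SNPs the unfavorable condition is the variant
(alternate) homozygote, so RR = VGF(eg) / VGF(all); for the wildtype-risk
exception SNPs the wild-type homozygote is unfavorable and
RR = WTGF(eg) / WTGF(all).  RR = 1 means the group matches the worldwide
population; RR > 1 flags elevated susceptibility.  This is a frequency-ratio
indicator, not an epidemiological incidence ratio: no outcome data enter it.

Heterozygous RRs (het-frequency ratios) are computed alongside for reporting
but do not enter the downstream profile areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigError, EmptyMatrixError, UndefinedRelativeRiskError
from .frequency import WORLDWIDE, FrequencyTable
from .panel import GenePanel, SnpDescriptor, VARIANT_RISK, WILDTYPE_RISK, load_panel

logger = logging.getLogger(__name__)

#: Analyzed ethnicities as 1000 Genomes super-population codes, in reporting order.
DEFAULT_ETHNICITIES: tuple[str, ...] = ("AFR", "EAS", "EUR", "SAS")

#: Display aliases for the super-population codes.
ETHNICITY_LABELS: dict[str, str] = {
    "AFR": "Africa",
    "EAS": "East Asia",
    "EUR": "Europe",
    "SAS": "South Asia",
    "ALL": "Worldwide",
}


def _ratio(f_eg: float, f_all: float, what: str) -> float:
    for name, v in (("ethnic", f_eg), ("worldwide", f_all)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} {what} frequency {v} outside [0, 1]")
    if f_all <= 0.0:
        raise UndefinedRelativeRiskError(
            f"worldwide {what} frequency is zero; relative risk undefined"
        )
    return f_eg / f_all


def relative_risk_variant(vgf_eg: float, vgf_all: float) -> float:
    """RR of the variant homozygote: VGF(eg) / VGF(all)."""
    return _ratio(vgf_eg, vgf_all, "variant-homozygote")


def relative_risk_wildtype(wtgf_eg: float, wtgf_all: float) -> float:
    """RR of the wild-type homozygote: WTGF(eg) / WTGF(all)."""
    return _ratio(wtgf_eg, wtgf_all, "wildtype-homozygote")


def heterozygous_relative_risk(het_eg: float, het_all: float) -> float:
    """RR of the heterozygous genotype: het(eg) / het(all)."""
    return _ratio(het_eg, het_all, "heterozygote")


@dataclass(frozen=True)
class RelativeRisk:
    """RR of one SNP in one ethnicity (unfavorable homozygote + heterozygote)."""

    rsid: str
    ethnicity: str
    rr_unfavorable: float
    basis: str  # variant_risk | wildtype_risk
    rr_het: float | None = None


class RelativeRiskMatrix:
    """Complete ethnicity-by-SNP grid of relative risks.

    ``rr`` and ``rr_het`` are DataFrames indexed by ethnicity code with one
    column per retained panel entry (column labels are the unique
    ``gene rsid`` labels, in panel order).  SNPs dropped during construction
    — missing in some population, or with a zero worldwide unfavorable
    frequency — are dropped for *all* ethnicities so the grid stays
    rectangular, and listed in ``dropped_snps`` with reasons.
    """

    def __init__(
        self,
        rr: pd.DataFrame,
        rr_het: pd.DataFrame,
        snps: Sequence[SnpDescriptor],
        dropped_snps: Sequence[tuple[str, str]] = (),
        source: str = "unspecified",
    ) -> None:
        self.rr = rr
        self.rr_het = rr_het
        self.snps = tuple(snps)
        self.dropped_snps = list(dropped_snps)
        self.source = source
        if list(rr.columns) != [s.label for s in self.snps]:
            raise ValueError("rr columns must match SNP labels in panel order")
        if not np.isfinite(rr.to_numpy(dtype=float)).all():
            raise ValueError("relative-risk grid contains non-finite values")

    @property
    def ethnicities(self) -> tuple[str, ...]:
        return tuple(self.rr.index)

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.snps:
            seen.setdefault(s.group, None)
        return tuple(seen)

    def group_snps(self, group: str) -> tuple[SnpDescriptor, ...]:
        return tuple(s for s in self.snps if s.group == group)

    def group_values(self, group: str) -> pd.DataFrame:
        """Ethnicity-by-SNP RR sub-grid for one functional group, panel order."""
        labels = [s.label for s in self.group_snps(group)]
        return self.rr[labels]

    def to_export_frame(self, het: bool = False) -> pd.DataFrame:
        """SNP-per-row layout (rsid, gene, group, basis + one column per ethnicity)."""
        grid = (self.rr_het if het else self.rr).T
        meta = pd.DataFrame(
            {
                "rsid": [s.rsid for s in self.snps],
                "gene": [s.gene for s in self.snps],
                "group": [s.group for s in self.snps],
                "basis": [s.risk_direction for s in self.snps],
            },
            index=grid.index,
        )
        return pd.concat([meta, grid], axis=1)


def build_rr_matrix(
    table: FrequencyTable,
    panel: GenePanel,
    ethnicities: Sequence[str] | None = None,
    pseudo_freq: float = 0.0,
) -> RelativeRiskMatrix:
    """Assemble the ethnicity-by-SNP relative-risk grid.

    For each panel SNP, the unfavorable-homozygote frequency (hom-alt for
    ``variant_risk`` SNPs, hom-ref for ``wildtype_risk``) of each ethnicity is
    divided by the worldwide frequency of the same genotype.  Heterozygous RRs
    are computed the same way from the het frequencies (NaN where the worldwide
    het frequency is zero).

    SNPs missing for any requested population, or whose worldwide unfavorable
    frequency is zero, are dropped for all ethnicities and reported in
    ``dropped_snps``.  ``pseudo_freq`` > 0 adds a small epsilon to both
    numerator and denominator of the unfavorable ratio instead of dropping on
    a zero denominator (sensitivity analysis only; default off).
    """
    ethnicities = tuple(DEFAULT_ETHNICITIES if ethnicities is None else ethnicities)
    if not table.has_worldwide:
        raise ConfigError(
            "frequency table has no ALL population; aggregate_worldwide() first"
        )
    unknown = [e for e in ethnicities if e not in table.populations]
    if unknown:
        raise ConfigError(
            f"ethnicities {unknown} absent from table populations {list(table.populations)}"
        )
    if pseudo_freq < 0:
        raise ConfigError("pseudo_freq must be nonnegative")

    retained: list[SnpDescriptor] = []
    dropped: list[tuple[str, str]] = []
    rr_cols: dict[str, list[float]] = {}
    het_cols: dict[str, list[float]] = {}

    for snp in panel:
        needed = (WORLDWIDE,) + ethnicities
        missing = [p for p in needed if (snp.rsid, p) not in table]
        if missing:
            dropped.append((snp.rsid, f"missing frequencies for populations {missing}"))
            continue
        entry_all = table.get(snp.rsid, WORLDWIDE)
        unfav = "f_hom_alt" if snp.risk_direction == VARIANT_RISK else "f_hom_ref"
        denom = getattr(entry_all, unfav)
        if denom <= 0.0 and pseudo_freq == 0.0:
            kind = "variant" if snp.risk_direction == VARIANT_RISK else "wild-type"
            dropped.append(
                (snp.rsid, f"worldwide unfavorable ({kind}-homozygote) frequency is zero")
            )
            continue
        rr_vals: list[float] = []
        het_vals: list[float] = []
        for eth in ethnicities:
            entry = table.get(snp.rsid, eth)
            num = getattr(entry, unfav)
            rr_vals.append((num + pseudo_freq) / (denom + pseudo_freq))
            if entry_all.f_het > 0:
                het_vals.append(entry.f_het / entry_all.f_het)
            else:
                het_vals.append(np.nan)
        retained.append(snp)
        rr_cols[snp.label] = rr_vals
        het_cols[snp.label] = het_vals

    if not retained:
        raise EmptyMatrixError(
            "no panel SNP retained; dropped: "
            + "; ".join(f"{r} ({why})" for r, why in dropped)
        )
    for rsid, why in dropped:
        logger.warning("dropped %s: %s", rsid, why)

    idx = pd.Index(ethnicities, name="ethnicity")
    rr = pd.DataFrame(rr_cols, index=idx)
    rr_het = pd.DataFrame(het_cols, index=idx)
    return RelativeRiskMatrix(
        rr=rr, rr_het=rr_het, snps=retained, dropped_snps=dropped, source=table.source
    )


class RelativeRiskModel(BaseEstimator):
    """Estimator-style wrapper: fit a frequency table, expose the RR grid.

    Parameters
    ----------
    panel : GenePanel, "builtin", "builtin:<variant>" or a panel-file path.
    ethnicities : population codes to analyze (default AFR, EAS, EUR, SAS).
    pseudo_freq : epsilon added to both sides of the unfavorable ratio instead
        of dropping SNPs with a zero worldwide denominator (default 0 = drop).

    Fitted attributes
    -----------------
    matrix_ : RelativeRiskMatrix
    rr_, rr_het_ : ethnicity-by-SNP DataFrames
    dropped_snps_ : list of (rsid, reason)
    """

    def __init__(
        self,
        panel: GenePanel | str = "builtin",
        ethnicities: Sequence[str] = DEFAULT_ETHNICITIES,
        pseudo_freq: float = 0.0,
    ) -> None:
        self.panel = panel
        self.ethnicities = ethnicities
        self.pseudo_freq = pseudo_freq

    def fit(self, X: FrequencyTable, y=None) -> "RelativeRiskModel":
        panel = self.panel if isinstance(self.panel, GenePanel) else load_panel(self.panel)
        self.panel_ = panel
        self.matrix_ = build_rr_matrix(
            X, panel, ethnicities=self.ethnicities, pseudo_freq=self.pseudo_freq
        )
        self.rr_ = self.matrix_.rr
        self.rr_het_ = self.matrix_.rr_het
        self.dropped_snps_ = self.matrix_.dropped_snps
        return self


def export_rr_matrix(matrix: RelativeRiskMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write ``rr.csv``, ``rr_het.csv`` and ``dropped.tsv`` into *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rr": out_dir / "rr.csv",
        "rr_het": out_dir / "rr_het.csv",
        "dropped": out_dir / "dropped.tsv",
    }
    matrix.to_export_frame().to_csv(paths["rr"], index=False, float_format="%.12g")
    matrix.to_export_frame(het=True).to_csv(paths["rr_het"], index=False, float_format="%.12g")
    with open(paths["dropped"], "w") as fh:
        fh.write("rsid\treason\n")
        for rsid, reason in matrix.dropped_snps:
            fh.write(f"{rsid}\t{reason}\n")
    return paths
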
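"""Synthetic multi-population genotype-frequency tables.

The generator emulates the shape of real super-population frequency exports:
several populations with differentiated allele frequencies at a controlled
FST plus a worldwide aggregate.  Differentiation follows the Balding–Nichols
model: given an ancestral alternate-allele frequency p and differentiation
parameter F, each population's frequency is drawn from
Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance F·p(1-p).
F = 0 means every population receives p exactly.

Genotype frequencies are produced either as exact Hardy–Weinberg triples
(``hwe_frequencies``) or as finite-sample proportions from a multinomial draw
of ``n_per_pop`` diploid genotypes (``genotype_counts``), which adds the
sampling noise real frequency tables carry.  A worldwide ``ALL`` row is
appended by sample-size-weighted aggregation (equal n per population by
default).

``estimate_fst`` closes the loop: a moment estimator of the differentiation
actually present in a table, used to verify parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FrequencyTableError
from .frequency import (
    TSV_COLUMNS,
    WORLDWIDE,
    FrequencyTable,
    aggregate_worldwide,
    hwe_expand,
)
from .panel import GenePanel

OUTPUT_MODES = ("hwe_frequencies", "genotype_counts")

#: Default population codes, mirroring the four analyzed super-populations.
DEFAULT_POPULATIONS: tuple[str, ...] = ("AFR", "EAS", "EUR", "SAS")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic frequency table.

    ``panel`` takes precedence over ``n_snps``: when given, one frequency row
    per distinct panel rsID is generated (a duplicated panel entry reuses the
    same frequencies, as it would with real data).
    """

    seed: int
    n_snps: int = 24
    panel: GenePanel | None = None
    population_codes: tuple[str, ...] = DEFAULT_POPULATIONS
    fst: float = 0.1
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    n_per_pop: int = 500
    output_mode: str = "hwe_frequencies"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("simulation seed is mandatory")
        if len(self.population_codes) < 2:
            raise ConfigError("need at least 2 populations")
        if WORLDWIDE in self.population_codes:
            raise ConfigError("population codes must not include ALL (added by aggregation)")
        if len(set(self.population_codes)) != len(self.population_codes):
            raise ConfigError("duplicate population codes")
        if not 0.0 <= self.fst < 1.0:
            raise ConfigError(f"fst={self.fst} outside [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError(f"ancestral_freq_range {self.ancestral_freq_range} not within (0, 1)")
        if self.panel is None and self.n_snps < 2:
            raise ConfigError("n_snps must be >= 2")
        if self.n_per_pop < 1:
            raise ConfigError("n_per_pop must be >= 1")
        if self.output_mode not in OUTPUT_MODES:
            raise ConfigError(f"output_mode must be one of {OUTPUT_MODES}")

    @property
    def rsids(self) -> tuple[str, ...]:
        if self.panel is not None:
            return self.panel.rsids
        return tuple(f"rs{1000001 + i}" for i in range(self.n_snps))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_snps": len(self.rsids),
            "panel": None if self.panel is None else self.panel.name,
            "population_codes": list(self.population_codes),
            "fst": self.fst,
            "ancestral_freq_range": list(self.ancestral_freq_range),
            "n_per_pop": self.n_per_pop,
            "output_mode": self.output_mode,
        }


def _balding_nichols(
    rng: np.random.Generator, p: np.ndarray, fst: float, n_pops: int
) -> np.ndarray:
    """Population frequencies (n_snps x n_pops) under Balding–Nichols at fst."""
    if fst == 0.0:
        return np.repeat(p[:, None], n_pops, axis=1)
    ratio = (1.0 - fst) / fst
    a = p * ratio
    b = (1.0 - p) * ratio
    return rng.beta(a[:, None], b[:, None], size=(p.size, n_pops))


def simulate_frequency_table(config: SimulationConfig) -> FrequencyTable:
    """Generate a differentiated multi-population table plus worldwide ALL row.

    Deterministic for a fixed config (the seed feeds a dedicated
    ``numpy.random.Generator``).  Ancestral frequencies are uniform on the
    configured open interval, so Beta shape parameters are always positive;
    should a degenerate draw still occur it is resampled.
    """
    rng = np.random.default_rng(config.seed)
    rsids = config.rsids
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=len(rsids))
    # guard against zero-width edge draws that would break the Beta shapes
    for _ in range(100):
        bad = (p_anc <= 0.0) | (p_anc >= 1.0)
        if not bad.any():
            break
        p_anc[bad] = rng.uniform(lo, hi, size=int(bad.sum()))
    pops = config.population_codes
    p_pop = _balding_nichols(rng, p_anc, config.fst, len(pops))

    rows = []
    for i, rsid in enumerate(rsids):
        for j, pop in enumerate(pops):
            f_rr, f_ra, f_aa = hwe_expand(float(p_pop[i, j]))
            if config.output_mode == "genotype_counts":
                counts = rng.multinomial(config.n_per_pop, (f_rr, f_ra, f_aa))
                f_rr, f_ra, f_aa = (counts / config.n_per_pop).tolist()
            rows.append((rsid, pop, config.n_per_pop, f_rr, f_ra, f_aa))
    df = pd.DataFrame(rows, columns=list(TSV_COLUMNS))
    table = FrequencyTable(
        df,
        source=(
            f"synthetic Balding-Nichols fst={config.fst} seed={config.seed} "
            f"mode={config.output_mode}"
        ),
    )
    return aggregate_worldwide(table, weights="by_n")


def estimate_fst(table: FrequencyTable) -> float:
    """Moment estimate of differentiation from a frequency table.

    Per SNP, with p_k the alternate-allele frequency of population k
    (``f_hom_alt + f_het/2``; ALL excluded), p̄ their unweighted mean and
    s² the sample variance (ddof=1) across the k populations:

        F̂ = s² / (p̄(1 − p̄) + s²/k)

    The s²/k term corrects the small-sample bias of the plain ratio
    Var(p)/(p̄(1 − p̄)), which underestimates the true differentiation by a
    factor of about (k − 1)/k when only a few populations are observed; the
    corrected form is unbiased to first order in the Balding–Nichols model
    (for a pair of populations fixed at p = 0 and p = 1 it still gives
    exactly 1).  The estimate is the mean of per-SNP ratios over SNPs with
    p̄(1 − p̄) > 0; a table monomorphic at every SNP has no defined estimate.
    """
    pops = [p for p in table.populations if p != WORLDWIDE]
    if len(pops) < 2:
        raise FrequencyTableError("FST estimation needs at least 2 populations besides ALL")
    ratios = []
    for rsid in table.rsids:
        present = [p for p in pops if (rsid, p) in table]
        if len(present) < 2:
            continue
        p_alt = np.array([table.get(rsid, p).p_alt for p in present])
        pbar = p_alt.mean()
        if pbar * (1.0 - pbar) <= 0.0:
            continue
        s2 = p_alt.var(ddof=1)
        ratios.append(s2 / (pbar * (1.0 - pbar) + s2 / len(present)))
    if not ratios:
        raise FrequencyTableError("all SNPs monomorphic; FST estimate undefined")
    return float(np.mean(ratios))


def make_null_table(
    panel: GenePanel,
    ethnicities: Sequence[str] = DEFAULT_POPULATIONS,
    p_alt: float = 0.3,
    n_per_pop: int = 500,
) -> FrequencyTable:
    """A no-differentiation table: every population *and* ALL share one HWE
    triple per SNP, so every downstream RR, index and PCA score is exactly at
    its null value (1, 1, origin)."""
    f_rr, f_ra, f_aa = hwe_expand(p_alt)
    rows = []
    for rsid in panel.rsids:
        for pop in tuple(ethnicities) + (WORLDWIDE,):
            rows.append((rsid, pop, n_per_pop, f_rr, f_ra, f_aa))
    df = pd.DataFrame(rows, columns=list(TSV_COLUMNS))
    return FrequencyTable(df, source=f"null table (HWE at p={p_alt})")


def simulated_panel_config(
    panel: GenePanel, seed: int, fst: float = 0.1, **kwargs
) -> SimulationConfig:
    """Convenience: a :class:`SimulationConfig` mirroring a panel.

    The builtin panel's wildtype-risk exception SNPs keep their direction, so
    simulated runs always exercise both ratio bases.
    """
    return SimulationConfig(seed=seed, panel=panel, fst=fst, **kwargs)
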
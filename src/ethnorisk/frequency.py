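"""Population genotype-frequency tables: TSV and VCF input, validation,
Hardy–Weinberg expansion, and construction of the worldwide reference.

The central container is :class:`FrequencyTable`, a validated, pandas-backed
collection of genotype-frequency triples — (hom-ref, het, hom-alt) proportions
— keyed by (rsID, population code).  Population codes follow the 1000 Genomes
super-population convention (AFR, EAS, EUR, SAS, ...) with ``ALL`` reserved
for the worldwide reference.

Two input carriers are supported:

* a TSV dialect with explicit genotype frequencies (the primary path, as
  exportable from Ensembl population-genetics pages), and
* VCF records carrying per-population alternate-allele-frequency INFO keys
  (``AF``, ``EAS_AF``, ...), expanded to genotype frequencies under
  Hardy–Weinberg equilibrium.

Input frequencies are validated (each in [0, 1], triple summing to one within
``SUM_TOLERANCE``) and never silently renormalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FrequencyTableError

logger = logging.getLogger(__name__)

#: Worldwide-reference population code.
WORLDWIDE = "ALL"

#: Tolerance on the sum-to-one invariant of a genotype-frequency triple.
SUM_TOLERANCE = 1e-6

#: Column order of the frequency TSV dialect.
TSV_COLUMNS = ("rsid", "population", "n", "f_hom_ref", "f_het", "f_hom_alt")

#: Default mapping population code -> VCF INFO key (1000 Genomes convention).
DEFAULT_VCF_KEY_MAP: dict[str, str] = {
    "ALL": "AF",
    "AFR": "AFR_AF",
    "EAS": "EAS_AF",
    "EUR": "EUR_AF",
    "SAS": "SAS_AF",
}


def hwe_expand(p_alt: float) -> tuple[float, float, float]:
    """Expand an alternate-allele frequency to genotype frequencies under HWE.

    Returns ``((1-p)^2, 2p(1-p), p^2)``; raises on p outside [0, 1].
    """
    if not 0.0 <= p_alt <= 1.0:
        raise FrequencyTableError(f"allele frequency {p_alt} outside [0, 1]")
    q = 1.0 - p_alt
    return (q * q, 2.0 * p_alt * q, p_alt * p_alt)


@dataclass(frozen=True)
class GenotypeFrequencySet:
    """Genotype-frequency triple (+ optional sample size) for one SNP in one population."""

    rsid: str
    population: str
    f_hom_ref: float
    f_het: float
    f_hom_alt: float
    n: int | None = None

    def __post_init__(self) -> None:
        for name in ("f_hom_ref", "f_het", "f_hom_alt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FrequencyTableError(
                    f"{self.rsid}/{self.population}: {name}={v} outside [0, 1]"
                )
        total = self.f_hom_ref + self.f_het + self.f_hom_alt
        if abs(total - 1.0) > SUM_TOLERANCE:
            raise FrequencyTableError(
                f"{self.rsid}/{self.population}: genotype frequencies sum to {total}, not 1"
            )
        if self.n is not None and (self.n < 0 or int(self.n) != self.n):
            raise FrequencyTableError(
                f"{self.rsid}/{self.population}: sample size n={self.n} must be a "
                "nonnegative integer"
            )

    @property
    def p_alt(self) -> float:
        """Alternate-allele frequency implied by the genotype triple."""
        return self.f_hom_alt + 0.5 * self.f_het

    @property
    def triple(self) -> tuple[float, float, float]:
        return (self.f_hom_ref, self.f_het, self.f_hom_alt)


class FrequencyTable:
    """Validated panel-by-population collection of genotype-frequency triples.

    Parameters
    ----------
    df : DataFrame with columns ``rsid, population, n, f_hom_ref, f_het, f_hom_alt``
        (``n`` may be missing/NaN).  Row order is preserved; population order
        is order of first appearance.
    source : free-text provenance string carried into downstream outputs.
    """

    def __init__(self, df: pd.DataFrame, source: str | None = None) -> None:
        df = df.copy().reset_index(drop=True)
        missing = [c for c in TSV_COLUMNS if c not in df.columns and c != "n"]
        if missing:
            raise FrequencyTableError(f"frequency table missing columns: {missing}")
        if "n" not in df.columns:
            df["n"] = np.nan
        df = df[list(TSV_COLUMNS)]
        self._validate(df)
        self.df = df
        self.source = source or "unspecified"
        self._index: dict[tuple[str, str], int] = {
            (r, p): i for i, (r, p) in enumerate(zip(df["rsid"], df["population"]))
        }

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        freqs = df[["f_hom_ref", "f_het", "f_hom_alt"]].to_numpy(dtype=float)
        bad_range = np.where((freqs < 0) | (freqs > 1))[0]
        if bad_range.size:
            rows = sorted(set(int(i) + 2 for i in bad_range))
            raise FrequencyTableError(f"frequencies outside [0, 1] at data rows {rows}")
        sums = freqs.sum(axis=1)
        bad_sum = np.where(np.abs(sums - 1.0) > SUM_TOLERANCE)[0]
        if bad_sum.size:
            rows = [int(i) + 2 for i in bad_sum[:10]]
            raise FrequencyTableError(
                f"genotype frequencies do not sum to 1 (tolerance {SUM_TOLERANCE}) "
                f"at data rows {rows}"
            )
        dup = df.duplicated(subset=["rsid", "population"])
        if dup.any():
            keys = df.loc[dup, ["rsid", "population"]].apply(tuple, axis=1).tolist()
            raise FrequencyTableError(f"duplicate (rsid, population) keys: {keys[:10]}")
        nvals = df["n"].dropna()
        if (nvals < 0).any():
            raise FrequencyTableError("negative sample sizes present")

    @classmethod
    def from_entries(
        cls, entries: Iterable[GenotypeFrequencySet], source: str | None = None
    ) -> "FrequencyTable":
        rows = [
            (e.rsid, e.population, np.nan if e.n is None else e.n,
             e.f_hom_ref, e.f_het, e.f_hom_alt)
            for e in entries
        ]
        df = pd.DataFrame(rows, columns=list(TSV_COLUMNS))
        return cls(df, source=source)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._index

    @property
    def populations(self) -> tuple[str, ...]:
        """Population codes in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.df["population"]:
            seen.setdefault(p, None)
        return tuple(seen)

    @property
    def rsids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.df["rsid"]:
            seen.setdefault(r, None)
        return tuple(seen)

    @property
    def has_worldwide(self) -> bool:
        return WORLDWIDE in self.populations

    def get(self, rsid: str, population: str) -> GenotypeFrequencySet:
        try:
            i = self._index[(rsid, population)]
        except KeyError:
            raise KeyError(f"no entry for ({rsid}, {population})") from None
        row = self.df.iloc[i]
        n = row["n"]
        return GenotypeFrequencySet(
            rsid=row["rsid"],
            population=row["population"],
            f_hom_ref=float(row["f_hom_ref"]),
            f_het=float(row["f_het"]),
            f_hom_alt=float(row["f_hom_alt"]),
            n=None if pd.isna(n) else int(n),
        )

    def entries(self) -> list[GenotypeFrequencySet]:
        return [self.get(r, p) for r, p in self._index]

    def to_tsv(self, path: str | Path) -> None:
        """Serialize in the frequency TSV dialect (round-trips via read_frequency_tsv)."""
        out = self.df.copy()
        out["n"] = out["n"].map(lambda v: "" if pd.isna(v) else str(int(v)))
        out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_frequency_tsv(path: str | Path) -> FrequencyTable:
    """Read a genotype-frequency TSV (columns ``rsid population n f_hom_ref
    f_het f_hom_alt``, ``#``-comments allowed) into a validated table.

    Raises :class:`FrequencyTableError` naming the offending column or data
    row on schema errors, non-numeric frequencies, and sum-to-one violations.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype={"rsid": str, "population": str},
            skip_blank_lines=True,
        )
    except OSError as exc:
        raise FrequencyTableError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in TSV_COLUMNS if c not in df.columns and c != "n"]
    if missing:
        raise FrequencyTableError(f"{path}: missing columns {missing}")
    for col in ("f_hom_ref", "f_het", "f_hom_alt", "n"):
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            rows = [int(i) + 2 for i in df.index[bad][:10]]
            raise FrequencyTableError(f"{path}: non-numeric {col} at data rows {rows}")
        df[col] = coerced
    try:
        return FrequencyTable(df, source=str(path))
    except FrequencyTableError as exc:
        raise FrequencyTableError(f"{path}: {exc}") from exc


def read_vcf_population_afs(
    path: str | Path, key_map: Mapping[str, str] | None = None
) -> FrequencyTable:
    """Build a frequency table from per-population allele-frequency INFO keys
    of a VCF, expanding each to genotype frequencies under Hardy–Weinberg.

    Only biallelic records with an rsID are used; multiallelic records and
    records missing a mapped INFO key are skipped/omitted with a logged
    warning.  Genotype triples produced this way assume HWE within each
    population, which real genotype counts need not satisfy — the table's
    ``source`` records the expansion so provenance stays visible.
    """
    import pysam

    key_map = dict(DEFAULT_VCF_KEY_MAP if key_map is None else key_map)
    entries: list[GenotypeFrequencySet] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                logger.warning(
                    "skipping multiallelic record at %s:%s (ALT=%s)",
                    rec.chrom, rec.pos, ",".join(rec.alts or ()),
                )
                continue
            rsid = rec.id
            if not rsid or rsid == ".":
                logger.warning("skipping record at %s:%s without rsID", rec.chrom, rec.pos)
                continue
            for population, key in key_map.items():
                if key not in rec.info:
                    logger.warning("record %s lacks INFO key %s; (%s, %s) omitted",
                                   rsid, key, rsid, population)
                    continue
                value = rec.info[key]
                p_alt = float(value[0] if isinstance(value, tuple) else value)
                f_rr, f_ra, f_aa = hwe_expand(p_alt)
                entries.append(
                    GenotypeFrequencySet(
                        rsid=rsid, population=population,
                        f_hom_ref=f_rr, f_het=f_ra, f_hom_alt=f_aa,
                    )
                )
    return FrequencyTable.from_entries(
        entries, source=f"{path} (VCF INFO AFs, HWE-expanded)"
    )


def aggregate_worldwide(
    table: FrequencyTable,
    weights: Mapping[str, float] | str = "by_n",
) -> FrequencyTable:
    """Append a worldwide ``ALL`` row per rsID as a weighted mean of the
    population genotype-frequency triples.

    ``weights`` is either ``"by_n"`` (weight each population by its per-rsID
    sample size; requires ``n`` everywhere) or an explicit population→weight
    mapping (normalized to sum to one over the populations present for each
    rsID).  An existing ``ALL`` population is never overwritten — that is an
    error.  Convexity preserves the sum-to-one invariant exactly.
    """
    if table.has_worldwide:
        raise FrequencyTableError(
            "table already contains an ALL population; refusing to overwrite it"
        )
    pops = table.populations
    if len(pops) < 2:
        raise FrequencyTableError("worldwide aggregation needs at least two populations")
    by_n = isinstance(weights, str)
    if by_n and weights != "by_n":
        raise FrequencyTableError(f"unknown weighting mode {weights!r}")
    if not by_n:
        zero = [p for p in pops if float(weights.get(p, 0.0)) == 0.0]
        if zero:
            logger.warning("populations with zero aggregation weight: %s", zero)

    new_rows = []
    for rsid in table.rsids:
        present = [p for p in pops if (rsid, p) in table]
        entries = [table.get(rsid, p) for p in present]
        if by_n:
            if any(e.n is None for e in entries):
                raise FrequencyTableError(
                    f"by_n aggregation requires sample sizes; missing n for {rsid}"
                )
            w = np.array([e.n for e in entries], dtype=float)
        else:
            w = np.array([float(weights.get(p, 0.0)) for p in present], dtype=float)
        if w.sum() <= 0:
            raise FrequencyTableError(f"aggregation weights sum to zero for {rsid}")
        w = w / w.sum()
        triples = np.array([e.triple for e in entries], dtype=float)
        agg = w @ triples
        n_all = int(sum(e.n for e in entries)) if by_n else None
        new_rows.append(
            (rsid, WORLDWIDE, np.nan if n_all is None else n_all, agg[0], agg[1], agg[2])
        )
    new_df = pd.concat(
        [table.df, pd.DataFrame(new_rows, columns=list(TSV_COLUMNS))], ignore_index=True
    )
    return FrequencyTable(new_df, source=table.source + " + ALL(by aggregation)")
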
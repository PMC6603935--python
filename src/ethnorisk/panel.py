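"""SNP panel definition and validation.

A *panel* is the ordered list of biallelic SNPs in xenobiotic-metabolism genes
over which risk profiles are computed.  Each SNP belongs to one of three
functional groups — oxidative stress, detoxification, DNA repair — and carries
a *risk direction*: whether the unfavorable genotype is the variant homozygote
(the usual case) or the wild-type homozygote (a handful of SNPs where the
variant allele is thought to be advantageous in at least one step of the
pathway).

Panel order is semantically meaningful: it defines the x-axis of the per-group
risk-profile curves, and therefore the trapezoid areas downstream.  The order
is preserved exactly as given in the panel file and round-trips through
serialization.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import PanelError

OXIDATIVE_STRESS = "oxidative_stress"
DETOXIFICATION = "detoxification"
DNA_REPAIR = "dna_repair"

#: The three functional groups, in canonical reporting order.
GROUPS: tuple[str, ...] = (OXIDATIVE_STRESS, DETOXIFICATION, DNA_REPAIR)

VARIANT_RISK = "variant_risk"
WILDTYPE_RISK = "wildtype_risk"
RISK_DIRECTIONS: tuple[str, ...] = (VARIANT_RISK, WILDTYPE_RISK)

#: SNPs for which the wild-type homozygote is the unfavorable condition:
#: the variant allele is advantageous in at least one step of the relevant
#: biochemical pathway, so high wild-type frequency marks higher susceptibility.
WILDTYPE_RISK_SNPS: frozenset[str] = frozenset(
    {"rs2234922", "rs6413432", "rs3813867", "rs2333227"}
)

_RSID_RE = re.compile(r"^rs[0-9]+$")

_PANEL_COLUMNS = ("rsid", "gene", "group", "risk_direction", "ref_allele", "alt_allele")


@dataclass(frozen=True)
class SnpDescriptor:
    """One panel entry: a biallelic SNP with its gene, group and risk direction."""

    rsid: str
    gene: str
    group: str
    risk_direction: str = VARIANT_RISK
    ref_allele: str | None = None
    alt_allele: str | None = None

    def __post_init__(self) -> None:
        if not _RSID_RE.match(self.rsid):
            raise PanelError(f"invalid rsID {self.rsid!r}: must match rs[0-9]+")
        if self.group not in GROUPS:
            raise PanelError(
                f"unknown group {self.group!r} for {self.rsid}; expected one of {GROUPS}"
            )
        if self.risk_direction not in RISK_DIRECTIONS:
            raise PanelError(
                f"unknown risk_direction {self.risk_direction!r} for {self.rsid}"
            )

    @property
    def label(self) -> str:
        """Unique display label (a gene may host several SNPs and vice versa)."""
        return f"{self.gene} {self.rsid}"


@dataclass(frozen=True)
class PanelFinding:
    """A validation finding: 'error' breaks invariants, 'warning' is advisory."""

    severity: str  # "error" | "warning"
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.severity}: {self.message}"


@dataclass(frozen=True)
class GenePanel:
    """Ordered, versioned collection of :class:`SnpDescriptor`."""

    snps: tuple[SnpDescriptor, ...]
    name: str = "custom"
    version: str = "0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "snps", tuple(self.snps))
        dup = [k for k, c in Counter((s.rsid, s.gene, s.group) for s in self.snps).items() if c > 1]
        if dup:
            raise PanelError(
                "duplicate panel entries (rsid, gene, group): "
                + ", ".join(f"({r}, {g}, {gr})" for r, g, gr in dup)
            )

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    @property
    def groups(self) -> tuple[str, ...]:
        """Groups present, in canonical order."""
        present = {s.group for s in self.snps}
        return tuple(g for g in GROUPS if g in present)

    def group_snps(self, group: str) -> tuple[SnpDescriptor, ...]:
        """SNPs of one group in panel order (the profile-curve x-axis)."""
        if group not in GROUPS:
            raise PanelError(f"unknown group {group!r}")
        return tuple(s for s in self.snps if s.group == group)

    @property
    def rsids(self) -> tuple[str, ...]:
        """Distinct rsIDs in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.snps:
            seen.setdefault(s.rsid, None)
        return tuple(seen)

    def group_summary(self) -> dict[str, dict[str, int]]:
        """Per group: number of panel entries (SNP rows) and distinct gene symbols.

        Gene symbols are collapsed on the root symbol (text before any space,
        ``_`` or ``*`` qualifier), so e.g. "EPHX1 Ex_3"/"EPHX1 Ex_4" count as
        one gene and "CYP2E1*6"/"CYP2E1*5B" as one.
        """
        out: dict[str, dict[str, int]] = {}
        for g in self.groups:
            snps = self.group_snps(g)
            roots = {re.split(r"[ _*]", s.gene)[0] for s in snps}
            out[g] = {"n_snps": len(snps), "n_genes": len(roots)}
        return out


# Table of builtin panel entries: (rsid, gene, group).  Order defines the
# profile-curve x-axis.  rs13181 appears twice in the DNA-repair block (under
# XRCC1 and under XPD/ERCC2); the verbatim panel keeps both rows, the dedup
# variant keeps only the XPD/ERCC2 one (its canonical gene, Lys751Gln).
_BUILTIN_ROWS: tuple[tuple[str, str, str], ...] = (
    ("rs6721961", "NRF2", OXIDATIVE_STRESS),
    ("rs35652124", "NRF2", OXIDATIVE_STRESS),
    ("rs2071746", "HO-1", OXIDATIVE_STRESS),
    ("rs1800566", "NQO1", OXIDATIVE_STRESS),
    ("rs1131341", "NQO1", OXIDATIVE_STRESS),
    ("rs4880", "SOD2", OXIDATIVE_STRESS),
    ("rs3957357", "GST-A1", DETOXIFICATION),
    ("rs366631", "GST-M1", DETOXIFICATION),
    ("rs17856199", "GST-T1", DETOXIFICATION),
    ("rs1695", "GST-P1", DETOXIFICATION),
    ("rs1051740", "EPHX1 Ex_3", DETOXIFICATION),
    ("rs2234922", "EPHX1 Ex_4", DETOXIFICATION),
    ("rs4646903", "CYP1A1_2A", DETOXIFICATION),
    ("rs1048943", "CYP1A1_2C", DETOXIFICATION),
    ("rs6413432", "CYP2E1*6", DETOXIFICATION),
    ("rs3813867", "CYP2E1*5B", DETOXIFICATION),
    ("rs2333227", "MPO", DETOXIFICATION),
    ("rs25487", "XRCC1", DNA_REPAIR),
    ("rs13181", "XRCC1", DNA_REPAIR),
    ("rs1799782", "XRCC3", DNA_REPAIR),
    ("rs861539", "XRCC3", DNA_REPAIR),
    ("rs1799793", "XPD/ERCC2", DNA_REPAIR),
    ("rs13181", "XPD/ERCC2", DNA_REPAIR),
    ("rs1052133", "hOGG1", DNA_REPAIR),
)

BUILTIN_VARIANTS = ("table1_verbatim", "table1_dedup")


def builtin_panel(variant: str = "table1_verbatim") -> GenePanel:
    """The built-in xenobiotic-metabolism panel.

    ``table1_verbatim`` (default) keeps the published panel exactly, including
    the rs13181 duplication in the DNA-repair group (24 entries); ``table1_dedup``
    lists rs13181 once (23 entries).
    """
    if variant not in BUILTIN_VARIANTS:
        raise PanelError(
            f"unknown builtin panel variant {variant!r}; choose from {BUILTIN_VARIANTS}"
        )
    rows = _BUILTIN_ROWS
    if variant == "table1_dedup":
        rows = tuple(r for r in rows if r != ("rs13181", "XRCC1", DNA_REPAIR))
    snps = tuple(
        SnpDescriptor(
            rsid=rsid,
            gene=gene,
            group=group,
            risk_direction=WILDTYPE_RISK if rsid in WILDTYPE_RISK_SNPS else VARIANT_RISK,
        )
        for rsid, gene, group in rows
    )
    return GenePanel(snps=snps, name=variant, version="1")


def validate_panel(panel: GenePanel) -> list[PanelFinding]:
    """Check panel invariants, returning findings instead of raising.

    Errors: empty panel.  Warnings: the same rsID listed twice within one
    group under different gene labels, an rsID appearing in more than one
    group, and a wildtype-risk direction on a SNP outside the known exception
    set (a legitimate user override, but worth flagging).  Exact duplicate
    (rsid, gene, group) entries are already rejected at construction time.
    """
    findings: list[PanelFinding] = []
    if len(panel) == 0:
        return [PanelFinding("error", "panel has no SNPs")]

    within = Counter((s.rsid, s.group) for s in panel.snps)
    for (rsid, group), count in within.items():
        if count > 1:
            genes = [s.gene for s in panel.snps if s.rsid == rsid and s.group == group]
            findings.append(
                PanelFinding(
                    "warning",
                    f"{rsid} appears {count} times in group {group} "
                    f"(under {', '.join(genes)})",
                )
            )

    group_of: dict[str, set[str]] = {}
    for s in panel.snps:
        group_of.setdefault(s.rsid, set()).add(s.group)
    for rsid, groups in group_of.items():
        if len(groups) > 1:
            findings.append(
                PanelFinding("warning", f"{rsid} appears in multiple groups: {sorted(groups)}")
            )

    for s in panel.snps:
        if s.risk_direction == WILDTYPE_RISK and s.rsid not in WILDTYPE_RISK_SNPS:
            findings.append(
                PanelFinding(
                    "warning",
                    f"{s.rsid} has risk_direction=wildtype_risk but is not a known "
                    "wildtype-risk exception SNP",
                )
            )
    return findings


def _parse_panel_tsv(path: Path) -> list[SnpDescriptor]:
    snps: list[SnpDescriptor] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = set(_PANEL_COLUMNS[:4]) - set(header)
                if missing:
                    raise PanelError(
                        f"{path}: line {lineno}: missing panel columns {sorted(missing)}"
                    )
                continue
            row = dict(zip(header, (f.strip() for f in fields)))
            try:
                snps.append(
                    SnpDescriptor(
                        rsid=row["rsid"],
                        gene=row["gene"],
                        group=row["group"],
                        risk_direction=row.get("risk_direction") or VARIANT_RISK,
                        ref_allele=row.get("ref_allele") or None,
                        alt_allele=row.get("alt_allele") or None,
                    )
                )
            except (KeyError, PanelError) as exc:
                raise PanelError(f"{path}: line {lineno}: {exc}") from exc
    if header is None:
        raise PanelError(f"{path}: empty panel file")
    return snps


def _parse_panel_json(path: Path) -> tuple[list[SnpDescriptor], str, str]:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        snps = [
            SnpDescriptor(
                rsid=e["rsid"],
                gene=e["gene"],
                group=e["group"],
                risk_direction=e.get("risk_direction", VARIANT_RISK),
                ref_allele=e.get("ref_allele"),
                alt_allele=e.get("alt_allele"),
            )
            for e in doc["snps"]
        ]
    except (KeyError, TypeError) as exc:
        raise PanelError(f"{path}: malformed panel JSON: {exc}") from exc
    return snps, doc.get("name", path.stem), str(doc.get("version", "0"))


def load_panel(source: str | Path = "builtin") -> GenePanel:
    """Load a panel from ``"builtin"`` (optionally ``"builtin:<variant>"``),
    a panel TSV, or a panel JSON file.

    Raises :class:`PanelError` on malformed files (naming the offending line)
    and on exact duplicate (rsid, gene, group) entries.
    """
    if isinstance(source, str) and (source == "builtin" or source.startswith("builtin:")):
        _, _, variant = source.partition(":")
        return builtin_panel(variant or "table1_verbatim")
    path = Path(source)
    if not path.exists():
        raise PanelError(f"panel file not found: {path}")
    if path.suffix.lower() == ".json":
        snps, name, version = _parse_panel_json(path)
        return GenePanel(snps=tuple(snps), name=name, version=version)
    snps = _parse_panel_tsv(path)
    return GenePanel(snps=tuple(snps), name=path.stem, version="0")


def write_panel(panel: GenePanel, path: str | Path) -> None:
    """Serialize a panel to TSV or JSON (by file suffix); round-trips exactly."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "name": panel.name,
            "version": panel.version,
            "snps": [
                {
                    "rsid": s.rsid,
                    "gene": s.gene,
                    "group": s.group,
                    "risk_direction": s.risk_direction,
                    "ref_allele": s.ref_allele,
                    "alt_allele": s.alt_allele,
                }
                for s in panel.snps
            ],
        }
        path.write_text(json.dumps(doc, indent=2) + "\n")
        return
    lines = ["\t".join(_PANEL_COLUMNS)]
    for s in panel.snps:
        lines.append(
            "\t".join(
                [s.rsid, s.gene, s.group, s.risk_direction, s.ref_allele or "", s.alt_allele or ""]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def override_risk_direction(panel: GenePanel, directions: dict[str, str]) -> GenePanel:
    """Return a copy of the panel with risk directions overridden per rsID."""
    snps = tuple(
        replace(s, risk_direction=directions.get(s.rsid, s.risk_direction)) for s in panel.snps
    )
    return GenePanel(snps=snps, name=panel.name, version=panel.version + "+override")
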
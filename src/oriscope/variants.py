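"""Populational variant tables: parsing, allele-frequency filters, codon
effect classification, and per-lineage summaries.

Input is a breseq-style TSV of population-level SNPs and DIPs (deletions,
insertions, and other polymorphisms) with allele frequencies in percent.
Codon changes are read from annotations of the form ``R69H (CGC→CAC)``;
effects are classified with the standard genetic code.  A transcription of
the published table of mutations at >=50% allele frequency in six evolved
E. coli lineages ships as a package fixture.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib.resources import files
from pathlib import Path
from typing import Iterable, List, Literal, Optional, Sequence, Tuple

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "VariantRecord",
    "EffectClass",
    "parse_variant_table",
    "write_variant_table",
    "filter_by_af",
    "classify_effect",
    "fixed_fraction",
    "summarize_by_lineage",
    "table1_fixture_path",
    "load_table1_fixture",
]

EffectClass = Literal["synonymous", "missense", "nonsense", "not_applicable"]

REQUIRED_COLUMNS = ("lineage", "gene", "annotation", "mutation",
                    "allele_frequency", "description")

_CODON_RE = re.compile(r"\(([ACGT]{3})(?:→|->)([ACGT]{3})\)")
_SNP_RE = re.compile(r"^[ACGT](?:→|->)[ACGT]$")


@dataclass(frozen=True)
class VariantRecord:
    """One populational mutation with its allele frequency in percent."""

    lineage: str
    gene_or_region: str
    annotation: str
    mutation: str
    allele_frequency: float
    description: str = ""

    @property
    def mutation_class(self) -> str:
        """"SNP" for single-base substitutions, "DIP" otherwise."""
        return "SNP" if _SNP_RE.match(self.mutation.strip()) else "DIP"

    @property
    def codon_change(self) -> Optional[Tuple[str, str]]:
        """(ref codon, alt codon) parsed from the annotation, if present."""
        m = _CODON_RE.search(self.annotation)
        return (m.group(1), m.group(2)) if m else None

    @property
    def effect(self) -> EffectClass:
        cc = self.codon_change
        if cc is None:
            return "not_applicable"
        return classify_effect(*cc)

    @property
    def is_fixed(self) -> bool:
        return abs(self.allele_frequency - 100.0) < 1e-9


def parse_variant_table(path) -> List[VariantRecord]:
    """Read a breseq-like variant TSV into records.

    Raises a parse error naming the offending row for missing columns or
    allele frequencies outside (0, 100].
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            af = float(row["allele_frequency"])
        except ValueError as exc:
            raise ValueError(f"row {i}: unparseable allele_frequency") from exc
        if not (0 < af <= 100):
            raise ValueError(f"row {i}: allele_frequency {af} outside (0, 100]")
        records.append(
            VariantRecord(
                lineage=row["lineage"],
                gene_or_region=row["gene"],
                annotation=row["annotation"],
                mutation=row["mutation"],
                allele_frequency=af,
                description=row["description"],
            )
        )
    return records


def write_variant_table(records: Iterable[VariantRecord], path) -> None:
    """Write records as TSV; round-trips losslessly through the parser."""
    pd.DataFrame(
        [
            {
                "lineage": r.lineage,
                "gene": r.gene_or_region,
                "annotation": r.annotation,
                "mutation": r.mutation,
                "allele_frequency": r.allele_frequency,
                "description": r.description,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def filter_by_af(records: Sequence[VariantRecord], min_af: float,
                 strict: bool = False) -> List[VariantRecord]:
    """Keep records at or above (default) or strictly above ``min_af``.

    Published thresholds mix "over X%" and "at least X%" phrasings, so the
    comparison mode is explicit: ``strict=False`` keeps AF >= min_af,
    ``strict=True`` keeps AF > min_af.
    """
    if not (0 <= min_af <= 100):
        raise ValueError("min_af must be in [0, 100]")
    if strict:
        return [r for r in records if r.allele_frequency > min_af]
    return [r for r in records if r.allele_frequency >= min_af]


def classify_effect(ref_codon: str, alt_codon: str) -> EffectClass:
    """Classify a codon substitution with the standard genetic code.

    Same amino acid -> synonymous; change to a stop -> nonsense; any other
    amino-acid change (including loss of a stop) -> missense.
    """
    for codon in (ref_codon, alt_codon):
        if len(codon) != 3 or any(b not in "ACGT" for b in codon.upper()):
            raise ValueError(f"invalid codon {codon!r}")
    ref_aa = str(Seq(ref_codon.upper()).translate())
    alt_aa = str(Seq(alt_codon.upper()).translate())
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    return "missense"


def fixed_fraction(records: Sequence[VariantRecord]) -> float:
    """Share of records fixed in the population (allele frequency 100%)."""
    if not records:
        raise ValueError("empty record list")
    return sum(r.is_fixed for r in records) / len(records)


def summarize_by_lineage(
    records: Sequence[VariantRecord],
    lineages: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-lineage counts of SNPs, DIPs, codon effects, and fixed mutations.

    ``lineages`` forces rows (all-zero if empty) for the given labels in
    addition to any lineage present in the records.
    """
    zero = {"n": 0, "snp": 0, "dip": 0, "missense": 0, "nonsense": 0,
            "synonymous": 0, "fixed": 0}
    rows = {lin: dict(zero) for lin in (lineages or ())}
    for r in records:
        row = rows.setdefault(r.lineage, dict(zero))
        row["n"] += 1
        row["snp" if r.mutation_class == "SNP" else "dip"] += 1
        if r.effect in ("missense", "nonsense", "synonymous"):
            row[r.effect] += 1
        row["fixed"] += int(r.is_fixed)
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "lineage"
    return df


def table1_fixture_path() -> Path:
    """Path to the bundled transcription of the published mutation table."""
    return Path(str(files("oriscope") / "fixtures" / "table1_variants.tsv"))


def load_table1_fixture() -> List[VariantRecord]:
    return parse_variant_table(table1_fixture_path())
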
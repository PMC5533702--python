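"""Canonical data model for diploid autosomal STR genotype tables.

Alleles at short tandem repeat loci are repeat-count designations rendered as
text: integral ("10") or microvariant with a single fractional digit ("9.3").
Sorting and comparison of allele labels is always numeric, never
lexicographic, so "9.3" < "10".

The module provides the :class:`GenotypeTable` container (individuals x loci
grid of diploid calls plus per-individual metadata), readers and writers for
the Genepop dialect and the two-row STRUCTURE matrix, a delimited wide-table
format, and QC reporting of microvariant alleles, tri-allelic patterns and
missing calls.

Tri-allelic calls (a third amplified allele, seen in real panels at TPOX) are
carried as genotype metadata and excluded from every downstream statistic;
they surface only through :func:`qc_flags`.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "encode_calls",
    "allele_value",
    "sort_alleles",
    "Genotype",
    "MISSING",
    "Individual",
    "GenotypeTable",
    "QCReport",
    "read_genepop",
    "write_genepop",
    "write_structure_matrix",
    "read_delimited",
    "write_delimited",
    "qc_flags",
    "GenepopParseError",
]

PHYLA = ("Bantu", "Khoisan", "unknown")
SUBGROUPS = (
    "Central-K", "Central-R", "Central-S",
    "Khoe-Kwadi", "Kx'a", "Tuu", "unknown",
)
#: subgroup -> phylum consistency map
SUBGROUP_PHYLUM = {
    "Central-K": "Bantu", "Central-R": "Bantu", "Central-S": "Bantu",
    "Khoe-Kwadi": "Khoisan", "Kx'a": "Khoisan", "Tuu": "Khoisan",
}
DISTRICTS = (
    "Central", "Ghanzi", "Kgalagadi", "Kgatleng", "Kweneng",
    "North-east", "North-west", "Southern", "South-east",
)

_ALLELE_RE = re.compile(r"^\d+(\.\d)?$")


class GenepopParseError(ValueError):
    """Raised when a Genepop file cannot be decoded; names the line."""


def allele_value(label: str) -> Fraction:
    """Numeric value of an allele label, exact (no float rounding).

    Raises ``ValueError`` for labels that are not a non-negative decimal
    with at most one fractional digit.
    """
    if not _ALLELE_RE.match(label):
        raise ValueError(f"invalid allele label {label!r}")
    return Fraction(int(label.replace(".", "")), 10 if "." in label else 1)


def sort_alleles(labels: Iterable[str]) -> list[str]:
    """Sort allele labels numerically: ['10', '9.3'] -> ['9.3', '10']."""
    return sorted(labels, key=allele_value)


@dataclass(frozen=True)
class Genotype:
    """A diploid call: an unordered allele pair, or missing.

    ``alleles`` is ``None`` when the call is missing (all-or-nothing per
    locus per individual) and otherwise a numerically sorted pair.
    ``extra`` holds any additional amplified alleles (tri-allelic pattern);
    it is empty for normal genotypes.
    """

    alleles: tuple[str, str] | None
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.alleles is not None:
            a, b = self.alleles
            ordered = tuple(sort_alleles([a, b]))
            object.__setattr__(self, "alleles", ordered)
        elif self.extra:
            raise ValueError("missing genotype cannot carry extra alleles")
        object.__setattr__(self, "extra", tuple(sort_alleles(self.extra)))

    @property
    def missing(self) -> bool:
        return self.alleles is None

    @property
    def heterozygous(self) -> bool:
        """True if the two (primary) alleles differ; False if missing."""
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def triallelic(self) -> bool:
        return bool(self.extra)

    def __iter__(self):
        if self.alleles is None:
            return iter(())
        return iter(self.alleles)


MISSING = Genotype(None)


@dataclass(frozen=True)
class Individual:
    """Sample metadata: id, ethno-linguistic labels, district, sex."""

    id: str
    phylum: str = "unknown"
    subgroup: str = "unknown"
    district: str = "unknown"
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.phylum not in PHYLA:
            raise ValueError(f"unknown phylum {self.phylum!r}")
        if self.subgroup not in SUBGROUPS:
            raise ValueError(f"unknown subgroup {self.subgroup!r}")
        if self.district not in DISTRICTS + ("unknown",):
            raise ValueError(f"unknown district {self.district!r}")
        if self.sex not in ("F", "M", "unknown"):
            raise ValueError(f"unknown sex {self.sex!r}")
        expected = SUBGROUP_PHYLUM.get(self.subgroup)
        if expected is not None and self.phylum != "unknown" and self.phylum != expected:
            raise ValueError(
                f"subgroup {self.subgroup!r} inconsistent with phylum {self.phylum!r}"
            )


class GenotypeTable:
    """Rectangular individuals x loci grid of diploid STR calls.

    Parameters
    ----------
    loci
        Ordered locus names, unique.
    individuals
        One :class:`Individual` per row.
    calls
        ``calls[i][j]`` is the :class:`Genotype` of individual ``i`` at
        locus ``j``.
    """

    def __init__(
        self,
        loci: Sequence[str],
        individuals: Sequence[Individual],
        calls: Sequence[Sequence[Genotype]],
    ) -> None:
        loci = list(loci)
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate locus names")
        individuals = list(individuals)
        calls = [list(row) for row in calls]
        if len(calls) != len(individuals):
            raise ValueError("calls/individuals length mismatch")
        for row in calls:
            if len(row) != len(loci):
                raise ValueError("ragged calls grid")
        self.loci = loci
        self.individuals = individuals
        self.calls = calls

    # -- basic introspection -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def column(self, locus: str) -> list[Genotype]:
        j = self.locus_index(locus)
        return [row[j] for row in self.calls]

    def allele_registry(self, locus: str) -> list[str]:
        """All allele labels observed at a locus, numerically sorted."""
        seen: set[str] = set()
        for g in self.column(locus):
            if not g.missing:
                seen.update(g.alleles)
                seen.update(g.extra)
        return sort_alleles(seen)

    def metadata_values(self, grouping: str) -> list[str]:
        """Per-individual values of a metadata field ('phylum', ...)."""
        return [getattr(ind, grouping) for ind in self.individuals]

    def group_indices(self, grouping: str) -> dict[str, list[int]]:
        """Row indices per group level, in first-appearance order.

        Individuals whose value for the field is 'unknown' are skipped.
        """
        out: dict[str, list[int]] = {}
        for i, val in enumerate(self.metadata_values(grouping)):
            if val == "unknown":
                continue
            out.setdefault(val, []).append(i)
        return out

    def subset(self, rows: Sequence[int]) -> "GenotypeTable":
        return GenotypeTable(
            self.loci,
            [self.individuals[i] for i in rows],
            [self.calls[i] for i in rows],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.individuals == other.individuals
            and self.calls == other.calls
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeTable({self.n_individuals} individuals x "
            f"{self.n_loci} loci)"
        )


# ---------------------------------------------------------------------------
# Genepop dialect
# ---------------------------------------------------------------------------

def _decode_code(code: str, lineno: int) -> str | None:
    """Decode a 2- or 3-digit Genepop allele code to an allele label.

    Three-digit codes follow the forensic convention label = code / 10
    ("093" -> "9.3", "100" -> "10"); two-digit codes are the label itself.
    "000"/"00" is the missing marker.
    """
    if int(code) == 0:
        return None
    if len(code) == 3:
        tenths = int(code)
        if tenths % 10 == 0:
            return str(tenths // 10)
        return f"{tenths // 10}.{tenths % 10}"
    if len(code) == 2:
        return str(int(code))
    raise GenepopParseError(f"line {lineno}: allele code {code!r} not decodable")


def _encode_label(label: str) -> str:
    code = int(allele_value(label) * 10)
    if code > 999:
        raise ValueError(f"allele label {label!r} not encodable in 3 digits")
    return f"{code:03d}"


def read_genepop(path: str | Path) -> GenotypeTable:
    """Read a Genepop genotype file into a :class:`GenotypeTable`.

    Layout: a title line, locus names (one per line or comma-separated on
    one line), then POP blocks of ``id , code1code2 ...`` rows with 2- or
    3-digit allele codes per allele.  POP block order is preserved as a
    grouping annotation: the i-th block's individuals get phylum/subgroup
    parsed from the block-leading id when it matches a known label, else
    the block index is recorded in the individual id prefix only.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise GenepopParseError("line 1: empty file")
    # locus names: lines 2.. until first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        part = [x.strip() for x in lines[i].split(",") if x.strip()]
        loci.extend(part)
        i += 1
    if len(set(loci)) != len(loci):
        raise GenepopParseError(f"line {i}: duplicate locus names")
    if i == len(lines):
        raise GenepopParseError(f"line {len(lines)}: no POP block found")

    individuals: list[Individual] = []
    calls: list[list[Genotype]] = []
    pop_index = -1
    pop_of_row: list[int] = []
    while i < len(lines):
        line = lines[i]
        if line.strip().lower() == "pop":
            pop_index += 1
            i += 1
            continue
        if not line.strip():
            i += 1
            continue
        lineno = i + 1
        if "," not in line:
            raise GenepopParseError(f"line {lineno}: expected 'id , genotypes'")
        ident, _, geno_part = line.partition(",")
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise GenepopParseError(
                f"line {lineno}: {len(fields)} genotype fields for {len(loci)} loci"
            )
        row: list[Genotype] = []
        for f_ in fields:
            if len(f_) not in (4, 6) or not f_.isdigit():
                raise GenepopParseError(
                    f"line {lineno}: genotype field {f_!r} not decodable"
                )
            half = len(f_) // 2
            a = _decode_code(f_[:half], lineno)
            b = _decode_code(f_[half:], lineno)
            if (a is None) != (b is None):
                # one-sided missing: treat whole call as missing
                row.append(MISSING)
            elif a is None:
                row.append(MISSING)
            else:
                row.append(Genotype((a, b)))
        individuals.append(Individual(id=ident.strip()))
        pop_of_row.append(pop_index)
        calls.append(row)
        i += 1
    table = GenotypeTable(loci, individuals, calls)
    table.pop_blocks = pop_of_row  # grouping annotation, block order preserved
    return table


def write_genepop(
    table: GenotypeTable,
    path: str | Path,
    grouping: str = "phylum",
    title: str = "strpopgen export",
) -> Path:
    """Write a Genepop file, one POP block per level of ``grouping``.

    Alleles are encoded as zero-padded 3-digit codes ``round(label*10)``;
    missing calls as "000000".  Output is deterministic (input order) and
    bit-identical for identical inputs.  Tri-allelic extras are dropped
    (the dialect is strictly diploid).
    """
    path = Path(path)
    groups = table.group_indices(grouping)
    if not groups:  # everything 'unknown': single block
        groups = {"all": list(range(table.n_individuals))}
    buf = io.StringIO()
    buf.write(title + "\n")
    for locus in table.loci:
        buf.write(locus + "\n")
    for _, rows in groups.items():
        buf.write("POP\n")
        for i in rows:
            codes = []
            for g in table.calls[i]:
                if g.missing:
                    codes.append("000000")
                else:
                    codes.append(_encode_label(g.alleles[0]) + _encode_label(g.alleles[1]))
            buf.write(f"{table.individuals[i].id} , " + " ".join(codes) + "\n")
    path.write_text(buf.getvalue())
    return path


# ---------------------------------------------------------------------------
# STRUCTURE matrix
# ---------------------------------------------------------------------------

def write_structure_matrix(
    table: GenotypeTable, path: str | Path
) -> tuple[Path, dict[str, dict[str, int]]]:
    """Write the two-rows-per-individual integer matrix format.

    Alleles are recoded to consecutive integers (1..k, numeric label order)
    per locus; missing is -9.  Returns the path and the per-locus recode map
    ``{locus: {label: code}}``, which is also persisted as a sidecar
    ``<path>.recode.tsv``.
    """
    path = Path(path)
    recode: dict[str, dict[str, int]] = {
        locus: {lab: i + 1 for i, lab in enumerate(table.allele_registry(locus))}
        for locus in table.loci
    }
    with open(path, "w") as fh:
        fh.write("\t".join(["id"] + table.loci) + "\n")
        for ind, row in zip(table.individuals, table.calls):
            for copy in (0, 1):
                cells = [ind.id]
                for locus, g in zip(table.loci, row):
                    if g.missing:
                        cells.append("-9")
                    else:
                        cells.append(str(recode[locus][g.alleles[copy]]))
                fh.write("\t".join(cells) + "\n")
    side = path.with_suffix(path.suffix + ".recode.tsv")
    with open(side, "w") as fh:
        fh.write("locus\tallele\tcode\n")
        for locus, m in recode.items():
            for lab, code in m.items():
                fh.write(f"{locus}\t{lab}\t{code}\n")
    return path, recode


# ---------------------------------------------------------------------------
# Delimited wide table
# ---------------------------------------------------------------------------

_META_COLS = ["id", "phylum", "subgroup", "district", "sex"]


def write_delimited(table: GenotypeTable, path: str | Path, sep: str = "\t") -> Path:
    """One row per individual; two columns per locus; empty cell = missing."""
    path = Path(path)
    cols: dict[str, list] = {c: [] for c in _META_COLS}
    for ind in table.individuals:
        for c in _META_COLS:
            cols[c].append(getattr(ind, c))
    for j, locus in enumerate(table.loci):
        a1, a2 = [], []
        for row in table.calls:
            g = row[j]
            a1.append("" if g.missing else g.alleles[0])
            a2.append("" if g.missing else g.alleles[1])
        cols[f"{locus}_1"] = a1
        cols[f"{locus}_2"] = a2
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)
    return path


def read_delimited(path: str | Path, sep: str = "\t") -> GenotypeTable:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    locus_cols = [c for c in df.columns if c.endswith("_1")]
    loci = [c[:-2] for c in locus_cols]
    individuals = [
        Individual(
            id=str(r["id"]),
            phylum=r.get("phylum", "unknown") or "unknown",
            subgroup=r.get("subgroup", "unknown") or "unknown",
            district=r.get("district", "unknown") or "unknown",
            sex=r.get("sex", "unknown") or "unknown",
        )
        for _, r in df.iterrows()
    ]
    calls = []
    for _, r in df.iterrows():
        row = []
        for locus in loci:
            a1, a2 = r[f"{locus}_1"], r[f"{locus}_2"]
            row.append(MISSING if a1 == "" or a2 == "" else Genotype((a1, a2)))
        calls.append(row)
    return GenotypeTable(loci, individuals, calls)


# ---------------------------------------------------------------------------
# Integer encoding for numeric stages
# ---------------------------------------------------------------------------

def encode_calls(
    table: GenotypeTable,
) -> tuple[np.ndarray, list[list[str]]]:
    """Integer-code the calls grid for vectorized statistics.

    Returns ``(codes, registries)`` where ``codes`` is an
    ``(n_individuals, n_loci, 2)`` int array with alleles coded 0..k-1 in
    numeric label order per locus and -1 for missing, and ``registries`` is
    the per-locus label list such that ``registries[j][code]`` recovers the
    label.  Tri-allelic calls are treated as missing, matching their
    exclusion from all statistics.
    """
    registries = [table.allele_registry(l) for l in table.loci]
    maps = [{lab: i for i, lab in enumerate(reg)} for reg in registries]
    codes = np.full((table.n_individuals, table.n_loci, 2), -1, dtype=np.int64)
    for i, row in enumerate(table.calls):
        for j, g in enumerate(row):
            if g.missing or g.triallelic:
                continue
            codes[i, j, 0] = maps[j][g.alleles[0]]
            codes[i, j, 1] = maps[j][g.alleles[1]]
    return codes, registries


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-locus QC counts plus itemized tri-allelic records."""

    microvariant_counts: dict[str, int]
    triallelic_counts: dict[str, int]
    missing_rate: dict[str, float]
    triallelic_records: list[dict]

    def to_frame(self) -> pd.DataFrame:
        loci = list(self.microvariant_counts)
        return pd.DataFrame(
            {
                "locus": loci,
                "microvariant_calls": [self.microvariant_counts[l] for l in loci],
                "triallelic_calls": [self.triallelic_counts[l] for l in loci],
                "missing_rate": [self.missing_rate[l] for l in loci],
            }
        )


def _is_microvariant(label: str) -> bool:
    return "." in label


def qc_flags(table: GenotypeTable) -> QCReport:
    """QC report: microvariant call counts, tri-allelic records, missing rate.

    A call counts as microvariant if any of its alleles has a fractional
    part.  Each tri-allelic call is itemized with individual id and sex.
    Counts are invariant to row/column permutation of the table.
    """
    micro = {l: 0 for l in table.loci}
    tri = {l: 0 for l in table.loci}
    miss = {l: 0 for l in table.loci}
    records: list[dict] = []
    for ind, row in zip(table.individuals, table.calls):
        for locus, g in zip(table.loci, row):
            if g.missing:
                miss[locus] += 1
                continue
            if any(_is_microvariant(a) for a in g.alleles) or any(
                _is_microvariant(a) for a in g.extra
            ):
                micro[locus] += 1
            if g.triallelic:
                tri[locus] += 1
                records.append(
                    {
                        "individual": ind.id,
                        "sex": ind.sex,
                        "locus": locus,
                        "alleles": list(g.alleles) + list(g.extra),
                    }
                )
    n = max(table.n_individuals, 1)
    rate = {l: miss[l] / n for l in table.loci}
    return QCReport(micro, tri, rate, records)
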
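"""Readers and writers for the flat-file tables the pipeline consumes.

Every external table is tab-separated UTF-8 with a header line; lines
starting with ``#`` are comments. Gene coordinates additionally accept BED
(0-based half-open, converted to 1-based inclusive on read). All readers
validate records against the domain-type invariants and raise on the first
violation, so downstream code only ever sees clean records.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

FUNCTION_CLASSES = frozenset(
    {"nonsynonymous", "coding-synonymous", "intronic", "intergenic", "other", "unknown"}
)
DISEASE_CLASSES = frozenset({"autoimmune", "cancer", "neuro_psych", "other"})


class SchemaError(ValueError):
    """A required column is missing or the file shape is wrong."""


class ParseError(ValueError):
    """A field could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A parsed record violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class SnpRecord:
    """One SNP on a genotyping panel.

    ``maf`` is the minor allele frequency, constrained to [0, 0.5];
    ``platform_flags`` names the high-throughput products carrying the SNP.
    """

    rsid: str
    chrom: str
    pos: int
    maf: float
    platform_flags: frozenset[str] = frozenset()
    function_class: str = "unknown"

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValidationError(f"{self.rsid}: maf {self.maf} outside [0, 0.5]")
        if self.pos < 1:
            raise ValidationError(f"{self.rsid}: pos {self.pos} < 1")
        if self.function_class not in FUNCTION_CLASSES:
            raise ValidationError(
                f"{self.rsid}: unknown function_class {self.function_class!r}"
            )


@dataclass(frozen=True)
class CatalogEntry:
    """A trait-associated SNP from a GWAS-catalog-style listing."""

    rsid: str
    trait: str
    disease_class: str
    reported_p: float

    def __post_init__(self) -> None:
        if self.disease_class not in DISEASE_CLASSES:
            raise ValidationError(
                f"{self.rsid}: unknown disease_class {self.disease_class!r}"
            )
        if not 0.0 < self.reported_p <= 1.0:
            raise ValidationError(f"{self.rsid}: reported_p {self.reported_p} not in (0, 1]")


@dataclass(frozen=True)
class GeneRecord:
    """Gene coordinates, 1-based inclusive on both ends."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class EqtlAssociation:
    """One SNP-transcript association p-value."""

    rsid: str
    gene_id: str
    p: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValidationError(f"{self.rsid}/{self.gene_id}: p {self.p} not in (0, 1]")


@dataclass(frozen=True)
class GwasRecord:
    """One GWAS summary-statistic row; ``rsid`` may be empty."""

    rsid: str
    chrom: str
    p: float
    maf: float
    missing_rate: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValidationError(f"{self.rsid or '<no rsid>'}: p {self.p} not in (0, 1]")
        if not 0.0 <= self.maf <= 0.5:
            raise ValidationError(f"{self.rsid or '<no rsid>'}: maf {self.maf} outside [0, 0.5]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValidationError(
                f"{self.rsid or '<no rsid>'}: missing_rate {self.missing_rate} outside [0, 1]"
            )


# ---------------------------------------------------------------------------
# low-level TSV plumbing


def _iter_rows(path: str | Path, required: Sequence[str]) -> Iterable[tuple[int, dict]]:
    """Yield (line_number, row_dict) from a commented TSV, checking the header."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        lines = ((i, line) for i, line in enumerate(handle, start=1) if not line.startswith("#"))
        try:
            header_no, header_line = next(lines)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, no header") from None
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in required if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        for lineno, line in lines:
            if not line.strip():
                continue
            values = line.rstrip("\n").split("\t")
            if len(values) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(values)}"
                )
            yield lineno, dict(zip(header, values))


def _parse_float(value: str, path: Path, lineno: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: malformed {column} value {value!r}") from None


def _parse_int(value: str, path: Path, lineno: int, column: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: malformed {column} value {value!r}") from None


def _wrap_invalid(record_factory, path, lineno):
    try:
        return record_factory()
    except ValidationError as exc:
        raise ValidationError(f"{path}:{lineno}: {exc}") from None


# ---------------------------------------------------------------------------
# readers


def read_catalog(path: str | Path, inclusion_threshold: float = 1e-5) -> list[CatalogEntry]:
    """Read a trait-associated SNP catalog, keeping entries at or below
    ``inclusion_threshold`` and collapsing duplicate rsids (first wins).
    """
    path = Path(path)
    entries: list[CatalogEntry] = []
    seen: set[str] = set()
    n_dup = 0
    for lineno, row in _iter_rows(path, ["rsid", "trait", "disease_class", "reported_p"]):
        p = _parse_float(row["reported_p"], path, lineno, "reported_p")
        entry = _wrap_invalid(
            lambda: CatalogEntry(row["rsid"], row["trait"], row["disease_class"], p),
            path,
            lineno,
        )
        if entry.reported_p > inclusion_threshold:
            continue
        if entry.rsid in seen:
            n_dup += 1
            continue
        seen.add(entry.rsid)
        entries.append(entry)
    if n_dup:
        logger.info("read_catalog: collapsed %d duplicate rsid row(s) in %s", n_dup, path)
    return entries


def read_panel(path: str | Path) -> list[SnpRecord]:
    """Read a SNP panel table (rsid, chrom, pos, maf, platforms, function_class).

    ``platforms`` is a comma-separated list; empty means no platform flags.
    """
    path = Path(path)
    records: list[SnpRecord] = []
    seen: set[str] = set()
    cols = ["rsid", "chrom", "pos", "maf", "platforms", "function_class"]
    for lineno, row in _iter_rows(path, cols):
        if row["rsid"] in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate rsid {row['rsid']}")
        seen.add(row["rsid"])
        flags = frozenset(f for f in row["platforms"].split(",") if f)
        records.append(
            _wrap_invalid(
                lambda: SnpRecord(
                    rsid=row["rsid"],
                    chrom=row["chrom"],
                    pos=_parse_int(row["pos"], path, lineno, "pos"),
                    maf=_parse_float(row["maf"], path, lineno, "maf"),
                    platform_flags=flags,
                    function_class=row["function_class"],
                ),
                path,
                lineno,
            )
        )
    return records


def read_eqtl_table(path: str | Path) -> list[EqtlAssociation]:
    """Read a SNP-by-transcript eQTL association table."""
    path = Path(path)
    out = []
    for lineno, row in _iter_rows(path, ["rsid", "gene_id", "p"]):
        p = _parse_float(row["p"], path, lineno, "p")
        out.append(_wrap_invalid(lambda: EqtlAssociation(row["rsid"], row["gene_id"], p), path, lineno))
    return out


def read_gwas_summary(path: str | Path) -> list[GwasRecord]:
    """Read GWAS summary statistics. No filtering happens here; QC is a
    separate explicit step (:func:`eqtl_enrich.gwas_annotation.qc_filter`).
    """
    path = Path(path)
    out = []
    for lineno, row in _iter_rows(path, ["rsid", "chrom", "p", "maf", "missing_rate"]):
        out.append(
            _wrap_invalid(
                lambda: GwasRecord(
                    rsid=row["rsid"],
                    chrom=row["chrom"],
                    p=_parse_float(row["p"], path, lineno, "p"),
                    maf=_parse_float(row["maf"], path, lineno, "maf"),
                    missing_rate=_parse_float(row["missing_rate"], path, lineno, "missing_rate"),
                ),
                path,
                lineno,
            )
        )
    return out


def read_genes(path: str | Path, fmt: str | None = None) -> list[GeneRecord]:
    """Read gene coordinates from BED (0-based half-open) or a GFF-lite TSV
    (header ``gene_id chrom start end``, already 1-based inclusive).

    ``fmt`` is ``"bed"`` or ``"tsv"``; inferred from the suffix when None.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() == ".bed" else "tsv"
    genes: list[GeneRecord] = []
    if fmt == "bed":
        with path.open(encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 4:
                    raise ParseError(f"{path}:{lineno}: BED needs chrom,start,end,name")
                chrom, start, end, name = fields[:4]
                genes.append(
                    _wrap_invalid(
                        lambda: GeneRecord(
                            gene_id=name,
                            chrom=chrom,
                            # BED half-open zero-based -> 1-based inclusive
                            start=_parse_int(start, path, lineno, "start") + 1,
                            end=_parse_int(end, path, lineno, "end"),
                        ),
                        path,
                        lineno,
                    )
                )
    elif fmt == "tsv":
        for lineno, row in _iter_rows(path, ["gene_id", "chrom", "start", "end"]):
            genes.append(
                _wrap_invalid(
                    lambda: GeneRecord(
                        gene_id=row["gene_id"],
                        chrom=row["chrom"],
                        start=_parse_int(row["start"], path, lineno, "start"),
                        end=_parse_int(row["end"], path, lineno, "end"),
                    ),
                    path,
                    lineno,
                )
            )
    else:
        raise ValueError(f"unknown gene format {fmt!r}")
    return genes


def read_r2_table(path: str | Path) -> dict[tuple[str, str], float]:
    """Read a pairwise r-squared table (columns rsid_a, rsid_b, r2) into a
    symmetric lookup keyed by sorted rsid pair.
    """
    path = Path(path)
    r2: dict[tuple[str, str], float] = {}
    for lineno, row in _iter_rows(path, ["rsid_a", "rsid_b", "r2"]):
        value = _parse_float(row["r2"], path, lineno, "r2")
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"{path}:{lineno}: r2 {value} outside [0, 1]")
        key = tuple(sorted((row["rsid_a"], row["rsid_b"])))
        r2[key] = value
    return r2


def read_frq(path: str | Path) -> dict[str, float]:
    """Read MAFs from a PLINK-style .frq table (CHR SNP A1 A2 MAF NCHROBS).

    The file is whitespace-delimited as PLINK writes it.
    """
    path = Path(path)
    mafs: dict[str, float] = {}
    with path.open(encoding="utf-8") as handle:
        header = handle.readline().split()
        for col in ("SNP", "MAF"):
            if col not in header:
                raise SchemaError(f"{path}: missing required column {col}")
        i_snp, i_maf = header.index("SNP"), header.index("MAF")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.split()
            maf = _parse_float(fields[i_maf], path, lineno, "MAF")
            if not 0.0 <= maf <= 0.5:
                raise ValidationError(f"{path}:{lineno}: MAF {maf} outside [0, 0.5]")
            mafs[fields[i_snp]] = maf
    return mafs


# ---------------------------------------------------------------------------
# writers


def write_score_table(records: Iterable[tuple[str, float, str]], path: str | Path) -> None:
    """Write (rsid, score, class) rows; scores rendered at 6 decimal places."""
    path = Path(path)
    rows = list(records)
    for rsid, score, _cls in rows:
        if not (math.isfinite(score) and score >= 0.0):
            raise ValidationError(f"{rsid}: score {score} must be finite and >= 0")
    with path.open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("rsid\tscore\tclass\n")
        for rsid, score, cls in rows:
            handle.write(f"{rsid}\t{score:.6f}\t{cls}\n")


def read_score_table(path: str | Path) -> list[tuple[str, float, str]]:
    path = Path(path)
    out = []
    for lineno, row in _iter_rows(path, ["rsid", "score", "class"]):
        out.append((row["rsid"], _parse_float(row["score"], path, lineno, "score"), row["class"]))
    return out


def write_panel(records: Iterable[SnpRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("rsid\tchrom\tpos\tmaf\tplatforms\tfunction_class\n")
        for r in records:
            flags = ",".join(sorted(r.platform_flags))
            handle.write(f"{r.rsid}\t{r.chrom}\t{r.pos}\t{r.maf:.6g}\t{flags}\t{r.function_class}\n")


def write_catalog(entries: Iterable[CatalogEntry], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("rsid\ttrait\tdisease_class\treported_p\n")
        for e in entries:
            handle.write(f"{e.rsid}\t{e.trait}\t{e.disease_class}\t{e.reported_p:.6g}\n")


def write_eqtl_table(associations: Iterable[EqtlAssociation], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("rsid\tgene_id\tp\n")
        for a in associations:
            handle.write(f"{a.rsid}\t{a.gene_id}\t{a.p:.6g}\n")


def write_gwas_summary(records: Iterable[GwasRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("rsid\tchrom\tp\tmaf\tmissing_rate\n")
        for r in records:
            handle.write(f"{r.rsid}\t{r.chrom}\t{r.p:.6g}\t{r.maf:.6g}\t{r.missing_rate:.6g}\n")


def write_genes_bed(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write genes as BED (converting back to 0-based half-open)."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        for g in genes:
            handle.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


def write_r2_table(r2: Mapping[tuple[str, str], float], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("rsid_a\trsid_b\tr2\n")
        for (a, b), value in sorted(r2.items()):
            handle.write(f"{a}\t{b}\t{value:.6g}\n")


def write_truth_json(truth: Mapping, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        json.dump(truth, handle, indent=1, sort_keys=True)
        handle.write("\n")
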
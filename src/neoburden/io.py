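"""Readers and writers for the pipeline's plain-text exchange formats.

Formats handled here:

* mutation table — TSV with a header row; ``#``-prefixed comment lines are
  ignored; unknown columns round-trip through ``MutationRecord.annotations``;
* protein FASTA — standard FASTA, identifier taken as the first
  whitespace-delimited header token;
* allele lists — either one allele name per line (a single anonymous sample)
  or a TSV keyed by sample;
* peptide windows / vaccine panels — FASTA and TSV exports.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import FormatError
from .records import (
    AA_ALPHABET_X,
    AlleleSet,
    MutationRecord,
    ProteinRecord,
    VariantClass,
)

#: Normalization map for variant-class spellings. MAF-style names (as used in
#: TCGA mutation annotation files) and the native lowercase names are both
#: accepted; anything else is an error rather than a silent drop.
VARIANT_CLASS_ALIASES: Mapping[str, VariantClass] = {
    "missense": VariantClass.MISSENSE,
    "missense_mutation": VariantClass.MISSENSE,
    "inframe_indel": VariantClass.INFRAME_INDEL,
    "in_frame_del": VariantClass.INFRAME_INDEL,
    "in_frame_ins": VariantClass.INFRAME_INDEL,
    "frameshift": VariantClass.FRAMESHIFT,
    "frame_shift_del": VariantClass.FRAMESHIFT,
    "frame_shift_ins": VariantClass.FRAMESHIFT,
    "nonsense": VariantClass.NONSENSE,
    "nonsense_mutation": VariantClass.NONSENSE,
    "synonymous": VariantClass.SYNONYMOUS,
    "silent": VariantClass.SYNONYMOUS,
}

REQUIRED_MUTATION_COLUMNS = (
    "sample_id",
    "gene",
    "protein_id",
    "variant_class",
    "position",
    "ref_aa",
    "alt_aa",
    "rna_reads_ref",
    "rna_reads_alt",
    "in_dbsnp",
    "somatic",
)

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


def normalize_variant_class(
    text: str, dialect: Mapping[str, VariantClass] | None = None
) -> VariantClass:
    """Map a variant-class spelling to its canonical class.

    Unknown spellings raise :class:`FormatError`.
    """
    table = dialect if dialect is not None else VARIANT_CLASS_ALIASES
    key = text.strip().lower()
    if key not in table:
        raise FormatError(f"unknown variant class spelling {text!r}")
    return table[key]


def _parse_int(value: str, column: str, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(
            f"line {lineno}: unparseable count {value!r} in column {column!r}"
        ) from None


def _parse_bool(value: str, column: str, lineno: int) -> bool:
    key = value.strip().lower()
    if key in _TRUE:
        return True
    if key in _FALSE:
        return False
    raise FormatError(
        f"line {lineno}: unparseable flag {value!r} in column {column!r}"
    )


def read_mutation_table(
    path: str | Path,
    dialect: Mapping[str, VariantClass] | None = None,
) -> list[MutationRecord]:
    """Read a tab-separated somatic mutation table.

    Comment lines starting with ``#`` are skipped. Required columns are
    checked by name; extra columns are preserved verbatim in each record's
    ``annotations``. Row order is preserved.
    """
    path = Path(path)
    records: list[MutationRecord] = []
    with path.open(newline="") as handle:
        header: list[str] | None = None
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = fields
                missing = [c for c in REQUIRED_MUTATION_COLUMNS if c not in header]
                if missing:
                    raise FormatError(
                        f"mutation table {path} is missing required "
                        f"column(s): {', '.join(missing)}"
                    )
                continue
            if len(fields) != len(header):
                raise FormatError(
                    f"line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            row = dict(zip(header, fields))
            annotations = {
                k: v for k, v in row.items() if k not in REQUIRED_MUTATION_COLUMNS
            }
            records.append(
                MutationRecord(
                    sample_id=row["sample_id"],
                    gene=row["gene"],
                    protein_id=row["protein_id"],
                    variant_class=normalize_variant_class(
                        row["variant_class"], dialect
                    ),
                    position=_parse_int(row["position"], "position", lineno),
                    ref_aa=row["ref_aa"],
                    alt_aa=row["alt_aa"],
                    rna_reads_ref=_parse_int(
                        row["rna_reads_ref"], "rna_reads_ref", lineno
                    ),
                    rna_reads_alt=_parse_int(
                        row["rna_reads_alt"], "rna_reads_alt", lineno
                    ),
                    in_dbsnp=_parse_bool(row["in_dbsnp"], "in_dbsnp", lineno),
                    somatic=_parse_bool(row["somatic"], "somatic", lineno),
                    annotations=annotations,
                )
            )
        if header is None:
            raise FormatError(f"mutation table {path} has no header line")
    return records


def write_mutation_table(
    records: Sequence[MutationRecord], path: str | Path
) -> None:
    """Write records as TSV, preserving annotation columns."""
    extra_cols: list[str] = []
    for rec in records:
        for key in rec.annotations:
            if key not in extra_cols:
                extra_cols.append(key)
    columns = list(REQUIRED_MUTATION_COLUMNS) + extra_cols
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for rec in records:
            row = [
                rec.sample_id,
                rec.gene,
                rec.protein_id,
                rec.variant_class.value,
                rec.position,
                rec.ref_aa,
                rec.alt_aa,
                rec.rna_reads_ref,
                rec.rna_reads_alt,
                rec.in_dbsnp,
                rec.somatic,
            ] + [rec.annotations.get(c, "") for c in extra_cols]
            writer.writerow(row)


def read_protein_fasta(path: str | Path) -> dict[str, ProteinRecord]:
    """Read a protein FASTA into a map keyed by identifier.

    Sequences are upper-cased; duplicate identifiers and residues outside the
    20-letter alphabet (plus ``X``) are rejected.
    """
    proteins: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in proteins:
            raise FormatError(f"duplicate protein identifier {pid!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - AA_ALPHABET_X
        if bad:
            raise FormatError(
                f"illegal residue character(s) {sorted(bad)!r} in record {pid!r}"
            )
        # Use the second header token as gene name when present.
        parts = rec.description.split()
        gene = parts[1] if len(parts) > 1 else pid
        proteins[pid] = ProteinRecord(protein_id=pid, gene=gene, sequence=seq)
    return proteins


def write_protein_fasta(
    proteins: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
    path: str | Path,
    width: int = 60,
) -> None:
    records = (
        proteins.values() if isinstance(proteins, Mapping) else proteins
    )
    with Path(path).open("w") as handle:
        for rec in records:
            handle.write(f">{rec.protein_id} {rec.gene}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def read_allele_list(path: str | Path) -> list[str]:
    """Read a plain allele list: one MHC allele name per line."""
    alleles = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            alleles.append(line)
    return alleles


def read_allele_sets(path: str | Path) -> dict[str, AlleleSet]:
    """Read a per-sample allele TSV.

    Columns: ``sample_id``, ``allele``, and optionally ``typed_loci``,
    ``total_loci``, ``unambiguous``. One row per allele; rows for the same
    sample are grouped.
    """
    path = Path(path)
    rows: list[dict[str, str]] = []
    with path.open(newline="") as handle:
        reader = csv.DictReader(
            (l for l in handle if not l.startswith("#")), delimiter="\t"
        )
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise FormatError(f"allele table {path} needs a 'sample_id' column")
        if "allele" not in reader.fieldnames:
            raise FormatError(f"allele table {path} needs an 'allele' column")
        rows = list(reader)

    grouped: dict[str, list[dict[str, str]]] = {}
    for row in rows:
        grouped.setdefault(row["sample_id"], []).append(row)

    out: dict[str, AlleleSet] = {}
    for sample_id, sample_rows in grouped.items():
        first = sample_rows[0]
        alleles = tuple(r["allele"] for r in sample_rows if r["allele"])
        out[sample_id] = AlleleSet(
            sample_id=sample_id,
            alleles=alleles,
            typed_loci=int(first.get("typed_loci") or 1),
            total_loci=int(first.get("total_loci") or 3),
            unambiguous=_parse_bool(
                first.get("unambiguous") or "true", "unambiguous", 0
            ),
        )
    return out


def write_allele_sets(
    allele_sets: Mapping[str, AlleleSet], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["sample_id", "allele", "typed_loci", "total_loci", "unambiguous"]
        )
        for sample_id in allele_sets:
            aset = allele_sets[sample_id]
            alleles = aset.alleles or ("",)
            for allele in alleles:
                writer.writerow(
                    [
                        sample_id,
                        allele,
                        aset.typed_loci,
                        aset.total_loci,
                        aset.unambiguous,
                    ]
                )
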
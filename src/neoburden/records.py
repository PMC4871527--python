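"""Core record types: proteins, annotated somatic mutations, MHC allele calls,
and the filtering-funnel audit.

Protein coordinates are 1-based throughout, matching the conventional
``V3088E`` notation for amino-acid substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import ParameterError

#: The 20 standard amino acids.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Standard residues plus the unknown-residue placeholder.
AA_ALPHABET_X = AA_ALPHABET | {"X"}


class VariantClass(str, Enum):
    """Protein-level consequence class of a somatic variant."""

    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    SYNONYMOUS = "synonymous"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classes retained by default in the filtering funnel. Nonsense variants are
#: dropped because premature stops are not expected to yield class-I epitopes;
#: synonymous variants change no residue.
DEFAULT_KEEP_CLASSES = frozenset(
    {VariantClass.MISSENSE, VariantClass.INFRAME_INDEL, VariantClass.FRAMESHIFT}
)


def _check_residues(seq: str, where: str, allow_x: bool = True) -> None:
    alphabet = AA_ALPHABET_X if allow_x else AA_ALPHABET
    bad = set(seq) - alphabet
    if bad:
        raise ParameterError(
            f"illegal residue character(s) {sorted(bad)!r} in {where}"
        )


@dataclass(frozen=True)
class ProteinRecord:
    """A wild-type protein sequence, optionally with its coding sequence.

    The CDS, when present, allows translation of frameshifted reading frames
    for variants whose novel C-terminal tail is not precomputed.
    """

    protein_id: str
    gene: str
    sequence: str
    cds: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParameterError(f"protein {self.protein_id}: empty sequence")
        _check_residues(self.sequence, f"protein {self.protein_id}")
        if self.cds is not None and len(self.cds) < 3 * len(self.sequence):
            raise ParameterError(
                f"protein {self.protein_id}: cds shorter than 3x protein length"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MutationRecord:
    """One annotated somatic protein-level variant with RNA read support.

    ``position`` is the 1-based index of the first affected residue. For a
    frameshift, ``alt_aa`` may carry the full novel C-terminal run if it was
    precomputed, or be empty (in which case a CDS is needed downstream).
    Unknown input columns are preserved in ``annotations``.
    """

    sample_id: str
    gene: str
    protein_id: str
    variant_class: VariantClass
    position: int
    ref_aa: str
    alt_aa: str
    rna_reads_ref: int
    rna_reads_alt: int
    in_dbsnp: bool
    somatic: bool
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ParameterError(
                f"{self.gene}: position must be >= 1, got {self.position}"
            )
        if self.rna_reads_ref < 0 or self.rna_reads_alt < 0:
            raise ParameterError(f"{self.gene}: negative RNA read count")
        if self.variant_class is VariantClass.MISSENSE:
            if len(self.ref_aa) != 1 or len(self.alt_aa) != 1:
                raise ParameterError(
                    f"{self.gene}: missense requires single ref/alt residues, "
                    f"got {self.ref_aa!r}>{self.alt_aa!r}"
                )
            if self.ref_aa == self.alt_aa:
                raise ParameterError(
                    f"{self.gene}: missense with ref_aa == alt_aa "
                    f"({self.ref_aa!r}) is synonymous"
                )

    @property
    def label(self) -> str:
        """Human-readable variant label, e.g. ``V3088E`` or ``532fs``."""
        if self.variant_class is VariantClass.MISSENSE:
            return f"{self.ref_aa}{self.position}{self.alt_aa}"
        if self.variant_class is VariantClass.FRAMESHIFT:
            return f"{self.position}fs"
        if self.variant_class is VariantClass.INFRAME_INDEL:
            if not self.alt_aa:
                end = self.position + len(self.ref_aa) - 1
                return f"{self.position}_{end}del"
            return f"{self.position}indel"
        return f"{self.ref_aa}{self.position}{self.alt_aa or '*'}"


@dataclass(frozen=True)
class AlleleSet:
    """Per-sample MHC class I allele calls.

    ``typed_loci`` counts how many class I loci the calls cover; the ratio
    ``total_loci / typed_loci`` extrapolates neoantigen counts to the loci
    that were not typed (e.g. x3 when only HLA-A of HLA-A/B/C was called).
    """

    sample_id: str
    alleles: tuple[str, ...]
    typed_loci: int
    total_loci: int = 3
    unambiguous: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(self.alleles))
        if not (1 <= self.typed_loci <= self.total_loci):
            raise ParameterError(
                f"{self.sample_id}: typed_loci must satisfy "
                f"1 <= {self.typed_loci} <= {self.total_loci}"
            )
        if self.unambiguous and not self.alleles:
            raise ParameterError(
                f"{self.sample_id}: unambiguous allele set must name alleles"
            )


@dataclass(frozen=True)
class FilterAudit:
    """Counts surviving each stage of the mutation-filtering funnel."""

    n_input: int
    n_after_somatic: int
    n_after_dbsnp: int
    n_after_expression: int
    n_after_class: int

    def __post_init__(self) -> None:
        stages = self.as_tuple()
        if any(c < 0 for c in stages):
            raise ParameterError("audit counts must be nonnegative")
        if any(a < b for a, b in zip(stages, stages[1:])):
            raise ParameterError(
                f"audit counts must be monotone nonincreasing, got {stages}"
            )

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (
            self.n_input,
            self.n_after_somatic,
            self.n_after_dbsnp,
            self.n_after_expression,
            self.n_after_class,
        )
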
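"""Mutant protein contexts, class-I candidate windows, and vaccine peptides.

A somatic variant is materialized into a :class:`MutantProteinContext`
holding the wild-type and mutant residue strings plus the set of novel
positions — the residues that differ from wild type or did not exist in it
(a frameshift tail, an indel junction). Every candidate MHC class I epitope
is an 8–11mer window of the mutant sequence overlapping at least one novel
position, and the synthetic-long-peptide vaccine design centers the novel
residues in a window with (by default) 14 wild-type flanking residues on
each side, clipped at the protein termini.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .errors import (
    CoordinateError,
    FormatError,
    ParameterError,
    ReferenceMismatchError,
    UnresolvableVariantError,
)
from .records import MutationRecord, ProteinRecord, VariantClass

CLASS1_LENGTHS = frozenset({8, 9, 10, 11})
#: Flank width giving the standard 29mer for an interior missense mutation.
DEFAULT_FLANK = 14
#: Novel tails longer than this are truncated (with a warning) in vaccine
#: design; epitope enumeration is unaffected.
DEFAULT_TAIL_CAP = 50

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class MutantProteinContext:
    """Wild-type vs mutant sequence plus the 1-based novel positions.

    ``novel_positions`` indexes ``mut_sequence``. It is empty only for the
    degenerate frameshift whose shifted frame opens on a stop codon (no novel
    peptide; such records are excluded downstream).
    """

    protein_id: str
    wt_sequence: str
    mut_sequence: str
    novel_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        positions = tuple(sorted(set(self.novel_positions)))
        object.__setattr__(self, "novel_positions", positions)
        for p in positions:
            if not 1 <= p <= len(self.mut_sequence):
                raise CoordinateError(
                    f"{self.protein_id}: novel position {p} outside mutant "
                    f"sequence of length {len(self.mut_sequence)}"
                )


@dataclass(frozen=True)
class PeptideWindow:
    """A slice of the mutant sequence overlapping a novel position.

    Standard class I windows are 8–11 residues; that range is enforced at
    enumeration (where it can be explicitly overridden), not here.
    """

    sequence: str
    start: int  # 1-based index into the mutant sequence
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ParameterError(f"window length {self.length} must be >= 1")
        if len(self.sequence) != self.length:
            raise ParameterError(
                f"window sequence length {len(self.sequence)} != {self.length}"
            )
        if self.start < 1:
            raise CoordinateError(f"window start {self.start} must be >= 1")

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + self.length - 1


@dataclass(frozen=True)
class FrameshiftTranslation:
    """Novel C-terminal tail read from a shifted frame.

    ``open_ended`` is set when no stop codon was reached before the end of
    the CDS (translation ran to the last complete codon).
    """

    tail: str
    open_ended: bool


def translate_frameshift(
    cds: str, shift_point: int, indel: str
) -> FrameshiftTranslation:
    """Translate the shifted reading frame created by an indel.

    ``shift_point`` is the number of intact codons preserved before the
    indel (the indel lands immediately after codon ``shift_point``).
    ``indel`` describes the event: ``"del:<n>"`` removes ``n`` bases,
    ``"ins:<seq>"`` inserts the given bases. Translation starts at the first
    affected codon and stops at (excluding) the first stop codon.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ParameterError("cds must be at least one codon long")
    if shift_point < 0 or 3 * shift_point >= len(cds):
        raise CoordinateError(
            f"shift_point {shift_point} beyond cds of {len(cds)} nt"
        )
    remaining = cds[3 * shift_point :]

    kind, _, arg = indel.partition(":")
    if kind == "del":
        try:
            n = int(arg)
        except ValueError:
            raise FormatError(f"bad deletion length in indel spec {indel!r}") from None
        if n < 1:
            raise ParameterError(f"deletion length must be >= 1, got {n}")
        if n >= len(remaining):
            raise CoordinateError("deletion removes the entire remaining cds")
        remaining = remaining[n:]
    elif kind == "ins":
        bad = set(arg) - _NUCLEOTIDES
        if not arg or bad:
            raise FormatError(f"bad inserted bases in indel spec {indel!r}")
        remaining = arg + remaining
    else:
        raise FormatError(f"unknown indel spec {indel!r} (use 'del:<n>' or 'ins:<seq>')")

    bad = set(remaining) - _NUCLEOTIDES
    if bad:
        raise FormatError(
            f"ambiguous nucleotide(s) {sorted(bad)!r} in shifted frame"
        )
    usable = remaining[: len(remaining) - len(remaining) % 3]
    protein = str(Seq(usable).translate())
    stop = protein.find("*")
    if stop >= 0:
        return FrameshiftTranslation(tail=protein[:stop], open_ended=False)
    return FrameshiftTranslation(tail=protein, open_ended=True)


def _frameshift_tail(
    protein: ProteinRecord,
    mutation: MutationRecord,
    frameshift_indel: str | None,
) -> str:
    if mutation.alt_aa:
        return mutation.alt_aa
    indel = frameshift_indel or mutation.annotations.get("fs_indel")
    if protein.cds is None or not indel:
        raise UnresolvableVariantError(
            f"{protein.protein_id} position {mutation.position}: frameshift "
            "with neither a precomputed tail nor a cds + indel description"
        )
    return translate_frameshift(
        protein.cds, shift_point=mutation.position - 1, indel=indel
    ).tail


def apply_mutation(
    protein: ProteinRecord,
    mutation: MutationRecord,
    frameshift_indel: str | None = None,
) -> MutantProteinContext:
    """Materialize a variant into a mutant protein context.

    * missense — single substitution after checking the wild-type residue;
    * in-frame indel — ``ref_aa`` residues replaced by ``alt_aa``; the novel
      set is the inserted residues plus one flanking residue on each side of
      the junction, so junction-spanning windows are always enumerated;
    * frameshift — wild-type prefix up to ``position - 1`` concatenated with
      the novel tail (from ``alt_aa``, or translated from the CDS in the
      shifted frame); every tail residue is novel.
    """
    seq = protein.sequence
    pos = mutation.position
    if pos > len(seq):
        raise CoordinateError(
            f"{protein.protein_id}: position {pos} beyond protein "
            f"of length {len(seq)}"
        )
    vc = mutation.variant_class

    if vc in (VariantClass.SYNONYMOUS, VariantClass.NONSENSE):
        raise ParameterError(
            f"{protein.protein_id}: {vc.value} variant yields no novel peptide"
        )

    if vc is VariantClass.MISSENSE:
        found = seq[pos - 1]
        if found != mutation.ref_aa:
            raise ReferenceMismatchError(
                f"{protein.protein_id} position {pos}: expected "
                f"{mutation.ref_aa!r}, found {found!r}"
            )
        mut = seq[: pos - 1] + mutation.alt_aa + seq[pos:]
        return MutantProteinContext(
            protein_id=protein.protein_id,
            wt_sequence=seq,
            mut_sequence=mut,
            novel_positions=(pos,),
        )

    if vc is VariantClass.INFRAME_INDEL:
        ref = "" if mutation.ref_aa == "-" else mutation.ref_aa
        alt = "" if mutation.alt_aa == "-" else mutation.alt_aa
        if ref and seq[pos - 1 : pos - 1 + len(ref)] != ref:
            raise ReferenceMismatchError(
                f"{protein.protein_id} position {pos}: expected {ref!r}, "
                f"found {seq[pos - 1 : pos - 1 + len(ref)]!r}"
            )
        mut = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
        inserted = range(pos, pos + len(alt))
        junction = {pos - 1, pos + len(alt)}
        novel = [p for p in (*inserted, *junction) if 1 <= p <= len(mut)]
        if not novel:
            raise UnresolvableVariantError(
                f"{protein.protein_id} position {pos}: indel leaves no "
                "residues flanking the junction"
            )
        return MutantProteinContext(
            protein_id=protein.protein_id,
            wt_sequence=seq,
            mut_sequence=mut,
            novel_positions=tuple(novel),
        )

    # frameshift
    tail = _frameshift_tail(protein, mutation, frameshift_indel)
    mut = seq[: pos - 1] + tail
    novel = tuple(range(pos, pos + len(tail)))
    return MutantProteinContext(
        protein_id=protein.protein_id,
        wt_sequence=seq,
        mut_sequence=mut,
        novel_positions=novel,
    )


def enumerate_class1_windows(
    ctx: MutantProteinContext,
    lengths: Iterable[int] = (8, 9, 10, 11),
    allow_nonstandard_lengths: bool = False,
) -> list[PeptideWindow]:
    """Enumerate every window of the requested lengths overlapping a novel
    position, sorted by (length, start) with no duplicates.

    Lengths outside the class I range [8, 11] are rejected unless the
    explicit override flag is set.
    """
    lens = sorted(set(lengths))
    if not lens:
        raise ParameterError("at least one window length is required")
    if not allow_nonstandard_lengths:
        bad = [l for l in lens if l not in CLASS1_LENGTHS]
        if bad:
            raise ParameterError(
                f"window length(s) {bad} outside the class I range [8, 11]; "
                "pass allow_nonstandard_lengths=True to override"
            )
    if any(l < 1 for l in lens):
        raise ParameterError("window lengths must be positive")

    mut = ctx.mut_sequence
    L = len(mut)
    windows: list[PeptideWindow] = []
    for length in lens:
        if length > L:
            continue
        # Union of start ranges covering each novel position.
        starts: set[int] = set()
        for q in ctx.novel_positions:
            lo = max(1, q - length + 1)
            hi = min(q, L - length + 1)
            if lo <= hi:
                starts.update(range(lo, hi + 1))
        for start in sorted(starts):
            windows.append(
                PeptideWindow(
                    sequence=mut[start - 1 : start - 1 + length],
                    start=start,
                    length=length,
                )
            )
    return windows


def design_vaccine_peptide(
    ctx: MutantProteinContext,
    flank: int = DEFAULT_FLANK,
    tail_cap: int = DEFAULT_TAIL_CAP,
) -> str:
    """Design the synthetic-long-peptide vaccine sequence for a context.

    Returns ``mut_sequence[max(1, p_min - flank) .. min(L, p_max + flank)]``
    where ``p_min``/``p_max`` bound the novel positions. For an interior
    missense this is the standard ``2*flank + 1 = 29``mer with the mutant
    residue central; near a terminus the window is clipped, not padded, so a
    mutation at residue 4 yields an 18mer. Novel runs longer than
    ``tail_cap`` are truncated with a warning.
    """
    if flank < 0:
        raise ParameterError(f"flank must be >= 0, got {flank}")
    if not ctx.novel_positions:
        raise ParameterError(
            f"{ctx.protein_id}: no novel residues to design a peptide around"
        )
    p_min = ctx.novel_positions[0]
    p_max = ctx.novel_positions[-1]
    L = len(ctx.mut_sequence)
    if p_max - p_min + 1 > tail_cap:
        warnings.warn(
            f"{ctx.protein_id}: novel run of {p_max - p_min + 1} residues "
            f"truncated to {tail_cap} for vaccine design",
            stacklevel=2,
        )
        # what follows the cap is still novel sequence, so no right flank
        end = min(L, p_min + tail_cap - 1)
    else:
        end = min(L, p_max + flank)
    start = max(1, p_min - flank)
    return ctx.mut_sequence[start - 1 : end]


def windows_to_fasta(
    windows: Sequence[PeptideWindow],
    path,
    record_id_prefix: str,
) -> None:
    """Write windows as FASTA with ids ``<prefix>|<start>|<length>``."""
    with open(path, "w") as handle:
        for w in windows:
            handle.write(f">{record_id_prefix}|{w.start}|{w.length}\n{w.sequence}\n")
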
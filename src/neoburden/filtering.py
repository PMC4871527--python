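"""The mutation-filtering funnel.

Somatic variants are retained in four fixed stages: somatic evidence,
absence from dbSNP, RNA expression of the mutant allele, and variant class.
The stage order mirrors the left-to-right funnel of the source analysis, and
the audit reports every intermediate count so alternative orders can be
compared. Expression evidence arrives as precomputed read counts; only the
mutant-allele read count is gated (a wild-type read count of zero is
permitted, as seen for genes whose wild-type allele is silenced).
"""

from __future__ import annotations

from typing import Iterable

from .errors import ParameterError
from .records import DEFAULT_KEEP_CLASSES, FilterAudit, MutationRecord, VariantClass


def filter_mutations(
    mutations: Iterable[MutationRecord],
    min_alt_reads: int = 1,
    keep_classes: frozenset[VariantClass] = DEFAULT_KEEP_CLASSES,
) -> tuple[list[MutationRecord], FilterAudit]:
    """Apply the four-stage funnel; returns retained records plus an audit.

    Input order is preserved, and the operation is idempotent: filtering its
    own output changes nothing.
    """
    if min_alt_reads < 0:
        raise ParameterError(f"min_alt_reads must be >= 0, got {min_alt_reads}")
    keep = frozenset(keep_classes)

    records = list(mutations)
    somatic = [m for m in records if m.somatic]
    not_dbsnp = [m for m in somatic if not m.in_dbsnp]
    expressed = [m for m in not_dbsnp if m.rna_reads_alt >= min_alt_reads]
    kept = [m for m in expressed if m.variant_class in keep]

    audit = FilterAudit(
        n_input=len(records),
        n_after_somatic=len(somatic),
        n_after_dbsnp=len(not_dbsnp),
        n_after_expression=len(expressed),
        n_after_class=len(kept),
    )
    return kept, audit
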
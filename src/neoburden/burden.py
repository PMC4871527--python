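"""The neoantigen-burden probability model and cohort statistics.

Empirical work on viral epitopes found that only a fraction *a* ≈ 0.08 of
peptides predicted to bind MHC I with IC50 < 100 nM are authentic epitopes
(naturally processed, presented, and recognized by autologous CD8 T cells).
Treating each of a patient's N predicted neoantigens as an independent
trial with success probability *a*:

* expected authentic neoantigens  E = a · N,
* probability of at least one     P = 1 − (1 − a)^N.

N is the loci-scaled predicted-neoantigen count: when only one of the
organism's class I loci was typed, the raw count is multiplied by
``total_loci / typed_loci`` (×3 for HLA-A of HLA-A/B/C), and the scaled —
possibly non-integer — N feeds the real-valued power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import AffinityLookup, affinity_lookup
from .errors import CoverageError, ParameterError
from .filtering import filter_mutations
from .peptidome import PeptideWindow, apply_mutation, enumerate_class1_windows
from .records import (
    DEFAULT_KEEP_CLASSES,
    AlleleSet,
    MutationRecord,
    ProteinRecord,
    VariantClass,
)

CountingMode = Literal["per_peptide", "per_mutation"]


@dataclass(frozen=True)
class BurdenParams:
    """Parameters of the burden model.

    ``counting_mode`` selects what N counts: distinct sub-threshold peptides
    (cohort analysis) or mutations carrying at least one such peptide
    (vaccine-panel analysis). ``loci_scale`` is the extrapolation factor
    applied when allele typing is incomplete; it is overridden by per-sample
    allele metadata when available.
    """

    authenticity_rate: float = 0.08
    loci_scale: float = 3.0
    threshold_nM: float = 100.0
    counting_mode: CountingMode = "per_peptide"
    likelihood_cutoff: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.authenticity_rate < 1:
            raise ParameterError(
                f"authenticity_rate must be in (0,1), got {self.authenticity_rate}"
            )
        if self.loci_scale <= 0:
            raise ParameterError(f"loci_scale must be positive, got {self.loci_scale}")
        if self.threshold_nM <= 0:
            raise ParameterError(
                f"threshold_nM must be positive, got {self.threshold_nM}"
            )
        if self.counting_mode not in ("per_peptide", "per_mutation"):
            raise ParameterError(f"unknown counting_mode {self.counting_mode!r}")
        if not 0 < self.likelihood_cutoff < 1:
            raise ParameterError(
                f"likelihood_cutoff must be in (0,1), got {self.likelihood_cutoff}"
            )


#: Defaults for the vaccine-panel workflow: count mutations, relaxed
#: threshold, no loci extrapolation (the mouse alleles are fully typed).
PANEL_PARAMS = BurdenParams(
    threshold_nM=1500.0, counting_mode="per_mutation", loci_scale=1.0
)
#: Defaults for the cohort workflow: count peptides at the high-affinity
#: threshold and extrapolate one typed locus to three.
COHORT_PARAMS = BurdenParams()


@dataclass(frozen=True)
class SampleBurden:
    """Per-sample funnel counts and burden-model outputs."""

    sample_id: str
    n_total: int
    n_transcribed: int
    n_predicted_raw: int
    N: float
    E: float
    P: float

    def __post_init__(self) -> None:
        if min(self.n_total, self.n_transcribed, self.n_predicted_raw) < 0:
            raise ParameterError(f"{self.sample_id}: negative funnel count")
        if self.N < 0 or self.E < 0:
            raise ParameterError(f"{self.sample_id}: negative N or E")
        if not 0 <= self.P <= 1:
            raise ParameterError(f"{self.sample_id}: P={self.P} outside [0,1]")


@dataclass(frozen=True)
class CohortSummary:
    """Rank-ordered cohort table plus headline statistics."""

    samples: tuple[SampleBurden, ...]
    median_N: float
    frac_above_cutoff: float
    n_samples: int


# ---------------------------------------------------------------------------
# The probability model


def expected_authentic(N: float, a: float) -> float:
    """Expected number of authentic neoantigens, a·N."""
    _check_rate(a)
    if N < 0:
        raise ParameterError(f"N must be nonnegative, got {N}")
    return a * N


def prob_at_least_one(N: float, a: float) -> float:
    """Probability of harboring at least one authentic neoantigen.

    ``1 - (1 - a)**N``; N may be non-integer (loci-scaled counts).
    """
    _check_rate(a)
    if N < 0:
        raise ParameterError(f"N must be nonnegative, got {N}")
    return 1.0 - (1.0 - a) ** N


def _check_rate(a: float) -> None:
    if not 0 < a < 1:
        raise ParameterError(f"authenticity rate must be in (0,1), got {a}")


def percent_likelihood(p: float) -> int:
    """Probability as an integer percentage, rounded half-up.

    0.3936 → 39, 0.8948 → 89.
    """
    if not 0 <= p <= 1:
        raise ParameterError(f"probability {p} outside [0,1]")
    return int(Decimal(repr(p * 100)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def min_neoantigens_for_likelihood(
    a: float = 0.08, cutoff: float = 0.90
) -> int:
    """Smallest integer N with P(at least one authentic) >= cutoff."""
    _check_rate(a)
    if not 0 < cutoff < 1:
        raise ParameterError(f"cutoff must be in (0,1), got {cutoff}")
    n = max(0, math.ceil(math.log1p(-cutoff) / math.log1p(-a)) - 2)
    while prob_at_least_one(n, a) < cutoff:
        n += 1
    return n


def scale_loci(n_typed: float, typed_loci: int, total_loci: int) -> float:
    """Extrapolate a count from the typed loci to all loci.

    Returns ``n_typed * total_loci / typed_loci``; fractional results are
    admitted (the probability model accepts real-valued N).
    """
    if typed_loci == 0:
        raise ParameterError("typed_loci must be nonzero")
    if not 1 <= typed_loci <= total_loci:
        raise ParameterError(
            f"typed_loci must satisfy 1 <= {typed_loci} <= {total_loci}"
        )
    if n_typed < 0:
        raise ParameterError(f"n_typed must be nonnegative, got {n_typed}")
    return n_typed * total_loci / typed_loci


# ---------------------------------------------------------------------------
# Counting


@dataclass(frozen=True)
class BinderCounts:
    per_peptide: int
    per_mutation: int


def count_binders(
    windows_by_mutation: Sequence[Sequence[PeptideWindow]],
    calls: AffinityLookup | Sequence | pd.DataFrame,
    alleles: AlleleSet | Sequence[str],
    threshold_nM: float,
) -> BinderCounts:
    """Count sub-threshold binders under both counting conventions.

    ``per_peptide`` counts distinct window sequences whose minimum IC50 over
    the sample's alleles is below the threshold; ``per_mutation`` counts
    mutations carrying at least one such window. ``per_peptide >=
    per_mutation`` always holds.
    """
    if threshold_nM <= 0:
        raise ParameterError(f"threshold_nM must be positive, got {threshold_nM}")
    names = alleles.alleles if isinstance(alleles, AlleleSet) else tuple(alleles)
    if not names:
        raise ParameterError("at least one allele is required")
    lookup = affinity_lookup(calls)

    binder_peptides: set[str] = set()
    mutations_with_binder = 0
    missing: list[tuple[str, str]] = []
    for windows in windows_by_mutation:
        has_binder = False
        for w in windows:
            ic50s = []
            for a in names:
                key = (w.sequence, a)
                if key not in lookup:
                    missing.append(key)
                    continue
                ic50s.append(lookup[key])
            if ic50s and min(ic50s) < threshold_nM:
                binder_peptides.add(w.sequence)
                has_binder = True
        if has_binder:
            mutations_with_binder += 1
    if missing:
        shown = ", ".join(f"{p}/{a}" for p, a in missing[:5])
        more = f" (+{len(missing) - 5} more)" if len(missing) > 5 else ""
        raise CoverageError(f"missing predictions for: {shown}{more}")
    return BinderCounts(
        per_peptide=len(binder_peptides), per_mutation=mutations_with_binder
    )


def count_predicted_neoantigens(
    filtered_mutations: Sequence[MutationRecord],
    windows_by_mutation: Sequence[Sequence[PeptideWindow]],
    calls,
    alleles: AlleleSet | Sequence[str],
    params: BurdenParams,
) -> int:
    """Predicted-neoantigen count under the configured counting mode."""
    if len(filtered_mutations) != len(windows_by_mutation):
        raise ParameterError(
            "windows_by_mutation must align with filtered_mutations"
        )
    counts = count_binders(windows_by_mutation, calls, alleles, params.threshold_nM)
    if params.counting_mode == "per_peptide":
        return counts.per_peptide
    return counts.per_mutation


def compute_sample_burden(
    sample_id: str,
    mutations: Sequence[MutationRecord],
    proteins: Mapping[str, ProteinRecord],
    calls,
    allele_set: AlleleSet,
    params: BurdenParams = COHORT_PARAMS,
    min_alt_reads: int = 1,
    keep_classes=DEFAULT_KEEP_CLASSES,
) -> SampleBurden:
    """Run the full per-sample funnel and burden model.

    ``n_total`` counts somatic, non-dbSNP, non-synonymous variants;
    ``n_transcribed`` those with RNA support for the mutant allele. The raw
    predicted-neoantigen count from the typed alleles is extrapolated to all
    loci via the sample's allele metadata.
    """
    non_syn = [
        m for m in mutations if m.variant_class is not VariantClass.SYNONYMOUS
    ]
    retained, audit = filter_mutations(
        non_syn, min_alt_reads=min_alt_reads, keep_classes=keep_classes
    )
    windows_by_mutation = []
    for m in retained:
        ctx = apply_mutation(proteins[m.protein_id], m)
        windows_by_mutation.append(enumerate_class1_windows(ctx))
    raw = count_predicted_neoantigens(
        retained, windows_by_mutation, calls, allele_set, params
    )
    N = scale_loci(raw, allele_set.typed_loci, allele_set.total_loci)
    return SampleBurden(
        sample_id=sample_id,
        n_total=audit.n_after_dbsnp,
        n_transcribed=audit.n_after_expression,
        n_predicted_raw=raw,
        N=N,
        E=expected_authentic(N, params.authenticity_rate),
        P=prob_at_least_one(N, params.authenticity_rate),
    )


# ---------------------------------------------------------------------------
# Cohort summary


def summarize_cohort(
    burdens: Sequence[SampleBurden], params: BurdenParams = COHORT_PARAMS
) -> CohortSummary:
    """Rank samples and compute the cohort's headline statistics.

    Samples are ordered by total mutation count descending (ties broken by
    sample id); the median of N uses the midpoint convention for even
    cohorts; ``frac_above_cutoff`` is the fraction of samples whose P meets
    the likelihood cutoff.
    """
    if not burdens:
        raise ParameterError("cohort must contain at least one sample")
    ordered = tuple(sorted(burdens, key=lambda b: (-b.n_total, b.sample_id)))
    median_N = float(np.median([b.N for b in ordered]))
    n_above = sum(1 for b in ordered if b.P >= params.likelihood_cutoff)
    return CohortSummary(
        samples=ordered,
        median_N=median_N,
        frac_above_cutoff=n_above / len(ordered),
        n_samples=len(ordered),
    )


def burdens_to_frame(burdens: Sequence[SampleBurden]) -> pd.DataFrame:
    """Per-sample burden table with P also as a rounded percentage."""
    return pd.DataFrame(
        {
            "sample_id": [b.sample_id for b in burdens],
            "n_total": [b.n_total for b in burdens],
            "n_transcribed": [b.n_transcribed for b in burdens],
            "n_predicted_raw": [b.n_predicted_raw for b in burdens],
            "N": [b.N for b in burdens],
            "E": [b.E for b in burdens],
            "P": [b.P for b in burdens],
            "P_pct": [percent_likelihood(b.P) for b in burdens],
        }
    )


def summary_to_dict(summary: CohortSummary, params: BurdenParams) -> dict:
    """JSON-ready cohort summary with a parameter echo."""
    return {
        "median_N": summary.median_N,
        "frac_above_cutoff": summary.frac_above_cutoff,
        "n_samples": summary.n_samples,
        "params": {
            "authenticity_rate": params.authenticity_rate,
            "loci_scale": params.loci_scale,
            "threshold_nM": params.threshold_nM,
            "counting_mode": params.counting_mode,
            "likelihood_cutoff": params.likelihood_cutoff,
        },
    }


def with_params(params: BurdenParams, **overrides) -> BurdenParams:
    """Copy params with field overrides (convenience for CLI flag handling)."""
    return replace(params, **overrides)
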
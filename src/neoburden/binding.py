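"""Uniform interface over MHC class I affinity predictors.

Three routes produce :class:`BindingCall` triples (peptide, allele, IC50 in
nM): a seeded synthetic predictor for tests and simulations, a parser for
external predictor tables (minimal TSV or NetMHCpan-style columnar text),
and in-memory tables. Downstream code only ever sees IC50 values in nM —
percentile ranks are deliberately not modeled. Binder classification uses a
strict ``<`` at the threshold, so boundary values are non-binders.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import CoverageError, FormatError, ParameterError
from .peptidome import PeptideWindow
from .records import AlleleSet

#: High-affinity threshold conventionally used to call likely epitopes.
HIGH_AFFINITY_NM = 100.0
#: Relaxed threshold admitting intermediate-affinity binders to a vaccine panel.
RELAXED_AFFINITY_NM = 1500.0
#: Alternate moderate threshold sometimes used for candidate reporting.
MODERATE_AFFINITY_NM = 500.0

DEFAULT_BASELINE_RANGE = (1.0, 50_000.0)
DEFAULT_MOTIF_RANGE = (1.0, 100.0)


@dataclass(frozen=True)
class BindingCall:
    """A predicted binding affinity for one (peptide, allele) pair."""

    peptide: str
    allele: str
    ic50_nM: float

    def __post_init__(self) -> None:
        if self.ic50_nM <= 0:
            raise ParameterError(
                f"ic50_nM must be positive, got {self.ic50_nM} "
                f"for {self.peptide}/{self.allele}"
            )
        if not 8 <= len(self.peptide) <= 11:
            raise ParameterError(
                f"peptide {self.peptide!r} length outside the class I "
                "range [8, 11]"
            )


@dataclass(frozen=True)
class PredictorContract:
    """Metadata describing a predictor behind the file-exchange interface.

    Predictors must be deterministic: the same (peptide, allele,
    configuration) yields the same IC50 on every invocation. Version
    differences between external predictors are dialect metadata, not
    separate code paths.
    """

    name: str
    deterministic: bool
    supported_alleles: frozenset[str]


def _unit_interval(key: str) -> float:
    """Deterministic hash of a key to [0, 1)."""
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") / 2.0**64


def _log_uniform(u: float, lo: float, hi: float) -> float:
    return lo * (hi / lo) ** u


class _MotifMatcher:
    """Substring matcher for planted anchor motifs, fast for large motif sets."""

    def __init__(self, motifs: Iterable[str]):
        self._by_length: dict[int, set[str]] = {}
        for m in motifs:
            self._by_length.setdefault(len(m), set()).add(m)

    def __bool__(self) -> bool:
        return bool(self._by_length)

    def matches(self, peptide: str) -> bool:
        n = len(peptide)
        for length, motifs in self._by_length.items():
            if length > n:
                continue
            if length == n:
                if peptide in motifs:
                    return True
                continue
            for i in range(n - length + 1):
                if peptide[i : i + length] in motifs:
                    return True
        return False


def synthetic_predict(
    peptides: Sequence[str],
    alleles: Sequence[str],
    seed: int,
    strong_motifs: Iterable[str] | None = None,
    *,
    baseline_range: tuple[float, float] = DEFAULT_BASELINE_RANGE,
    motif_range: tuple[float, float] = DEFAULT_MOTIF_RANGE,
) -> list[BindingCall]:
    """Deterministic synthetic affinity predictor.

    Each (peptide, allele, seed) triple hashes to a log-uniform IC50 in
    ``baseline_range``; peptides containing any planted anchor motif are
    instead mapped into ``motif_range`` (below the high-affinity threshold
    by default). Hashing rather than sequential sampling makes results
    order-independent: the same pair always gets the same affinity.
    """
    if not alleles:
        raise ParameterError("at least one allele is required")
    matcher = _MotifMatcher(strong_motifs or ())
    calls: list[BindingCall] = []
    for peptide in peptides:
        planted = bool(matcher) and matcher.matches(peptide)
        lo, hi = motif_range if planted else baseline_range
        for allele in alleles:
            u = _unit_interval(f"{peptide}|{allele}|{seed}")
            calls.append(
                BindingCall(peptide=peptide, allele=allele, ic50_nM=_log_uniform(u, lo, hi))
            )
    return calls


def synthetic_ic50(
    peptide: str,
    allele: str,
    seed: int,
    lo: float = DEFAULT_BASELINE_RANGE[0],
    hi: float = DEFAULT_BASELINE_RANGE[1],
) -> float:
    """Single deterministic affinity draw in a caller-specified band."""
    return _log_uniform(_unit_interval(f"{peptide}|{allele}|{seed}"), lo, hi)


# ---------------------------------------------------------------------------
# Parsing and serialization


_TSV_ALIASES = {
    "peptide": "peptide",
    "allele": "allele",
    "ic50_nm": "ic50_nM",
    "ic50": "ic50_nM",
    "affinity_nm": "ic50_nM",
    "affinity": "ic50_nM",
}


def parse_predictions(
    path: str | Path, dialect: str | Mapping = "tsv"
) -> list[BindingCall]:
    """Parse a predictor output table into binding calls.

    Two dialects: ``"tsv"`` — a headed TSV with peptide/allele/IC50(nM)
    columns; or a mapping configuring NetMHCpan-style columnar text, e.g.
    ``{"format": "columns", "peptide_col": 2, "allele_col": 1,
    "ic50_col": 12}`` with optional ``skip_prefixes``. ``#`` banners are
    ignored in both. Nonpositive or non-numeric affinities raise a row
    error naming the line.
    """
    path = Path(path)
    if dialect == "tsv":
        return _parse_tsv(path)
    if isinstance(dialect, Mapping) and dialect.get("format") == "columns":
        return _parse_columns(path, dialect)
    raise FormatError(f"unknown prediction dialect {dialect!r}")


def _parse_affinity(token: str, lineno: int) -> float:
    try:
        value = float(token)
    except ValueError:
        raise FormatError(
            f"line {lineno}: non-numeric affinity {token!r}"
        ) from None
    if not math.isfinite(value) or value <= 0:
        raise FormatError(f"line {lineno}: affinity must be positive, got {token!r}")
    return value


def _parse_tsv(path: Path) -> list[BindingCall]:
    calls: list[BindingCall] = []
    header: dict[str, int] | None = None
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = {}
                for i, name in enumerate(fields):
                    canonical = _TSV_ALIASES.get(name.strip().lower())
                    if canonical:
                        header[canonical] = i
                missing = {"peptide", "allele", "ic50_nM"} - set(header)
                if missing:
                    raise FormatError(
                        f"prediction table {path} is missing column(s): "
                        f"{', '.join(sorted(missing))}"
                    )
                continue
            calls.append(
                BindingCall(
                    peptide=fields[header["peptide"]].strip(),
                    allele=fields[header["allele"]].strip(),
                    ic50_nM=_parse_affinity(fields[header["ic50_nM"]], lineno),
                )
            )
    if header is None:
        raise FormatError(f"prediction table {path} has no header line")
    return calls


def _parse_columns(path: Path, dialect: Mapping) -> list[BindingCall]:
    pep_col = int(dialect["peptide_col"])
    allele_col = int(dialect["allele_col"])
    ic50_col = int(dialect["ic50_col"])
    skip_prefixes = tuple(dialect.get("skip_prefixes", ("#", "-", "Pos", "pos")))
    needed = max(pep_col, allele_col, ic50_col) + 1
    calls: list[BindingCall] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(skip_prefixes):
                continue
            fields = stripped.split()
            if len(fields) < needed:
                continue  # banner/footer line
            calls.append(
                BindingCall(
                    peptide=fields[pep_col],
                    allele=fields[allele_col],
                    ic50_nM=_parse_affinity(fields[ic50_col], lineno),
                )
            )
    return calls


def write_predictions(
    calls: Sequence[BindingCall] | pd.DataFrame, path: str | Path
) -> None:
    """Serialize calls as a minimal TSV (peptide, allele, ic50_nM)."""
    frame = calls_to_frame(calls)
    frame.to_csv(path, sep="\t", index=False)


def calls_to_frame(calls: Sequence[BindingCall] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls[["peptide", "allele", "ic50_nM"]]
    return pd.DataFrame(
        {
            "peptide": [c.peptide for c in calls],
            "allele": [c.allele for c in calls],
            "ic50_nM": [c.ic50_nM for c in calls],
        }
    )


AffinityLookup = dict[tuple[str, str], float]


def affinity_lookup(
    calls: Sequence[BindingCall] | pd.DataFrame | AffinityLookup,
) -> AffinityLookup:
    """Index calls by (peptide, allele); first occurrence wins."""
    if isinstance(calls, dict):
        return calls
    lookup: AffinityLookup = {}
    if isinstance(calls, pd.DataFrame):
        for peptide, allele, ic50 in zip(
            calls["peptide"], calls["allele"], calls["ic50_nM"]
        ):
            lookup.setdefault((peptide, allele), float(ic50))
        return lookup
    for call in calls:
        lookup.setdefault((call.peptide, call.allele), call.ic50_nM)
    return lookup


# ---------------------------------------------------------------------------
# Reduction and classification


@dataclass(frozen=True)
class BestAffinity:
    """The strongest predicted binder over a mutation's windows and alleles."""

    ic50_nM: float
    window: PeptideWindow
    allele: str


def _allele_names(alleles: AlleleSet | Sequence[str]) -> tuple[str, ...]:
    if isinstance(alleles, AlleleSet):
        return alleles.alleles
    return tuple(alleles)


def best_affinity_per_mutation(
    calls: Sequence[BindingCall] | pd.DataFrame | AffinityLookup,
    windows: Sequence[PeptideWindow],
    alleles: AlleleSet | Sequence[str],
) -> BestAffinity:
    """Minimum IC50 over all (window, allele) pairs, with its argmin.

    Ties are broken toward the lexicographically smallest (length, start)
    window, then the earliest allele in the listed order. Missing
    predictions raise a coverage error listing the gaps.
    """
    names = _allele_names(alleles)
    if not windows:
        raise ParameterError("at least one window is required")
    if not names:
        raise ParameterError("at least one allele is required")
    lookup = affinity_lookup(calls)

    ordered = sorted(windows, key=lambda w: (w.length, w.start))
    missing = [
        (w.sequence, a)
        for w in ordered
        for a in names
        if (w.sequence, a) not in lookup
    ]
    if missing:
        shown = ", ".join(f"{p}/{a}" for p, a in missing[:5])
        more = f" (+{len(missing) - 5} more)" if len(missing) > 5 else ""
        raise CoverageError(f"missing predictions for: {shown}{more}")

    best: BestAffinity | None = None
    for w in ordered:
        for a in names:
            ic50 = lookup[(w.sequence, a)]
            if best is None or ic50 < best.ic50_nM:
                best = BestAffinity(ic50_nM=ic50, window=w, allele=a)
    assert best is not None
    return best


def classify_binder(ic50_nM: float, threshold_nM: float) -> bool:
    """True iff the affinity is strictly below the threshold."""
    if threshold_nM <= 0:
        raise ParameterError(f"threshold_nM must be positive, got {threshold_nM}")
    if ic50_nM <= 0:
        raise ParameterError(f"ic50_nM must be positive, got {ic50_nM}")
    return ic50_nM < threshold_nM
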
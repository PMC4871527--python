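"""The two end-to-end analyses.

* **panel** — single-tumor vaccine design: filter the mutanome, enumerate
  candidate windows, take each mutation's best predicted affinity over
  windows and alleles, admit mutations below a (relaxed, 1500 nM by
  default) threshold to the vaccine panel, and design the long peptide for
  every retained mutation.
* **cohort** — multi-sample burden analysis: per sample, count distinct
  high-affinity (100 nM) binder peptides, extrapolate across untyped loci,
  and evaluate the authenticity probability model; samples with ambiguous
  allele calls are dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .binding import affinity_lookup, best_affinity_per_mutation, classify_binder
from .burden import (
    BurdenParams,
    COHORT_PARAMS,
    PANEL_PARAMS,
    CohortSummary,
    SampleBurden,
    burdens_to_frame,
    compute_sample_burden,
    summarize_cohort,
    summary_to_dict,
)
from .errors import ParameterError
from .filtering import filter_mutations
from .peptidome import (
    apply_mutation,
    design_vaccine_peptide,
    enumerate_class1_windows,
)
from .records import (
    AlleleSet,
    FilterAudit,
    MutationRecord,
    ProteinRecord,
)

logger = logging.getLogger("neoburden")


@dataclass
class PanelResult:
    """Vaccine-panel outputs: funnel audit, per-mutation table, binder panel."""

    audit: FilterAudit
    table: pd.DataFrame
    panel: pd.DataFrame

    @property
    def funnel(self) -> tuple[int, int, int, int]:
        """(input, transcribed, class-kept, predicted binders)."""
        return (
            self.audit.n_input,
            self.audit.n_after_expression,
            self.audit.n_after_class,
            len(self.panel),
        )


def run_panel(
    mutations: Sequence[MutationRecord],
    proteome: Mapping[str, ProteinRecord],
    calls,
    allele_set: AlleleSet,
    params: BurdenParams = PANEL_PARAMS,
    min_alt_reads: int = 1,
    flank: int = 14,
) -> PanelResult:
    """Run the single-tumor vaccine-panel workflow."""
    retained, audit = filter_mutations(mutations, min_alt_reads=min_alt_reads)
    lookup = affinity_lookup(calls)
    rows = []
    for m in retained:
        ctx = apply_mutation(proteome[m.protein_id], m)
        windows = enumerate_class1_windows(ctx)
        if not windows:
            logger.warning("%s %s: no candidate windows; skipped", m.gene, m.label)
            continue
        best = best_affinity_per_mutation(lookup, windows, allele_set)
        rows.append(
            {
                "gene": m.gene,
                "substitution": m.label,
                "best_epitope": best.window.sequence,
                "ic50_nM": best.ic50_nM,
                "allele": best.allele,
                "rna_reads_ref": m.rna_reads_ref,
                "rna_reads_alt": m.rna_reads_alt,
                "vaccine_peptide": design_vaccine_peptide(ctx, flank=flank),
                "binder": classify_binder(best.ic50_nM, params.threshold_nM),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "substitution",
            "best_epitope",
            "ic50_nM",
            "allele",
            "rna_reads_ref",
            "rna_reads_alt",
            "vaccine_peptide",
            "binder",
        ],
    )
    panel = table[table["binder"]].drop(columns="binder").reset_index(drop=True)
    if panel.empty:
        logger.warning(
            "no mutation met the %.0f nM threshold; panel is empty",
            params.threshold_nM,
        )
    return PanelResult(audit=audit, table=table, panel=panel)


def write_panel_outputs(
    result: PanelResult, out_dir: str | Path, params: BurdenParams, seed=None
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    audit = result.audit
    pd.DataFrame(
        {
            "stage": [
                "input",
                "somatic",
                "not_dbsnp",
                "expressed",
                "class_kept",
                "predicted_binder",
            ],
            "count": [*audit.as_tuple(), len(result.panel)],
        }
    ).to_csv(out / "funnel_audit.tsv", sep="\t", index=False)
    result.table.to_csv(out / "mutations_scored.tsv", sep="\t", index=False)
    result.panel.to_csv(out / "vaccine_panel.tsv", sep="\t", index=False)
    _write_provenance(out, "panel", params, seed)


@dataclass
class CohortResult:
    """Cohort outputs: per-sample burdens, summary, drop accounting."""

    burdens: list[SampleBurden]
    summary: CohortSummary
    n_dropped_ambiguous: int

    @property
    def table(self) -> pd.DataFrame:
        return burdens_to_frame(self.summary.samples)


def run_cohort(
    mutations: Sequence[MutationRecord],
    proteome: Mapping[str, ProteinRecord],
    calls,
    allele_sets: Mapping[str, AlleleSet],
    params: BurdenParams = COHORT_PARAMS,
    min_alt_reads: int = 1,
) -> CohortResult:
    """Run the cohort burden workflow over every unambiguous sample."""
    lookup = affinity_lookup(calls)
    by_sample: dict[str, list[MutationRecord]] = {s: [] for s in allele_sets}
    for m in mutations:
        if m.sample_id in by_sample:
            by_sample[m.sample_id].append(m)

    dropped = sum(1 for a in allele_sets.values() if not a.unambiguous)
    if dropped:
        logger.info("dropping %d sample(s) with ambiguous allele calls", dropped)
    usable = {s: a for s, a in allele_sets.items() if a.unambiguous}
    if not usable:
        raise ParameterError("no samples with unambiguous allele calls")

    burdens = [
        compute_sample_burden(
            sample_id,
            by_sample[sample_id],
            proteome,
            lookup,
            allele_set,
            params=params,
            min_alt_reads=min_alt_reads,
        )
        for sample_id, allele_set in usable.items()
    ]
    summary = summarize_cohort(burdens, params)
    return CohortResult(
        burdens=burdens, summary=summary, n_dropped_ambiguous=dropped
    )


def write_cohort_outputs(
    result: CohortResult, out_dir: str | Path, params: BurdenParams, seed=None
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = result.table
    table.to_csv(out / "sample_burden.tsv", sep="\t", index=False)
    # Rank-ordered table for burden-vs-rank plots.
    rank = table.copy()
    rank.insert(0, "rank", range(1, len(rank) + 1))
    rank.to_csv(out / "burden_rank.tsv", sep="\t", index=False)
    payload = summary_to_dict(result.summary, params)
    payload["n_dropped_ambiguous"] = result.n_dropped_ambiguous
    (out / "cohort_summary.json").write_text(json.dumps(payload, indent=1))
    _write_provenance(out, "cohort", params, seed)


def _write_provenance(
    out: Path, workflow: str, params: BurdenParams, seed
) -> None:
    """Machine-readable record sufficient to reproduce the run."""
    (out / "provenance.json").write_text(
        json.dumps(
            {
                "workflow": workflow,
                "seed": seed,
                "version": __version__,
                "params": {
                    "authenticity_rate": params.authenticity_rate,
                    "loci_scale": params.loci_scale,
                    "threshold_nM": params.threshold_nM,
                    "counting_mode": params.counting_mode,
                    "likelihood_cutoff": params.likelihood_cutoff,
                },
            },
            indent=1,
        )
    )
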
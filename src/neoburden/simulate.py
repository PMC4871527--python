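"""Seeded generators emulating the statistical structure of a tumor mutanome
study: per-sample somatic mutation tables, allele calls, and affinity tables,
plus an exactly-constructed single-sample fixture mirroring the
92 → 42 → 39 → 17 filtering funnel of the murine ovarian (ID8-G7-like)
vaccine study.

The cohort generator draws per-sample non-synonymous burdens from an
overdispersed count distribution (negative binomial by default; log-normal
for heavy-tailed, lung-like cohorts), marks each mutation as transcribed
with a fixed probability (anchored to the 42/92 expressed fraction observed
in the murine study), and plants a high-affinity binding window in a
Bernoulli fraction of the transcribed, epitope-eligible mutations. Affinity
tables are emitted through the deterministic synthetic predictor; non-planted
windows draw from a band strictly above the high-affinity threshold, so the
planted windows are exactly the binders. The recorded truth is nevertheless
recounted from the generated affinities, so truth and emitted files cannot
drift apart.

Everything is deterministic per (config, seed); identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import io as nio
from .binding import synthetic_ic50
from .burden import (
    BurdenParams,
    COHORT_PARAMS,
    min_neoantigens_for_likelihood,
    prob_at_least_one,
    scale_loci,
)
from .errors import ConfigConflictError, ParameterError
from .peptidome import apply_mutation, enumerate_class1_windows
from .records import (
    DEFAULT_KEEP_CLASSES,
    AlleleSet,
    MutationRecord,
    ProteinRecord,
    VariantClass,
)

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Affinity bands used when emitting simulated predictions (nM). Baseline
#: windows sit strictly above the 100 nM high-affinity threshold; planted
#: windows strictly below it.
BASELINE_BAND = (120.0, 50_000.0)
PLANTED_BAND = (3.0, 95.0)

_HLA_A_POOL = (
    "HLA-A*02:01",
    "HLA-A*01:01",
    "HLA-A*03:01",
    "HLA-A*24:02",
    "HLA-A*11:01",
)

#: Variant-class mix for simulated somatic non-synonymous mutations:
#: predominantly missense, with small nonsense and indel fractions.
DEFAULT_CLASS_MIX: Mapping[VariantClass, float] = {
    VariantClass.MISSENSE: 0.93,
    VariantClass.NONSENSE: 0.05,
    VariantClass.FRAMESHIFT: 0.01,
    VariantClass.INFRAME_INDEL: 0.01,
}


@dataclass(frozen=True)
class BurdenDist:
    """Distribution of per-sample somatic non-synonymous mutation counts."""

    family: Literal["negative_binomial", "log_normal"]
    mean: float = 0.0  # negative binomial mean
    dispersion: float = 0.0  # negative binomial size parameter r
    median: float = 0.0  # log-normal median (= exp of the log-mean)
    sigma: float = 0.0  # log-normal shape

    def __post_init__(self) -> None:
        if self.family == "negative_binomial":
            if self.mean <= 0 or self.dispersion <= 0:
                raise ParameterError(
                    "negative_binomial needs positive mean and dispersion"
                )
        elif self.family == "log_normal":
            if self.median <= 0 or self.sigma <= 0:
                raise ParameterError("log_normal needs positive median and sigma")
        else:
            raise ParameterError(f"unknown burden family {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "negative_binomial":
            p = self.dispersion / (self.dispersion + self.mean)
            return rng.negative_binomial(self.dispersion, p, size=size)
        draws = rng.lognormal(math.log(self.median), self.sigma, size=size)
        return np.rint(draws).astype(int)

    def thinned_sf(self, q: float, k: int) -> float:
        """P(thinned count > k) when each of n events survives w.p. q."""
        if self.family == "negative_binomial":
            # Poisson-gamma thinning: a q-thinned NB(r, mean mu) is
            # NB(r, mean mu*q) exactly.
            mu = self.mean * q
            p = self.dispersion / (self.dispersion + mu)
            return float(stats.nbinom.sf(k, self.dispersion, p))
        # Rounded log-normal mixed with binomial thinning: numeric sum.
        dist = stats.lognorm(s=self.sigma, scale=self.median)
        kmax = int(math.ceil(dist.ppf(1 - 1e-9)))
        ns = np.arange(0, kmax + 1)
        upper = dist.cdf(ns + 0.5)
        lower = dist.cdf(np.maximum(ns - 0.5, 0.0))
        weights = upper - lower  # mass of the log-normal rounding to each n
        weights /= weights.sum()
        return float(np.sum(weights * stats.binom.sf(k, ns, q)))


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration of a simulated cohort.

    ``transcribed_prob`` is the per-mutation probability of at least one
    supporting RNA read; ``binder_prob`` the probability that a transcribed,
    epitope-eligible mutation harbors a sub-threshold window at the typed
    locus; ``ambiguous_prob`` the fraction of samples whose allele calls are
    ambiguous (such samples are dropped by the cohort workflow, as in the
    human analysis).
    """

    n_samples: int
    burden_dist: BurdenDist
    transcribed_prob: float
    binder_prob: float
    seed: int
    ambiguous_prob: float = 0.2
    class_mix: Mapping[VariantClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    allele_pool: tuple[str, ...] = _HLA_A_POOL
    typed_loci: int = 1
    total_loci: int = 3
    preset: str | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ParameterError("n_samples must be >= 1")
        if not 0 < self.transcribed_prob < 1:
            raise ParameterError("transcribed_prob must be in (0,1)")
        if not 0 <= self.binder_prob < 1:
            raise ParameterError("binder_prob must be in [0,1)")
        if not 0 <= self.ambiguous_prob < 1:
            raise ParameterError("ambiguous_prob must be in [0,1)")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"class_mix must sum to 1, got {total}")


#: Fraction of mutations with RNA support, anchored to the 42-of-92
#: expressed fraction observed in the murine mutanome.
TRANSCRIBED_FRACTION = 42.0 / 92.0

# Preset shape and binder probabilities are frozen by
# scripts/calibrate_presets.py, which solves the analytic compound
# distribution for a target median raw predicted-neoantigen count (2 for
# the ovarian-like preset, 9 for the lung-like preset; x3 loci scaling then
# gives medians 6 and 27) and requires the empirical cohort median to be
# stable to within its binomial sampling error at 200 samples.
HGSC_BINDER_PROB = 0.121766
LUNG_SIGMA = 0.5
LUNG_BINDER_PROB = 0.104320

_PRESETS: dict[str, dict] = {
    "hgsc_like": {
        "burden_dist": BurdenDist(
            family="negative_binomial", mean=43.0, dispersion=8.0
        ),
        "transcribed_prob": TRANSCRIBED_FRACTION,
        "binder_prob": HGSC_BINDER_PROB,
    },
    "lung_like": {
        "burden_dist": BurdenDist(family="log_normal", median=200.0, sigma=LUNG_SIGMA),
        "transcribed_prob": TRANSCRIBED_FRACTION,
        "binder_prob": LUNG_BINDER_PROB,
    },
}


def make_config(
    n_samples: int,
    seed: int,
    preset: str | None = None,
    burden_dist: BurdenDist | None = None,
    transcribed_prob: float | None = None,
    binder_prob: float | None = None,
    **kwargs,
) -> CohortSimConfig:
    """Build a cohort configuration from a preset or explicit parameters.

    Supplying both a preset and an explicit burden distribution is a
    configuration conflict.
    """
    if preset is not None:
        if burden_dist is not None:
            raise ConfigConflictError(
                "preset and explicit burden_dist are mutually exclusive"
            )
        if preset not in _PRESETS:
            raise ParameterError(
                f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}"
            )
        chosen = _PRESETS[preset]
        return CohortSimConfig(
            n_samples=n_samples,
            seed=seed,
            preset=preset,
            burden_dist=chosen["burden_dist"],
            transcribed_prob=(
                transcribed_prob
                if transcribed_prob is not None
                else chosen["transcribed_prob"]
            ),
            binder_prob=(
                binder_prob if binder_prob is not None else chosen["binder_prob"]
            ),
            **kwargs,
        )
    if burden_dist is None:
        raise ParameterError("either a preset or a burden_dist is required")
    if transcribed_prob is None or binder_prob is None:
        raise ParameterError(
            "explicit configs need transcribed_prob and binder_prob"
        )
    return CohortSimConfig(
        n_samples=n_samples,
        seed=seed,
        burden_dist=burden_dist,
        transcribed_prob=transcribed_prob,
        binder_prob=binder_prob,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Proteome


def simulate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (60, 120),
    seed: int = 0,
) -> dict[str, ProteinRecord]:
    """Random proteins with residues uniform over the 20-letter alphabet.

    Lengths below 30 are rejected: every protein must admit a full 29mer
    vaccine design.
    """
    lo, hi = length_range
    if lo < 30:
        raise ParameterError(
            f"minimum protein length must be >= 30, got {lo}"
        )
    if hi < lo:
        raise ParameterError(f"bad length range {length_range}")
    rng = np.random.default_rng(seed)
    proteome: dict[str, ProteinRecord] = {}
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_AA20, size=length))
        pid = f"prot{i:04d}"
        proteome[pid] = ProteinRecord(
            protein_id=pid, gene=f"gene{i:04d}", sequence=seq
        )
    return proteome


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class SimulatedCohort:
    """A simulated cohort: inputs in pipeline dialects plus exact truth.

    ``truth`` holds per-sample counts at every funnel stage, recounted from
    the generated data; ``planted`` maps each sample to the window sequences
    it was seeded with.
    """

    config: CohortSimConfig
    proteome: dict[str, ProteinRecord]
    mutations: list[MutationRecord]
    allele_sets: dict[str, AlleleSet]
    calls: pd.DataFrame
    truth: pd.DataFrame
    planted: dict[str, list[str]]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit all inputs plus the truth record to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "mutations": out / "mutations.tsv",
            "proteome": out / "proteome.fasta",
            "alleles": out / "alleles.tsv",
            "predictions": out / "predictions.tsv",
            "truth": out / "truth.json",
        }
        nio.write_mutation_table(self.mutations, paths["mutations"])
        nio.write_protein_fasta(self.proteome, paths["proteome"])
        nio.write_allele_sets(self.allele_sets, paths["alleles"])
        self.calls.to_csv(paths["predictions"], sep="\t", index=False)
        truth_payload = {
            "samples": self.truth.to_dict(orient="records"),
            "planted": self.planted,
        }
        paths["truth"].write_text(json.dumps(truth_payload, indent=1, sort_keys=True))
        return paths


def _draw_reads(rng: np.random.Generator, transcribed: bool) -> tuple[int, int]:
    """RNA read support; geometric-like, spanning 0 to ~2000 reads."""
    ref = min(int(rng.geometric(0.05)) - 1, 2000)
    if transcribed:
        alt = min(int(rng.geometric(0.05)), 2000)
    else:
        alt = 0
    return ref, alt


def simulate_cohort(
    config: CohortSimConfig,
    proteome: Mapping[str, ProteinRecord] | None = None,
    params: BurdenParams = COHORT_PARAMS,
) -> SimulatedCohort:
    """Generate a cohort's mutation tables, allele calls, and affinities."""
    rng = np.random.default_rng(config.seed)
    if proteome is None:
        proteome = simulate_proteome(
            2000, (60, 120), seed=int(rng.integers(0, 2**31 - 1))
        )
    protein_ids = list(proteome)
    classes = list(config.class_mix)
    class_probs = np.array([config.class_mix[c] for c in classes], dtype=float)
    class_probs /= class_probs.sum()

    mutations: list[MutationRecord] = []
    allele_sets: dict[str, AlleleSet] = {}
    call_table: dict[tuple[str, str], float] = {}
    truth_rows: list[dict] = []
    planted: dict[str, list[str]] = {}
    # windows per sample, for the generation-time recount
    sample_windows: dict[str, list[tuple[int, list[str]]]] = {}
    planted_keys: set[tuple[str, str]] = set()
    pending: list[tuple[str, str, list[str]]] = []  # sample, allele, peptides

    for s in range(config.n_samples):
        sample_id = f"S{s:04d}"
        allele = str(rng.choice(np.array(config.allele_pool)))
        ambiguous = bool(rng.random() < config.ambiguous_prob)
        allele_sets[sample_id] = AlleleSet(
            sample_id=sample_id,
            alleles=(allele,),
            typed_loci=config.typed_loci,
            total_loci=config.total_loci,
            unambiguous=not ambiguous,
        )
        n_total = int(config.burden_dist.sample(rng, 1)[0])
        n_transcribed = 0
        n_retained = 0
        sample_planted: list[str] = []
        windows_here: list[tuple[int, list[str]]] = []

        for j in range(n_total):
            vclass: VariantClass = classes[
                int(rng.choice(len(classes), p=class_probs))
            ]
            pid = protein_ids[int(rng.integers(0, len(protein_ids)))]
            protein = proteome[pid]
            L = len(protein.sequence)
            pos = int(rng.integers(16, L - 15 + 1))
            ref = protein.sequence[pos - 1]
            if vclass is VariantClass.MISSENSE:
                alt = str(rng.choice(_AA20[_AA20 != ref]))
            elif vclass is VariantClass.NONSENSE:
                alt = "*"
            elif vclass is VariantClass.FRAMESHIFT:
                alt = "".join(rng.choice(_AA20, size=10))
            else:  # in-frame deletion of two residues
                ref = protein.sequence[pos - 1 : pos + 1]
                alt = ""
            transcribed = bool(rng.random() < config.transcribed_prob)
            reads_ref, reads_alt = _draw_reads(rng, transcribed)
            mutations.append(
                MutationRecord(
                    sample_id=sample_id,
                    gene=protein.gene,
                    protein_id=pid,
                    variant_class=vclass,
                    position=pos,
                    ref_aa=ref,
                    alt_aa=alt,
                    rna_reads_ref=reads_ref,
                    rna_reads_alt=reads_alt,
                    in_dbsnp=False,
                    somatic=True,
                )
            )
            if transcribed:
                n_transcribed += 1
            if transcribed and vclass in DEFAULT_KEEP_CLASSES:
                n_retained += 1
                ctx = apply_mutation(protein, mutations[-1])
                peptides = [
                    w.sequence for w in enumerate_class1_windows(ctx)
                ]
                windows_here.append((j, peptides))
                if rng.random() < config.binder_prob and peptides:
                    chosen = peptides[int(rng.integers(0, len(peptides)))]
                    sample_planted.append(chosen)
                    planted_keys.add((chosen, allele))
                pending.append((sample_id, allele, peptides))

        planted[sample_id] = sorted(set(sample_planted))
        sample_windows[sample_id] = windows_here
        truth_rows.append(
            {
                "sample_id": sample_id,
                "unambiguous": not ambiguous,
                "n_total": n_total,
                "n_transcribed": n_transcribed,
                "n_retained": n_retained,
            }
        )

    # Affinities: planted windows below the threshold, everything else above.
    # Planting is by exact (window, allele) identity — not substring — so
    # each planted mutation contributes exactly one binder peptide.
    for sample_id, allele, peptides in pending:
        for peptide in peptides:
            key = (peptide, allele)
            if key in call_table:
                continue
            if key in planted_keys:
                lo, hi = PLANTED_BAND
            else:
                lo, hi = BASELINE_BAND
            call_table[key] = synthetic_ic50(
                peptide, allele, config.seed, lo=lo, hi=hi
            )

    calls = pd.DataFrame(
        {
            "peptide": [k[0] for k in call_table],
            "allele": [k[1] for k in call_table],
            "ic50_nM": list(call_table.values()),
        }
    )

    # Recount truth from the generated affinities (no drift possible).
    for row in truth_rows:
        sample_id = row["sample_id"]
        allele = allele_sets[sample_id].alleles[0]
        binder_peptides: set[str] = set()
        binder_mutations = 0
        for _, peptides in sample_windows[sample_id]:
            hits = [
                p
                for p in peptides
                if call_table[(p, allele)] < params.threshold_nM
            ]
            if hits:
                binder_mutations += 1
                binder_peptides.update(hits)
        raw = (
            len(binder_peptides)
            if params.counting_mode == "per_peptide"
            else binder_mutations
        )
        N = scale_loci(raw, config.typed_loci, config.total_loci)
        row["n_binder_mutations"] = binder_mutations
        row["n_binder_peptides"] = len(binder_peptides)
        row["N"] = N
        row["P"] = prob_at_least_one(N, params.authenticity_rate)

    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(
        config=config,
        proteome=dict(proteome),
        mutations=mutations,
        allele_sets=allele_sets,
        calls=calls,
        truth=truth,
        planted=planted,
    )


# ---------------------------------------------------------------------------
# Analytic properties of the generative model


def per_mutation_binder_prob(config: CohortSimConfig) -> float:
    """Probability that one simulated mutation yields a planted binder."""
    kept = sum(
        p for c, p in config.class_mix.items() if c in DEFAULT_KEEP_CLASSES
    )
    return config.transcribed_prob * config.binder_prob * kept


def analytic_raw_sf(config: CohortSimConfig, k: int) -> float:
    """P(raw predicted-neoantigen count > k) under the generative model."""
    return config.burden_dist.thinned_sf(per_mutation_binder_prob(config), k)


def analytic_median_raw(config: CohortSimConfig, kmax: int = 10_000) -> int:
    """Median raw count: smallest k with CDF(k) >= 1/2."""
    for k in range(kmax):
        if 1.0 - analytic_raw_sf(config, k) >= 0.5:
            return k
    raise ParameterError("median search exceeded kmax")


def analytic_frac_high_likelihood(
    config: CohortSimConfig, params: BurdenParams = COHORT_PARAMS
) -> float:
    """Analytic fraction of samples whose authenticity probability meets the
    likelihood cutoff, under the configured generative model."""
    scale = config.total_loci / config.typed_loci
    n_star = min_neoantigens_for_likelihood(
        params.authenticity_rate, params.likelihood_cutoff
    )
    raw_star = math.ceil(n_star / scale)
    while prob_at_least_one(raw_star * scale, params.authenticity_rate) < (
        params.likelihood_cutoff
    ):
        raw_star += 1
    while raw_star > 0 and prob_at_least_one(
        (raw_star - 1) * scale, params.authenticity_rate
    ) >= params.likelihood_cutoff:
        raw_star -= 1
    return analytic_raw_sf(config, raw_star - 1)


# ---------------------------------------------------------------------------
# The single-sample vaccine-study fixture


@dataclass
class Id8Fixture:
    """A constructed single-sample mutanome with a known filtering funnel.

    92 somatic mutations, 42 with RNA support, 39 of those non-nonsense, and
    exactly 17 carrying one planted window with IC50 in [103, 1460] nM (the
    intermediate-affinity range; nothing below 100 nM). The funnel the
    pipeline recovers is therefore fixed by construction — this asserts the
    filtering and threshold logic, not any particular biology.
    """

    sample_id: str
    mutations: list[MutationRecord]
    proteome: dict[str, ProteinRecord]
    calls: pd.DataFrame
    allele_set: AlleleSet
    expected_funnel: tuple[int, int, int, int]
    panel_genes: frozenset[str]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "mutations": out / "mutations.tsv",
            "proteome": out / "proteome.fasta",
            "alleles": out / "alleles.tsv",
            "predictions": out / "predictions.tsv",
        }
        nio.write_mutation_table(self.mutations, paths["mutations"])
        nio.write_protein_fasta(self.proteome, paths["proteome"])
        nio.write_allele_sets({self.sample_id: self.allele_set}, paths["alleles"])
        self.calls.to_csv(paths["predictions"], sep="\t", index=False)
        return paths


def make_id8_fixture(seed: int = 0) -> Id8Fixture:
    """Construct the seeded single-sample fixture with funnel 92→42→39→17."""
    rng = np.random.default_rng(seed)
    sample_id = "ID8G7"
    alleles = ("H-2Kb", "H-2Db")
    allele_set = AlleleSet(
        sample_id=sample_id, alleles=alleles, typed_loci=2, total_loci=2
    )

    n_total, n_transcribed, n_kept, n_binders = 92, 42, 39, 17
    proteome: dict[str, ProteinRecord] = {}
    for i in range(n_total):
        pid = f"m{i:03d}"
        seq = "".join(rng.choice(_AA20, size=60))
        proteome[pid] = ProteinRecord(
            protein_id=pid, gene=f"g{i:03d}", sequence=seq
        )

    # Roles by index, then shuffled into table order.
    roles = (
        ["silent"] * (n_total - n_transcribed)
        + ["nonsense"] * (n_transcribed - n_kept)
        + ["kept"] * n_kept
    )
    order = rng.permutation(n_total)
    kept_indices = [i for i in order if roles[i] == "kept"]
    binder_indices = set(
        rng.choice(np.array(kept_indices), size=n_binders, replace=False).tolist()
    )
    # One frameshift and one in-frame deletion among the kept mutations.
    frameshift_idx, inframe_idx = kept_indices[0], kept_indices[1]

    mutations: list[MutationRecord] = []
    call_table: dict[tuple[str, str], float] = {}
    panel_genes: set[str] = set()

    for i in order:
        role = roles[i]
        pid = f"m{i:03d}"
        protein = proteome[pid]
        pos = int(rng.integers(16, len(protein.sequence) - 15 + 1))
        ref = protein.sequence[pos - 1]
        transcribed = role != "silent"
        reads_ref, reads_alt = _draw_reads(rng, transcribed)
        if role == "nonsense":
            vclass, alt = VariantClass.NONSENSE, "*"
        elif i == frameshift_idx:
            vclass, alt = VariantClass.FRAMESHIFT, "".join(
                rng.choice(_AA20, size=12)
            )
        elif i == inframe_idx:
            vclass = VariantClass.INFRAME_INDEL
            ref = protein.sequence[pos - 1 : pos + 1]
            alt = ""
        else:
            vclass = VariantClass.MISSENSE
            alt = str(rng.choice(_AA20[_AA20 != ref]))
        record = MutationRecord(
            sample_id=sample_id,
            gene=protein.gene,
            protein_id=pid,
            variant_class=vclass,
            position=pos,
            ref_aa=ref,
            alt_aa=alt,
            rna_reads_ref=reads_ref,
            rna_reads_alt=reads_alt,
            in_dbsnp=False,
            somatic=True,
        )
        mutations.append(record)

        if role == "kept":
            ctx = apply_mutation(protein, record)
            windows = enumerate_class1_windows(ctx)
            if i in binder_indices:
                chosen = windows[int(rng.integers(0, len(windows)))]
                chosen_allele = alleles[int(rng.integers(0, 2))]
                u = rng.random()
                call_table[(chosen.sequence, chosen_allele)] = 103.0 * (
                    (1460.0 / 103.0) ** u
                )
                panel_genes.add(protein.gene)
            for w in windows:
                for a in alleles:
                    call_table.setdefault(
                        (w.sequence, a),
                        synthetic_ic50(w.sequence, a, seed, lo=1600.0, hi=50_000.0),
                    )

    calls = pd.DataFrame(
        {
            "peptide": [k[0] for k in call_table],
            "allele": [k[1] for k in call_table],
            "ic50_nM": list(call_table.values()),
        }
    )
    return Id8Fixture(
        sample_id=sample_id,
        mutations=mutations,
        proteome=proteome,
        calls=calls,
        allele_set=allele_set,
        expected_funnel=(n_total, n_transcribed, n_kept, n_binders),
        panel_genes=frozenset(panel_genes),
    )
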
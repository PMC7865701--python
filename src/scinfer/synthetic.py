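"""Synthetic cell-line and patient cohorts with known ground truth.

The generators emit exactly the TSV/MAF dialects the ingest module reads, so
every pipeline stage can be exercised end-to-end without external downloads.

Cell-line cohort
    Per sample and gene, disruption is Bernoulli(f_g); each disruption is
    realised as a disruptive variant row (intolerant missense or
    loss-of-function) or a homozygous deletion, chosen at random. ln IC50 for
    the screened drug is mu + sum_p delta_p * 1[both genes of planted pair p
    disrupted] + Normal(0, sigma^2) noise; additional drugs either share the
    planted deltas or are pure noise.

Patient cohort
    Anchor and partner disruptions are independent Bernoulli draws; survival
    is exponential with hazard

        h = baseline_hazard * hr_per_burden_in_anchor ** (burden * anchor),

    censored by an independent exponential clock, so the planted hazard ratio
    per disrupted partner applies only in the anchor-mutant stratum --
    mirroring the with/without-anchor validation contrast.

All generators are seed-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .screen import SCPairResult

__all__ = [
    "CellCohortConfig",
    "PatientCohortConfig",
    "CellCohort",
    "PatientCohort",
    "simulate_cell_cohort",
    "simulate_patient_cohort",
    "recovery_metrics",
]

_LOF_CHOICES = (
    "stop_gained",
    "frameshift_variant",
    "start_lost",
    "splice_acceptor_variant",
    "splice_donor_variant",
)

_MAF_DISRUPTIVE_LOF = (
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
    "Translation_Start_Site",
)


def default_gene_names(n_genes: int) -> list[str]:
    return [f"G{i + 1:03d}" for i in range(n_genes)]


@dataclass(frozen=True)
class CellCohortConfig:
    """Conditions for the simulated cell-line cohort.

    ``disruption_freqs`` may be a per-gene array; by default each gene's
    frequency is drawn once from U(0.1, 0.3) -- the range typical of
    frequently altered cancer genes, comfortably above the screen's 5%
    entry filter. ``planted_pairs`` are (gene_a, gene_b, delta) triples;
    delta is the additive shift on ln IC50 when both genes are disrupted
    (negative = sensitising). The first drug is the screened agent and always
    carries the planted effects; drugs named in ``shared_effect_drugs`` reuse
    them, all others are noise-only.
    """

    n_samples: int = 400
    n_genes: int = 50
    disruption_freqs: tuple[float, ...] | None = None
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    baseline_mu: float = -2.0
    noise_sd: float = 1.0
    seed: int = 0
    n_drugs: int = 1
    drug_names: tuple[str, ...] | None = None
    shared_effect_drugs: tuple[str, ...] = ()
    gene_names: tuple[str, ...] | None = None
    het_loss_rate: float = 0.05  # non-disruptive cn=1 rows, for realism

    def resolved_drugs(self) -> list[str]:
        if self.drug_names is not None:
            return list(self.drug_names)
        return ["paclitaxel"] + [f"drug_{i + 2}" for i in range(self.n_drugs - 1)]

    def resolved_genes(self) -> list[str]:
        return list(self.gene_names) if self.gene_names is not None else default_gene_names(self.n_genes)


@dataclass
class CellCohort:
    variants: pd.DataFrame
    copy_number: pd.DataFrame
    response: pd.DataFrame
    truth: dict
    disruption_truth: pd.DataFrame  # samples x genes bool, the generating states

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
        self.copy_number.to_csv(out / "copy_number.tsv", sep="\t", index=False)
        self.response.to_csv(out / "response.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2)


def simulate_cell_cohort(cfg: CellCohortConfig) -> CellCohort:
    """Generate variant, copy-number and drug-response tables with planted SC pairs."""
    if cfg.noise_sd <= 0:
        raise ParameterError("noise_sd must be positive")
    genes = cfg.resolved_genes()
    gene_set = set(genes)
    for a, b, _ in cfg.planted_pairs:
        if a == b:
            raise ParameterError(f"planted pair genes must be distinct, got ({a}, {b})")
        if a not in gene_set or b not in gene_set:
            raise ParameterError(f"planted pair ({a}, {b}) outside the gene set")
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_samples, len(genes)
    samples = [f"S{i + 1:04d}" for i in range(n)]

    if cfg.disruption_freqs is not None:
        freqs = np.asarray(cfg.disruption_freqs, dtype=float)
        if freqs.size != g:
            raise ParameterError("disruption_freqs length must equal n_genes")
    else:
        freqs = rng.uniform(0.1, 0.3, size=g)
    if ((freqs <= 0) | (freqs >= 1)).any():
        raise ParameterError("disruption frequencies must lie in (0, 1)")

    disrupted = rng.random((n, g)) < freqs

    # realise each disruption as a variant or a homozygous deletion
    si, gi = np.nonzero(disrupted)
    as_deletion = rng.random(si.size) < 0.5
    as_missense = ~as_deletion & (rng.random(si.size) < 0.5)
    as_lof = ~as_deletion & ~as_missense

    var_rows = {
        "sample_id": [], "gene": [], "consequence": [], "sift_score": [],
        "esp_af": [], "kg_af": [],
    }
    mis_idx = np.nonzero(as_missense)[0]
    lof_idx = np.nonzero(as_lof)[0]
    sift = rng.uniform(0.0, 0.0499, size=mis_idx.size)
    lof_terms = rng.choice(_LOF_CHOICES, size=lof_idx.size)
    for k, idx in enumerate(mis_idx):
        var_rows["sample_id"].append(samples[si[idx]])
        var_rows["gene"].append(genes[gi[idx]])
        var_rows["consequence"].append("missense_variant")
        var_rows["sift_score"].append(round(float(sift[k]), 6))
        var_rows["esp_af"].append(np.nan)
        var_rows["kg_af"].append(np.nan)
    for k, idx in enumerate(lof_idx):
        var_rows["sample_id"].append(samples[si[idx]])
        var_rows["gene"].append(genes[gi[idx]])
        var_rows["consequence"].append(str(lof_terms[k]))
        var_rows["sift_score"].append(np.nan)
        var_rows["esp_af"].append(np.nan)
        var_rows["kg_af"].append(np.nan)
    variants = pd.DataFrame(var_rows).sort_values(["sample_id", "gene"], kind="stable").reset_index(drop=True)

    # full copy-number grid: 2 baseline, 0 for deletion events, sprinkled cn=1
    cn = np.full((n, g), 2, dtype=int)
    het = rng.random((n, g)) < cfg.het_loss_rate
    cn[het] = 1
    cn[si[as_deletion], gi[as_deletion]] = 0
    copy_number = pd.DataFrame(
        {
            "sample_id": np.repeat(samples, g),
            "gene": np.tile(genes, n),
            "total_copy_number": cn.ravel(),
        }
    )

    # responses
    gene_pos = {gname: i for i, gname in enumerate(genes)}
    planted_effect = np.zeros(n)
    for a, b, delta in cfg.planted_pairs:
        both = disrupted[:, gene_pos[a]] & disrupted[:, gene_pos[b]]
        planted_effect += delta * both
    drugs = cfg.resolved_drugs()
    shared = set(cfg.shared_effect_drugs) | {drugs[0]}
    resp_frames = []
    for drug in drugs:
        eps = rng.normal(0.0, cfg.noise_sd, size=n)
        y = cfg.baseline_mu + (planted_effect if drug in shared else 0.0) + eps
        resp_frames.append(pd.DataFrame({"sample_id": samples, "drug": drug, "ln_ic50": y}))
    response = pd.concat(resp_frames, ignore_index=True)

    truth = {
        "planted_pairs": [[a, b, float(d)] for a, b, d in cfg.planted_pairs],
        "disruption_freqs": [float(f) for f in freqs],
        "baseline_mu": cfg.baseline_mu,
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
        "drugs": drugs,
        "shared_effect_drugs": sorted(shared),
    }
    dis_truth = pd.DataFrame(disrupted, index=pd.Index(samples, name="sample_id"), columns=genes)
    return CellCohort(variants, copy_number, response, truth, dis_truth)


@dataclass(frozen=True)
class PatientCohortConfig:
    """Conditions for the simulated patient cohort.

    Hazard for a patient with partner burden k: baseline_hazard *
    hr_per_burden_in_anchor**k if the anchor gene is mutated, baseline_hazard
    otherwise. Times are in days; defaults give roughly half the cohort
    anchor-mutant with a stage mix resembling an advanced urothelial-cancer
    case mix.
    """

    n_patients: int = 800
    anchor_gene: str = "TP53"
    partner_genes: tuple[str, ...] = ("SYNE2", "SON")
    anchor_mut_frac: float = 0.5
    partner_mut_fracs: tuple[float, ...] = (0.3, 0.15)
    hr_per_burden_in_anchor: float = 0.4
    baseline_hazard: float = 0.001
    censoring_rate: float = 0.0008
    stage_probs: tuple[float, float, float, float] = (0.05, 0.30, 0.35, 0.30)
    seed: int = 0


@dataclass
class PatientCohort:
    maf: pd.DataFrame
    clinical: pd.DataFrame
    truth: dict

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.maf.to_csv(out / "cohort.maf", sep="\t", index=False)
        self.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2)


def simulate_patient_cohort(cfg: PatientCohortConfig) -> PatientCohort:
    """Generate a MAF mutation table and clinical table with a planted
    burden-by-anchor survival interaction."""
    fracs = (cfg.anchor_mut_frac, *cfg.partner_mut_fracs)
    if any(not (0 < f < 1) for f in fracs):
        raise ParameterError("mutation fractions must lie in (0, 1)")
    if len(cfg.partner_mut_fracs) != len(cfg.partner_genes):
        raise ParameterError("one mutation fraction per partner gene is required")
    if abs(sum(cfg.stage_probs) - 1.0) > 1e-12:
        raise ParameterError("stage_probs must sum to 1")
    if cfg.baseline_hazard <= 0 or cfg.censoring_rate <= 0:
        raise ParameterError("baseline_hazard and censoring_rate must be positive")

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    patients = [f"P{i + 1:04d}" for i in range(n)]

    anchor = rng.random(n) < cfg.anchor_mut_frac
    partners = {
        g: rng.random(n) < f for g, f in zip(cfg.partner_genes, cfg.partner_mut_fracs)
    }
    burden = np.sum([v for v in partners.values()], axis=0).astype(int)

    hazard = cfg.baseline_hazard * cfg.hr_per_burden_in_anchor ** (burden * anchor)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / cfg.censoring_rate, size=n)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=cfg.stage_probs)

    maf_rows = {"Hugo_Symbol": [], "Tumor_Sample_Barcode": [], "Variant_Classification": [], "SIFT": []}

    def add_mutation(gene: str, mask: np.ndarray) -> None:
        idx = np.nonzero(mask)[0]
        missense = rng.random(idx.size) < 0.5
        lof_terms = rng.choice(_MAF_DISRUPTIVE_LOF, size=idx.size)
        sift = rng.uniform(0.0, 0.0499, size=idx.size)
        for k, i in enumerate(idx):
            maf_rows["Hugo_Symbol"].append(gene)
            maf_rows["Tumor_Sample_Barcode"].append(patients[i])
            if missense[k]:
                maf_rows["Variant_Classification"].append("Missense_Mutation")
                maf_rows["SIFT"].append(f"deleterious({sift[k]:.4f})")
            else:
                maf_rows["Variant_Classification"].append(str(lof_terms[k]))
                maf_rows["SIFT"].append("")

    add_mutation(cfg.anchor_gene, anchor)
    for g, mask in partners.items():
        add_mutation(g, mask)
    maf = (
        pd.DataFrame(maf_rows)
        .sort_values(["Tumor_Sample_Barcode", "Hugo_Symbol"], kind="stable")
        .reset_index(drop=True)
    )

    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "os_time": np.round(os_time, 3),
            "os_event": os_event,
            "stage": stage,
            "anchor_mutant": anchor.astype(int),
        }
    )
    truth = {
        "anchor_gene": cfg.anchor_gene,
        "partner_genes": list(cfg.partner_genes),
        "hr_per_burden_in_anchor": cfg.hr_per_burden_in_anchor,
        "baseline_hazard": cfg.baseline_hazard,
        "censoring_rate": cfg.censoring_rate,
        "seed": cfg.seed,
        "burden": burden.tolist(),
        "anchor_status": anchor.astype(int).tolist(),
    }
    return PatientCohort(maf, clinical, truth)


def recovery_metrics(
    truth_pairs: Iterable[Sequence[str]], inferred: Iterable[SCPairResult]
) -> dict:
    """Precision/recall of declared SC pairs against planted truth.

    Pairs are compared as unordered sets. With nothing declared, precision is
    undefined and reported as None.
    """
    truth = {frozenset((p[0], p[1])) for p in truth_pairs}
    declared = {r.as_pair() for r in inferred if r.is_sc}
    detected = {tuple(sorted(p)): (p in declared) for p in truth}
    n_hit = sum(detected.values())
    recall = n_hit / len(truth) if truth else float("nan")
    precision = (
        sum(1 for p in declared if p in truth) / len(declared) if declared else None
    )
    return {"precision": precision, "recall": recall, "detected": detected}
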
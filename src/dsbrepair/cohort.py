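"""Synthetic case-control cohort generation.

Generates cohorts with the statistical structure the downstream analysis
assumes, so that repair scoring, association statistics, expression
comparison and the classifier can all be exercised without any external
data.  Each subject carries:

* an arm label (``case`` = rheumatoid arthritis, ``control`` = healthy),
* a comet-assay damage pair (percent DNA damage right after the bleomycin
  challenge and after 120 min of recovery),
* one genotype string per SNP in the panel, and
* one (Ct_target, Ct_reference) qPCR pair per expression gene.

The sampling model: each subject draws a repair group from the per-arm
group distribution and a percent-repaired value uniform inside that
group's bin; ``damage_t0`` is uniform on an arbitrary comet-unit range and
``damage_t120 = damage_t0 * (1 - r/100)``, so the recomputed repair
efficiency equals the sampled ``r`` (only the damage ratio is
identifiable, since the initial damage is normalised to 100%).  Genotypes
are sampled independently per locus (no linkage disequilibrium), and
expression folds are log2-normal around the per-arm median with the Ct
pair back-derived from the fold.  Defaults are calibrated to the
reference study's published per-arm summaries (:mod:`dsbrepair.study_data`).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import study_data

ARMS = study_data.ARMS

_PROB_TOL = 1e-12


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class SNPDescriptor:
    """One locus of the SNP panel: identifier, gene, repair pathway and
    the declared genotype categories (first category = odds-ratio
    reference)."""

    snp_id: str
    gene: str
    pathway: str
    alleles: tuple[str, str]
    genotypes: tuple[str, ...]


@dataclass
class SubjectRecord:
    """One study participant."""

    subject_id: str
    arm: str
    damage_t0: float
    damage_t120: float
    genotypes: dict[str, str]
    ct_values: dict[str, tuple[float, float]]
    #: Repair group (1-4) sampled by the generator; ``None`` for real data.
    true_repair_group: int | None = None


@dataclass
class CohortConfig:
    """Full parameterisation of the synthetic cohort generator.

    ``genotype_probs`` maps SNP id -> arm -> probability vector aligned
    with the descriptor's genotype order; ``repair_group_probs`` maps arm
    -> probability vector over groups 1..4 (1 = highly efficient);
    ``repair_bins`` are the three percent-repaired cut points separating
    group 4|3, 3|2 and 2|1; ``expression_params`` maps gene -> arm ->
    median fold of a log2-normal fold distribution with spread
    ``expression_sigma_log2``.
    """

    n_cases: int
    n_controls: int
    seed: int
    snp_panel: list[SNPDescriptor]
    genotype_probs: dict[str, dict[str, np.ndarray]]
    repair_group_probs: dict[str, np.ndarray]
    repair_bins: tuple[float, float, float] = study_data.REPAIR_BIN_EDGES
    repeff_range: tuple[float, float] = (0.0, 100.0)
    expression_params: dict[str, dict[str, float]] = field(default_factory=dict)
    expression_sigma_log2: float = 1.0
    damage_t0_range: tuple[float, float] = (80.0, 120.0)
    ct_reference_range: tuple[float, float] = (18.0, 25.0)

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigError("n_cases and n_controls must be positive")
        c1, c2, c3 = self.repair_bins
        if not (c1 < c2 < c3):
            raise ConfigError("repair_bins must be strictly increasing")
        lo, hi = self.repeff_range
        if not (lo < c1 and c3 < hi):
            raise ConfigError("repair_bins must lie inside repeff_range")
        for arm in ARMS:
            _check_probs(self.repair_group_probs[arm],
                         f"repair_group_probs[{arm}]", 4)
        for snp in self.snp_panel:
            probs = self.genotype_probs.get(snp.snp_id)
            if probs is None:
                raise ConfigError(f"missing genotype_probs for {snp.snp_id}")
            for arm in ARMS:
                _check_probs(probs[arm],
                             f"genotype_probs[{snp.snp_id}][{arm}]",
                             len(snp.genotypes))
        for gene, medians in self.expression_params.items():
            for arm in ARMS:
                if not (medians[arm] > 0):
                    raise ConfigError(
                        f"expression median for {gene}/{arm} must be > 0")

    def snp(self, snp_id: str) -> SNPDescriptor:
        for snp in self.snp_panel:
            if snp.snp_id == snp_id:
                return snp
        raise KeyError(snp_id)


def _check_probs(p: Sequence[float], name: str, k: int) -> None:
    p = np.asarray(p, dtype=float)
    if p.shape != (k,):
        raise ConfigError(f"{name} must have length {k}")
    if np.any(p < 0) or abs(p.sum() - 1.0) > _PROB_TOL:
        raise ConfigError(f"{name} must be non-negative and sum to 1")


# ---------------------------------------------------------------------------
# summary-count helpers

def genotype_probs_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert a genotype x arm count table to per-arm probabilities.

    ``counts`` has one row per genotype and one column per arm.  Each arm
    column is normalised by its total.  An arm with no observations is
    degenerate and raises :class:`ConfigError`.
    """
    counts = pd.DataFrame(counts)
    if (counts.to_numpy() < 0).any():
        raise ConfigError("genotype counts must be non-negative")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        empty = list(totals.index[totals <= 0])
        raise ConfigError(f"empty arm(s) in genotype count table: {empty}")
    return counts / totals


def genotype_count_frame(snp_id: str) -> pd.DataFrame:
    """Published genotype x arm counts for one panel SNP."""
    row = study_data.snp_row(snp_id)
    return pd.DataFrame(
        {arm: list(row[arm]) for arm in ARMS},
        index=list(row["genotypes"]),
    )


def allele_frequencies(counts: Mapping[str, int]) -> dict[str, float]:
    """Allele frequencies from genotype counts (keys like ``"G/C"``)."""
    tally: dict[str, float] = {}
    total = 0
    for genotype, n in counts.items():
        for allele in genotype.split("/"):
            tally[allele] = tally.get(allele, 0) + n
            total += n
    if total == 0:
        raise ConfigError("no genotype observations")
    return {a: c / total for a, c in tally.items()}


def minor_allele_frequency(counts: Mapping[str, int]) -> float:
    """Minor allele frequency from genotype counts of one arm."""
    return min(allele_frequencies(counts).values())


# ---------------------------------------------------------------------------
# configuration construction

def default_config(n_cases: int = 45, n_controls: int = 45,
                   seed: int = 0) -> CohortConfig:
    """Generator configuration calibrated to the reference study.

    Genotype probabilities come from the published per-arm genotype
    counts, the repair-group distribution from the published 2 x 4 group
    table (controls 12/11/11/11, RA 1/1/5/38) and the expression medians
    from the published per-arm medians of the seven DSB-repair genes.
    """
    panel = [
        SNPDescriptor(row["snp_id"], row["gene"], row["pathway"],
                      tuple(row["alleles"]), tuple(row["genotypes"]))
        for row in study_data.SNP_TABLE
    ]
    genotype_probs = {}
    for row in study_data.SNP_TABLE:
        genotype_probs[row["snp_id"]] = {
            arm: np.asarray(row[arm], dtype=float) / sum(row[arm])
            for arm in ARMS
        }
    repair_group_probs = {
        arm: np.asarray(study_data.REPAIR_GROUP_COUNTS[arm], dtype=float)
        / sum(study_data.REPAIR_GROUP_COUNTS[arm])
        for arm in ARMS
    }
    config = CohortConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
        snp_panel=panel,
        genotype_probs=genotype_probs,
        repair_group_probs=repair_group_probs,
        expression_params=copy.deepcopy(study_data.EXPRESSION_MEDIANS),
    )
    config.validate()
    return config


def plant_association(config: CohortConfig, snp_id: str,
                      target_or: float,
                      genotype: str | None = None) -> CohortConfig:
    """Return a config whose case-arm genotype probabilities encode a
    planted odds ratio.

    The case-arm distribution is rebuilt from the control-arm one by
    multiplying the weight of the variant ``genotype`` (default: the
    last-listed, homozygous-variant category) by ``target_or`` and
    renormalising.  Within-arm renormalisation leaves the exposure-odds
    ratio of variant vs reference untouched, so the population odds ratio
    of ``genotype`` vs the reference category equals ``target_or``
    exactly; all other categories keep an odds ratio of 1.
    """
    if not target_or > 0:
        raise ConfigError("target_or must be > 0")
    snp = config.snp(snp_id)
    if genotype is None:
        genotype = snp.genotypes[-1]
    if genotype not in snp.genotypes:
        raise ConfigError(f"{genotype!r} not a genotype of {snp_id}")
    idx = snp.genotypes.index(genotype)
    control = np.asarray(config.genotype_probs[snp_id]["control"], float)
    if control[0] <= 0 or control[idx] <= 0:
        raise ConfigError(
            "reference and variant genotype need positive control-arm "
            "probability to plant a finite odds ratio")
    weights = control.copy()
    weights[idx] *= target_or
    case = weights / weights.sum()
    if np.any(case < 0) or np.any(case > 1):
        raise ConfigError("planted probabilities fall outside [0, 1]")
    new = copy.deepcopy(config)
    new.genotype_probs[snp_id]["case"] = case
    return new


# ---------------------------------------------------------------------------
# generation

def _group_intervals(config: CohortConfig) -> dict[int, tuple[float, float]]:
    lo, hi = config.repeff_range
    c1, c2, c3 = config.repair_bins
    return {1: (c3, hi), 2: (c2, c3), 3: (c1, c2), 4: (lo, c1)}


def generate_cohort_frame(config: CohortConfig) -> pd.DataFrame:
    """Generate a cohort as a tidy DataFrame (one row per subject).

    Columns: ``subject_id``, ``arm``, ``true_group``, ``damage_t0``,
    ``damage_t120``, one column per SNP (genotype strings) and a
    ``<gene>_ct_target`` / ``<gene>_ct_ref`` pair per expression gene.
    Identical config (including seed) always produces an identical frame.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    intervals = _group_intervals(config)
    frames = []
    for arm, n, prefix in (("control", config.n_controls, "HC"),
                           ("case", config.n_cases, "RA")):
        groups = rng.choice(4, size=n, p=config.repair_group_probs[arm]) + 1
        t0 = rng.uniform(*config.damage_t0_range, size=n)
        low = np.array([intervals[g][0] for g in groups])
        high = np.array([intervals[g][1] for g in groups])
        repaired = rng.uniform(low, high)
        t120 = t0 * (1.0 - repaired / 100.0)
        data: dict[str, object] = {
            "subject_id": [f"{prefix}{i + 1:03d}" for i in range(n)],
            "arm": arm,
            "true_group": groups,
            "damage_t0": t0,
            "damage_t120": t120,
        }
        for snp in config.snp_panel:
            probs = config.genotype_probs[snp.snp_id][arm]
            idx = rng.choice(len(snp.genotypes), size=n, p=probs)
            data[snp.snp_id] = [snp.genotypes[i] for i in idx]
        for gene, medians in config.expression_params.items():
            log2_fold = rng.normal(math.log2(medians[arm]),
                                   config.expression_sigma_log2, size=n)
            ct_ref = rng.uniform(*config.ct_reference_range, size=n)
            data[f"{gene}_ct_target"] = ct_ref - log2_fold
            data[f"{gene}_ct_ref"] = ct_ref
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate a cohort as :class:`SubjectRecord` objects."""
    frame = generate_cohort_frame(config)
    genes = list(config.expression_params)
    snp_ids = [s.snp_id for s in config.snp_panel]
    records = []
    for row in frame.itertuples(index=False):
        row = row._asdict()
        records.append(SubjectRecord(
            subject_id=row["subject_id"],
            arm=row["arm"],
            damage_t0=row["damage_t0"],
            damage_t120=row["damage_t120"],
            genotypes={s: row[s] for s in snp_ids},
            ct_values={g: (row[f"{g}_ct_target"], row[f"{g}_ct_ref"])
                       for g in genes},
            true_repair_group=int(row["true_group"]),
        ))
    return records


# ---------------------------------------------------------------------------
# I/O

def write_cohort_csv(frame: pd.DataFrame, path, include_truth: bool = False) -> None:
    """Write the cohort table as CSV (drops generator truth by default)."""
    out = frame if include_truth else frame.drop(columns=["true_group"],
                                                 errors="ignore")
    out.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def config_to_yaml(config: CohortConfig, path=None) -> str:
    """Serialise a config as flat YAML; optionally write it to ``path``."""
    doc = {
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "seed": config.seed,
        "repair_bins": list(config.repair_bins),
        "repeff_range": list(config.repeff_range),
        "damage_t0_range": list(config.damage_t0_range),
        "ct_reference_range": list(config.ct_reference_range),
        "expression_sigma_log2": config.expression_sigma_log2,
        "repair_group_probs": {arm: [float(p) for p in v]
                               for arm, v in config.repair_group_probs.items()},
        "snp_panel": [
            {
                "snp_id": s.snp_id, "gene": s.gene, "pathway": s.pathway,
                "alleles": list(s.alleles), "genotypes": list(s.genotypes),
                "probs": {arm: [float(p) for p in
                                config.genotype_probs[s.snp_id][arm]]
                          for arm in ARMS},
            }
            for s in config.snp_panel
        ],
        "expression_params": {
            gene: {arm: float(m[arm]) for arm in ARMS}
            for gene, m in config.expression_params.items()
        },
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_from_yaml(source) -> CohortConfig:
    """Load a config written by :func:`config_to_yaml` (path or text)."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        text = str(source)
        if "\n" not in text and not text.lstrip().startswith("{"):
            with open(text) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)
    panel = [SNPDescriptor(e["snp_id"], e["gene"], e["pathway"],
                           tuple(e["alleles"]), tuple(e["genotypes"]))
             for e in doc["snp_panel"]]
    genotype_probs = {
        e["snp_id"]: {arm: np.asarray(e["probs"][arm], float) for arm in ARMS}
        for e in doc["snp_panel"]
    }
    config = CohortConfig(
        n_cases=int(doc["n_cases"]),
        n_controls=int(doc["n_controls"]),
        seed=int(doc["seed"]),
        snp_panel=panel,
        genotype_probs=genotype_probs,
        repair_group_probs={arm: np.asarray(doc["repair_group_probs"][arm],
                                            float) for arm in ARMS},
        repair_bins=tuple(doc["repair_bins"]),
        repeff_range=tuple(doc["repeff_range"]),
        expression_params={g: {arm: float(v[arm]) for arm in ARMS}
                           for g, v in doc["expression_params"].items()},
        expression_sigma_log2=float(doc["expression_sigma_log2"]),
        damage_t0_range=tuple(doc["damage_t0_range"]),
        ct_reference_range=tuple(doc["ct_reference_range"]),
    )
    config.validate()
    return config
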
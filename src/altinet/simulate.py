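"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes can be generated here: a paired pre/post
count matrix for two exposure groups (negative-binomial counts with planted
differential expression), per-group expression matrices with a planted
co-expressed module, a cytokine cohort with a planted change-vs-severity
correlation, and FASTQ files with planted read-level contamination. All
generators are deterministic given the configuration seed.

The defaults emulate the statistical structure of a high-altitude exposure
study: 5 subjects per group sampled before and after ascent, two overlapping
differential-expression programmes (group-exclusive plus common genes), a
group-specific co-expression module, and a 22-subject validation cohort
(12 AMS, 10 non-AMS) in which the change in an anti-inflammatory cytokine
correlates negatively (target r = -0.52) with the Lake Louise severity
score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io import CountMatrix, GROUPS, write_tsv

#: Illumina TruSeq universal adapter, the default planted contaminant
DEFAULT_ADAPTOR = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


@dataclass
class SimConfig:
    """Configuration for all synthetic-data generators.

    Group 1 is "AMS", group 2 is "non-AMS". ``de_frac_group1`` and
    ``de_frac_group2`` are the fractions of genes differentially expressed
    *exclusively* in each group; ``de_frac_common`` is the fraction shared
    by both, so a group's full DE set is its exclusive set plus the common
    set. Truth-set sizes are ``floor(frac * n_genes)`` exactly.
    """

    n_subjects_per_group: int = 5
    n_genes: int = 2000
    nb_mean_range: tuple[float, float] = (5.0, 500.0)
    nb_dispersion: float = 0.1
    de_frac_group1: float = 0.05
    de_frac_group2: float = 0.04
    de_frac_common: float = 0.015
    de_log2fc: float = 2.0
    subject_effect_sd: float = 0.15
    module_size: int = 30
    module_latent_sd: float = 5.0
    coexpr_n_samples: int = 20
    cohort_n: int = 22
    cohort_n_ams: int = 12
    cohort_target_r: float = -0.52
    cohort_noise_sd: float = 1.0
    contamination_rates: tuple[float, float, float] = (0.05, 0.05, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_subjects_per_group <= 0:
            raise ValueError("n_genes and n_subjects_per_group must be positive")
        fracs = (self.de_frac_group1, self.de_frac_group2, self.de_frac_common)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("DE fractions must lie in [0, 1]")
        if sum(fracs) > 1.0:
            raise ValueError("DE fractions must sum to <= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.module_latent_sd < 0:
            raise ValueError("module_latent_sd must be non-negative")
        if self.module_size >= self.n_genes:
            raise ValueError("module_size must be smaller than n_genes")
        if abs(self.cohort_target_r) >= 1.0 and self.cohort_noise_sd > 0:
            raise ValueError("|cohort_target_r| >= 1 requires zero noise")
        if not -1.0 <= self.cohort_target_r <= 1.0:
            raise ValueError("cohort_target_r must lie in [-1, 1]")
        if any(not 0.0 <= c <= 1.0 for c in self.contamination_rates):
            raise ValueError("contamination rates must lie in [0, 1]")
        if sum(self.contamination_rates) > 1.0:
            raise ValueError("contamination rates must sum to <= 1")


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated data set."""

    de_genes_group1: frozenset[str] = frozenset()
    de_genes_group2: frozenset[str] = frozenset()
    common_de_genes: frozenset[str] = frozenset()
    de_direction: dict[str, int] = field(default_factory=dict)
    module_genes: frozenset[str] = frozenset()
    cohort_slope: float = 0.0


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Paired pre/post count matrix
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Simulate the paired two-group count matrix with planted DE genes.

    Counts are negative binomial with log-uniform per-gene baseline means and
    a log-normal per-subject size factor shared by that subject's pre and
    post samples (which is what makes paired tests worthwhile). Planted DE
    genes have their post-timepoint mean multiplied by ``2**(+-de_log2fc)``
    in the group(s) they belong to; the sign is drawn per gene and shared
    between groups for common genes.

    Returns (CountMatrix, design table, SimTruth).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = _gene_ids(n)

    n1 = math.floor(config.de_frac_group1 * n)
    n2 = math.floor(config.de_frac_group2 * n)
    nc = math.floor(config.de_frac_common * n)
    picked = rng.choice(n, size=n1 + n2 + nc, replace=False)
    excl1 = frozenset(genes[i] for i in picked[:n1])
    excl2 = frozenset(genes[i] for i in picked[n1:n1 + n2])
    common = frozenset(genes[i] for i in picked[n1 + n2:])
    signs = {genes[i]: int(s) for i, s in zip(picked, rng.choice([-1, 1], size=len(picked)))}

    lo, hi = config.nb_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    lengths = pd.Series(rng.integers(500, 5000, size=n), index=genes, name="length_bp")

    fc = {g: 2.0 ** (signs[g] * config.de_log2fc) for g in signs}
    de_by_group = {
        GROUPS[0]: excl1 | common,
        GROUPS[1]: excl2 | common,
    }

    columns: dict[str, np.ndarray] = {}
    design_rows = []
    subj_idx = 0
    for group in GROUPS:
        for _ in range(config.n_subjects_per_group):
            subj_idx += 1
            subject = f"subj{subj_idx:02d}"
            size_factor = np.exp(rng.normal(0.0, config.subject_effect_sd))
            for timepoint in ("pre", "post"):
                mean = base_mean * size_factor
                if timepoint == "post":
                    shift = np.array(
                        [fc[g] if g in de_by_group[group] else 1.0 for g in genes]
                    )
                    mean = mean * shift
                sample = f"{subject}_{timepoint}"
                columns[sample] = _nb_draw(rng, mean, config.nb_dispersion)
                design_rows.append((sample, subject, group, timepoint))

    counts = pd.DataFrame(columns, index=genes)
    design = pd.DataFrame(
        design_rows, columns=["sample_id", "subject_id", "group", "timepoint"]
    ).set_index("sample_id")
    truth = SimTruth(
        de_genes_group1=excl1 | common,
        de_genes_group2=excl2 | common,
        common_de_genes=common,
        de_direction=signs,
    )
    return CountMatrix(counts=counts, lengths=lengths), design, truth


# ---------------------------------------------------------------------------
# Group-specific co-expression module
# ---------------------------------------------------------------------------


def simulate_coexpression(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Two expression matrices with a latent-factor module in group 1 only.

    In group 1 each module gene is ``latent_sd * f_s + noise`` with a shared
    per-sample factor f_s ~ N(0,1) and unit noise, so within-module pairwise
    correlation is ``latent_sd^2 / (latent_sd^2 + 1)``. Group 2 module genes
    are independent draws with the same marginal variance; background genes
    are independent unit-variance noise in both groups. Values are offset to
    a log2-expression-like scale.
    """
    if config.module_size < 3:
        raise ValueError("module_size must be >= 3")
    rng = np.random.default_rng(config.seed)
    n, m = config.n_genes, config.coexpr_n_samples
    s = config.module_latent_sd
    genes = _gene_ids(n)
    module_idx = rng.choice(n, size=config.module_size, replace=False)
    module = frozenset(genes[i] for i in module_idx)

    baseline = 8.0
    marg_sd = math.sqrt(s * s + 1.0)

    def one_group(correlated: bool) -> np.ndarray:
        x = rng.normal(0.0, 1.0, size=(n, m))
        if correlated:
            factor = rng.normal(0.0, 1.0, size=m)
            x[module_idx, :] += s * factor[None, :]
        else:
            x[module_idx, :] = rng.normal(0.0, marg_sd, size=(len(module_idx), m))
        return baseline + x

    cols1 = [f"a{j:02d}" for j in range(m)]
    cols2 = [f"b{j:02d}" for j in range(m)]
    expr1 = pd.DataFrame(one_group(True), index=genes, columns=cols1)
    expr2 = pd.DataFrame(one_group(False), index=genes, columns=cols2)
    return expr1, expr2, SimTruth(module_genes=module)


# ---------------------------------------------------------------------------
# Cytokine cohort
# ---------------------------------------------------------------------------


def simulate_cytokine_cohort(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Cohort table with a planted change-vs-severity correlation.

    Lake Louise scores respect the diagnosis rule (AMS members score >= 3,
    non-AMS < 3). The cytokine change (post - pre, pg/mL) is
    ``slope * LLS + noise`` with the slope calibrated as
    ``b = r * sd_noise / (sd_LLS * sqrt(1 - r^2))`` so the population
    correlation between change and LLS equals ``cohort_target_r``. With zero
    noise the relation is perfectly linear and the sample correlation is
    exactly the sign of the target.
    """
    if config.cohort_n < 4:
        raise ValueError("cohort_n must be >= 4")
    if not 0 < config.cohort_n_ams < config.cohort_n:
        raise ValueError("cohort_n_ams must split the cohort into two non-empty groups")
    rng = np.random.default_rng(config.seed)
    n_ams = config.cohort_n_ams
    n_non = config.cohort_n - n_ams

    lls_ams = 3 + rng.binomial(7, 0.4, size=n_ams)
    lls_non = rng.integers(0, 3, size=n_non)
    lls = np.concatenate([lls_ams, lls_non]).astype(float)
    groups = [GROUPS[0]] * n_ams + [GROUPS[1]] * n_non

    r = config.cohort_target_r
    sd_noise = config.cohort_noise_sd
    sd_lls = float(np.std(lls, ddof=1))
    if sd_noise > 0:
        slope = r * sd_noise / (sd_lls * math.sqrt(1.0 - r * r))
        noise = rng.normal(0.0, sd_noise, size=config.cohort_n)
    else:
        slope = math.copysign(1.0, r) if r != 0 else 0.0
        noise = np.zeros(config.cohort_n)
    change = slope * lls + noise

    pre = rng.lognormal(mean=math.log(20.0), sigma=0.2, size=config.cohort_n)
    cohort = pd.DataFrame(
        {
            "subject_id": [f"v{i:02d}" for i in range(config.cohort_n)],
            "group": groups,
            "LLS": lls.astype(int),
            "cytokine_pre": pre,
            "cytokine_post": pre + change,
        }
    ).set_index("subject_id")
    return cohort, SimTruth(cohort_slope=slope)


# ---------------------------------------------------------------------------
# FASTQ with planted contamination
# ---------------------------------------------------------------------------


def simulate_fastq(
    config: SimConfig,
    n_reads: int,
    read_len: int,
    path: str | Path,
    truth_path: str | Path | None = None,
    adaptor: str = DEFAULT_ADAPTOR,
) -> pd.DataFrame:
    """Write a FASTQ file with exact planted counts of contaminated reads.

    Three contamination classes, in the proportions of
    ``config.contamination_rates`` (exact counts ``floor(rate * n_reads)``):

    * ``adaptor``     — the full adapter sequence embedded in the read
    * ``high_n``      — strictly more than 10% unknown (N) bases
    * ``low_quality`` — strictly more than 50% of bases at Phred <= 5

    Clean reads contain no N and no base below Q30, and non-adaptor reads
    are rejection-sampled so they cannot contain the adapter by chance.
    Qualities are Phred+33. A per-read truth table is returned and, when
    ``truth_path`` is given, written as TSV.
    """
    if read_len < len(adaptor):
        raise ValueError("read_len must be >= adaptor length")
    rng = np.random.default_rng(config.seed)
    n_adapt, n_highn, n_lowq = (math.floor(c * n_reads) for c in config.contamination_rates)
    labels = (
        ["adaptor"] * n_adapt
        + ["high_n"] * n_highn
        + ["low_quality"] * n_lowq
        + ["clean"] * (n_reads - n_adapt - n_highn - n_lowq)
    )
    rng.shuffle(labels)

    bases = np.array(list("ACGT"))
    # forbid every 10-mer of the adapter so non-adapter reads can never
    # trigger a prefix-overlap match downstream
    forbidden = {adaptor[i : i + 10] for i in range(len(adaptor) - 9)}

    def random_seq() -> str:
        while True:
            seq = "".join(rng.choice(bases, size=read_len))
            if not any(f in seq for f in forbidden):
                return seq

    records = []
    rows = []
    for i, label in enumerate(labels):
        read_id = f"read{i:06d}"
        seq = list(random_seq())
        quals = rng.integers(30, 41, size=read_len).tolist()
        if label == "adaptor":
            pos = int(rng.integers(0, read_len - len(adaptor) + 1))
            seq[pos : pos + len(adaptor)] = list(adaptor)
        elif label == "high_n":
            k = math.floor(0.10 * read_len) + 1  # strictly more than 10%
            for j in rng.choice(read_len, size=k, replace=False):
                seq[j] = "N"
        elif label == "low_quality":
            k = math.floor(0.50 * read_len) + 1  # strictly more than 50%
            for j in rng.choice(read_len, size=k, replace=False):
                quals[j] = 2
        rec = SeqRecord(Seq("".join(seq)), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = quals
        records.append(rec)
        rows.append((read_id, label))

    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")
    truth = pd.DataFrame(rows, columns=["read_id", "label"]).set_index("read_id")
    if truth_path is not None:
        write_tsv(truth, truth_path)
    return truth
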
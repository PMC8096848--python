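"""Synthetic multi-cohort generator for the sex-disparity pipeline.

Emulates the statistical structure the analysis assumes, on the log2
intensity scale typical of expression arrays:

* male-biased cohorts (default male fraction 0.66, matching the ~2:1
  male:female incidence ratio of gastric cancer);
* Y-linked genes expressed only in males (females pinned at a floor value),
  an XIST-like stratum expressed only in females, and XCI-escape genes
  shifted upward in females by a configurable log2 effect;
* a hormone module: an AR-like receptor gene correlated with a
  miR-125b-like miRNA, itself correlated with two host-lncRNA genes
  (MIR100HG / MIR99AHG analogues);
* proportional-hazards survival times with planted log hazard ratios and
  independent exponential censoring calibrated to a target censor rate;
* 3'-UTR sequences with planted miRNA seed sites, and decoys guaranteed
  site-free by rejection sampling.

One master seed spawns per-cohort child seeds through
``numpy.random.SeedSequence.spawn``, so cohorts share planted gene
identities but draw independent noise, and every output is reproducible
byte-for-byte.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionMatrix, GeneAnnotation, SampleTable
from .targets import (
    ARE_HALF_SITE,
    MirnaSeed,
    SITE_TYPES,
    compile_seed_patterns,
    scan_promoter_halfsites,
    scan_utr,
)


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort family.

    Expression is Gaussian on the log2 scale: baseline per gene drawn
    uniformly in [4, 12] log2 units, i.i.d. noise with ``noise_sd``.
    ``sex_effect_size`` is the female-vs-male log2 shift of XCI-escape
    genes. ``floor_value`` is the value planted for absent expression
    (Y-linked genes in females, XIST-like genes in males); the default 1.0
    sits at the array noise floor rather than exact zero so downstream
    scaling stays well-defined.

    ``scale="counts"`` instead emits negative-binomial read counts with
    mean 2^(log2 value) and dispersion ``nb_dispersion``, the input
    expected by ``cpm_log_normalize``; planted floor values then hold in
    expectation rather than exactly.
    """

    n_samples: int = 300
    n_genes: int = 2000
    male_fraction: float = 0.66
    n_y_linked: int = 10
    n_xist_like: int = 5
    n_xci_escape: int = 15
    sex_effect_size: float = 1.0
    rho_ar_mir: float = 0.5
    rho_host_mir: float = 0.6
    noise_sd: float = 1.0
    floor_value: float = 1.0
    scale: str = "log2"          # "counts" draws NB reads around 2^log2-mean
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("n_samples and n_genes must be positive")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        if min(self.n_y_linked, self.n_xist_like, self.n_xci_escape) < 0:
            raise ValueError("planted gene counts must be nonnegative")
        if self.n_planted > self.n_genes:
            raise ValueError(
                f"planted gene counts ({self.n_planted}) exceed n_genes ({self.n_genes})"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.floor_value < 0:
            raise ValueError("floor_value must be nonnegative")
        for name in ("rho_ar_mir", "rho_host_mir"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"{name} must be in [-1, 1]")
        if self.scale not in ("log2", "counts"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")

    @property
    def n_planted(self) -> int:
        return self.n_y_linked + self.n_xist_like + self.n_xci_escape

    @property
    def planted_sex_genes(self) -> list[str]:
        """Gene ids of the Y-linked, XIST-like and XCI-escape strata."""
        ids = []
        ids += [f"Y{i:03d}" for i in range(self.n_y_linked)]
        ids += [f"XIST{i:02d}" for i in range(self.n_xist_like)]
        ids += [f"XESC{i:03d}" for i in range(self.n_xci_escape)]
        return ids


def _gene_ids(config: CohortConfig) -> tuple[list[str], GeneAnnotation]:
    planted = config.planted_sex_genes
    n_auto = config.n_genes - len(planted)
    autos = [f"G{i:05d}" for i in range(n_auto)]
    ids = planted + autos
    chrom = (
        ["Y"] * config.n_y_linked
        + ["X"] * (config.n_xist_like + config.n_xci_escape)
        + [str((i % 22) + 1) for i in range(n_auto)]
    )
    klass = (
        ["mRNA"] * config.n_y_linked
        + ["lncRNA"] * config.n_xist_like
        + ["mRNA"] * (config.n_xci_escape + n_auto)
    )
    ann = GeneAnnotation(
        gene_id=ids,
        chromosome=chrom,
        gene_class=klass,
        tss=[1000 * (i + 1) for i in range(config.n_genes)],
        strand=["+" if i % 2 == 0 else "-" for i in range(config.n_genes)],
    )
    return ids, ann


def _one_cohort(config: CohortConfig, cohort_id: str, rng: np.random.Generator,
                gene_ids: list[str]) -> tuple[ExpressionMatrix, SampleTable]:
    n, g = config.n_samples, config.n_genes
    n_male = int(round(config.male_fraction * n))
    sexes = ["male"] * n_male + ["female"] * (n - n_male)
    sample_ids = [f"{cohort_id}_S{i:04d}" for i in range(n)]
    is_male = np.array([s == "male" for s in sexes])

    baseline = rng.uniform(4.0, 12.0, size=g)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(g, n))

    ny, nx = config.n_y_linked, config.n_xist_like
    # Y-linked: silent in every female
    values[:ny, ~is_male] = config.floor_value
    # XIST-like: silent in every male
    values[ny:ny + nx, is_male] = config.floor_value
    # XCI-escape: elevated in females
    values[ny + nx:config.n_planted, ~is_male] += config.sex_effect_size

    if config.scale == "counts":
        # NB read counts around the 2^log2 mean: the floor contract holds
        # in expectation only, since counts add sampling noise
        mu = 2.0 ** values
        r = 1.0 / config.nb_dispersion
        values = rng.negative_binomial(r, r / (r + mu)).astype(float)

    mat = ExpressionMatrix(values=values, gene_ids=gene_ids,
                           sample_ids=sample_ids, scale=config.scale)
    table = SampleTable(sample_id=sample_ids, sex=sexes,
                        cohort_id=[cohort_id] * n)
    return mat, table


def generate_cohorts(
    config: CohortConfig, n_cohorts: int = 5, seed: int | None = None
) -> list[tuple[ExpressionMatrix, SampleTable, GeneAnnotation]]:
    """Generate ``n_cohorts`` cohorts sharing planted gene identities.

    Each cohort draws independent noise from a child seed of the master
    seed (``SeedSequence(seed).spawn``), so results are deterministic for a
    fixed seed and the planted Y/XIST/XCI-escape genes are the same genes
    in every cohort.
    """
    if n_cohorts < 1:
        raise ValueError("n_cohorts must be >= 1")
    master = config.seed if seed is None else seed
    gene_ids, ann = _gene_ids(config)
    children = np.random.SeedSequence(master).spawn(n_cohorts)
    out = []
    for k in range(n_cohorts):
        rng = np.random.default_rng(children[k])
        mat, table = _one_cohort(config, f"C{k}", rng, gene_ids)
        out.append((mat, table, ann))
    return out


def plant_hormone_module(
    matrix: ExpressionMatrix,
    ar_gene: str,
    mir_gene: str,
    host_genes: tuple[str, ...] = (),
    rho: float = 0.5,
    rho_host: float = 0.6,
    seed: int = 0,
    mean: float = 8.0,
    sd: float = 1.0,
) -> ExpressionMatrix:
    """Overwrite named rows with a correlated hormone module.

    The miRNA row is a latent standard normal z; the AR-like row is drawn
    so that corr(AR, miR) = ``rho``; each host-lncRNA row so that
    corr(host, miR) = ``rho_host``. Rows are then placed on the log2 scale
    as ``mean + sd * value``. Returns a new matrix; the input is untouched.
    """
    if abs(rho) > 1 or abs(rho_host) > 1:
        raise ValueError("correlations must be in [-1, 1]")
    vals = matrix.values.copy()
    n = matrix.n_samples
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)

    def correlated(r: float) -> np.ndarray:
        return r * z + np.sqrt(max(0.0, 1.0 - r * r)) * rng.normal(size=n)

    rows = {mir_gene: z, ar_gene: correlated(rho)}
    for h in host_genes:
        rows[h] = correlated(rho_host)
    for gid, row in rows.items():
        vals[matrix.gene_index(gid)] = mean + sd * row
    return ExpressionMatrix(values=vals, gene_ids=matrix.gene_ids,
                            sample_ids=matrix.sample_ids, scale=matrix.scale)


def _censor_rate_for(lams: np.ndarray, target: float) -> float:
    """Bisection for the exponential censoring rate c.

    With event time T_i ~ Exp(lam_i) and censoring C ~ Exp(c) independent,
    P(censored_i) = c / (c + lam_i); we solve mean_i = target analytically
    (no Monte Carlo), to well within the +-2% calibration band.
    """
    if target <= 0:
        return 0.0
    if target >= 1:
        raise ValueError("censor_rate must be < 1")
    lo, hi = 0.0, float(np.max(lams))
    while np.mean(hi / (hi + lams)) < target:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(mid / (mid + lams)) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_survival(
    table: SampleTable,
    covariate_values: np.ndarray,
    betas: np.ndarray,
    baseline_rate: float = 0.02,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> SampleTable:
    """Attach proportional-hazards survival to a sample table.

    Event times are exponential with hazard ``baseline_rate * exp(beta.x)``
    (months^-1); censoring is an independent exponential clock whose rate is
    calibrated by bisection so the expected censored fraction hits
    ``censor_rate``.
    """
    X = np.atleast_2d(np.asarray(covariate_values, dtype=float))
    if X.shape[0] == len(table) and X.shape[1] != len(table):
        X = X.T  # accept samples-by-covariates too
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    if X.shape[1] != len(table):
        raise ValueError("covariate columns must align with samples")
    if X.shape[0] != len(betas):
        raise ValueError("one beta per covariate row required")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    rng = np.random.default_rng(seed)
    lams = baseline_rate * np.exp(betas @ X)
    t_event = rng.exponential(1.0 / lams)
    c = _censor_rate_for(lams, censor_rate)
    if c > 0:
        t_cens = rng.exponential(1.0 / c, size=len(table))
    else:
        t_cens = np.full(len(table), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-9)
    return SampleTable(
        sample_id=list(table.sample_id),
        sex=list(table.sex),
        cohort_id=list(table.cohort_id),
        time=time,
        event=event,
    )


@dataclass
class UtrSequenceSet:
    """Synthetic 3'-UTRs with a ground-truth site plan."""

    sequences: dict[str, str]
    plan: dict[str, dict[str, int]]       # gene -> site_type -> planted count
    mirna: MirnaSeed


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _site_counts(seq: str, seed: MirnaSeed) -> dict[str, int]:
    counts = {t: 0 for t in SITE_TYPES}
    for s in scan_utr(seq, seed):
        counts[s.site_type] += 1
    return counts


def generate_utrs(
    target_genes: list[str],
    decoy_genes: list[str],
    mirna_sequence: str,
    sites_per_target: dict[str, dict[str, int]] | None = None,
    utr_length: int = 500,
    seed: int = 0,
) -> UtrSequenceSet:
    """Generate UTRs with exactly the planted seed sites, plus clean decoys.

    Each target gene gets the site counts requested in ``sites_per_target``
    (default: one 8mer). Sequences are rejection-sampled until a scan
    reports exactly the plan — no spurious sites, none missing. Decoys are
    rejection-sampled to contain zero sites of any type.
    """
    mir = compile_seed_patterns(mirna_sequence)
    if utr_length < mir.longest_pattern:
        raise ValueError("utr_length shorter than the longest site pattern")
    if sites_per_target is None:
        sites_per_target = {g: {"8mer": 1} for g in target_genes}
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    plan: dict[str, dict[str, int]] = {}

    for g in target_genes:
        want = {t: int(sites_per_target.get(g, {}).get(t, 0)) for t in SITE_TYPES}
        total_len = sum(len(mir.patterns[t]) * c for t, c in want.items())
        if total_len > utr_length:
            raise ValueError(f"site plan for {g} does not fit in utr_length")
        for _ in range(10000):
            seq = list(_random_seq(rng, utr_length))
            # place requested sites at non-overlapping random offsets
            taken: list[tuple[int, int]] = []
            ok = True
            for t in SITE_TYPES:
                for _c in range(want[t]):
                    pat = mir.patterns[t]
                    for _try in range(200):
                        pos = int(rng.integers(0, utr_length - len(pat) + 1))
                        span = (pos, pos + len(pat))
                        if all(span[1] <= a or span[0] >= b for a, b in taken):
                            taken.append(span)
                            seq[span[0]:span[1]] = pat
                            break
                    else:
                        ok = False
                if not ok:
                    break
            if not ok:
                continue
            cand = "".join(seq)
            if _site_counts(cand, mir) == want:
                sequences[g] = cand
                plan[g] = want
                break
        else:
            raise RuntimeError(f"could not realize site plan for {g}")

    empty = {t: 0 for t in SITE_TYPES}
    for g in decoy_genes:
        for _ in range(10000):
            cand = _random_seq(rng, utr_length)
            if _site_counts(cand, mir) == empty:
                sequences[g] = cand
                plan[g] = dict(empty)
                break
        else:
            raise RuntimeError(f"could not generate site-free decoy for {g}")

    return UtrSequenceSet(sequences=sequences, plan=plan, mirna=mir)


def generate_promoters(
    gene_sites: dict[str, int],
    promoter_length: int = 2000,
    motif: str = ARE_HALF_SITE,
    seed: int = 0,
) -> dict[str, str]:
    """Generate promoter sequences with exact planted ARE half-site counts.

    ``gene_sites`` maps gene id to the number of half-sites wanted in its
    2-kb upstream region (strand of each planted site chosen at random).
    Rejection sampling guarantees a scan reports exactly the requested
    count — accidental extra occurrences of the motif or its reverse
    complement are rejected.
    """
    from Bio.Seq import Seq

    rc = str(Seq(motif).reverse_complement())
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for gene, want in gene_sites.items():
        if want * len(motif) > promoter_length:
            raise ValueError(f"{want} sites do not fit in {promoter_length} nt")
        for _ in range(10000):
            seq = list(_random_seq(rng, promoter_length))
            taken: list[tuple[int, int]] = []
            ok = True
            for _c in range(want):
                pat = motif if rng.random() < 0.5 else rc
                for _try in range(200):
                    pos = int(rng.integers(0, promoter_length - len(pat) + 1))
                    span = (pos, pos + len(pat))
                    if all(span[1] <= a or span[0] >= b for a, b in taken):
                        taken.append(span)
                        seq[span[0]:span[1]] = pat
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            cand = "".join(seq)
            if len(scan_promoter_halfsites(cand, motif, span=promoter_length)) == want:
                out[gene] = cand
                break
        else:
            raise RuntimeError(f"could not realize promoter plan for {gene}")
    return out
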
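"""End-to-end orchestration of the sex-disparity analysis.

Stage order mirrors the discovery chain: simulate (or load) cohorts ->
preprocess -> train the sex classifier per cohort -> integrated-gradient
attribution and top-k consensus -> preranked GSEA -> AR-associated
differential expression -> LASSO-Cox marker selection -> survival
stratification -> miRNA target screen and promoter ARE scan. Every stage
emits plain-text artifacts (TSV/JSON/FASTA) into the output directory and
the run manifest records the configuration, master seed and per-stage seeds
so a run is reproducible byte-for-byte.

The master seed spawns one child seed per stage through
``numpy.random.SeedSequence`` in a fixed order; stage code never touches
global random state.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as gio
from .attribution import (
    attribute_cohort,
    attribution_scores,
    consensus_sets,
    consensus_table,
    top_k,
)
from .datatypes import ExpressionMatrix
from .de import deg_filter, group_de, pearson_r
from .enrichment import GeneSetCollection, gsea_preranked
from .preprocess import split_train_validation, zscale_genes
from .sexnet import DenseSexClassifier
from .simulate import (
    CohortConfig,
    generate_cohorts,
    generate_promoters,
    generate_survival,
    generate_utrs,
    plant_hormone_module,
)
from .survival import combo_stratify, cox_fit, dichotomize, lasso_cox, logrank
from .targets import MIR125B_5P, compile_seed_patterns, integrate_evidence, inverse_targets, scan_promoter_halfsites, scan_utr

STAGES = ("simulate", "preprocess", "train", "attribute", "consensus", "gsea",
          "de", "survival", "targets")

# designated members of the planted hormone module (autosomal block)
AR_GENE = "G00000"
MIR_GENE = "G00001"
HOST_GENES = ("G00002", "G00003")


@dataclass
class PipelineConfig:
    """Full-run configuration; defaults mirror the published settings
    (11 layers, 200 epochs, 10% validation, top-100, P<0.05 and
    |log2FC|>0.5, tenfold CV, median/upper-quartile cutoffs)."""

    outdir: str = "gcsex_run"
    seed: int = 0
    n_cohorts: int = 5
    cohort: dict = field(default_factory=dict)
    expression_path: str | None = None      # load instead of simulate
    samples_path: str | None = None
    # classifier
    total_layers: int = 11
    hidden_width: int = 16
    activation: str = "relu"
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32
    validation_fraction: float = 0.10
    # attribution
    ig_steps: int = 64
    attribution_group: str = "male"
    top_k: int = 100
    # enrichment
    n_perm: int = 500
    gsea_weight: float = 1.0
    # DE screen
    de_p: float = 0.05
    de_lfc: float = 0.5
    # survival
    ar_rule: str = "median"
    mir_rule: str = "upper_quartile"
    marker_hr: float = 1.45
    baseline_rate: float = 0.02
    censor_rate: float = 0.2
    n_folds: int = 10
    n_lasso_features: int = 40
    # target screen
    mirna_sequence: str = MIR125B_5P
    r_threshold: float = 0.3
    n_targets: int = 12
    n_decoys: int = 12
    utr_length: int = 300
    promoter_sites: dict = field(default_factory=lambda: {"MIR125B1_prom": 1,
                                                          "MIR125B2_prom": 3})

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for p in (cfg.expression_path, cfg.samples_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config references missing file: {p}")
        return cfg

    def to_dict(self, include_outdir: bool = True) -> dict:
        d = asdict(self)
        if not include_outdir:
            d.pop("outdir")
        return d

    def config_hash(self) -> str:
        """Hash of the analysis settings (the output location is excluded,
        so the same analysis written elsewhere hashes identically)."""
        blob = json.dumps(self.to_dict(include_outdir=False), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the pipeline (optionally only a prefix of the stage list).

    Returns a summary dict; artifacts land under ``config.outdir``. A
    failing stage raises with the stage name; later artifacts are not
    written.
    """
    wanted = STAGES if stages is None else tuple(stages)
    for s in wanted:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    last = max(STAGES.index(s) for s in wanted)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(STAGES, np.random.SeedSequence(config.seed).spawn(len(STAGES)))}
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    ctx: dict = {}

    try:
        for idx, stage in enumerate(STAGES[: last + 1]):
            _STAGE_FUNCS[stage](config, ctx, out, stage_seeds[stage], summary)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(include_outdir=False),
        "config_hash": config.config_hash(),
        "stage_seeds": stage_seeds,
        "stages_run": list(STAGES[: last + 1]),
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    gio.write_json(manifest, out / "manifest.json")
    gio.write_json(summary, out / "summary.json")
    return summary


def _stage_simulate(config, ctx, out, seed, summary):
    cohort_cfg = CohortConfig(**{**config.cohort, "seed": seed})
    cohorts = generate_cohorts(cohort_cfg, n_cohorts=config.n_cohorts, seed=seed)
    planted = []
    for k, (mat, table, ann) in enumerate(cohorts):
        mat = plant_hormone_module(
            mat, AR_GENE, MIR_GENE, HOST_GENES,
            rho=cohort_cfg.rho_ar_mir, rho_host=cohort_cfg.rho_host_mir,
            seed=seed + 17 * (k + 1),
        )
        cohorts[k] = (mat, table, ann)
        gio.write_expression(mat, out / f"expression_C{k}.tsv")
        gio.write_samples(table, out / f"samples_C{k}.tsv")
    gio.write_annotation(cohorts[0][2], out / "annotation.tsv")
    ctx["cohorts"] = cohorts
    ctx["cohort_cfg"] = cohort_cfg
    summary["n_cohorts"] = len(cohorts)
    summary["planted_sex_genes"] = cohort_cfg.planted_sex_genes


def _stage_preprocess(config, ctx, out, seed, summary):
    prepped = []
    for k, (mat, table, ann) in enumerate(ctx["cohorts"]):
        scaled = zscale_genes(mat)
        plan = split_train_validation(
            scaled.sample_ids, fraction=config.validation_fraction,
            seed=seed + k, stratify_by_sex=list(table.sex),
        )
        gio.write_json({"train": plan.train_ids, "validation": plan.validation_ids,
                        "fraction": plan.fraction, "seed": plan.seed},
                       out / f"split_C{k}.json")
        prepped.append((scaled, plan, table))
    ctx["prepped"] = prepped


def _stage_train(config, ctx, out, seed, summary):
    models, traces = [], []
    for k, (scaled, plan, table) in enumerate(ctx["prepped"]):
        sex_of = dict(zip(scaled.sample_ids, table.sex))
        y = {sid: 1 if sex_of[sid] == "male" else 0 for sid in scaled.sample_ids}
        Xtr = scaled.subset_samples(plan.train_ids).samples_by_genes()
        ytr = np.array([y[s] for s in plan.train_ids])
        Xva = scaled.subset_samples(plan.validation_ids).samples_by_genes()
        yva = np.array([y[s] for s in plan.validation_ids])
        clf = DenseSexClassifier(
            total_layers=config.total_layers, hidden_width=config.hidden_width,
            activation=config.activation, epochs=config.epochs,
            learning_rate=config.learning_rate, batch_size=config.batch_size,
            random_state=seed + 101 * k,
        ).fit(Xtr, ytr, Xva, yva)
        models.append(clf)
        traces.append({"best_epoch": clf.best_epoch_,
                       "best_val": clf.validation_trace_[clf.best_epoch_],
                       "trace": clf.validation_trace_})
    gio.write_json(traces, out / "training_traces.json")
    ctx["models"] = models
    summary["validation_accuracy"] = [t["best_val"] for t in traces]


def _stage_attribute(config, ctx, out, seed, summary):
    rankings, topsets = [], []
    for k, ((scaled, plan, table), model) in enumerate(zip(ctx["prepped"], ctx["models"])):
        attr = attribute_cohort(
            model, scaled.samples_by_genes(), scaled.sample_ids,
            scaled.gene_ids, steps=config.ig_steps,
        )
        ranking = attribution_scores(attr, list(table.sex), group=config.attribution_group)
        gio.write_ranking(ranking, out / f"ranking_C{k}.rnk")
        rankings.append(ranking)
        topsets.append(top_k(ranking, config.top_k))
    ctx["rankings"] = rankings
    ctx["topsets"] = topsets


def _stage_consensus(config, ctx, out, seed, summary):
    res = consensus_sets(ctx["topsets"])
    names = [f"C{k}" for k in range(len(ctx["topsets"]))]
    consensus_table(res, names).to_csv(out / "consensus.tsv", sep="\t", index=False)
    gio.write_json({"degree_counts": {str(k): v for k, v in res.degree_counts.items()},
                    "full_intersection": sorted(res.full_intersection)},
                   out / "consensus_counts.json")
    ctx["consensus"] = res
    planted = set(ctx["cohort_cfg"].planted_sex_genes)
    in4 = res.at_least(min(4, len(names)))
    summary["consensus_full_intersection"] = len(res.full_intersection)
    summary["planted_recovered_in_4of5"] = len(planted & in4)
    summary["planted_recovery_fraction"] = (
        len(planted & in4) / len(planted) if planted else float("nan")
    )


def _build_collections(cfg: CohortConfig, gene_ids: list[str], seed: int) -> GeneSetCollection:
    """Synthetic gene-set collection: planted strata plus random sets."""
    ny, nx, ne = cfg.n_y_linked, cfg.n_xist_like, cfg.n_xci_escape
    planted = cfg.planted_sex_genes
    sets = {
        "Y_LINKED": planted[:ny],
        "XIST_LIKE": planted[ny:ny + nx],
        "XCI_ESCAPE": planted[ny + nx:],
        "SEX_CHROMOSOME_ALL": planted,
    }
    rng = np.random.default_rng(seed)
    for i in range(6):
        sets[f"RANDOM_{i}"] = list(rng.choice(gene_ids, size=30, replace=False))
    return GeneSetCollection(sets={k: v for k, v in sets.items() if v})


def _stage_gsea(config, ctx, out, seed, summary):
    ranking = ctx["rankings"][0]
    coll = _build_collections(ctx["cohort_cfg"], ranking.gene_ids, seed)
    res = gsea_preranked(ranking, coll, n_perm=config.n_perm,
                         weight=config.gsea_weight, seed=seed)
    res.table.to_csv(out / "gsea.tsv", sep="\t", index=False)
    ctx["gsea"] = res
    sex_row = res.table.set_index("set").loc["SEX_CHROMOSOME_ALL"]
    summary["gsea_sex_set_es"] = float(sex_row["es"])
    summary["gsea_sex_set_p"] = float(sex_row["p"])


def _stage_de(config, ctx, out, seed, summary):
    mat, table, ann = ctx["cohorts"][0]
    de_sex = group_de(mat, list(table.sex))
    de_sex.to_csv(out / "de_sex.tsv", sep="\t")
    degs_sex = deg_filter(de_sex, config.de_p, config.de_lfc)
    # AR-associated screen: dichotomize AR-like expression at the median
    ar = mat.row(AR_GENE)
    ar_lab, _ = dichotomize(ar, config.ar_rule)
    de_ar = group_de(mat, list(ar_lab))
    de_ar.to_csv(out / "de_ar.tsv", sep="\t")
    r, p = pearson_r(ar, mat.row(MIR_GENE))
    ctx["de_ar"] = de_ar
    ctx["ar_labels"] = ar_lab
    summary["n_degs_sex"] = len(degs_sex)
    summary["n_degs_ar"] = len(deg_filter(de_ar, config.de_p, config.de_lfc))
    summary["pearson_ar_mir"] = r
    summary["pearson_ar_mir_p"] = p


def _stage_survival(config, ctx, out, seed, summary):
    mat, table, ann = ctx["cohorts"][0]
    ar = mat.row(AR_GENE)
    mir = mat.row(MIR_GENE)
    ar_hi = (dichotomize(ar, config.ar_rule)[0] == "high").astype(float)
    mir_hi = (dichotomize(mir, config.mir_rule)[0] == "high").astype(float)
    beta = np.log(config.marker_hr)
    surv = generate_survival(
        table, np.vstack([ar_hi, mir_hi]), np.array([beta, beta]),
        baseline_rate=config.baseline_rate, censor_rate=config.censor_rate,
        seed=seed,
    )
    gio.write_samples(surv, out / "survival_samples.tsv")
    four, merged = combo_stratify(ar, mir, config.ar_rule, config.mir_rule)
    chi2, p_merged = logrank(surv.time, surv.event, merged)
    import pandas as pd

    df = pd.DataFrame({"time": surv.time, "event": surv.event,
                       "ar_high": ar_hi, "mir_high": mir_hi})
    fit = cox_fit(df, ["ar_high", "mir_high"])
    fit.summary().to_csv(out / "cox_fit.tsv", sep="\t")
    # LASSO screen over the top AR-associated genes (planted markers first)
    de_ar = ctx["de_ar"].drop(index=[g for g in (AR_GENE,) if g in ctx["de_ar"].index])
    feats = list(de_ar.sort_values("p").head(config.n_lasso_features).index)
    for g in (MIR_GENE,):
        if g not in feats:
            feats = [g] + feats[:-1]
    X = np.column_stack([mat.row(g) for g in feats])
    res = lasso_cox(X, surv.time, surv.event, feature_names=feats,
                    n_folds=config.n_folds, seed=seed + 1)
    pd.DataFrame(res.coef_path, columns=feats,
                 index=pd.Index(res.lambda_path, name="lambda")
                 ).to_csv(out / "lasso_path.tsv", sep="\t", float_format="%.10g")
    gio.write_json({"best_lambda": res.best_lambda, "selected": res.selected},
                   out / "lasso_selected.json")
    summary["logrank_merged_chi2"] = chi2
    summary["logrank_merged_p"] = p_merged
    summary["cox_hr_ar"] = float(fit.hr[0])
    summary["cox_hr_mir"] = float(fit.hr[1])
    summary["lasso_selected"] = res.selected
    ctx["survival"] = surv


def _stage_targets(config, ctx, out, seed, summary):
    rng = np.random.default_rng(seed)
    mat, table, ann = ctx["cohorts"][0]
    mir_vec = mat.row(MIR_GENE)
    target_genes = [f"T{i:03d}" for i in range(config.n_targets)]
    decoy_genes = [f"D{i:03d}" for i in range(config.n_decoys)]
    utrs = generate_utrs(target_genes, decoy_genes, config.mirna_sequence,
                         utr_length=config.utr_length, seed=seed)
    gio.write_sequences(utrs.sequences, out / "utrs.fasta")
    seed_pat = compile_seed_patterns(config.mirna_sequence)
    predicted = {g for g, s in utrs.sequences.items()
                 if scan_utr(s, seed_pat, gene_id=g)}
    # patient evidence: targets anti-correlated with the miRNA, decoys not
    n = len(mir_vec)
    z = (mir_vec - mir_vec.mean()) / mir_vec.std()
    rows, ids = [], []
    for g in target_genes:
        rows.append(8.0 - 0.6 * z + rng.normal(0, 0.8, n))
        ids.append(g)
    for g in decoy_genes:
        rows.append(8.0 + rng.normal(0, 1.0, n))
        ids.append(g)
    tmat = ExpressionMatrix(values=np.array(rows), gene_ids=ids,
                            sample_ids=mat.sample_ids, scale="log2")
    patient_inverse = inverse_targets(mir_vec, tmat, config.r_threshold)
    # transfection evidence: mimic-vs-control with targets knocked down
    n_rep = 12
    tr_rows = []
    for g in ids:
        ctrl = 8.0 + rng.normal(0, 0.3, n_rep)
        mimic = ctrl - (1.0 if g in target_genes else 0.0) + rng.normal(0, 0.3, n_rep)
        tr_rows.append(np.concatenate([ctrl, mimic]))
    trmat = ExpressionMatrix(
        values=np.array(tr_rows), gene_ids=ids,
        sample_ids=[f"ctrl{i}" for i in range(n_rep)] + [f"mimic{i}" for i in range(n_rep)],
        scale="log2",
    )
    de_tr = group_de(trmat, ["a_ctrl"] * n_rep + ["b_mimic"] * n_rep)
    transfection_down = set(de_tr.index[(de_tr["p"] < config.de_p)
                                        & (de_tr["log_fc"] < -config.de_lfc)])
    ev = integrate_evidence(predicted, transfection_down, patient_inverse)
    gio.write_json(
        {"predicted": ev.predicted, "transfection_down": ev.transfection_down,
         "patient_inverse": ev.patient_inverse, "final": ev.final,
         "region_counts": {"".join("PTI"[i] for i in range(3) if k[i]): v
                           for k, v in ev.region_counts.items()}},
        out / "target_evidence.json")
    # promoter ARE half-site scan
    proms = generate_promoters(config.promoter_sites, seed=seed + 5)
    gio.write_sequences(proms, out / "promoters.fasta")
    hits = {g: [f"{h.label()}({h.strand})" for h in scan_promoter_halfsites(s)]
            for g, s in proms.items()}
    gio.write_json(hits, out / "promoter_halfsites.json")
    summary["n_predicted_targets"] = len(ev.predicted)
    summary["n_final_targets"] = len(ev.final)
    summary["n_are_halfsites"] = sum(len(v) for v in hits.values())


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "train": _stage_train,
    "attribute": _stage_attribute,
    "consensus": _stage_consensus,
    "gsea": _stage_gsea,
    "de": _stage_de,
    "survival": _stage_survival,
    "targets": _stage_targets,
}


def demo_config(outdir: str, seed: int = 0) -> PipelineConfig:
    """A small configuration exercising every stage in a couple of minutes."""
    return PipelineConfig(
        outdir=outdir,
        seed=seed,
        n_cohorts=3,
        cohort={"n_samples": 120, "n_genes": 400, "n_y_linked": 6,
                "n_xist_like": 3, "n_xci_escape": 9},
        hidden_width=8,
        epochs=30,
        ig_steps=32,
        top_k=40,
        n_perm=200,
        n_lasso_features=20,
        n_folds=5,
        n_targets=8,
        n_decoys=8,
    )
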
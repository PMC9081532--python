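"""End-to-end synthetic study: simulate, refit, select, train, trace, score.

One `RunConfig` drives every stage; the single global seed fans out to
per-stage seeds by fixed offsets so each stage is reproducible standalone.
The report is a plain JSON-serializable dict, byte-identical across runs
with the same config.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, connection, cts, similarity, synthetic
from .signature_fit import refit_cohort

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets
_OFF_CATALOG = 101
_OFF_TRAIN = 202
_OFF_TEST = 303
_OFF_METS = 404
_OFF_CFDNA = 505
_OFF_PPI = 606
_OFF_MODSETS = 707
_OFF_NN = 808


@dataclass
class RunConfig:
    """All knobs of the synthetic study, with the standard thresholds.

    Thresholds: presence 0.06, prevalence fraction 0.20, fold change 1.5,
    absolute difference 0.1, mutation-marker frequency 0.05, de novo
    mapping 0.75, cascade stage-1 0.5.
    """

    seed: int = 17
    # cohort scale
    n_signatures: int = 12
    n_train: int = 100
    n_test: int = 100
    concentration: float = 50.0
    burden_mu: float = math.log(500.0)
    burden_sigma: float = 0.3
    # thresholds
    presence_cutoff: float = 0.06
    min_fraction: float = 0.20
    min_fc: float = 1.5
    min_diff: float = 0.1
    mutation_freq: float = 0.05
    mutation_diff: float = 0.1
    mapping_threshold: float = 0.75
    stage1_threshold: float = 0.5
    refit_cutoff: float = 0.06
    refit_tol: float = 1e-3
    # variant switches
    eq2_variant: str = "mean"
    connection_reading: str = "induced"
    cts_center: str = "mean"
    # metastasis / cfDNA stages
    liver_type: str = "LIHC"
    origin_types: list[str] = field(default_factory=lambda: ["BRCA", "ESCA", "PRAD"])
    n_met_pairs: int = 50
    drift: float = 0.05
    cfdna_types: list[str] = field(default_factory=lambda: ["BRCA", "PRAD"])
    dilution: float = 0.3
    dropout: float = 0.1
    # PPI stage
    ppi_module_size: int = 30
    ppi_background: int = 200
    p_in: float = 0.3
    p_out: float = 0.01
    n_connection_samples: int = 50
    n_mutations_per_sample: int = 20

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _per_type_models(
    exposures: pd.DataFrame,
    types: pd.Series,
    patterns: dict[str, cts.CTSMSPattern],
    seed: int,
) -> dict[str, classify.CancerModel]:
    models = {}
    for tname in sorted(types.unique()):
        candidates = patterns[tname].signatures
        if not candidates:
            logger.warning("%s: no CTS-MS found, using all signatures", tname)
            candidates = list(exposures.columns)
        labels = (types == tname).astype(int).to_numpy()
        models[tname] = classify.fit_one_vs_rest(
            exposures, labels, candidates, type_name=tname, seed=seed
        )
    return models


def run_full_synthetic_study(config: RunConfig) -> dict:
    """Execute every stage of the synthetic study; returns the report dict."""
    stage = "setup"
    try:
        catalog = synthetic.random_catalog(config.n_signatures, seed=config.seed + _OFF_CATALOG)
        profiles = synthetic.default_profiles(catalog)
        burden = (config.burden_mu, config.burden_sigma)

        stage = "simulate"
        tr_spectra, tr_genes, tr_truth = synthetic.simulate_cohort(
            profiles, config.n_train, catalog, seed=config.seed + _OFF_TRAIN,
            burden_dist=burden, concentration=config.concentration, id_prefix="TR",
        )
        te_spectra, te_genes, te_truth = synthetic.simulate_cohort(
            profiles, config.n_test, catalog, seed=config.seed + _OFF_TEST,
            burden_dist=burden, concentration=config.concentration, id_prefix="TE",
        )

        stage = "refit"
        tr_expo = refit_cohort(tr_spectra, catalog, cutoff=config.refit_cutoff, tol=config.refit_tol)
        te_expo = refit_cohort(te_spectra, catalog, cutoff=config.refit_cutoff, tol=config.refit_tol)
        tr_types, te_types = tr_truth.types(), te_truth.types()

        stage = "ctsms"
        cohort = cts.CohortExposures(tr_expo, tr_types)
        patterns = {
            t: cts.select_cts_ms(
                cohort, t,
                min_fraction=config.min_fraction, min_fc=config.min_fc,
                min_diff=config.min_diff, presence_cutoff=config.presence_cutoff,
                center=config.cts_center,
            )
            for t in sorted(tr_types.unique())
        }

        stage = "train"
        models = _per_type_models(tr_expo, tr_types, patterns, config.seed)

        stage = "evaluate"
        aucs = {}
        for tname, model in models.items():
            scores = classify.score_many(model, te_expo)
            aucs[tname] = classify.auc(scores, (te_types == tname).astype(int).to_numpy())

        stage = "trace"
        met_spectra = []
        for k, origin in enumerate(config.origin_types):
            src = [s for s in te_truth.ids_in("tissue") if te_truth.samples[s].type_name == origin]
            sp, te_truth = synthetic.simulate_metastases(
                te_truth, catalog, min(config.n_met_pairs, len(src)), config.drift,
                seed=config.seed + _OFF_METS + k, source_ids=src, burden_dist=burden,
            )
            met_spectra.extend(sp)
        met_expo = refit_cohort(met_spectra, catalog, cutoff=config.refit_cutoff, tol=config.refit_tol)
        met_ids = [s.sample_id for s in met_spectra]
        met_truth_types = pd.Series({i: te_truth.samples[i].type_name for i in met_ids})

        liver_model = models[config.liver_type]
        liver_te = te_expo[te_types == config.liver_type]
        stage1_expo = pd.concat([liver_te, met_expo])
        stage1_truth = ["liver_primary"] * len(liver_te) + ["non_liver_origin"] * len(met_expo)
        s1_scores = classify.score_many(liver_model, stage1_expo)
        s1_pred = ["liver_primary" if s >= config.stage1_threshold else "non_liver_origin" for s in s1_scores]
        s1_acc, s1_sens, s1_spec = classify.confusion_stats(s1_pred, stage1_truth, "liver_primary")

        sig_feats = sorted({s for t in config.origin_types for s in patterns[t].signatures})
        origin_models = {t: models[t] for t in config.origin_types}
        tr_origin_mask = tr_types.isin(config.origin_types)
        nn_features = classify.build_origin_features(
            tr_expo[tr_origin_mask], origin_models, sig_feats
        )
        origin_model = classify.fit_origin_model(
            nn_features, list(tr_types[tr_origin_mask]), seed=config.seed + _OFF_NN
        )
        traces = classify.trace_metastasis(
            met_expo, liver_model, origin_model, origin_models, sig_feats,
            threshold=config.stage1_threshold,
        )
        routed = [t for t in traces if t.stage1_call == "non_liver_origin"]
        s2_acc = (
            float(np.mean([t.origin == met_truth_types[t.sample_id] for t in routed]))
            if routed else float("nan")
        )

        stage = "similarity"
        pairs = [
            (te_expo.loc[te_truth.samples[mid].paired_primary_id].to_numpy(),
             met_expo.loc[mid].to_numpy())
            for mid in met_ids
        ]
        bg = [
            te_expo.loc[s].to_numpy()
            for s in te_expo.index[: 10 * len(config.origin_types)]
            if te_types[s] not in config.origin_types
        ]
        within, between, conc_p = similarity.primary_met_concordance(pairs, bg)
        type_names = sorted(tr_types.unique())
        agg = np.array([
            [
                similarity.aggregate_similarity(
                    similarity.pairwise_rho(
                        tr_expo[tr_types == a].to_numpy(), te_expo[te_types == b].to_numpy()
                    ),
                    variant=config.eq2_variant,
                )
                for b in type_names
            ]
            for a in type_names
        ])
        norm = similarity.normalize_similarity(agg)

        stage = "connection-score"
        genes = list(tr_genes.columns)
        module = genes[: config.ppi_module_size]
        net = synthetic.simulate_ppi(
            module, config.ppi_background, config.p_in, config.p_out,
            seed=config.seed + _OFF_PPI,
        )
        universe = sorted(net.genes)
        mod_sets = synthetic.simulate_mutation_sets(
            module, universe, config.n_connection_samples,
            config.n_mutations_per_sample, "module", seed=config.seed + _OFF_MODSETS,
        )
        rnd_sets = synthetic.simulate_mutation_sets(
            module, universe, config.n_connection_samples,
            config.n_mutations_per_sample, "random", seed=config.seed + _OFF_MODSETS + 1,
        )
        mod_scores = [
            connection.connection_score(s, net, reading=config.connection_reading).score
            for s in mod_sets
        ]
        rnd_scores = [
            connection.connection_score(s, net, reading=config.connection_reading).score
            for s in rnd_sets
        ]
        conn = connection.compare_score_groups({"module": mod_scores, "random": rnd_scores})
        conn_stat, conn_p = conn[("module", "random")]

        stage = "cfdna"
        a_type, b_type = config.cfdna_types
        cf_src = [
            s for s in te_truth.ids_in("tissue")
            if te_truth.samples[s].type_name in config.cfdna_types
        ]
        cf_spectra, cf_genes, te_truth = synthetic.simulate_cfdna(
            te_truth, te_spectra, te_genes, config.dilution, config.dropout,
            seed=config.seed + _OFF_CFDNA, source_ids=cf_src,
        )
        cf_expo = refit_cohort(cf_spectra, catalog, cutoff=config.refit_cutoff, tol=config.refit_tol)
        cf_types = pd.Series({s.sample_id: te_truth.samples[s.sample_id].type_name for s in cf_spectra})

        pair_mask = tr_types.isin(config.cfdna_types)
        pair_expo, pair_genes = tr_expo[pair_mask], tr_genes[pair_mask]
        pair_types = tr_types[pair_mask]
        markers = sorted({
            g
            for t in config.cfdna_types
            for g, _, _ in cts.select_specific_mutations(
                pair_genes, pair_types, t,
                min_freq=config.mutation_freq, min_diff=config.mutation_diff,
            )
        })
        ms_models, combined_models = {}, {}
        train_combined = pd.concat([pair_expo, pair_genes[markers]], axis=1)
        for t in config.cfdna_types:
            cand_ms = patterns[t].signatures or list(tr_expo.columns)
            labels = (pair_types == t).astype(int).to_numpy()
            ms_models[t] = classify.fit_one_vs_rest(
                pair_expo, labels, cand_ms, type_name=t, seed=config.seed
            )
            combined_models[t] = classify.fit_one_vs_rest(
                train_combined, labels, cand_ms + markers, type_name=t, seed=config.seed
            )
        cf_combined = pd.concat([cf_expo, cf_genes[markers]], axis=1)
        ms_pred = [
            classify.classify_cfdna(cf_expo.loc[sid], ms_models[a_type], ms_models[b_type])
            for sid in cf_expo.index
        ]
        comb_pred = [
            classify.classify_cfdna(cf_combined.loc[sid], combined_models[a_type], combined_models[b_type])
            for sid in cf_combined.index
        ]
        truth_labels = [cf_types[sid] for sid in cf_expo.index]
        ms_acc, _, _ = classify.confusion_stats(ms_pred, truth_labels, a_type)
        comb_acc, _, _ = classify.confusion_stats(comb_pred, truth_labels, a_type)

    except Exception:
        logger.exception("synthetic study failed at stage %r", stage)
        raise RuntimeError(f"synthetic study failed at stage {stage!r}") from None

    return {
        "config": asdict(config),
        "catalog": {"n_signatures": len(catalog), "names": catalog.names},
        "ctsms": {t: [e.signature for e in p.entries] for t, p in patterns.items()},
        "per_type_auc": {t: round(a, 6) for t, a in sorted(aucs.items())},
        "cascade": {
            "stage1_accuracy": round(s1_acc, 6),
            "stage1_sensitivity": round(s1_sens, 6),
            "stage1_specificity": round(s1_spec, 6),
            "stage2_accuracy": round(s2_acc, 6),
            "n_metastases": len(met_ids),
            "n_routed_to_stage2": len(routed),
        },
        "concordance": {
            "median_within": round(float(np.median(within)), 6),
            "median_between": round(float(np.median(between)), 6),
            "rank_sum_p": float(f"{conc_p:.6g}"),
        },
        "type_similarity": {
            "types": type_names,
            "aggregate": [[round(float(v), 6) for v in row] for row in agg],
            "normalized": [[round(float(v), 6) for v in row] for row in norm],
        },
        "connection": {
            "mean_module_score": round(float(np.mean(mod_scores)), 6),
            "mean_random_score": round(float(np.mean(rnd_scores)), 6),
            "rank_sum_p": float(f"{conn_p:.6g}"),
        },
        "cfdna": {
            "types": list(config.cfdna_types),
            "n_markers": len(markers),
            "ms_only_accuracy": round(ms_acc, 6),
            "combined_accuracy": round(comb_acc, 6),
        },
    }


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def report_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
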
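"""End-to-end orchestration of the analysis pipeline.

The eight stages, in order: (1) regression features per reaction flux,
(2) per-reaction PCA to two dimensions, (3) wild-type boundaries and weak
labels, (4) per-reaction classifier training and filtering, (5) binary
flux profiles, (6) profile PCA, (7) stoichiometric-network and driver-node
analysis, (8) phenotype-marker discovery.  Stages 7 and 8 degrade
gracefully: without a stoichiometric matrix the network stages are marked
skipped, and without phenotype flags the marker stage is.

Every run writes its artifacts under ``config.output_dir`` together with a
JSON manifest recording package/library versions, the seed, the config
hash, and per-stage record counts.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    ClassifierSpec,
    cross_validate,
    filter_classifiers,
    full_grid,
    grid_search,
    make_flux_profile,
    prepare_classifier_input,
    train_reaction_classifier,
    ClassifierRecord,
)
from .errors import DegenerateLabelError, InvalidArgumentError, WcfluxError
from .features import feature_matrix, fit_linear_features, reduce_features
from .io import (
    PipelineConfig,
    read_annotation_table,
    read_flux_table,
    read_genotypes,
    read_phenotype_flags,
    read_stoichiometric_matrix,
    write_profiles,
)
from .labelling import build_boundary, combine_labels, label_matrix
from .markers import (
    classify_phenotype,
    contingency_from_labels,
    marker_report,
    phi_coefficient,
    reduce_profiles,
    svm_separability,
)
from .network import (
    abnormality_frequencies,
    adjacency_from_stoichiometry,
    annotate_pathways,
    class_subnetwork,
    find_driver_nodes,
    noise_threshold,
)
from .types import ABNORMAL, WILD_TYPE, PhenotypeClass, SimulationRecord

logger = logging.getLogger("wcflux")


def _stage_seed(base: int, index: int) -> int:
    """Stable per-unit sub-seed below 2**31."""
    return (base * 1_000_003 + index * 7_919 + 17) % (2**31)


@dataclass
class PipelineResult:
    """In-memory view of a run: the manifest plus the heavyweight
    intermediate objects a caller may want to inspect."""

    manifest: dict
    weak_labels: dict[str, pd.DataFrame] = field(default_factory=dict)
    classifier_records: list[ClassifierRecord] = field(default_factory=list)
    profiles: list = field(default_factory=list)
    profile_scores: Optional[np.ndarray] = None
    drivers: Optional[tuple] = None
    marker_table: Optional[pd.DataFrame] = None


def _load_records(config: PipelineConfig) -> list[SimulationRecord]:
    genotypes: dict[str, str] = {}
    if config.genotypes_path and Path(config.genotypes_path).exists():
        genotypes.update(read_genotypes(config.genotypes_path))
    flags = {}
    if config.phenotype_flags_path and Path(config.phenotype_flags_path).exists():
        flags = read_phenotype_flags(config.phenotype_flags_path)
        genotypes.update({sim: geno for sim, (geno, _) in flags.items()})
    records = read_flux_table(config.flux_path, genotypes=genotypes or None)
    for rec in records:
        if rec.simulation_id in flags:
            rec.phenotype_flags = flags[rec.simulation_id][1]
    return records


def run_pipeline(
    config: PipelineConfig,
    records: Optional[list[SimulationRecord]] = None,
) -> PipelineResult:
    """Run stages 1-8 on the configured inputs.

    ``records`` may be passed directly (e.g. a freshly generated synthetic
    ensemble); otherwise the flux table at ``config.flux_path`` is read.
    Simulations whose genotype is not ``wild_type`` are treated as
    knockouts.  Raises on the first stage failure, naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "run: boundary_schemes=%s matching=%s label_backend=%s input=%s",
        config.boundary_schemes,
        config.matching_strategy,
        config.label_backend,
        config.classifier_input,
    )
    stages: dict[str, dict] = {}
    result = PipelineResult(manifest={})

    if records is None:
        records = _load_records(config)
    if not records:
        raise InvalidArgumentError("no simulations to analyse")
    wt = [r for r in records if r.genotype == WILD_TYPE]
    ko = [r for r in records if r.genotype != WILD_TYPE]
    if len(wt) < 3:
        raise InvalidArgumentError(
            "need >= 3 wild-type simulations to define normal behaviour"
        )
    reaction_ids = sorted(
        set.intersection(*(set(r.series) for r in records))
    )
    sim_order = [r.simulation_id for r in records]
    wt_mask = np.array([r.genotype == WILD_TYPE for r in records])

    # -- stage 1: regression features ------------------------------------
    features_by_reaction: dict[str, np.ndarray] = {}
    rows = []
    for rid in reaction_ids:
        vecs = [fit_linear_features(r.series[rid]) for r in records]
        features_by_reaction[rid] = feature_matrix(vecs)
        for r, v in zip(records, vecs):
            rows.append(
                {
                    "simulation_id": r.simulation_id,
                    "reaction_id": rid,
                    "intercept": v.intercept,
                    "gradient": v.gradient,
                    "r2": v.r_squared,
                    "mse": v.mse,
                }
            )
    pd.DataFrame(rows).to_csv(out / "features.tsv", sep="\t", index=False)
    stages["features"] = {"status": "ok", "records": len(rows)}

    # -- stages 2-3: per-reaction PCA, boundaries, weak labels ------------
    weak_by_reaction: dict[str, np.ndarray] = {}
    label_rows = []
    feature_evf = []
    boundary_audit: dict[str, list[dict]] = {}
    for rid in reaction_ids:
        reduced = reduce_features(features_by_reaction[rid], n_components=2)
        feature_evf.append(reduced.explained_variance_fraction)
        scores = reduced.scores
        boundaries = [
            build_boundary(scores[wt_mask], s)
            for s in config.boundary_schemes
        ]
        boundary_audit[rid] = [
            {
                "scheme": b.scheme,
                "lower": [float(v) for v in b.lower],
                "upper": [float(v) for v in b.upper],
            }
            for b in boundaries
        ]
        L = label_matrix(boundaries, scores)
        weak = combine_labels(L)
        weak_by_reaction[rid] = np.array([w.label for w in weak])
        for sim, w in zip(sim_order, weak):
            label_rows.append(
                {
                    "simulation_id": sim,
                    "reaction_id": rid,
                    "label": w.label,
                    "probability": w.probability,
                }
            )
    pd.DataFrame(label_rows).to_csv(
        out / "weak_labels.tsv", sep="\t", index=False
    )
    with open(out / "boundaries.yaml", "w") as fh:
        yaml.safe_dump(boundary_audit, fh, sort_keys=True)
    stages["weak_labels"] = {
        "status": "ok",
        "records": len(label_rows),
        "mean_feature_pca_variance": float(np.mean(feature_evf)),
    }

    # -- stage 4: classifiers ---------------------------------------------
    trained = {}
    records_out = []
    for i, rid in enumerate(reaction_ids):
        if config.classifier_input == "features":
            X = features_by_reaction[rid]
        else:
            X = np.vstack(
                [
                    prepare_classifier_input(
                        r.series[rid], config.input_length
                    )
                    for r in records
                ]
            )
        y = weak_by_reaction[rid]
        seed = _stage_seed(config.seed, i)
        try:
            if config.use_grid_search:
                clf, rec = grid_search(X, y, full_grid(seed), rid)
            else:
                spec = ClassifierSpec(
                    width=config.classifier_width,
                    epochs=config.classifier_epochs,
                    batch_size=config.classifier_batch,
                    seed=seed,
                )
                clf = train_reaction_classifier(X, y, spec, rid)
                rec = ClassifierRecord(
                    reaction_id=rid,
                    spec=clf.spec,
                    holdout_accuracy=clf.holdout_accuracy,
                )
        except DegenerateLabelError:
            logger.info("reaction %s unclassifiable (single-class labels)", rid)
            continue
        if config.cv_folds >= 2:
            folds = cross_validate(X, y, rec.spec, k=config.cv_folds)
            rec = ClassifierRecord(
                reaction_id=rid,
                spec=rec.spec,
                holdout_accuracy=rec.holdout_accuracy,
                fold_accuracies=folds,
            )
        trained[rid] = clf
        records_out.append(rec)
    retained = filter_classifiers(
        records_out, min_accuracy=config.min_classifier_accuracy
    )
    retained_ids = [r.reaction_id for r in retained]
    classifiers = {rid: trained[rid] for rid in retained_ids}
    pd.DataFrame(
        [
            {
                "reaction_id": r.reaction_id,
                "epochs": r.spec.epochs,
                "batch": r.spec.batch_size,
                "width": r.spec.width,
                "holdout_accuracy": r.holdout_accuracy,
                "mean_cv_accuracy": r.mean_cv_accuracy,
                "retained": r.reaction_id in retained_ids,
            }
            for r in records_out
        ]
    ).to_csv(out / "classifiers.tsv", sep="\t", index=False)
    result.classifier_records = records_out
    stages["classifiers"] = {
        "status": "ok",
        "records": len(records_out),
        "retained": len(retained_ids),
    }
    if not retained_ids:
        raise WcfluxError(
            "stage 'classifiers' failed: no classifier reached the "
            "retention threshold"
        )

    # -- stage 5: flux profiles -------------------------------------------
    profiles = [make_flux_profile(r, classifiers) for r in records]
    write_profiles(profiles, out / "profiles.tsv")
    result.profiles = profiles
    stages["profiles"] = {"status": "ok", "records": len(profiles)}

    # -- stage 6: profile PCA (knockout simulations) ----------------------
    ko_profiles = [
        p
        for p, r in zip(profiles, records)
        if r.genotype != WILD_TYPE
    ]
    if len(ko_profiles) >= 2:
        P = np.vstack([p.bits for p in ko_profiles])
        reduced = reduce_profiles(P, n_components=2)
        score_df = pd.DataFrame(
            reduced.scores[:, : min(2, reduced.scores.shape[1])],
            columns=["PC1", "PC2"][: reduced.scores.shape[1]],
        )
        score_df.insert(
            0, "simulation_id", [p.simulation_id for p in ko_profiles]
        )
        score_df.to_csv(out / "profile_scores.tsv", sep="\t", index=False)
        result.profile_scores = reduced.scores
        stages["profile_pca"] = {
            "status": "ok",
            "records": len(ko_profiles),
            "explained_variance_fraction": reduced.explained_variance_fraction,
        }
    else:
        stages["profile_pca"] = {"status": "skipped", "records": 0}

    # -- stage 7: network and driver nodes --------------------------------
    drivers = None
    adjacency = None
    if config.stoichiometry_path and Path(config.stoichiometry_path).exists():
        S = read_stoichiometric_matrix(config.stoichiometry_path)
        adjacency = adjacency_from_stoichiometry(S)
        drivers = find_driver_nodes(
            adjacency, strategy=config.matching_strategy
        )
        result.drivers = drivers
        nx.write_graphml(adjacency, out / "reaction_graph.graphml")
        pd.DataFrame(
            sorted(adjacency.edges()), columns=["reaction_a", "reaction_b"]
        ).to_csv(out / "reaction_graph_edges.tsv", sep="\t", index=False)
        wt_profiles = [
            p for p, r in zip(profiles, records) if r.genotype == WILD_TYPE
        ]
        threshold = 0.0
        if wt_profiles:
            wt_freq = abnormality_frequencies(wt_profiles)["all"]
            threshold = noise_threshold(
                wt_freq, coverage=config.noise_coverage
            ).threshold
        groups = {}
        for r in records:
            if r.genotype == WILD_TYPE:
                continue
            if r.phenotype_flags is not None:
                groups[r.simulation_id] = classify_phenotype(
                    r.phenotype_flags
                ).value
            else:
                groups[r.simulation_id] = r.genotype
        sub_rows = []
        if groups and ko_profiles:
            freq_by_group = abnormality_frequencies(ko_profiles, groups)
            for gname, freqs in sorted(freq_by_group.items()):
                sub = class_subnetwork(adjacency, freqs, threshold)
                for node, data in sub.nodes(data=True):
                    sub_rows.append(
                        {
                            "group": gname,
                            "reaction_id": node,
                            "frequency": data["frequency"],
                            "selected": True,
                        }
                    )
        pd.DataFrame(
            sub_rows,
            columns=["group", "reaction_id", "frequency", "selected"],
        ).to_csv(out / "subnetworks.tsv", sep="\t", index=False)
        stages["network"] = {
            "status": "ok",
            "records": adjacency.number_of_nodes(),
            "drivers": len(drivers.drivers),
            "noise_threshold": threshold,
        }
    else:
        stages["network"] = {"status": "skipped", "records": 0}

    # -- stage 8: markers ---------------------------------------------------
    have_flags = any(
        r.phenotype_flags is not None for r in records if r.genotype != WILD_TYPE
    )
    if drivers is not None and have_flags and result.profile_scores is not None:
        ko_records = [r for r in records if r.genotype != WILD_TYPE]
        classes = np.array(
            [
                classify_phenotype(r.phenotype_flags).value
                if r.phenotype_flags is not None
                else "unlabelled"
                for r in ko_records
            ]
        )
        rid_index = {p: i for i, p in enumerate(ko_profiles[0].reaction_ids)}
        separability = {}
        phi_by_class: dict[str, dict[PhenotypeClass, float]] = {}
        for rid in drivers.drivers:
            if rid not in rid_index:
                continue
            bits = np.array(
                [p.bits[rid_index[rid]] for p in ko_profiles]
            )
            try:
                separability[rid] = svm_separability(
                    result.profile_scores[:, :2],
                    bits,
                    reaction_id=rid,
                    pass_accuracy=config.separability_accuracy,
                )
            except DegenerateLabelError:
                logger.info(
                    "driver %s: single-class behaviour, separability skipped",
                    rid,
                )
            phis = {}
            for cls in PhenotypeClass:
                in_class = classes == cls.value
                if in_class.sum() in (0, len(classes)):
                    continue
                table = contingency_from_labels(bits == ABNORMAL, in_class)
                try:
                    phis[cls] = phi_coefficient(table)
                except WcfluxError:
                    continue
            if phis:
                phi_by_class[rid] = phis
        annotation = (
            read_annotation_table(config.annotation_path)
            if config.annotation_path
            and Path(config.annotation_path).exists()
            else {}
        )
        pathways = annotate_pathways(drivers, annotation, adjacency)
        table = marker_report(drivers, separability, phi_by_class, pathways)
        table.to_csv(out / "markers.tsv", sep="\t", index=False)
        result.marker_table = table
        stages["markers"] = {"status": "ok", "records": len(table)}
    else:
        stages["markers"] = {"status": "skipped", "records": 0}

    import sklearn

    manifest = {
        "wcflux_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "networkx": nx.__version__,
        },
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "knobs": {
            "boundary_schemes": list(config.boundary_schemes),
            "matching_strategy": config.matching_strategy,
            "label_backend": config.label_backend,
            "classifier_input": config.classifier_input,
        },
        "stages": stages,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    result.manifest = manifest
    return result
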
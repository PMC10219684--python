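"""End-to-end orchestration: counts → DE → TF activity → candidate table.

`analyze_compendium` runs the full RNA-seq discovery procedure on a count
compendium whose design table groups samples into datasets:

* the in-house dataset (conditions ``D12, 2D_D26, 2D_D40, 3D_D26, 3D_D40``)
  supplies the two expression contrasts (mature-3D vs mature-2D and
  mature-3D vs early) and the activity contrast;
* comparator datasets with ``adult_*``/``fetal_*`` conditions supply the
  adult-vs-fetal concordance criteria;
* model datasets (conditions ``*_mat`` / ``*_ctrl``) feed the final vote.

Each dataset is normalized, dispersion-estimated and scored independently
(z-scores for activity are taken across the samples of one dataset, never
across datasets). `run_manifest` drives the whole thing, optionally
starting from the synthetic-data generators, and writes every stage output.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity as act
from . import assays, de, io, sarcomere, simulate
from .prioritize import (
    COMPARATOR_CONTRAST,
    INHOUSE_ACTIVITY_CONTRAST,
    INHOUSE_EXPRESSION_CONTRASTS,
    MODEL_CONTRAST,
    ContrastBundle,
    SelectionConfig,
    deg_overlap,
    model_vote,
    sample_structure,
    select_candidates,
)

__all__ = [
    "analyze_dataset",
    "analyze_compendium",
    "evaluate_recovery",
    "run_manifest",
]


def _dataset_contrasts(conditions: set[str]) -> tuple[str, dict[str, tuple[str, str]]]:
    """Infer a dataset's role and named (a, b) contrasts from its conditions."""
    if {"3D_D40", "2D_D40", "D12"} <= conditions:
        return "inhouse", {
            "3D_D40_vs_2D_D40": ("3D_D40", "2D_D40"),
            "3D_D40_vs_D12": ("3D_D40", "D12"),
        }
    adult = sorted(c for c in conditions if c.startswith("adult"))
    fetal = sorted(c for c in conditions if c.startswith("fetal"))
    if adult and fetal:
        return "comparator", {COMPARATOR_CONTRAST: (adult[0], fetal[0])}
    mat = sorted(c for c in conditions if c.endswith("_mat"))
    ctrl = sorted(c for c in conditions if c.endswith("_ctrl"))
    if mat and ctrl:
        return "model", {MODEL_CONTRAST: (mat[0], ctrl[0])}
    raise ValueError(f"cannot infer contrasts for conditions {sorted(conditions)}")


def analyze_dataset(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    regulon_edges: pd.DataFrame,
    selection: SelectionConfig,
    dispersion_shrinkage: float = 0.9,
    min_confidence: str = "C",
    min_targets: int = 5,
) -> ContrastBundle:
    """Run DE and activity scoring for one dataset's samples."""
    role, contrasts = _dataset_contrasts(set(design["condition"]))
    factors = de.size_factors(counts)
    dispersions = de.estimate_dispersions(counts, factors, design, shrinkage=dispersion_shrinkage)
    norm = de.normalize_counts(counts, factors)

    expression = {
        name: de.wald_contrast(counts, factors, dispersions, design, a, b)
        for name, (a, b) in contrasts.items()
    }

    expressed = set(norm.index[norm.mean(axis=1) >= de.LOW_COUNT_FLOOR])
    regset = act.build_regulons(
        regulon_edges,
        min_confidence=min_confidence,
        min_targets=min_targets,
        expressed_genes=expressed,
    )
    scores = act.score_activity(norm, regset)
    activity_cmp = {}
    for name, (a, b) in contrasts.items():
        if role == "inhouse" and name != INHOUSE_ACTIVITY_CONTRAST:
            continue
        activity_cmp[name] = act.compare_activity(
            scores,
            design,
            a,
            b,
            fold_threshold=selection.activity_fold,
            margin=selection.activity_margin,
        )

    dataset = design["dataset"].iloc[0]
    bundle = ContrastBundle(dataset=dataset, role=role, expression=expression, activity=activity_cmp)
    bundle.extras = {
        "size_factors": factors,
        "activity_scores": scores,
        "normalized": norm,
        "regulons": regset,
    }
    return bundle


def analyze_compendium(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    regulon_edges: pd.DataFrame,
    selection: SelectionConfig | None = None,
    dispersion_shrinkage: float = 0.9,
) -> dict:
    """Full discovery procedure over all datasets in the design.

    Returns a dict with the per-dataset ``bundles``, the ``candidates``
    table (tiers + model votes), ``deg_overlaps`` of the in-house DEG set
    against each comparator's adult-vs-fetal DEG set, and the in-house
    ``structure`` (dendrogram + PCA).
    """
    if selection is None:
        selection = SelectionConfig()
    missing = set(counts.columns) - set(design.index)
    if missing:
        raise ValueError(f"samples without design rows: {sorted(missing)[:5]}")

    bundles = []
    for _, sub in design.loc[counts.columns].groupby("dataset", sort=True):
        bundles.append(
            analyze_dataset(
                counts[sub.index], sub, regulon_edges, selection, dispersion_shrinkage
            )
        )

    inout = [b for b in bundles if b.role in ("inhouse", "comparator")]
    models = [b for b in bundles if b.role == "model"]
    candidates = select_candidates(inout, selection)
    if models:
        candidates = model_vote(models, candidates, selection)

    inhouse = next(b for b in bundles if b.role == "inhouse")
    inhouse_degs = de.call_degs(inhouse.expression["3D_D40_vs_2D_D40"])
    overlaps = {}
    for b in bundles:
        if b.role == "comparator":
            comp_degs = de.call_degs(b.expression[COMPARATOR_CONTRAST])
            overlaps[b.dataset] = deg_overlap(inhouse_degs, comp_degs)

    ih_samples = design.index[design["dataset"] == inhouse.dataset]
    ih_counts = counts[ih_samples]
    structure = sample_structure(ih_counts, de.size_factors(ih_counts))

    return {
        "bundles": bundles,
        "candidates": candidates,
        "deg_overlaps": overlaps,
        "structure": structure,
        "inhouse_degs": inhouse_degs,
    }


def evaluate_recovery(candidates: pd.DataFrame, truth: simulate.TruthTable) -> dict:
    """Compare the candidate table against planted ground truth.

    Sensitivity counts planted TFs recovered in the core or extended tier;
    the false-discovery proportion is the share of recovered TFs that were
    not planted; vote agreement is the fraction of planted TFs whose model
    vote equals the number of models that truly activated them.
    """
    planted = set(truth.planted_tf_ids)
    recovered = set(candidates.index[candidates["tier"].isin(["core", "extended"])])
    sensitivity = len(planted & recovered) / len(planted) if planted else float("nan")
    fdp = len(recovered - planted) / len(recovered) if recovered else 0.0
    agree = float("nan")
    if truth.true_votes is not None and len(planted):
        votes = candidates["model_vote"].reindex(sorted(planted))
        agree = float(
            np.mean([votes[tf] == truth.true_votes[tf] for tf in sorted(planted)])
        )
    return {"sensitivity": sensitivity, "fdp": fdp, "vote_agreement": agree}


# ---------------------------------------------------------------------------
# Manifest-driven runs


def run_manifest(manifest: dict | str | Path, overwrite: bool = False) -> dict:
    """Execute a run described by a manifest (dict or YAML path).

    Manifest keys: ``seed`` (int), ``outdir`` (path), and either
    ``simulate`` (a mapping of :class:`simulate.SimulationConfig` overrides)
    or ``inputs`` (paths ``counts``, ``design``, ``regulons``); optional
    ``selection`` (SelectionConfig overrides) and ``stages`` (booleans
    ``rnaseq, calcium, sarcomere, assays``, all defaulting to ``rnaseq``
    only). All randomness flows from ``seed``. Outputs plus a run log are
    written to ``outdir``; existing files are refused unless ``overwrite``.
    """
    if not isinstance(manifest, dict):
        manifest = io.read_manifest_yaml(manifest)
    seed = int(manifest.get("seed", 0))
    outdir = Path(manifest.get("outdir", "cardiomat_out"))
    stages = {"rnaseq": True, "calcium": False, "sarcomere": False, "assays": False}
    stages.update(manifest.get("stages", {}))
    selection = SelectionConfig(**manifest.get("selection", {}))
    selection.validate()

    checksums: dict[str, str] = {}
    outputs: dict[str, object] = {}
    results: dict[str, object] = {}

    sim_cfg = None
    if "simulate" in manifest:
        overrides = dict(manifest["simulate"] or {})
        for key in ("trace_params", "image_params"):
            if key in overrides:
                cls = simulate.TraceParams if key == "trace_params" else simulate.ImageParams
                overrides[key] = cls(**overrides[key])
        sim_cfg = simulate.SimulationConfig(seed=seed, **overrides)
        sim_cfg.validate()

    if stages["rnaseq"]:
        if sim_cfg is not None:
            edges, _ = simulate.simulate_regulons(sim_cfg)
            counts, design, truth = simulate.simulate_count_compendium(sim_cfg, edges)
            outputs["counts.tsv"] = counts
            outputs["design.tsv"] = design
            outputs["regulons.tsv"] = edges.set_index("tf")
            outputs["truth.json"] = {
                "planted_tf_ids": truth.planted_tf_ids,
                "true_votes": truth.true_votes.to_dict(),
            }
        else:
            paths = manifest.get("inputs", {})
            for key in ("counts", "design", "regulons"):
                if key not in paths:
                    raise ValueError(f"manifest inputs missing {key!r} path")
                if not Path(paths[key]).exists():
                    raise FileNotFoundError(f"manifest input {key!r}: {paths[key]} does not exist")
            counts = io.read_validate(paths["counts"], "counts_tsv")
            design = io.read_validate(paths["design"], "design_tsv")
            edges = io.read_validate(paths["regulons"], "regulon_tsv")
            truth = None
            for key, p in paths.items():
                checksums[key] = io.file_checksum(p)

        analysis = analyze_compendium(counts, design, edges, selection)
        results["analysis"] = analysis
        outputs["candidates.tsv"] = analysis["candidates"]
        outputs["deg_overlaps.json"] = analysis["deg_overlaps"]
        outputs["dendrogram.nwk"] = analysis["structure"]["newick"]
        outputs["pca_coordinates.tsv"] = analysis["structure"]["pc_coordinates"]
        outputs["inhouse_degs.tsv"] = analysis["inhouse_degs"]
        for b in analysis["bundles"]:
            for name, table in b.expression.items():
                outputs[f"de_{b.dataset}_{name}.tsv"] = table
        if truth is not None:
            results["recovery"] = evaluate_recovery(analysis["candidates"], truth)
            outputs["recovery.json"] = results["recovery"]

    if stages["calcium"]:
        cfg = sim_cfg or simulate.SimulationConfig(seed=seed)
        traces, trace_truth = simulate.simulate_traces(cfg)
        feats = []
        for (cond, vid, cell), grp in traces.groupby(["condition", "video_id", "cell_id"]):
            dff, _ = assays.normalize_trace(grp["time_s"].to_numpy(), grp["intensity"].to_numpy())
            f = assays.extract_transients(grp["time_s"].to_numpy(), dff)
            feats.append({"condition": cond, "video_id": vid, "cell_id": cell, **f.as_dict()})
        features = pd.DataFrame(feats)
        per_video, per_condition = assays.summarize_group(features, seed=seed)
        outputs["traces.csv"] = traces
        outputs["calcium_features.tsv"] = features.set_index("cell_id")
        outputs["calcium_by_condition.tsv"] = per_condition.set_index("condition")
        results["calcium"] = per_condition

    if stages["sarcomere"]:
        cfg = sim_cfg or simulate.SimulationConfig(seed=seed)
        image, img_truth = simulate.simulate_striation_image(cfg)
        field = sarcomere.orientation_field(image, tile_size=cfg.image_params.tile_size)
        axis, frac = sarcomere.alignment_metrics(field)
        length = sarcomere.sarcomere_length(image, axis, cfg.image_params.pixel_size)
        metrics = {
            "principal_axis_deg": axis,
            "alignment_fraction": frac,
            "sarcomere_length_um": length,
        }
        outputs["striation.tiff"] = image
        outputs["sarcomere_metrics.json"] = metrics
        results["sarcomere"] = metrics

    if stages["assays"]:
        cfg = sim_cfg or simulate.SimulationConfig(seed=seed)
        ct, plate, assay_truth = simulate.simulate_assay_tables(cfg)
        ct_design = assay_truth.extras["ct_design"]
        rel = assays.ddct_relative_expression(
            ct, ct_design, assay_truth.extras["housekeeping"], assay_truth.extras["reference_group"]
        )
        atp = assays.atp_normalize(plate)
        outputs["ct_table.tsv"] = ct
        outputs["qpcr_relative_expression.tsv"] = rel
        outputs["plate.tsv"] = plate.set_index("group")
        outputs["atp_normalized.tsv"] = atp
        results["qpcr"] = rel
        results["atp"] = atp

    params = {
        "stages": stages,
        "selection": asdict(selection),
        "simulate": asdict(sim_cfg) if sim_cfg is not None else None,
    }
    written = io.write_results(
        outputs, outdir, seed=seed, parameters=params,
        input_checksums=checksums, overwrite=overwrite,
    )
    results["written"] = written
    return results
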
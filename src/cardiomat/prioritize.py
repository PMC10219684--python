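"""Candidate-TF selection across datasets and maturation models.

The selection joins per-dataset evidence: a TF enters the *core* tier when
it clears the expression-fold criterion in both in-house contrasts
(mature-3D vs mature-2D and mature-3D vs early), the activity criterion,
and the same criteria in every adult-vs-fetal comparator dataset. TFs that
clear the expression criteria and belong to a declared gene family join the
*extended* tier (no activity requirement — regulon resources cover a
limited set of TFs); an allow-list adds *manual* entries with recorded
rationales. A final vote counts, per candidate, how many independent
maturation-model datasets show the expression and/or activity criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

__all__ = [
    "ContrastBundle",
    "SelectionConfig",
    "select_candidates",
    "model_vote",
    "deg_overlap",
    "sample_structure",
    "linkage_to_newick",
]

INHOUSE_EXPRESSION_CONTRASTS = ("3D_D40_vs_2D_D40", "3D_D40_vs_D12")
INHOUSE_ACTIVITY_CONTRAST = "3D_D40_vs_2D_D40"
COMPARATOR_CONTRAST = "adult_vs_fetal"
MODEL_CONTRAST = "mat_vs_ctrl"


@dataclass
class ContrastBundle:
    """All contrasts computed on one dataset.

    ``expression`` maps contrast name → Wald-contrast result table (indexed
    by gene, with a ``log2fc`` column); ``activity`` maps contrast name →
    per-TF activity comparison table (indexed by TF, with ``passed`` and
    ``evaluable`` columns). ``role`` is one of ``inhouse``, ``comparator``,
    ``model``.
    """

    dataset: str
    role: str
    expression: dict[str, pd.DataFrame] = field(default_factory=dict)
    activity: dict[str, pd.DataFrame] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


@dataclass
class SelectionConfig:
    expression_fold: float = 1.5
    activity_fold: float = 1.5
    activity_margin: float = 0.5
    allow_list: dict[str, str] = field(default_factory=dict)  # tf -> rationale
    family_expansion: dict[str, list[str]] = field(default_factory=dict)
    vote_rule: str = "all"  # "all" = expression AND activity; "any" = either

    def validate(self) -> None:
        if self.expression_fold <= 1.0 or self.activity_fold <= 1.0:
            raise ValueError("fold thresholds must exceed 1")
        if self.vote_rule not in ("any", "all"):
            raise ValueError("vote_rule must be 'any' or 'all'")

    @property
    def lfc_threshold(self) -> float:
        return math.log2(self.expression_fold)


def _expression_flag(de: pd.DataFrame, tf: str, lfc_threshold: float) -> bool | None:
    """Pass iff log2fc >= threshold; None when the TF is not in the table."""
    if tf not in de.index:
        return None
    return bool(de.loc[tf, "log2fc"] >= lfc_threshold)


def _activity_flag(cmp: pd.DataFrame, tf: str) -> bool | None:
    if tf not in cmp.index or not bool(cmp.loc[tf, "evaluable"]):
        return None
    return bool(cmp.loc[tf, "passed"])


def select_candidates(
    bundles: list[ContrastBundle],
    config: SelectionConfig,
) -> pd.DataFrame:
    """Assign candidate tiers from in-house and comparator evidence.

    Returns the candidate table: one row per TF considered, one boolean
    column per criterion flag (``None``/NaN where not evaluable), the tier
    (``core``/``extended``/``manual``/``none``) and a rationale string.
    """
    config.validate()
    inhouse = [b for b in bundles if b.role == "inhouse"]
    comparators = [b for b in bundles if b.role == "comparator"]
    if len(inhouse) != 1:
        raise ValueError("exactly one in-house bundle is required")
    if not comparators:
        raise ValueError("at least one comparator bundle is required")
    ih = inhouse[0]
    for c in INHOUSE_EXPRESSION_CONTRASTS:
        if c not in ih.expression:
            raise ValueError(f"in-house bundle missing expression contrast {c!r}")
    if INHOUSE_ACTIVITY_CONTRAST not in ih.activity:
        raise ValueError(f"in-house bundle missing activity contrast {INHOUSE_ACTIVITY_CONTRAST!r}")
    for b in comparators:
        if COMPARATOR_CONTRAST not in b.expression or COMPARATOR_CONTRAST not in b.activity:
            raise ValueError(f"comparator bundle {b.dataset!r} missing contrast {COMPARATOR_CONTRAST!r}")

    family_members = {m for members in config.family_expansion.values() for m in members}
    universe = set(ih.activity[INHOUSE_ACTIVITY_CONTRAST].index)
    universe |= family_members | set(config.allow_list)

    lfc = config.lfc_threshold
    rows = []
    for tf in sorted(universe):
        flags: dict[str, bool | None] = {}
        for c in INHOUSE_EXPRESSION_CONTRASTS:
            flags[f"expr_{ih.dataset}_{c}"] = _expression_flag(ih.expression[c], tf, lfc)
        flags[f"act_{ih.dataset}_{INHOUSE_ACTIVITY_CONTRAST}"] = _activity_flag(
            ih.activity[INHOUSE_ACTIVITY_CONTRAST], tf
        )
        for b in comparators:
            flags[f"expr_{b.dataset}_{COMPARATOR_CONTRAST}"] = _expression_flag(
                b.expression[COMPARATOR_CONTRAST], tf, lfc
            )
            flags[f"act_{b.dataset}_{COMPARATOR_CONTRAST}"] = _activity_flag(
                b.activity[COMPARATOR_CONTRAST], tf
            )

        expr_flags = [v for k, v in flags.items() if k.startswith("expr_")]
        act_flags = [v for k, v in flags.items() if k.startswith("act_")]
        all_expr = all(v is True for v in expr_flags)
        all_act = all(v is True for v in act_flags)

        if all_expr and all_act:
            tier, rationale = "core", "passed expression and activity criteria in all datasets"
        elif all_expr and tf in family_members:
            fams = [f for f, members in config.family_expansion.items() if tf in members]
            tier, rationale = "extended", f"expression criteria + family membership ({', '.join(fams)})"
        elif tf in config.allow_list:
            tier, rationale = "manual", config.allow_list[tf]
        else:
            tier, rationale = "none", ""
        rows.append({"tf": tf, **flags, "tier": tier, "rationale": rationale})

    table = pd.DataFrame(rows).set_index("tf")
    table["model_vote"] = pd.NA
    return table


def model_vote(
    model_bundles: list[ContrastBundle],
    candidates: pd.DataFrame,
    config: SelectionConfig,
) -> pd.DataFrame:
    """Count, per candidate TF, the models in which it meets the criteria.

    Per model the TF counts once when it meets the expression criterion
    and/or the activity criterion (``config.vote_rule`` switches to the
    conjunction). A TF absent from a model's tables is not met there and is
    noted in the ``vote_notes`` column.
    """
    config.validate()
    lfc = config.lfc_threshold
    out = candidates.copy()
    votes = {}
    notes = {}
    for tf in out.index:
        n = 0
        missing = []
        for b in model_bundles:
            if b.role != "model":
                raise ValueError(f"bundle {b.dataset!r} has role {b.role!r}, expected 'model'")
            de = b.expression.get(MODEL_CONTRAST)
            cmp = b.activity.get(MODEL_CONTRAST)
            e = _expression_flag(de, tf, lfc) if de is not None else None
            a = _activity_flag(cmp, tf) if cmp is not None else None
            if e is None and a is None:
                missing.append(b.dataset)
                continue
            met = (
                (e is True) or (a is True)
                if config.vote_rule == "any"
                else (e is True) and (a is True)
            )
            n += int(met)
        votes[tf] = n
        notes[tf] = f"not evaluable in: {', '.join(missing)}" if missing else ""
    out["model_vote"] = pd.Series(votes)
    out["vote_notes"] = pd.Series(notes)
    return out


def deg_overlap(set_a: pd.DataFrame, set_b: pd.DataFrame) -> dict[str, float]:
    """Overlap statistics between two signed DEG sets.

    Both inputs are DEG tables indexed by gene with a ``direction`` column
    (±1). Returns the overlap count, the Jaccard index of the gene sets, and
    the directional concordance — the fraction of shared genes regulated in
    the same direction (NaN when the overlap is empty).
    """
    genes_a, genes_b = set(set_a.index), set(set_b.index)
    inter = genes_a & genes_b
    union = genes_a | genes_b
    jaccard = len(inter) / len(union) if union else float("nan")
    if inter:
        idx = sorted(inter)
        same = (set_a.loc[idx, "direction"].to_numpy() == set_b.loc[idx, "direction"].to_numpy())
        concordance = float(same.mean())
    else:
        concordance = float("nan")
    return {"overlap": len(inter), "jaccard": jaccard, "concordance": concordance}


def sample_structure(
    counts: pd.DataFrame, factors: pd.Series
) -> dict[str, object]:
    """Sample-level structure: average-linkage dendrogram and PCA.

    Relative expression is per-gene centered log2(normalized count + 1).
    Hierarchical clustering uses average linkage on Euclidean sample
    distances; PCA comes from the eigendecomposition of the sample
    covariance. Returns ``linkage`` (scipy linkage matrix), ``newick``,
    ``pc_coordinates`` (samples × components) and ``variance_fractions``.
    """
    from .de import normalize_counts

    if counts.shape[1] < 3:
        raise ValueError("sample structure needs >= 3 samples")
    logn = np.log2(normalize_counts(counts, factors) + 1.0)
    rel = logn.sub(logn.mean(axis=1), axis=0)
    X = rel.to_numpy().T  # samples × genes
    if np.allclose(X, X[0]):
        raise ValueError("expression matrix is constant across samples; covariance degenerate")

    Z = linkage(X, method="average", metric="euclidean")

    Xc = X - X.mean(axis=0)
    cov = Xc @ Xc.T / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(np.maximum(evals, 0.0)) * math.sqrt(X.shape[0] - 1)
    k = min(10, X.shape[0] - 1)
    pcs = pd.DataFrame(
        coords[:, :k],
        index=counts.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    total = evals.sum()
    frac = evals / total if total > 0 else evals
    return {
        "linkage": Z,
        "newick": linkage_to_newick(Z, list(counts.columns)),
        "pc_coordinates": pcs,
        "variance_fractions": pd.Series(
            frac, index=[f"PC{i + 1}" for i in range(len(frac))]
        ),
    }


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + len(Z) - 1] + ";"
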
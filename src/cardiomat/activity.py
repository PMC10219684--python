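"""Regulon-based transcription-factor activity scoring.

A TF's activity in a sample is inferred from the expression of its regulon
targets, not from the TF's own transcript. Regulons arrive as signed,
confidence-graded edge tables (columns ``tf, confidence, target, mor``);
after filtering to high-confidence edges over expressed genes, activity is
the signed mean target z-score scaled by the square root of regulon size —
a normalized-enrichment statistic that is approximately standard normal
under an independent-targets null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegulonSet",
    "build_regulons",
    "score_activity",
    "compare_activity",
]

GRADE_ORDER = {"A": 0, "B": 1, "C": 2, "D": 3, "E": 4}


@dataclass
class RegulonSet:
    """Filtered regulons: an edge table plus the exclusion report.

    ``edges`` has columns ``tf, confidence, target, mor``; ``excluded`` maps
    each dropped TF to the reason it was dropped.
    """

    edges: pd.DataFrame
    min_confidence: str = "C"
    min_targets: int = 5
    excluded: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges["tf"].unique())

    def regulon(self, tf: str) -> pd.DataFrame:
        return self.edges[self.edges["tf"] == tf]

    def sizes(self) -> pd.Series:
        return self.edges.groupby("tf").size()


def _validate_edges(edges: pd.DataFrame) -> None:
    required = {"tf", "confidence", "target", "mor"}
    if not required <= set(edges.columns):
        raise ValueError(f"edge table must have columns {sorted(required)}")
    bad_mode = ~edges["mor"].isin([1, -1])
    if bad_mode.any():
        i = edges.index[bad_mode][0]
        raise ValueError(f"edge row {i}: mor must be +1 or -1, got {edges.loc[i, 'mor']!r}")
    bad_grade = ~edges["confidence"].isin(GRADE_ORDER)
    if bad_grade.any():
        i = edges.index[bad_grade][0]
        raise ValueError(f"edge row {i}: invalid confidence grade {edges.loc[i, 'confidence']!r}")
    if edges.duplicated(subset=["tf", "target"]).any():
        dup = edges[edges.duplicated(subset=["tf", "target"])].iloc[0]
        raise ValueError(f"duplicate edge ({dup['tf']}, {dup['target']})")


def build_regulons(
    edges: pd.DataFrame,
    min_confidence: str = "C",
    min_targets: int = 5,
    expressed_genes: set[str] | None = None,
) -> RegulonSet:
    """Filter an edge table into usable regulons.

    Edges with confidence worse than ``min_confidence`` are dropped (grades
    ordered A best … E worst); edges whose targets are not in
    ``expressed_genes`` are dropped; TFs left with fewer than ``min_targets``
    edges are excluded and reported.
    """
    _validate_edges(edges)
    if min_confidence not in GRADE_ORDER:
        raise ValueError(f"invalid confidence grade {min_confidence!r}")

    cutoff = GRADE_ORDER[min_confidence]
    kept = edges[edges["confidence"].map(GRADE_ORDER) <= cutoff]
    excluded: dict[str, str] = {}
    low_conf_tfs = set(edges["tf"]) - set(kept["tf"])
    for tf in low_conf_tfs:
        excluded[tf] = f"no edges at confidence {min_confidence} or better"

    if expressed_genes is not None:
        before = kept.groupby("tf").size()
        kept = kept[kept["target"].isin(expressed_genes)]
        gone = set(before.index) - set(kept["tf"])
        for tf in gone:
            excluded[tf] = "no expressed targets"

    sizes = kept.groupby("tf").size()
    small = sizes[sizes < min_targets].index
    for tf in small:
        excluded[tf] = f"only {sizes[tf]} usable targets (< {min_targets})"
    kept = kept[~kept["tf"].isin(small)]

    if kept.empty:
        reasons = "; ".join(f"{tf}: {why}" for tf, why in sorted(excluded.items()))
        raise ValueError(f"no regulon survived filtering ({reasons})")
    return RegulonSet(
        edges=kept.reset_index(drop=True),
        min_confidence=min_confidence,
        min_targets=min_targets,
        excluded=excluded,
    )


def score_activity(expression: pd.DataFrame, regulons: RegulonSet) -> pd.DataFrame:
    """Score TF activity per sample from normalized expression.

    ``expression`` is a gene × sample matrix of normalized counts. Per gene,
    ``z = z-score of log2(x + 1) across samples``; the activity of TF with
    regulon R in sample j is ``sum_t mode_t * z_tj / sqrt(|R|)``. Targets
    with zero variance across samples carry no information and are dropped
    from the sum with a warning.
    """
    if expression.shape[1] < 3:
        raise ValueError("activity z-scoring needs at least 3 samples")
    missing = set(regulons.edges["target"]) - set(expression.index)
    if missing:
        raise ValueError(f"expression matrix lacks {len(missing)} regulon targets")

    logx = np.log2(expression + 1.0)
    mu = logx.mean(axis=1)
    sd = logx.std(axis=1, ddof=1)
    zero_var = sd == 0
    z = logx.sub(mu, axis=0).div(sd.where(~zero_var, 1.0), axis=0)
    z[zero_var] = 0.0

    rows = {}
    n_dropped = 0
    for tf, ed in regulons.edges.groupby("tf"):
        targets = ed["target"].to_numpy()
        informative = ~zero_var.reindex(targets).to_numpy()
        n_dropped += int((~informative).sum())
        size = len(targets)  # normalization uses the nominal regulon size
        zt = z.loc[targets[informative]].to_numpy()
        modes = ed["mor"].to_numpy()[informative]
        rows[tf] = (modes[:, None] * zt).sum(axis=0) / np.sqrt(size)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero-variance targets from activity sums", stacklevel=2)
    out = pd.DataFrame(rows, index=expression.columns).T
    out.index.name = "tf"
    return out.sort_index()


def compare_activity(
    activity: pd.DataFrame,
    design: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    fold_threshold: float = 1.5,
    margin: float = 0.5,
    tfs: list[str] | None = None,
) -> pd.DataFrame:
    """Per-TF activity-fold criterion between two conditions.

    Activity scores are signed, so a pure ratio rule is ill-defined; the
    criterion is made total with two branches, both recorded per TF:

    * ratio branch — if the reference mean ``A_b > 0``, pass iff
      ``A_a >= fold_threshold * A_b``;
    * sign-guard branch — if ``A_b <= 0``, pass iff ``A_a > 0`` and
      ``A_a >= A_b + margin``.

    TFs requested but absent from the activity matrix are recorded as
    not evaluable rather than failed.
    """
    if fold_threshold <= 1.0:
        raise ValueError("fold_threshold must exceed 1")
    if margin <= 0:
        raise ValueError("margin must be positive")
    cond = design["condition"]
    sa = cond.index[cond == condition_a]
    sb = cond.index[cond == condition_b]
    if len(sa) == 0 or len(sb) == 0:
        raise ValueError(f"conditions {condition_a!r}/{condition_b!r} need >= 1 sample each")

    if tfs is None:
        tfs = list(activity.index)
    rows = []
    for tf in tfs:
        if tf not in activity.index:
            rows.append((tf, np.nan, np.nan, "absent", False, False))
            continue
        a = float(activity.loc[tf, sa].mean())
        b = float(activity.loc[tf, sb].mean())
        if b > 0:
            passed = a >= fold_threshold * b
            branch = "ratio"
        else:
            passed = (a > 0) and (a >= b + margin)
            branch = "sign_guard"
        rows.append((tf, a, b, branch, passed, True))
    return pd.DataFrame(
        rows,
        columns=["tf", "mean_a", "mean_b", "branch", "passed", "evaluable"],
    ).set_index("tf")
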
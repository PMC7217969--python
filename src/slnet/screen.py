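"""Scoring of plate-based viability screens.

Single-gene knockdown screens are scored per gene as a signed -log10
t-test p-value comparing normalized proliferation between a mutant arm and
a control arm (negative = synthetic sick/lethal, positive = enhancement),
with Benjamini-Hochberg FDR across genes.  Drug screens are summarized by
the per-arm dose-response AUC (sum of normalized proliferation over the
dose series).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bh_fdr, signed_log10_t

NT_LABEL = "NT"

PLATE_COLUMNS = ["plate_id", "well", "cell_line", "condition", "perturbation", "replicate", "count"]


def validate_plate_table(table: pd.DataFrame, nt_label: str = NT_LABEL) -> None:
    """Check the plate-table contract: columns, counts, NT wells, replicates."""
    missing = [c for c in PLATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    if (table["count"] < 0).any():
        raise ValueError("negative cell counts")
    for plate, sub in table.groupby("plate_id"):
        if not (sub["perturbation"] == nt_label).any():
            raise ValueError(f"plate {plate!r} has no {nt_label} control wells")
    dup = table.duplicated(subset=["plate_id", "perturbation", "replicate"])
    if dup.any():
        raise ValueError("duplicate replicate index within (plate, perturbation)")


def normalize_to_nt(table: pd.DataFrame, nt_label: str = NT_LABEL) -> pd.DataFrame:
    """Divide each well's count by the mean NT count of its own plate.

    Adds a ``norm`` column; raises naming the plate if a plate lacks NT
    wells or their mean is zero.
    """
    out = table.copy()
    nt_means = (
        out[out["perturbation"] == nt_label].groupby("plate_id")["count"].mean()
    )
    for plate in out["plate_id"].unique():
        if plate not in nt_means.index:
            raise ValueError(f"plate {plate!r} has no {nt_label} control wells")
        if nt_means[plate] == 0:
            raise ValueError(f"plate {plate!r}: NT control mean is zero")
    out["norm"] = out["count"].to_numpy(dtype=float) / nt_means.loc[out["plate_id"]].to_numpy()
    return out


@dataclass
class GIScore:
    """Signed genetic-interaction score for one gene in one contrast."""

    gene: str
    condition: str
    S: float
    p_value: float
    fdr_q: float | None
    mean_norm_mut: float
    mean_norm_ctrl: float
    n_reps: int


def gi_score(
    norm_mut: Sequence[float],
    norm_ctrl: Sequence[float],
    gene: str = "",
    condition: str = "",
    equal_var: bool = True,
) -> GIScore:
    """Signed -log10 p from a two-sided Student's t of mutant vs control.

    Pooled-variance by default; pass ``equal_var=False`` for Welch.
    Swapping arms flips the sign of S and leaves p unchanged.
    """
    mut = np.asarray(norm_mut, dtype=float)
    ctrl = np.asarray(norm_ctrl, dtype=float)
    s, p = signed_log10_t(mut, ctrl, equal_var=equal_var)
    return GIScore(
        gene=gene, condition=condition, S=s, p_value=p, fdr_q=None,
        mean_norm_mut=float(mut.mean()), mean_norm_ctrl=float(ctrl.mean()),
        n_reps=min(mut.size, ctrl.size),
    )


def score_screen(
    table: pd.DataFrame,
    mut_arm: tuple[str, str],
    ctrl_arm: tuple[str, str],
    nt_label: str = NT_LABEL,
    equal_var: bool = True,
    fdr_thresholds: Sequence[float] = (0.01, 0.05, 0.10),
) -> pd.DataFrame:
    """Full screen contrast: normalize, t-test per gene, BH across genes.

    ``mut_arm`` / ``ctrl_arm`` are (cell_line, condition) pairs; the
    default study design contrasts the mutant line in minimal media with
    the control line in full media.  Returns a volcano-ready frame with
    one row per gene (NT excluded) plus hit flags at each FDR threshold
    (hit = below threshold, any sign; direction column separates synthetic
    lethal from enhancer calls).
    """
    normed = normalize_to_nt(table, nt_label=nt_label)

    def _arm(frame: pd.DataFrame, arm: tuple[str, str]) -> pd.DataFrame:
        line, cond = arm
        sub = frame[(frame["cell_line"] == line) & (frame["condition"] == cond)]
        if sub.empty:
            raise ValueError(f"arm {arm!r} missing from plate table")
        return sub

    mut = _arm(normed, mut_arm)
    ctrl = _arm(normed, ctrl_arm)
    genes = sorted(set(mut["perturbation"]) & set(ctrl["perturbation"]) - {nt_label})
    if not genes:
        raise ValueError("no common perturbations between arms")
    rows = []
    mut_groups = {g: v["norm"].to_numpy() for g, v in mut.groupby("perturbation")}
    ctrl_groups = {g: v["norm"].to_numpy() for g, v in ctrl.groupby("perturbation")}
    for gene in genes:
        sc = gi_score(
            mut_groups[gene], ctrl_groups[gene], gene=gene,
            condition=mut_arm[1], equal_var=equal_var,
        )
        rows.append(
            {
                "gene": gene, "condition": mut_arm[1], "S": sc.S, "p": sc.p_value,
                "mean_norm_mut": sc.mean_norm_mut, "mean_norm_ctrl": sc.mean_norm_ctrl,
                "n_reps": sc.n_reps,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["direction"] = np.where(df["S"] < 0, "synthetic_lethal", np.where(df["S"] > 0, "enhancer", "neutral"))
    for thr in fdr_thresholds:
        df[f"hit_fdr_{int(round(thr * 100))}"] = df["q"] < thr
    return df.sort_values("S", kind="mergesort").reset_index(drop=True)


def condition_concordance(
    scores: pd.DataFrame,
    q_values: pd.DataFrame | None = None,
    fdr: float = 0.10,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise Pearson r between condition score vectors + per-gene labels.

    ``scores`` is a gene x condition matrix of S values.  A gene is a hit
    in a condition when q < fdr and S < 0 (q matrix optional; without it
    labels use S < 0 in every/some condition at face value is meaningless,
    so q_values is required for labeling).  Condition pairs sharing < 3
    genes get r = NaN.
    """
    conds = list(scores.columns)
    r = pd.DataFrame(np.nan, index=conds, columns=conds, dtype=float)
    for i, a in enumerate(conds):
        for b in conds[i:]:
            pair = scores[[a, b]].dropna()
            if len(pair) < 3 or a == b:
                val = 1.0 if a == b and len(pair) >= 1 else np.nan
            else:
                val = float(stats.pearsonr(pair[a], pair[b])[0])
            r.loc[a, b] = r.loc[b, a] = val
    if q_values is None:
        labels = pd.Series("unlabeled", index=scores.index)
        return r, labels
    hit = (q_values < fdr) & (scores < 0)
    n_hit = hit.sum(axis=1)
    labels = pd.Series(
        np.where(n_hit == len(conds), "consistent_sl", np.where(n_hit > 0, "condition_specific", "non_hit")),
        index=scores.index,
    )
    return r, labels


@dataclass
class DrugResponse:
    drug: str
    auc_ctrl: float
    auc_mut: float
    delta_auc: float


def drug_auc(
    dose_table: pd.DataFrame,
    ctrl_arm: str,
    mut_arm: str,
    n_doses: int = 4,
) -> pd.DataFrame:
    """Per-drug dose-response AUC and control-minus-mutant difference.

    ``dose_table`` columns: drug, arm, dose, norm_prolif (already
    normalized to vehicle).  AUC = sum of normalized proliferation over
    the dose series; each drug/arm must have exactly ``n_doses`` doses.
    Drugs are ranked by delta AUC descending (most mutant-selective
    first).
    """
    rows = []
    for drug, sub in dose_table.groupby("drug"):
        aucs = {}
        for arm in (ctrl_arm, mut_arm):
            arm_doses = sub[sub["arm"] == arm]
            if len(arm_doses) != n_doses:
                raise ValueError(
                    f"drug {drug!r} arm {arm!r}: expected {n_doses} doses, got {len(arm_doses)}"
                )
            aucs[arm] = float(arm_doses["norm_prolif"].sum())
        rows.append(
            {
                "drug": drug, "auc_ctrl": aucs[ctrl_arm], "auc_mut": aucs[mut_arm],
                "delta_auc": aucs[ctrl_arm] - aucs[mut_arm],
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["delta_auc", "drug"], ascending=[False, True], kind="mergesort"
    )
    out["rank"] = range(1, len(out) + 1)
    return out.reset_index(drop=True)
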
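"""Desk-scale benchmark computations: worked examples, statistical
calibration and planted-structure recovery.

Each function recomputes its quantity from scratch by running the package
on generated (or supplied) inputs, so the same code backs both the test
suite's acceptance checks and the standalone acceptance report script.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import (
    SimulationConfig,
    gen_emap_counts,
    gen_network_and_truth,
    gen_screen_counts,
    gen_studies,
)
from .cross_study import overlap_hypergeom, permutation_null_p
from .mcode import ModuleResult, extract_network_sl_genes, mcode_find_modules, novel_fraction
from .screen import score_screen
from .emap import average_replicates, pathway_bundle_test, suppressor_counts, zscore_plates
from .context import composite_rank
from .network import GeneSetCollection

CONDITIONS = ("full", "intermediate", "minimal")


# ---------------------------------------------------------------------------
# worked examples: printed counts run through the package machinery

def worked_example_novel_percent(n_network_genes: int = 105, n_novel: int = 68) -> int:
    """Percent of module genes absent from the input hit lists.

    Builds a module with ``n_network_genes`` members of which ``n_novel``
    are not in any input top-k list, then reads the fraction back through
    the extraction machinery.
    """
    genes = [f"G{i:03d}" for i in range(n_network_genes)]
    module = ModuleResult(genes=frozenset(genes), mcode_score=1.0)
    input_hits = set(genes[n_novel:])
    annotated = extract_network_sl_genes([module], input_hits=input_hits)
    return round(100 * novel_fraction(annotated))


def worked_example_hit_rate_percent(n_hits: int = 13, n_tested: int = 39, fdr: float = 0.10) -> int:
    """Percent of tested candidate genes called hits at the FDR cutoff.

    Builds a scored table in which exactly ``n_hits`` of ``n_tested``
    genes fall below the cutoff and counts through the same hit-flag
    logic used for screen output.
    """
    q = np.where(np.arange(n_tested) < n_hits, fdr / 2, min(1.0, fdr * 5))
    scored = pd.DataFrame(
        {"gene": [f"G{i:02d}" for i in range(n_tested)], "S": -1.0, "q": q}
    )
    hits = scored[(scored["q"] < fdr) & (scored["S"] < 0)]
    return round(100 * len(hits) / len(scored))


def worked_example_mean_suppressors(n_calls: int = 170, n_queries: int = 31) -> float:
    """Mean positive calls per query from a table with the printed totals."""
    base, extra = divmod(n_calls, n_queries)
    rows = []
    for qi in range(n_queries):
        n_pos = base + (1 if qi < extra else 0)
        for ai in range(max(n_pos, 1) + 2):
            rows.append(
                {
                    "query_gene": f"Q{qi:02d}",
                    "array_gene": f"A{ai:02d}",
                    "z_mean": 3.0 if ai < n_pos else 0.0,
                }
            )
    counts, mean = suppressor_counts(pd.DataFrame(rows))
    assert int(counts.sum()) == n_calls and len(counts) == n_queries
    return round(mean, 1)


# ---------------------------------------------------------------------------
# statistical calibration

def permutation_p_uniformity(n_datasets: int = 200, n_perm: int = 1000, seed: int = 0) -> dict:
    """KS test of permutation p-values under a null world (no planted effect)."""
    ps = []
    for i in range(n_datasets):
        cfg = SimulationConfig(
            seed=seed + i, n_genes=200, planted_complexes=[(5, 0.5)],
            background_edge_prob=0.01, n_studies=2, tested_fraction=0.8,
            hit_k=30, pathway_effect=0.0, detection_prob=0.0,
        )
        net, truth = gen_network_and_truth(cfg)
        s1, s2 = gen_studies(cfg, truth)
        perm = permutation_null_p(net, s1, s2, k=30, n_perm=n_perm, seed=seed + i + 7)
        ps.append(perm.p_empirical)
    ks = stats.kstest(ps, "uniform")
    return {"n": n_datasets, "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue)}


def screen_type_one_error(n_seeds: int = 200, n_genes: int = 25, seed: int = 0) -> dict:
    """Fraction of null genes with p < 0.05; NT wells are plentiful so the
    shared normalization noise is negligible (see decisions notes)."""
    n_sig = n_tot = 0
    ps = []
    for i in range(n_seeds):
        cfg = SimulationConfig(seed=seed + i, count_cv=0.1, n_nt_wells=256)
        genes = [f"G{i:02d}" for i in range(n_genes)]
        table = gen_screen_counts(cfg, genes, ["min"], ["MUT", "CTRL"])
        scored = score_screen(table, mut_arm=("MUT", "min"), ctrl_arm=("CTRL", "min"))
        n_sig += int((scored["p"] < 0.05).sum())
        n_tot += len(scored)
        ps.extend(scored["p"].tolist())
    ks = stats.kstest(ps, "uniform")
    return {"rate": n_sig / n_tot, "n_tests": n_tot, "ks_p": float(ks.pvalue)}


def bundle_false_positive_rate(n_seeds: int = 100, seed: int = 0, alpha: float = 0.01) -> dict:
    """Bundle-test significance rate on null N(0,1) member scores."""
    rng = np.random.default_rng(seed)
    arrays = [f"A{i:02d}" for i in range(60)]
    paths = GeneSetCollection()
    for j in range(12):
        paths.add(f"PW{j:02d}", arrays[j * 5 : j * 5 + 5])
    n_sig = n_tot = 0
    for _ in range(n_seeds):
        rows = [
            {"query_gene": f"Q{q}", "array_gene": a, "z_mean": rng.standard_normal()}
            for q in range(5)
            for a in arrays
        ]
        out = pathway_bundle_test(pd.DataFrame(rows), paths, alpha=alpha)
        n_sig += int(out["significant"].sum())
        n_tot += len(out)
    return {"rate": n_sig / n_tot, "n_bundles": n_tot}


# ---------------------------------------------------------------------------
# planted-structure recovery

def clique_recovery_rate(n_seeds: int = 100, seed: int = 0) -> dict:
    """Fraction of worlds where the planted 8-clique is recovered at
    Jaccard >= 0.9 among 100 background genes."""
    n_success = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            seed=seed + i, n_genes=108, planted_complexes=[(8, 1.0)], background_edge_prob=0.05
        )
        net, truth = gen_network_and_truth(cfg)
        planted = truth.genes("PLANTED_1")
        best = 0.0
        for mod in mcode_find_modules(net):
            jac = len(mod.genes & planted) / len(mod.genes | planted)
            best = max(best, jac)
        if best >= 0.9:
            n_success += 1
    return {"rate": n_success / n_seeds, "n": n_seeds}


def convergence_signature_rate(n_seeds: int = 100, seed: int = 0, n_perm: int = 500) -> dict:
    """Fraction of pathway-convergent worlds (delta = 3, q = 0.4) showing
    permutation p <= 0.01 together with gene-overlap p > 0.05."""
    n_both = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            seed=seed + i, n_genes=800, planted_complexes=[(24, 1.0)] * 3,
            background_edge_prob=0.0001, n_studies=2, tested_fraction=0.4,
            hit_k=60, pathway_effect=3.0, detection_prob=0.4,
        )
        net, truth = gen_network_and_truth(cfg)
        s1, s2 = gen_studies(cfg, truth)
        ov = overlap_hypergeom(s1, s2, k=cfg.hit_k)
        perm = permutation_null_p(net, s1, s2, k=cfg.hit_k, n_perm=n_perm, seed=seed + i + 1)
        if perm.p_empirical <= 0.01 and ov.p_value > 0.05:
            n_both += 1
    return {"rate": n_both / n_seeds, "n": n_seeds}


def context_rank_recovery(n_seeds: int = 100, seed: int = 0) -> dict:
    """Fraction of worlds where the planted context-independent gene
    (deficit in every condition, no suppressors) attains rank 1."""
    n_rank1 = 0
    sl = [f"S{i}" for i in range(8)]
    ctx = sl[0]
    arrays = [f"A{i:02d}" for i in range(20)]
    for i in range(n_seeds):
        cfg = SimulationConfig(seed=seed + i, count_cv=0.1, sl_effect=0.5, suppressor_rescue=1.0)
        effects = {(g, "MUT", "minimal"): 0.5 for g in sl}
        for cond in CONDITIONS:
            effects[(ctx, "MUT", cond)] = 0.5
        table = gen_screen_counts(cfg, sl, list(CONDITIONS), ["MUT", "CTRL"], effects)
        s_mat = {}
        for cond in CONDITIONS:
            scored = score_screen(table, mut_arm=("MUT", cond), ctrl_arm=("CTRL", "full"))
            s_mat[cond] = scored.set_index("gene")["S"]
        s_mat = pd.DataFrame(s_mat)
        pairs = [(g, arrays[j + 1]) for j, g in enumerate(sl) if g != ctx]
        emap = gen_emap_counts(cfg, sl, arrays, pairs, {g: 0.5 for g in sl})
        counts, _ = suppressor_counts(average_replicates(zscore_plates(emap)))
        entries = pd.DataFrame(
            {
                "gene": sl,
                "cellular_score": [float(s_mat.loc[g].var(ddof=1)) for g in sl],
                "genetic_score": [int(counts.get(g, 0)) for g in sl],
            }
        )
        ranked = composite_rank(entries).set_index("gene")
        if ranked.loc[ctx, "rank"] == 1:
            n_rank1 += 1
    return {"rate": n_rank1 / n_seeds, "n": n_seeds}


def emap_suppressor_recovery(n_seeds: int = 100, seed: int = 0) -> dict:
    """Sensitivity and FDR for planted suppressor pairs at cv = 0.1."""
    tp = fn = fp = 0
    queries = [f"Q{i}" for i in range(6)]
    arrays = [f"A{i:02d}" for i in range(30)]
    pairs = [(q, arrays[2 * j]) for j, q in enumerate(queries)]
    planted = set(pairs)
    for i in range(n_seeds):
        cfg = SimulationConfig(seed=seed + i, count_cv=0.1, suppressor_rescue=1.0)
        emap = gen_emap_counts(cfg, queries, arrays, pairs, {q: 0.5 for q in queries})
        scores = average_replicates(zscore_plates(emap))
        pos = {
            (r.query_gene, r.array_gene)
            for r in scores[scores["z_mean"] > 2].itertuples()
        }
        tp += len(pos & planted)
        fn += len(planted - pos)
        fp += len(pos - planted)
    return {
        "sensitivity": tp / (tp + fn),
        "fdr": fp / max(tp + fp, 1),
        "n_planted": tp + fn,
    }


# ---------------------------------------------------------------------------
# supplementary-data recomputation (real mode; files supplied by the user)

SUPPLEMENTARY_DIR = Path("data/supplementary")
ISOGENIC_FILE = "isogenic_screen_counts.csv"
EMAP_FILE = "emap_scores.tsv"


def isogenic_hits_at_fdr(
    counts_path: str | Path,
    mut_arm: tuple[str, str] = ("KRAS_G12D", "minimal"),
    ctrl_arm: tuple[str, str] = ("eGFP", "full"),
    fdr: float = 0.05,
) -> int:
    """Number of genes below the FDR cutoff in the isogenic screen contrast.

    Expects a long-form plate CSV with the standard plate-table columns.
    """
    table = pd.read_csv(counts_path)
    scored = score_screen(table, mut_arm=mut_arm, ctrl_arm=ctrl_arm)
    return int((scored["q"] < fdr).sum())


def emap_call_counts(scores_path: str | Path, cutoff: float = 2.0) -> tuple[int, int]:
    """(positive, negative) interaction counts from a mean-Z score TSV
    with columns query_gene, array_gene, z_mean."""
    scores = pd.read_csv(scores_path, sep="\t")
    n_pos = int((scores["z_mean"] > cutoff).sum())
    n_neg = int((scores["z_mean"] < -cutoff).sum())
    return n_pos, n_neg
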
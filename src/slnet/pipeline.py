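"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes the stages in dependency order on a run
directory, with a single global seed expanded into independent per-stage
streams.  Each output directory carries a ``provenance.json`` embedding
the configuration hash, seed and package version so runs are auditable
and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .network import GeneSetCollection, restrict_to_seed_incident
from .cross_study import overlap_hypergeom, permutation_null_p
from .mcode import (
    McodeParams,
    enrich_module,
    extract_network_sl_genes,
    filter_multistudy_modules,
    mcode_find_modules,
)
from .holdout import accuracy_at_percentile, percentile_rank
from .screen import condition_concordance, score_screen
from .emap import average_replicates, call_interactions, pathway_bundle_test, suppressor_counts, zscore_plates
from .context import composite_rank, group_rank_test
from .simulate import SimulationConfig, gen_emap_counts, gen_network_and_truth, gen_screen_counts, gen_studies

logger = logging.getLogger(__name__)

CELL_LINES = ("CTRL", "MUT")
CONDITIONS = ("full", "intermediate", "minimal")

STAGES = ("simulate", "integrate", "cluster", "validate", "score-screen", "score-emap", "rank-context")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "slnet_run"
    stages: tuple[str, ...] = STAGES
    # simulation world
    n_genes: int = 120
    planted_complexes: tuple[tuple[int, float], ...] = ((8, 0.9), (8, 0.9), (6, 0.9))
    background_edge_prob: float = 0.01
    n_studies: int = 3
    tested_fraction: float = 0.8
    hit_k: int = 25
    pathway_effect: float = 3.0
    detection_prob: float = 0.4
    count_cv: float = 0.1
    sl_effect: float = 0.5
    suppressor_rescue: float = 1.0
    # analysis knobs
    k: int = 25
    n_perm: int = 1000
    null_mode: str = "gene-resample"
    mcode: McodeParams = field(default_factory=McodeParams)
    fdr_thresholds: tuple[float, ...] = (0.01, 0.05, 0.10)
    emap_cutoff: float = 2.0
    bundle_alpha: float = 0.01
    accuracy_cutoffs: tuple[float, ...] = (1.0, 5.0)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if "mcode" in raw and isinstance(raw["mcode"], dict):
            raw["mcode"] = McodeParams(**raw["mcode"])
        for key in ("planted_complexes",):
            if key in raw:
                raw[key] = tuple(tuple(x) for x in raw[key])
        for key in ("stages", "fdr_thresholds", "accuracy_cutoffs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        return cfg

    def config_hash(self) -> str:
        def _default(o):
            return asdict(o) if hasattr(o, "__dataclass_fields__") else str(o)

        fields_dict = asdict(self)
        fields_dict.pop("out_dir", None)  # hash the analytic config, not the destination
        payload = json.dumps(fields_dict, sort_keys=True, default=_default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def sim_config(self, seed_offset: int = 0) -> SimulationConfig:
        return SimulationConfig(
            seed=self.seed + seed_offset,
            n_genes=self.n_genes,
            planted_complexes=self.planted_complexes,
            background_edge_prob=self.background_edge_prob,
            n_studies=self.n_studies,
            tested_fraction=self.tested_fraction,
            hit_k=self.hit_k,
            pathway_effect=self.pathway_effect,
            detection_prob=self.detection_prob,
            count_cv=self.count_cv,
            sl_effect=self.sl_effect,
            suppressor_rescue=self.suppressor_rescue,
        )


def _write_provenance(out: Path, cfg: PipelineConfig, stage: str) -> None:
    (out / "provenance.json").write_text(
        json.dumps(
            {"stage": stage, "seed": cfg.seed, "config_hash": cfg.config_hash(), "version": __version__},
            indent=2,
        )
    )


class PipelineState:
    """In-memory handles passed between stages."""

    def __init__(self) -> None:
        self.network = None
        self.truth = None
        self.studies = None
        self.screen_counts = None
        self.emap_counts = None
        self.sl_genes: list[str] = []
        self.context_gene: str | None = None
        self.suppressor_pairs: list[tuple[str, str]] = []
        self.network_sl: dict[str, dict] = {}
        self.score_tables: dict[str, pd.DataFrame] = {}
        self.emap_scores: pd.DataFrame | None = None


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the requested stages in dependency order on synthetic inputs.

    Returns the run directory.  A stage failure raises with the stage
    name; identical config + seed reproduces identical outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state = PipelineState()
    runners = {
        "simulate": _stage_simulate,
        "integrate": _stage_integrate,
        "cluster": _stage_cluster,
        "validate": _stage_validate,
        "score-screen": _stage_score_screen,
        "score-emap": _stage_score_emap,
        "rank-context": _stage_rank_context,
    }
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        stage_dir = out / stage.replace("-", "_")
        stage_dir.mkdir(exist_ok=True)
        logger.info("running stage %s", stage)
        try:
            runners[stage](cfg, state, stage_dir)
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        _write_provenance(stage_dir, cfg, stage)
    return out


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise RuntimeError(message)


def _ensure_world(cfg: PipelineConfig, state: PipelineState) -> None:
    if state.network is None:
        _stage_simulate(cfg, state, None)


def _stage_simulate(cfg: PipelineConfig, state: PipelineState, out: Path | None) -> None:
    sim = cfg.sim_config()
    net, truth = gen_network_and_truth(sim)
    studies = gen_studies(sim, truth)
    complexes = [sorted(truth.genes(n)) for n in truth.names()]
    sl_genes = complexes[0]
    # one designated context-independent gene: deficit in every condition,
    # no suppressors; the rest of the complex is minimal-media specific
    context_gene = sl_genes[0]
    effects: dict[tuple[str, str, str], float] = {}
    for gene in sl_genes:
        effects[(gene, "MUT", "minimal")] = cfg.sl_effect
    for cond in CONDITIONS:
        effects[(context_gene, "MUT", cond)] = cfg.sl_effect
    screen_genes = sorted(truth.all_genes())
    screen_counts = gen_screen_counts(sim, screen_genes, list(CONDITIONS), list(CELL_LINES), effects)

    queries = sl_genes
    arrays = sorted(set(net.nodes) - set(queries))[: max(20, len(queries) * 3)]
    rng = sim.rng("emap", 9999)
    suppressor_pairs = []
    for q in queries[1:]:  # the context-independent gene gets none
        a = arrays[int(rng.integers(len(arrays)))]
        suppressor_pairs.append((q, a))
    single_effects = {g: cfg.sl_effect for g in queries}
    emap_counts = gen_emap_counts(sim, queries, arrays, suppressor_pairs, single_effects)

    state.network, state.truth, state.studies = net, truth, studies
    state.screen_counts, state.emap_counts = screen_counts, emap_counts
    state.sl_genes, state.context_gene = sl_genes, context_gene
    state.suppressor_pairs = suppressor_pairs
    if out is not None:
        net.to_sif_tsv(out / "network.tsv")
        truth.write_gmt(out / "truth.gmt")
        pd.concat(
            [
                pd.DataFrame({"study_id": st.study_id, "gene": list(st.scores), "score": list(st.scores.values())})
                for st in studies
            ]
        ).to_csv(out / "studies.tsv", sep="\t", index=False)
        screen_counts.to_csv(out / "screen_counts.csv", index=False)
        emap_counts.to_csv(out / "emap_counts.csv", index=False)
        (out / "planted.json").write_text(
            json.dumps(
                {
                    "sl_genes": sl_genes,
                    "context_independent_gene": context_gene,
                    "suppressor_pairs": suppressor_pairs,
                },
                indent=2,
            )
        )


def _stage_integrate(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    _ensure_world(cfg, state)
    rows = []
    studies = state.studies
    for i, sa in enumerate(studies):
        for sb in studies[i + 1 :]:
            ov = overlap_hypergeom(sa, sb, k=cfg.k)
            perm = permutation_null_p(
                state.network, sa, sb, k=cfg.k, n_perm=cfg.n_perm,
                seed=cfg.seed + 101, null_mode=cfg.null_mode,
            )
            rows.append(
                {
                    "study_a": sa.study_id, "study_b": sb.study_id,
                    "overlap_x": ov.x, "overlap_p": ov.p_value,
                    "edges_observed": perm.observed, "perm_p": perm.p_empirical,
                    "perm_p_label": perm.p_label, "fold_over_null": perm.fold_over_null,
                    "null_mode": perm.null_mode, "n_perm": perm.n_perm,
                }
            )
    pd.DataFrame(rows).to_csv(out / "cross_study.tsv", sep="\t", index=False)


def _stage_cluster(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    _ensure_world(cfg, state)
    all_hits = set()
    for st in state.studies:
        all_hits |= set(st.hits)
    sub = restrict_to_seed_incident(state.network, all_hits)
    modules = mcode_find_modules(sub, cfg.mcode)
    filtered = filter_multistudy_modules(modules, state.studies, min_studies=2)
    background = sorted(state.network.nodes)
    for mod in filtered:
        mod.enrichments = enrich_module(mod, state.truth, background)
    annotated = extract_network_sl_genes(filtered, input_hits=all_hits)
    state.network_sl = annotated
    payload = [
        {
            "genes": sorted(m.genes), "score": m.mcode_score,
            "studies_present": sorted(m.studies_present), "enrichments": m.enrichments,
        }
        for m in filtered
    ]
    (out / "modules.json").write_text(json.dumps(payload, indent=2))
    (out / "correction.json").write_text(
        json.dumps({"enrichment_correction": "benjamini-hochberg"})
    )
    gmt = GeneSetCollection()
    for i, m in enumerate(filtered, 1):
        gmt.add(f"MODULE_{i}", sorted(m.genes), description=f"score={m.mcode_score:.3f}")
    if len(gmt):
        gmt.write_gmt(out / "modules.gmt")
    pd.DataFrame(
        [
            {"gene": g, "modules": ",".join(map(str, rec["modules"])), "was_in_input_hits": rec["was_in_input_hits"]}
            for g, rec in sorted(annotated.items())
        ]
    ).to_csv(out / "network_sl_genes.tsv", sep="\t", index=False)


def _stage_validate(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    _ensure_world(cfg, state)
    _require(bool(state.network_sl), "cluster stage must run before validate")
    holdout_sim = cfg.sim_config(seed_offset=7717)
    holdout = gen_studies(holdout_sim, state.truth)[0]
    table = percentile_rank(holdout.scores)
    rows = []
    rng = np.random.default_rng(cfg.seed + 404)
    candidates = sorted(state.network_sl)
    random_set = rng.choice(sorted(table), size=min(len(candidates), len(table)), replace=False)
    for cutoff in cfg.accuracy_cutoffs:
        for category, genes in (("network_sl", candidates), ("random", random_set)):
            acc = accuracy_at_percentile(genes, table, cutoff=cutoff)
            rows.append(
                {
                    "category": category, "study": holdout.study_id, "cutoff": cutoff,
                    "n_tested": acc.n_tested, "n_top": acc.n_top,
                    "accuracy": acc.accuracy if acc.accuracy is not None else float("nan"),
                }
            )
    pd.DataFrame(rows).to_csv(out / "holdout_accuracy.tsv", sep="\t", index=False)


def _stage_score_screen(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    _ensure_world(cfg, state)
    tables = {}
    for cond in CONDITIONS:
        scored = score_screen(
            state.screen_counts, mut_arm=("MUT", cond), ctrl_arm=("CTRL", "full"),
            fdr_thresholds=cfg.fdr_thresholds,
        )
        tables[cond] = scored
        scored.to_csv(out / f"scores_{cond}.tsv", sep="\t", index=False)
    state.score_tables = tables
    s_mat = pd.DataFrame({c: t.set_index("gene")["S"] for c, t in tables.items()})
    q_mat = pd.DataFrame({c: t.set_index("gene")["q"] for c, t in tables.items()})
    r, labels = condition_concordance(s_mat, q_mat, fdr=max(cfg.fdr_thresholds))
    r.to_csv(out / "condition_correlation.tsv", sep="\t")
    labels.rename("label").to_csv(out / "condition_labels.tsv", sep="\t")


def _stage_score_emap(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    _ensure_world(cfg, state)
    z = zscore_plates(state.emap_counts)
    scores = average_replicates(z)
    called, summary = call_interactions(scores, cutoff=cfg.emap_cutoff)
    counts, mean_suppressors = suppressor_counts(scores, cutoff=cfg.emap_cutoff)
    bundles = pathway_bundle_test(scores, state.truth, alpha=cfg.bundle_alpha)
    state.emap_scores = scores
    called.to_csv(out / "emap_scores.tsv", sep="\t", index=False)
    counts.rename("n_suppressors").to_csv(out / "suppressor_counts.tsv", sep="\t")
    bundles.to_csv(out / "bundles.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(
        json.dumps({**summary, "mean_suppressors_per_query": mean_suppressors}, indent=2)
    )


def _stage_rank_context(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    _ensure_world(cfg, state)
    _require(bool(state.score_tables), "score-screen stage must run before rank-context")
    _require(state.emap_scores is not None, "score-emap stage must run before rank-context")
    s_mat = pd.DataFrame({c: t.set_index("gene")["S"] for c, t in state.score_tables.items()})
    counts, _ = suppressor_counts(state.emap_scores, cutoff=cfg.emap_cutoff)
    genes = [g for g in s_mat.index if g in counts.index]
    entries = pd.DataFrame(
        {
            "gene": genes,
            "cellular_score": [float(s_mat.loc[g].var(ddof=1)) for g in genes],
            "genetic_score": [int(counts[g]) for g in genes],
            "category": ["network_sl" if g in state.network_sl else "other" for g in genes],
        }
    )
    ranked = composite_rank(entries)
    ranked.to_csv(out / "context_ranking.tsv", sep="\t", index=False)
    groups = ranked.groupby("category")["rank"]
    if {"network_sl", "other"} <= set(ranked["category"]):
        p = group_rank_test(groups.get_group("network_sl"), groups.get_group("other"))
        (out / "group_test.json").write_text(json.dumps({"rank_sum_p_network_vs_other": p}))
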
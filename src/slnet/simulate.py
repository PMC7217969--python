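"""Synthetic-data generators for every pipeline input.

A configured world plants dense gene complexes in a random background
network, lets independent screens each detect complex members with
probability q (producing pathway-level but weak gene-level convergence),
and emits plate-count tables for single-gene, combinatorial and drug
screens with lognormal count noise.  Every generator is a pure function of
(config, stage tag): the same seed reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import GeneSetCollection, InteractionNetwork, SYNTHETIC
from .cross_study import ScreenStudy, top_k_hits

# per-stage entropy tags: toggling one stage never perturbs another's stream
_STAGE_TAGS = {"network": 11, "studies": 23, "screen": 37, "emap": 53, "drug": 71}


@dataclass
class SimulationConfig:
    """Knobs for one synthetic world; probabilities validated on creation."""

    seed: int = 0
    n_genes: int = 120
    planted_complexes: Sequence[tuple[int, float]] = ((8, 0.9), (8, 0.9), (6, 0.9))
    background_edge_prob: float = 0.01
    n_studies: int = 3
    tested_fraction: float = 0.8
    hit_k: int = 25
    pathway_effect: float = 3.0  # score shift delta for detected SL-complex genes
    detection_prob: float = 0.4  # per-study Bernoulli detection q of each member
    n_replicates: int = 4
    count_cv: float = 0.1  # lognormal sigma of count noise
    base_count: float = 1000.0
    sl_effect: float = 0.5  # proliferation multiplier for planted SL genes
    suppressor_rescue: float = 1.0
    n_nt_wells: int = 4

    def __post_init__(self) -> None:
        for name, p in (
            ("background_edge_prob", self.background_edge_prob),
            ("tested_fraction", self.tested_fraction),
            ("detection_prob", self.detection_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for size, p in self.planted_complexes:
            if not 0.0 <= p <= 1.0:
                raise ValueError("within_edge_prob must be in [0, 1]")
            if size < 1:
                raise ValueError("complex sizes must be positive")
        if min(self.n_genes, self.n_studies, self.hit_k, self.n_replicates) < 1:
            raise ValueError("counts must be positive")
        if self.count_cv < 0 or self.base_count <= 0:
            raise ValueError("count noise parameters invalid")

    def rng(self, stage: str, extra: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STAGE_TAGS[stage], extra])


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def gen_network_and_truth(cfg: SimulationConfig) -> tuple[InteractionNetwork, GeneSetCollection]:
    """Plant near-clique complexes over Erdos-Renyi background edges.

    Complex memberships are disjoint, drawn from the head of the gene
    universe after a seeded shuffle; ground truth is returned as a gene-set
    collection whose universe is the full gene list.
    """
    total_planted = sum(size for size, _ in cfg.planted_complexes)
    if total_planted > cfg.n_genes:
        raise ValueError(
            f"planted complex sizes ({total_planted}) exceed n_genes ({cfg.n_genes})"
        )
    rng = cfg.rng("network")
    genes = _gene_names(cfg.n_genes)
    order = rng.permutation(cfg.n_genes)
    net = InteractionNetwork()
    for g in genes:
        net.add_node(g)
    truth = GeneSetCollection(universe=frozenset(genes))
    cursor = 0
    planted_pairs: set[frozenset[str]] = set()
    for ci, (size, p_within) in enumerate(cfg.planted_complexes, 1):
        members = sorted(genes[order[j]] for j in range(cursor, cursor + size))
        cursor += size
        truth.add(f"PLANTED_{ci}", members, description=f"planted complex {ci}")
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                planted_pairs.add(frozenset((a, b)))
                if rng.random() < p_within:
                    net.add_edge(a, b, source=SYNTHETIC)
    if cfg.background_edge_prob > 0:
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                if frozenset((a, b)) in planted_pairs:
                    continue
                if rng.random() < cfg.background_edge_prob:
                    net.add_edge(a, b, source=SYNTHETIC)
    return net, truth


def gen_studies(cfg: SimulationConfig, truth: GeneSetCollection) -> list[ScreenStudy]:
    """Independent screens over random subsets of the universe.

    Per-gene score = N(0, 1) noise minus the pathway effect delta for each
    planted-complex member the study detects (independent Bernoulli(q) per
    member per study).  Lower = stronger; hits = top ``hit_k`` ascending.
    """
    if len(truth) == 0:
        raise ValueError("empty ground-truth collection")
    universe = sorted(truth.universe or truth.all_genes())
    n_tested = max(2, int(round(cfg.tested_fraction * len(universe))))
    if cfg.hit_k > n_tested:
        raise ValueError(f"hit_k={cfg.hit_k} exceeds {n_tested} tested genes")
    studies = []
    for si in range(cfg.n_studies):
        rng = cfg.rng("studies", si)
        tested = sorted(rng.choice(universe, size=n_tested, replace=False).tolist())
        scores = dict(zip(tested, rng.standard_normal(n_tested)))
        for _, _, members in truth.items():
            for gene in sorted(members):
                if gene in scores and rng.random() < cfg.detection_prob:
                    scores[gene] -= cfg.pathway_effect
        study = ScreenStudy(study_id=f"study{si + 1}", scores=scores)
        study.hits = top_k_hits(study, cfg.hit_k)
        studies.append(study)
    return studies


def _noisy_counts(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    """Lognormal counts with median base*effect; cv=0 is the exact limit."""
    mean = np.asarray(mean, dtype=float)
    if cv == 0:
        return mean.copy()
    return mean * np.exp(rng.standard_normal(mean.shape) * cv)


def gen_screen_counts(
    cfg: SimulationConfig,
    genes: Sequence[str],
    conditions: Sequence[str],
    cell_lines: Sequence[str],
    effects: Mapping[tuple[str, str, str], float] | None = None,
) -> pd.DataFrame:
    """Plate counts for the single-gene screens: one plate per
    (cell line, condition), each gene and the NT control in replicate.

    ``effects`` maps (gene, cell_line, condition) to a multiplicative
    proliferation effect (default 1 everywhere = global null).
    """
    if cfg.n_nt_wells < 1:
        raise ValueError("configuration must include non-targeting control wells")
    effects = dict(effects or {})
    rows = []
    for li, line in enumerate(cell_lines):
        for ci, cond in enumerate(conditions):
            plate = f"{line}_{cond}"
            rng = cfg.rng("screen", li * 1000 + ci)
            well = 0
            for gene in genes:
                eff = effects.get((gene, line, cond), 1.0)
                means = np.full(cfg.n_replicates, cfg.base_count * eff)
                counts = _noisy_counts(rng, means, cfg.count_cv)
                for rep in range(cfg.n_replicates):
                    well += 1
                    rows.append(
                        (plate, f"W{well:04d}", line, cond, gene, rep + 1, counts[rep])
                    )
            nt_counts = _noisy_counts(
                rng, np.full(cfg.n_nt_wells, cfg.base_count), cfg.count_cv
            )
            for rep in range(cfg.n_nt_wells):
                well += 1
                rows.append((plate, f"W{well:04d}", line, cond, "NT", rep + 1, nt_counts[rep]))
    return pd.DataFrame(
        rows,
        columns=["plate_id", "well", "cell_line", "condition", "perturbation", "replicate", "count"],
    )


def gen_emap_counts(
    cfg: SimulationConfig,
    queries: Sequence[str],
    arrays: Sequence[str],
    suppressor_pairs: Iterable[tuple[str, str]] = (),
    single_effects: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Combinatorial counts: one plate per query, full array in replicate.

    Double-knockdown expectation is the product of single effects
    (multiplicative neutrality); configured suppressor (query, array)
    pairs are rescued toward 1 by ``suppressor_rescue``.
    """
    single_effects = dict(single_effects or {})
    suppressors = set()
    for q, a in suppressor_pairs:
        if q not in queries or a not in arrays:
            raise ValueError(f"suppressor pair {(q, a)!r} not in queries x arrays")
        suppressors.add((q, a))
    rows = []
    for qi, query in enumerate(queries):
        rng = cfg.rng("emap", qi)
        plate = f"EMAP_{query}"
        eff_q = single_effects.get(query, 1.0)
        well = 0
        for array in arrays:
            eff = eff_q * single_effects.get(array, 1.0)
            if (query, array) in suppressors:
                eff = eff + cfg.suppressor_rescue * (1.0 - eff)
            means = np.full(cfg.n_replicates, cfg.base_count * eff)
            counts = _noisy_counts(rng, means, cfg.count_cv)
            for rep in range(cfg.n_replicates):
                well += 1
                rows.append((plate, f"W{well:04d}", query, array, rep + 1, counts[rep]))
    return pd.DataFrame(
        rows, columns=["plate_id", "well", "query_gene", "array_gene", "replicate", "count"]
    )


def gen_drug_counts(
    cfg: SimulationConfig,
    drugs: Sequence[str],
    arms: Sequence[str],
    n_doses: int = 4,
    effects: Mapping[tuple[str, str], Sequence[float]] | None = None,
    cv: float = 0.02,
) -> pd.DataFrame:
    """Dose-response table: per (drug, arm) one normalized value per dose.

    ``effects`` maps (drug, arm) to per-dose proliferation fractions
    (default all 1 = inert compound); noise is lognormal at ``cv``.
    """
    effects = dict(effects or {})
    rows = []
    for di, drug in enumerate(drugs):
        rng = cfg.rng("drug", di)
        for arm in arms:
            base = np.asarray(effects.get((drug, arm), np.ones(n_doses)), dtype=float)
            if base.size != n_doses:
                raise ValueError(f"drug {drug!r} arm {arm!r}: need {n_doses} dose effects")
            vals = _noisy_counts(rng, base, cv)
            for dose_i, v in enumerate(vals, 1):
                rows.append((drug, arm, dose_i, float(v)))
    return pd.DataFrame(rows, columns=["drug", "arm", "dose", "norm_prolif"])
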
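"""Seeded synthetic ingredient/target/pathway mappings and LC-MS peak tables.

The generator emulates the annotation structure behind the ASH
topoisomerase-I study: a handful of screened ingredients, a target panel of
SEA-style predictions (~160 proteins), and DAVID/KEGG-style pathway
annotations (~90 pathways).  Two idealizations shape it:

* Bernoulli annotation with a broad/narrow target mixture.  Real pathway
  annotation is heavily skewed — a minority of promiscuous signaling
  proteins sit in dozens of pathways and generate most pathway-pathway
  co-membership.  Each target is therefore "broad" with probability
  ``broad_target_fraction`` (per-pathway inclusion probability
  ``p_broad_target_pathway``), otherwise "narrow"
  (``p_target_pathway``).  A plain single-probability model cannot produce
  both the observed ingredient-pathway edge count and the observed
  pathway-pathway density at once.
* Hub structure.  A fraction of ingredients (``hub_fraction``) is forced to
  cover every pathway, mirroring the two main active ingredients
  (isorhamnetin/quercetin, bipartite degree 90), and a few "hub" pathways
  receive boosted annotation probability so centrality concentrates on
  them, as it does on hsa05208.

Targets whose pathway draw comes up empty are re-drawn once and then
dropped from the target->pathway map (logged); they may still appear as
predicted targets of ingredients.  Identical seeds give identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotation import CompoundRecord, PeakRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "generate_mappings",
    "generate_peak_table",
    "expected_edge_counts",
    "BUILTIN_FORMULAS",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the mapping generator (defaults calibrated to the
    published aggregates: 160 targets, 90 pathways, ~479 ingredient-pathway
    edges, pathway-pathway density ~0.77)."""

    n_ingredients: int = 6
    n_targets: int = 160
    n_pathways: int = 90
    p_ingredient_target: float = 0.25
    p_target_pathway: float = 0.02
    broad_target_fraction: float = 0.10
    p_broad_target_pathway: float = 0.30
    hub_fraction: float = 2 / 6
    hub_pathway_fraction: float = 2 / 90
    hub_pathway_boost: float = 2.5
    ensure_pathway_coverage: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_ingredient_target",
            "p_target_pathway",
            "broad_target_fraction",
            "p_broad_target_pathway",
            "hub_fraction",
            "hub_pathway_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_ingredients", "n_targets", "n_pathways"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.hub_pathway_boost < 0:
            raise ValueError("hub_pathway_boost must be >= 0")

    @property
    def ingredient_ids(self) -> list[str]:
        return [f"ING{i + 1:02d}" for i in range(self.n_ingredients)]

    @property
    def target_ids(self) -> list[str]:
        return [f"T{i + 1:03d}" for i in range(self.n_targets)]

    @property
    def pathway_ids(self) -> list[str]:
        return [f"hsa{i + 1:05d}" for i in range(self.n_pathways)]

    @property
    def n_hub_ingredients(self) -> int:
        return int(round(self.hub_fraction * self.n_ingredients))

    @property
    def n_hub_pathways(self) -> int:
        return int(round(self.hub_pathway_fraction * self.n_pathways))

    def pathway_probs(self, broad: bool) -> np.ndarray:
        """Per-pathway inclusion probability for one target of the given
        kind, with the hub-pathway boost applied to the leading pathways."""
        base = self.p_broad_target_pathway if broad else self.p_target_pathway
        probs = np.full(self.n_pathways, base)
        probs[: self.n_hub_pathways] = np.minimum(1.0, base * self.hub_pathway_boost)
        return probs


def generate_mappings(
    cfg: GeneratorConfig,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Draw an (ingredient->targets, target->pathways) pair from ``cfg``.

    Hub ingredients are post-processed to cover every pathway (their
    bipartite degree equals ``n_pathways``); with
    ``ensure_pathway_coverage`` every pathway keeps at least one annotated
    target so full coverage is attainable.
    """
    rng = np.random.default_rng(cfg.seed)
    ingredients = cfg.ingredient_ids
    targets = cfg.target_ids
    pathways = np.array(cfg.pathway_ids)

    # target -> pathways with one re-draw for empty sets
    broad_mask = rng.random(cfg.n_targets) < cfg.broad_target_fraction
    tpm: dict[str, set[str]] = {}
    dropped = []
    for t_idx, target in enumerate(targets):
        probs = cfg.pathway_probs(bool(broad_mask[t_idx]))
        chosen = rng.random(cfg.n_pathways) < probs
        if not chosen.any():
            chosen = rng.random(cfg.n_pathways) < probs
        if chosen.any():
            tpm[target] = set(pathways[chosen])
        else:
            dropped.append(target)
    if dropped:
        logger.info(
            "dropped %d target(s) with no pathway annotation after re-draw: %s",
            len(dropped),
            ", ".join(dropped[:8]) + ("..." if len(dropped) > 8 else ""),
        )

    if cfg.ensure_pathway_coverage and tpm:
        covered = set().union(*tpm.values())
        for pathway in cfg.pathway_ids:
            if pathway not in covered:
                target = sorted(tpm)[int(rng.integers(len(tpm)))]
                tpm[target].add(pathway)

    # ingredient -> targets (over the full predicted panel, annotated or not)
    itm: dict[str, set[str]] = {}
    for ingredient in ingredients:
        chosen = rng.random(cfg.n_targets) < cfg.p_ingredient_target
        itm[ingredient] = {targets[i] for i in np.flatnonzero(chosen)}

    # force hub ingredients to reach every pathway
    pathway_to_targets: dict[str, list[str]] = {p: [] for p in cfg.pathway_ids}
    for target, pws in tpm.items():
        for p in pws:
            pathway_to_targets[p].append(target)
    for ingredient in ingredients[: cfg.n_hub_ingredients]:
        reached = set().union(*(tpm.get(t, set()) for t in itm[ingredient])) if itm[ingredient] else set()
        for pathway in cfg.pathway_ids:
            if pathway in reached:
                continue
            candidates = sorted(pathway_to_targets[pathway])
            if not candidates:
                logger.warning(
                    "pathway %s has no annotated target; hub %s cannot reach it",
                    pathway,
                    ingredient,
                )
                continue
            extra = candidates[int(rng.integers(len(candidates)))]
            itm[ingredient].add(extra)
            reached |= tpm[extra]
    return itm, tpm


def expected_edge_counts(cfg: GeneratorConfig) -> dict[str, float]:
    """Closed-form expected edge counts of the three subnetworks under the
    generator model, exact when ``hub_fraction = 0`` and
    ``ensure_pathway_coverage = False`` (the two post-processing steps only
    add edges).

    A kept-or-dropped target's final annotation to pathway j happens with
    probability q_j (1 + e), where q_j is the per-draw inclusion
    probability and e the probability the first draw was empty (the one
    re-draw); annotations of different targets are independent.
    """
    weights = (1.0 - cfg.broad_target_fraction, cfg.broad_target_fraction)
    link = np.zeros(cfg.n_pathways)
    colink = np.zeros((cfg.n_pathways, cfg.n_pathways))
    for w, broad in zip(weights, (False, True)):
        q = cfg.pathway_probs(broad)
        empty = float(np.prod(1.0 - q))
        link += w * q * (1.0 + empty)
        colink += w * np.outer(q, q) * (1.0 + empty)
    p_it = cfg.p_ingredient_target
    n_t = cfg.n_targets
    tti = (
        cfg.n_ingredients * (cfg.n_ingredients - 1) / 2
        * (1.0 - (1.0 - p_it**2) ** n_t)
    )
    ipb = float(np.sum(1.0 - (1.0 - p_it * link) ** n_t)) * cfg.n_ingredients
    iu = np.triu_indices(cfg.n_pathways, k=1)
    ppi = float(np.sum(1.0 - (1.0 - colink[iu]) ** n_t))
    return {"TTI": tti, "IPB": ipb, "PPI": ppi, "IPI": tti + ipb + ppi}


#: Plausible phytochemical compositions (unique monoisotopic masses) used
#: by the peak-table generator; drawn from flavones, coumarins, phenolic
#: acids, terpenes and alkaloids typical of a herb extract.
BUILTIN_FORMULAS: list[str] = [
    "C11H10O5", "C10H8O4", "C11H10O4", "C27H30O15", "C15H10O7", "C15H10O6",
    "C16H12O7", "C18H16O8", "C16H12O6", "C18H16O7", "C16H12O5", "C20H18O8",
    "C9H11NO2", "C16H24O10", "C16H18O9", "C18H30O2", "C12H16O3", "C14H20O7.NH3",
    "C12H18O2", "C17H14O7", "C9H10O3", "C11H14O3", "C17H24O3", "C11H14O5",
    "C15H22O2", "C15H16O4", "C15H24", "C10H12O", "C8H11NO3", "C6H6N2O",
    "C10H13N5O3", "C20H17NO6", "C17H19NO3", "C21H20O11", "C22H22O11",
    "C19H18O8", "C13H18O2", "C14H12O4",
]


def generate_peak_table(
    n_compounds: int,
    n_enriched: int,
    noise_ppm: float,
    seed: int,
) -> tuple[list[CompoundRecord], list[PeakRecord]]:
    """A compound library plus a matching LC-MS peak table.

    Each compound gets a distinct formula from the built-in set; its peak's
    measured m/z is the theoretical [M+H]+ perturbed by uniform noise within
    +/- ``noise_ppm``.  Exactly ``n_enriched`` randomly chosen peaks get a
    sample/control area ratio > 1 (drawn U(1.5, 5); the rest U(0.2, 0.95)).
    """
    if n_enriched > n_compounds:
        raise ValueError(f"n_enriched ({n_enriched}) exceeds n_compounds ({n_compounds})")
    if noise_ppm < 0:
        raise ValueError(f"noise_ppm must be >= 0, got {noise_ppm}")
    if n_compounds > len(BUILTIN_FORMULAS):
        raise ValueError(
            f"at most {len(BUILTIN_FORMULAS)} distinct compounds supported, "
            f"got {n_compounds}"
        )
    rng = np.random.default_rng(seed)
    formulas = [BUILTIN_FORMULAS[i] for i in rng.permutation(len(BUILTIN_FORMULAS))[:n_compounds]]
    enriched_idx = set(rng.permutation(n_compounds)[:n_enriched].tolist())
    compounds = []
    peaks = []
    for i, formula in enumerate(formulas):
        compound = CompoundRecord.from_formula(
            name=f"SYN{i + 1:03d}", category="synthetic", formula_text=formula
        )
        compounds.append(compound)
        rel = rng.uniform(-noise_ppm, noise_ppm) if noise_ppm > 0 else 0.0
        control = rng.uniform(1.0e4, 1.0e6)
        ratio = rng.uniform(1.5, 5.0) if i in enriched_idx else rng.uniform(0.2, 0.95)
        peaks.append(
            PeakRecord(
                feature_id=f"P{i + 1:03d}",
                measured_mz=compound.theoretical_mh_mz * (1.0 + rel * 1e-6),
                retention_time=float(rng.uniform(0.5, 15.0)),
                area_sample=control * ratio,
                area_control=control,
            )
        )
    return compounds, peaks
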
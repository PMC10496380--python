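"""End-to-end run: annotation -> enrichment screen -> network construction
-> statistics -> key-element tables.

The run mirrors the ligand-fishing study design: LC-MS features are
annotated against a compound library by accurate mass, the
ultrafiltration screen keeps the receptor-enriched compounds, the
ingredient/target/pathway mappings of the screened compounds yield the
merged ingredient-pathway network and its three subnetworks, and the
statistics suite nominates main active ingredients (bipartite degree) and
the critical pathway (centrality on the pathway-pathway network).
All randomness flows from a single seed, so a run is reproducible
file-for-file.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import io as pio
from .annotation import AnnotationHit, annotate_peaks, screen_enriched
from .network_build import (
    INGREDIENT,
    PATHWAY,
    Network,
    build_ipb,
    build_ipi,
    build_ppi,
    build_tti,
    prune_isolated,
)
from .network_metrics import MetricsReport, compute_metrics, rank_key_nodes
from .synthetic_data import GeneratorConfig, generate_mappings, generate_peak_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs and knobs of one end-to-end run.

    Either the four input paths or a generator config must be provided
    (generator mode synthesizes both the peak table and the mappings).
    """

    library_path: str | None = None
    peaks_path: str | None = None
    itm_path: str | None = None
    tpm_path: str | None = None
    generator: GeneratorConfig | None = None
    n_library_compounds: int = 34
    tol_ppm: float = 5.0
    ratio_threshold: float = 1.0
    noise_ppm: float = 2.0
    k_min: int | None = None
    prune: bool = False
    outdir: str = "phytonet_out"
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.itm_path is not None and self.tpm_path is not None
        if not has_files and self.generator is None:
            raise ValueError(
                "config needs either mapping-table paths or a generator config"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw, generator=GeneratorConfig(**gen) if gen is not None else None)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    hits: list[AnnotationHit]
    screened: list[AnnotationHit]
    networks: dict[str, Network] = field(default_factory=dict)
    reports: dict[str, MetricsReport] = field(default_factory=dict)
    ranked_ingredients: list[str] = field(default_factory=list)
    ranked_pathways: list[str] = field(default_factory=list)


def _annotation_stage(cfg: PipelineConfig) -> tuple[list[AnnotationHit], list[AnnotationHit]]:
    if cfg.library_path and cfg.peaks_path:
        library = pio.read_compound_library(cfg.library_path)
        peaks = pio.read_peak_table(cfg.peaks_path)
    elif cfg.generator is not None:
        n_enriched = cfg.generator.n_ingredients
        library, peaks = generate_peak_table(
            n_compounds=max(cfg.n_library_compounds, n_enriched),
            n_enriched=n_enriched,
            noise_ppm=cfg.noise_ppm,
            seed=cfg.seed,
        )
    else:
        return [], []
    hits = annotate_peaks(peaks, library, tol_ppm=cfg.tol_ppm)
    screened = screen_enriched(hits, ratio_threshold=cfg.ratio_threshold)
    return hits, screened


def _mapping_stage(
    cfg: PipelineConfig, screened: list[AnnotationHit]
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    if cfg.itm_path and cfg.tpm_path:
        itm = pio.read_mapping_table(cfg.itm_path, "ingredient-target")
        tpm = pio.read_mapping_table(cfg.tpm_path, "target-pathway")
        if screened:
            names = {h.compound_name for h in screened}
            keep = {i: t for i, t in itm.items() if i in names}
            if keep:
                if len(keep) < len(itm):
                    logger.info(
                        "restricting ingredient map to %d screened compound(s)", len(keep)
                    )
                itm = keep
            else:
                logger.warning(
                    "no screened compound matches the ingredient map; using the full map"
                )
        return itm, tpm
    assert cfg.generator is not None
    gen_cfg = dataclasses.replace(
        cfg.generator,
        n_ingredients=len({h.compound_name for h in screened}) or cfg.generator.n_ingredients,
        seed=cfg.seed,
    )
    itm, tpm = generate_mappings(gen_cfg)
    if screened:
        # name synthetic ingredients after the screened compounds
        names = sorted({h.compound_name for h in screened})
        rename = dict(zip(sorted(itm), names))
        itm = {rename[i]: t for i, t in itm.items()}
    return itm, tpm


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage and write all report files under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    hits, screened = _annotation_stage(cfg)
    result = PipelineResult(hits=hits, screened=screened)
    pio.write_hits_csv(hits, outdir / "annotation_hits.csv")
    pio.write_hits_csv(screened, outdir / "screened_hits.csv")
    logger.info(
        "annotation: %d feature(s) annotated, %d screened as enriched",
        len({h.feature_id for h in hits}),
        len({h.feature_id for h in screened}),
    )
    if (cfg.library_path or cfg.generator is not None) and hits and not screened:
        logger.warning("enrichment screen kept nothing; skipping network stages")
        return result

    itm, tpm = _mapping_stage(cfg, screened)
    pio.write_mapping_table(itm, outdir / "ingredient_target_map.csv", ("ingredient", "target"))
    pio.write_mapping_table(tpm, outdir / "target_pathway_map.csv", ("target", "pathway"))

    networks = {
        "IPI": build_ipi(itm, tpm),
        "TTI": build_tti(itm),
        "IPB": build_ipb(itm, tpm),
        "PPI": build_ppi(tpm),
    }
    if cfg.prune:
        networks = {name: prune_isolated(net) for name, net in networks.items()}
    result.networks = networks

    for name, net in networks.items():
        pio.write_pajek(net, outdir / f"{name.lower()}.net")
        pio.write_graphml(net, outdir / f"{name.lower()}.graphml")
        report = compute_metrics(net, k_min=cfg.k_min)
        result.reports[name] = report
        pio.write_per_node_csv(report, outdir / f"per_node_{name.lower()}.csv")
        pio.write_spectrum_csv(
            report.degree_distribution, outdir / f"degree_distribution_{name.lower()}.csv", "P_k"
        )
        pio.write_spectrum_csv(
            report.clustering_spectrum, outdir / f"clustering_spectrum_{name.lower()}.csv", "C_k"
        )
    pio.write_metrics_summary(
        [result.reports[n] for n in ("IPI", "TTI", "IPB", "PPI")],
        outdir / "metrics_summary.csv",
    )

    ipb_rank = rank_key_nodes(result.reports["IPB"], by="degree")
    result.ranked_ingredients = [
        v for v in ipb_rank if networks["IPB"].node_types[v] == INGREDIENT
    ]
    ppi_rank = rank_key_nodes(result.reports["PPI"], by="composite")
    result.ranked_pathways = [
        v for v in ppi_rank if networks["PPI"].node_types[v] == PATHWAY
    ]
    _write_ranked(
        result.ranked_ingredients, result.reports["IPB"], outdir / "ranked_ingredients.csv"
    )
    _write_ranked(
        result.ranked_pathways, result.reports["PPI"], outdir / "ranked_pathways.csv"
    )
    logger.info(
        "top ingredient(s): %s; top pathway: %s",
        ", ".join(result.ranked_ingredients[:2]),
        result.ranked_pathways[0] if result.ranked_pathways else "n/a",
    )
    return result


def _write_ranked(order: list[str], report: MetricsReport, path: Path) -> None:
    import csv

    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rank", "node", "degree", "C_d", "C_b", "C_c"])
        for rank, node in enumerate(order, 1):
            m = report.per_node[node]
            writer.writerow(
                [rank, node, m.degree, f"{m.degree_centrality:.3f}",
                 f"{m.betweenness:.3f}", f"{m.closeness:.3f}"]
            )
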
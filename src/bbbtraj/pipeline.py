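"""End-to-end pipeline: simulate/load -> drop sparse -> impute ->
correlation structure -> module composites -> trajectory suite -> t-SNE.

Every stage writes its artifact under the output directory and the run
manifest records inputs, seeds and per-stage shapes, so any stage can be
re-run from the saved intermediates and a re-run with the same manifest
reproduces all deterministic artifacts.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .cohort import CohortTable
from .composites import append_module_scores, module_pc1
from .correlation import cluster_features, plot_heatmap, propose_modules, spearman_matrix
from .embedding import plot_embedding, select_complete, tsne_embed
from .preprocess import drop_sparse_features, impute_hierarchical
from .simulate import SimConfig, default_sim_config, generate_cohort
from .trajectory import Contrast, reports_to_csv, reports_to_json, trajectory_suite

log = logging.getLogger("bbbtraj")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Configuration of one full run.

    ``input_csv`` takes precedence over ``sim``; with neither, the
    default synthetic study is generated.  ``modules`` maps module name
    -> member feature list; when empty, modules are proposed from the
    correlation-structure cut with ``n_module_clusters`` clusters.
    """

    out_dir: Path
    input_csv: Path | None = None
    sim: SimConfig | None = None
    sparse_threshold: float = 0.70
    modules: Mapping[str, Sequence[str]] = field(default_factory=dict)
    n_module_clusters: int = 5
    contrast: Contrast = field(default_factory=lambda: Contrast(within={"group": "injured"}))
    min_n: int = 2
    n_perm: int | None = 500
    embed_features: Sequence[str] | None = None  # default: module score columns
    perplexity: float | None = None
    seed: int = 0
    make_figures: bool = True

    @classmethod
    def from_file(cls, path: str | Path, out_dir: str | Path) -> "PipelineConfig":
        import yaml

        path = Path(path)
        raw = yaml.safe_load(path.read_text()) if path.suffix in {".yml", ".yaml"} \
            else json.loads(path.read_text())
        contrast_raw = raw.get("contrast", {})
        contrast = Contrast(
            column=contrast_raw.get("column", "sex"),
            label_a=contrast_raw.get("label_a", "male"),
            label_b=contrast_raw.get("label_b", "female"),
            within=contrast_raw.get("within", {"group": "injured"}),
        )
        sim = SimConfig.from_dict(raw["sim"]) if "sim" in raw else None
        return cls(
            out_dir=Path(out_dir),
            input_csv=Path(raw["input_csv"]) if raw.get("input_csv") else None,
            sim=sim,
            sparse_threshold=float(raw.get("sparse_threshold", 0.70)),
            modules=raw.get("modules", {}),
            n_module_clusters=int(raw.get("n_module_clusters", 5)),
            contrast=contrast,
            min_n=int(raw.get("min_n", 2)),
            n_perm=raw.get("n_perm", 500),
            embed_features=raw.get("embed_features"),
            perplexity=raw.get("perplexity"),
            seed=int(raw.get("seed", 0)),
            make_figures=bool(raw.get("make_figures", True)),
        )


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        log.info("[%s] %s", stage, info)

    try:
        # -- input ------------------------------------------------------
        if config.input_csv is not None:
            table = CohortTable.from_csv(config.input_csv)
            manifest["input"] = str(config.input_csv)
        else:
            sim = config.sim or default_sim_config(seed=config.seed)
            table = generate_cohort(sim)
            sim.to_file(out / "sim_config.json")
            manifest["input"] = "synthetic:sim_config.json"
        table.to_csv(out / "cohort_raw.csv")
        record("input", n_animals=table.n_animals, n_features=len(table.feature_names))

        # -- preprocess --------------------------------------------------
        table, dropped = drop_sparse_features(table, config.sparse_threshold)
        record("drop_sparse", dropped=dropped, kept=len(table.feature_names))
        table, implog = impute_hierarchical(table)
        implog.to_json(out / "imputation_log.json")
        table.to_csv(out / "cohort_imputed.csv")
        record("impute", **implog.actions())

        # -- correlation structure --------------------------------------
        # fallback-imputed copy keeps the correlation matrix total
        filled, _ = impute_hierarchical(table, allow_global_fallback=True)
        structure = spearman_matrix(filled)
        structure = cluster_features(structure)
        structure.rho_to_csv(out / "spearman_rho.csv")
        structure.linkage_to_json(out / "linkage.json")
        if config.make_figures:
            plot_heatmap(structure, out / "heatmap.png")
        record("correlate", n_features=len(structure.features))

        # -- modules -----------------------------------------------------
        modules_def = dict(config.modules)
        if not modules_def:
            proposed = propose_modules(structure, config.n_module_clusters)
            modules_def = {name: m for name, m in proposed if len(m) >= 2}
        fitted = []
        for name, members in modules_def.items():
            fitted.append(
                module_pc1(table, name, list(members), fallback_impute=True)
            )
        table = append_module_scores(table, fitted)
        table.to_csv(out / "cohort_with_modules.csv")
        pd.DataFrame(
            [
                {
                    "module": m.name,
                    "members": ";".join(m.members),
                    "explained_variance_fraction": m.explained_variance_fraction,
                    "n_animals": m.n_animals,
                }
                for m in fitted
            ]
        ).to_csv(out / "modules.csv", index=False)
        record("composites", modules={m.name: m.members for m in fitted})

        # -- trajectory --------------------------------------------------
        score_cols = [f"module_{m.name}" for m in fitted]
        reports = trajectory_suite(
            table, score_cols, config.contrast, min_n=config.min_n,
            n_perm=config.n_perm, seed=config.seed,
        )
        reports_to_json(reports, out / "trajectory.json")
        reports_to_csv(reports, out / "trajectory.csv")
        record(
            "trajectory",
            features=score_cols,
            contrast=config.contrast.describe(),
            n_perm=config.n_perm,
        )

        # -- embedding ---------------------------------------------------
        embed_feats = list(config.embed_features or score_cols)
        complete = select_complete(table, embed_feats)
        emb = tsne_embed(
            complete, embed_feats, perplexity=config.perplexity, seed=config.seed
        )
        emb.to_csv(out / "embedding.csv")
        if config.make_figures:
            plot_embedding(emb, out / "embedding.png")
        record(
            "embed",
            n_complete=complete.n_animals,
            n_dropped=table.n_animals - complete.n_animals,
            perplexity=emb.perplexity,
        )
    except Exception as exc:  # annotate the failing stage
        done = list(manifest["stages"])
        stage = done[-1] if done else "startup"
        raise PipelineError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )
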
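"""End-to-end orchestration: simulate -> metrics -> screen -> attention /
gain variance / modulation indices -> clustering -> behavior.

A :class:`RunConfig` fixes every analysis choice and a master seed; every
stochastic stage receives a seed derived deterministically from it, so a
rerun with the same config reproduces identical outputs (recorded in a
manifest with a config hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import attention as attn
from . import behavior as beh
from . import clustering as clus
from . import io as fio
from . import metrics, modulation, synth
from .archetypes import study_population

log = logging.getLogger("fefattn")


@dataclass
class RunConfig:
    out_dir: str = "fefattn_run"
    input_dir: str | None = None  # load canonical CSVs instead of simulating
    drug_name: str = "ACh"
    cells_per_archetype: int = 12
    n_trials_per_condition: int = 15
    alpha: float = 0.05
    epoch: str = "dim"  # window for screen, AUROC and NB counts
    pool_away: bool = True
    nb_min_trials: int = 5
    cluster_k_min: int = 2
    cluster_k_max: int = 12
    cluster_restarts: int = 50
    dip_n_boot: int = 2000
    behavior_hit_p: float = 0.997
    behavior_fa_p: float = 0.041
    behavior_n_trials: int = 2000
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seed(config: RunConfig, stage: str) -> int:
    h = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the canonical outputs; returns the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_dir is not None:
        cells = fio.read_population(config.input_dir)
        labels = None
    else:
        design = synth.TaskDesign(
            n_trials_per_condition=config.n_trials_per_condition
        )
        cells, labels = synth.simulate_population(
            study_population(config.drug_name),
            config.cells_per_archetype,
            design,
            seed=_stage_seed(config, "simulate"),
            drug_name=config.drug_name,
        )
        fio.write_population(cells, out / "data", labels)

    # per-cell metrics
    metric_rows = [metrics.cell_metrics(c) for c in cells]
    metrics_df = pd.DataFrame(metric_rows)

    # ANOVA screen + attention quantification
    screen_rows, attn_rows = [], []
    for cell in cells:
        screen = attn.screen_cell(cell, config.epoch)
        screen_rows.append(
            dict(
                cell_id=cell.cell_id,
                attention_modulated=screen.attention_modulated,
                drug_modulated=screen.drug_modulated,
                **{f"p_{k}": v for k, v in screen.p_values.items()},
            )
        )
        res = attn.attention_result(cell, config.epoch, config.pool_away)
        res["auroc_nodrug_folded"] = attn.auroc_folding(res["auroc_nodrug"])
        attn_rows.append(res)
    screen_df = pd.DataFrame(screen_rows)
    attn_df = pd.DataFrame(attn_rows)
    metrics_df = metrics_df.merge(
        attn_df[["cell_id", "auroc_nodrug"]].rename(
            columns={"auroc_nodrug": "auroc"}
        ),
        on="cell_id",
    )

    # drug MIs and gain-variance MIs
    has_drug = any(t.drug == "on" for c in cells for t in c.trials)
    mi_rows = []
    if has_drug:
        for cell in cells:
            row = dict(cell_id=cell.cell_id)
            row["drug_mi"] = modulation.cell_drug_mi(cell, config.epoch).value
            row.update(modulation.cell_gain_mis(cell, config.epoch))
            mi_rows.append(row)
    else:
        log.warning("no drug-on trials; drug-MI stage skipped")
    mi_df = pd.DataFrame(mi_rows)

    # clustering on the candidate feature set
    features = metrics_df[list(clus.CANDIDATE_FEATURES)]
    k_max = min(config.cluster_k_max, max(config.cluster_k_min, len(cells) // 3))
    if k_max < config.cluster_k_max:
        log.warning("k range capped at %d for %d cells", k_max, len(cells))
    model = clus.cluster_cells(
        features,
        metrics_df["cell_id"].tolist(),
        k_range=range(config.cluster_k_min, k_max + 1),
        restarts=config.cluster_restarts,
        seed=_stage_seed(config, "cluster"),
        n_boot=config.dip_n_boot,
    )
    assign_df = pd.DataFrame(
        dict(cell_id=model.cell_ids, cluster=model.assignments)
    )

    # behavior
    design = synth.TaskDesign(
        n_trials_per_condition=config.n_trials_per_condition
    )
    btrials = synth.simulate_behavior(
        design,
        config.behavior_hit_p,
        config.behavior_fa_p,
        seed=_stage_seed(config, "behavior"),
        n_trials=config.behavior_n_trials,
        drug_name=config.drug_name,
    )
    bsummary = beh.behavior_summary(btrials)

    # outputs
    metrics_df.to_csv(out / "cell_metrics.csv", index=False)
    screen_df.to_csv(out / "cell_screen.csv", index=False)
    attn_df.to_csv(out / "attention_results.csv", index=False)
    if not mi_df.empty:
        mi_df.to_csv(out / "modulation_indices.csv", index=False)
    model.sweep.to_csv(out / "cluster_sweep.csv", index=False)
    assign_df.to_csv(out / "cluster_assignments.csv", index=False)
    btrials.to_csv(out / "behavior_trials.csv", index=False)
    cluster_report = dict(
        selected_features=model.selected_features,
        explained_fraction=model.explained_fraction,
        k_aic=model.k_aic,
        k_bic=model.k_bic,
        k_used=model.k_used,
        excluded_cells=model.excluded_cells,
        composition=model.composition.to_dict(orient="records"),
        dip=model.dip_results.to_dict(orient="records"),
    )
    (out / "cluster_report.json").write_text(
        json.dumps(cluster_report, indent=1, default=float)
    )
    manifest = dict(
        version=__version__,
        config=dataclasses.asdict(config),
        config_hash=config.config_hash(),
        n_cells=len(cells),
        n_trials=int(sum(len(c.trials) for c in cells)),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    report = dict(
        manifest=manifest,
        behavior=bsummary,
        cluster=cluster_report,
        n_attention_modulated=int(screen_df["attention_modulated"].sum()),
        n_drug_modulated=int(screen_df["drug_modulated"].sum()),
        n_cells=len(cells),
    )
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
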
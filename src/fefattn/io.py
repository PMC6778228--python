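"""Canonical on-disk schema: plain-text CSV tables plus JSON sidecars.

trials.csv    cell_id, trial_id, attention {RF,away1,away2}, direction {d1,d2},
              drug {off,on}, drug_name, stim_on_ms, cue_on_ms, dim1_ms,
              outcome, rt_ms
spikes.csv    cell_id, trial_id, t_ms   (relative to stimulus onset)
waveforms.csv cell_id, sample_index, amplitude, sampling_khz

Times are milliseconds with stimulus onset at 0.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import CellRecording, TrialRecord

TRIAL_COLUMNS = [
    "cell_id", "trial_id", "attention", "direction", "drug", "drug_name",
    "stim_on_ms", "cue_on_ms", "dim1_ms", "outcome", "rt_ms",
]


def population_to_frames(
    cells: list[CellRecording],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(trials, spikes, waveforms) DataFrames in the canonical schema."""
    trial_rows, spike_rows, wf_rows = [], [], []
    for cell in cells:
        for t in cell.trials:
            trial_rows.append(
                dict(
                    cell_id=cell.cell_id, trial_id=t.trial_id,
                    attention=t.attention, direction=t.direction,
                    drug=t.drug, drug_name=t.drug_name,
                    stim_on_ms=t.stim_on_ms, cue_on_ms=t.cue_on_ms,
                    dim1_ms=t.dim1_ms, outcome=t.outcome, rt_ms=t.rt_ms,
                )
            )
            for s in t.spikes_ms:
                spike_rows.append(
                    dict(cell_id=cell.cell_id, trial_id=t.trial_id, t_ms=s)
                )
        for i, a in enumerate(cell.waveform):
            wf_rows.append(
                dict(cell_id=cell.cell_id, sample_index=i, amplitude=a,
                     sampling_khz=cell.sampling_khz)
            )
    return (
        pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS),
        pd.DataFrame(spike_rows, columns=["cell_id", "trial_id", "t_ms"]),
        pd.DataFrame(
            wf_rows,
            columns=["cell_id", "sample_index", "amplitude", "sampling_khz"],
        ),
    )


def write_population(
    cells: list[CellRecording],
    out_dir: str | Path,
    labels: list[str] | None = None,
    float_format: str = "%.6f",
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials, spikes, wfs = population_to_frames(cells)
    trials.to_csv(out / "trials.csv", index=False, float_format=float_format)
    spikes.to_csv(out / "spikes.csv", index=False, float_format=float_format)
    wfs.to_csv(out / "waveforms.csv", index=False, float_format=float_format)
    sidecar = {
        "cells": [
            dict(cell_id=c.cell_id, drug_name=c.drug_name,
                 archetype=c.archetype)
            for c in cells
        ]
    }
    if labels is not None:
        sidecar["ground_truth"] = dict(zip((c.cell_id for c in cells), labels))
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))


def read_population(in_dir: str | Path) -> list[CellRecording]:
    """Rebuild CellRecording objects from the canonical CSV schema."""
    src = Path(in_dir)
    trials = pd.read_csv(src / "trials.csv")
    spikes = pd.read_csv(src / "spikes.csv")
    wfs = pd.read_csv(src / "waveforms.csv")
    meta = {}
    gt_path = src / "ground_truth.json"
    if gt_path.exists():
        sidecar = json.loads(gt_path.read_text())
        meta = {c["cell_id"]: c for c in sidecar.get("cells", [])}
    spike_groups = {
        key: grp["t_ms"].to_numpy()
        for key, grp in spikes.groupby(["cell_id", "trial_id"])
    }
    cells = []
    for cell_id, cell_trials in trials.groupby("cell_id", sort=False):
        recs = []
        for _, row in cell_trials.iterrows():
            recs.append(
                TrialRecord(
                    trial_id=int(row["trial_id"]),
                    attention=row["attention"],
                    direction=row["direction"],
                    drug=row["drug"],
                    drug_name=row["drug_name"],
                    stim_on_ms=float(row["stim_on_ms"]),
                    cue_on_ms=float(row["cue_on_ms"]),
                    dim1_ms=float(row["dim1_ms"]),
                    spikes_ms=np.sort(
                        spike_groups.get((cell_id, int(row["trial_id"])),
                                         np.empty(0))
                    ),
                    outcome=row["outcome"],
                    rt_ms=float(row["rt_ms"]),
                )
            )
        wf = wfs[wfs["cell_id"] == cell_id].sort_values("sample_index")
        info = meta.get(cell_id, {})
        cells.append(
            CellRecording(
                cell_id=cell_id,
                drug_name=info.get("drug_name", recs[0].drug_name),
                trials=recs,
                waveform=wf["amplitude"].to_numpy(),
                sampling_khz=float(wf["sampling_khz"].iloc[0]),
                archetype=info.get("archetype"),
            )
        )
    return cells
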
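"""TSV readers/writers for the pipeline's tabular interfaces.

All tables are tab-separated with a header row and ``NA`` for missing
values.  Beta matrices and reference panels are probes x columns with the
probe id in the first column; everything else is tidy long/row-per-record.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .synthetic import ReferencePanel, SimConfig, TruthLabels

_TSV = dict(sep="\t", na_rep="NA")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, index=index, **_TSV)


def read_beta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values="NA")


def write_beta(beta: pd.DataFrame, path) -> None:
    beta.rename_axis("probe_id").to_csv(path, **_TSV)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values="NA")


def write_panel(panel: ReferencePanel, path) -> None:
    out = panel.values.copy()
    out.columns = [f"{panel.cell_types[c]}:{c}" for c in out.columns]
    out.rename_axis("probe_id").to_csv(path, **_TSV)


def read_panel(path) -> ReferencePanel:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    types = pd.Series({c: c.split(":", 1)[0] for c in df.columns})
    df.columns = [c.split(":", 1)[1] for c in df.columns]
    types.index = df.columns
    return ReferencePanel(values=df, cell_types=types)


def write_truth(truth: TruthLabels, path) -> None:
    rows = [{"probe_id": p, "label": "acquired",
             "direction": truth.planted_direction[p]}
            for p in sorted(truth.acquired_truth)]
    rows += [{"probe_id": p, "label": "celltype", "direction": "NA"}
             for p in sorted(truth.celltype_truth)]
    write_tsv(pd.DataFrame(rows), path)


def read_config(path) -> SimConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") \
            else json.load(fh)
    return SimConfig(**raw)


def write_config(cfg: SimConfig, path) -> None:
    path = Path(path)
    data = {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in cfg.__dict__.items()}
    with open(path, "w") as fh:
        if path.suffix in (".yml", ".yaml"):
            yaml.safe_dump(data, fh)
        else:
            json.dump(data, fh, indent=2)
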
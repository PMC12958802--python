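"""Plain-text writers/readers for simulated datasets.

Genotypes go to a tab-separated matrix (individuals x loci), phenotypes and
soil to CSV, weather to long-format CSV (site_year, variable, day, value).
Every write records the generating seed and configuration in a JSON sidecar
so a dataset on disk can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix, PhenotypeTable, SimConfig, TrialDesign

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
    "write_trial",
    "write_sidecar",
]


def write_sidecar(path, config: SimConfig, extra: dict = None):
    meta = dataclasses.asdict(config)
    meta.update(extra or {})
    Path(path).write_text(json.dumps(meta, indent=2, default=str))


def write_genotypes(path, G: GenotypeMatrix):
    df = pd.DataFrame(G.calls, index=G.individual_ids, columns=G.locus_ids)
    df.to_csv(path, sep="\t")


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        calls=df.to_numpy(),
        individual_ids=list(df.index),
        locus_ids=list(df.columns),
    )


def write_phenotypes(path, table: PhenotypeTable):
    table.data.to_csv(path, index=False)


def read_phenotypes(path) -> PhenotypeTable:
    data = pd.read_csv(path)
    if "partition" not in data:
        data["partition"] = None
    table = PhenotypeTable(data=data)
    if "y_std" in data and (data["partition"] == "train").any():
        train = data[data["partition"] == "train"]
        table.train_mean = float(train["yield"].mean())
        table.train_sd = float(train["yield"].std(ddof=0))
    return table


def write_trial(soil_path, weather_path, trial: TrialDesign):
    trial.soil.to_csv(soil_path)
    rows = []
    for k, sy in enumerate(trial.site_years):
        for v, var in enumerate(trial.weather_vars):
            rows.append(
                pd.DataFrame(
                    {
                        "site_year": sy,
                        "variable": var,
                        "day": trial.days,
                        "value": trial.weather[k, v],
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(weather_path, index=False)


def read_weather_long(path, site_years, variables, days) -> np.ndarray:
    df = pd.read_csv(path)
    arr = np.empty((len(site_years), len(variables), len(days)))
    sy_i = {s: i for i, s in enumerate(site_years)}
    v_i = {v: i for i, v in enumerate(variables)}
    d_i = {d: i for i, d in enumerate(days)}
    for (sy, var), grp in df.groupby(["site_year", "variable"]):
        arr[sy_i[sy], v_i[var], [d_i[d] for d in grp["day"]]] = grp["value"].to_numpy()
    return arr
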
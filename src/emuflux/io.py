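"""Readers and writers for the package's tabular text formats.

* measurement tables: TSV with columns ``emu_id, timepoint, mean_0...mean_n,
  sd_0...sd_n`` ("ss" or seconds in ``timepoint``; trailing columns beyond a
  fragment's size left blank);
* flux measurement tables: TSV ``reaction_id, mean, sd``;
* flux bounds: TSV ``flux_id, lb, ub`` over total fluxes;
* tracer strategies: YAML mapping substrate -> list of
  ``{isotopomer, fraction, purity}``;
* networks: see :func:`emuflux.network.read_network` (TSV/CSV) and
  :func:`emuflux.network.read_network_xlsx` (spreadsheet layout).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .constraint import FluxBounds
from .emu import parse_emu
from .estimate import FluxMeasurement, MDVMeasurement
from .labeling import LabelingStrategy

__all__ = ["read_mdv_measurements", "write_mdv_measurements",
           "read_flux_measurements", "write_flux_measurements",
           "read_flux_bounds", "write_flux_bounds",
           "read_tracer_yaml", "write_tracer_yaml"]


def _parse_timepoint(tok):
    s = str(tok).strip()
    return "ss" if s.lower() == "ss" else float(s)


def read_mdv_measurements(path) -> List[MDVMeasurement]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        emu = parse_emu(str(row["emu_id"]))
        n = emu.size + 1
        mean = np.array([row[f"mean_{i}"] for i in range(n)], dtype=float)
        sd = np.array([row[f"sd_{i}"] for i in range(n)], dtype=float)
        out.append(MDVMeasurement(emu, _parse_timepoint(row["timepoint"]),
                                  mean, sd))
    return out


def write_mdv_measurements(measurements: Sequence[MDVMeasurement], path) -> None:
    nmax = max(m.mean.size for m in measurements)
    rows = []
    for m in measurements:
        row: Dict = {"emu_id": m.emu.name, "timepoint": m.timepoint}
        for i in range(nmax):
            row[f"mean_{i}"] = m.mean[i] if i < m.mean.size else ""
        for i in range(nmax):
            row[f"sd_{i}"] = m.sd[i] if i < m.sd.size else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_flux_measurements(path) -> List[FluxMeasurement]:
    df = pd.read_csv(path, sep="\t")
    return [FluxMeasurement(str(r["reaction_id"]), float(r["mean"]),
                            float(r["sd"]))
            for _, r in df.iterrows()]


def write_flux_measurements(measurements: Sequence[FluxMeasurement], path) -> None:
    pd.DataFrame([{"reaction_id": m.reaction_id, "mean": m.mean, "sd": m.sd}
                  for m in measurements]).to_csv(path, sep="\t", index=False)


def read_flux_bounds(path) -> FluxBounds:
    df = pd.read_csv(path, sep="\t")
    fb = FluxBounds()
    for _, r in df.iterrows():
        fb.set(str(r["flux_id"]), float(r["lb"]), float(r["ub"]))
    return fb


def write_flux_bounds(bounds: FluxBounds, path) -> None:
    pd.DataFrame([{"flux_id": fid, "lb": lo, "ub": hi}
                  for fid, (lo, hi) in bounds.bounds.items()]
                 ).to_csv(path, sep="\t", index=False)


def read_tracer_yaml(path) -> LabelingStrategy:
    """YAML tracer file, e.g.::

        Glc:
          - {isotopomer: "100000", fraction: 0.8, purity: 0.995}
          - {isotopomer: "111111", fraction: 0.2, purity: 0.995}
    """
    data = yaml.safe_load(Path(path).read_text())
    tracers = {}
    for met, comps in data.items():
        tracers[met] = [(str(c["isotopomer"]), float(c["fraction"]),
                         float(c.get("purity", 1.0))) for c in comps]
    return LabelingStrategy(tracers)


def write_tracer_yaml(strategy: LabelingStrategy, path) -> None:
    data = {met: [{"isotopomer": mask, "fraction": frac, "purity": purity}
                  for mask, frac, purity in comps]
            for met, comps in strategy.tracers.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
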
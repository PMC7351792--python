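"""HDF5 persistence for the analysis artifacts."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .popdata import Condition, ConditionDesign, PopulationResponse, TrialCounts
from .otdr_core import RegressionAxes, EpochSpec


def _cond_to_json(c: Condition) -> list:
    return [int(c.offer), int(c.choice), bool(c.singleton)]


def _cond_from_json(v) -> Condition:
    return Condition(int(v[0]), int(v[1]), bool(v[2]))


def save_population(path, pop: PopulationResponse, M: TrialCounts,
                    design: ConditionDesign | None = None,
                    mode: str = "w") -> None:
    with h5py.File(path, mode) as f:
        g = f.create_group("population")
        g.create_dataset("tensor", data=pop.tensor)
        g.create_dataset("cc", data=pop.cc)
        g.create_dataset("bin_starts", data=pop.bin_starts)
        g.create_dataset("M", data=M.M)
        g.attrs["mean_subtracted"] = pop.mean_subtracted
        g.attrs["bin_width"] = pop.bin_width
        g.attrs["alignment"] = pop.alignment
        g.attrs["condition_index"] = json.dumps(
            [_cond_to_json(c) for c in pop.condition_index])
        if pop.zmean is not None:
            g.create_dataset("zmean", data=pop.zmean)
            g.create_dataset("zstd", data=pop.zstd)
        if design is not None:
            d = f.create_group("design")
            d.create_dataset("P", data=design.P)
            d.attrs["variables"] = json.dumps(design.variables)
            d.attrs["conditions"] = json.dumps(
                [_cond_to_json(c) for c in design.conditions])
            d.attrs["scaling"] = json.dumps(design.scaling)


def load_population(path):
    with h5py.File(path, "r") as f:
        g = f["population"]
        conds = [_cond_from_json(v) for v in json.loads(g.attrs["condition_index"])]
        pop = PopulationResponse(
            tensor=g["tensor"][()], cc=g["cc"][()],
            mean_subtracted=bool(g.attrs["mean_subtracted"]),
            bin_starts=g["bin_starts"][()], bin_width=float(g.attrs["bin_width"]),
            alignment=str(g.attrs["alignment"]), condition_index=conds,
            zmean=g["zmean"][()] if "zmean" in g else None,
            zstd=g["zstd"][()] if "zstd" in g else None)
        M = TrialCounts(g["M"][()], conds)
        design = None
        if "design" in f:
            d = f["design"]
            design = ConditionDesign(
                d["P"][()], json.loads(d.attrs["variables"]),
                [_cond_from_json(v) for v in json.loads(d.attrs["conditions"])],
                json.loads(d.attrs["scaling"]))
    return pop, M, design


def save_axes(path, axes: RegressionAxes, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        if "axes" in f:
            del f["axes"]
        g = f.create_group("axes")
        g.create_dataset("B", data=axes.B)
        g.create_dataset("B0", data=axes.B0)
        g.attrs["columns"] = json.dumps(axes.columns)
        g.attrs["epoch_names"] = json.dumps(axes.epoch_names)
        g.attrs["orthogonalized"] = axes.orthogonalized
        g.attrs["objective_value"] = axes.objective_value
        if axes.spec is not None:
            g.attrs["epochs"] = json.dumps(
                {k: list(v) for k, v in axes.spec.epochs.items()})
            g.attrs["assignment"] = json.dumps(axes.spec.assignment)


def load_axes(path) -> RegressionAxes:
    with h5py.File(path, "r") as f:
        g = f["axes"]
        spec = None
        if "epochs" in g.attrs:
            spec = EpochSpec(
                epochs={k: tuple(v) for k, v in
                        json.loads(g.attrs["epochs"]).items()},
                assignment=json.loads(g.attrs["assignment"]))
        return RegressionAxes(
            B=g["B"][()], B0=g["B0"][()],
            columns=[tuple(c) for c in json.loads(g.attrs["columns"])],
            epoch_names=json.loads(g.attrs["epoch_names"]),
            orthogonalized=bool(g.attrs["orthogonalized"]),
            objective_value=float(g.attrs["objective_value"]), spec=spec)
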
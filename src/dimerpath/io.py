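"""File formats: YAML configs, HDF5 run containers and TSV tables.

Layout of the run container (HDF5):

* ``results/`` -- one dataset per shooting-record field, frame-major;
  coordinates in the toy system's native units, descriptors dimensionless.
* ``series/`` -- cumulative n_generated and n_expected, one value per MC step.
* ``chains/chain_<i>/`` -- accepted-TP history (mc_step, terminal_state) and
  the switch count.
* ``model/`` -- the committor-model checkpoint arrays.

Two-helix configuration sets are stored as stacked coordinate arrays
(n, 37, 3) per point class, coordinates in nm.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import yaml

from .landscape import ToyLandscapeSpec
from .network import CommittorNet
from .system import Configuration

__all__ = ["load_landscape_config", "save_landscape_config", "save_run",
           "load_run_summary", "save_configurations", "load_configurations",
           "write_tsv"]


def load_landscape_config(path) -> ToyLandscapeSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ToyLandscapeSpec.from_dict(data.get("landscape", data))


def save_landscape_config(spec: ToyLandscapeSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"landscape": spec.to_dict()}, fh)


def _channel_code(ch):
    return {"upper": 1, "lower": 2}.get(ch, 0)


def save_run(run, path) -> None:
    """Persist a TPS run (results, series, chain histories, model)."""
    with h5py.File(path, "w") as h5:
        h5.attrs["seed"] = run.seed
        g = h5.create_group("results")
        g.create_dataset("points", data=np.array([r.point for r in run.results]))
        g.create_dataset("descriptors",
                         data=np.array([r.descriptor for r in run.results]))
        for name in ("p_pred", "selection_weight"):
            g.create_dataset(name,
                             data=np.array([getattr(r, name) for r in run.results]))
        for name in ("outcome_1", "outcome_2", "n_a", "n_b", "mc_step", "chain_id"):
            g.create_dataset(name, data=np.array(
                [getattr(r, name) for r in run.results], dtype=int))
        g.create_dataset("is_tp",
                         data=np.array([r.is_tp for r in run.results], dtype=bool))
        s = h5.create_group("series")
        s.create_dataset("n_generated", data=run.n_generated_series)
        s.create_dataset("n_expected", data=run.n_expected_series)
        c = h5.create_group("chains")
        for ch in run.chains:
            gc = c.create_group(f"chain_{ch.chain_id}")
            gc.attrs["switches"] = ch.switches
            gc.attrs["accepted"] = ch.accepted
            gc.create_dataset("mc_step", data=np.array(
                [h["mc_step"] for h in ch.history], dtype=int))
            gc.create_dataset("terminal_state", data=np.array(
                [h["terminal_state"] for h in ch.history], dtype=int))
            gc.create_dataset("channel", data=np.array(
                [_channel_code(h["channel"]) for h in ch.history], dtype=int))
        m = h5.create_group("model")
        m.attrs["architecture"] = json.dumps({
            "input_dim": run.model.input_dim, "bottleneck": run.model.bottleneck,
            "n_pyramid": run.model.n_pyramid, "n_blocks": run.model.n_blocks,
            "block_layers": run.model.block_layers,
            "descriptor_hash": run.model.descriptor_hash or ""})
        for i, (W, b) in enumerate(run.model.params):
            m.create_dataset(f"W{i}", data=W)
            m.create_dataset(f"b{i}", data=b)


def load_run_summary(path) -> dict:
    """Load the arrays of a stored run (not the live objects)."""
    out = {"results": {}, "series": {}, "chains": {}}
    with h5py.File(path, "r") as h5:
        out["seed"] = int(h5.attrs["seed"])
        for k, v in h5["results"].items():
            out["results"][k] = v[()]
        for k, v in h5["series"].items():
            out["series"][k] = v[()]
        for name, gc in h5["chains"].items():
            out["chains"][name] = {
                "switches": int(gc.attrs["switches"]),
                "accepted": int(gc.attrs["accepted"]),
                "mc_step": gc["mc_step"][()],
                "terminal_state": gc["terminal_state"][()],
                "channel": gc["channel"][()],
            }
        arch = json.loads(h5["model"].attrs["architecture"])
        model = CommittorNet(input_dim=arch["input_dim"],
                             bottleneck=arch["bottleneck"],
                             n_pyramid=arch["n_pyramid"],
                             n_blocks=arch["n_blocks"],
                             block_layers=arch["block_layers"],
                             descriptor_hash=arch["descriptor_hash"] or None)
        n = len([k for k in h5["model"].keys() if k.startswith("W")])
        model.params = [(h5["model"][f"W{i}"][()], h5["model"][f"b{i}"][()])
                        for i in range(n)]
        out["model"] = model
    return out


def save_configurations(configs: list, path) -> None:
    """Store a list of two-helix configurations (coordinates in nm)."""
    with h5py.File(path, "w") as h5:
        for name in ("bb1", "bb2", "sc1", "sc2"):
            h5.create_dataset(name,
                              data=np.stack([getattr(c, name) for c in configs]))
        h5.create_dataset("residue_ids", data=configs[0].residue_ids)
        h5.create_dataset("glycine_mask",
                          data=np.stack([c.glycine_mask for c in configs]))
        labels = [str(c.meta.get("archetype", "")) for c in configs]
        h5.create_dataset("labels", data=np.array(labels, dtype="S16"))


def load_configurations(path) -> list:
    with h5py.File(path, "r") as h5:
        bb1, bb2 = h5["bb1"][()], h5["bb2"][()]
        sc1, sc2 = h5["sc1"][()], h5["sc2"][()]
        rid = h5["residue_ids"][()]
        gly = h5["glycine_mask"][()]
        labels = [s.decode() for s in h5["labels"][()]]
    configs = []
    for i in range(len(bb1)):
        meta = {"archetype": labels[i]} if labels[i] else {}
        configs.append(Configuration(bb1[i], bb2[i], sc1[i], sc2[i],
                                     residue_ids=rid, glycine_mask=gly[i],
                                     meta=meta))
    return configs


def write_tsv(path, columns: dict) -> None:
    """Write a dict of equal-length columns as a TSV table with a header."""
    keys = list(columns)
    arrays = [np.asarray(columns[k]) for k in keys]
    n = len(arrays[0])
    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for i in range(n):
            fh.write("\t".join(str(a[i]) for a in arrays) + "\n")
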
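"""Delimited-text persistence for cohorts and spike trains.

A cohort directory holds one TSV per sample (rows = time, columns =
channels, header = channel labels), a ``psychometrics.tsv`` table and a JSON
manifest recording participant, group, time point, stimulus and the
generating seed.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ERPSample, GROUPS, STIMULI, TIME_POINTS

__all__ = ["FormatError", "write_cohort", "read_cohort", "write_spike_trains",
           "write_reservoir", "read_reservoir", "write_firing_log",
           "fin_edge_list"]


class FormatError(ValueError):
    pass


def _sample_filename(s: ERPSample) -> str:
    return f"{s.participant_id}_{s.time_point}_{s.stimulus}.tsv"


def write_cohort(samples, psychometrics: pd.DataFrame, directory,
                 seed: int | None = None) -> Path:
    """Write samples, psychometrics and a manifest to ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in samples:
        fname = _sample_filename(s)
        df = pd.DataFrame(s.data.T, columns=list(s.channels))
        df.to_csv(d / fname, sep="\t", index=False, float_format="%.6f")
        entries.append(
            {
                "file": fname,
                "participant_id": s.participant_id,
                "group": s.group,
                "time_point": s.time_point,
                "stimulus": s.stimulus,
                "n_channels": len(s.channels),
                "epoch_len": int(s.data.shape[1]),
            }
        )
    psychometrics.to_csv(d / "psychometrics.tsv", sep="\t")
    manifest = {
        "channels": list(samples[0].channels) if samples else [],
        "seed": seed,
        "samples": entries,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return d


def read_cohort(directory, montage=None):
    """Read a cohort directory back into memory.

    Samples are validated against the montage (channel count, labels) and
    channel order is normalised to the montage order.  Dimension or label
    mismatches raise :class:`FormatError` naming the offending file.
    """
    d = Path(directory)
    mpath = d / "manifest.json"
    if not mpath.exists():
        raise FormatError(f"no manifest.json in {d}")
    manifest = json.loads(mpath.read_text())
    if montage is None:
        from .fixtures import load_montage

        montage = load_montage()
    want = list(montage.channels)
    samples = []
    for entry in manifest["samples"]:
        fname = entry["file"]
        if entry["group"] not in GROUPS:
            raise FormatError(
                f"{fname}: unknown group {entry['group']!r}; allowed: {GROUPS}"
            )
        if entry["time_point"] not in TIME_POINTS:
            raise FormatError(
                f"{fname}: unknown time point {entry['time_point']!r}; allowed: {TIME_POINTS}"
            )
        if entry["stimulus"] not in STIMULI:
            raise FormatError(
                f"{fname}: unknown stimulus {entry['stimulus']!r}; allowed: {STIMULI}"
            )
        df = pd.read_csv(d / fname, sep="\t")
        if set(df.columns) != set(want):
            raise FormatError(
                f"{fname}: channel labels do not match the montage "
                f"({len(df.columns)} channels, expected {len(want)})"
            )
        data = df[want].to_numpy(dtype=float).T
        if not np.isfinite(data).all():
            raise FormatError(f"{fname}: non-finite values")
        samples.append(
            ERPSample(
                participant_id=entry["participant_id"],
                group=entry["group"],
                time_point=entry["time_point"],
                stimulus=entry["stimulus"],
                data=data,
                channels=tuple(want),
            )
        )
    ppath = d / "psychometrics.tsv"
    psych = pd.read_csv(ppath, sep="\t", index_col=0) if ppath.exists() else None
    return samples, psych


def write_reservoir(reservoir, directory) -> Path:
    """Serialise a reservoir as a JSON descriptor plus a delimited edge list
    (pre, post, weight) and a coordinate table."""
    import dataclasses

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"pre": reservoir.pre, "post": reservoir.post,
                  "weight": reservoir.weights}).to_csv(
        d / "edges.tsv", sep="\t", index=False)
    pd.DataFrame(reservoir.coords, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
        d / "coords.tsv", sep="\t", index=False)
    meta = {
        "input_channels": list(reservoir.input_channels),
        "input_neurons": reservoir.input_neurons.tolist(),
        "inhibitory": np.flatnonzero(reservoir.inhibitory).tolist(),
        "swc": dataclasses.asdict(reservoir.swc),
    }
    (d / "reservoir.json").write_text(json.dumps(meta, indent=2) + "\n")
    return d


def read_reservoir(directory):
    from .reservoir import Reservoir, SWCConfig

    d = Path(directory)
    meta = json.loads((d / "reservoir.json").read_text())
    edges = pd.read_csv(d / "edges.tsv", sep="\t")
    coords = pd.read_csv(d / "coords.tsv", sep="\t").to_numpy(dtype=float)
    inhibitory = np.zeros(len(coords), dtype=bool)
    inhibitory[meta["inhibitory"]] = True
    return Reservoir(
        coords=coords,
        input_channels=tuple(meta["input_channels"]),
        input_neurons=np.asarray(meta["input_neurons"], dtype=np.int64),
        pre=edges["pre"].to_numpy(np.int64),
        post=edges["post"].to_numpy(np.int64),
        weights=edges["weight"].to_numpy(float),
        inhibitory=inhibitory,
        swc=SWCConfig(**meta["swc"]),
    )


def write_firing_log(log, path) -> Path:
    """Export a firing log as (neuron, t, polarity) triples."""
    p = Path(path)
    pd.DataFrame({"neuron": log.neuron, "t": log.t,
                  "polarity": log.polarity}).to_csv(p, sep="\t", index=False)
    return p


def fin_edge_list(fin: pd.DataFrame) -> pd.DataFrame:
    """Square FIN matrix -> long (source, target, count) edge list,
    nonzero entries only."""
    long = fin.stack()
    long = long[long > 0].reset_index()
    long.columns = ["source", "target", "count"]
    return long


def write_spike_trains(spike_set, path) -> Path:
    """Export a spike-train set as a -1/0/+1 delimited table (rows=time)."""
    p = Path(path)
    pd.DataFrame(spike_set.spikes.T, columns=list(spike_set.channels)).to_csv(
        p, sep="\t", index=False
    )
    return p
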
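"""Summaries of trained reservoirs: activation level, region x hemisphere
weight tables, and feature interaction networks (FIN).

Reservoir neurons are assigned to scalp regions by Voronoi partition over
the input neurons: every neuron belongs to the region of its nearest input
channel.  A connection belongs to its presynaptic neuron's region by default
(postsynaptic and midpoint attribution are available).  Region cells report
the mean absolute connection weight, so inhibitory edges do not cancel
excitatory ones; midline-assigned connections are excluded from hemispheric
cells but included in per-model totals.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnalysisError",
    "RegionWeightTable",
    "activation_level",
    "assign_neuron_regions",
    "region_weights",
    "region_weight_table",
    "build_fin",
]

SITES = ("frontal", "temporal", "frontocentral", "centroparietal", "occipitoparietal")
HEMISPHERES = ("left", "right")


class AnalysisError(ValueError):
    pass


def activation_level(reservoir, signed: bool = False) -> float:
    """Mean connection weight of a trained reservoir (absolute by default)."""
    if reservoir.n_edges == 0:
        raise AnalysisError("reservoir has no connections")
    w = reservoir.weights
    return float(np.mean(w) if signed else np.mean(np.abs(w)))


def assign_neuron_regions(reservoir, regions: pd.DataFrame) -> pd.DataFrame:
    """Per-neuron (channel, site, hemisphere) via nearest input neuron.

    ``regions`` maps channel label -> site, hemisphere (the packaged
    ``regions_fig5`` fixture).
    """
    missing = set(reservoir.input_channels) - set(regions.index)
    if missing:
        raise AnalysisError(f"channels without region assignment: {sorted(missing)}")
    inp_coords = reservoir.coords[reservoir.input_neurons]
    d = np.linalg.norm(
        reservoir.coords[:, None, :] - inp_coords[None, :, :], axis=2
    )
    nearest = np.argmin(d, axis=1)
    chans = [reservoir.input_channels[i] for i in nearest]
    return pd.DataFrame(
        {
            "channel": chans,
            "site": [regions.loc[c, "site"] for c in chans],
            "hemisphere": [regions.loc[c, "hemisphere"] for c in chans],
        }
    )


def _edge_regions(reservoir, neuron_regions: pd.DataFrame, attribution: str):
    if attribution == "pre":
        idx = reservoir.pre
    elif attribution == "post":
        idx = reservoir.post
    elif attribution == "midpoint":
        mid = 0.5 * (reservoir.coords[reservoir.pre] + reservoir.coords[reservoir.post])
        inp_coords = reservoir.coords[reservoir.input_neurons]
        d = np.linalg.norm(mid[:, None, :] - inp_coords[None, :, :], axis=2)
        nearest = np.argmin(d, axis=1)
        site = neuron_regions["site"].to_numpy()[reservoir.input_neurons[nearest]]
        hemi = neuron_regions["hemisphere"].to_numpy()[reservoir.input_neurons[nearest]]
        return site, hemi
    else:
        raise AnalysisError(f"unknown attribution {attribution!r}")
    return (
        neuron_regions["site"].to_numpy()[idx],
        neuron_regions["hemisphere"].to_numpy()[idx],
    )


def region_weights(reservoir, regions: pd.DataFrame, attribution: str = "pre",
                   signed: bool = False) -> pd.DataFrame:
    """Mean (absolute) weight per site x hemisphere for one reservoir.

    Returns a DataFrame with one row per (site, hemisphere) plus columns
    ``mean_w`` and ``n_edges``; cells with no member connection carry NaN and
    are flagged ``missing``.  The per-model total (unweighted mean over all
    connections, midline included) is attached as ``df.attrs['total']``.
    """
    if reservoir.n_edges == 0:
        raise AnalysisError("reservoir has no connections")
    nr = assign_neuron_regions(reservoir, regions)
    site, hemi = _edge_regions(reservoir, nr, attribution)
    w = reservoir.weights if signed else np.abs(reservoir.weights)
    rows = []
    for s in SITES:
        for h in HEMISPHERES:
            sel = (site == s) & (hemi == h)
            n = int(sel.sum())
            rows.append(
                {
                    "site": s,
                    "hemisphere": h,
                    "mean_w": float(w[sel].mean()) if n else np.nan,
                    "n_edges": n,
                    "missing": n == 0,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["total"] = float(w.mean())
    return out


@dataclass(frozen=True)
class RegionWeightTable:
    """Region weights for a set of trained models.

    ``per_model`` has one row per model x site x hemisphere (long format,
    with the model's metadata columns); ``cells`` averages over the
    participants within each group x time x stimulus cell and appends the
    per-cell mean total weight.
    """

    per_model: pd.DataFrame
    cells: pd.DataFrame
    totals: pd.DataFrame


def region_weight_table(models, regions: pd.DataFrame, attribution: str = "pre",
                        signed: bool = False) -> RegionWeightTable:
    """Aggregate region weights across trained per-participant models.

    Parameters
    ----------
    models : iterable of (meta, reservoir)
        ``meta`` is a mapping with at least ``participant_id``, ``group``,
        ``time_point``, ``stimulus``.
    """
    long_rows = []
    for meta, res in models:
        rw = region_weights(res, regions, attribution=attribution, signed=signed)
        for _, r in rw.iterrows():
            long_rows.append({**meta, **r.to_dict(), "total_w": rw.attrs["total"]})
    if not long_rows:
        raise AnalysisError("no models supplied")
    per_model = pd.DataFrame(long_rows)
    keys = ["group", "time_point", "stimulus"]
    cells = (
        per_model.groupby(keys + ["site", "hemisphere"], sort=True)["mean_w"]
        .mean()
        .reset_index()
    )
    totals = (
        per_model.drop_duplicates(subset=keys + ["participant_id"])
        .groupby(keys, sort=True)["total_w"]
        .mean()
        .reset_index()
    )
    return RegionWeightTable(per_model=per_model, cells=cells, totals=totals)


def build_fin(log, reservoir, clusters=None, channels=None) -> pd.DataFrame:
    """Feature interaction network: spike transmission counts between input
    clusters.

    Entry (a, b) counts spikes emitted by neurons of cluster ``a`` that are
    delivered along existing edges to neurons of cluster ``b`` during the
    logged run.  By default clusters are the Voronoi cells of the input
    neurons, one per channel.
    """
    n = reservoir.n_neurons
    if clusters is None:
        inp_coords = reservoir.coords[reservoir.input_neurons]
        d = np.linalg.norm(
            reservoir.coords[:, None, :] - inp_coords[None, :, :], axis=2
        )
        clusters = np.argmin(d, axis=1)
        channels = list(reservoir.input_channels)
    clusters = np.asarray(clusters)
    if clusters.shape[0] != n or np.any(clusters < 0):
        raise AnalysisError("every reservoir neuron needs a cluster assignment")
    n_clusters = int(clusters.max()) + 1 if clusters.size else 0
    if channels is None:
        channels = [str(i) for i in range(n_clusters)]
    events_per_neuron = np.bincount(log.neuron, minlength=n)
    mat = np.zeros((len(channels), len(channels)), dtype=np.int64)
    np.add.at(
        mat,
        (clusters[reservoir.pre], clusters[reservoir.post]),
        events_per_neuron[reservoir.pre],
    )
    return pd.DataFrame(mat, index=channels, columns=channels)
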
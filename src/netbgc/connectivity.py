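"""Functional-connectivity matrices and between-network global connectivity.

The central statistic of the package is *between-network global connectivity*
(BGC).  For a region ``i`` belonging to network ``C`` it is the mean
functional-connectivity weight from ``i`` to every region outside ``C``::

    BGC_i = sum_{j not in C} W_ij / (N_total - N_C)

where ``W`` is the region-by-region Pearson correlation matrix, ``N_total``
the total number of regions and ``N_C`` the size of ``i``'s network.  Because
the denominator excludes the region's own network, the statistic is not
inflated for regions that happen to sit in large networks, unlike plain
weighted degree.  A network-level BGC is the unweighted mean of the regional
values over the network's members.

Connectivity weights are averaged as raw Pearson r (no Fisher transform
before averaging): the statistic is defined directly on the FC weights and
its typical values after global-signal regression are near zero, where the
transform is immaterial anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NetworkPartition",
    "FCMatrix",
    "BGCProfile",
    "fc_matrix",
    "bgc_profile",
    "within_network_fc",
    "bgc_excluding",
    "between_network_fc",
]


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of ordered regions to functional networks.

    Region order is the single source of truth for every matrix in the
    package: FC matrices and time series are validated against it.
    """

    region_ids: tuple
    network_of: tuple

    def __post_init__(self):
        if len(self.region_ids) != len(self.network_of):
            raise ValueError("region_ids and network_of must have equal length")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("duplicate region ids")
        if len(self.networks) < 2:
            raise ValueError("a partition needs at least 2 networks")

    @property
    def networks(self) -> tuple:
        """Network labels in order of first appearance."""
        seen: dict = {}
        for n in self.network_of:
            seen.setdefault(n, None)
        return tuple(seen)

    @property
    def n_total(self) -> int:
        return len(self.region_ids)

    @property
    def sizes(self) -> dict:
        out: dict = {}
        for n in self.network_of:
            out[n] = out.get(n, 0) + 1
        return out

    def indices(self, network) -> np.ndarray:
        """Row/column indices of the given network's regions."""
        if network not in self.networks:
            raise KeyError(f"unknown network {network!r}")
        labels = np.asarray(self.network_of, dtype=object)
        return np.flatnonzero(labels == network)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region_id": list(self.region_ids), "network": list(self.network_of)}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NetworkPartition":
        if not {"region_id", "network"} <= set(df.columns):
            raise ValueError("partition table needs columns region_id, network")
        return cls(tuple(df["region_id"]), tuple(df["network"]))


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric region-by-region Pearson correlation matrix."""

    values: np.ndarray
    region_ids: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if v.shape[0] != len(self.region_ids):
            raise ValueError("region_ids length does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _check_alignment(fc: FCMatrix, partition: NetworkPartition) -> None:
    if tuple(fc.region_ids) != tuple(partition.region_ids):
        raise ValueError("FC matrix region order does not match partition")


@dataclass(frozen=True)
class BGCProfile:
    """Per-region BGC values plus their per-network means."""

    region_bgc: np.ndarray
    network_bgc: Mapping
    region_ids: tuple
    excluded_networks: frozenset = field(default_factory=frozenset)


def fc_matrix(data: np.ndarray, region_ids: Sequence) -> FCMatrix:
    """Sample Pearson correlation between every pair of region time series.

    Parameters
    ----------
    data : array, regions x frames
        Cleaned BOLD time series (only retained frames).
    region_ids : sequence
        Region labels in row order.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a regions x frames matrix")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 frames to correlate")
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [region_ids[i] for i in dead]
        raise ValueError(f"zero-variance region(s): {names}")
    w = np.corrcoef(x)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 1.0)
    return FCMatrix(w, tuple(region_ids))


def _region_means(
    fc: FCMatrix, partition: NetworkPartition, source: object, excluded: Iterable
) -> np.ndarray:
    """Mean FC from each region of `source` to all regions whose network is
    neither `source` nor in `excluded`.  Shared kernel for bgc_profile and
    bgc_excluding so the two agree bitwise when `excluded` is empty."""
    excluded = set(excluded)
    rows = partition.indices(source)
    labels = np.asarray(partition.network_of, dtype=object)
    allowed = np.flatnonzero(
        (labels != source) & ~np.isin(labels, sorted(excluded, key=str))
    )
    if allowed.size == 0:
        raise ValueError(
            f"no eligible target regions for network {source!r} "
            f"after excluding {sorted(map(str, excluded))}"
        )
    return fc.values[np.ix_(rows, allowed)].mean(axis=1)


def bgc_profile(fc: FCMatrix, partition: NetworkPartition) -> BGCProfile:
    """Between-network global connectivity for every region and network.

    Each region's value is the mean correlation to all out-of-network
    regions; the diagonal never enters (a region's own network contains it).
    """
    _check_alignment(fc, partition)
    region_bgc = np.empty(partition.n_total, dtype=float)
    network_bgc: dict = {}
    for net in partition.networks:
        rows = partition.indices(net)
        vals = _region_means(fc, partition, net, ())
        region_bgc[rows] = vals
        network_bgc[net] = float(vals.mean())
    return BGCProfile(region_bgc, network_bgc, tuple(partition.region_ids))


def within_network_fc(fc: FCMatrix, partition: NetworkPartition, network) -> float:
    """Mean FC over unordered within-network region pairs (diagonal excluded)."""
    _check_alignment(fc, partition)
    idx = partition.indices(network)
    if idx.size < 2:
        raise ValueError(f"network {network!r} has fewer than 2 regions")
    block = fc.values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(block[iu].mean())


def bgc_excluding(
    fc: FCMatrix, partition: NetworkPartition, network, excluded: Iterable = ()
) -> float:
    """Network-level BGC with connections to `excluded` networks removed.

    Used for the control analysis asking whether a network's BGC-symptom
    association is driven by its coupling to a small set of companion
    networks: those networks' regions are dropped from the target set.
    With an empty exclusion set this is exactly the network's ordinary BGC.
    """
    _check_alignment(fc, partition)
    vals = _region_means(fc, partition, network, excluded)
    return float(vals.mean())


def between_network_fc(
    fc: FCMatrix, partition: NetworkPartition, net_a, net_b
) -> float:
    """Mean FC over all region pairs spanning two distinct networks."""
    _check_alignment(fc, partition)
    if net_a == net_b:
        raise ValueError("networks must differ; use within_network_fc")
    ia = partition.indices(net_a)
    ib = partition.indices(net_b)
    return float(fc.values[np.ix_(ia, ib)].mean())
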
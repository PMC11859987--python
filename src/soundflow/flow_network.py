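"""Directed acoustic flow networks from transfer-entropy matrices.

For every unordered site pair the two directed TE values are reduced to a
net flow DTEM = TE(X->Y) - TE(Y->X); the arrow points toward the larger
(exact ties emit no arrow).  Arrows whose oriented DTEM exceeds a percentile
cutoff — computed over the pooled oriented values of one (index, estimator,
q) configuration — are drawn as edges with their Euclidean length attached.
Summary statistics follow the flow-map reading of the analysis:

* emission/reception profile: row sums (information emitted from a site) and
  column sums (received), whose difference classifies biophonic 'hot'
  (net-emitting) and 'cold' (net-receiving) sites;
* arrow density: edges attributed to a site group (by source site) divided
  by the group size;
* normalized distance index (NDI): mean edge length over the maximum drawn
  edge length, d_n = (1/n) sum d_i / d_max in (0, 1] — a proxy for the
  spatial scale of acoustic interconnection.

Time-of-day periods follow dawn [05:00, 08:00), day [08:00, 18:00) and
night [18:00, 05:00) with night wrapping midnight.  When periods are
compared, all period networks share one percentile cutoff pooled across
periods, so a period with systematically stronger net flows (dawn) keeps
more arrows than a quiet one (night).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .sites import SiteMap

__all__ = [
    "FlowEdge",
    "FlowNetwork",
    "split_periods",
    "dtem",
    "percentile_threshold",
    "oriented_flows",
    "build_network",
    "emission_reception",
    "arrow_density",
    "ndi",
    "period_networks",
]

PERIODS = ("dawn", "day", "night")


def split_periods(timestamps) -> pd.Series:
    """Label each timestamp dawn/day/night by local time of day.

    Half-open intervals: dawn [05:00, 08:00), day [08:00, 18:00), night
    [18:00, 05:00) wrapping midnight; every window gets exactly one label.
    """
    ts = pd.to_datetime(pd.Series(timestamps))
    hours = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    labels = np.where(
        (hours >= 5.0) & (hours < 8.0),
        "dawn",
        np.where((hours >= 8.0) & (hours < 18.0), "day", "night"),
    )
    return pd.Series(labels, index=ts.index, name="period")


def dtem(te_forward: float, te_reverse: float):
    """Oriented net flow: (magnitude, direction) with direction in
    {'forward', 'reverse', None}; an exact tie yields no direction."""
    diff = te_forward - te_reverse
    if diff > 0:
        return diff, "forward"
    if diff < 0:
        return -diff, "reverse"
    return 0.0, None


def percentile_threshold(values, p: float) -> float:
    """Linear-interpolation percentile of a pooled value set."""
    values = np.asarray(list(values), float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a percentile cutoff")
    return float(np.percentile(values, p))


@dataclass
class FlowEdge:
    source: object
    target: object
    dtem: float          # oriented net flow, > 0
    te_forward: float    # TE(source -> target)
    te_reverse: float    # TE(target -> source)
    d_i: float           # Euclidean arrow length, m


@dataclass
class FlowNetwork:
    """Thresholded directed arrows plus their geometry and summaries."""

    edges: list = field(default_factory=list)
    percentile_used: float = 95.0
    threshold_value: float = 0.0
    d_max_mode: str = "arrows"   # or "all_pairs"
    d_max: float = float("nan")
    period_label: str = "all"
    ties: list = field(default_factory=list)

    @property
    def n_bar(self) -> int:
        return len(self.edges)

    @property
    def d_n(self) -> float:
        """Normalized distance index; NaN (flagged) on an empty network."""
        if self.n_bar == 0 or not np.isfinite(self.d_max) or self.d_max <= 0:
            return float("nan")
        return float(np.mean([e.d_i for e in self.edges]) / self.d_max)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for e in self.edges:
            g.add_edge(e.source, e.target, dtem=e.dtem, d_i=e.d_i,
                       te_forward=e.te_forward, te_reverse=e.te_reverse)
        return g

    def to_dict(self) -> dict:
        return {
            "period": self.period_label,
            "percentile": self.percentile_used,
            "threshold_bits": self.threshold_value,
            "n_bar": self.n_bar,
            "d_max_m": self.d_max,
            "d_max_mode": self.d_max_mode,
            "d_n": self.d_n,
            "edges": [
                {
                    "source": str(e.source), "target": str(e.target),
                    "dtem_bits": e.dtem, "te_forward": e.te_forward,
                    "te_reverse": e.te_reverse, "d_i_m": e.d_i,
                }
                for e in self.edges
            ],
            "ties": [[str(a), str(b)] for a, b in self.ties],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def oriented_flows(te_matrix: pd.DataFrame) -> list[tuple]:
    """(source, target, dtem, te_fwd, te_rev) per non-tied unordered pair."""
    sites = list(te_matrix.index)
    out = []
    for a, b in itertools.combinations(sites, 2):
        fwd = float(te_matrix.loc[a, b])
        rev = float(te_matrix.loc[b, a])
        mag, direction = dtem(fwd, rev)
        if direction == "forward":
            out.append((a, b, mag, fwd, rev))
        elif direction == "reverse":
            out.append((b, a, mag, rev, fwd))
        else:
            out.append((a, b, 0.0, fwd, rev, "tie"))
    return out


def build_network(
    te_matrix: pd.DataFrame,
    site_map: SiteMap,
    p: float = 95.0,
    pool=None,
    d_max_mode: str = "arrows",
    period_label: str = "all",
) -> FlowNetwork:
    """Orient every pair, keep arrows strictly above the percentile cutoff.

    ``pool`` supplies the oriented-DTEM values over which the cutoff is
    computed; by default the matrix's own oriented values (pass a pooled
    vector to share a cutoff across periods).  ``d_max_mode='arrows'`` reads
    d_max as the longest drawn arrow (so a single-arrow network has
    d_n = 1); ``'all_pairs'`` uses the site diameter instead.
    """
    missing = set(te_matrix.index) - set(site_map.site_ids)
    if missing:
        raise ValueError(f"sites missing coordinates: {sorted(missing)}")
    flows = oriented_flows(te_matrix)
    ties = [(f[0], f[1]) for f in flows if len(f) == 6]
    flows = [f for f in flows if len(f) == 5]
    if pool is None:
        pool = [f[2] for f in flows]
    cutoff = percentile_threshold(pool, p)
    edges = [
        FlowEdge(src, tgt, mag, fwd, rev, site_map.distance(src, tgt))
        for src, tgt, mag, fwd, rev in flows
        if mag > cutoff
    ]
    if d_max_mode == "arrows":
        d_max = max((e.d_i for e in edges), default=float("nan"))
    elif d_max_mode == "all_pairs":
        ids = site_map.site_ids
        d_max = max(
            site_map.distance(a, b) for a, b in itertools.combinations(ids, 2)
        )
    else:
        raise ValueError("d_max_mode must be 'arrows' or 'all_pairs'")
    return FlowNetwork(
        edges=edges,
        percentile_used=p,
        threshold_value=cutoff,
        d_max_mode=d_max_mode,
        d_max=d_max,
        period_label=period_label,
        ties=ties,
    )


def emission_reception(te_matrix: pd.DataFrame) -> pd.DataFrame:
    """Total TE emitted/received per site, net flow, hot/cold class.

    emitted(X) = sum_Y TE(X->Y) (row sum), received(X) = sum_Y TE(Y->X)
    (column sum); the nets cancel pairwise, so their exact (fsum) total is 0.
    """
    t = te_matrix.to_numpy(float)
    np.fill_diagonal(t, 0.0)
    emitted = t.sum(axis=1)
    received = t.sum(axis=0)
    net = np.array(
        [
            math.fsum(t[i, :]) - math.fsum(t[:, i])
            for i in range(t.shape[0])
        ]
    )
    return pd.DataFrame(
        {
            "emitted": emitted,
            "received": received,
            "net": net,
            "classification": np.where(
                net > 0, "hot", np.where(net < 0, "cold", "neutral")
            ),
        },
        index=te_matrix.index,
    )


def total_net_flow(te_matrix: pd.DataFrame) -> float:
    """Exactly-summed total net emission (0 for any complete matrix)."""
    t = te_matrix.to_numpy(float)
    np.fill_diagonal(t, 0.0)
    diff = t - t.T  # antisymmetric entry-by-entry in exact float arithmetic
    return math.fsum(diff.ravel())


def arrow_density(
    network: FlowNetwork, site_map: SiteMap, groups: dict | None = None
) -> dict:
    """Arrows per site for each site group, attributed by source site."""
    if groups is None:
        groups = {
            g: ids for g, ids in site_map.groups().items() if g != "none"
        }
    for g, ids in groups.items():
        if len(ids) == 0:
            raise ValueError(f"empty site group {g!r}")
    counts = {g: 0 for g in groups}
    lookup = {sid: g for g, ids in groups.items() for sid in ids}
    for e in network.edges:
        g = lookup.get(e.source)
        if g is not None:
            counts[g] += 1
    return {g: counts[g] / len(ids) for g, ids in groups.items()}


def ndi(network: FlowNetwork) -> float:
    """Normalized distance index d_n of a network (NaN when empty)."""
    return network.d_n


def period_networks(
    te_by_period: dict,
    site_map: SiteMap,
    p: float = 95.0,
    d_max_mode: str = "arrows",
) -> dict:
    """Build one network per period with a shared cross-period cutoff.

    ``te_by_period`` maps period label -> TE matrix from that period's
    windows (one estimator/index configuration).  The percentile pool is the
    union of every period's oriented DTEM values, matching the way period
    densities are compared against common percentile lines.
    """
    flows = {
        label: [f for f in oriented_flows(mat) if len(f) == 5]
        for label, mat in te_by_period.items()
    }
    pool = [f[2] for fl in flows.values() for f in fl]
    return {
        label: build_network(
            mat, site_map, p=p, pool=pool, d_max_mode=d_max_mode,
            period_label=label,
        )
        for label, mat in te_by_period.items()
    }
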
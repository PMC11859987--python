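"""Directed flow networks, arrow densities and normalized distance index.

Orients every site pair by its net transfer DTEM = TE(X->Y) - TE(Y->X) and
keeps arrows strictly above the 95th percentile of the oriented values of
one (index, estimator) configuration.  For the river park the percentile
pool is shared across dawn/day/night so period arrow counts are comparable;
for the urban park the single network is summarized by internal- vs
external-group arrow density.  NDI (d_n) is reported per network; the
cross-period comparison uses the site-diameter normalization, the
single-network summaries the longest-drawn-arrow one.

Reads results/te/, writes results/networks/ plus coordinate flow plots.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from soundflow import flow_network as fn
from soundflow.sites import SiteMap, river_park_sites, urban_park_sites

ROOT = Path(__file__).resolve().parent.parent / "results"
ESTIMATOR_TAGS = ["shannon", "renyi_q0.1", "renyi_q0.5"]


def load_te(tag, label):
    return pd.read_csv(ROOT / "te" / f"{tag}_{label}.csv", index_col=0)


def plot_network(net, site_map: SiteMap, path):
    fig, ax = plt.subplots(figsize=(5, 5))
    pts = site_map.active
    ax.scatter(pts["x"], pts["y"], c="seagreen", zorder=3)
    for sid, row in pts.iterrows():
        ax.annotate(str(sid), (row["x"], row["y"]),
                    textcoords="offset points", xytext=(4, 4))
    if site_map.road is not None:
        (x0, y0), (x1, y1) = site_map.road
        ax.plot([x0, x1], [y0, y1], "r--", lw=2, label="road")
    for e in net.edges:
        a, b = site_map.coords(e.source), site_map.coords(e.target)
        ax.annotate(
            "", xy=b, xytext=a,
            arrowprops=dict(arrowstyle="-|>", color="steelblue", lw=1.2),
        )
    ax.set_title(f"{net.period_label}: {net.n_bar} arrows, "
                 f"d_n={net.d_n:.2f}" if net.n_bar else "no arrows")
    ax.set_aspect("equal")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def main() -> None:
    out = ROOT / "networks"
    out.mkdir(parents=True, exist_ok=True)
    maps = {"urban": urban_park_sites(), "river": river_park_sites()}
    rep_index = {}
    for name in maps:
        with open(ROOT / "pca" / f"{name}_pca.json") as fh:
            rep_index[name] = [
                r["index"]
                for r in json.load(fh)["representatives"]
            ]
    summary = {}

    for name, site_map in maps.items():
        for index_name in dict.fromkeys(rep_index[name]):
            for est in ESTIMATOR_TAGS:
                tag = f"{name}_{index_name}_{est}"
                full = load_te(tag, "all")
                full.index = full.index.astype(str)
                full.columns = full.columns.astype(str)
                sm = relabel(site_map)
                net = fn.build_network(full, sm, p=95)
                net.to_json(out / f"{tag}_all.json")
                entry = {
                    "n_bar": net.n_bar,
                    "d_n": net.d_n,
                    "density_by_group": fn.arrow_density(net, sm),
                }
                if name == "river":
                    per = {
                        lab: load_te(tag, lab) for lab in fn.PERIODS
                    }
                    for lab in per:
                        per[lab].index = per[lab].index.astype(str)
                        per[lab].columns = per[lab].columns.astype(str)
                    nets = fn.period_networks(
                        per, sm, p=95, d_max_mode="all_pairs"
                    )
                    entry["arrows_by_period"] = {
                        lab: n.n_bar for lab, n in nets.items()
                    }
                    entry["dn_by_period"] = {
                        lab: n.d_n for lab, n in nets.items()
                    }
                    for lab, n in nets.items():
                        n.to_json(out / f"{tag}_{lab}.json")
                        plot_network(n, sm, out / f"{tag}_{lab}.png")
                plot_network(net, sm, out / f"{tag}_all.png")
                summary[tag] = entry
                if est == "shannon":
                    print(f"{tag}: {entry['n_bar']} arrows, "
                          f"density by group {entry['density_by_group']}")
                    if "arrows_by_period" in entry:
                        print(f"  arrows by period: "
                              f"{entry['arrows_by_period']}")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)


def relabel(site_map: SiteMap) -> SiteMap:
    """String site ids to match the CSV round trip of the TE matrices."""
    table = site_map.table.assign(site_id=site_map.table["site_id"].astype(str))
    excluded = {str(k): v for k, v in site_map.excluded.items()}
    return SiteMap(table, excluded=excluded, road=site_map.road)


if __name__ == "__main__":
    main()
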
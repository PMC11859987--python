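"""All-pairs transfer-entropy matrices for the representative indices.

For each park and each representative index (the Dim-1 representative and
BI), estimates Shannon TE and Renyi TE (q = 0.1 and 0.5) between every
ordered site pair from tail-coded symbols (5th/95th-percentile bins).  The
river park's duty-cycle series are additionally split into dawn
[05:00, 08:00), day [08:00, 18:00) and night [18:00, 05:00) windows before
estimation.  Also reports each site's total emitted and received TE and its
biophonic hot/cold classification.

Reads results/data/ and results/pca/, writes results/te/.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from soundflow import flow_network as fn
from soundflow import transfer_entropy as te
from soundflow.index_engine import contiguity_blocks

ROOT = Path(__file__).resolve().parent.parent / "results"
WINDOW_STEP = {"urban": 60.0, "river": 360.0}
ESTIMATORS = [("shannon", None), ("renyi", 0.1), ("renyi", 0.5)]


def series_by_site(matrix, index_name, step, mask=None):
    series, blocks = {}, {}
    sel = matrix if mask is None else matrix.loc[mask]
    for sid, grp in sel.groupby("site_id", sort=True):
        grp = grp.sort_values("timestamp")
        series[sid] = grp[index_name].to_numpy(float)
        blocks[sid] = contiguity_blocks(grp["timestamp"], step)
    return series, blocks


def representative_indices(name):
    with open(ROOT / "pca" / f"{name}_pca.json") as fh:
        reps = json.load(fh)["representatives"]
    return list(dict.fromkeys(r["index"] for r in reps))


def main() -> None:
    out = ROOT / "te"
    out.mkdir(parents=True, exist_ok=True)
    for name in ("urban", "river"):
        matrix = pd.read_csv(
            ROOT / "data" / f"{name}_indices.csv", parse_dates=["timestamp"]
        )
        step = WINDOW_STEP[name]
        periods = fn.split_periods(matrix["timestamp"])
        labels = ["all"] + (list(fn.PERIODS) if name == "river" else [])
        for index_name in representative_indices(name):
            for est, q in ESTIMATORS:
                params = te.TEParams(estimator=est, q=q)
                tag = f"{name}_{index_name}_{est}" + (
                    f"_q{q}" if q is not None else ""
                )
                for label in labels:
                    mask = None if label == "all" else (periods == label)
                    series, blocks = series_by_site(
                        matrix, index_name, step, mask
                    )
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        mat = te.te_matrix(
                            series, params, blocks_by_site=blocks,
                            period_label=label,
                        )
                    mat.to_csv(out / f"{tag}_{label}.csv")
                    if label == "all" and est == "shannon":
                        prof = fn.emission_reception(mat)
                        prof.to_csv(out / f"{name}_{index_name}_emission.csv")
                        hot = prof.index[prof["classification"] == "hot"]
                        print(
                            f"{name}/{index_name}: mean STE "
                            f"{mat.to_numpy().mean():.4f} bits; "
                            f"hot (net-emitting) sites: {list(hot)}"
                        )


if __name__ == "__main__":
    main()
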
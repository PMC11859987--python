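"""PCA over each park's index matrix and representative-index selection.

Pools all (site, window) observations per park, standardizes the eight
index columns, and reports explained variances, the cumulative EV of the
first two dimensions, and per-index contributions.  The downstream TE
analysis tracks one representative index per retained dimension: the top
Dim-1 contributor, and BI for Dim 2 by manual override (BI reads directly
as biophony level, which is the quantity the flow networks are meant to
trace, so interpretability wins over a few contribution points).

Reads results/data/, writes results/pca/.
"""

import json
from pathlib import Path

import pandas as pd

from soundflow import dimension_reduction as dr

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "pca"
    out.mkdir(parents=True, exist_ok=True)
    for name in ("urban", "river"):
        matrix = pd.read_csv(ROOT / "data" / f"{name}_indices.csv")
        z, dropped = dr.standardize(matrix)
        res = dr.run_pca(z)
        kept, cum = dr.retain_dimensions(res, k=2)
        reps = dr.select_representatives(res, kept, overrides={2: "BI"})
        ev = ", ".join(f"{100 * v:.1f}" for v in res.explained_variance)
        print(f"{name}: EV per dimension = ({ev})%")
        print(
            f"{name}: first two dimensions carry {100 * cum:.1f}% of the "
            f"variance; representatives: "
            + ", ".join(
                f"Dim{r.dimension}={r.chosen_index} "
                f"({r.contribution_pct:.0f}%, {r.policy})"
                for r in reps
            )
        )
        payload = res.to_dict()
        payload["retained"] = kept
        payload["cumulative_ev_retained"] = cum
        payload["representatives"] = [
            {
                "dimension": r.dimension,
                "index": r.chosen_index,
                "policy": r.policy,
                "contribution_pct": r.contribution_pct,
            }
            for r in reps
        ]
        with open(out / f"{name}_pca.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        res.loadings.to_csv(out / f"{name}_loadings.csv")


if __name__ == "__main__":
    main()
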
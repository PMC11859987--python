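"""Ground-truth the flow maps against the aural-survey label fractions.

Summarizes each park's survey table into per-site fractions of recordings
with many birds singing and with high traffic intensity, then checks the
separation the flow analysis predicts: interior sites should show high
many-birds and low high-traffic fractions, road-side sites the reverse.

Reads results/data/, writes results/survey/.
"""

from pathlib import Path

import pandas as pd

from soundflow.reporting import summarize_survey
from soundflow.sites import river_park_sites, urban_park_sites

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "survey"
    out.mkdir(parents=True, exist_ok=True)
    maps = {"urban": urban_park_sites(), "river": river_park_sites()}
    for name, site_map in maps.items():
        table = pd.read_csv(ROOT / "data" / f"{name}_survey.csv")
        summary = summarize_survey(table)
        summary.round(2).to_csv(out / f"{name}_summary.csv")
        groups = site_map.active["group"]
        merged = summary.join(groups)
        by_group = merged.groupby("group")[
            ["many_birds", "high_traffic"]
        ].mean()
        print(f"{name} mean fractions by site group:")
        print(by_group.round(2).to_string())


if __name__ == "__main__":
    main()
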
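"""Survey summarization and end-to-end pipeline orchestration.

The aural-survey table records, per labelled 1-min recording, what a single
expert listener perceived: how many birds were singing (none/few/many), how
many species, the singing-time fraction band, and the character and
intensity of traffic noise.  :func:`summarize_survey` reduces it to the two
per-site fractions used for ground-truthing flow maps — recordings with
*many* birds singing and recordings with *high* traffic intensity.

:func:`run_pipeline` chains the whole analysis over a synthetic soundscape:
index matrix -> PCA -> representative indices -> per-period TE matrices
(Shannon, plus Renyi at the configured q values) -> thresholded flow
networks with densities and NDI -> survey summary.  Every artifact carries
the exact configuration that produced it, and a rerun with the same
configuration is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dimension_reduction as dr
from . import flow_network as fn
from . import transfer_entropy as te
from .index_engine import INDEX_NAMES, contiguity_blocks
from .synthetic import (
    SoundscapeSpec,
    SurveyThresholds,
    gen_soundscape,
    gen_survey_labels,
)

__all__ = [
    "SURVEY_VOCABULARY",
    "validate_survey",
    "summarize_survey",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]

SURVEY_VOCABULARY = {
    "birds_singing": {"none", "few", "many"},
    "bird_species": {"none", "<=2", ">2"},
    "singing_activity": {"0", "(0, 25]", "(25, 50]", "(50, 75]", "(75, 100]"},
    "traffic_characteristics": {"none", "continuous", "intermittent"},
    "traffic_intensity": {"none", "low", "high"},
    "other_sources": {"none", "presence"},
}


def validate_survey(table: pd.DataFrame) -> None:
    """Reject any label outside the closed survey vocabulary, by row."""
    if len(table) == 0:
        raise ValueError("empty survey table")
    for col, vocab in SURVEY_VOCABULARY.items():
        if col not in table.columns:
            raise ValueError(f"survey table missing column {col!r}")
        bad = ~table[col].isin(vocab)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"unknown label {table[col].iloc[row]!r} in column {col!r} "
                f"at row {row}"
            )


def summarize_survey(table: pd.DataFrame) -> pd.DataFrame:
    """Per-site fractions of many-birds and high-traffic recordings.

    Fractions are labelled-count / total-count at full precision (round only
    for display); sites with no recordings are excluded with a warning.
    """
    validate_survey(table)
    rows = []
    for sid, grp in table.groupby("site_id", sort=True):
        n = len(grp)
        if n == 0:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"site {sid!r} has no recordings; excluded")
            continue
        rows.append(
            {
                "site_id": sid,
                "many_birds": float((grp["birds_singing"] == "many").mean()),
                "high_traffic": float(
                    (grp["traffic_intensity"] == "high").mean()
                ),
                "n_recordings": n,
            }
        )
    return pd.DataFrame(rows).set_index("site_id")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """One structured configuration drives a full run."""

    soundscape: SoundscapeSpec = field(default_factory=SoundscapeSpec)
    keep_dimensions: int = 2
    representative_overrides: dict | None = None
    renyi_q: tuple = (0.1, 0.5)
    percentile: float = 95.0
    boundaries: tuple = (5.0, 95.0)
    split_by_period: bool = True
    survey_thresholds: SurveyThresholds = field(
        default_factory=SurveyThresholds
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["soundscape"].pop("site_map", None)
        d["soundscape"]["site_ids"] = list(self.soundscape.site_map.site_ids)
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    index_matrix: pd.DataFrame
    pca: dr.PCAResult
    representatives: list
    te_matrices: dict     # (index, estimator, q, period) -> DataFrame
    networks: dict        # (index, estimator, q) -> {period: FlowNetwork}
    densities: dict       # (index, estimator, q) -> {period or group: value}
    ndi: dict             # (index, estimator, q) -> {period: d_n}
    emission: dict        # (index, estimator, q) -> DataFrame (all-period)
    survey_summary: pd.DataFrame

    def write(self, outdir) -> None:
        """Persist every stage as delimited text / JSON with provenance."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.json", "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=2, sort_keys=True,
                      default=str)
        self.index_matrix.to_csv(out / "index_matrix.csv", index=False)
        with open(out / "pca.json", "w") as fh:
            payload = self.pca.to_dict()
            payload["representatives"] = [
                dataclasses.asdict(r) for r in self.representatives
            ]
            json.dump(payload, fh, indent=2, sort_keys=True)
        for key, mat in self.te_matrices.items():
            name = "te_" + "_".join(str(k) for k in key) + ".csv"
            mat.to_csv(out / name)
        for key, by_period in self.networks.items():
            for period, net in by_period.items():
                name = "network_" + "_".join(str(k) for k in key)
                net.to_json(out / f"{name}_{period}.json")
        summary = {
            "densities": {
                "_".join(map(str, k)): v for k, v in self.densities.items()
            },
            "ndi": {"_".join(map(str, k)): v for k, v in self.ndi.items()},
        }
        with open(out / "network_summaries.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        self.survey_summary.to_csv(out / "survey_summary.csv")


def _series_by_site(index_matrix, index_name, mask=None):
    series = {}
    blocks = {}
    step = index_matrix.attrs.get("window_s") or index_matrix.attrs.get(
        "window_step_s"
    )
    for sid, grp in index_matrix.groupby("site_id", sort=True):
        grp = grp.sort_values("timestamp")
        sel = grp if mask is None else grp.loc[mask.reindex(grp.index,
                                                            fill_value=False)]
        series[sid] = sel[index_name].to_numpy(float)
        if step is not None and len(sel):
            blocks[sid] = contiguity_blocks(sel["timestamp"], float(step))
    return series, (blocks or None)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis on one seeded synthetic soundscape."""
    real = gen_soundscape(config.soundscape)
    matrix = real.index_matrix
    spec = config.soundscape
    window_step = (
        spec.window_s if spec.protocol == "continuous"
        else spec.window_s + spec.pause_s
    )
    matrix.attrs["window_s"] = window_step

    z, _ = dr.standardize(matrix)
    pca = dr.run_pca(z)
    kept, _ = dr.retain_dimensions(pca, k=config.keep_dimensions)
    reps = dr.select_representatives(
        pca, kept, overrides=config.representative_overrides
    )
    rep_indices = list(dict.fromkeys(r.chosen_index for r in reps))

    periods = fn.split_periods(matrix["timestamp"])
    period_labels = (
        list(fn.PERIODS) if config.split_by_period else []
    )
    scheme = te.DiscretizationScheme(boundaries=config.boundaries)
    estimators = [("shannon", None)] + [("renyi", q) for q in config.renyi_q]

    te_matrices = {}
    networks = {}
    densities = {}
    ndis = {}
    emission = {}
    for index_name in rep_indices:
        for est, q in estimators:
            params = te.TEParams(estimator=est, q=q)
            key = (index_name, est, q if q is not None else "")
            per_period = {}
            series, blocks = _series_by_site(matrix, index_name)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = te.te_matrix(series, params, scheme, blocks)
            te_matrices[(index_name, est, q, "all")] = full
            emission[key] = fn.emission_reception(full)
            for period in period_labels:
                mask = periods == period
                p_series, p_blocks = _series_by_site(
                    matrix, index_name, mask
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    per_period[period] = te.te_matrix(
                        p_series, params, scheme, p_blocks,
                        period_label=period,
                    )
                te_matrices[(index_name, est, q, period)] = (
                    per_period[period]
                )
            nets = {}
            nets["all"] = fn.build_network(
                full, spec.site_map, p=config.percentile, period_label="all"
            )
            if per_period:
                nets.update(
                    fn.period_networks(
                        per_period, spec.site_map, p=config.percentile
                    )
                )
            networks[key] = nets
            dens = {}
            nd = {}
            groups = {
                g: ids
                for g, ids in spec.site_map.groups().items()
                if g != "none"
            }
            for label, net in nets.items():
                if groups and label == "all":
                    for g, v in fn.arrow_density(
                        net, spec.site_map, groups
                    ).items():
                        dens[f"group_{g}"] = v
                dens[label] = net.n_bar / len(spec.site_map.site_ids)
                nd[label] = net.d_n
            densities[key] = dens
            ndis[key] = nd

    labels = gen_survey_labels(
        real, config.survey_thresholds, seed=spec.seed
    )
    survey = summarize_survey(labels)

    return PipelineResult(
        config=config,
        index_matrix=matrix,
        pca=pca,
        representatives=reps,
        te_matrices=te_matrices,
        networks=networks,
        densities=densities,
        ndi=ndis,
        emission=emission,
        survey_summary=survey,
    )
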
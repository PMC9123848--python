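"""End-to-end orchestration: simulate -> connect -> normalize -> features
-> classify -> stats, with all artifacts written to one output directory.

Each stage is usable on its own (the CLI maps onto these functions); the
full run is deterministic given the root seed, from which every stage
draws a named substream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from ._rng import child_seed
from .bands import BandSpec
from .classify import FEATURE_SETS, CohortEvaluation, evaluate_model
from .config import PipelineConfig
from .containers import RoiTimeSeries
from .features import (
    SubjectConnectivity,
    build_control_reference,
    feature_table,
    reduce_to_modules,
    zscore_subject,
)
from .outcomes import SubjectOutcome
from .parcellation import Parcellation, make_parcellation
from .spectral import roi_connectivity, segment_epochs, select_resting_segment
from .stats import fdr_adjust, group_compare, lobar_mean_table, spearman_association
from .synthetic import CohortPlan, iter_cohort, plan_cohort


def band_specs(config: PipelineConfig) -> dict[str, BandSpec]:
    return {name: BandSpec(name, lo, hi) for name, (lo, hi) in config.bands.items()}


def subject_connectivity(
    ts: RoiTimeSeries, parcellation: Parcellation, config: PipelineConfig
) -> SubjectConnectivity:
    """Module-level connectivity for one subject.

    Parses the recording into epochs, keeps the first ``n_epochs`` clean
    ones, estimates ROI-level imaginary coherence per band on the
    concatenated segment and reduces to module level.
    """
    epochs = segment_epochs(ts, config.epoch_len)
    segment = select_resting_segment(epochs, ts.epoch_flags, config.n_epochs)
    analysis = RoiTimeSeries(
        subject_id=ts.subject_id,
        sampling_rate=ts.sampling_rate,
        roi_ids=ts.roi_ids,
        data=segment,
        epoch_flags=np.ones(int(segment.shape[1] / ts.sampling_rate // 15), bool),
    )
    records = roi_connectivity(
        analysis,
        bands=band_specs(config),
        window_len=config.welch_window,
        overlap=config.welch_overlap,
        mode=config.imcoh_mode,
        per_epoch=config.per_epoch,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # singleton-module warnings surface once
        return {rec.band: reduce_to_modules(rec, parcellation) for rec in records}


def compute_connectivity(
    plan: CohortPlan,
    config: PipelineConfig,
    on_timeseries: Callable[[RoiTimeSeries], None] | None = None,
) -> dict[str, SubjectConnectivity]:
    """Simulate and reduce every planned subject, one at a time."""
    out: dict[str, SubjectConnectivity] = {}
    for subject, ts in iter_cohort(plan):
        try:
            if on_timeseries is not None:
                on_timeseries(ts)
            out[subject.subject_id] = subject_connectivity(
                ts, plan.parcellation, config
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage 'connect' failed for subject {subject.subject_id}: {exc}"
            ) from exc
    return out


@dataclass
class CohortResults:
    """In-memory results of a full cohort analysis."""

    parcellation: Parcellation
    outcomes: list[SubjectOutcome]
    control_ids: list[str]
    nfcs: dict[str, object] = field(repr=False)
    features: pd.DataFrame = field(repr=False, default=None)
    evaluations: dict[str, CohortEvaluation] = field(default_factory=dict)
    group_stats: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)

    def wide_features(self) -> pd.DataFrame:
        """Per-subject feature matrix with columns like ``alpha_mean``."""
        wide = {}
        for band, df in self.features.groupby("band", sort=False):
            d = df.set_index("subject_id")
            wide[f"{band}_mean"] = d["global_mean"]
            wide[f"{band}_sd"] = d["global_sd"]
            wide[f"{band}_hemi"] = d["hemispheric_mean"]
            wide[f"{band}_lobar"] = d["lobar_mean"]
        return pd.DataFrame(wide)

    def labels(self, ids: Sequence[str]) -> np.ndarray:
        by_id = {o.subject_id: o for o in self.outcomes}
        return np.array([int(by_id[i].responder) for i in ids])


def analyze_cohort(
    module_conn: Mapping[str, SubjectConnectivity],
    outcomes: Sequence[SubjectOutcome],
    control_ids: Sequence[str],
    parcellation: Parcellation,
    config: PipelineConfig,
    models: Sequence[str] | None = None,
    do_stats: bool = True,
    n_boot: int | None = None,
) -> CohortResults:
    """Normalize to the control reference and run classification + stats.

    The primary cohort consists of patients with stimulation enabled;
    responder labels follow the >= 50% reduction rule applied to the
    averaged follow-up samplings.
    """
    controls = [module_conn[cid] for cid in control_ids]
    reference = build_control_reference(controls)
    patients = [o for o in outcomes if o.stim_enabled]
    nfcs = {
        o.subject_id: zscore_subject(module_conn[o.subject_id], reference)
        for o in patients
    }
    leads = {o.subject_id: (o.lead_hemispheres, o.lead_lobes) for o in patients}
    feats = feature_table(
        list(nfcs.values()), leads, parcellation, config.hemispheric_mode
    )
    results = CohortResults(
        parcellation=parcellation,
        outcomes=list(patients),
        control_ids=list(control_ids),
        nfcs=nfcs,
        features=feats,
    )
    wide = results.wide_features()
    ids = list(wide.index)
    y = results.labels(ids)
    n_boot = config.bootstrap_reps if n_boot is None else n_boot
    for name in models if models is not None else FEATURE_SETS:
        cols = list(FEATURE_SETS[name])
        X = wide.loc[ids, cols].to_numpy()
        results.evaluations[name] = evaluate_model(
            X, y, name=name, features=tuple(cols), n_boot=n_boot,
            seed=child_seed(config.seed, "bootstrap", name),
        )
    if do_stats:
        groups = {o.subject_id: ("R" if o.responder else "NR") for o in patients}
        table = lobar_mean_table(list(nfcs.values()), groups, parcellation)
        comparisons = group_compare(table, config.random_slope_lobe)
        p_fdr = fdr_adjust({b: c.p_value for b, c in comparisons.items()})
        results.group_stats = {
            band: {
                "raw_p": comp.p_value,
                "fdr_p": p_fdr[band],
                "ls_mean_R": comp.ls_means["R"],
                "ls_mean_NR": comp.ls_means["NR"],
                "method": comp.method,
            }
            for band, comp in comparisons.items()
        }
        red = np.array([o.percent_reduction for o in patients])
        order = [o.subject_id for o in patients]
        for band in ("alpha", "beta"):
            for stat, col in (("mean", f"{band}_mean"), ("sd", f"{band}_sd"),
                              ("hemispheric_mean", f"{band}_hemi"),
                              ("lobar_mean", f"{band}_lobar")):
                vals = wide.loc[order, col].to_numpy()
                if np.any(~np.isfinite(vals)):
                    continue
                rho, p = spearman_association(vals, red)
                results.association[f"{band}_{stat}"] = {
                    "rho": rho, "p": p, "n": len(vals),
                }
    return results


def build_report(results: CohortResults, config: PipelineConfig) -> dict:
    return {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "cohort": {
            "n_controls": len(results.control_ids),
            "n_patients": len(results.outcomes),
            "n_responders": int(sum(o.responder for o in results.outcomes)),
            "n_nonresponders": int(sum(not o.responder for o in results.outcomes)),
            "n_connections": results.parcellation.n_connections,
        },
        "models": {k: v.to_dict() for k, v in results.evaluations.items()},
        "group_stats": results.group_stats,
        "association": results.association,
    }


def _stats_frame(results: CohortResults) -> pd.DataFrame:
    rows = []
    for band, s in results.group_stats.items():
        rows.append(
            {
                "scale": "global", "band": band, "raw_p": s["raw_p"],
                "fdr_p": s["fdr_p"], "ls_mean_R": s["ls_mean_R"][0],
                "ls_mean_NR": s["ls_mean_NR"][0], "method": s["method"],
            }
        )
    return pd.DataFrame(rows)


def _association_frame(results: CohortResults) -> pd.DataFrame:
    rows = []
    for key, a in results.association.items():
        band, stat = key.split("_", 1)
        rows.append({"band": band, "statistic": stat, **a})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    With ``config.data_dir`` unset, a synthetic cohort is planned from the
    design and simulated on the fly; otherwise a previously written cohort
    is read back from disk.  Returns the report dictionary (also written
    as ``report.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.data_dir is None:
        parcellation = make_parcellation(config.n_rois, config.n_modules)
        plan = plan_cohort(config.design, parcellation)
        writer = None
        if config.write_timeseries:
            data_dir = out_dir / "cohort"
            data_dir.mkdir(exist_ok=True)
            ext = ".h5" if config.timeseries_format == "hdf5" else ".csv"
            writer = lambda ts: _io.write_timeseries(  # noqa: E731
                ts, data_dir / f"{ts.subject_id}{ext}", config.timeseries_format
            )
        module_conn = compute_connectivity(plan, config, on_timeseries=writer)
        outcomes = [s.outcome for s in plan.patients]
        control_ids = [s.subject_id for s in plan.controls]
        _io.write_json_report(plan.truth(), out_dir / "ground_truth.json")
    else:
        data_dir = Path(config.data_dir)
        parc_path = data_dir / "parcellation.tsv"
        if not parc_path.exists():
            raise FileNotFoundError(f"missing parcellation file: {parc_path}")
        parcellation = Parcellation.from_tsv(parc_path)
        control_ids, outcomes = _io.read_metadata(data_dir / "metadata.csv")
        module_conn = {}
        for sid in [*control_ids, *[o.subject_id for o in outcomes]]:
            candidates = [data_dir / f"{sid}.h5", data_dir / f"{sid}.csv"]
            path = next((p for p in candidates if p.exists()), None)
            if path is None:
                raise FileNotFoundError(
                    f"stage 'connect': no time series found for subject {sid}"
                )
            ts = _io.read_timeseries(path)
            try:
                module_conn[sid] = subject_connectivity(ts, parcellation, config)
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'connect' failed for subject {sid}: {exc}"
                ) from exc

    results = analyze_cohort(
        module_conn, outcomes, control_ids, parcellation, config
    )
    report = build_report(results, config)

    records = [rec for conn in module_conn.values() for rec in conn.values()]
    _io.connectivity_to_tsv(records, out_dir / "connectivity.tsv")
    _io.zscores_to_tsv(list(results.nfcs.values()), out_dir / "zscores.tsv")
    _io.features_to_tsv(results.features, out_dir / "features.tsv")
    _io.write_metadata(outcomes, control_ids, out_dir / "metadata.csv")
    parcellation.to_tsv(out_dir / "parcellation.tsv")
    _stats_frame(results).to_csv(out_dir / "stats.tsv", sep="\t", index=False)
    _association_frame(results).to_csv(
        out_dir / "association.tsv", sep="\t", index=False
    )
    _io.write_json_report(report, out_dir / "report.json")
    config.to_yaml(out_dir / "resolved_config.yaml")
    return report
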
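"""End-to-end orchestration: simulate → clean → ICA → localize → cluster →
band features → state-specific LOPO regression → group statistics.

Every stage draws randomness from a named SeedSequence stream derived from
the run seed, so a rerun with the same config is bit-identical.  The final
report has one row per (cluster, axis, state): mean r (Fisher-z averaged),
MSE, t, raw and Holm-adjusted p, significance at the configured alpha, and
mean (SD) band coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bandpower import aggregate_cluster_features
from .cluster import ICCluster, ICFeatureSet, ICRecord, build_features, cluster_ics
from .config import PipelineConfig
from .dipole import BrainICSelection, DipoleFit, fit_all_dipoles, select_brain_ics
from .groupstats import GroupStats, group_significance, stats_table
from .headmodel import HeadModel
from .ica import Decomposition, run_ica
from .io import load_cohort, save_cohort, write_results
from .preprocess import CleaningReport, EpochedData, clean_epochs, prepare_for_ica
from .regression import STATE_KEYS, RegressionOutcome, regress_cluster
from .simulate import ParticipantRecording, simulate_cohort
from .stimuli import StimulusSet, TrialSchedule

logger = logging.getLogger("eegaffect")


@dataclass
class ParticipantAnalysis:
    participant_id: str
    cleaned: EpochedData
    cleaning_report: CleaningReport
    decomposition: Decomposition
    fits: list[DipoleFit]
    selection: BrainICSelection


@dataclass
class PipelineResult:
    config: PipelineConfig
    results: pd.DataFrame
    group_stats: list[GroupStats]
    clusters: list[ICCluster]
    feature_set: ICFeatureSet | None
    outcomes: dict[tuple[int, str, str], RegressionOutcome]
    participants: list[ParticipantAnalysis] = field(repr=False, default_factory=list)
    stimuli: StimulusSet | None = None
    schedule: TrialSchedule | None = None
    report: dict = field(default_factory=dict)


def _stage_seed(root: int, label: str, index: int = 0) -> int:
    """A deterministic per-stage seed below 2**31."""
    import zlib

    ss = np.random.SeedSequence([root, zlib.crc32(label.encode()), index])
    return int(ss.generate_state(1)[0] % (2**31))


def process_participant(
    recording: ParticipantRecording,
    config: PipelineConfig,
    head: HeadModel,
    ica_seed: int,
) -> ParticipantAnalysis:
    """Clean, decompose and localize one participant's epochs."""
    epoched = EpochedData(
        data=np.asarray(recording.epochs),
        sampling_rate=recording.sampling_rate,
        channel_names=list(recording.channel_names),
        channel_positions=np.asarray(recording.channel_positions),
        stimulus_ids=np.asarray(recording.stimulus_ids),
    )
    cleaned, report = clean_epochs(
        epoched,
        channel_z_thresh=config.cleaning.channel_z_thresh,
        epoch_ptp_thresh=config.cleaning.epoch_ptp_thresh,
        epoch_z_thresh=config.cleaning.epoch_z_thresh,
    )
    prepared = prepare_for_ica(cleaned)
    deco = run_ica(
        prepared,
        algorithm=config.ica.algorithm,
        seed=ica_seed,
        max_iter=config.ica.max_iter,
        tol=config.ica.tol,
        sample_step=config.ica.sample_step,
    )
    fits = fit_all_dipoles(
        deco, head, grid_step_mm=config.dipole.grid_step_mm,
        refine_tol=config.dipole.refine_tol_mm,
    )
    selection = select_brain_ics(
        deco,
        fits,
        head,
        sampling_rate=cleaned.sampling_rate,
        rv_max=config.dipole.rv_max,
        brain_margin=config.dipole.brain_margin,
        psd_slope_band=config.dipole.psd_slope_band,
        frontal_fraction_max=config.dipole.frontal_fraction_max,
        n_frontal=config.dipole.n_frontal,
    )
    logger.info(
        "%s: %d channels interpolated, %.1f%% epochs removed, %d/%d ICs kept",
        recording.participant_id,
        report.n_channels_interpolated,
        100 * report.fraction_epochs_removed,
        sum(selection.kept),
        deco.n_components,
    )
    return ParticipantAnalysis(
        participant_id=recording.participant_id,
        cleaned=cleaned,
        cleaning_report=report,
        decomposition=deco,
        fits=fits,
        selection=selection,
    )


def collect_brain_ics(analyses: list[ParticipantAnalysis]) -> list[ICRecord]:
    records = []
    for pa in analyses:
        for j in pa.selection.kept_indices:
            records.append(
                ICRecord(
                    participant_id=pa.participant_id,
                    ic_index=j,
                    topography=pa.decomposition.mixing[:, j],
                    dipole_location_mm=pa.fits[j].location_mm,
                    epoch_activations=pa.decomposition.epoch_activations(j),
                    sampling_rate=pa.cleaned.sampling_rate,
                )
            )
    return records


def analyze_cohort(
    recordings: list[ParticipantRecording],
    stimuli: StimulusSet,
    config: PipelineConfig,
) -> PipelineResult:
    """Run every analysis stage on an in-memory cohort."""
    head = HeadModel(
        sphere_radius=config.cohort.sphere_radius_mm,
        channel_names=list(recordings[0].channel_names),
        channel_positions=np.asarray(recordings[0].channel_positions),
    )
    analyses = [
        process_participant(
            rec, config, head, ica_seed=_stage_seed(config.seed, "ica", i)
        )
        for i, rec in enumerate(recordings)
    ]

    records = collect_brain_ics(analyses)
    feature_set = None
    clusters: list[ICCluster] = []
    outcomes: dict[tuple[int, str, str], RegressionOutcome] = {}
    all_stats: list[GroupStats] = []
    if len(records) >= max(config.cluster.n_topo_pcs, config.cluster.n_erp_pcs) + 1:
        feature_set = build_features(
            records,
            erp_window_s=config.cluster.erp_window_s,
            n_topo_pcs=config.cluster.n_topo_pcs,
            n_erp_pcs=config.cluster.n_erp_pcs,
        )
        clusters = cluster_ics(
            feature_set,
            k=min(config.cluster.k, len(records) - 1),
            outlier_sd=config.cluster.outlier_sd,
            seed=_stage_seed(config.seed, "cluster"),
            n_restarts=config.cluster.n_restarts,
            n_participants=len(recordings),
        )
        by_pid = {pa.participant_id: pa for pa in analyses}
        cluster_tables = {}
        for cl in clusters:
            if not cl.retained:
                continue
            member_acts: dict[str, np.ndarray] = {}
            sid_map: dict[str, np.ndarray] = {}
            for pid in cl.participant_ids:
                pa = by_pid[pid]
                ics = [ic for p, ic in cl.members if p == pid]
                member_acts[pid] = np.stack(
                    [pa.decomposition.epoch_activations(j) for j in ics]
                )
                sid_map[pid] = pa.cleaned.stimulus_ids
            cluster_tables[cl.cluster_index] = aggregate_cluster_features(
                member_acts,
                sampling_rate=analyses[0].cleaned.sampling_rate,
                cluster_index=cl.cluster_index,
                stimulus_ids=sid_map,
            )
        for ci, table in cluster_tables.items():
            if table["participant_id"].nunique() < 3:
                logger.info("cluster %d: fewer than 3 participants, skipped", ci)
                continue
            try:
                outcomes.update(
                    {
                        (ci, axis, state): o
                        for (axis, state), o in regress_cluster(
                            table,
                            stimuli,
                            cluster_index=ci,
                            min_epochs_per_participant=config.regression.min_epochs_per_participant,
                        ).items()
                    }
                )
            except ValueError as err:
                logger.info("cluster %d regression skipped: %s", ci, err)
        for axis, state in STATE_KEYS:
            fam = [o for (ci, a, s), o in outcomes.items() if a == axis and s == state]
            fam = [o for o in fam if o.n_folds >= 3]
            all_stats.extend(group_significance(fam, alpha=config.regression.alpha))

    results = stats_table(all_stats)
    report = {
        "n_participants": len(recordings),
        "cleaning": {
            pa.participant_id: pa.cleaning_report.as_dict() for pa in analyses
        },
        "ics_kept": {
            pa.participant_id: int(sum(pa.selection.kept)) for pa in analyses
        },
        "n_brain_ics": len(records),
        "clusters": [
            {
                "cluster_index": cl.cluster_index,
                "n_members": len(cl.members),
                "n_participants": len(cl.participant_ids),
                "retained": cl.retained,
                "centroid_location_mm": cl.centroid_location_mm.tolist(),
            }
            for cl in clusters
        ],
    }
    return PipelineResult(
        config=config,
        results=results,
        group_stats=all_stats,
        clusters=clusters,
        feature_set=feature_set,
        outcomes=outcomes,
        participants=analyses,
        stimuli=stimuli,
        report=report,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Simulate (or load) a cohort, analyze it, and archive artifacts.

    The exit contract reflects completion: failures raise, an analysis with
    no significant cluster is still a successful run.
    """
    config.validate()
    if config.simulate:
        sim_seed = _stage_seed(config.seed, "simulate")
        recordings, stimuli, schedule = simulate_cohort(config.cohort, seed=sim_seed)
    else:
        recordings, stimuli, schedule = load_cohort(config.input_dir)
    result = analyze_cohort(recordings, stimuli, config)
    result.schedule = schedule
    if config.out_dir:
        from pathlib import Path

        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        if config.simulate:
            save_cohort(recordings, stimuli, schedule, out / "cohort")
        write_results(result.results, out / "results", report=result.report)
    return result
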
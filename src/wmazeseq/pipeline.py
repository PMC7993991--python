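"""End-to-end orchestration of the analysis stages on one session.

Stage order: behavior -> rate maps -> LFP events -> behavioral decoding
-> theta sequences / cycle skipping / phase precession / replay ->
reactivation -> prediction.  Each stage function is independently
callable; ``run_pipeline`` chains them and collects a results dict.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import cycleskip as cs
from . import decode as dec
from . import lfp as lfpmod
from . import phaseprec as pp
from . import ratemaps as rmaps
from . import replay as rp
from . import thetaseq as ts
from .config import TRAJECTORY_TYPES, traj_of
from .io import Session


@dataclass
class PipelineResults:
    linearized: pd.DataFrame
    trials: pd.DataFrame
    rate_maps: Dict
    selectivity: pd.DataFrame
    swrs: List
    theta_cycles: List
    behavioral: Dict[str, object]         # (region, travel) -> BehavioralDecode
    sequence_results: Dict[str, List]     # region -> [SequenceResult]
    csi: pd.DataFrame
    precession: pd.DataFrame
    replay_results: List
    reactivation: List
    predictions: Dict[str, object]
    distance_indices: Dict[str, object] = field(default_factory=dict)
    coherence_table: Optional[pd.DataFrame] = None
    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)

    def result_hash(self) -> str:
        """Deterministic digest of the main result tables."""
        h = hashlib.sha256()
        for name in sorted(self.tables):
            h.update(name.encode())
            h.update(self.tables[name].round(9).to_csv(index=False).encode())
        return h.hexdigest()


def _run_intervals(session: Session) -> pd.DataFrame:
    if session.ground_truth is not None:
        return session.ground_truth.run_intervals
    return session.trials.rename(columns={"arrival_trigger_s": "end_s"})[
        ["start_s", "end_s", "traj_type", "trial_id"]
    ]


def prepare_behavior(session: Session):
    """Linearized table, augmented trials, masks and dwell intervals."""
    speed = bhv.compute_speed(session.position)
    linearized = bhv.linearize(
        session.position,
        session.config.maze,
        session.trials,
        run_intervals=_run_intervals(session),
        speed=speed,
    )
    trials = bhv.add_well_events(session.trials, session.position, speed)
    loco, immob = bhv.locomotor_mask(speed)
    t = session.position.time_s.to_numpy(float)
    loco_ivals = bhv.mask_to_intervals(t, loco)
    immob_ivals = bhv.mask_to_intervals(t, immob)
    dwell_ivals = trials[["well_entry_s", "well_exit_s"]].dropna().to_numpy(float)
    return linearized, trials, loco_ivals, immob_ivals, dwell_ivals


def detect_events(session: Session, immob_ivals, loco_ivals):
    """SWRs and theta cycles from the reference LFP."""
    swrs = lfpmod.detect_swrs(session.lfp, session.fs_lfp, immob_ivals)
    phase = lfpmod.theta_phase(session.lfp["ca1_ref"], session.fs_lfp)
    ca1_trains = {
        uid: session.spikes.trains[uid] for uid in session.spikes.unit_ids("CA1")
    }
    cycles, boundary = lfpmod.segment_theta_cycles(phase, ca1_trains, loco_ivals)
    return swrs, phase, cycles, boundary


def compute_maps(session: Session, linearized, swr_ivals):
    maze = session.config.maze
    maps = rmaps.compute_all_rate_maps(
        session.spikes, linearized, maze.path_length_cm, swr_ivals
    )
    sel_rows = []
    regions = session.spikes.units.set_index("unit_id")["region"]
    for uid in session.spikes.unit_ids():
        for travel in ("outbound", "inbound"):
            res = rmaps.selectivity_index(
                maps.get((uid, traj_of(travel, "L"))),
                maps.get((uid, traj_of(travel, "R"))),
                uid,
                regions.loc[uid],
                travel,
            )
            if res is not None:
                sel_rows.append(
                    dict(unit_id=uid, region=regions.loc[uid], travel=travel,
                         fr_l=res.fr_l, fr_r=res.fr_r, si=res.si,
                         selective=res.selective, preferred=res.preferred)
                )
    return maps, pd.DataFrame(sel_rows)


def decoder_units(session: Session, maps, region: str, travel: str) -> List[int]:
    """Units contributing templates: mapped on some trajectory of the travel,
    peak >= 3 Hz for CA1 (place-cell criterion)."""
    tts = [traj_of(travel, s) for s in ("L", "R")]
    out = []
    for uid in session.spikes.unit_ids(region):
        peaks = [
            maps[(uid, tt)].peak_rate_hz for tt in tts if (uid, tt) in maps
        ]
        if not peaks:
            continue
        if region == "CA1" and max(peaks) < rmaps.PLACE_CELL_PEAK_HZ:
            continue
        out.append(uid)
    return out


def run_pipeline(
    session: Session,
    seed: int = 0,
    n_seq_shuffles: int = 200,
    n_replay_shuffles: int = 200,
    n_react_shuffles: int = 200,
    n_permutations: int = 200,
    do_predict: bool = True,
) -> PipelineResults:
    rng = np.random.default_rng([seed, 17])
    maze = session.config.maze
    linearized, trials, loco_ivals, immob_ivals, dwell_ivals = prepare_behavior(
        session
    )
    swrs, phase, cycles, _ = detect_events(session, immob_ivals, loco_ivals)
    swr_ivals = lfpmod.swr_intervals(swrs)
    maps, selectivity = compute_maps(session, linearized, swr_ivals)

    trains = session.spikes.trains
    # encoding models per (region, travel) where enough units exist
    models: Dict[Tuple[str, str], dec.EncodingModel] = {}
    for region in ("CA1", "PFC"):
        for travel in ("outbound", "inbound"):
            uids = decoder_units(session, maps, region, travel)
            try:
                models[(region, travel)] = dec.build_templates(
                    maps, travel, region, uids
                )
            except ValueError:
                pass

    behavioral = {}
    for key, model in models.items():
        behavioral[key] = dec.decode_behavioral(
            model, trains, linearized, maze.path_length_cm, swr_ivals
        )

    # theta sequences per region
    sequence_results: Dict[str, List[ts.SequenceResult]] = {}
    event_posteriors: Dict[str, List[ts.EventPosterior]] = {}
    for region in ("CA1", "PFC"):
        uids = session.spikes.unit_ids(region)
        cands = ts.find_candidates(
            cycles, trains, uids, linearized, trials, region
        )
        results = []
        eps = []
        for cand in cands:
            model = models.get((region, cand.travel))
            if model is None:
                continue
            ep = ts.decode_event(model, trains, cand)
            if ep is None:
                continue
            ev_rng = np.random.default_rng([seed, 23, cand.event_id])
            scores = {
                side: ts.shuffle_significance(
                    pm, ep.bin_cm, n_seq_shuffles, ev_rng, t_idx=ep.window_idx
                )
                for side, pm in ep.pmats.items()
            }
            results.append(ts.classify_sequence(ep, scores, cand))
            eps.append(ep)
        ts.label_segments(results, maze.cp_arclength_cm)
        sequence_results[region] = results
        event_posteriors[region] = eps
    distance_indices = {
        region: ts.distance_index(event_posteriors[region],
                                  sequence_results[region], phase)
        for region in sequence_results
    }
    coherence_table = ts.coherent_pairs(
        sequence_results.get("CA1", []), sequence_results.get("PFC", [])
    )

    # cycle skipping per unit x travel
    run_ints = _run_intervals(session)
    csi_rows = []
    for uid in session.spikes.unit_ids():
        for travel in ("outbound", "inbound"):
            ivals = run_ints[
                run_ints.traj_type.isin([traj_of(travel, s) for s in ("L", "R")])
            ][["start_s", "end_s"]].to_numpy(float)
            acg = cs.compute_acg(trains[uid], ivals)
            if acg is None:
                continue
            csi = cs.cycle_skipping_index(acg)
            csi_rows.append(
                dict(unit_id=uid, travel=travel,
                     relative_theta_power=acg.relative_theta_power,
                     theta_modulated=acg.theta_modulated,
                     csi=np.nan if csi is None else csi)
            )
    csi_df = pd.DataFrame(csi_rows)

    # phase precession per CA1 unit field
    prec_rows = []
    for uid in session.spikes.unit_ids("CA1"):
        for tt in TRAJECTORY_TYPES:
            rm = maps.get((uid, tt))
            if rm is None or rm.peak_rate_hz < rmaps.PLACE_CELL_PEAK_HZ:
                continue
            fields = rmaps.detect_fields(rm)
            best_field = max(
                fields, default=None,
                key=lambda f: np.nan_to_num(rm.rate_hz, nan=0.0)[
                    int((f[2] - rm.bin_edges[0]) // (rm.bin_edges[1] - rm.bin_edges[0]))
                ],
            )
            for fld in fields:
                res = pp.field_precession(
                    uid, trains[uid], phase, fld, tt, linearized
                )
                if res is None:
                    continue
                ai = np.nan
                # asymmetry only for the unit's highest-peak field showing
                # significant precession and spanning >= 20 cm
                if res.significant and fld == best_field:
                    fa = rmaps.asymmetry_index(rm, fld)
                    if fa is not None:
                        ai = fa.ai
                prec_rows.append(
                    dict(unit_id=uid, traj_type=tt, field_lo=res.field_lo_cm,
                         field_hi=res.field_hi_cm,
                         slope_deg_per_cm=res.slope_deg_per_cm, r=res.r,
                         p=res.p, n_spikes=res.n_spikes, ai=ai)
                )
    prec_df = pd.DataFrame(prec_rows)

    # replay + reactivation at wells (outbound model; SWRs during well dwell)
    replay_results: List[rp.ReplayResult] = []
    reactivation: List[rp.ReactivationResult] = []
    model_out = models.get(("CA1", "outbound"))
    if model_out is not None and len(swrs):
        well_swrs = [
            ev for ev in swrs
            if bhv.in_intervals(
                np.array([(ev.start_s + ev.end_s) / 2]), dwell_ivals
            )[0]
        ]
        replay_results = rp.detect_replay(
            model_out, well_swrs, trains, n_replay_shuffles,
            np.random.default_rng([seed, 29]),
        )
        ca1_ids = decoder_units(session, maps, "CA1", "outbound")
        pfc_ids = [
            u for u in session.spikes.unit_ids("PFC")
            if any((u, traj_of("outbound", s)) in maps for s in ("L", "R"))
        ]
        for res in replay_results:
            if not res.significant:
                continue
            ra = rp.reactivation_strength(
                res.swr, trains, maps, ca1_ids, pfc_ids,
                [traj_of("outbound", s) for s in ("L", "R")],
                n_react_shuffles, np.random.default_rng([seed, 31, res.swr.swr_id]),
            )
            if ra is not None:
                reactivation.append(ra)

    predictions: Dict[str, object] = {}
    if do_predict:
        predictions = _run_predictions(
            sequence_results, trials, seed, n_permutations
        )

    tables = {
        "selectivity": selectivity,
        "csi": csi_df,
        "precession": prec_df,
        "swrs": lfpmod.swrs_to_frame(swrs),
    }
    for region, results in sequence_results.items():
        tables[f"sequences_{region}"] = ts.results_to_frame(results)
    if coherence_table is not None:
        tables["coherent_pairs"] = coherence_table
    for key, bd in behavioral.items():
        tables[f"decode_{key[0]}_{key[1]}"] = pd.DataFrame(
            {
                "window_center_s": bd.window_centers,
                "map_position_cm": bd.map_position_cm,
                "map_side": bd.map_side,
                "correct": bd.choice_correct,
            }
        )
    return PipelineResults(
        linearized=linearized,
        trials=trials,
        rate_maps=maps,
        selectivity=selectivity,
        swrs=swrs,
        theta_cycles=cycles,
        behavioral=behavioral,
        sequence_results=sequence_results,
        csi=csi_df,
        precession=prec_df,
        replay_results=replay_results,
        reactivation=reactivation,
        predictions=predictions,
        distance_indices=distance_indices,
        coherence_table=coherence_table,
        tables=tables,
    )


def sequence_features(
    results: List[ts.SequenceResult], trials: pd.DataFrame, segment: str
):
    """(features, labels) for choice prediction from one region/segment.

    Only correct outbound trials with at least one sequence of each
    representation label are used, per the classifier's contract.
    """
    _, _, per_trial = ts.choice_representation(results, segment)
    if per_trial.empty:
        return np.empty((0, 2)), np.empty(0, dtype=object)
    usable = per_trial[(per_trial.n_actual >= 1) & (per_trial.n_alternative >= 1)]
    tr = trials.set_index("trial_id")
    rows, labels = [], []
    for rec in usable.itertuples():
        trial = tr.loc[rec.trial_id]
        if trial.travel != "outbound" or not bool(trial.correct):
            continue
        rows.append([rec.n_actual, rec.n_alternative])
        labels.append(str(trial.choice))
    return np.array(rows, float), np.array(labels, dtype=object)


def _run_predictions(sequence_results, trials, seed, n_permutations):
    from . import predict as pred

    out = {}
    for region, results in sequence_results.items():
        for segment in ("before_cp", "after_cp"):
            X, y = sequence_features(results, trials, segment)
            if len(y) >= 10 and len(np.unique(y)) == 2:
                out[f"choice_{region}_{segment}"] = pred.predict_choice(
                    X, y, n_permutations=n_permutations, seed=seed
                )
    return out


def reactivation_features(
    reactivation: List[rp.ReactivationResult],
    trials: pd.DataFrame,
    direction_of: Optional[Dict[int, str]] = None,
    direction: Optional[str] = None,
):
    """Per-outbound-trial mean reactivation strength (actual, alternative).

    Events are attributed to the next outbound trial after the SWR; the
    actual trajectory is that trial's choice.  Returns (features, correct
    labels, trial ids).
    """
    out_trials = trials[trials.travel == "outbound"].sort_values("start_s")
    feats, labels, ids = [], [], []
    for trial in out_trials.itertuples():
        evs = [
            ra for ra in reactivation
            if ra.swr.end_s <= trial.start_s
            and ra.swr.start_s >= trial.start_s - 60.0
        ]
        if direction is not None and direction_of is not None:
            evs = [
                ra for ra in evs
                if direction_of.get(ra.swr.swr_id) == direction
            ]
        if not evs:
            continue
        actual_tt = traj_of("outbound", str(trial.choice))
        alt_tt = traj_of("outbound", "R" if trial.choice == "L" else "L")
        r_act = np.nanmean([ra.strength.get(actual_tt, np.nan) for ra in evs])
        r_alt = np.nanmean([ra.strength.get(alt_tt, np.nan) for ra in evs])
        if not (np.isfinite(r_act) and np.isfinite(r_alt)):
            continue
        feats.append([r_act, r_alt])
        labels.append(bool(trial.correct))
        ids.append(trial.trial_id)
    return np.array(feats, float), np.array(labels, bool), ids
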
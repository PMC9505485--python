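"""End-to-end feature extraction from a multimodal study dataset.

Turns per-trial raw traces into the per-modality feature tables consumed by
the statistical suite and the classifiers:

* ``pcps``       — the 2.5 s percentage-change-in-pupil-size series (500 columns)
* ``pcps_stats`` — APCPS plus PCPS mean/variance (the handcrafted features)
* ``fix``        — fixation count and mean fixation duration
* ``eeg``        — 32-d band-power vector (8 channels x 4 bands)
* ``hrv``        — 11 heart-rate-variability features (30 s windows)
* ``bpv``        — 20 blood-pressure-variability features (30 s windows)

A trial is flagged low-quality when more than half its pupil samples were
interpolated, its ABP window yields fewer than 10 accepted beats, or any EEG
channel saturates; flagged trials are dropped and classes re-balanced by
seeded subsampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import abp as abp_mod
from . import cardio, eeg as eeg_mod, pupil as pupil_mod
from .core import (FeatureTable, InsufficientBeatsError, InsufficientDataError,
                   PhysioLoadError, assemble_dataset)
from .simulate import StudyDataset

log = logging.getLogger("physioload")


@dataclass
class QualityThresholds:
    max_interpolated_fraction: float = 0.5
    min_abp_beats: int = 10
    eeg_saturation_uV: float = 500.0


def extract_features(dataset: StudyDataset, seed: int = 0, balance: bool = True,
                     thresholds: QualityThresholds | None = None,
                     denoise_eeg: bool = True,
                     ) -> dict[str, FeatureTable]:
    """Run preprocessing + feature extraction for every trial and modality.

    Returns a dict of balanced, quality-filtered feature tables keyed by
    modality tag. ``denoise_eeg=False`` skips the ICA/Kalman stage (band-pass
    only), trading artifact suppression for speed.
    """
    thr = thresholds or QualityThresholds()
    rows: dict[str, list[dict]] = {k: [] for k in
                                   ("pcps", "pcps_stats", "fix", "eeg", "hrv", "bpv")}
    labels: list[int] = []
    flags: list[bool] = []

    for ti, trial in enumerate(dataset.trials):
        good = True
        # --- pupil
        try:
            clean, frac = pupil_mod.preprocess_pupil(trial.pupil)
            ptrial = pupil_mod.compute_pcps(clean, onset=0.0,
                                            interpolated_fraction=frac)
        except PhysioLoadError as exc:
            log.warning("trial %d: pupil unusable (%s)", ti, exc)
            good, ptrial, frac = False, None, 1.0
        if frac > thr.max_interpolated_fraction:
            good = False
        if ptrial is not None:
            series = pupil_mod.pupil_feature_vector(ptrial, "series")
            rows["pcps"].append({f"pcps_{i:03d}": v for i, v in enumerate(series)})
            mean, var = pupil_mod.pupil_feature_vector(ptrial, "mean_var")
            rows["pcps_stats"].append({
                "apcps": pupil_mod.apcps(ptrial.pcps),
                "pcps_mean": mean, "pcps_var": var,
            })
        else:
            rows["pcps"].append({})
            rows["pcps_stats"].append({})

        # --- fixations
        fix = pupil_mod.detect_fixations(trial.gaze)
        rows["fix"].append({"fix_count": float(fix.count),
                            "fix_dur_mean": fix.mean_duration_s})

        # --- EEG
        if np.abs(trial.eeg.values).max() > thr.eeg_saturation_uV:
            good = False
        if denoise_eeg:
            clean_eeg, _ = eeg_mod.preprocess_eeg(trial.eeg)
        else:
            clean_eeg, _ = eeg_mod.preprocess_eeg(trial.eeg, remove_blinks=False,
                                                  smooth=False)
        bp = eeg_mod.psd_feature_vector(clean_eeg)
        rows["eeg"].append(dict(zip(bp.feature_names(), bp.flattened())))

        # --- ABP -> HRV/BPV
        try:
            clean_abp = abp_mod.preprocess_abp(trial.abp)
            beats = abp_mod.detect_beats(clean_abp)
            if beats.sp_times.size < thr.min_abp_beats:
                good = False
            hrv, bpv = cardio.hrv_bpv_features(beats)
            rows["hrv"].append(hrv)
            rows["bpv"].append(bpv)
        except (InsufficientBeatsError, InsufficientDataError) as exc:
            log.warning("trial %d: ABP unusable (%s)", ti, exc)
            good = False
            rows["hrv"].append({})
            rows["bpv"].append({})

        labels.append(trial.level)
        flags.append(good)

    labels_arr = np.asarray(labels)
    usable = np.asarray(flags)
    frames = {key: pd.DataFrame(row_list) for key, row_list in rows.items()}
    for frame in frames.values():
        # rows from unusable trials may carry NaNs; they are flagged and dropped
        usable &= ~frame.isna().any(axis=1).to_numpy()

    # quality filtering and balancing are decided once so that rows stay
    # aligned across modalities (required for fusion)
    ref_key = next(iter(frames))
    ref = assemble_dataset(FeatureTable(frames[ref_key].fillna(0.0), labels_arr),
                           usable, balance=balance, seed=seed)
    idx = np.asarray(ref.meta["selected_indices"], dtype=int)
    tables: dict[str, FeatureTable] = {ref_key: ref}
    for key, frame in frames.items():
        if key == ref_key:
            continue
        tables[key] = FeatureTable(
            frame.fillna(0.0).iloc[idx].reset_index(drop=True),
            labels_arr[idx], dict(ref.meta))
    return tables
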
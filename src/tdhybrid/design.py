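"""Model-based fMRI design construction.

Builds the event timeline implied by a session's timing, attaches the four
parametric modulators derived from a fitted model's latent trace — SVPE,
state value V, AVPE, and action value Q — plus unmodulated indicator
regressors for every stimulus class, convolves everything with the canonical
double-gamma hemodynamic response function (peak 6 s, undershoot 16 s,
peak/undershoot ratio 6) on a 10 ms grid, and samples at the scan repetition
time (TR = 2.770 s).

Conventions: value (V, Q) boxcars persist beyond stimulus offset through the
following interstimulus interval, on the grounds that expectations do not
change during the empty delay; prediction-error boxcars span the stimulus
immediately following the predicting state; the ITI fixation and the
pre-trial cues are coded as passive states with their own state-value and
SVPE modulators (requiring the extended forward pass, which appends ITI and
cue states to the critic's chain without affecting behavioral fits);
modulators are mean-centered per regressor before convolution; no
orthogonalization is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from nilearn.glm.first_level.hemodynamic_models import spm_hrf

from .models import LatentTrace, ModelSpec, ParamVector, forward_pass, get_model
from .task import TimingSpec

__all__ = [
    "TR_DEFAULT",
    "MODULATED_REGRESSORS",
    "UNMODULATED_REGRESSORS",
    "EventTimeline",
    "DesignMatrix",
    "extended_forward_pass",
    "build_timeline",
    "attach_modulators",
    "convolve_and_sample",
    "modulator_collinearity",
    "build_design",
]

TR_DEFAULT = 2.770
MODULATED_REGRESSORS = ("sv", "svpe", "av", "avpe")
UNMODULATED_REGRESSORS = (
    "cue_passive",
    "cue_active",
    "fractal_passive",
    "active_left",
    "active_right",
    "outcome_rewarded",
    "outcome_unrewarded",
    "fixation",
    "error",
)

_TIMELINE_COLS = ["trial", "regressor", "slot", "onset", "duration", "value"]


@dataclass
class EventTimeline:
    """Long-form event table: one row per boxcar.

    ``regressor`` names the design column the event feeds; modulated events
    carry a ``slot`` (which within-trial epoch) and, after
    :func:`attach_modulators`, a ``value``.
    """

    events: pd.DataFrame

    def validated(self) -> "EventTimeline":
        ev = self.events
        if (ev["duration"] < 0).any():
            raise ValueError("negative event duration")
        for reg, grp in ev.groupby("regressor"):
            onsets = grp["onset"].to_numpy()
            if (np.diff(np.sort(onsets)) < -1e-9).any():
                raise ValueError(f"non-increasing onsets in {reg}")
        return self

    def to_bids_tsv(self, path) -> None:
        out = self.events.rename(columns={"regressor": "trial_type", "value": "modulator"})
        out[["onset", "duration", "trial_type", "slot", "modulator"]].to_csv(
            path, sep="\t", index=False, na_rep="n/a"
        )

    def to_three_column(self, out_dir) -> list:
        """Write one three-column (onset, duration, weight) text file per
        regressor; unmodulated regressors get unit weights.  Returns the
        written paths."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for reg, grp in self.events.groupby("regressor"):
            weights = grp["value"].fillna(1.0)
            frame = pd.DataFrame(
                {"onset": grp["onset"], "duration": grp["duration"], "weight": weights}
            )
            path = out / f"{reg}.txt"
            frame.to_csv(path, sep="\t", index=False, header=False,
                         float_format="%.6f")
            paths.append(path)
        return paths


def extended_forward_pass(
    model_spec: Union[str, ModelSpec], params: ParamVector, session: pd.DataFrame
) -> LatentTrace:
    """Forward pass whose critic chain includes the ITI and pre-trial cue
    states (regressor generation only; choice likelihood is unchanged)."""
    spec = get_model(model_spec) if isinstance(model_spec, str) else model_spec
    return forward_pass(spec, params, session, extended=True)


def build_timeline(session: pd.DataFrame, timing: Optional[TimingSpec] = None) -> EventTimeline:
    """Emit the boxcar events implied by one session's schedule.

    Modulated slots are created with placeholder values (NaN) to be filled by
    :func:`attach_modulators`; AVPE/AV slots exist only on valid active
    trials.  Error trials contribute their ITI fixation and pre-trial cue
    plus a dedicated unmodulated ``error`` event covering the aborted
    remainder of the trial, and nothing else.
    """
    t = timing or TimingSpec()
    stim, isi, cue_d = t.stimulus_s, t.isi_s, t.pretrial_cue_s
    rows: list = []

    def add(trial, regressor, onset, duration, slot=None):
        rows.append((trial, regressor, slot, onset, duration, np.nan))

    for _, row in session.iterrows():
        trial = int(row["trial_index"])
        active = row["trial_type"] == "active"
        on = {k: row[f"onset_{k}"] for k in ("iti", "cue", "first", "isi1", "second",
                                             "isi2", "outcome")}
        add(trial, "fixation", on["iti"], row["iti_s"])
        add(trial, "cue_active" if active else "cue_passive", on["cue"], cue_d)
        if row["error_flag"] != "none":
            add(trial, "error", on["first"], on["outcome"] + t.outcome_s - on["first"])
            continue
        # unmodulated stimulus indicators
        if active:
            add(trial, "active_left" if row["action"] == "L" else "active_right",
                on["first"], stim)
        else:
            add(trial, "fractal_passive", on["first"], stim)
        add(trial, "fixation", on["isi1"], isi)
        add(trial, "fractal_passive", on["second"], stim)
        add(trial, "fixation", on["isi2"], isi)
        add(trial, "outcome_rewarded" if int(row["reward"]) else "outcome_unrewarded",
            on["outcome"], t.outcome_s)
        # state-value boxcars persist through the subsequent ISI
        add(trial, "sv", on["iti"], row["iti_s"], slot="iti")
        add(trial, "sv", on["cue"], cue_d, slot="cue")
        add(trial, "sv", on["first"], stim + isi, slot="first")
        add(trial, "sv", on["second"], stim + isi, slot="second")
        # SVPE boxcars span the stimulus following the predicting state
        add(trial, "svpe", on["cue"], cue_d, slot="cue")
        add(trial, "svpe", on["first"], stim, slot="first")
        add(trial, "svpe", on["second"], stim, slot="second")
        add(trial, "svpe", on["outcome"], t.outcome_s, slot="outcome")
        if active:
            add(trial, "av", on["first"], stim + isi, slot="first")
            add(trial, "avpe", on["second"], stim, slot="second")
            add(trial, "avpe", on["outcome"], t.outcome_s, slot="outcome")
    events = pd.DataFrame(rows, columns=_TIMELINE_COLS).sort_values(
        ["onset", "regressor"], kind="stable"
    )
    return EventTimeline(events=events.reset_index(drop=True)).validated()


_SLOT_SOURCE = {
    # (regressor, slot) -> (trace step, trace column)
    ("sv", "iti"): ("iti", "V"),
    ("sv", "cue"): ("cue", "V"),
    ("sv", "first"): ("first", "V"),
    ("sv", "second"): ("second", "V"),
    ("svpe", "cue"): ("cue", "dV"),
    ("svpe", "first"): ("first", "dV"),
    ("svpe", "second"): ("second", "dV"),
    ("svpe", "outcome"): ("outcome", "dV"),
    ("av", "first"): ("first", "Q"),
    ("avpe", "second"): ("second", "dQ"),
    ("avpe", "outcome"): ("outcome", "dQ"),
}


def attach_modulators(timeline: EventTimeline, trace: LatentTrace) -> EventTimeline:
    """Fill modulator values from an extended-pass latent trace.

    Positive and negative prediction errors share one linear scale (no
    rectification).  Modulated events the trace cannot value (e.g. any AVPE
    slot under a model without a Q-learner) are dropped.
    """
    lookup: dict = {}
    for _, row in trace.events.iterrows():
        lookup[(int(row["trial"]), row["step"])] = row
    ev = timeline.events.copy()
    values = []
    for _, row in ev.iterrows():
        key = (row["regressor"], row["slot"])
        if key not in _SLOT_SOURCE:
            values.append(np.nan)
            continue
        step, col = _SLOT_SOURCE[key]
        src = lookup.get((int(row["trial"]), step))
        if src is None:
            raise ValueError(f"trace missing trial {row['trial']} step {step!r}")
        values.append(src[col])
    ev["value"] = values
    keep = ~ev["regressor"].isin(MODULATED_REGRESSORS) | ev["value"].notna()
    return EventTimeline(events=ev[keep].reset_index(drop=True))


@dataclass
class DesignMatrix:
    """Convolved regressors sampled at the TR, plus a constant column."""

    frame: pd.DataFrame
    tr: float
    dt: float
    provenance: Mapping[str, str]

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()


def _hrf_kernel(dt: float) -> np.ndarray:
    # canonical double-gamma at resolution dt (peak 6 s, undershoot 16 s)
    return spm_hrf(t_r=dt, oversampling=1, time_length=32.0)


def boxcar_signal(
    onsets: Sequence[float],
    durations: Sequence[float],
    amplitudes: Sequence[float],
    n_fine: int,
    dt: float,
) -> np.ndarray:
    """Sum of boxcars on the fine grid (pre-convolution regressor input)."""
    signal = np.zeros(n_fine)
    for onset, dur, a in zip(onsets, durations, amplitudes):
        i0 = int(round(onset / dt))
        i1 = int(round((onset + dur) / dt))
        signal[i0: max(i1, i0 + 1)] += a
    return signal


def convolve_and_sample(
    timeline: EventTimeline,
    tr: float = TR_DEFAULT,
    duration: Optional[float] = None,
    dt: float = 0.01,
    center: bool = True,
) -> DesignMatrix:
    """Build boxcars on a fine grid, convolve with the canonical HRF, and
    downsample at the TR.  ``center=True`` mean-centers each modulated
    regressor's values across its events before convolution (the standard
    parametric-modulator convention); disable for strict additivity checks.
    """
    ev = timeline.events
    end = float((ev["onset"] + ev["duration"]).max()) if len(ev) else 0.0
    total = duration if duration is not None else end + 32.0
    if len(ev) and end > total + 1e-9:
        raise ValueError("events extend beyond the requested duration")
    n_fine = int(np.ceil(total / dt))
    kernel = _hrf_kernel(dt)
    sample_times = np.arange(0.0, total, tr)
    sample_idx = np.minimum((sample_times / dt).astype(int), n_fine - 1)

    columns: dict = {}
    provenance: dict = {}
    for reg in list(UNMODULATED_REGRESSORS) + list(MODULATED_REGRESSORS):
        grp = ev[ev["regressor"] == reg]
        if grp.empty:
            continue
        modulated = reg in MODULATED_REGRESSORS
        amp = grp["value"].to_numpy(dtype=float) if modulated else np.ones(len(grp))
        if modulated and center:
            amp = amp - np.nanmean(amp)
        signal = boxcar_signal(
            grp["onset"].to_numpy(), grp["duration"].to_numpy(), amp, n_fine, dt
        )
        conv = np.convolve(signal, kernel)[:n_fine]
        columns[reg] = conv[sample_idx]
        provenance[reg] = (
            f"{'parametric' if modulated else 'indicator'}; {len(grp)} events; "
            f"{'mean-centered; ' if modulated and center else ''}double-gamma HRF; dt={dt}s"
        )
    columns["constant"] = np.ones(len(sample_times))
    provenance["constant"] = "intercept"
    frame = pd.DataFrame(columns, index=pd.Index(sample_times, name="time_s"))
    if not np.isfinite(frame.to_numpy()).all():
        raise ValueError("non-finite entries in design matrix")
    return DesignMatrix(frame=frame, tr=tr, dt=dt, provenance=provenance)


def modulator_collinearity(design: DesignMatrix) -> dict:
    """Pairwise Pearson correlations among the modulated columns.

    The SVPE-AVPE correlation is the headline dissociability diagnostic; no
    orthogonalization is applied anywhere in this module.
    """
    cols = [c for c in MODULATED_REGRESSORS if c in design.frame.columns]
    for c in cols:
        if np.ptp(design.frame[c].to_numpy()) == 0:
            raise ValueError(f"constant design column {c!r}")
    corr = design.frame[cols].corr()
    out = {"pairwise": corr}
    if "svpe" in cols and "avpe" in cols:
        out["svpe_avpe_r"] = float(corr.loc["svpe", "avpe"])
    return out


def build_design(
    session: pd.DataFrame,
    model_spec: Union[str, ModelSpec],
    params: ParamVector,
    timing: Optional[TimingSpec] = None,
    tr: float = TR_DEFAULT,
    dt: float = 0.01,
) -> DesignMatrix:
    """Session + fitted model -> sampled design matrix (one call)."""
    trace = extended_forward_pass(model_spec, params, session)
    timeline = attach_modulators(build_timeline(session, timing), trace)
    return convolve_and_sample(timeline, tr=tr, dt=dt)
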
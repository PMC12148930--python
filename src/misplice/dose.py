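"""Repeat-length dose-response and MBNL x SRRM combination-index synergy.

The per-sample dysregulation score is the mean, over a fixed mis-spliced
event set, of |PSI_sample - mean control PSI|; its Pearson correlation with
CTG repeat length is the dose-response.  Synergy between two splicing-factor
depletions uses the Bliss combination index

    CI = (EA + EB - EA*EB) / EAB

where EA/EB/EAB are the single and double perturbation effects; CI < 1 is
synergy, CI > 1 antagonism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import linregress


@dataclass
class SampleDysregulationScore:
    sample_id: str
    mean_abs_dpsi: float
    n_events_used: int


@dataclass
class DoseResponseResult:
    pearson_r: float
    p: float
    slope: float
    intercept: float
    n: int


@dataclass
class SynergyResult:
    event_id: str
    ci_mean: float
    ci_sd: float
    classification: str  # synergistic | antagonistic | independent
    n_replicates: int


def sample_dysregulation(
    psi_matrix: pd.DataFrame,
    missplice_event_ids: Iterable[str],
    design: pd.DataFrame,
) -> list[SampleDysregulationScore]:
    """Per-case-sample mean |PSI_s - mean control PSI| over the given events.

    ``psi_matrix`` is the wide event x sample PSI table (NaN = undefined);
    events undefined in a sample are dropped from that sample's mean.
    """
    ctrl_ids = [s for s in design.loc[design["group"] == "control", "sample_id"] if s in psi_matrix.columns]
    case_ids = [s for s in design.loc[design["group"] == "case", "sample_id"] if s in psi_matrix.columns]
    if not ctrl_ids:
        raise ValueError("control group empty or absent from PSI matrix")
    ids = [e for e in missplice_event_ids if e in psi_matrix.index]
    if not ids:
        raise ValueError("no usable mis-spliced events in PSI matrix")
    sub = psi_matrix.loc[ids]
    ctrl_mean = sub[ctrl_ids].mean(axis=1, skipna=True)
    scores = []
    for s in case_ids:
        dev = (sub[s] - ctrl_mean).abs().dropna()
        if len(dev) == 0:
            warnings.warn(f"sample {s}: no events with defined PSI; score undefined")
            scores.append(SampleDysregulationScore(s, float("nan"), 0))
        else:
            scores.append(SampleDysregulationScore(s, float(dev.mean()), int(len(dev))))
    return scores


def correlate_dose(
    scores: list[SampleDysregulationScore] | pd.Series,
    repeat_lengths: pd.Series | dict[str, float],
) -> DoseResponseResult:
    """Pearson correlation (two-tailed p) and OLS line of score vs repeat length."""
    if isinstance(scores, list):
        score_map = {s.sample_id: s.mean_abs_dpsi for s in scores if np.isfinite(s.mean_abs_dpsi)}
    else:
        score_map = dict(scores.dropna())
    if isinstance(repeat_lengths, pd.Series):
        repeat_lengths = dict(repeat_lengths.dropna())
    common = sorted(set(score_map) & set(repeat_lengths))
    x = np.array([repeat_lengths[s] for s in common], dtype=float)
    y = np.array([score_map[s] for s in common], dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate: zero variance in dose or score")
    fit = linregress(x, y)
    return DoseResponseResult(
        pearson_r=float(fit.rvalue),
        p=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(x),
    )


def classify_concordance(dpsi_a: float, dpsi_b: float) -> str:
    """'concordant' when the two dPSI changes share a sign, else 'opposite'."""
    if dpsi_a == 0.0 or dpsi_b == 0.0:
        raise ValueError("not classifiable: zero delta-PSI")
    return "concordant" if (dpsi_a > 0) == (dpsi_b > 0) else "opposite"


def combination_index(ea: float, eb: float, eab: float) -> float:
    """Bliss combination index (EA + EB - EA*EB) / EAB."""
    if eab == 0.0:
        raise ValueError("undefined CI: EAB = 0")
    return (ea + eb - ea * eb) / eab


def effects_from_psi_table(psi_table: pd.DataFrame, mode: str = "concordant") -> pd.DataFrame:
    """Per-event, per-replicate (EA, EB, EAB) from a long condition table.

    Conditions: ctrl, A, B, AB.  ``concordant`` mode uses dPSI vs control;
    ``opposite`` mode uses the raw PSI of each perturbed condition, exactly
    as the combination index is defined for discordant events.
    """
    if mode not in ("concordant", "opposite"):
        raise ValueError(f"unknown mode {mode!r}")
    wide = psi_table.pivot_table(
        index=["event_id", "replicate"], columns="condition", values="psi"
    ).reset_index()
    for cond in ("ctrl", "A", "B", "AB"):
        if cond not in wide.columns:
            raise ValueError(f"condition {cond!r} missing from PSI table")
    if mode == "concordant":
        wide["EA"] = wide["A"] - wide["ctrl"]
        wide["EB"] = wide["B"] - wide["ctrl"]
        wide["EAB"] = wide["AB"] - wide["ctrl"]
    else:
        wide["EA"] = wide["A"]
        wide["EB"] = wide["B"]
        wide["EAB"] = wide["AB"]
    return wide[["event_id", "replicate", "EA", "EB", "EAB"]]


def synergy_summary(
    effects: pd.DataFrame, tolerance: float = 0.05
) -> list[SynergyResult]:
    """Per-event CI mean/sd over replicates and the synergy classification.

    Replicates with EAB = 0 are dropped with a warning; ci_mean below
    1 - tolerance is synergistic, above 1 + tolerance antagonistic,
    otherwise independent (tolerance 0 restores the strict <1 / >1 rule).
    """
    results = []
    for event_id, sub in effects.groupby("event_id", sort=True):
        cis = []
        for row in sub.itertuples(index=False):
            if row.EAB == 0.0:
                warnings.warn(f"{event_id}: replicate with EAB = 0 dropped")
                continue
            cis.append(combination_index(row.EA, row.EB, row.EAB))
        if len(cis) == 0:
            raise ValueError(f"{event_id}: all replicates have EAB = 0")
        if len(cis) < 2:
            warnings.warn(f"{event_id}: fewer than 2 usable replicates")
        ci_mean = float(np.mean(cis))
        ci_sd = float(np.std(cis, ddof=1)) if len(cis) > 1 else 0.0
        if ci_mean < 1.0 - tolerance:
            cls = "synergistic"
        elif ci_mean > 1.0 + tolerance:
            cls = "antagonistic"
        else:
            cls = "independent"
        results.append(SynergyResult(event_id, ci_mean, ci_sd, cls, len(cis)))
    return results


def synergy_frame(results: list[SynergyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": r.event_id,
                "ci_mean": r.ci_mean,
                "ci_sd": r.ci_sd,
                "classification": r.classification,
                "n_replicates": r.n_replicates,
            }
            for r in results
        ]
    )
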
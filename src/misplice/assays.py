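"""Assay-quantification formulas and behavioral statistics.

One-site specific binding (Y = Bmax*X/(Kd+X)) for filter-binding data,
native-RIP relative IP/INPUT enrichment, qPCR 2^-ddCt fold change, the
exact binomial dyad test, and timed-event inter-observer agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import binom


@dataclass
class BindingFit:
    kd: float
    bmax: float
    kd_se: float
    bmax_se: float


def one_site_binding(x, bmax, kd):
    """Specific one-site binding: Y = Bmax * X / (Kd + X)."""
    x = np.asarray(x, dtype=float)
    return bmax * x / (kd + x)


def fit_binding(concentrations, signals, normalize: bool = True) -> BindingFit:
    """Nonlinear least-squares fit of the one-site binding curve.

    Signals are min-max normalized to [0, 1] before fitting (the assay's
    stated convention); Kd and Bmax are constrained positive.  Warns when
    Kd exceeds the probed concentration range (non-saturating data).
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(signals, dtype=float)
    if len(x) != len(y):
        raise ValueError("X and Y must have equal length")
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if (x <= 0).any():
        raise ValueError("concentrations must be positive")
    if np.max(x) / np.min(x) < 10:
        raise ValueError("X must span at least one order of magnitude")
    if normalize:
        if np.ptp(y) == 0:
            raise ValueError("degenerate signals: zero range")
        y = (y - y.min()) / (y.max() - y.min())
    try:
        popt, pcov = curve_fit(
            one_site_binding,
            x,
            y,
            p0=(max(y.max(), 1e-6), float(np.median(x))),
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"binding fit did not converge: {exc}") from exc
    bmax, kd = popt
    bmax_se, kd_se = np.sqrt(np.diag(pcov))
    if kd > 10 * x.max():
        warnings.warn("non-saturating data: fitted Kd far beyond probed range")
    return BindingFit(kd=float(kd), bmax=float(bmax), kd_se=float(kd_se), bmax_se=float(bmax_se))


def fit_binding_replicates(
    curves: Sequence[tuple[Sequence[float], Sequence[float]]], normalize: bool = True
) -> dict:
    """Fit each replicate separately; report mean +/- s.d. of Kd and Bmax."""
    fits = [fit_binding(x, y, normalize=normalize) for x, y in curves]
    kds = np.array([f.kd for f in fits])
    bmaxs = np.array([f.bmax for f in fits])
    return {
        "kd_mean": float(kds.mean()),
        "kd_sd": float(kds.std(ddof=1)) if len(kds) > 1 else 0.0,
        "bmax_mean": float(bmaxs.mean()),
        "bmax_sd": float(bmaxs.std(ddof=1)) if len(bmaxs) > 1 else 0.0,
        "fits": fits,
    }


def ddct(ct_target_case: float, ct_ref_case: float, ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """qPCR relative expression by the 2^-ddCt method."""
    ddct_val = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct_val))


def rip_enrichment(
    ct_table: pd.DataFrame,
    negative_controls: Sequence[str],
    sign_flip: bool = False,
) -> pd.DataFrame:
    """Native-RIP relative IP/INPUT per target, normalized to two negative
    controls.

    ``ct_table`` columns: target, fraction (IP | INPUT), condition (bait |
    control-bait), ct.  Replicate Cts for the same cell are averaged.  The
    exponent x = (Ct_IP,bait - Ct_INPUT,bait) - (Ct_IP,ctrl - Ct_INPUT,ctrl)
    is applied literally as 2^x; ``sign_flip`` computes 2^-x instead (the
    conventional enrichment orientation).  The normalized value divides each
    raw 2^x by the mean raw value of the two negative controls.
    """
    if len(negative_controls) != 2:
        raise ValueError("exactly two negative-control targets required")
    ct = ct_table.groupby(["target", "fraction", "condition"])["ct"].mean()
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    def raw(target: str) -> float:
        try:
            x = (ct[(target, "IP", "bait")] - ct[(target, "INPUT", "bait")]) - (
                ct[(target, "IP", "control-bait")] - ct[(target, "INPUT", "control-bait")]
            )
        except KeyError as exc:
            raise ValueError(f"missing Ct for target {target!r}: {exc}") from exc
        return float(2.0 ** (-x if sign_flip else x))

    targets = sorted(ct_table["target"].unique())
    for nc in negative_controls:
        if nc not in targets:
            raise ValueError(f"negative control {nc!r} absent from Ct table")
    raws = {t: raw(t) for t in targets}
    norm = float(np.mean([raws[nc] for nc in negative_controls]))
    return pd.DataFrame(
        [
            {"target": t, "raw_ip_over_input": raws[t], "normalized": raws[t] / norm}
            for t in targets
        ]
    )


@dataclass(frozen=True)
class DyadCounts:
    k_wt: int
    n_wt: int
    k_ko: int
    n_ko: int

    def __post_init__(self) -> None:
        if min(self.k_wt, self.n_wt, self.k_ko, self.n_ko) < 0:
            raise ValueError("counts must be non-negative")
        if self.k_wt > self.n_wt or self.k_ko > self.n_ko:
            raise ValueError("k must be <= n")
        if self.n_wt < 1 or self.n_ko < 1:
            raise ValueError("n must be >= 1")


def dyad_binomial_test(counts: DyadCounts, direction: str = "greater") -> float:
    """Exact binomial test of the KO dyad count against the WT rate.

    Null rate p0 = k_wt / n_wt; ``greater`` gives P(X >= k_ko),
    ``less`` P(X <= k_ko), ``two_sided`` the sum of outcomes with
    probability <= the observed outcome's.
    """
    if direction not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown direction {direction!r}")
    p0 = counts.k_wt / counts.n_wt
    k, n = counts.k_ko, counts.n_ko
    if p0 in (0.0, 1.0):
        # degenerate null: only the trivially consistent tails are defined
        if p0 == 0.0 and direction == "greater" and k == 0:
            return 1.0
        if p0 == 1.0 and direction == "less" and k == n:
            return 1.0
        raise ValueError("degenerate null: WT rate is 0 or 1")
    if direction == "greater":
        return float(binom.sf(k - 1, n, p0))
    if direction == "less":
        return float(binom.cdf(k, n, p0))
    pmf = binom.pmf(np.arange(n + 1), n, p0)
    obs = binom.pmf(k, n, p0)
    return float(pmf[pmf <= obs * (1 + 1e-12)].sum())


@dataclass(frozen=True)
class PointEvent:
    time: float
    label: str = ""


@dataclass(frozen=True)
class Bout:
    start: float
    stop: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.stop < self.start:
            raise ValueError(f"malformed bout: stop {self.stop} < start {self.start}")


def _greedy_match(items_a, items_b, agree) -> tuple[int, int]:
    """Greedy one-to-one matching in time order; returns (matched, unmatched)."""
    used = [False] * len(items_b)
    matched = 0
    for a in items_a:
        for j, b in enumerate(items_b):
            if not used[j] and agree(a, b):
                used[j] = True
                matched += 1
                break
    unmatched = (len(items_a) - matched) + (len(items_b) - matched)
    return matched, unmatched


def interobserver_agreement(
    stream_a: dict,
    stream_b: dict,
    point_tol: float = 1.0,
    bound_tol: float = 2.0,
    threshold: float = 85.0,
) -> tuple[float, bool]:
    """Percent agreement between two observers' scoring streams.

    Streams carry ``points`` (:class:`PointEvent`) and ``bouts``
    (:class:`Bout`).  Point events agree when scored within ``point_tol``
    seconds; bouts when both start and stop lie within ``bound_tol`` seconds
    (labels must match).  Greedy one-to-one matching in time order;
    agreement % = matched / (matched + unmatched in either stream) * 100;
    the pass flag applies the >= ``threshold`` cutoff.
    """
    pa = sorted(stream_a.get("points", []), key=lambda e: e.time)
    pb = sorted(stream_b.get("points", []), key=lambda e: e.time)
    ba = sorted(stream_a.get("bouts", []), key=lambda e: e.start)
    bb = sorted(stream_b.get("bouts", []), key=lambda e: e.start)
    m1, u1 = _greedy_match(
        pa, pb, lambda a, b: a.label == b.label and abs(a.time - b.time) <= point_tol
    )
    m2, u2 = _greedy_match(
        ba,
        bb,
        lambda a, b: a.label == b.label
        and abs(a.start - b.start) <= bound_tol
        and abs(a.stop - b.stop) <= bound_tol,
    )
    matched, unmatched = m1 + m2, u1 + u2
    if matched + unmatched == 0:
        return 100.0, True
    pct = 100.0 * matched / (matched + unmatched)
    return pct, pct >= threshold
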
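"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator emulates a two-group (case vs control) junction-count study:
a fraction of events carries a true splicing shift of fixed magnitude
``delta_psi_effect`` with random sign; replicate counts follow a
beta-binomial with intra-class correlation ``rho`` around the sample-level
PSI; case samples carry a CTG repeat length that linearly scales their
effect (``dose_slope``); gene-set membership is planted so that affected
events concentrate in the first synthetic set; and a gapped YGCY motif is
planted near regulated exons at a higher rate than elsewhere.  Everything is
deterministic under (spec, seed).

Default parameter values correspond to the study-scale conditions the
analysis is designed for: 2,000 events, 8 vs 8 replicates, mean junction
depth 100, |dPSI| = 0.3 on 20% of events, rho = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .events import EventType, GeneSet, SpliceEvent, events_to_frame
from .motifs import MBNL_YGCY, compile_pattern, scan

_EVENT_TYPE_WEIGHTS = {
    EventType.SE: 0.60,
    EventType.MXE: 0.10,
    EventType.A5SS: 0.10,
    EventType.A3SS: 0.10,
    EventType.RI: 0.10,
}


@dataclass
class SimulationSpec:
    """Knobs of the synthetic study; defaults are the reference conditions."""

    n_genes: int = 500
    events_per_gene: int = 4
    mie_fraction: float = 0.25      # fraction of SE events drawn as 3-33 nt microexons
    asd_set_fraction: float = 0.15  # fraction of genes in each synthetic gene set
    n_gene_sets: int = 2
    frac_missplice: float = 0.2
    delta_psi_effect: float = 0.3
    rho: float = 0.05               # beta-binomial intra-class correlation
    depth: float = 100.0            # mean total junction reads / event / sample
    n_case: int = 8
    n_ctrl: int = 8
    dose_slope: float = 0.0
    motif_plant_rate_affected: float = 0.9
    motif_plant_rate_null: float = 0.5
    motif_window: int = 250
    clean_background: bool = False  # scrub accidental YGCY from non-planted windows
    affected_in_set_odds: float = 1.0  # enrichment of affected events in set 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "mie_fraction",
            "asd_set_fraction",
            "frac_missplice",
            "motif_plant_rate_affected",
            "motif_plant_rate_null",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0.0 < self.delta_psi_effect < 1.0:
            raise ValueError("delta_psi_effect must be in (0, 1)")
        if self.n_genes < 1 or self.events_per_gene < 1:
            raise ValueError("n_genes and events_per_gene must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth: per-event effects, per-gene memberships, per-sample dose."""

    events: pd.DataFrame   # event_id, gene_id, psi_base, delta_true, affected, motif_planted
    genes: pd.DataFrame    # gene_id, in_<set> columns
    samples: pd.DataFrame  # sample_id, group, repeat_length


@dataclass
class SyntheticBundle:
    spec: SimulationSpec
    events: list[SpliceEvent]
    design: pd.DataFrame
    counts: pd.DataFrame
    sequences: dict[str, str]
    regions: dict[str, tuple[int, int]]
    gene_sets: list[GeneSet]
    truth: GroundTruth


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_annotation(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
):
    """Lay events on a synthetic chromosome and plant truth labels.

    Returns (events, gene_frame, gene_sets, truth_events_frame).  Events are
    spaced so scan regions never overlap; ``mie_fraction`` of SE events get
    exon lengths in [3, 33], the rest in [60, 300].
    """
    rng = rng if rng is not None else _rng(spec.seed)
    gene_ids = [f"g{i:04d}" for i in range(spec.n_genes)]

    # gene-set membership
    sets: dict[str, set[str]] = {}
    genes_rows = []
    membership = {}
    for s in range(spec.n_gene_sets):
        name = f"set{s + 1}"
        mask = rng.random(spec.n_genes) < spec.asd_set_fraction
        sets[name] = {g for g, m in zip(gene_ids, mask) if m}
        membership[name] = dict(zip(gene_ids, mask))
    for g in gene_ids:
        genes_rows.append({"gene_id": g, **{f"in_{n}": bool(membership[n][g]) for n in sets}})
    gene_frame = pd.DataFrame(genes_rows)
    gene_sets = [GeneSet.from_iterable(n, s) for n, s in sets.items() if s]

    etypes = list(_EVENT_TYPE_WEIGHTS)
    eweights = np.array(list(_EVENT_TYPE_WEIGHTS.values()))
    spacing_margin = 2 * spec.motif_window + 600
    pos = 1000
    events: list[SpliceEvent] = []
    truth_rows = []
    in_set1 = sets.get("set1", set())
    for gi, gene in enumerate(gene_ids):
        for ei in range(spec.events_per_gene):
            etype = etypes[rng.choice(len(etypes), p=eweights / eweights.sum())]
            if etype is EventType.SE and rng.random() < spec.mie_fraction:
                exon_len = int(rng.integers(3, 34))
            else:
                exon_len = int(rng.integers(60, 301))
            intron_up = int(rng.integers(spec.motif_window + 50, spec.motif_window + 300))
            intron_down = int(rng.integers(spec.motif_window + 50, spec.motif_window + 300))
            flank_len = 100
            fu_start = pos
            fu_end = fu_start + flank_len
            ex_start = fu_end + intron_up
            ex_end = ex_start + exon_len
            fd_start = ex_end + intron_down
            fd_end = fd_start + flank_len
            event_id = f"ev{gi * spec.events_per_gene + ei:05d}"
            events.append(
                SpliceEvent(
                    event_id=event_id,
                    gene_id=gene,
                    event_type=etype,
                    chrom="chrS",
                    strand="+" if rng.random() < 0.5 else "-",
                    exon_start=ex_start,
                    exon_end=ex_end,
                    flank_up_start=fu_start,
                    flank_up_end=fu_end,
                    flank_down_start=fd_start,
                    flank_down_end=fd_end,
                )
            )
            pos = fd_end + spacing_margin

            # planted truth: affected events may concentrate in set1
            p_aff = spec.frac_missplice
            if spec.affected_in_set_odds != 1.0:
                # odds-scaled so the in-set/out-set affected odds ratio is
                # affected_in_set_odds while the overall rate stays close
                odds = p_aff / (1 - p_aff)
                if gene in in_set1:
                    odds *= spec.affected_in_set_odds
                p_aff = odds / (1 + odds)
            affected = bool(rng.random() < p_aff)
            psi_base = float(rng.uniform(0.15, 0.85))
            if affected:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                # keep the shifted mean inside [0.02, 0.98]
                if psi_base + sign * spec.delta_psi_effect > 0.98 or (
                    psi_base + sign * spec.delta_psi_effect < 0.02
                ):
                    sign = -sign
                delta_true = sign * spec.delta_psi_effect
            else:
                delta_true = 0.0
            rate = spec.motif_plant_rate_affected if (affected and gene in in_set1) else spec.motif_plant_rate_null
            truth_rows.append(
                {
                    "event_id": event_id,
                    "gene_id": gene,
                    "event_type": etype.value,
                    "psi_base": psi_base,
                    "delta_true": delta_true,
                    "affected": affected,
                    "motif_planted": bool(rng.random() < rate),
                }
            )
    return events, gene_frame, gene_sets, pd.DataFrame(truth_rows)


def generate_design(spec: SimulationSpec, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Sample table: cases carry a CTG repeat length (uniform 80-1000)."""
    rng = rng if rng is not None else _rng(spec.seed)
    rows = []
    for i in range(spec.n_case):
        rows.append(
            {
                "sample_id": f"case{i + 1:02d}",
                "group": "case",
                "repeat_length": float(rng.integers(80, 1001)),
            }
        )
    for i in range(spec.n_ctrl):
        rows.append({"sample_id": f"ctrl{i + 1:02d}", "group": "control", "repeat_length": np.nan})
    return pd.DataFrame(rows)


_YGCY = compile_pattern(MBNL_YGCY)


def _scrub_ygcy(seq: list[str], rng: np.random.Generator) -> None:
    """Destroy every YGCY match by mutating its G to A (cannot create new
    matches: YGCY contains no A)."""
    while True:
        hits = scan("".join(seq), _YGCY)
        if not hits:
            return
        for h in hits:
            seq[h.start + 1] = "A"


def generate_sequences(
    events: list[SpliceEvent],
    truth: pd.DataFrame,
    spec: SimulationSpec,
    rng: Optional[np.random.Generator] = None,
):
    """Per-event scan-region sequences (exon +/- motif_window, sense strand).

    Background is i.i.d. ACGT at GC 0.5.  For motif-planted events one
    concrete YGCY(N)k YGCY instance (k uniform in 0-5) is written at a
    uniform offset within ``motif_window`` nt of a randomly chosen exon
    boundary.  In ``clean_background`` mode accidental YGCY matches are
    scrubbed first, so non-planted regions carry no YGCY at all.

    Returns (sequences, regions): event_id -> sequence and event_id ->
    genomic (start, end) of the region.
    """
    rng = rng if rng is not None else _rng(spec.seed + 1)
    planted = dict(zip(truth["event_id"], truth["motif_planted"]))
    w = spec.motif_window
    seqs: dict[str, str] = {}
    regions: dict[str, tuple[int, int]] = {}
    alphabet = np.array(list("ACGT"))
    for ev in events:
        if w > min(ev.exon_start - ev.flank_up_end, ev.flank_down_start - ev.exon_end):
            raise ValueError(f"{ev.event_id}: motif window larger than flanking intron")
        length = ev.exon_length + 2 * w
        seq = list(rng.choice(alphabet, size=length))
        if spec.clean_background:
            _scrub_ygcy(seq, rng)
        if planted.get(ev.event_id, False):
            k = int(rng.integers(0, 6))
            inst = "".join(
                [
                    rng.choice(["C", "T"]), "G", "C", rng.choice(["C", "T"]),
                    *rng.choice(alphabet, size=k),
                    rng.choice(["C", "T"]), "G", "C", rng.choice(["C", "T"]),
                ]
            )
            # uniform offset within `w` nt of a random exon boundary, kept
            # fully inside the flanking intron
            side = "up" if rng.random() < 0.5 else "down"
            max_off = w - len(inst)
            off = int(rng.integers(0, max_off + 1))
            if side == "up":
                start = w - off - len(inst)
            else:
                start = w + ev.exon_length + off
            seq[start : start + len(inst)] = list(inst)
        seqs[ev.event_id] = "".join(seq)
        regions[ev.event_id] = (ev.exon_start - w, ev.exon_end + w)
    return seqs, regions


def betabinom_variance(n: float, p: float, rho: float) -> float:
    """Variance of a beta-binomial count: n p (1-p) (1 + (n-1) rho)."""
    return n * p * (1 - p) * (1 + (n - 1) * rho)


def simulate_junction_counts(
    events: list[SpliceEvent],
    design: pd.DataFrame,
    truth: pd.DataFrame,
    spec: SimulationSpec,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Beta-binomial junction counts per event x sample.

    Per sample: total n ~ Poisson(depth); sample-level PSI p* ~ Beta with
    mean p and ICC rho; inclusion reads I ~ Binomial(n, p* lI / (p* lI +
    (1 - p*) lS)); S = n - I.  Case effects scale with normalized repeat
    length when ``dose_slope`` > 0.
    """
    rng = rng if rng is not None else _rng(spec.seed + 2)
    if spec.depth <= 0:
        raise ValueError("depth must be > 0")
    tr = truth.set_index("event_id")
    case_mask = design["group"] == "case"
    rl = design.loc[case_mask, "repeat_length"].to_numpy(dtype=float)
    if spec.dose_slope != 0.0 and np.isnan(rl).any():
        raise ValueError("dose_slope requires repeat_length for all case samples")
    if len(rl) and np.nanmax(rl) > np.nanmin(rl):
        z_case = (rl - np.nanmin(rl)) / (np.nanmax(rl) - np.nanmin(rl))
    else:
        z_case = np.zeros(len(rl))
    z_by_sample = dict(zip(design.loc[case_mask, "sample_id"], z_case))
    samples = list(zip(design["sample_id"], design["group"]))
    rows = []
    for ev in events:
        base = float(tr.at[ev.event_id, "psi_base"])
        delta = float(tr.at[ev.event_id, "delta_true"])
        lI, lS = ev.effective_lengths
        for sample_id, group in samples:
            if group == "case":
                eff = delta * (1.0 + spec.dose_slope * z_by_sample[sample_id])
                p = float(np.clip(base + eff, 0.0, 1.0))
            else:
                p = base
            n = int(rng.poisson(spec.depth))
            if n == 0:
                inc = 0
            else:
                if spec.rho < 1e-9 or p <= 0.0 or p >= 1.0:
                    p_star = p
                else:
                    a = p * (1 - spec.rho) / spec.rho
                    b = (1 - p) * (1 - spec.rho) / spec.rho
                    p_star = float(rng.beta(a, b))
                pi = p_star * lI / (p_star * lI + (1 - p_star) * lS) if 0 < p_star < 1 else p_star
                inc = int(rng.binomial(n, pi))
            rows.append(
                {
                    "event_id": ev.event_id,
                    "sample_id": sample_id,
                    "inclusion": inc,
                    "skipping": n - inc,
                    "inc_len": lI,
                    "skp_len": lS,
                }
            )
    return pd.DataFrame(rows)


def simulate_bundle(spec: SimulationSpec) -> SyntheticBundle:
    """Full seeded input bundle: annotation, design, counts, sequences, truth."""
    rng = _rng(spec.seed)
    events, gene_frame, gene_sets, truth_events = generate_annotation(spec, rng)
    design = generate_design(spec, rng)
    seqs, regions = generate_sequences(events, truth_events, spec, rng)
    counts = simulate_junction_counts(events, design, truth_events, spec, rng)
    truth = GroundTruth(events=truth_events, genes=gene_frame, samples=design.copy())
    return SyntheticBundle(spec, events, design, counts, seqs, regions, gene_sets, truth)


def simulate_dual_perturbation(
    n_events: int,
    effects: Optional[pd.DataFrame] = None,
    noise_sd: float = 0.02,
    n_reps: int = 3,
    seed: int = 0,
    synergy_factor: float = 1.25,
    class_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate PSI tables for control / A-depleted / B-depleted / AB-depleted.

    Truth labels each event synergistic (EAB = synergy_factor x Bliss),
    antagonistic (EAB = Bliss / synergy_factor) or independent (EAB exactly
    Bliss, so CI = 1 before noise).  Returns (psi_table, truth); psi_table is
    long: event_id, condition in {ctrl, A, B, AB}, replicate, psi.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = _rng(seed)
    if effects is None:
        ea = rng.uniform(0.15, 0.35, size=n_events)
        eb = rng.uniform(0.15, 0.35, size=n_events)
        effects = pd.DataFrame({"EA": ea, "EB": eb})
    classes = rng.choice(["synergistic", "antagonistic", "independent"], size=n_events, p=class_probs)
    base = rng.uniform(0.05, 0.25, size=n_events)
    rows = []
    truth_rows = []
    for i in range(n_events):
        ea, eb = float(effects["EA"].iloc[i]), float(effects["EB"].iloc[i])
        bliss = ea + eb - ea * eb
        if classes[i] == "synergistic":
            eab = bliss * synergy_factor
        elif classes[i] == "antagonistic":
            eab = bliss / synergy_factor
        else:
            eab = bliss
        event_id = f"dp{i:04d}"
        truth_rows.append(
            {"event_id": event_id, "EA": ea, "EB": eb, "EAB": eab, "class": classes[i]}
        )
        for cond, eff in (("ctrl", 0.0), ("A", ea), ("B", eb), ("AB", eab)):
            for rep in range(1, n_reps + 1):
                psi = float(np.clip(base[i] + eff + rng.normal(0.0, noise_sd), 0.0, 1.0))
                rows.append(
                    {"event_id": event_id, "condition": cond, "replicate": rep, "psi": psi}
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_dyads(
    n_wt: int, n_ko: int, p_wt: float, p_ko: float, seed: int = 0
) -> pd.DataFrame:
    """Bernoulli dyad outcomes (behavior observed / not) per genotype."""
    for name, p in (("p_wt", p_wt), ("p_ko", p_ko)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = _rng(seed)
    rows = [
        {"dyad_id": f"wt{i + 1:02d}", "genotype": "WT", "positive": bool(rng.random() < p_wt)}
        for i in range(n_wt)
    ] + [
        {"dyad_id": f"ko{i + 1:02d}", "genotype": "KO", "positive": bool(rng.random() < p_ko)}
        for i in range(n_ko)
    ]
    return pd.DataFrame(rows)
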
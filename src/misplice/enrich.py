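"""Fisher odds-ratio enrichment machinery.

Every enrichment here reduces to a 2x2 contingency table tested with a
two-sided Fisher exact test (minimum-likelihood rule).  The point odds ratio
is the sample OR = (a*d)/(b*c); the 95% CI is the Woolf log-OR normal
approximation, with a Haldane-Anscombe 0.5 correction applied to the CI
(never the point estimate) when any cell is zero.  BH adjustment is applied
across the supplied list of gene sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .events import GeneSet
from .psi import bh_fdr

Z95 = 1.959963984540054


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cells: a = focal & positive, b = focal & negative,
    c = other & positive, d = other & negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.total < 1:
            raise ValueError("contingency table is all zeros")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class EnrichmentResult:
    set_name: str
    table: ContingencyTable2x2
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    q: Optional[float] = None
    warning: Optional[str] = None
    extras: dict = field(default_factory=dict)


@dataclass
class OverlapResult:
    n_overlap: int
    n_universe: int
    n_called_a: int
    n_called_b: int
    table: ContingencyTable2x2
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    fraction_in_focal_sets: dict[str, float] = field(default_factory=dict)


def fisher_or(table: ContingencyTable2x2) -> tuple[float, float, float, float]:
    """(odds_ratio, ci_low, ci_high, p) for a 2x2 table.

    OR is +inf when b*c = 0 with a*d > 0, 0 when a*d = 0 with b*c > 0, and
    NaN when both diagonals vanish.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a * d == 0 and b * c == 0:
        or_ = math.nan
    elif b * c == 0:
        or_ = math.inf
    else:
        or_ = (a * d) / (b * c)
    p = float(fisher_exact(table.as_array(), alternative="two-sided")[1])
    cells = [a, b, c, d]
    if 0 in cells:
        cells = [x + 0.5 for x in cells]  # Haldane-Anscombe, CI only
    ah, bh_, ch, dh = cells
    log_or = math.log(ah * dh / (bh_ * ch))
    se = math.sqrt(1 / ah + 1 / bh_ + 1 / ch + 1 / dh)
    return or_, math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se), p


def _result(set_name: str, a: int, b: int, c: int, d: int, **extras) -> EnrichmentResult:
    table = ContingencyTable2x2(a, b, c, d)
    warning = None
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        warning = "degenerate margin; odds ratio undefined or extreme"
        warnings.warn(f"{set_name}: {warning}", stacklevel=3)
    or_, lo, hi, p = fisher_or(table)
    return EnrichmentResult(set_name, table, or_, lo, hi, p, warning=warning, extras=extras)


def event_level_enrichment(differential: pd.DataFrame, gene_set: GeneSet) -> EnrichmentResult:
    """Mis-spliced events in the gene set vs mis-spliced events elsewhere.

    The universe is all tested events; rows of the table split events by
    gene-set membership, columns by the mis-splicing call.
    """
    in_set = differential["gene_id"].isin(gene_set.gene_ids)
    called = differential["is_missplicing"].astype(bool)
    a = int((in_set & called).sum())
    b = int((in_set & ~called).sum())
    c = int((~in_set & called).sum())
    d = int((~in_set & ~called).sum())
    return _result(gene_set.name, a, b, c, d)


def gene_level_enrichment(
    differential: pd.DataFrame, gene_set: GeneSet, detected_genes: Iterable[str]
) -> EnrichmentResult:
    """Genes with >= 1 mis-spliced event vs other detected genes."""
    detected = set(detected_genes)
    tested_genes = set(differential["gene_id"])
    if not tested_genes <= detected:
        raise ValueError("detected_genes must cover all genes of tested events")
    missed = set(differential.loc[differential["is_missplicing"].astype(bool), "gene_id"])
    a = b = c = d = 0
    for g in detected:
        if g in gene_set.gene_ids:
            if g in missed:
                a += 1
            else:
                b += 1
        elif g in missed:
            c += 1
        else:
            d += 1
    return _result(gene_set.name, a, b, c, d)


def enrichment_table(
    differential: pd.DataFrame,
    gene_sets: Sequence[GeneSet],
    mode: str = "event",
    detected_genes: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Run one enrichment per gene set and BH-adjust p across the sets."""
    results = []
    for gs in gene_sets:
        if mode == "event":
            results.append(event_level_enrichment(differential, gs))
        elif mode == "gene":
            genes = detected_genes if detected_genes is not None else set(differential["gene_id"])
            results.append(gene_level_enrichment(differential, gs, genes))
        elif mode == "mie":
            results.append(mie_enrichment(differential, gs))
        else:
            raise ValueError(f"unknown enrichment mode {mode!r}")
    qs = bh_fdr([r.p for r in results]) if results else []
    rows = []
    for r, q in zip(results, qs):
        r.q = float(q)
        rows.append(
            {
                "set_name": r.set_name,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "q": r.q,
                **r.extras,
            }
        )
    return pd.DataFrame(rows)


def classify_microexon(event_type: str, exon_length: int, min_len: int = 3, max_len: int = 33) -> bool:
    """A microexon (miE) is an SE event with a 3-33 nt alternative exon."""
    return str(event_type) == "SE" and min_len <= exon_length <= max_len


def mie_enrichment(
    differential: pd.DataFrame,
    gene_set: GeneSet,
    min_len: int = 3,
    max_len: int = 33,
) -> EnrichmentResult:
    """Microexon enrichment among mis-spliced in-set SE events.

    Universe: all detected (tested) SE events.  Rows: miE vs non-miE.
    Columns: (mis-spliced AND in gene set) vs all other detected SE events.
    Also reports the descriptive miE percentages among all detected SE,
    among mis-spliced SE, and among mis-spliced in-set SE.
    """
    se = differential[differential["event_type"] == "SE"]
    if len(se) == 0:
        raise ValueError("no SE events in differential table")
    is_mie = se.apply(
        lambda r: classify_microexon(r["event_type"], r["exon_length"], min_len, max_len), axis=1
    )
    called = se["is_missplicing"].astype(bool)
    in_set = se["gene_id"].isin(gene_set.gene_ids)
    positive = called & in_set
    a = int((is_mie & positive).sum())
    b = int((is_mie & ~positive).sum())
    c = int((~is_mie & positive).sum())
    d = int((~is_mie & ~positive).sum())

    def pct(mask):
        return 100.0 * float((is_mie & mask).sum()) / max(int(mask.sum()), 1)

    extras = {
        "pct_mie_detected_se": 100.0 * float(is_mie.sum()) / len(se),
        "pct_mie_missplice_se": pct(called),
        "pct_mie_missplice_in_set": pct(positive),
    }
    res = _result(gene_set.name, a, b, c, d, **extras)
    return res


def overlap_events(
    called_a: Iterable[str],
    called_b: Iterable[str],
    mapping: Sequence[tuple[str, str]],
    universe: Iterable[str],
    gene_of: Optional[dict[str, str]] = None,
    gene_sets: Sequence[GeneSet] = (),
) -> OverlapResult:
    """Cross-dataset overlap of mis-splicing calls under an id mapping.

    ``mapping`` holds (id_A, id_B) equivalence pairs (e.g., LiftOver-matched
    events); ``universe`` lists A-space ids tested in both datasets.  The
    Fisher table crosses called-in-A with called-in-B over the universe.
    """
    a_to_b = dict(mapping)
    if len(a_to_b) != len(mapping):
        raise ValueError("mapping must be injective on id_A")
    b_ids = [b for _, b in mapping]
    if len(set(b_ids)) != len(b_ids):
        raise ValueError("mapping must be injective on id_B")
    universe = sorted(set(universe))
    unknown = set(universe) - set(a_to_b)
    if unknown:
        raise ValueError(f"universe ids missing from mapping: {sorted(unknown)[:5]}")
    called_a = set(called_a)
    called_b = set(called_b)
    both = only_a = only_b = neither = 0
    overlap_ids = []
    for ida in universe:
        ina = ida in called_a
        inb = a_to_b[ida] in called_b
        if ina and inb:
            both += 1
            overlap_ids.append(ida)
        elif ina:
            only_a += 1
        elif inb:
            only_b += 1
        else:
            neither += 1
    table = ContingencyTable2x2(both, only_a, only_b, neither)
    or_, lo, hi, p = fisher_or(table)
    fractions = {}
    if gene_of is not None:
        for gs in gene_sets:
            if overlap_ids:
                frac = sum(gene_of[i] in gs.gene_ids for i in overlap_ids) / len(overlap_ids)
            else:
                frac = math.nan
            fractions[gs.name] = frac
    return OverlapResult(
        n_overlap=both,
        n_universe=len(universe),
        n_called_a=len(called_a & set(universe)),
        n_called_b=sum(1 for i in universe if a_to_b[i] in called_b),
        table=table,
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        p=p,
        fraction_in_focal_sets=fractions,
    )
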
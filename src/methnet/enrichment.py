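"""Enrichment statistics around called DREs.

Covers: TF binding-site association (motif hits within +/- 250 bp of the
probe), odds-ratio enrichment of a TF within a DRE category against the
full DRE background with a 95% Wald confidence interval, hypergeometric
category enrichment (e.g. chromatin states, with the full probe universe
as control), and the TF-expression vs binding-site-methylation
correlation ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .containers import AnnotationMap, OmicsMatrix, VariableVector
from .dre import DrePair
from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

FLANK_BP = 250  # motif search half-window around a probe


@dataclass(frozen=True)
class ContingencyCounts:
    """Counts for the category-vs-background odds ratio.

    a: DREs in the category carrying the TF site; b: in the category
    without the site; c: all DREs carrying the site; d: all DREs without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")
        if self.a > self.c or self.b > self.d:
            raise ValidationError(
                "category counts cannot exceed background counts (a<=c, b<=d)"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    enriched: bool


@dataclass(frozen=True)
class HypergeomResult:
    N: int
    K: int
    n: int
    x: int
    fold_change: float
    p_value: float


@dataclass(frozen=True)
class MotifHit:
    """One TF binding-site interval (1-based inclusive coordinates)."""

    tf: str
    chrom: str
    start: int
    end: int


def _trees_by_tf(motif_hits: Sequence[MotifHit]) -> dict[str, dict[str, IntervalTree]]:
    trees: dict[str, dict[str, IntervalTree]] = {}
    for hit in motif_hits:
        # IntervalTree is half-open; +1 keeps the 1-based inclusive end
        trees.setdefault(hit.tf, {}).setdefault(hit.chrom, IntervalTree()).addi(
            hit.start, hit.end + 1, hit.tf
        )
    return trees


def tf_binding_association(
    dres: Sequence[DrePair],
    motif_hits: Sequence[MotifHit],
    annotations: AnnotationMap,
    flank_bp: int = FLANK_BP,
) -> dict[str, set[str]]:
    """Map each TF to the probes whose +/- flank overlaps one of its hits.

    Overlap is closed at the boundary: a hit starting exactly at
    probe_pos + flank_bp counts.  A disjoint chromosome namespace between
    probes and motif hits raises (usually a chr-prefix mismatch).
    """
    probe_ids = sorted({p.probe_id for p in dres})
    probe_chroms = {annotations[p].chrom for p in probe_ids}
    hit_chroms = {h.chrom for h in motif_hits}
    if motif_hits and probe_ids and not (probe_chroms & hit_chroms):
        raise ValidationError(
            "no chromosome shared between probes and motif hits: "
            f"probes use {sorted(probe_chroms)}, hits use {sorted(hit_chroms)}"
        )
    trees = _trees_by_tf(motif_hits)
    assoc: dict[str, set[str]] = {tf: set() for tf in trees}
    for pid in probe_ids:
        ann = annotations[pid]
        lo, hi = ann.position - flank_bp, ann.position + flank_bp
        for tf, by_chrom in trees.items():
            tree = by_chrom.get(ann.chrom)
            if tree is not None and tree.overlap(lo, hi + 1):
                assoc[tf].add(pid)
    return assoc


def odds_ratio_enrichment(
    counts: ContingencyCounts,
    threshold: float = 1.05,
    haldane: bool = False,
) -> EnrichmentResult:
    """OR = (a/c)/(b/d) with 95% CI exp(ln OR +/- 1.96*sqrt(sum 1/cell)).

    Zero cells are a hard error unless ``haldane`` adds 0.5 to each cell.
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValidationError(
                "zero cell in contingency counts; pass haldane=True for the "
                "+0.5 continuity correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a / c) / (b / d)
    half = 1.96 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EnrichmentResult(
        odds_ratio=odds,
        ci_low=math.exp(math.log(odds) - half),
        ci_high=math.exp(math.log(odds) + half),
        enriched=odds > threshold,
    )


def hypergeometric_enrichment(N: int, K: int, n: int, x: int) -> HypergeomResult:
    """Upper-tail hypergeometric enrichment P(X >= x) with fold change.

    N: universe size (all probes); K: universe members in the category;
    n: DREs drawn from the universe; x: DREs in the category.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= x <= min(K, n)):
        raise ValidationError(
            f"inconsistent counts N={N}, K={K}, n={n}, x={x}"
        )
    if n == 0 or N == 0:
        raise ValidationError("n and N must be positive")
    fold = (x / n) / (K / N) if K > 0 else math.inf
    p = float(stats.hypergeom.sf(x - 1, N, K, n))
    return HypergeomResult(N=N, K=K, n=n, x=x, fold_change=fold, p_value=min(p, 1.0))


def category_odds_ratios(
    dres: Sequence[DrePair],
    association: Mapping[str, set[str]],
    threshold: float = 1.05,
    haldane: bool = False,
) -> pd.DataFrame:
    """Per (category, TF) odds ratios against the union-of-categories background.

    Categories are the four sign/direction subgroups (negative-up,
    negative-down, positive-up, positive-down); pairs without a target
    direction fall into sign-only categories.
    """
    def cat(p: DrePair) -> str:
        return (f"{p.corr_sign}-{p.target_direction}"
                if p.target_direction != "NA" else p.corr_sign)

    all_probes = {p.probe_id for p in dres}
    rows = []
    for tf, bound in sorted(association.items()):
        c = len(all_probes & bound)
        d = len(all_probes) - c
        for category in sorted({cat(p) for p in dres}):
            members = {p.probe_id for p in dres if cat(p) == category}
            a = len(members & bound)
            b = len(members) - a
            try:
                res = odds_ratio_enrichment(
                    ContingencyCounts(a, b, c, d), threshold, haldane
                )
            except ValidationError:
                continue  # zero cell without correction: skip, not a call
            rows.append({
                "tf": tf, "category": category, "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "enriched": res.enriched,
            })
    return pd.DataFrame(rows, columns=[
        "tf", "category", "a", "b", "c", "d",
        "odds_ratio", "ci_low", "ci_high", "enriched",
    ])


def tf_methylation_correlation(
    tf_expr: VariableVector,
    dre_meth: OmicsMatrix,
) -> float:
    """PCC between TF expression and the mean methylation of its bound sites."""
    if dre_meth.data.shape[1] == 0:
        raise ValidationError("TF has no associated DREs")
    avg = dre_meth.data.mean(axis=1).to_numpy()
    if np.var(avg) == 0.0:
        raise DegenerateInputError("average site methylation is constant")
    if np.var(tf_expr.values) == 0.0:
        raise DegenerateInputError(f"TF {tf_expr.id!r} expression is constant")
    return float(stats.pearsonr(tf_expr.values, avg)[0])


def rank_tf_correlations(pcc_by_tf: Mapping[str, float]) -> pd.DataFrame:
    """Rank TFs by PCC ascending: strongest negative correlation first."""
    frame = pd.DataFrame(
        sorted(pcc_by_tf.items(), key=lambda kv: kv[1]), columns=["tf", "pcc"]
    )
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame
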
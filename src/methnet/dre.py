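"""Direct regulatory element (DRE) calling around target genes.

For each target gene a merged window matrix is assembled: the gene's
expression, every neighboring gene whose TSS lies within +/- window_bp
(default 300 kb) of the target TSS, and every CpG probe in the same
window.  The PC-algorithm network is inferred on that matrix and every
probe directly connected to the target gene becomes a DRE-target pair,
annotated with its Pearson correlation, signed TSS distance,
promoter/distal class, and (optionally) the target's differential
expression direction.

Also provided: the methylation-dynamics classifier (initiation vs
progression beta shifts) and precision evaluation of called pairs
against chromatin-interaction anchor pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnnotationMap, GenomicAnnotation, OmicsMatrix
from .errors import ValidationError
from .pcnet import PcParams, infer_network

logger = logging.getLogger(__name__)

PROMOTER_BP = 2000  # |distance| <= 2 kb from the TSS -> promoter DRE


@dataclass
class DrePair:
    """One called probe -> target-gene regulatory pair."""

    probe_id: str
    gene_id: str
    pcc: float
    distance_bp: int
    locus_class: str = ""  # promoter | distal
    corr_sign: str = ""  # negative | positive
    target_direction: str = "NA"  # up | down | NA
    mi_bits: float = math.nan
    p_value: float = math.nan


@dataclass(frozen=True)
class DynamicsCall:
    """Methylation-change pattern across tumor initiation and progression."""

    probe_id: str
    delta_initiation: float
    delta_progression: float
    category: str  # consistent | reversed | stronger | weaker


@dataclass(frozen=True)
class AnchorPair:
    """One chromatin-interaction pair; coordinates 1-based inclusive."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int


def signed_tss_distance(
    probe: GenomicAnnotation, gene: GenomicAnnotation
) -> int:
    """Probe - TSS distance measured 5' -> 3' along the gene's strand."""
    raw = probe.position - gene.position
    return raw if gene.strand == "+" else -raw


def assemble_window(
    gene_id: str,
    annotations: AnnotationMap,
    expr: OmicsMatrix,
    meth: OmicsMatrix,
    window_bp: int = 300_000,
) -> OmicsMatrix | None:
    """Merged expression+methylation matrix for one target-gene window.

    Returns the matrix over shared samples containing the target gene,
    all annotated genes with TSS within +/- window_bp of the target TSS
    (closed interval, same chromosome), and all probes within the window.
    Returns ``None`` (with a warning) when no probe falls in the window.
    """
    if gene_id not in annotations:
        raise KeyError(f"gene {gene_id!r} missing from annotations")
    if gene_id not in expr.data.columns:
        raise KeyError(f"gene {gene_id!r} missing from expression matrix")
    target = annotations[gene_id]
    lo, hi = target.position - window_bp, target.position + window_bp

    genes, probes = [], []
    for ann in annotations.values():
        if ann.chrom != target.chrom or not (lo <= ann.position <= hi):
            continue
        if ann.kind == "gene" and ann.id in expr.data.columns:
            genes.append(ann.id)
        elif ann.kind == "probe" and ann.id in meth.data.columns:
            probes.append(ann.id)
    if gene_id not in genes:
        genes.append(gene_id)
    if not probes:
        logger.warning("gene %s: no probes within +/-%d bp; skipped",
                       gene_id, window_bp)
        return None
    merged = expr.subset(sorted(genes)).merge(meth.subset(sorted(probes)))
    return merged.drop_incomplete()


def call_dres(
    gene_id: str,
    merged: OmicsMatrix,
    annotations: AnnotationMap,
    params: PcParams | None = None,
) -> list[DrePair]:
    """Infer the window network and emit probes directly linked to the gene."""
    params = params or PcParams()
    net = infer_network(merged.vectors(), params)
    gene_vals = merged.data[gene_id].to_numpy()
    pairs: list[DrePair] = []
    for nbr in sorted(net.graph[gene_id]) if gene_id in net.graph else []:
        if merged.kind_of(nbr) != "methylation":
            continue
        attrs = net.edge_attrs(gene_id, nbr)
        pcc = float(stats.pearsonr(merged.data[nbr].to_numpy(), gene_vals)[0])
        dist = signed_tss_distance(annotations[nbr], annotations[gene_id])
        pair = DrePair(
            probe_id=nbr,
            gene_id=gene_id,
            pcc=pcc,
            distance_bp=dist,
            mi_bits=attrs.get("mi_bits", math.nan),
            p_value=attrs.get("p_value", math.nan),
        )
        pairs.append(classify_dre(pair))
    return pairs


def classify_dre(
    pair: DrePair, deg_table: pd.DataFrame | None = None
) -> DrePair:
    """Fill locus class, correlation sign and target regulation direction.

    ``deg_table`` (optional) is a differential-expression table with
    columns (gene, log2fc, adj_p); the usual filter |log2FC| > 0.58 and
    adjusted p < 0.01 is applied before assigning up/down.
    """
    locus = "promoter" if abs(pair.distance_bp) <= PROMOTER_BP else "distal"
    if pair.pcc == 0.0:
        logger.info("probe %s: PCC exactly 0; sign tie broken to positive",
                    pair.probe_id)
        sign = "positive"
    else:
        sign = "negative" if pair.pcc < 0 else "positive"
    direction = "NA"
    if deg_table is not None:
        hit = deg_table.loc[deg_table["gene"] == pair.gene_id]
        if len(hit):
            row = hit.iloc[0]
            if abs(row["log2fc"]) > 0.58 and row["adj_p"] < 0.01:
                direction = "up" if row["log2fc"] > 0 else "down"
    return replace(
        pair, locus_class=locus, corr_sign=sign, target_direction=direction
    )


def classify_dynamics(
    probe_id: str,
    delta_initiation: float,
    delta_progression: float,
    tol: float = 0.05,
) -> DynamicsCall:
    """Categorize the two-stage methylation shift of a probe.

    delta_initiation = mean beta (tumor) - mean beta (normal);
    delta_progression = mean beta (late stage) - mean beta (early stage).
    Opposite signs with both shifts above ``tol`` -> "reversed"; same
    magnitude within ``tol`` -> "consistent"; otherwise "stronger" or
    "weaker" depending on whether the progression shift exceeds the
    initiation shift in absolute value.
    """
    di, dp = float(delta_initiation), float(delta_progression)
    if not (math.isfinite(di) and math.isfinite(dp)):
        raise ValidationError("dynamics deltas must be finite")
    if di * dp < 0 and abs(di) > tol and abs(dp) > tol:
        category = "reversed"
    elif abs(abs(dp) - abs(di)) <= tol:
        category = "consistent"
    elif abs(dp) > abs(di):
        category = "stronger"
    else:
        category = "weaker"
    return DynamicsCall(probe_id, di, dp, category)


def _in_anchor(chrom: str, pos_lo: int, pos_hi: int,
               a_chrom: str, a_start: int, a_end: int) -> bool:
    return chrom == a_chrom and pos_lo <= a_end and pos_hi >= a_start


def pair_precision(
    pairs: Sequence[DrePair],
    interactions: Sequence[AnchorPair],
    annotations: AnnotationMap,
    distance_bins: Sequence[int] = (25_000, 50_000, 100_000, 200_000, 300_000),
    promoter_halfwidth: int = PROMOTER_BP,
) -> pd.DataFrame:
    """Positive predictive value of negatively-correlated pairs.

    A pair is confirmed when its probe position falls inside one anchor
    of an interaction and the target TSS +/- promoter_halfwidth overlaps
    the mate anchor, in either orientation.  Returns a table with one
    row per |distance| bin plus an "overall" row (columns: bin_max_bp,
    n_pairs, n_confirmed, ppv).
    """
    neg = [p for p in pairs if p.corr_sign == "negative" or p.pcc < 0]
    if not interactions:
        logger.warning("empty interaction set: PPV is 0 by convention")
    confirmed_flags: list[bool] = []
    for p in neg:
        probe = annotations[p.probe_id]
        gene = annotations[p.gene_id]
        g_lo = gene.position - promoter_halfwidth
        g_hi = gene.position + promoter_halfwidth
        ok = False
        for ia in interactions:
            fwd = _in_anchor(probe.chrom, probe.position, probe.position,
                             ia.chrom1, ia.start1, ia.end1) and _in_anchor(
                gene.chrom, g_lo, g_hi, ia.chrom2, ia.start2, ia.end2)
            rev = _in_anchor(probe.chrom, probe.position, probe.position,
                             ia.chrom2, ia.start2, ia.end2) and _in_anchor(
                gene.chrom, g_lo, g_hi, ia.chrom1, ia.start1, ia.end1)
            if fwd or rev:
                ok = True
                break
        confirmed_flags.append(ok)

    rows = []
    edges = [0, *sorted(distance_bins)]
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = [
            (p, c)
            for p, c in zip(neg, confirmed_flags)
            if lo < abs(p.distance_bp) <= hi or (lo == 0 and abs(p.distance_bp) == 0)
        ]
        n = len(sel)
        k = sum(c for _, c in sel)
        rows.append({"bin_max_bp": hi, "n_pairs": n, "n_confirmed": k,
                     "ppv": (k / n) if n else math.nan})
    n_all = len(neg)
    k_all = sum(confirmed_flags)
    rows.append({"bin_max_bp": -1, "n_pairs": n_all, "n_confirmed": k_all,
                 "ppv": (k_all / n_all) if n_all else 0.0})
    return pd.DataFrame(rows)


def infer_dre_pairs(
    gene_ids: Iterable[str],
    annotations: AnnotationMap,
    expr: OmicsMatrix,
    meth: OmicsMatrix,
    params: PcParams | None = None,
    window_bp: int = 300_000,
    deg_table: pd.DataFrame | None = None,
) -> list[DrePair]:
    """Per-gene window inference over many targets.

    Pairs duplicated across overlapping windows are deduplicated by
    (probe, gene), keeping the smallest p-value.
    """
    params = params or PcParams()
    best: dict[tuple[str, str], DrePair] = {}
    for gene_id in gene_ids:
        merged = assemble_window(gene_id, annotations, expr, meth, window_bp)
        if merged is None:
            continue
        for pair in call_dres(gene_id, merged, annotations, params):
            pair = classify_dre(pair, deg_table)
            key = (pair.probe_id, pair.gene_id)
            if key not in best or pair.p_value < best[key].p_value:
                best[key] = pair
    return sorted(best.values(), key=lambda p: (p.gene_id, p.probe_id))


def pairs_to_frame(pairs: Sequence[DrePair]) -> pd.DataFrame:
    """DRE table with one row per pair (stable column order)."""
    return pd.DataFrame(
        [
            {
                "probe_id": p.probe_id,
                "gene_id": p.gene_id,
                "pcc": p.pcc,
                "distance_bp": p.distance_bp,
                "locus_class": p.locus_class,
                "corr_sign": p.corr_sign,
                "target_direction": p.target_direction,
                "mi_bits": p.mi_bits,
                "p_value": p.p_value,
            }
            for p in pairs
        ],
        columns=[
            "probe_id", "gene_id", "pcc", "distance_bp", "locus_class",
            "corr_sign", "target_direction", "mi_bits", "p_value",
        ],
    )


def two_group_t(expr: OmicsMatrix, labels: pd.Series) -> pd.DataFrame:
    """Plain Welch t-statistics between two sample groups (plumbing).

    Returns a (gene, t, p) table; not a moderated differential-expression
    fit — supply your own DEG table for classification when you have one.
    """
    groups = labels.dropna().unique()
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {list(groups)}")
    g1 = expr.data.loc[labels[labels == groups[0]].index]
    g2 = expr.data.loc[labels[labels == groups[1]].index]
    if len(g1) < 3 or len(g2) < 3:
        raise ValidationError("each group needs >= 3 samples")
    t, p = stats.ttest_ind(g2, g1, equal_var=False, axis=0)
    return pd.DataFrame({"gene": expr.variables, "t": t, "p": p})
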
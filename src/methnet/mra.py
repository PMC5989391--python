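"""Master regulator analysis (MRA).

A transcription factor's regulon — the genes whose expression depends on
it — is inferred from expression alone: candidate members are genes with
permutation-significant mutual information to the TF, the data processing
inequality (DPI) removes the weakest edge of every fully-significant
triangle (presumed indirect), and the surviving members are split into
positive and negative groups by the sign of their Spearman correlation
with the TF.

The TF is then scored against a ranked differential-expression signature
(per-gene Welch t values): run 1 tests regulon(+) for enrichment at the
upregulated end and regulon(-) at the downregulated end; run 2 swaps the
ends.  Within a run the two one-sided rank-sum p-values are combined by
Fisher's method (-2 * sum(ln p) against chi-square with 4 df).  Across
TFs, run p-values are adjusted by Benjamini-Hochberg, and a TF whose best
run passes the q threshold is called oncogenic (run 1 wins) or
tumor-suppressive (run 2 wins).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import OmicsMatrix
from .errors import ValidationError
from .infotheory import mutual_information, permutation_significance
from .pcnet import PcParams, edge_seed

logger = logging.getLogger(__name__)


@dataclass
class Regulon:
    """Signed target set of one TF."""

    tf_id: str
    positive_members: set[str] = field(default_factory=set)
    negative_members: set[str] = field(default_factory=set)
    member_mi: dict[str, float] = field(default_factory=dict)  # gene -> bits

    @property
    def members(self) -> set[str]:
        return self.positive_members | self.negative_members

    def __post_init__(self) -> None:
        if self.positive_members & self.negative_members:
            raise ValidationError("regulon sign groups must be disjoint")
        if self.tf_id in self.members:
            raise ValidationError("TF cannot be a member of its own regulon")


@dataclass(frozen=True)
class MraCall:
    """Outcome of the two-run enrichment for one TF."""

    tf_id: str
    q_run1: float
    q_run2: float
    direction: str  # oncogenic | tumor_suppressive | ns
    combined_stat: float  # Fisher statistic of the winning run
    p_run1: float = math.nan
    p_run2: float = math.nan


def infer_regulon(
    tf_id: str,
    expr: OmicsMatrix,
    mi_params: PcParams | None = None,
    dpi_tolerance: float = 0.1,
) -> Regulon:
    """Infer the signed regulon of one TF from the expression matrix."""
    mi_params = mi_params or PcParams()
    if tf_id not in expr.data.columns:
        raise KeyError(f"TF {tf_id!r} not in expression matrix")
    tf_vec = expr.vector(tf_id)
    tf_vals = tf_vec.values

    candidates: dict[str, float] = {}  # gene -> MI bits with the TF
    for gene in expr.variables:
        if gene == tf_id:
            continue
        sig = permutation_significance(
            tf_vec, expr.vector(gene),
            n_perm=mi_params.n_perm,
            seed=edge_seed(mi_params.seed, tf_id, gene),
        )
        if sig.p_value < mi_params.p_cutoff:
            candidates[gene] = mutual_information(tf_vec, expr.vector(gene)).raw_bits

    # DPI over triangles (tf, g1, g2) where all three edges are significant.
    pair_mi: dict[frozenset, float] = {}
    genes = sorted(candidates)
    for g1, g2 in combinations(genes, 2):
        sig = permutation_significance(
            expr.vector(g1), expr.vector(g2),
            n_perm=mi_params.n_perm,
            seed=edge_seed(mi_params.seed, g1, g2),
        )
        if sig.p_value < mi_params.p_cutoff:
            pair_mi[frozenset((g1, g2))] = mutual_information(
                expr.vector(g1), expr.vector(g2)
            ).raw_bits

    doomed: set[str] = set()  # tf-edges removed by DPI (deferred)
    for g1, g2 in combinations(genes, 2):
        key = frozenset((g1, g2))
        if key not in pair_mi:
            continue
        edges = {g1: candidates[g1], g2: candidates[g2], "_pair": pair_mi[key]}
        weakest = min(edges, key=edges.get)
        others = sorted(v for k, v in edges.items() if k != weakest)
        if edges[weakest] < (1.0 - dpi_tolerance) * others[0]:
            if weakest != "_pair":
                doomed.add(weakest)

    regulon = Regulon(tf_id=tf_id)
    for gene, bits in candidates.items():
        if gene in doomed:
            continue
        rho = stats.spearmanr(tf_vals, expr.data[gene].to_numpy()).statistic
        if rho == 0 or not np.isfinite(rho):
            logger.info("regulon %s: member %s has rho==0; assigned positive",
                        tf_id, gene)
            regulon.positive_members.add(gene)
        elif rho > 0:
            regulon.positive_members.add(gene)
        else:
            regulon.negative_members.add(gene)
        regulon.member_mi[gene] = bits
    return regulon


def rank_signature(expr: OmicsMatrix, group_labels: pd.Series) -> pd.DataFrame:
    """Per-gene Welch t (group 2 minus group 1), sorted descending by t."""
    labels = group_labels.reindex(expr.data.index).dropna()
    groups = sorted(pd.unique(labels))  # stable group order
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {list(groups)}")
    g1 = expr.data.loc[labels.index[labels == groups[0]]]
    g2 = expr.data.loc[labels.index[labels == groups[1]]]
    if len(g1) < 3 or len(g2) < 3:
        raise ValidationError("each group needs >= 3 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = stats.ttest_ind(g2, g1, equal_var=False, axis=0)
    if not np.all(np.isfinite(t)):
        raise ValidationError("degenerate group: non-finite t statistics")
    sig = pd.DataFrame({"gene": expr.variables, "t": t})
    return sig.sort_values("t", ascending=False, ignore_index=True)


def _side_p(member_t: np.ndarray, other_t: np.ndarray, alternative: str,
            method: str) -> float:
    """One-sided enrichment p of members vs non-members on the t scale."""
    if member_t.size == 0 or other_t.size == 0:
        return 1.0
    if method == "ranksum":
        return float(
            stats.mannwhitneyu(member_t, other_t, alternative=alternative).pvalue
        )
    if method == "ks":
        return float(
            stats.ks_2samp(member_t, other_t, alternative={
                "greater": "less", "less": "greater"}[alternative]).pvalue
        )
    raise ValidationError(f"unknown enrichment method {method!r}")


def _fisher_combine(p1: float, p2: float) -> tuple[float, float]:
    stat = -2.0 * (math.log(max(p1, 1e-300)) + math.log(max(p2, 1e-300)))
    return stat, float(stats.chi2.sf(stat, df=4))


def master_regulator_test(
    regulon: Regulon,
    signature: pd.DataFrame,
    method: str = "ranksum",
) -> dict:
    """Two-run enrichment of one regulon in a ranked signature.

    Returns per-run Fisher-combined p-values and statistics; q-values and
    the final direction call are assigned across TFs by :func:`run_mra`.
    """
    sig = signature.set_index("gene")["t"]
    pos = sorted(regulon.positive_members & set(sig.index))
    neg = sorted(regulon.negative_members & set(sig.index))
    members = set(pos) | set(neg)
    others = sig.drop(index=list(members))
    if not members:
        logger.warning("TF %s: empty regulon after intersection; ns",
                       regulon.tf_id)
        return {"tf_id": regulon.tf_id, "p_run1": 1.0, "p_run2": 1.0,
                "stat_run1": 0.0, "stat_run2": 0.0, "empty": True}
    pos_t, neg_t = sig[pos].to_numpy(), sig[neg].to_numpy()
    other_t = others.to_numpy()
    # run 1: regulon(+) at the upregulated end, regulon(-) downregulated
    p1a = _side_p(pos_t, other_t, "greater", method)
    p1b = _side_p(neg_t, other_t, "less", method)
    stat1, p_run1 = _fisher_combine(p1a, p1b)
    # run 2: the reverse
    p2a = _side_p(pos_t, other_t, "less", method)
    p2b = _side_p(neg_t, other_t, "greater", method)
    stat2, p_run2 = _fisher_combine(p2a, p2b)
    return {"tf_id": regulon.tf_id, "p_run1": p_run1, "p_run2": p_run2,
            "stat_run1": stat1, "stat_run2": stat2, "empty": False}


def run_mra(
    regulons: list[Regulon],
    signature: pd.DataFrame,
    q_threshold: float = 0.05,
    method: str = "ranksum",
) -> list[MraCall]:
    """Score every regulon, BH-adjust per run across TFs, call directions."""
    raw = [master_regulator_test(r, signature, method) for r in regulons]
    if not raw:
        return []
    q1 = multipletests([r["p_run1"] for r in raw], method="fdr_bh")[1]
    q2 = multipletests([r["p_run2"] for r in raw], method="fdr_bh")[1]
    calls = []
    for r, a, b in zip(raw, q1, q2):
        if r["empty"] or min(a, b) >= q_threshold or a == b:
            direction = "ns"
        elif a < b:
            direction = "oncogenic"
        else:
            direction = "tumor_suppressive"
        winning = r["stat_run1"] if a <= b else r["stat_run2"]
        calls.append(MraCall(
            tf_id=r["tf_id"], q_run1=float(a), q_run2=float(b),
            direction=direction, combined_stat=float(winning),
            p_run1=r["p_run1"], p_run2=r["p_run2"],
        ))
    return calls


def regulon_frame(regulons: list[Regulon]) -> pd.DataFrame:
    """Long-format regulon table: tf, member, sign, mi_bits."""
    rows = []
    for r in regulons:
        for m in sorted(r.positive_members):
            rows.append({"tf": r.tf_id, "member": m, "sign": "+",
                         "mi_bits": r.member_mi.get(m, math.nan)})
        for m in sorted(r.negative_members):
            rows.append({"tf": r.tf_id, "member": m, "sign": "-",
                         "mi_bits": r.member_mi.get(m, math.nan)})
    return pd.DataFrame(rows, columns=["tf", "member", "sign", "mi_bits"])


def mra_frame(calls: list[MraCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"tf": c.tf_id, "q_run1": c.q_run1, "q_run2": c.q_run2,
          "direction": c.direction, "combined_stat": c.combined_stat}
         for c in calls],
        columns=["tf", "q_run1", "q_run2", "direction", "combined_stat"],
    )
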
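"""Seeded generators for synthetic regulatory scenes and benchmarks.

``simulate_scene`` emulates the kind of data the pipeline consumes in
practice — a continuous expression matrix and a beta-valued methylation
matrix over one cohort, with genomic coordinates — from a latent linear
Gaussian system with known structure:

* each probe has a latent methylation signal m_i ~ N(0, 1);
* ``n_direct_edges`` probes are causal: the target gene's expression is
  effect_size * sum(sign_j * m_cj) plus N(0, noise_sd) noise;
* each confounder links one non-causal probe to the target only through
  a mediator: in single-gene scenes the probe is correlated with a causal
  probe (q = alpha * m_c + sqrt(1-alpha^2) * noise); in multi-gene scenes
  the probe's latent drives a mediator gene which in turn feeds the
  target, so the probe-target correlation is entirely indirect — the
  correlations the CMI pruning must reject;
* observed methylation is the logistic squash of the latent signal into
  (0, 1); extra genes in the window are independent noise;
* probes and genes are placed at seeded random coordinates within the
  window around the target TSS.

``fdr_experiment`` runs the full DRE-calling pipeline over many seeded
scenes and over sample-label-shuffled null copies, reporting true calls,
chance calls and the aggregated false discovery rate per p-value cutoff.

``simulate_tf_program`` plants TF -> target programs plus matching motif
hits and super-enhancers so regulon inference and CRC assembly can be
validated against known structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    EXPRESSION,
    METHYLATION,
    GenomicAnnotation,
    OmicsMatrix,
)
from .dre import DrePair, assemble_window, call_dres
from .enrichment import MotifHit
from .errors import ValidationError
from .circuits import SeRegion
from .pcnet import PcParams

logger = logging.getLogger(__name__)

#: Correlation between a confounded probe and its causal partner.
CONFOUNDER_ALPHA = 0.7


@dataclass(frozen=True)
class SceneConfig:
    """Size and strength of one simulated regulatory scene.

    Defaults mirror the desk-scale error-control benchmark: one target
    gene, 30 probes, 3 direct edges, 300 samples, effect size 0.8 of the
    noise scale (detection power about 0.9 at these sizes).
    """

    n_samples: int = 300
    n_genes: int = 1
    n_probes: int = 30
    n_direct_edges: int = 3
    n_confounders: int = 5
    effect_size: float = 0.8
    noise_sd: float = 1.0
    window_bp: int = 300_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_probes,
               self.n_direct_edges) < 1:
            raise ValidationError("all scene counts must be positive")
        if self.n_direct_edges > self.n_probes:
            raise ValidationError("n_direct_edges cannot exceed n_probes")
        if self.n_confounders > self.n_probes - self.n_direct_edges:
            raise ValidationError(
                "not enough non-causal probes for the requested confounders"
            )
        if self.n_genes > 1 and self.n_confounders > self.n_genes - 1:
            raise ValidationError(
                "gene-mediated confounding needs n_confounders <= n_genes - 1"
            )
        if self.noise_sd <= 0 or self.n_samples < 10:
            raise ValidationError("need noise_sd > 0 and n_samples >= 10")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a scene."""

    direct_edges: frozenset  # {(probe_id, gene_id)}
    indirect_correlations: frozenset  # {(probe_id, gene_id, mediator_id)}

    def __post_init__(self) -> None:
        direct = {(p, g) for p, g in self.direct_edges}
        indirect = {(p, g) for p, g, _ in self.indirect_correlations}
        if direct & indirect:
            raise ValidationError("direct and indirect edge sets must be disjoint")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_scene(
    config: SceneConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, dict[str, GenomicAnnotation], GroundTruth]:
    """Generate one scene: (expression, methylation, annotations, truth)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    probe_ids = [f"cg{i:05d}" for i in range(config.n_probes)]
    gene_ids = [f"G{i:03d}" for i in range(config.n_genes)]
    target = gene_ids[0]

    latent = rng.standard_normal((n, config.n_probes))
    causal = list(range(config.n_direct_edges))
    free = list(range(config.n_direct_edges, config.n_probes))

    indirect = set()
    alpha = CONFOUNDER_ALPHA
    gene_mediated = config.n_genes > 1
    if not gene_mediated:
        for j in range(config.n_confounders):
            q = free[j]
            c = causal[j % len(causal)]
            latent[:, q] = alpha * latent[:, c] + np.sqrt(1 - alpha**2) * (
                rng.standard_normal(n)
            )
            indirect.add((probe_ids[q], target, probe_ids[c]))

    signs = rng.choice([-1.0, 1.0], size=len(causal))
    expr = np.empty((n, config.n_genes))
    expr[:, 0] = (
        config.effect_size * (latent[:, causal] * signs).sum(axis=1)
        + config.noise_sd * rng.standard_normal(n)
    )
    for g in range(1, config.n_genes):
        expr[:, g] = rng.standard_normal(n)
    if gene_mediated:
        # probe q -> mediator gene -> target: q reaches the target only
        # through the mediator's expression
        scale = config.effect_size / np.sqrt(1.0 + config.noise_sd**2)
        for j in range(config.n_confounders):
            q = free[j]
            mg = 1 + j
            expr[:, mg] = latent[:, q] + config.noise_sd * rng.standard_normal(n)
            expr[:, 0] += scale * expr[:, mg]
            indirect.add((probe_ids[q], target, gene_ids[mg]))

    meth = _logistic(latent)

    tss = 1_000_000
    annotations: dict[str, GenomicAnnotation] = {
        target: GenomicAnnotation(target, "chr1", tss, "gene", "+")
    }
    gene_pos = rng.integers(
        tss - config.window_bp, tss + config.window_bp + 1, size=config.n_genes
    )
    for g in range(1, config.n_genes):
        annotations[gene_ids[g]] = GenomicAnnotation(
            gene_ids[g], "chr1", int(gene_pos[g]), "gene",
            "+" if rng.random() < 0.5 else "-",
        )
    probe_pos = rng.integers(
        tss - config.window_bp, tss + config.window_bp + 1, size=config.n_probes
    )
    for i, pid in enumerate(probe_ids):
        annotations[pid] = GenomicAnnotation(pid, "chr1", int(probe_pos[i]), "probe")

    expr_m = OmicsMatrix.from_frame(
        pd.DataFrame(expr, index=samples, columns=gene_ids), EXPRESSION
    )
    meth_m = OmicsMatrix.from_frame(
        pd.DataFrame(meth, index=samples, columns=probe_ids), METHYLATION
    )
    truth = GroundTruth(
        direct_edges=frozenset((probe_ids[c], target) for c in causal),
        indirect_correlations=frozenset(indirect),
    )
    return expr_m, meth_m, annotations, truth


def shuffle_null(
    expr: OmicsMatrix, meth: OmicsMatrix, seed: int
) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Null copy of a scene: methylation sample order permuted.

    Permuting the methylation matrix rows against the expression matrix
    destroys every probe-gene dependence while preserving the marginal
    distributions and probe-probe structure; calls on this null measure
    what the pipeline finds by chance.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(meth.n_samples)
    shuffled = pd.DataFrame(
        meth.data.to_numpy()[perm], index=meth.data.index,
        columns=meth.data.columns,
    )
    return expr, OmicsMatrix(shuffled, meth.kinds.copy())


def _scene_calls(
    config: SceneConfig,
    params: PcParams,
    null_seed: int | None,
) -> list[DrePair]:
    expr, meth, annotations, _ = simulate_scene(config)
    if null_seed is not None:
        expr, meth = shuffle_null(expr, meth, null_seed)
    target = expr.variables[0]
    merged = assemble_window(
        target, annotations, expr, meth, config.window_bp
    )
    if merged is None:
        return []
    return call_dres(target, merged, annotations, params)


def fdr_experiment(
    config: SceneConfig | None = None,
    p_cutoffs: tuple[float, ...] = (0.01,),
    n_reps: int = 20,
    seed: int = 0,
    mi_floor_bits: float = 0.1,
    n_perm: int = 100,
) -> pd.DataFrame:
    """Aggregated FDR of DRE calls over seeded scenes, per p-value cutoff.

    For each replicate a fresh scene is simulated and the full calling
    pipeline is run on it (true_calls = calls matching planted direct
    edges; false_calls = the rest) and on its label-shuffled null
    (chance_calls).  fdr = false / (false + true), aggregated over
    replicates.  Deterministic for fixed seed.
    """
    if n_reps < 3:
        raise ValidationError("n_reps must be >= 3")
    config = config or SceneConfig()
    base = np.random.default_rng(seed)
    scene_seeds = base.integers(0, 2**31 - 1, size=n_reps)
    null_seeds = base.integers(0, 2**31 - 1, size=n_reps)
    perm_seeds = base.integers(0, 2**31 - 1, size=n_reps)

    rows = []
    for cutoff in p_cutoffs:
        true_calls = false_calls = chance_calls = 0
        for rep in range(n_reps):
            cfg = SceneConfig(**{**config.__dict__, "seed": int(scene_seeds[rep])})
            params = PcParams(
                p_cutoff=cutoff, mi_floor_bits=mi_floor_bits,
                n_perm=n_perm, seed=int(perm_seeds[rep]),
            )
            _, _, _, truth = simulate_scene(cfg)
            for pair in _scene_calls(cfg, params, None):
                if (pair.probe_id, pair.gene_id) in truth.direct_edges:
                    true_calls += 1
                else:
                    false_calls += 1
            chance_calls += len(_scene_calls(cfg, params, int(null_seeds[rep])))
        total = true_calls + false_calls
        rows.append({
            "cutoff": cutoff,
            "true_calls": true_calls,
            "false_calls": false_calls,
            "chance_calls": chance_calls,
            "fdr": (false_calls / total) if total else 0.0,
        })
    return pd.DataFrame(rows)


@dataclass
class TfProgram:
    """Planted TF program: data plus every fixture CRC assembly needs."""

    expr: OmicsMatrix
    meth: OmicsMatrix
    tf_list: list[str]
    regulons: dict[str, dict[str, set[str]]]  # tf -> {"+": set, "-": set}
    dre_pairs: list[DrePair]
    annotations: dict[str, GenomicAnnotation]
    motif_hits: list[MotifHit]
    se_regions: list[SeRegion]
    crc_edges: set[tuple[str, str]]  # planted regulator -> target


def simulate_tf_program(
    n_tfs: int = 3,
    targets_per_tf: int = 10,
    n_noise_genes: int = 20,
    n_samples: int = 300,
    seed: int = 0,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    cross_regulation: bool = True,
) -> TfProgram:
    """Plant TF->target programs with matching motif/SE genomic fixtures.

    Each TF drives ``targets_per_tf`` genes linearly with mixed signs.
    Each TF also gets one distal DRE probe (50 kb upstream of its TSS)
    overlapping a super-enhancer; the probe carries the TF's own motif
    (auto-loop) and, with ``cross_regulation``, the motif of the next TF
    in a ring (cross edges), so CRC assembly can recover the planted
    loops exactly.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    tf_ids = [f"TF{i}" for i in range(n_tfs)]
    regulons: dict[str, dict[str, set[str]]] = {}
    cols, names = [], []

    tf_expr = rng.standard_normal((n_samples, n_tfs))
    for t, tf in enumerate(tf_ids):
        cols.append(tf_expr[:, t])
        names.append(tf)
    for t, tf in enumerate(tf_ids):
        pos, neg = set(), set()
        for j in range(targets_per_tf):
            gene = f"{tf}_T{j}"
            sign = 1.0 if j % 2 == 0 else -1.0
            vals = sign * effect_size * tf_expr[:, t] + noise_sd * (
                rng.standard_normal(n_samples)
            )
            (pos if sign > 0 else neg).add(gene)
            cols.append(vals)
            names.append(gene)
        regulons[tf] = {"+": pos, "-": neg}
    for j in range(n_noise_genes):
        cols.append(rng.standard_normal(n_samples))
        names.append(f"N{j:03d}")

    expr = OmicsMatrix.from_frame(
        pd.DataFrame(np.column_stack(cols), index=samples, columns=names),
        EXPRESSION,
    )

    # Genomic layer: one distal, SE-overlapping DRE per TF.
    annotations: dict[str, GenomicAnnotation] = {}
    dre_pairs: list[DrePair] = []
    motif_hits: list[MotifHit] = []
    se_regions: list[SeRegion] = []
    crc_edges: set[tuple[str, str]] = set()
    probe_meth = {}
    for t, tf in enumerate(tf_ids):
        tss = 1_000_000 + t * 1_000_000
        probe_pos = tss - 50_000
        probe_id = f"cgTF{t}"
        annotations[tf] = GenomicAnnotation(tf, "chr1", tss, "gene", "+")
        annotations[probe_id] = GenomicAnnotation(probe_id, "chr1", probe_pos, "probe")
        latent = -tf_expr[:, t] + 0.3 * rng.standard_normal(n_samples)
        probe_meth[probe_id] = _logistic(latent)
        dre_pairs.append(DrePair(
            probe_id=probe_id, gene_id=tf, pcc=-0.9,
            distance_bp=probe_pos - tss, locus_class="distal",
            corr_sign="negative",
        ))
        se_regions.append(SeRegion(f"SE{t}", "chr1", probe_pos - 5_000,
                                   probe_pos + 5_000))
        motif_hits.append(MotifHit(tf, "chr1", probe_pos - 10, probe_pos + 10))
        crc_edges.add((tf, tf))
        if cross_regulation and n_tfs > 1:
            regulator = tf_ids[(t + 1) % n_tfs]
            motif_hits.append(
                MotifHit(regulator, "chr1", probe_pos - 10, probe_pos + 10)
            )
            crc_edges.add((regulator, tf))

    meth = OmicsMatrix.from_frame(
        pd.DataFrame(probe_meth, index=samples), METHYLATION
    )
    return TfProgram(
        expr=expr, meth=meth, tf_list=tf_ids, regulons=regulons,
        dre_pairs=dre_pairs, annotations=annotations,
        motif_hits=motif_hits, se_regions=se_regions, crc_edges=crc_edges,
    )
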
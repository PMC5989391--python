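"""Window assembly, DRE calling, classification and precision evaluation."""

import numpy as np
import pandas as pd
import pytest

from methnet.containers import (
    EXPRESSION,
    METHYLATION,
    GenomicAnnotation,
    OmicsMatrix,
)
from methnet.dre import (
    AnchorPair,
    DrePair,
    assemble_window,
    call_dres,
    classify_dre,
    classify_dynamics,
    infer_dre_pairs,
    pair_precision,
    signed_tss_distance,
    two_group_t,
)
from methnet.pcnet import PcParams
from methnet.synthetic import SceneConfig, simulate_scene


def _toy_inputs(probe_positions, gene_positions=None, n=50, seed=0):
    rng = np.random.default_rng(seed)
    gene_positions = gene_positions or {"G1": 1_000_000}
    samples = [f"s{i}" for i in range(n)]
    ann = {}
    expr = {}
    for g, pos in gene_positions.items():
        ann[g] = GenomicAnnotation(g, "chr1", pos, "gene", "+")
        expr[g] = rng.standard_normal(n)
    meth = {}
    for p, pos in probe_positions.items():
        ann[p] = GenomicAnnotation(p, "chr1", pos, "probe")
        meth[p] = rng.uniform(0.1, 0.9, n)
    expr_m = OmicsMatrix.from_frame(pd.DataFrame(expr, index=samples), EXPRESSION)
    meth_m = OmicsMatrix.from_frame(pd.DataFrame(meth, index=samples), METHYLATION)
    return ann, expr_m, meth_m


class TestAssembleWindow:
    def test_window_is_closed_at_boundary(self):
        ann, expr, meth = _toy_inputs({
            "in_near": 1_250_000,
            "at_edge": 1_300_000,
            "outside": 1_350_000,
        })
        merged = assemble_window("G1", ann, expr, meth, window_bp=300_000)
        assert set(merged.variables) == {"G1", "in_near", "at_edge"}

    def test_merged_column_count(self):
        ann, expr, meth = _toy_inputs(
            {"p1": 900_000, "p2": 1_100_000},
            {"G1": 1_000_000, "G2": 1_200_000, "Gfar": 2_000_000},
        )
        merged = assemble_window("G1", ann, expr, meth)
        assert len(merged.variables) == 2 + 2  # target + G2 + both probes

    def test_absent_gene_errors(self):
        ann, expr, meth = _toy_inputs({"p1": 1_000_500})
        with pytest.raises(KeyError):
            assemble_window("NOPE", ann, expr, meth)

    def test_no_probes_in_window_skips(self):
        ann, expr, meth = _toy_inputs({"far": 5_000_000})
        assert assemble_window("G1", ann, expr, meth) is None


class TestCallDres:
    def test_causal_found_confounded_rejected(self):
        exact = 0
        no_false = 0
        n_seeds = 5
        for seed in range(n_seeds):
            cfg = SceneConfig(
                n_genes=3, n_probes=10, n_direct_edges=2, n_confounders=2,
                effect_size=1.2, seed=seed,
            )
            expr, meth, ann, truth = simulate_scene(cfg)
            merged = assemble_window("G000", ann, expr, meth)
            calls = call_dres("G000", merged, ann, PcParams(seed=seed))
            got = {(p.probe_id, p.gene_id) for p in calls}
            indirect = {(p, g) for p, g, _ in truth.indirect_correlations}
            no_false += not (got & indirect)
            exact += got == set(truth.direct_edges)
        assert no_false == n_seeds
        assert exact >= n_seeds - 1

    def test_distal_probe_at_240kb_called_distal(self):
        rng = np.random.default_rng(0)
        n = 300
        latent = rng.standard_normal(n)
        ann, expr, meth = _toy_inputs({"cg_far": 1_240_000}, n=n, seed=1)
        meth.data["cg_far"] = 1.0 / (1.0 + np.exp(-latent))
        expr.data["G1"] = -1.0 * latent + 0.5 * rng.standard_normal(n)
        merged = assemble_window("G1", ann, expr, meth)
        calls = call_dres("G1", merged, ann, PcParams(seed=0))
        assert len(calls) == 1
        assert calls[0].locus_class == "distal"
        assert calls[0].distance_bp == 240_000
        assert calls[0].corr_sign == "negative"

    def test_no_signal_returns_empty(self):
        ann, expr, meth = _toy_inputs({"p1": 1_001_000, "p2": 999_000}, n=200)
        merged = assemble_window("G1", ann, expr, meth)
        assert call_dres("G1", merged, ann, PcParams(seed=3)) == []


class TestClassification:
    def test_promoter_boundary_closed(self):
        near = classify_dre(DrePair("p", "g", -0.4, 1500))
        edge = classify_dre(DrePair("p", "g", -0.4, -2000))
        far = classify_dre(DrePair("p", "g", -0.4, 22_595))
        assert near.locus_class == "promoter"
        assert edge.locus_class == "promoter"
        assert far.locus_class == "distal"
        assert far.corr_sign == "negative"

    def test_zero_pcc_tie_positive(self):
        assert classify_dre(DrePair("p", "g", 0.0, 10)).corr_sign == "positive"

    def test_direction_from_deg_table(self):
        deg = pd.DataFrame({
            "gene": ["g", "h", "k"],
            "log2fc": [1.2, -0.9, 0.2],
            "adj_p": [1e-5, 1e-4, 1e-9],
        })
        up = classify_dre(DrePair("p", "g", -0.5, 10), deg)
        down = classify_dre(DrePair("p", "h", -0.5, 10), deg)
        weak = classify_dre(DrePair("p", "k", -0.5, 10), deg)
        missing = classify_dre(DrePair("p", "zzz", -0.5, 10), deg)
        assert up.target_direction == "up"
        assert down.target_direction == "down"
        assert weak.target_direction == "NA"  # below the fold-change filter
        assert missing.target_direction == "NA"

    def test_signed_distance_respects_strand(self):
        probe = GenomicAnnotation("p", "chr1", 1_010_000, "probe")
        plus = GenomicAnnotation("g", "chr1", 1_000_000, "gene", "+")
        minus = GenomicAnnotation("g", "chr1", 1_000_000, "gene", "-")
        assert signed_tss_distance(probe, plus) == 10_000
        assert signed_tss_distance(probe, minus) == -10_000


class TestDynamics:
    @pytest.mark.parametrize("di,dp,expected", [
        (-0.2, 0.15, "reversed"),
        (0.2, 0.2, "consistent"),
        (0.1, 0.3, "stronger"),
        (0.3, 0.1, "weaker"),
        (0.2, 0.24, "consistent"),
        (-0.3, -0.1, "weaker"),
    ])
    def test_categories(self, di, dp, expected):
        assert classify_dynamics("cg1", di, dp, tol=0.05).category == expected

    def test_nonfinite_errors(self):
        with pytest.raises(Exception):
            classify_dynamics("cg1", float("nan"), 0.1)


class TestPairPrecision:
    def _ann(self):
        return {
            "cg1": GenomicAnnotation("cg1", "chr1", 10_000, "probe"),
            "cg2": GenomicAnnotation("cg2", "chr1", 50_000, "probe"),
            "cg3": GenomicAnnotation("cg3", "chr1", 90_000, "probe"),
            "cg4": GenomicAnnotation("cg4", "chr1", 130_000, "probe"),
            "G": GenomicAnnotation("G", "chr1", 200_000, "gene", "+"),
        }

    def _pairs(self, ann):
        return [
            classify_dre(DrePair(p, "G", -0.5, ann[p].position - 200_000))
            for p in ("cg1", "cg2", "cg3", "cg4")
        ]

    def test_half_confirmed(self):
        ann = self._ann()
        inter = [
            AnchorPair("chr1", 9_000, 11_000, "chr1", 199_000, 201_000),
            AnchorPair("chr1", 49_000, 51_000, "chr1", 199_000, 201_000),
        ]
        table = pair_precision(self._pairs(ann), inter, ann)
        overall = table[table.bin_max_bp == -1].iloc[0]
        assert overall.n_pairs == 4
        assert overall.ppv == 0.5

    def test_orientation_symmetric(self):
        ann = self._ann()
        flipped = [AnchorPair("chr1", 199_000, 201_000, "chr1", 9_000, 11_000)]
        table = pair_precision(self._pairs(ann)[:1], flipped, ann)
        assert table[table.bin_max_bp == -1].iloc[0].ppv == 1.0

    def test_empty_interactions_zero(self):
        ann = self._ann()
        table = pair_precision(self._pairs(ann), [], ann)
        assert table[table.bin_max_bp == -1].iloc[0].ppv == 0.0

    def test_all_confirmed(self):
        ann = self._ann()
        inter = [
            AnchorPair("chr1", 1, 150_000, "chr1", 195_000, 205_000),
        ]
        table = pair_precision(self._pairs(ann), inter, ann)
        assert table[table.bin_max_bp == -1].iloc[0].ppv == 1.0

    def test_positive_pairs_excluded(self):
        ann = self._ann()
        pos = [classify_dre(DrePair("cg1", "G", 0.5, -190_000))]
        table = pair_precision(pos, [], ann)
        assert table[table.bin_max_bp == -1].iloc[0].n_pairs == 0


class TestPipeline:
    def test_dedup_keeps_best_p(self):
        cfg = SceneConfig(n_probes=8, n_direct_edges=2, n_samples=200,
                          n_confounders=1, seed=4)
        expr, meth, ann, truth = simulate_scene(cfg)
        pairs = infer_dre_pairs(["G000"], ann, expr, meth, PcParams(seed=4))
        keys = [(p.probe_id, p.gene_id) for p in pairs]
        assert len(keys) == len(set(keys))

    def test_distances_recomputable(self):
        cfg = SceneConfig(n_probes=6, n_direct_edges=2, n_samples=200,
                          n_confounders=0, seed=5)
        expr, meth, ann, truth = simulate_scene(cfg)
        pairs = infer_dre_pairs(["G000"], ann, expr, meth, PcParams(seed=5))
        for p in pairs:
            assert p.distance_bp == signed_tss_distance(
                ann[p.probe_id], ann[p.gene_id]
            )


class TestTwoGroupT:
    def test_shifted_gene_detected(self):
        rng = np.random.default_rng(0)
        n = 40
        frame = pd.DataFrame(
            {"g1": rng.standard_normal(n), "g2": rng.standard_normal(n)},
            index=[f"s{i}" for i in range(n)],
        )
        frame.loc[frame.index[20:], "g1"] += 2.0
        expr = OmicsMatrix.from_frame(frame, EXPRESSION)
        labels = pd.Series(["a"] * 20 + ["b"] * 20, index=frame.index)
        table = two_group_t(expr, labels)
        t1 = table.set_index("gene").loc["g1", "t"]
        t2 = table.set_index("gene").loc["g2", "t"]
        assert t1 > 4
        assert abs(t2) < 3
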
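"""Candidate classification, ranking and cross-species intersection logic."""

import numpy as np
import pandas as pd
import pytest

from ahgscreen import (
    AffinityProfile,
    PPINetwork,
    ScreenParams,
    aggregate_scores,
    classify_candidates,
    cross_species_overlap,
    filter_secretory,
    rank_top_k,
    read_deg_table,
    run_screen,
    score_contexts,
    secretory_fraction,
    write_screen_result,
)

from conftest import dense_rwr_oracle


def profile(species, direction, scores, tissue="T1", cell="C1"):
    return AffinityProfile(
        scores=pd.Series(scores),
        n_iter=1,
        converged=True,
        species=species,
        tissue=tissue,
        cell_type=cell,
        direction=direction,
    )


def scores_frame(rows):
    return pd.DataFrame(rows, columns=["species", "direction", "gene", "score"])


class TestReadDegTable:
    def test_reads_and_normalizes(self, tmp_path):
        p = tmp_path / "degs.tsv"
        p.write_text(
            "species\ttissue\tcell_type\tgene\tdirection\n"
            "human\tliver\thep\ts100a8\tup\n"
            "human\tliver\thep\ts100a8\tup\n"
            "human\tliver\thep\tapoe\tdown\n"
        )
        table = read_deg_table(p)
        assert len(table) == 2  # duplicate collapsed
        assert set(table["gene"]) == {"S100A8", "APOE"}

    def test_bad_direction_rejected(self, tmp_path):
        p = tmp_path / "degs.tsv"
        p.write_text(
            "species\ttissue\tcell_type\tgene\tdirection\nh\tt\tc\tg1\tsideways\n"
        )
        with pytest.raises(ValueError, match="direction"):
            read_deg_table(p)


class TestAggregate:
    def test_single_context_is_identity(self):
        agg = aggregate_scores([profile("H", "up", {"A": 0.2, "B": 0.8})])
        assert agg.loc[agg["gene"] == "A", "score"].item() == 0.2

    def test_mean_of_two_contexts(self):
        agg = aggregate_scores(
            [
                profile("H", "up", {"G": 0.2}, cell="C1"),
                profile("H", "up", {"G": 0.4}, cell="C2"),
            ]
        )
        assert agg["score"].item() == pytest.approx(0.3)

    def test_max_matches_direct_enumeration(self):
        rng = np.random.default_rng(42)
        genes = [f"G{i}" for i in range(8)]
        profs = [
            profile("H", "up", dict(zip(genes, rng.random(8))), cell=f"C{j}")
            for j in range(3)
        ]
        agg = aggregate_scores(profs, "max").set_index("gene")["score"]
        for g in genes:
            expected = max(p.scores[g] for p in profs)
            assert agg[g] == pytest.approx(expected)

    def test_missing_genes_not_zero_padded(self):
        # gene B appears in one of two contexts; its mean is over that one
        agg = aggregate_scores(
            [
                profile("H", "up", {"A": 0.5, "B": 0.5}, cell="C1"),
                profile("H", "up", {"A": 0.9}, cell="C2"),
            ]
        ).set_index("gene")["score"]
        assert agg["B"] == pytest.approx(0.5)
        assert agg["A"] == pytest.approx(0.7)

    def test_empty_collection_is_an_error(self):
        with pytest.raises(ValueError):
            aggregate_scores([])


class TestClassify:
    def test_up_specific(self):
        scores = scores_frame(
            [("H", "up", "G1", 2e-4), ("H", "down", "G1", 1e-5)]
        )
        result = classify_candidates(scores, 1e-4)
        assert result.category["G1"] == "up_specific"

    def test_threshold_is_inclusive_boundary_gives_shared(self):
        scores = scores_frame(
            [("H", "up", "G1", 1e-4), ("H", "down", "G1", 1e-4)]
        )
        assert classify_candidates(scores, 1e-4).category["G1"] == "shared"

    def test_any_species_union_semantics(self):
        scores = scores_frame(
            [
                ("H", "up", "G1", 2e-4),
                ("M", "up", "G1", 1e-6),
                ("M", "down", "G1", 5e-4),
                ("H", "down", "G1", 1e-6),
            ]
        )
        assert classify_candidates(scores, 1e-4).category["G1"] == "shared"

    def test_none_category_for_subthreshold_genes(self):
        scores = scores_frame([("H", "up", "G1", 1e-6)])
        result = classify_candidates(scores, 1e-4)
        assert result.category["G1"] == "none"
        assert result.candidates == ()

    def test_partition_identity(self):
        rng = np.random.default_rng(0)
        rows = [
            (sp, d, f"G{i}", float(rng.uniform(0, 3e-4)))
            for sp in ("H", "M")
            for d in ("up", "down")
            for i in range(50)
        ]
        result = classify_candidates(scores_frame(rows), 1e-4)
        counts = result.category_counts()
        assert (
            counts["up_specific"] + counts["down_specific"] + counts["shared"]
            == len(result.candidates)
        )


class TestSecretomeAndRanking:
    def _result(self):
        scores = scores_frame(
            [
                ("H", "up", "A", 3e-4),
                ("H", "up", "B", 2e-4),
                ("H", "up", "C", 1.5e-4),
                ("H", "down", "X", 2e-4),
            ]
        )
        return classify_candidates(scores, 1e-4)

    def test_only_secreted_candidates_rankable(self):
        result = filter_secretory(self._result(), {"B"})
        ranked = rank_top_k(result, 50)
        assert ranked.ranks["H"] == ("B",)

    def test_disjoint_secretome_logged_not_fatal(self, caplog):
        result = filter_secretory(self._result(), {"ZZZ"})
        assert rank_top_k(result, 5).ranks["H"] == ()
        assert "disjoint" in caplog.text

    def test_empty_secretome_is_an_error(self):
        with pytest.raises(ValueError):
            filter_secretory(self._result(), set())

    def test_k_exceeding_pool_keeps_everything(self):
        result = rank_top_k(filter_secretory(self._result(), {"A", "B", "C"}), 50)
        assert result.ranks["H"] == ("A", "B", "C")

    def test_score_ties_break_by_symbol(self):
        scores = scores_frame([("H", "up", "X", 2e-4), ("H", "up", "A", 2e-4)])
        result = rank_top_k(
            filter_secretory(classify_candidates(scores, 1e-4), {"A", "X"}), 2
        )
        assert result.ranks["H"] == ("A", "X")

    def test_ordering_matches_independent_sort(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(20)]
        vals = {g: float(rng.uniform(1e-4, 1e-2)) for g in genes}
        scores = scores_frame([("H", "up", g, v) for g, v in vals.items()])
        result = rank_top_k(
            filter_secretory(classify_candidates(scores, 1e-4), set(genes)), 10
        )
        expected = tuple(sorted(genes, key=lambda g: (-vals[g], g))[:10])
        assert result.ranks["H"] == expected

    def test_ranking_requires_per_species_candidacy(self):
        # B passes only in M; it must not appear in H's ranking
        scores = scores_frame(
            [
                ("H", "up", "A", 3e-4),
                ("H", "up", "B", 1e-6),
                ("M", "up", "B", 3e-4),
                ("M", "up", "A", 3e-4),
            ]
        )
        result = rank_top_k(
            filter_secretory(classify_candidates(scores, 1e-4), {"A", "B"}), 5
        )
        assert result.ranks["H"] == ("A",)
        assert result.ranks["M"] == ("A", "B")


class TestOverlap:
    def _ranked(self, lists):
        rows = []
        for sp, genes in lists.items():
            for i, g in enumerate(genes):
                rows.append((sp, "up", g, 1e-3 / (i + 1)))
        result = classify_candidates(scores_frame(rows), 1e-4)
        result = filter_secretory(result, {g for gs in lists.values() for g in gs})
        return rank_top_k(result, 50)

    def test_identical_lists_intersect_to_themselves(self):
        result = cross_species_overlap(
            self._ranked({"H": ["A", "B"], "M": ["A", "B"]})
        )
        assert result.ahgs == ("A", "B")

    def test_disjoint_lists_give_empty_set(self):
        result = cross_species_overlap(self._ranked({"H": ["A"], "M": ["B"]}))
        assert result.ahgs == ()

    def test_single_species_is_an_error(self):
        with pytest.raises(ValueError, match="2 species"):
            cross_species_overlap(self._ranked({"H": ["A"]}))

    def test_average_score_is_mean_of_best_direction_scores(self):
        rows = [
            ("H", "up", "A", 4e-4),
            ("H", "down", "A", 1e-4),
            ("M", "up", "A", 2e-4),
        ]
        result = classify_candidates(scores_frame(rows), 1e-4)
        result = rank_top_k(filter_secretory(result, {"A"}), 5)
        result = cross_species_overlap(result)
        assert result.ahg_avg_score["A"] == pytest.approx((4e-4 + 2e-4) / 2)


class TestSecretoryFraction:
    def test_fraction_of_candidates(self):
        rows = [("H", "up", f"G{i}", 2e-4) for i in range(10)]
        result = filter_secretory(classify_candidates(scores_frame(rows), 1e-4), {"G0"})
        assert secretory_fraction(result)["H"] == pytest.approx(0.1)

    def test_zero_secreted_gives_zero(self):
        rows = [("H", "up", f"G{i}", 2e-4) for i in range(4)]
        result = filter_secretory(classify_candidates(scores_frame(rows), 1e-4), {"Q"})
        assert secretory_fraction(result)["H"] == 0.0

    def test_no_candidates_reported_missing(self):
        rows = [("H", "up", "G0", 1e-9)]
        result = filter_secretory(classify_candidates(scores_frame(rows), 1e-4), {"G0"})
        assert np.isnan(secretory_fraction(result)["H"])


class TestBruteForceEquivalence:
    """Pipeline classification vs exhaustive closed-form enumeration.

    Twelve-node network, two species sharing it, two contexts each; the
    oracle recomputes every context's steady state with a dense solve and
    applies the category rules by plain set logic.
    """

    NET = [
        ("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"), ("D", "E"),
        ("E", "F"), ("F", "G"), ("G", "H"), ("H", "E"), ("H", "I"),
        ("I", "J"), ("J", "K"), ("K", "L"), ("L", "I"), ("C", "H"),
    ]
    CONTEXTS = {
        ("S1", "T1"): {"up": ["A", "B"], "down": ["K"]},
        ("S1", "T2"): {"up": ["C"], "down": ["L", "J"]},
        ("S2", "T1"): {"up": ["E"], "down": ["I"]},
        ("S2", "T2"): {"up": ["F", "G"], "down": ["I", "K"]},
    }
    THRESHOLD = 1e-2

    def test_categories_match_exhaustive_enumeration(self):
        net = PPINetwork.from_edges(self.NET)
        rows = [
            (sp, t, "C1", g, d)
            for (sp, t), dirs in self.CONTEXTS.items()
            for d, gs in dirs.items()
            for g in gs
        ]
        table = pd.DataFrame(
            rows, columns=["species", "tissue", "cell_type", "gene", "direction"]
        )
        profiles = score_contexts(net, table)
        result = classify_candidates(aggregate_scores(profiles, "mean"), self.THRESHOLD)

        # independent oracle: dense solves, brute-force aggregation and rules
        oracle_scores: dict[tuple, dict[str, list[float]]] = {}
        for (sp, t), dirs in self.CONTEXTS.items():
            for d, gs in dirs.items():
                per_gene = dense_rwr_oracle(net, gs, r=0.7)
                bucket = oracle_scores.setdefault((sp, d), {})
                for g, v in per_gene.items():
                    bucket.setdefault(g, []).append(v)
        passes = {"up": set(), "down": set()}
        for (sp, d), bucket in oracle_scores.items():
            for g, vals in bucket.items():
                if sum(vals) / len(vals) >= self.THRESHOLD:
                    passes[d].add(g)
        for gene in net.nodes:
            u, d = gene in passes["up"], gene in passes["down"]
            expected = "shared" if (u and d) else "up_specific" if u else (
                "down_specific" if d else "none"
            )
            assert result.category[gene] == expected, gene


class TestDeterminism:
    def test_export_is_byte_identical_under_input_permutation(self, tmp_path):
        rng = np.random.default_rng(3)
        rows = [
            (sp, d, f"G{i}", float(rng.uniform(0, 3e-4)))
            for sp in ("H", "M")
            for d in ("up", "down")
            for i in range(30)
        ]
        secretome = {f"G{i}" for i in range(0, 30, 3)}

        def export(row_order):
            frame = scores_frame([rows[i] for i in row_order])
            result = classify_candidates(frame, 1e-4)
            result = rank_top_k(filter_secretory(result, secretome), 5)
            result = cross_species_overlap(result)
            out = tmp_path / f"r{hash(tuple(row_order)) % 10**6}.tsv"
            write_screen_result(result, out)
            return out.read_bytes()

        order = list(range(len(rows)))
        shuffled = list(rng.permutation(len(rows)))
        assert export(order) == export(shuffled)
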
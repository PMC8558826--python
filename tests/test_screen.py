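"""Core screen logic checked against independent brute-force oracles."""

import numpy as np
import pytest

from lratlas import (
    CurationList,
    LigandRef,
    LRPair,
    ScreenConfig,
    assign_quadrant,
    build_pair_table,
    build_report,
    count_quadrants,
    find_orphans,
    identify_ligand_genes,
    identify_receptors,
    rank_top,
)
from lratlas.lr_database import CATEGORIES
from conftest import make_pair, make_summary

PROTEIN_CATS = sorted(CATEGORIES - {"small_molecule"})


def random_instance(rng, config):
    """A small random DB + tissue summaries with TPM straddling the cutoffs."""
    receptors = [f"R{i}" for i in range(rng.integers(1, 7))]
    ligand_pool = [f"L{i}" for i in range(rng.integers(1, 8))]
    db, seen = [], set()
    for r in receptors:
        k = rng.integers(0, min(4, len(ligand_pool) + 1))
        for l in rng.choice(ligand_pool, size=k, replace=False):
            if (r, l) in seen:
                continue
            seen.add((r, l))
            if rng.random() < 0.15:
                pair = make_pair(r, l, categories=("small_molecule",),
                                 kind="synthesis_enzyme_proxy", molecule="x")
            else:
                k = 1 + (rng.random() < 0.2)
                cats = rng.choice(PROTEIN_CATS, size=k, replace=False)
                pair = make_pair(r, l, categories=tuple(cats))
            db.append(pair)

    def tpm():
        return float(10 ** rng.uniform(-1, 2.2))

    receiver = [make_summary(g, tpm(), config) for g in receptors + ligand_pool]
    # drop some ligands from the sender table to exercise the missing path
    sender_genes = [g for g in ligand_pool if rng.random() > 0.2]
    sender = [make_summary(g, tpm(), config) for g in sender_genes]
    curation = CurationList(
        include={r for r in receptors if rng.random() < 0.1} | ({"ORPHX"} if rng.random() < 0.3 else set()),
    )
    if "ORPHX" in curation.include:
        receiver.append(make_summary("ORPHX", tpm(), config))
    return db, receiver, sender, curation


def oracle_pair_table(records, sender, db, config):
    """Naive double loop over (receptor record, db row, category)."""
    sender_tpm = {s.gene_id: s.mean_tpm for s in sender}
    rows = []
    for rec in records:
        for pair in db:
            if pair.receptor_gene != rec.gene_id:
                continue
            ltpm = sender_tpm.get(pair.ligand.gene_id, 0.0)
            r_high = rec.mean_tpm > config.high_cutoff
            l_high = ltpm > config.high_cutoff
            quadrant = f"{'high' if r_high else 'low'}_{'high' if l_high else 'low'}"
            for cat in pair.categories:
                rows.append(
                    (
                        cat,
                        rec.gene_id,
                        pair.ligand.gene_id,
                        round(ltpm, 9),
                        pair.ligand.gene_id not in sender_tpm,
                        quadrant,
                        rec.mean_tpm > config.expressed_cutoff
                        and ltpm > config.ligand_plot_cutoff,
                    )
                )
    return sorted(rows)


class TestIdentifyReceptors:
    def test_strict_boundary_and_sorting(self, config):
        db = [make_pair(r, "L1") for r in ("A", "B", "C")]
        receiver = [
            make_summary("A", 5, config),
            make_summary("B", 2, config),
            make_summary("C", 0.1, config),
        ]
        records = identify_receptors(receiver, db, None, config)
        assert [r.gene_id for r in records] == ["A"]  # 2 is not > 2

    def test_exclusion_empties_result(self, config):
        db = [make_pair("A", "L1")]
        receiver = [make_summary("A", 5, config)]
        out = identify_receptors(receiver, db, CurationList(exclude={"A"}), config)
        assert out == []

    def test_force_include_below_cutoff_stays_out(self, config):
        db = [make_pair("A", "L1")]
        receiver = [make_summary("A", 5, config), make_summary("D", 1.0, config)]
        out = identify_receptors(receiver, db, CurationList(include={"D"}), config)
        assert [r.gene_id for r in out] == ["A"]

    def test_categories_union_and_ligand_order(self, toy_db, config):
        receiver = [make_summary("SDC4", 50, config), make_summary("ITGB1", 20, config)]
        records = identify_receptors(receiver, toy_db, None, config)
        sdc4 = next(r for r in records if r.gene_id == "SDC4")
        assert [l.gene_id for l in sdc4.ligands] == ["CCL5", "CXCL10", "MDK"]
        assert sdc4.categories == {"growth_factor_wnt", "cytokine_chemokine"}


class TestAssignQuadrant:
    @pytest.mark.parametrize(
        "r, l, expected",
        [
            (15, 12, "high_high"),
            (10, 12, "low_high"),  # exactly 10 is not high
            (2.5, 0, "low_low"),
            (11, 10, "high_low"),
        ],
    )
    def test_boundaries(self, r, l, expected, config):
        assert assign_quadrant(r, l, config) == expected

    def test_negative_rejected(self, config):
        with pytest.raises(ValueError):
            assign_quadrant(-1, 5, config)


class TestPairTableAndCounts:
    def test_direct_rule_application(self, config):
        db = [make_pair("R", "L1"), make_pair("R", "L2")]
        records = identify_receptors([make_summary("R", 20, config)], db, None, config)
        sender = [make_summary("L1", 15, config), make_summary("L2", 0.5, config)]
        rows = build_pair_table(records, sender, db, config)
        by_ligand = {r.ligand_gene: r for r in rows}
        assert by_ligand["L1"].quadrant == "high_high" and by_ligand["L1"].plotted
        assert by_ligand["L2"].quadrant == "high_low" and not by_ligand["L2"].plotted

    def test_missing_ligand_flagged_not_dropped(self, config):
        db = [make_pair("R", "LGONE")]
        records = identify_receptors([make_summary("R", 20, config)], db, None, config)
        (row,) = build_pair_table(records, [], db, config)
        assert row.ligand_tpm == 0 and row.ligand_missing
        assert row.quadrant == "high_low"

    def test_oracle_equivalence_on_random_instances(self, config):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            db, receiver, sender, curation = random_instance(rng, config)
            records = identify_receptors(receiver, db, curation, config)
            rows = build_pair_table(records, sender, db, config)
            got = sorted(
                (
                    r.category,
                    r.receptor_gene,
                    r.ligand_gene,
                    round(r.ligand_tpm, 9),
                    r.ligand_missing,
                    r.quadrant,
                    r.plotted,
                )
                for r in rows
            )
            assert got == oracle_pair_table(records, sender, db, config)
            # quadrant counting vs naive recount, and partition per category
            for cat in CATEGORIES:
                counts = count_quadrants(rows, cat)
                naive = {q: 0 for q in ("high_high", "high_low", "low_high", "low_low")}
                for r in rows:
                    if r.category == cat:
                        naive[r.quadrant] += 1
                assert counts == naive
                assert sum(counts.values()) == sum(1 for r in rows if r.category == cat)

    def test_unknown_category_rejected(self, config):
        with pytest.raises(ValueError, match="unknown category"):
            count_quadrants([], "hormone")

    def test_empty_pairs_all_zero(self, config):
        assert set(count_quadrants([], "growth_factor_wnt").values()) == {0}

    def test_multi_category_pair_counted_once_per_panel(self, toy_db, config):
        receiver = [make_summary("ITGB1", 20, config)]
        records = identify_receptors(receiver, toy_db, None, config)
        sender = [make_summary("VEGFA", 30, config), make_summary("MDK", 30, config)]
        rows = build_pair_table(records, sender, toy_db, config)
        vegfa_rows = [r for r in rows if r.ligand_gene == "VEGFA"]
        assert {r.category for r in vegfa_rows} == {
            "growth_factor_wnt", "juxtacrine_matricellular"
        }

    def test_proxy_pairs_excluded_from_headline_counts(self, config):
        db = [
            make_pair("R", "ENZ", categories=("small_molecule",),
                      kind="synthesis_enzyme_proxy", molecule="x"),
        ]
        records = identify_receptors([make_summary("R", 20, config)], db, None, config)
        rows = build_pair_table(records, [make_summary("ENZ", 50, config)], db, config)
        assert count_quadrants(rows, "small_molecule")["high_high"] == 1
        assert count_quadrants(rows, "small_molecule", exclude_proxies=True)["high_high"] == 0


class TestMonotonicity:
    def test_raising_high_cutoff_never_raises_high_high(self, config):
        rng = np.random.default_rng(3)
        for _ in range(50):
            db, receiver, sender, curation = random_instance(rng, config)
            counts = []
            for high in (5.0, 10.0, 20.0):
                cfg = ScreenConfig(high_cutoff=high, very_high_cutoff=1000.0)
                records = identify_receptors(receiver, db, curation, cfg)
                rows = build_pair_table(records, sender, db, cfg)
                counts.append(
                    sum(count_quadrants(rows, c)["high_high"] for c in CATEGORIES)
                )
            assert counts[0] >= counts[1] >= counts[2]

    def test_lowering_expressed_cutoff_never_loses_receptors(self, config):
        rng = np.random.default_rng(4)
        for _ in range(50):
            db, receiver, sender, curation = random_instance(rng, config)
            sizes = [
                len(identify_receptors(receiver, db, curation, ScreenConfig(expressed_cutoff=e)))
                for e in (4.0, 2.0, 1.0)
            ]
            assert sizes[0] <= sizes[1] <= sizes[2]


class TestRankingAndInventories:
    def test_tie_broken_alphabetically(self, config):
        items = [make_summary(g, t, config) for g, t in [("A", 5), ("B", 7), ("C", 7)]]
        assert [s.gene_id for s in rank_top(items, 2)] == ["B", "C"]

    def test_n_larger_than_input(self, config):
        items = [make_summary(g, t, config) for g, t in [("A", 5), ("B", 7)]]
        assert [s.gene_id for s in rank_top(items, 10)] == ["B", "A"]

    def test_agrees_with_sort_oracle(self, config):
        rng = np.random.default_rng(5)
        for _ in range(200):
            items = [
                make_summary(f"G{i}", float(rng.choice([1, 5, 5, 9, 50])), config)
                for i in range(rng.integers(1, 15))
            ]
            n = int(rng.integers(1, 20))
            expected = sorted(items, key=lambda s: (-s.mean_tpm, s.gene_id))[:n]
            assert rank_top(items, n) == expected
            assert rank_top(items, n) == rank_top(items, n)  # stable under repeats

    def test_orphans_are_exactly_ligandless_records(self, config):
        db = [make_pair("A", "L1")]
        receiver = [make_summary("A", 5, config), make_summary("ORPH", 8, config)]
        records = identify_receptors(receiver, db, CurationList(include={"ORPH"}), config)
        orphans = find_orphans(records)
        assert [r.gene_id for r in orphans] == ["ORPH"]
        assert orphans[0].orphan and orphans[0].ligands == ()

    def test_no_orphans_when_all_have_ligands(self, config):
        db = [make_pair("A", "L1")]
        records = identify_receptors([make_summary("A", 5, config)], db, None, config)
        assert find_orphans(records) == []

    def test_autocrine_inventory_excludes_proxies_and_low(self, toy_db, config):
        receiver = [
            make_summary("MDK", 30, config),
            make_summary("IL18", 1, config),  # below expressed cutoff
            make_summary("ACHE", 50, config),  # proxy: excluded
        ]
        hits = identify_ligand_genes(receiver, toy_db, config)
        assert [s.gene_id for s in hits] == ["MDK"]


class TestReportDeterminism:
    def test_identical_inputs_give_identical_serialization(self, toy_db, config):
        receiver = [make_summary(g, t, config) for g, t in
                    [("SDC4", 50), ("ITGB1", 20), ("MDK", 12), ("CHRNB2", 3)]]
        sender = [make_summary(g, t, config) for g, t in
                  [("MDK", 40), ("CXCL10", 15), ("CCL5", 0.5), ("ACHE", 2)]]
        a = build_report(receiver, sender, toy_db, config=config)
        b = build_report(list(receiver), list(sender), list(toy_db), config=config)
        assert a.to_json() == b.to_json()
        # every count in the summary is reproducible from the stored tables
        summary = a.summary_dict()
        assert summary["n_pairs"] == len(a.pairs)
        for cat, counts in summary["quadrant_counts"].items():
            assert counts == count_quadrants(a.pairs, cat)
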
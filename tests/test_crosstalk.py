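"""Pair mapping rules, Spearman oracle, co-expression filter, network assembly."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lrcrosstalk.crosstalk import CandidatePair, cofilter, map_pairs, spearman_rho
from lrcrosstalk.de import DEResult
from lrcrosstalk.exceptions import ValidationError
from lrcrosstalk.io import LigandReceptorDB
from lrcrosstalk.simulate import SimConfig, generate_bulk


def de(gene, cell_type, direction):
    lfc = 1.0 if direction == "up" else -1.0
    return DEResult(gene, cell_type, lfc, 1e-4, 1e-3, direction)


class TestMapPairs:
    db = LigandReceptorDB.from_pairs([("CTHRC1", "FZD6"), ("MDK", "SDC1")])

    def test_autocrine_concordant_up(self):
        pairs = map_pairs([de("CTHRC1", "B", "up")], [de("FZD6", "B", "up")], self.db, "autocrine")
        assert [(p.ligand, p.receptor, p.regulation) for p in pairs] == [("CTHRC1", "FZD6", "up")]

    def test_autocrine_concordant_down(self):
        pairs = map_pairs([de("MDK", "B", "down")], [de("SDC1", "B", "down")], self.db, "autocrine")
        assert pairs[0].regulation == "down"

    def test_autocrine_discordant_excluded(self):
        pairs = map_pairs([de("CTHRC1", "B", "up")], [de("FZD6", "B", "down")], self.db, "autocrine")
        assert pairs == []

    def test_autocrine_concordance_relaxation_flag(self):
        pairs = map_pairs([de("CTHRC1", "B", "up")], [de("FZD6", "B", "down")], self.db,
                          "autocrine", require_concordance=False)
        assert [(p.ligand, p.regulation) for p in pairs] == [("CTHRC1", "mixed")]

    def test_paracrine_requires_both_up(self):
        up_b, up_m = [de("MDK", "B", "up")], [de("SDC1", "MYELOID", "up")]
        assert len(map_pairs(up_b, up_m, self.db, "paracrine_up")) == 1
        down_m = [de("SDC1", "MYELOID", "down")]
        assert map_pairs(up_b, down_m, self.db, "paracrine_up") == []

    def test_empty_de_lists(self):
        assert map_pairs([], [], self.db, "autocrine") == []

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            map_pairs([], [], self.db, "paracrine_down")


def brute_force_spearman(x, y):
    """Independent oracle: explicit mid-ranks + textbook Pearson formula."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and v[order[j]] == v[order[i]]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0  # average of 1-based positions
            i = j
        return ranks

    rx, ry = midranks(x), midranks(y)
    num = ((rx - rx.mean()) * (ry - ry.mean())).sum()
    den = np.sqrt(((rx - rx.mean()) ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
    return num / den


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho, p = spearman_rho(x, x**3)
        assert rho == pytest.approx(1.0)

    def test_reversal(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho, _ = spearman_rho(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_tied_example_matches_rank_pearson(self):
        x = [1, 2, 3, 4, 5]
        y = [5, 6, 7, 8, 7]  # ranks [1, 2, 3.5, 5, 3.5]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            spearman_rho([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            spearman_rho([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        x = rng.integers(0, 6, n).astype(float)  # heavy ties
        y = x * 0.3 + rng.normal(0, 1, n)
        y = np.round(y, 1)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_p_value_matches_scipy(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        x, y = rng.normal(size=50), rng.normal(size=50)
        rho, p = spearman_rho(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


@pytest.fixture(scope="module")
def bulk():
    cfg = SimConfig(
        n_genes=400, cell_types={"B": 5}, n_tumor_samples=1, n_normal_samples=1,
        n_bulk_samples=300, corr_plan=[("LGT", "RCT", 0.6), ("LGN", "RCN", 0.0)], seed=13,
    )
    return generate_bulk(cfg)


class TestCofilter:

    def test_planted_pair_retained_null_dropped(self, bulk):
        cands = [CandidatePair("LGT", "RCT", "B", "B", "up"),
                 CandidatePair("LGN", "RCN", "B", "B", "up")]
        kept = cofilter(cands, bulk)
        assert [(p.ligand, p.receptor) for p in kept] == [("LGT", "RCT")]
        assert kept[0].rho > 0.3 and kept[0].corr_adj_p < 0.05

    def test_null_pairs_rarely_pass(self):
        false_hits = 0
        for seed in range(20):
            cfg = SimConfig(n_genes=60, cell_types={"B": 5}, n_tumor_samples=1,
                            n_normal_samples=1, n_bulk_samples=300, seed=seed)
            bulk = generate_bulk(cfg)
            cands = [CandidatePair("G00001", "G00002", "B", "B", "up")]
            false_hits += len(cofilter(cands, bulk))
        assert false_hits <= 1  # pass probability well under 5%

    def test_unreachable_threshold_empty(self, bulk):
        cands = [CandidatePair("LGT", "RCT", "B", "B", "up")]
        assert cofilter(cands, bulk, rho_min=1.0) == []

    def test_missing_gene_candidates_dropped(self, bulk):
        cands = [CandidatePair("NOTPRESENT", "RCT", "B", "B", "up")]
        assert cofilter(cands, bulk) == []

    def test_empty_subset_rejected(self, bulk):
        with pytest.raises(ValidationError):
            cofilter([], bulk, sample_subset=[])

    def test_sample_subset_restricts_columns(self, bulk):
        cands = [CandidatePair("LGT", "RCT", "B", "B", "up")]
        kept = cofilter(cands, bulk, sample_subset=list(bulk.column_ids[:150]))
        assert len(kept) == 1


class TestBuildNetworks:
    def test_end_to_end_recovery(self, small_study):
        from lrcrosstalk.crosstalk import build_networks
        from lrcrosstalk.qc import filter_cells, lognormalize

        filtered, _ = filter_cells(small_study.counts)
        norm = lognormalize(filtered)
        ann = small_study.annotation.subset(norm.column_ids)
        nets = build_networks(norm, ann, small_study.lr_db, small_study.bulk)
        # emitted pairs always satisfy the thresholds and come from the database
        for pairs in nets.values():
            for p in pairs:
                assert p.rho > 0.3 and p.corr_adj_p < 0.05
                assert (p.ligand, p.receptor) in small_study.lr_db
        truth_auto = {(l, r) for l, r, nw in small_study.truth.true_pairs if nw.startswith("autocrine")}
        got_auto = {(p.ligand, p.receptor) for p in nets["autocrine"]}
        assert len(got_auto & truth_auto) >= len(truth_auto) - 2  # small-study power

    def test_db_without_de_genes_gives_empty_networks(self, small_study):
        from lrcrosstalk.crosstalk import build_networks
        from lrcrosstalk.qc import filter_cells, lognormalize

        filtered, _ = filter_cells(small_study.counts)
        norm = lognormalize(filtered)
        ann = small_study.annotation.subset(norm.column_ids)
        db = LigandReceptorDB.from_pairs([("G00001", "G00002")])
        nets = build_networks(norm, ann, db, small_study.bulk)
        assert all(len(v) == 0 for v in nets.values())
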
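"""Correlation screens, the hypergeometric sponge test and network assembly."""

import itertools
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cernet import cerna, examples, simdata
from cernet._hypergeom import hypergeom_upper_tail, hypergeom_upper_tail_exact
from cernet.cerna import (
    CeRNAPair,
    assemble_network,
    mrna_partners_via,
    pearson,
    screen_lnc_mrna_pairs,
    screen_mirna_pairs,
    spearman,
    sponge_test,
)
from cernet.seqio import ValidationError
from conftest import make_matrix


def enumeration_oracle(x: int, N: int, K: int, n: int) -> Fraction:
    """Brute force: count draws of n items from N with >= x of the K marked."""
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        hits += len(marked & set(draw)) >= x
    return Fraction(hits, total)


class TestCorrelations:
    def test_perfect_antimonotone_scc(self):
        assert spearman([1, 2, 3], [6, 4, 2]).value == pytest.approx(-1.0)

    def test_identity_pcc(self):
        assert pearson([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]).value == pytest.approx(1.0)

    def test_constant_input_flagged_undefined(self):
        rec = spearman([1, 1, 1], [1, 2, 3])
        assert not rec.defined and np.isnan(rec.value)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError, match="3 samples"):
            pearson([1, 2], [3, 4])

    def test_scc_ties_use_midranks(self):
        # mid-rank oracle: rank then Pearson
        x = [1.0, 2.0, 2.0, 3.0, 5.0]
        y = [9.0, 7.0, 7.0, 7.0, 1.0]
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        naive = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).value == pytest.approx(naive, abs=1e-12)

    def test_matches_naive_recomputation_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            x, y = rng.normal(size=(2, 20))
            mx, my = x - x.mean(), y - y.mean()
            naive_p = (mx @ my) / np.sqrt((mx @ mx) * (my @ my))
            assert pearson(x, y).value == pytest.approx(naive_p, abs=1e-12)
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            rx, ry = rx - rx.mean(), ry - ry.mean()
            naive_s = (rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry))
            assert spearman(x, y).value == pytest.approx(naive_s, abs=1e-12)


def _pair(x, N, K, n, **kw):
    defaults = dict(lncrna="l", mrna="m", shared_mirnas=frozenset(f"mir{i}" for i in range(x)),
                    pcc=0.8)
    defaults.update(kw)
    return CeRNAPair(K=K, n=n, N=N, x=x, **defaults)


class TestSpongeTest:
    def test_zero_overlap_certain(self):
        assert sponge_test(_pair(0, 30, 5, 7, shared_mirnas=frozenset())) == 1.0

    def test_worked_example_exact_fraction(self):
        # N=10, K=4, n=5, x=3: 66 of the 252 possible draws have >= 3 hits
        assert hypergeom_upper_tail_exact(3, 10, 4, 5) == Fraction(66, 252)
        assert sponge_test(_pair(3, 10, 4, 5)) == pytest.approx(66 / 252)

    def test_forced_full_overlap(self):
        assert sponge_test(_pair(4, 4, 4, 4)) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            _pair(5, 10, 4, 5)
        with pytest.raises(ValidationError):
            _pair(2, 3, 4, 2)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(3, 10, 11, 5)

    @given(
        N=st.integers(1, 40),
        data=st.data(),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_monotone_decreasing_in_overlap(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        tail = [hypergeom_upper_tail(x, N, K, n) for x in range(min(K, n) + 1)]
        assert all(a >= b for a, b in zip(tail, tail[1:]))

    @given(N=st.integers(1, 25), data=st.data())
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_agrees_with_scipy_survival_function(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        x = data.draw(st.integers(0, min(K, n)))
        ours = hypergeom_upper_tail(x, N, K, n)
        ref = stats.hypergeom.sf(x - 1, N, K, n)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_exact_agreement_with_enumeration_small(self):
        for N in (4, 7):
            for K in range(N + 1):
                for n in range(N + 1):
                    for x in range(min(K, n) + 1):
                        assert hypergeom_upper_tail_exact(
                            x, N, K, n
                        ) == enumeration_oracle(x, N, K, n)


class TestScreens:
    def _matrices(self):
        mir = make_matrix({"m1": [10, 20, 30, 40, 50, 60]}, rna_class="miRNA")
        lnc = make_matrix({"l1": [60, 50, 40, 30, 20, 10],
                           "l2": [1, 2, 3, 4, 5, 6]}, rna_class="lncRNA")
        targets = simdata.TargetTable(pd.DataFrame(
            {"mirna": ["m1", "m1"], "target": ["l1", "l2"],
             "target_class": ["lncRNA", "lncRNA"],
             "tools": [frozenset({"TargetScan"})] * 2}))
        return mir, lnc, targets

    def test_negative_scc_kept_positive_dropped(self):
        mir, lnc, targets = self._matrices()
        out = screen_mirna_pairs(mir, lnc, targets,
                                 expression_mir=mir.counts.astype(float),
                                 expression_other=lnc.counts.astype(float))
        assert out["target"].tolist() == ["l1"]
        assert out["scc"].iloc[0] == pytest.approx(-1.0)

    def test_scc_zero_exactly_is_dropped(self):
        mir = make_matrix({"m1": [1, 2, 3, 4, 1, 1]}, rna_class="miRNA")
        lnc = make_matrix({"l1": [3, 1, 4, 2, 9, 9]}, rna_class="lncRNA")
        e_mir = pd.DataFrame([[1.0, 2, 3, 4, 5, 6]], index=["m1"], columns=mir.samples)
        e_lnc = pd.DataFrame([[3.0, 1, 4, 2, 6, 5]], index=["l1"], columns=lnc.samples)
        assert spearman(e_mir.loc["m1"][:4], e_lnc.loc["l1"][:4]).value == 0.0
        targets = simdata.TargetTable(pd.DataFrame(
            {"mirna": ["m1"], "target": ["l1"], "target_class": ["lncRNA"],
             "tools": [frozenset({"miRDB"})]}))
        mir4 = make_matrix({"m1": [1, 2, 3, 4]}, rna_class="miRNA")
        lnc4 = make_matrix({"l1": [3, 1, 4, 2]}, rna_class="lncRNA")
        out = screen_mirna_pairs(mir4, lnc4, targets,
                                 expression_mir=mir4.counts.astype(float),
                                 expression_other=lnc4.counts.astype(float))
        assert out.empty

    def test_anticorrelated_pair_outside_target_table_dropped(self):
        mir, lnc, _ = self._matrices()
        empty = simdata.TargetTable(pd.DataFrame(columns=["mirna", "target",
                                                          "target_class", "tools"]))
        out = screen_mirna_pairs(mir, lnc, empty)
        assert out.empty

    def test_pair_sharing_no_screened_mirna_dropped(self):
        lnc = make_matrix({"l1": [1, 2, 3, 4, 5, 6]}, rna_class="lncRNA")
        mrna = make_matrix({"r1": [2, 4, 6, 8, 10, 12]}, rna_class="mRNA")
        no_shared = screen_lnc_mrna_pairs(
            lnc, mrna,
            screened_lnc=pd.DataFrame({"mirna": ["mA"], "target": ["l1"],
                                       "target_class": ["lncRNA"], "scc": [-0.9]}),
            screened_mrna=pd.DataFrame({"mirna": ["mB"], "target": ["r1"],
                                        "target_class": ["mRNA"], "scc": [-0.9]}),
        )
        assert no_shared == []

    def test_pcc_boundary_is_strict(self):
        lnc = make_matrix({"l1": [1, 2, 3, 1, 2, 3]}, rna_class="lncRNA")
        mrna = make_matrix({"r1": [1, 3, 2, 1, 3, 2]}, rna_class="mRNA")
        e_lnc = pd.DataFrame([[1.0, 2, 3, 1, 2, 3]], index=["l1"], columns=lnc.samples)
        e_mrna = pd.DataFrame([[1.0, 3, 2, 1, 3, 2]], index=["r1"], columns=mrna.samples)
        assert pearson(e_lnc.loc["l1"], e_mrna.loc["r1"]).value == pytest.approx(0.5)
        screened = dict(
            screened_lnc=pd.DataFrame({"mirna": ["mA"], "target": ["l1"],
                                       "target_class": ["lncRNA"], "scc": [-0.9]}),
            screened_mrna=pd.DataFrame({"mirna": ["mA"], "target": ["r1"],
                                        "target_class": ["mRNA"], "scc": [-0.8]}),
        )
        out = screen_lnc_mrna_pairs(lnc, mrna, expression_lnc=e_lnc,
                                    expression_mrna=e_mrna, **screened)
        assert out == []
        # nudge one value so PCC > 0.5: the same pair is retained
        e_mrna2 = pd.DataFrame([[1.0, 3.0, 2.5, 1.0, 3.0, 2.5]], index=["r1"],
                               columns=mrna.samples)
        assert pearson(e_lnc.loc["l1"], e_mrna2.loc["r1"]).value > 0.5
        out2 = screen_lnc_mrna_pairs(lnc, mrna, expression_lnc=e_lnc,
                                     expression_mrna=e_mrna2, **screened)
        assert len(out2) == 1 and out2[0].x == 1


class TestNetwork:
    def test_assembly_order_invariant(self, reference_dataset):
        lnc, mir, mrna, truth, targets = reference_dataset
        result = cerna.run_pipeline(lnc, mir, mrna, targets)
        pairs = result.pairs
        directions = {f: d for f, d in truth.direction.items()}
        directions.update({p.lncrna: "up" for p in pairs})
        g1 = assemble_network(pairs, truth.direction)
        g2 = assemble_network(list(reversed(pairs)), truth.direction)
        assert dict(g1.nodes(data=True)) == dict(g2.nodes(data=True))
        assert {frozenset(e) for e in g1.edges} == {frozenset(e) for e in g2.edges}
        for u, v, d in g1.edges(data=True):
            assert g2.edges[u, v] == d

    def test_network_is_tripartite_with_complete_paths(self, reference_dataset):
        lnc, mir, mrna, _, targets = reference_dataset
        truth = reference_dataset[3]
        G = cerna.run_pipeline(lnc, mir, mrna, targets).network
        for u, v in G.edges:
            classes = {G.nodes[u]["rna_class"], G.nodes[v]["rna_class"]}
            assert classes in ({"lncRNA", "miRNA"}, {"miRNA", "mRNA"})
        for node, data in G.nodes(data=True):
            if data["rna_class"] == "miRNA":
                neigh = {G.nodes[v]["rna_class"] for v in G[node]}
                assert neigh == {"lncRNA", "mRNA"}

    def test_missing_direction_rejected(self):
        pair = _pair(1, 10, 2, 2, shared_mirnas=frozenset({"mirX"}), p_sponge=0.01)
        with pytest.raises(ValidationError, match="direction"):
            assemble_network([pair], {"l": "up", "m": "up"})

    def test_published_axes_worked_example(self):
        """The published network: 23 mRNAs exclusive to the miR484x axis,
        14 exclusive to rno-miR-653-5p, and Il6r reachable through both."""
        G = examples.aed_network()
        via_484 = mrna_partners_via(G, examples.LNCRNA, examples.MIR_484X)
        via_653 = mrna_partners_via(G, examples.LNCRNA, examples.MIR_653)
        assert len(via_484 - via_653) == 23
        assert len(via_653 - via_484) == 14
        assert via_484 & via_653 == {"Il6r"}
        assert all(d == "up" for n, d in G.nodes(data="direction")
                   if G.nodes[n]["rna_class"] != "miRNA")
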
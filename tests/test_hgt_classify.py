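"""Transfer classification: support classes, tree walks, tallies, co-transfer."""

import random
from importlib import resources

import pytest

from symtrophy import hgt_classify as hc
from symtrophy.hgt_classify import (
    ClassifierConfig,
    HGTCall,
    classify,
    detect_cotransfer,
    support_class,
    tally_calls,
)
from symtrophy.phylo import parse_newick
from symtrophy.synthetic_data import SimConfig, simulate_gene_tree


def fixture_calls(cfg=ClassifierConfig()):
    text = (resources.files("symtrophy") / "data" / "gene_calls_39.tsv").read_text()
    return hc.load_affiliation_table(text, cfg)


class TestSupportClass:
    @pytest.mark.parametrize(
        "bsv,expected",
        [
            (100, "strong"),
            (80, "strong"),
            (79, "moderate"),
            (50, "moderate"),
            (49, "unsupported"),
            (0, "unsupported"),
            (None, "unsupported"),
        ],
    )
    def test_boundaries(self, bsv, expected):
        assert support_class(bsv) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            support_class(101)
        with pytest.raises(ValueError):
            support_class(-1)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ClassifierConfig(strong_bsv=40, moderate_bsv=50)
        with pytest.raises(ValueError):
            ClassifierConfig(donor_majority=0.5)


# taxa covering the handcrafted trees below
def _taxa(tree):
    out = {}
    for l in tree.leaves:
        if l.startswith("q"):
            out[l] = ("Eukaryota", "Trypanosomatidae")
        elif l.startswith("f"):
            out[l] = ("Bacteria", "Firmicutes")
        elif l.startswith("g"):
            out[l] = ("Bacteria", "Gammaproteobacteria")
        else:
            out[l] = ("Eukaryota", "Opisthokonta")
    return out


class TestClassify:
    def test_query_sister_to_firmicutes_at_bsv_100(self):
        # mimics the homoserine dehydrogenase topology: trypanosomatid clade
        # nested next to Solibacillus/Lysinibacillus-like Firmicutes
        nwk = "(((q1,q2)99,(f1,f2)95)100,((f3,f4)90,(e1,(e2,e3)88)92)75);"
        tree = parse_newick(nwk)
        call = classify(tree, _taxa(tree), {"q1", "q2"}, gene_id="hsd")
        assert call.call == "HGT"
        assert call.donor == "Firmicutes"
        assert call.support_class == "strong"
        assert call.decisive_bsv == 100

    def test_query_nested_among_eukaryotes(self):
        nwk = "(((q1,q2)99,(e1,e2)90)95,((f1,f2)91,(f3,e3)85)80);"
        tree = parse_newick(nwk)
        call = classify(tree, _taxa(tree), {"q1", "q2"})
        assert call.call == "native_eukaryotic"
        assert call.donor is None

    def test_unsupported_decisive_edge_is_undetermined(self):
        nwk = "(((q1,q2)99,(f1,f2)30)20,((f3,f4)10,(e1,(e2,e3)25)15)5);"
        tree = parse_newick(nwk)
        call = classify(tree, _taxa(tree), {"q1", "q2"})
        assert call.call == "undetermined"
        assert call.support_class == "unsupported"

    def test_rotation_invariance(self):
        # same unrooted topology written with different rotations and root
        # positions (trifurcating base, so each edge has a single label)
        a = parse_newick("((q1,q2)99,(f1,f2)95,((f3,f4)90,(e1,(e2,e3)88)92)75);")
        b = parse_newick("(((f4,f3)90,((e3,e2)88,e1)92)75,(f2,f1)95,(q2,q1)99);")
        ca = classify(a, _taxa(a), {"q1", "q2"})
        cb = classify(b, _taxa(b), {"q1", "q2"})
        assert (ca.call, ca.donor, ca.decisive_bsv) == (cb.call, cb.donor, cb.decisive_bsv)

    def test_mixed_donor_composition(self):
        # decisive clade contains equal Firmicutes and Gammaproteobacteria
        nwk = "(((q1,q2)99,(f1,g1)95)100,((f2,g2)90,(e1,(e2,e3)88)92)75);"
        tree = parse_newick(nwk)
        call = classify(tree, _taxa(tree), {"q1", "q2"})
        assert call.call == "HGT"
        assert call.donor.startswith("mixed:")

    def test_query_leaf_missing_from_taxa_is_error(self):
        tree = parse_newick("((q1,q2)99,(f1,f2)95,(e1,e2)90);")
        taxa = _taxa(tree)
        del taxa["q1"]
        with pytest.raises(ValueError):
            classify(tree, taxa, {"q1", "q2"})

    def test_query_equal_to_all_leaves_is_error(self):
        tree = parse_newick("((q1,q2)99,(q3,q4)95);")
        taxa = {l: ("Eukaryota", "Trypanosomatidae") for l in tree.leaves}
        with pytest.raises(ValueError):
            classify(tree, taxa, set(tree.leaves))

    def test_non_monophyletic_query_undetermined_on_disagreement(self):
        # one query clade inside Firmicutes, the other among eukaryotes
        nwk = "(((q1,f1)95,f2)90,((q2,e1)92,(e2,e3)88)85);"
        tree = parse_newick(nwk)
        call = classify(tree, _taxa(tree), {"q1", "q2"})
        assert not call.query_monophyletic
        assert call.call == "undetermined"
        assert len(call.subcalls) == 2


class TestTruthRecovery:
    def test_implanted_transfers_recovered(self):
        n, ok = 60, 0
        for i in range(n):
            rng = random.Random(i)
            donor = rng.choice(["Firmicutes", "Bacteroidetes", "Gammaproteobacteria"])
            cfg = SimConfig(
                seed=5000 + i,
                implant_transfer=True,
                donor_group=donor,
                decisive_support=rng.randint(80, 100),
            )
            tree, taxa, truth = simulate_gene_tree(cfg)
            q = frozenset(l for l in tree.leaves if l.startswith("Trypanosomatidae"))
            call = classify(tree, taxa, q)
            ok += call.call == "HGT" and call.donor == truth.donor
        assert ok / n >= 0.95

    def test_no_implant_rarely_called_hgt(self):
        n, fp = 60, 0
        for i in range(n):
            tree, taxa, _ = simulate_gene_tree(SimConfig(seed=7000 + i))
            q = frozenset(l for l in tree.leaves if l.startswith("Trypanosomatidae"))
            fp += classify(tree, taxa, q).call == "HGT"
        assert fp / n <= 0.05

    def test_threshold_monotonicity(self):
        tree, taxa, _ = simulate_gene_tree(
            SimConfig(seed=42, implant_transfer=True, donor_group="Firmicutes",
                      decisive_support=70)
        )
        q = frozenset(l for l in tree.leaves if l.startswith("Trypanosomatidae"))
        lax = classify(tree, taxa, q, ClassifierConfig(moderate_bsv=50))
        strict = classify(tree, taxa, q, ClassifierConfig(moderate_bsv=75, strong_bsv=90))
        # raising moderate_bsv can only demote, never promote, an HGT call
        order = {"undetermined": 0, "native_eukaryotic": 0, "HGT": 1}
        assert order[strict.call] <= order[lax.call]


class TestTally:
    def test_shipped_39_gene_table(self):
        summary = tally_calls(fixture_calls())
        assert summary["n_total"] == 39
        assert summary["n_hgt"] == 18
        assert summary["n_undetermined"] == 3
        assert summary["n_native"] == 18

    def test_donor_phylum_counts(self):
        per_donor = tally_calls(fixture_calls())["per_donor_counts"]
        for phylum in ("Firmicutes", "Bacteroidetes", "Gammaproteobacteria"):
            assert per_donor[phylum] >= 3
        for minor in ("Actinobacteria", "Betaproteobacteria", "Acidobacteria",
                      "Alphaproteobacteria"):
            assert per_donor.get(minor, 0) <= 2

    def test_empty_list(self):
        s = tally_calls([])
        assert s == {
            "n_total": 0, "n_hgt": 0, "n_native": 0, "n_undetermined": 0,
            "per_donor_counts": {},
        }

    def test_duplicate_gene_id_rejected(self):
        c = HGTCall("g", True, "undetermined")
        with pytest.raises(ValueError):
            tally_calls([c, HGTCall("g", True, "undetermined")])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_counts_equal_independent_recount(self, seed):
        rng = random.Random(seed)
        calls = []
        for i in range(50):
            kind = rng.choice(["HGT", "native_eukaryotic", "undetermined"])
            donor = rng.choice(["Firmicutes", "mixed:a,b"]) if kind == "HGT" else None
            calls.append(
                HGTCall(f"g{i}", True, kind, donor,
                        "strong" if kind == "HGT" else "unsupported")
            )
        s = tally_calls(calls)
        assert s["n_hgt"] == sum(c.call == "HGT" for c in calls)
        assert s["n_native"] == sum(c.call == "native_eukaryotic" for c in calls)
        assert s["n_undetermined"] == sum(c.call == "undetermined" for c in calls)
        assert sum(s["per_donor_counts"].values()) == s["n_hgt"]


class TestCotransfer:
    def _call(self, gid, donor="Firmicutes"):
        return HGTCall(gid, True, "HGT", donor, "strong", 90)

    def test_tandem_pair_detected(self):
        # argininosuccinate synthase + lyase adjacent on one contig
        calls = [self._call("argG"), self._call("argH"), self._call("hsd")]
        locs = {"argG": ("contig7", 4), "argH": ("contig7", 5), "hsd": ("contig2", 1)}
        assert detect_cotransfer(calls, locs) == [("argG", "argH")]

    def test_no_shared_contig(self):
        calls = [self._call("a"), self._call("b")]
        locs = {"a": ("c1", 1), "b": ("c2", 1)}
        assert detect_cotransfer(calls, locs) == []

    def test_different_donors_not_paired(self):
        calls = [self._call("a"), self._call("b", donor="Bacteroidetes")]
        locs = {"a": ("c1", 1), "b": ("c1", 2)}
        assert detect_cotransfer(calls, locs) == []

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_all_pairs_oracle(self, seed):
        rng = random.Random(seed)
        calls = [
            self._call(f"g{i}", rng.choice(["Firmicutes", "Bacteroidetes"]))
            for i in range(20)
        ]
        locs = {f"g{i}": (f"c{rng.randint(0, 3)}", rng.randint(0, 5)) for i in range(20)}
        expected = set()
        for a in calls:
            for b in calls:
                if a.gene_id < b.gene_id and a.donor == b.donor:
                    ca, pa = locs[a.gene_id]
                    cb, pb = locs[b.gene_id]
                    if ca == cb and abs(pa - pb) == 1:
                        expected.add((a.gene_id, b.gene_id))
        assert set(detect_cotransfer(calls, locs)) == expected
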
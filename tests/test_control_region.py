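"""Box scanning, tandem repeats, CR identity, domain and GO classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mitobias as mb
from mitobias.control_region import DOMAINS
from mitobias.genetic_code import reverse_complement


def plant(background: str, inserts: dict[int, str]) -> str:
    """Place exact sequences at given offsets in a background string."""
    seq = list(background)
    for pos, ins in inserts.items():
        seq[pos:pos + len(ins)] = list(ins)
    return "".join(seq)


@pytest.fixture(scope="module")
def background() -> str:
    rng = np.random.default_rng(99)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))


class TestScanBoxes:
    def test_planted_exact_consensus_found(self, box_library, background):
        csbb = box_library.get("CSBb")
        consensus = csbb.consensus.replace("R", "A")
        cr = plant(background, {300: consensus})
        hits = [h for h in mb.scan_boxes(cr, box_library) if h.box == "CSBb"]
        assert any(h.start == 300 and h.mismatches == 0 for h in hits)

    def test_single_mismatch_within_budget(self, box_library, background):
        csbb = box_library.get("CSBb")
        consensus = csbb.consensus.replace("R", "A")
        mutated = "T" + consensus[1:] if consensus[0] != "T" else "A" + consensus[1:]
        cr = plant(background, {500: mutated})
        hits = [h for h in mb.scan_boxes(cr, box_library)
                if h.box == "CSBb" and h.start == 500]
        assert hits and hits[0].mismatches == 1

    def test_duplicated_box_gets_copy_indices(self, box_library, background):
        consensus = box_library.get("CSBb").consensus.replace("R", "G")
        cr = plant(background, {300: consensus, 900: consensus})
        hits = [h for h in mb.scan_boxes(cr, box_library) if h.box == "CSBb"]
        assert [h.copy_index for h in hits] == [1, 2]
        assert [h.start for h in hits] == [300, 900]

    def test_strand_consistency(self, box_library, background):
        consensus = box_library.get("D-box").consensus.replace("R", "A")
        cr = plant(background, {700: consensus})
        fwd = {(h.box, h.start, h.end) for h in mb.scan_boxes(cr, box_library)}
        rev = {(h.box, len(cr) - h.end, len(cr) - h.start)
               for h in mb.scan_boxes(reverse_complement(cr), box_library)}
        assert fwd == rev

    def test_empty_hit_list_is_valid(self, box_library):
        assert mb.scan_boxes("A" * 10, box_library) == []


class TestTandemRepeats:
    def test_perfect_repeat(self):
        reps = mb.find_tandem_repeats("ACGT" * 10)
        assert len(reps) == 1
        r = reps[0]
        assert (r.motif, r.period, r.copies, r.purity) == ("ACGT", 4, 10.0, 1.0)

    def test_one_substitution_lowers_purity(self):
        s = list("ACGT" * 10)
        s[17] = "A"
        reps = mb.find_tandem_repeats("".join(s))
        assert len(reps) == 1
        assert reps[0].period == 4
        assert reps[0].purity == pytest.approx(39 / 40)

    def test_no_trivial_full_length_period(self):
        rng = np.random.default_rng(4)
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        reps = mb.find_tandem_repeats(s + s, max_period=len(s))
        assert any(r.period <= len(s) for r in reps)
        assert all(r.period <= len(s) for r in reps)

    def test_false_positive_control_on_random_sequence(self):
        """i.i.d. random 1 kb sequences yield no long, pure, multi-copy
        repeat calls."""
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(10_000 + seed)
            s = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
            reps = mb.find_tandem_repeats(s, min_period=5, min_copies=3.0,
                                          min_purity=0.95)
            hits += sum(1 for r in reps
                        if r.copies >= 3 and r.purity >= 0.95 and r.period >= 5)
        assert hits == 0

    def test_t_rich_and_at_rich_classification(self):
        t_rich = mb.find_tandem_repeats("TTTTA" * 8)[0]
        assert t_rich.composition_class == "T-rich"
        at_rich = mb.find_tandem_repeats("TATAAT" * 8)[0]
        assert at_rich.composition_class == "AT-rich"


class TestPairwiseIdentity:
    def test_identical_is_100(self):
        assert mb.pairwise_identity("ACGTACGT", "ACGTACGT") == 100.0

    def test_single_mismatch(self):
        assert mb.pairwise_identity("AAAA", "AATA") == pytest.approx(75.0)

    @given(st.text(alphabet="ACGT", min_size=5, max_size=60),
           st.text(alphabet="ACGT", min_size=5, max_size=60))
    def test_symmetric(self, a, b):
        assert mb.pairwise_identity(a, b) == pytest.approx(
            mb.pairwise_identity(b, a))

    @given(st.text(alphabet="ACGT", min_size=5, max_size=60))
    def test_100_iff_identical(self, a):
        assert mb.pairwise_identity(a, a) == 100.0

    def test_gap_columns_count_in_denominator(self):
        # 8-mer vs its 6-mer prefix: 2 gap columns out of 8
        assert mb.pairwise_identity("ACGTACGT", "ACGTAC") == pytest.approx(75.0)


class TestDomains:
    def _profile_with(self, boxes):
        p = mb.CRProfile(which="CR1", length=1000)
        p.hits = [mb.BoxHit(b, 10 * i, 10 * i + 8, "+", 0) for i, b in enumerate(boxes)]
        return p

    def test_all_boxes_give_all_domains(self, box_library):
        p = self._profile_with(box_library.names)
        assert mb.classify_domains(p) == set(DOMAINS)

    def test_no_hits_give_empty_set(self):
        assert mb.classify_domains(self._profile_with([])) == set()

    def test_missing_csb1_only(self):
        p = self._profile_with(["ETAS", "D-box", "C-box"])
        assert mb.classify_domains(p) == {"ETAS", "Central"}

    def test_central_requires_dbox_and_cbox_or_csbb(self):
        assert mb.classify_domains(self._profile_with(["D-box", "CSBb"])) == {"Central"}
        assert mb.classify_domains(self._profile_with(["D-box"])) == set()
        assert mb.classify_domains(self._profile_with(["CSBb"])) == set()


class TestGeneOrderClassification:
    def test_go2_when_cr2_is_exact_copy(self, dataset_go2):
        for g in dataset_go2.genomes:
            got = mb.classify_gene_order(g)
            assert got.go_type == "GO-II"
            assert got.cr1_cr2_identity > 60

    def test_go4_when_cr2_degraded(self, dataset_go4):
        for g in dataset_go4.genomes:
            got = mb.classify_gene_order(g)
            assert got.go_type == "GO-IV"

    def test_other_when_cr2_absent(self, small_config):
        import dataclasses
        cfg = dataclasses.replace(small_config, go_type="single")
        g = mb.gen_mitogenome(cfg, species="solo")
        assert mb.classify_gene_order(g).go_type == "other"

    def test_degeneration_monotonicity(self, box_library):
        """Rising substitution rate on CR2 never raises identity, and past
        box destruction the classification flips GO-II -> GO-IV."""
        plan = mb.CRPlan(length=1200)
        cr1, layout = mb.build_control_region(plan, box_library, seed=8)
        identities = []
        go_types = []
        for rate in (0.0, 0.05, 0.15, 0.35, 0.6):
            delete = plan.boxes if rate >= 0.35 else frozenset()
            cr2 = mb.degrade_cr(cr1, sub_rate=rate, delete_boxes=delete,
                                layout=layout, seed=9)
            identities.append(mb.pairwise_identity(cr1, cr2))
            domains = mb.classify_domains(
                mb.profile_cr(cr2, "CR2", box_library))
            go_types.append("GO-II" if domains == set(DOMAINS)
                            and identities[-1] >= 60 else "GO-IV")
        assert identities == sorted(identities, reverse=True)
        assert go_types[0] == "GO-II" and go_types[-1] == "GO-IV"


class TestCRReport:
    def test_fixture_round_trip(self, dataset_go2, dataset_go4, box_library):
        genomes = dataset_go2.genomes + dataset_go4.genomes
        table, tracks = mb.cr_report(genomes, box_library)
        assert len(table) == len(genomes)
        assert table["complete"].all()
        go2 = table[table["go_type"] == "GO-II"]
        go4 = table[table["go_type"] == "GO-IV"]
        assert len(go2) == len(dataset_go2.genomes)
        assert len(go4) == len(dataset_go4.genomes)
        # all CR1 copies carry all domains; degenerate CR2s lack them
        for d in DOMAINS:
            assert go2[f"CR1_{d}"].all() and go4[f"CR1_{d}"].all()
        assert not go4[[f"CR2_{d}" for d in DOMAINS]].all(axis=1).any()
        # identity separation between concerted and degenerate duplicates
        assert go2["identity_pct"].min() > go4["identity_pct"].max()
        assert {"chrom", "start", "end", "name", "score", "strand"} <= set(tracks.columns)
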
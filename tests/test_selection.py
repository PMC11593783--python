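"""Distances, nucleotide diversity, NG86 Ka/Ks and neighbor joining."""

import itertools
import math
import warnings

import numpy as np
import pytest

import mitobias as mb
from mitobias.genetic_code import SENSE_CODONS, codons_of
from mitobias.selection import _codon_sites, pairwise_counts


# ---------------------------------------------------------------------------
# independent oracles

def tn93_oracle(a: str, b: str) -> float:
    """Direct transcription of the Tamura-Nei (1993) distance estimator,
    kept independent of the implementation under test."""
    pairs = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    n = len(pairs)
    freq = {base: 0.0 for base in "ACGT"}
    for x, y in pairs:
        freq[x] += 1
        freq[y] += 1
    g = {base: freq[base] / (2 * n) for base in "ACGT"}
    gA, gC, gG, gT = g["A"], g["C"], g["G"], g["T"]
    gR, gY = gA + gG, gC + gT
    P1 = sum(1 for x, y in pairs if {x, y} == {"A", "G"}) / n
    P2 = sum(1 for x, y in pairs if {x, y} == {"C", "T"}) / n
    Q = sum(1 for x, y in pairs if x != y
            and {x, y} not in ({"A", "G"}, {"C", "T"})) / n
    a1 = 1 - gR * P1 / (2 * gA * gG) - Q / (2 * gR)
    a2 = 1 - gY * P2 / (2 * gC * gT) - Q / (2 * gY)
    bterm = 1 - Q / (2 * gR * gY)
    return (-2 * gA * gG / gR * math.log(a1)
            - 2 * gC * gT / gY * math.log(a2)
            - 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY) * math.log(bterm))


def mutate_pair(rng, n=1000, ts_rate=0.06, tv_rate=0.03):
    bases = np.array(list("ACGT"))
    a = bases[rng.integers(0, 4, n)]
    b = a.copy()
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for i in range(n):
        r = rng.random()
        if r < ts_rate:
            b[i] = transitions[b[i]]
        elif r < ts_rate + tv_rate:
            choices = [x for x in "ACGT" if x != b[i] and x != transitions[b[i]]]
            b[i] = choices[rng.integers(0, 2)]
    return "".join(a), "".join(b)


class TestK2P:
    def test_identical_sequences(self):
        assert mb.k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_p01_q005(self):
        # 100 sites: 10 transitions, 5 transversions
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        d = mb.k2p_distance(a, b)
        assert d == pytest.approx(-0.5 * math.log(0.75 * math.sqrt(0.9)), abs=1e-12)
        assert d == pytest.approx(0.17018, abs=1e-5)

    def test_exceeds_p_distance(self, rng):
        for _ in range(20):
            a, b = mutate_pair(rng)
            if a != b:
                assert mb.k2p_distance(a, b) >= mb.p_distance(a, b)

    def test_saturation_returns_missing(self):
        assert mb.k2p_distance("A" * 10, "G" * 10) is None

    def test_pairwise_deletion_of_gap_and_n(self):
        c = pairwise_counts("ACGTN-", "ACGAAC")
        assert c.sites == 4 and c.Q == pytest.approx(0.25)


class TestTN93:
    def test_identical_sequences(self):
        assert mb.tn93_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_matches_oracle_on_100_random_pairs(self, rng):
        checked = 0
        for _ in range(100):
            a, b = mutate_pair(rng, n=1000)
            expected = tn93_oracle(a, b)
            assert mb.tn93_distance(a, b) == pytest.approx(expected, abs=1e-10)
            checked += 1
        assert checked == 100

    def test_reduces_to_k2p_under_equal_frequencies(self):
        # balanced composition, transitions split evenly between purine and
        # pyrimidine classes, evenly spread transversions
        a = "ACGT" * 250
        b = list(a)
        b[0] = "G"; b[4] = "A"         # A<->G transitions
        b[1] = "T"; b[5] = "C"         # C<->T transitions
        b[2] = "C"; b[7] = "A"         # transversions
        b = "".join(b)
        assert mb.tn93_distance(a, b) == pytest.approx(mb.k2p_distance(a, b), abs=1e-6)


class TestNucleotideDiversity:
    def test_identical_pair(self):
        assert mb.nucleotide_diversity(["AAAA", "AAAA"]) == 0.0

    def test_single_difference(self):
        assert mb.nucleotide_diversity(["AAAA", "AAAT"]) == pytest.approx(0.25)

    def test_average_over_pairs(self):
        # pairs: (s1,s2)=1/4, (s1,s3)=2/4, (s2,s3)=1/4 -> mean = 1/3
        pi = mb.nucleotide_diversity(["AAAA", "AAAT", "AATT"])
        assert pi == pytest.approx((0.25 + 0.5 + 0.25) / 3)

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            mb.nucleotide_diversity(["ACGT"])


class TestNG86:
    def test_identical_sequences(self):
        r = mb.ng86_ka_ks("ATGCTAAAA", "ATGCTAAAA")
        assert r.ka == 0.0 and r.ks == 0.0

    def test_single_synonymous_change(self):
        r = mb.ng86_ka_ks("ATGCTA", "ATGCTG")
        assert r.ka == 0.0
        assert r.ks > 0.0
        # hand-enumerated sites: S(ATG)=1/3, S(CTA)=S(CTG)=4/3
        assert r.s_sites == pytest.approx(1 / 3 + 4 / 3)
        assert r.sd == pytest.approx(1.0) and r.nd == 0.0

    def test_site_conservation_s_plus_n_is_three_per_codon(self):
        for codon in SENSE_CODONS:
            s, n = _codon_sites(codon)
            assert s + n == pytest.approx(3.0)

    @staticmethod
    def _some_path_avoids_stops(c1: str, c2: str) -> bool:
        from mitobias.genetic_code import STOP_CODONS
        diff = [i for i in range(3) if c1[i] != c2[i]]
        for order in itertools.permutations(diff):
            cur, ok = c1, True
            for pos in order:
                cur = cur[:pos] + c2[pos] + cur[pos + 1:]
                if cur in STOP_CODONS:
                    ok = False
                    break
            if ok:
                return True
        return False

    def test_agrees_with_independent_ng86_implementation(self):
        """Exact agreement with Biopython's NG86 on every codon pair whose
        shortest pathways avoid stop codons (the two implementations differ
        by construction on stop-passing pathways: ours excludes them, the
        convention mandated here; Biopython weights them in)."""
        from Bio.Data import CodonTable
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        table2 = CodonTable.unambiguous_dna_by_id[2]
        pad = "ATGGCA" * 5
        checked = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for c1, c2 in itertools.combinations(SENSE_CODONS, 2):
                if not (self._some_path_avoids_stops(c1, c2)
                        and self._all_paths_avoid_stops(c1, c2)):
                    continue
                mine = mb.ng86_ka_ks(pad + c1, pad + c2)
                dn, ds = cal_dn_ds(CodonSeq(pad + c1), CodonSeq(pad + c2),
                                   method="NG86", codon_table=table2)
                assert mine.ka == pytest.approx(dn, abs=1e-12), (c1, c2)
                assert mine.ks == pytest.approx(ds, abs=1e-12), (c1, c2)
                checked += 1
        assert checked > 1000

    @staticmethod
    def _all_paths_avoid_stops(c1: str, c2: str) -> bool:
        from mitobias.genetic_code import STOP_CODONS
        diff = [i for i in range(3) if c1[i] != c2[i]]
        for order in itertools.permutations(diff):
            cur = c1
            for pos in order:
                cur = cur[:pos] + c2[pos] + cur[pos + 1:]
                if cur in STOP_CODONS:
                    return False
        return True

    def test_pathway_counts_conserve_observed_differences(self):
        from mitobias.selection import _codon_pair_subs
        for c1, c2 in itertools.combinations(SENSE_CODONS, 2):
            sd, nd = _codon_pair_subs(c1, c2)
            diffs = sum(1 for x, y in zip(c1, c2) if x != y)
            assert sd + nd == pytest.approx(diffs)

    def test_codons_with_n_skipped(self):
        r = mb.ng86_ka_ks("ATGNNNCTA", "ATGAAACTG")
        assert r.codons == 2

    @staticmethod
    def small_t_calibration_factor(codons: list[str]) -> float:
        """Expected NG86 ratio at omega=1 and small divergence, from first
        principles: the generator cannot mutate into stop codons, while
        NG86 counts stop-adjacent changes as nonsynonymous sites, so the
        neutral expectation is slightly below 1."""
        from mitobias.genetic_code import CODON_TO_AA, STOP_CODONS
        syn_ch = ns_ch = s_sites = 0.0
        for c in codons:
            for pos in range(3):
                for b in "ACGT":
                    if b == c[pos]:
                        continue
                    nb = c[:pos] + b + c[pos + 1:]
                    if nb in STOP_CODONS:
                        continue
                    if CODON_TO_AA[nb] == CODON_TO_AA[c]:
                        syn_ch += 1
                        s_sites += 1 / 3
                    else:
                        ns_ch += 1
        n_sites = 3 * len(codons) - s_sites
        return (ns_ch / n_sites) / (syn_ch / s_sites)

    def test_omega_recovery_brackets_truth(self):
        """Simulated pairs at omega in {0.1, 0.5, 1.0} recover the target
        scaled by the predictable stop-channel factor, within Monte-Carlo
        error plus a small multiple-hit allowance."""
        for omega in (0.1, 0.5, 1.0):
            ratios = []
            factors = []
            for seed in range(8):
                cds = mb.gen_cds(1500, 1e6, seed=1000 + seed)
                out, _ = mb.evolve(cds, 0.2, omega=omega, kappa=1.0,
                                   seed=2000 + seed)
                ratios.append(mb.ng86_ka_ks(cds.coding_nt, out.coding_nt).ratio)
                factors.append(self.small_t_calibration_factor(
                    codons_of(cds.coding_nt)))
            mean = np.mean(ratios)
            expected = omega * np.mean(factors)
            se = np.std(ratios, ddof=1) / math.sqrt(len(ratios))
            assert abs(mean - expected) <= 3 * se + 0.03 * omega
            assert 0.88 < np.mean(factors) < 0.95


class TestGeneSummary:
    def test_identical_species_all_zero(self):
        cds = mb.gen_cds(100, 5.0, seed=5)
        s = mb.gene_summary("g", {"a": cds.coding_nt, "b": cds.coding_nt})
        assert s.mean_k2p == 0.0 and s.pi == 0.0
        assert s.ka == 0.0 and s.ks == 0.0
        assert s.ka_ks is None

    def test_recovers_simulation_omega(self):
        cfg = mb.SimConfig(seed=77, n_species=6, omega=0.3, kappa=1.0,
                           gene_lengths={"ND5": 1000}, branch_length=0.05,
                           codon_bias=1e6)
        data = mb.simulate_dataset(cfg)
        per_species = {sp: genes["ND5"] for sp, genes in data.cds_sets.items()}
        s = mb.gene_summary("ND5", per_species)
        assert s.ka_ks == pytest.approx(0.3, abs=0.07)

    def test_codon_aware_alignment_restores_frame(self):
        a = "ATGAAACCCGGGTTA"
        b = "ATGAAAGGGTTA"      # one codon deleted
        aligned_a, aligned_b = mb.codon_align_pair(a, b)
        assert len(aligned_a) == len(aligned_b)
        assert "-" * 3 in aligned_b
        assert [c for c in codons_of(aligned_b) if c != "---"] == codons_of(b)


def additive_matrix_from_tree(branch: dict[str, float], pairs) -> np.ndarray:
    labels = sorted({x for p in pairs for x in p})
    n = len(labels)
    d = np.zeros((n, n))
    for (i, j), path in pairs.items():
        total = sum(branch[e] for e in path)
        a, b = labels.index(i), labels.index(j)
        d[a, b] = d[b, a] = total
    return d


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        # tree ((A:2,B:3):1,(C:4,D:5)); internal edge 1
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 5, 7, 8],
                      [5, 0, 8, 9],
                      [7, 8, 0, 9],
                      [8, 9, 9, 0]], float)
        tree = mb.nj_tree(mb.DistanceMatrix(labels, d))
        assert "(A:2.000000,B:3.000000)" in tree
        assert tree.endswith(";")

    def test_additive_five_taxon_recovers_topology(self):
        # caterpillar (((A:1,B:1):1,C:2):1,D:3,E:4)
        labels = ["A", "B", "C", "D", "E"]
        d = np.zeros((5, 5))
        paths = {("A", "B"): 2, ("A", "C"): 4, ("A", "D"): 6, ("A", "E"): 7,
                 ("B", "C"): 4, ("B", "D"): 6, ("B", "E"): 7,
                 ("C", "D"): 6, ("C", "E"): 7, ("D", "E"): 7}
        for (x, y), dist in paths.items():
            i, j = labels.index(x), labels.index(y)
            d[i, j] = d[j, i] = dist
        tree = mb.nj_tree(mb.DistanceMatrix(labels, d))
        assert "(A:1.000000,B:1.000000)" in tree

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = mb.nj_tree(mb.DistanceMatrix(["A", "B", "C"], d))
        # b_A = (3+4-5)/2 = 1, b_B = (3+5-4)/2 = 2, b_C = (4+5-3)/2 = 3
        assert tree == "(A:1.000000,B:2.000000,C:3.000000);"

    def test_matches_skbio_topology(self):
        pytest.importorskip("skbio")
        from io import StringIO

        from skbio import DistanceMatrix as SkbioDM, TreeNode
        from skbio.tree import nj

        rng = np.random.default_rng(5)
        n = 7
        coords = rng.uniform(0, 1, size=(n, 4))
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0)
        labels = [f"t{i}" for i in range(n)]
        ours = TreeNode.read(StringIO(mb.nj_tree(mb.DistanceMatrix(labels, d))))
        theirs = nj(SkbioDM(d, labels))
        assert ours.compare_rfd(theirs) == 0.0

    def test_deterministic_under_label_permutation_ties(self):
        d = np.array([[0, 2, 4, 4],
                      [2, 0, 4, 4],
                      [4, 4, 0, 2],
                      [4, 4, 2, 0]], float)
        t1 = mb.nj_tree(mb.DistanceMatrix(["A", "B", "C", "D"], d))
        t2 = mb.nj_tree(mb.DistanceMatrix(["A", "B", "C", "D"], d))
        assert t1 == t2

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            mb.DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]], float))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            mb.nj_tree(mb.DistanceMatrix(["A", "B"], np.zeros((2, 2))))
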